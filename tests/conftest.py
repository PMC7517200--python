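"""Shared, session-scoped simulation fixtures.

The heavy two-network batch simulations are run once per session and shared
by the behavioural and acceptance tests.
"""

import pytest

from pottsbuffer.config import load_profile
from pottsbuffer.production import run_ablation, run_batch, run_sob_batch

SEED = 1


@pytest.fixture(scope="session")
def full_model_result():
    """Complete model, 3 batches x 50 cued words."""
    return run_batch(load_profile("pob_step4"), seed=SEED, n_batches=3)


@pytest.fixture(scope="session")
def step2_result():
    """Cascade + fast inhibition, constant threshold, single adaptation; 2x50."""
    return run_batch(load_profile("pob_step2"), seed=SEED, n_batches=2)


@pytest.fixture(scope="session")
def no_fast_inhibition_result():
    """Full model with gamma_A = 0; 2x50 trials."""
    return run_ablation(load_profile("pob_step4"), "no_fast_local_inhibition",
                        seed=SEED, n_batches=2)


@pytest.fixture(scope="session")
def sob_result():
    """Mixed sign/word buffer, every stored item cued once (25+25)."""
    return run_sob_batch(load_profile("sob_default"), seed=SEED)
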