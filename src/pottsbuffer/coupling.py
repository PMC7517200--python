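"""Heteroassociative coupling from the lexicon network to the buffer network.

Each buffer unit receives ``C_m_het`` inputs from lexicon units.  The
instruction matrix ``G`` (rows: lexicon patterns, columns: buffer patterns)
defines which buffer components a lexicon item drives and with what graded
strength; the per-item coupling scale ``lambda`` (0.2 for words, 1.4 for
signs) is folded into the stored tensor

    J_ij^kl,het = c_ij lam_mu / (C_het a (1 - a/S))
                  * sum_{mu,nu} G_mu,nu (d(xi_i^nu,buf, k) - a/S)(d(xi_j^mu,lex, l) - a/S).

By default the hetero field is a sigma-sigma interaction (it reads the
lexicon's activations, favouring synchronous dynamics of the two networks); a
theta-sigma variant that reads the lexicon's adaptive thresholds instead is
kept behind ``interaction_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import Connectivity, _expand_mask, pattern_kernel, NetworkParams
from .patterns import Lexicon, PatternSet

__all__ = ["HeteroWeights", "store_heteroassociative", "compute_hetero_field"]


@dataclass
class HeteroWeights:
    W: np.ndarray  # (N_buffer*S, N_lexicon*S) float32
    N_post: int
    N_pre: int
    S: int
    interaction_mode: Literal["sigma_sigma", "theta_sigma"] = "sigma_sigma"


def store_heteroassociative(
    lexicon_patterns: PatternSet,
    buffer_patterns: PatternSet,
    lexicon: Lexicon,
    conn_het: Connectivity,
    params: NetworkParams,
    interaction_mode: str = "sigma_sigma",
) -> HeteroWeights:
    """Build the lexicon->buffer tensor with lambda folded in per item kind."""
    G = lexicon.G
    if np.any(G < 0) or np.any(G > 1):
        raise ValueError("G entries must lie in [0, 1]")
    S, a = params.S, params.a
    C_het = conn_het.C_m
    # scale each lexicon row by the coupling strength of the item stored there
    row_scale = np.zeros(G.shape[0])
    for it in lexicon.items:
        row_scale[it.lexicon_pattern] = lexicon.lambda_by_kind[it.item_kind]
    Gs = G * row_scale[:, None]

    V_lex = pattern_kernel(lexicon_patterns, S, a)   # (p_lex, N_lex*S)
    V_buf = pattern_kernel(buffer_patterns, S, a)    # (p_buf, N_buf*S)
    norm = np.float32(1.0 / (C_het * a * (1.0 - a / S)))
    # J[b_flat, l_flat] = sum_nu V_buf[nu, b] * sum_mu Gs[mu, nu] V_lex[mu, l]
    W = V_buf.T @ (Gs.astype(np.float32).T @ V_lex) * norm
    _expand_mask(conn_het.c, S, W)
    return HeteroWeights(
        W=W,
        N_post=buffer_patterns.N,
        N_pre=lexicon_patterns.N,
        S=S,
        interaction_mode=interaction_mode,
    )


def compute_hetero_field(het: HeteroWeights, source_state) -> np.ndarray:
    """Field increment on the buffer from the lexicon's current state.

    ``source_state`` may be a NetworkState or a raw sigma array; in
    theta_sigma mode the lexicon's summed adaptive thresholds are read
    instead of its activations.
    """
    if het.interaction_mode == "sigma_sigma":
        sigma = getattr(source_state, "sigma", source_state)
        src = np.asarray(sigma)[..., 1:]
    else:
        src = np.asarray(source_state.theta_fast + source_state.theta_slow)
    lead = src.shape[:-2]
    flat = src.reshape(*lead, het.N_pre * het.S).astype(np.float32)
    h = (flat @ het.W.T).astype(np.float64)
    return h.reshape(*lead, het.N_post, het.S)
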