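"""Experiment configuration: named parameter profiles and seed fan-out.

Profiles are flat YAML files shipped with the package, one per published
parameter set (``pol_default``, ``pob_step1`` .. ``pob_step4``, the three
ablations, ``sob_default``, ``fig5_latching``).  Loading is strict: an unknown
key anywhere is a hard error, so typos cannot silently fall back to defaults.

A single master seed fans out deterministically to one RNG stream per concern
(pattern generation, connectivity, lexicon design, timescale sampling, ...),
keyed by name and batch index, so that e.g. changing the number of batches
never perturbs the patterns drawn for the first one.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .core import NetworkParams

__all__ = ["ExperimentConfig", "load_profile", "derive_rng", "derive_seed", "PROFILE_NAMES"]

PROFILE_NAMES = (
    "pol_default",
    "pob_step1",
    "pob_step2",
    "pob_step3",
    "pob_step4",
    "pob_no_slow_adaptation",
    "pob_no_dynamic_threshold",
    "pob_no_fast_inhibition",
    "sob_default",
    "fig5_latching",
)

_NETWORK_KEYS = {
    "N", "S", "a", "C_m", "p", "beta", "U", "w", "tau1",
    "tau2_fast", "tau2_slow", "gamma2_fast", "tau_A", "tau_B", "gamma_A",
    "tau_U", "a_U", "dt", "dynamic_threshold",
}
_COUPLING_KEYS = {"C_m_het", "lambda_word", "lambda_sign", "interaction_mode"}
_LEXICON_KEYS = {
    "n_words", "n_signs", "n_syllables", "n_gesture_elements", "n_clusters",
    "a_word", "a_sign", "kind",
}
_PROTOCOL_KEYS = {
    "cue_strength", "cue_duration", "T_max", "n_batches",
    "theta_on", "theta_off", "d_min", "early_stop", "init_inhibition",
}
_TOP_KEYS = {"description", "lexicon_network", "buffer_network", "coupling", "lexicon", "protocol"}


@dataclass
class ExperimentConfig:
    name: str
    buffer_network: dict
    lexicon_network: dict | None = None
    coupling: dict = field(default_factory=dict)
    lexicon: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    description: str = ""

    def buffer_params(self, **overrides) -> NetworkParams:
        return _to_params(self.buffer_network, **overrides)

    def lexicon_params(self, **overrides) -> NetworkParams:
        if self.lexicon_network is None:
            raise ValueError(f"profile {self.name!r} has no lexicon network")
        return _to_params(self.lexicon_network, **overrides)

    def with_buffer(self, **overrides) -> "ExperimentConfig":
        buf = dict(self.buffer_network)
        buf.update(overrides)
        return replace(self, buffer_network=buf)


def _to_params(section: dict, **overrides) -> NetworkParams:
    d = {k: v for k, v in section.items() if k != "p"}
    d.update(overrides)
    return NetworkParams(**d)


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise KeyError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_profile(name_or_path: str | Path) -> ExperimentConfig:
    """Load a shipped profile by name, or any YAML file by path."""
    path = Path(str(name_or_path))
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
        name = path.stem
    else:
        name = str(name_or_path)
        ref = resources.files("pottsbuffer").joinpath(f"profiles/{name}.yaml")
        if not ref.is_file():
            raise FileNotFoundError(
                f"unknown profile {name!r}; available: {', '.join(PROFILE_NAMES)}"
            )
        text = ref.read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"profile {name!r} is not a mapping")
    _check_keys(raw, _TOP_KEYS, f"profile {name!r}")
    for key, allowed in (
        ("lexicon_network", _NETWORK_KEYS),
        ("buffer_network", _NETWORK_KEYS),
        ("coupling", _COUPLING_KEYS),
        ("lexicon", _LEXICON_KEYS),
        ("protocol", _PROTOCOL_KEYS),
    ):
        if key in raw and raw[key] is not None:
            _check_keys(raw[key], allowed, f"{name}:{key}")
    return ExperimentConfig(
        name=name,
        buffer_network=raw["buffer_network"],
        lexicon_network=raw.get("lexicon_network"),
        coupling=raw.get("coupling") or {},
        lexicon=raw.get("lexicon") or {},
        protocol=raw.get("protocol") or {},
        description=raw.get("description", ""),
    )


def derive_seed(master_seed: int, *keys) -> int:
    """Stable sub-seed (< 2^31) for a named concern."""
    h = zlib.crc32(str(int(master_seed)).encode())
    for k in keys:
        h = zlib.crc32(str(k).encode(), h)
    return h & 0x7FFFFFFF


def derive_rng(master_seed: int, *keys) -> np.random.Generator:
    """One independent RNG stream per (master seed, concern name, index...)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), derive_seed(master_seed, *keys)])
    )
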