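"""Trajectory measurement, utterance extraction, and the error taxonomy.

The retrieval order parameter (overlap) of a stored pattern is the standard
mean-subtracted Potts correlation

    m^mu = 1 / (n_mu (1 - a/S)) * sum_i sum_{k>=1} (d(xi_i^mu, k) - a/S) sigma_i^k

with ``n_mu`` the pattern's active-unit count (= a*N for distributed
patterns), so that m = 1 at perfect retrieval for any pattern sparsity.

A production episode is read off the overlap traces by hysteresis: a pattern
"opens" an utterance when its overlap crosses ``theta_on`` while being the
largest among all stored buffer patterns, and closes when it falls below
``theta_off`` or is overtaken; episodes shorter than ``d_min`` steps are
discarded.  Each trial is then scored against its target triple into exactly
one of five categories: correct, wrong order (transposition), repetition
(perseveration), shorter sequence (omission), wrong syllable (insertion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .patterns import PatternSet

__all__ = [
    "Utterance",
    "ErrorLabel",
    "CATEGORIES",
    "compute_overlap",
    "overlap_matrix",
    "normalized_activity",
    "shared_active_fraction",
    "extract_utterances",
    "classify_error",
    "classify_latching_regime",
    "aggregate_labels",
]

CATEGORIES = ("correct", "wrong_order", "repetition", "shorter_sequence", "wrong_syllable")


@dataclass
class Utterance:
    pattern_id: int
    onset: int
    offset: int
    peak_overlap: float


@dataclass
class ErrorLabel:
    category: str
    first_error_position: int | None  # 1..3 or None for correct trials


def _kernel_and_norm(patterns: PatternSet, S: int, a: float):
    from .core import pattern_kernel

    V = pattern_kernel(patterns, S, a, dtype=np.float64)  # (p, N*S)
    n_active = np.maximum(patterns.active_counts(), 1)
    norm = n_active.astype(np.float64) * (1.0 - a / S)
    return V, norm


def compute_overlap(sigma: np.ndarray, patterns: PatternSet, mu: int,
                    S: int | None = None, a: float | None = None):
    """Overlap of the state(s) with stored pattern ``mu``; batched over leading axes."""
    S = patterns.S if S is None else S
    a = patterns.a if a is None else a
    V, norm = _kernel_and_norm(patterns, S, a)
    act = np.asarray(sigma)[..., 1:]
    flat = act.reshape(*act.shape[:-2], -1)
    return (flat @ V[mu]) / norm[mu]


def overlap_matrix(sigma: np.ndarray, patterns: PatternSet,
                   S: int | None = None, a: float | None = None) -> np.ndarray:
    """Overlaps with every stored pattern: returns (..., p)."""
    S = patterns.S if S is None else S
    a = patterns.a if a is None else a
    V, norm = _kernel_and_norm(patterns, S, a)
    act = np.asarray(sigma)[..., 1:]
    flat = act.reshape(*act.shape[:-2], -1).astype(np.float32)
    return (flat @ V.T) / norm


def normalized_activity(sigma: np.ndarray, patterns: PatternSet, mu: int):
    """State-blind mean activation of the units a pattern recruits.

    (1/n_mu) sum_i (1 - sigma_i^0) over units active in pattern mu; equals 1
    when all recruited units are fully active in any states, ~0 in the null
    state.
    """
    support = patterns.states[mu] > 0
    n = max(int(support.sum()), 1)
    active = 1.0 - np.asarray(sigma)[..., 0]
    return active[..., support].sum(axis=-1) / n


def shared_active_fraction(pattern_a: np.ndarray, pattern_b: np.ndarray) -> float:
    """Fraction of all units active in both patterns."""
    a = np.asarray(pattern_a) > 0
    b = np.asarray(pattern_b) > 0
    return float((a & b).sum() / a.size)


def extract_utterances(
    overlaps: np.ndarray,
    theta_on: float = 0.5,
    theta_off: float = 0.35,
    d_min: int = 10,
) -> list[Utterance]:
    """Read the utterance sequence off a (T, p) overlap trajectory.

    Hysteresis (theta_on > theta_off) prevents flicker double-counts; distinct
    episodes of the same pattern are kept separate so repetitions remain
    observable.
    """
    if theta_on <= theta_off:
        raise ValueError("theta_on must exceed theta_off")
    m = np.asarray(overlaps)
    T = m.shape[0]
    argmax = np.argmax(m, axis=1)
    mx = m[np.arange(T), argmax]

    out: list[Utterance] = []
    open_id: int | None = None
    onset = 0
    peak = 0.0

    def close(t_end: int) -> None:
        nonlocal open_id
        if open_id is not None and t_end - onset >= d_min and peak >= theta_on:
            out.append(Utterance(int(open_id), int(onset), int(t_end), float(peak)))
        open_id = None

    for t in range(T):
        if open_id is None:
            if mx[t] >= theta_on:
                open_id, onset, peak = int(argmax[t]), t, float(mx[t])
        else:
            cur = m[t, open_id]
            overtaken = argmax[t] != open_id and mx[t] >= theta_on
            if cur < theta_off or overtaken:
                close(t)
                if overtaken:
                    open_id, onset, peak = int(argmax[t]), t, float(mx[t])
            else:
                peak = max(peak, float(cur))
    close(T)
    return out


def classify_error(
    sequence: Sequence[int] | Sequence[Utterance], target: Sequence[int]
) -> ErrorLabel:
    """Score one trial's utterance sequence against its target triple.

    Categories are mutually exclusive, assigned in priority order: intrusion
    of a non-target pattern (wrong_syllable) > repeated target (repetition) >
    fewer than three utterances (shorter_sequence) > full set out of order
    (wrong_order) > correct.  ``first_error_position`` is the serial position
    (1-based) of the first utterance deviating from the target order; for
    truncated sequences it is length+1 capped at 3.
    """
    target = tuple(int(t) for t in target)
    if len(target) != 3:
        raise ValueError("target must have exactly 3 components")
    ids = [u.pattern_id if isinstance(u, Utterance) else int(u) for u in sequence]

    def first_deviation() -> int:
        for pos, (got, want) in enumerate(zip(ids, target), start=1):
            if got != want:
                return pos
        return min(len(ids) + 1, 3)

    if any(u not in target for u in ids):
        pos = next(p for p, u in enumerate(ids, start=1) if u not in target)
        return ErrorLabel("wrong_syllable", min(pos, 3))
    if any(ids.count(t) > 1 for t in target):
        return ErrorLabel("repetition", first_deviation())
    if len(ids) < 3:
        return ErrorLabel("shorter_sequence", min(len(ids) + 1, 3))
    if tuple(ids[:3]) != target:
        return ErrorLabel("wrong_order", first_deviation())
    return ErrorLabel("correct", None)


def classify_latching_regime(
    utterance_lists: Sequence[list[Utterance]],
    horizon: int,
    well_retrieved: float = 0.7,
    max_mean_retrieved: float = 1.5,
    persist_fraction: float = 0.8,
    persist_margin: int = 50,
) -> str:
    """Label a batch of free-latching trajectories.

    ``no_latching`` if on average at most 1.5 distinct patterns are well
    retrieved per trajectory; ``infinite`` if in >= 80% of runs the sequence
    is still going within ``persist_margin`` steps of the horizon; otherwise
    ``finite``.
    """
    if len(utterance_lists) < 10:
        raise ValueError("need at least 10 trajectories")
    distinct = [
        len({u.pattern_id for u in utts if u.peak_overlap >= well_retrieved})
        for utts in utterance_lists
    ]
    if np.mean(distinct) <= max_mean_retrieved:
        return "no_latching"
    persists = [
        bool(utts) and utts[-1].offset >= horizon - persist_margin
        for utts in utterance_lists
    ]
    if np.mean(persists) >= persist_fraction:
        return "infinite"
    return "finite"


def aggregate_labels(labels: Sequence[ErrorLabel]):
    """Per-category percentages with the standard error of the mean.

    Returns a dict category -> (percent, sem_percent) plus a first-error
    position breakdown, computed over all trials.
    """
    n = len(labels)
    if n == 0:
        raise ValueError("no trials to aggregate")
    table = {}
    for cat in CATEGORIES:
        x = np.array([1.0 if lab.category == cat else 0.0 for lab in labels])
        pct = 100.0 * x.mean()
        sem = 100.0 * x.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        table[cat] = (pct, sem)
    positions = {
        pos: sum(1 for lab in labels if lab.first_error_position == pos)
        for pos in (1, 2, 3)
    }
    return {"n": n, "categories": table, "first_error_positions": positions}
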