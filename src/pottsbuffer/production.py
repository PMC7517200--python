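"""Production experiments: cue a lexicon item, co-simulate lexicon and buffer.

A trial cues one stored item in the lexicon network with a brief strong
external field; the item's attractor then persists autonomously and feeds a
constant graded input to the buffer through the heteroassociative couplings.
The buffer serializes (words) or co-activates (signs) the item's three
component patterns via latching, until adaptation extinguishes the lexicon
attractor and both networks fall back toward the null state.

All trials of a batch share one realization of patterns, connectivity and
weights, so they are integrated as a single vectorized sweep (the dominant
cost is one dense matrix product per network per step).  Scoring follows the
first three extracted utterances; production beyond the third utterance is
tracked as a separate diagnostic, not an error category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import analysis
from .analysis import ErrorLabel, Utterance, aggregate_labels, classify_error, extract_utterances
from .config import ExperimentConfig, derive_rng
from .core import (
    NetworkParams,
    PottsNetwork,
    build_connectivity,
    store_autoassociative,
    wm_kick_mask,
)
from .coupling import compute_hetero_field, store_heteroassociative
from .patterns import (
    PatternSet,
    build_word_lexicon,
    compose_mixed_lexicon,
    generate_cluster_patterns,
    generate_random_patterns,
)

__all__ = [
    "TrialRecord",
    "BatchResult",
    "ProductionExperiment",
    "cue_field",
    "run_production",
    "run_batch",
    "run_ablation",
    "run_sob_batch",
    "run_sob_sequence",
    "build_sob_adaptation_profile",
    "run_free_latching",
]

ABLATION_FLAGS = {
    "no_slow_adaptation": dict(gamma2_fast=1.0),
    "no_dynamic_threshold": dict(dynamic_threshold=False, U=0.216),
    "no_fast_local_inhibition": dict(gamma_A=0.0),
}


@dataclass
class TrialRecord:
    item_index: int
    item_kind: str
    target: tuple[int, int, int]
    utterances: list[Utterance]
    label: ErrorLabel
    n_utterances: int
    sign_success: bool | None = None
    min_coactivation_activity: float | None = None
    min_coactivation_shared: float | None = None
    diverged: bool = False
    trajectory: dict | None = None  # only kept when requested


@dataclass
class BatchResult:
    records: list[TrialRecord]
    aggregate: dict

    @property
    def correct_fraction(self) -> float:
        n = len(self.records)
        return sum(1 for r in self.records if r.label.category == "correct") / n


def cue_field(patterns: PatternSet, pattern_id: int, strength: float, S: int) -> np.ndarray:
    """External field aligned with one stored pattern: +strength on matching states."""
    xi = patterns.states[pattern_id]
    ks = np.arange(1, S + 1)
    return strength * (xi[:, None] == ks[None, :]).astype(np.float64)


def build_sob_adaptation_profile(
    gestures: PatternSet,
    syllables: PatternSet,
    N: int,
    S: int,
    b_fast: float = 0.09,
    b_slow: float = 0.03,
    rng=None,
    tau_floor_rate: float = 1e-4,
):
    """Per-(unit,state) adaptation mix and random timescales for the sign buffer.

    gamma2_fast(i,k) is 0 where only gesture elements recruit the pair (signs
    need no fast adaptation: they are sustained, not latched through),
    0.5*n_syll/(n_sign+n_syll) where both classes recruit it, and 0.5
    elsewhere.  The inverse timescales are drawn from normal distributions
    centred on the homogeneous values (1/11.1 and 1/33.3) with SD b_slow/4,
    truncated away from zero.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ks = np.arange(1, S + 1)
    n_sign = (gestures.states[:, :, None] == ks[None, None, :]).sum(axis=0)  # (N, S)
    n_syll = (syllables.states[:, :, None] == ks[None, None, :]).sum(axis=0)

    gamma = np.full((N, S), 0.5)
    both = (n_sign > 0) & (n_syll > 0)
    gamma[both] = 0.5 * n_syll[both] / (n_sign[both] + n_syll[both])
    gamma[(n_sign > 0) & (n_syll == 0)] = 0.0

    inv_fast = np.maximum(rng.normal(b_fast, b_slow / 4, size=(N, S)), tau_floor_rate)
    inv_slow = np.maximum(rng.normal(b_slow, b_slow / 4, size=(N, S)), tau_floor_rate)
    return gamma, 1.0 / inv_fast, 1.0 / inv_slow


class ProductionExperiment:
    """One realization (patterns, lexicon, weights) of a two-network experiment."""

    def __init__(self, config: ExperimentConfig, seed: int, batch_index: int = 0):
        self.config = config
        self.seed = int(seed)
        self.batch_index = int(batch_index)
        lex_cfg = config.lexicon
        self.kind = lex_cfg.get("kind", "word")

        pol = config.lexicon_params()
        self.pol_params = pol
        p_pol = config.lexicon_network["p"]
        self.pol_patterns = generate_random_patterns(
            pol.N, pol.S, pol.a, p_pol,
            derive_rng(seed, "patterns_pol", batch_index),
        )

        buf = config.buffer_params()
        p_buf = config.buffer_network["p"]
        cluster_ids = None
        cluster_sizes = None
        rng_buf = derive_rng(seed, "patterns_pob", batch_index)
        rng_lex = derive_rng(seed, "lexicon", batch_index)

        if self.kind == "mixed":
            n_clusters = lex_cfg["n_clusters"]
            gestures = generate_cluster_patterns(
                buf.N, n_clusters, lex_cfg["a_sign"], lex_cfg["n_gesture_elements"],
                S=buf.S, seed=rng_buf,
            )
            syllables = generate_random_patterns(
                buf.N, buf.S, lex_cfg["a_word"], lex_cfg["n_syllables"], rng_buf
            )
            distractors = generate_random_patterns(
                buf.N, buf.S, lex_cfg["a_word"], p_buf - gestures.p - syllables.p, rng_buf
            )
            states = np.vstack([gestures.states, syllables.states, distractors.states])
            self.buf_patterns = PatternSet(
                states=states, S=buf.S, a=buf.a, cluster_bounds=gestures.cluster_bounds
            )
            self.gesture_ids = list(range(gestures.p))
            self.syllable_ids = list(range(gestures.p, gestures.p + syllables.p))
            self.lexicon = compose_mixed_lexicon(
                gestures, gestures.p, syllables.p, self.pol_patterns, p_buf,
                lex_cfg["n_signs"], lex_cfg["n_words"], rng_lex,
                lambda_word=config.coupling.get("lambda_word", 0.2),
                lambda_sign=config.coupling.get("lambda_sign", 1.4),
            )
            gamma, tau_f, tau_s = build_sob_adaptation_profile(
                gestures, syllables, buf.N, buf.S,
                rng=derive_rng(seed, "timescales", batch_index),
            )
            buf = config.buffer_params(
                gamma2_fast=gamma, tau2_fast=tau_f, tau2_slow=tau_s
            )
            size = buf.N // n_clusters
            cluster_ids = np.repeat(np.arange(n_clusters), size)
            cluster_sizes = np.full(n_clusters, size)
        else:
            self.buf_patterns = generate_random_patterns(
                buf.N, buf.S, buf.a, p_buf, rng_buf
            )
            self.gesture_ids = []
            self.syllable_ids = None
            self.lexicon = build_word_lexicon(
                lex_cfg.get("n_words", 50), self.pol_patterns, self.buf_patterns, rng_lex
            )
            self.lexicon.lambda_by_kind = {
                "word": config.coupling.get("lambda_word", 0.2),
                "sign": config.coupling.get("lambda_sign", 1.4),
            }
        self.buf_params = buf

        conn_pol = build_connectivity(
            pol.N, pol.N, pol.C_m, seed=derive_rng(seed, "connectivity_pol", batch_index)
        )
        conn_buf = build_connectivity(
            buf.N, buf.N, buf.C_m, seed=derive_rng(seed, "connectivity_pob", batch_index)
        )
        conn_het = build_connectivity(
            buf.N, pol.N, config.coupling.get("C_m_het", 150), self_allowed=True,
            seed=derive_rng(seed, "connectivity_het", batch_index),
        )
        self.pol = PottsNetwork(pol, store_autoassociative(self.pol_patterns, conn_pol, pol))
        self.buf = PottsNetwork(
            buf,
            store_autoassociative(self.buf_patterns, conn_buf, buf),
            cluster_ids=cluster_ids,
            cluster_sizes=cluster_sizes,
        )
        self.het = store_heteroassociative(
            self.pol_patterns, self.buf_patterns, self.lexicon, conn_het, buf,
            interaction_mode=config.coupling.get("interaction_mode", "sigma_sigma"),
        )

    # ------------------------------------------------------------------
    def simulate(
        self,
        cue_events: Sequence[tuple[int, int, int]],
        n_trials: int,
        T_max: int | None = None,
        record_targets: np.ndarray | None = None,
        keep_overlaps: bool = False,
    ):
        """Integrate ``n_trials`` coupled trials.

        ``cue_events`` is a list of (trial, item_index, t_on); each event adds
        the item's lexicon cue field for ``cue_duration`` steps from t_on.
        Returns a dict of recorded traces.
        """
        proto = self.config.protocol
        dt = self.buf_params.dt
        # protocol durations are expressed in time units; convert to steps
        T_max = int(round((proto.get("T_max", 500) if T_max is None else T_max) / dt))
        cue_dur = int(round(float(proto.get("cue_duration", 100)) / dt))
        strength = float(proto.get("cue_strength", 1.0))
        early = bool(proto.get("early_stop", True))

        pol_state = self.pol.null_state((n_trials,))
        buf_state = self.buf.null_state(
            (n_trials,), theta_B0=float(proto.get("init_inhibition", 0.0))
        )

        events = []
        last_cue_end = 0
        for trial, item, t_on in cue_events:
            f = cue_field(
                self.pol_patterns, self.lexicon.items[item].lexicon_pattern, strength,
                self.pol_params.S,
            )
            t_on = int(round(t_on / dt))
            events.append((int(trial), t_on, t_on + cue_dur, f))
            last_cue_end = max(last_cue_end, t_on + cue_dur)

        # per-trial lexicon pattern (for the word-active trace)
        lex_pat = np.zeros(n_trials, dtype=np.int64)
        for trial, item, _ in cue_events:
            lex_pat[trial] = self.lexicon.items[item].lexicon_pattern

        p_buf = self.buf_patterns.p
        m_buf = np.zeros((T_max, n_trials, p_buf), dtype=np.float32)
        m_pol_item = np.zeros((T_max, n_trials), dtype=np.float32)

        track_act = record_targets is not None
        if track_act:
            # support masks of each trial's three target components, (B, 3, N)
            supp = (self.buf_patterns.states[record_targets] > 0).astype(np.float64)
            supp_n = supp.sum(axis=-1)
            pairs = [(0, 1), (0, 2), (1, 2)]
            shared = np.stack([supp[:, i] * supp[:, j] for i, j in pairs], axis=1)
            shared_n = np.maximum(shared.sum(axis=-1), 1.0)
            act_trace = np.zeros((T_max, n_trials, 3), dtype=np.float32)
            shared_trace = np.zeros((T_max, n_trials, 3), dtype=np.float32)

        from .analysis import overlap_matrix

        t_end = T_max
        for t in range(T_max):
            h_pol = self.pol.fields(pol_state.sigma)
            for trial, t_on, t_off, f in events:
                if t_on <= t < t_off:
                    h_pol[trial] += f
            h_buf = self.buf.fields(buf_state.sigma)
            h_buf += compute_hetero_field(self.het, pol_state)
            self.pol.step(pol_state, h_pol)
            self.buf.step(buf_state, h_buf)

            m_buf[t] = overlap_matrix(buf_state.sigma, self.buf_patterns)
            m_pol = overlap_matrix(pol_state.sigma, self.pol_patterns)
            m_pol_item[t] = m_pol[np.arange(n_trials), lex_pat]
            if track_act:
                active = 1.0 - buf_state.sigma[..., 0]  # (B, N)
                act_trace[t] = np.einsum("bn,bcn->bc", active, supp) / supp_n
                shared_trace[t] = np.einsum("bn,bcn->bc", active, shared) / shared_n
            if early and t > last_cue_end + int(100 / dt) and t % 50 == 0:
                if m_buf[t].max() < 0.3 and m_pol_item[t].max() < 0.3:
                    t_end = t + 1
                    break

        out = {
            "m_buf": m_buf[:t_end],
            "m_pol_item": m_pol_item[:t_end],
            "t_end": t_end,
            "final_pol_state": pol_state,
            "final_buf_state": buf_state,
        }
        if track_act:
            out["activity"] = act_trace[:t_end]
            out["shared_activity"] = shared_trace[:t_end]
        if keep_overlaps:
            out["m_pol"] = m_pol
        return out

    # ------------------------------------------------------------------
    def run_items(self, item_indices: Sequence[int], keep_trajectories: bool = False,
                  T_max: int | None = None) -> list[TrialRecord]:
        """Cue each listed item once (one trial per item), score each trial."""
        proto = self.config.protocol
        items = [self.lexicon.items[i] for i in item_indices]
        targets = np.array([it.component_ids for it in items], dtype=np.int64)
        cue_events = [(b, idx, 0) for b, idx in enumerate(item_indices)]
        res = self.simulate(
            cue_events, n_trials=len(items), T_max=T_max, record_targets=targets
        )
        records = []
        for b, (idx, it) in enumerate(zip(item_indices, items)):
            records.append(
                self._score_trial(
                    b, idx, it, res,
                    theta_on=float(proto.get("theta_on", 0.5)),
                    theta_off=float(proto.get("theta_off", 0.35)),
                    d_min=int(round(float(proto.get("d_min", 10)) / self.buf_params.dt)),
                    keep_trajectory=keep_trajectories,
                )
            )
        return records

    def _score_trial(self, b, item_index, item, res, theta_on, theta_off, d_min,
                     keep_trajectory=False) -> TrialRecord:
        m = res["m_buf"][:, b, :]
        utts = extract_utterances(m, theta_on, theta_off, d_min)
        target = tuple(item.component_ids)

        sign_success = None
        if item.item_kind == "sign":
            sign_success = self._sign_success(
                b, item, res, d_min=int(round(50 / self.buf_params.dt))
            )
            intrusions = [
                u for u in utts
                if self.syllable_ids is not None and u.pattern_id not in target
            ]
            label = ErrorLabel(
                "correct" if sign_success and not intrusions else
                ("wrong_syllable" if intrusions else "shorter_sequence"),
                None if sign_success and not intrusions else 1,
            )
        else:
            label = classify_error(utts[:3], target)

        min_act = min_shared = None
        if "activity" in res:
            min_act, min_shared = self._coactivation(b, res)

        traj = None
        if keep_trajectory:
            traj = {
                "m_buf": m.copy(),
                "m_pol_item": res["m_pol_item"][:, b].copy(),
            }
            if "activity" in res:
                traj["activity"] = res["activity"][:, b].copy()
        return TrialRecord(
            item_index=item_index,
            item_kind=item.item_kind,
            target=target,
            utterances=utts,
            label=label,
            n_utterances=len(utts),
            sign_success=sign_success,
            min_coactivation_activity=min_act,
            min_coactivation_shared=min_shared,
            trajectory=traj,
        )

    def _sign_success(self, b, item, res, d_min=50) -> bool:
        """All three elements simultaneously active (>0.5, argmax in cluster)."""
        m = res["m_buf"][:, b, :]
        act = res["activity"][:, b, :]  # (T, 3) element-support activities
        ok = np.all(act > 0.5, axis=1)
        # each element must also dominate its cluster's other elements
        per_cluster = len(self.gesture_ids) // 3
        for c, comp in enumerate(item.component_ids):
            members = self.gesture_ids[c * per_cluster:(c + 1) * per_cluster]
            ok &= m[:, members].argmax(axis=1) == members.index(comp)
        # require a sustained stretch of simultaneity
        run, best = 0, 0
        for flag in ok:
            run = run + 1 if flag else 0
            best = max(best, run)
        return best >= d_min

    def _coactivation(self, b, res):
        """Mean (over the word-active window) of the minimum co-activation.

        Two readings: min across the three target syllables of the state-blind
        normalized activity, and min across syllable pairs of the activation
        of their shared support.  The window is where the cued word's lexicon
        overlap exceeds 0.5, skipping a 30-step onset transient.
        """
        word_on = res["m_pol_item"][:, b] > 0.5
        idx = np.flatnonzero(word_on)
        if idx.size <= 30:
            return None, None
        window = idx[30:]
        min_act = res["activity"][window, b, :].min(axis=1)
        min_shared = res["shared_activity"][window, b, :].min(axis=1)
        return float(min_act.mean()), float(min_shared.mean())


# ----------------------------------------------------------------------
def run_production(config: ExperimentConfig, item_index: int, seed: int,
                   keep_trajectories: bool = True) -> TrialRecord:
    """Cue a single lexicon item and return its full production record."""
    exp = ProductionExperiment(config, seed)
    return exp.run_items([item_index], keep_trajectories=keep_trajectories)[0]


def run_batch(config: ExperimentConfig, seed: int, n_batches: int | None = None,
              items_per_batch: int | None = None) -> BatchResult:
    """The batch protocol: fresh patterns per batch, every item cued once."""
    n_batches = int(config.protocol.get("n_batches", 3)) if n_batches is None else n_batches
    records: list[TrialRecord] = []
    for batch in range(n_batches):
        exp = ProductionExperiment(config, seed, batch_index=batch)
        idx = list(range(len(exp.lexicon)))
        if items_per_batch is not None:
            idx = idx[:items_per_batch]
        records.extend(exp.run_items(idx))
    labels = [r.label for r in records]
    return BatchResult(records=records, aggregate=aggregate_labels(labels))


def run_ablation(config: ExperimentConfig, flag: str, seed: int,
                 n_batches: int | None = None,
                 items_per_batch: int | None = None) -> BatchResult:
    """Re-run the batch protocol with one model component removed."""
    if flag not in ABLATION_FLAGS:
        raise ValueError(f"unknown ablation flag {flag!r}; choose from {sorted(ABLATION_FLAGS)}")
    return run_batch(config.with_buffer(**ABLATION_FLAGS[flag]), seed,
                     n_batches=n_batches, items_per_batch=items_per_batch)


def run_sob_batch(config: ExperimentConfig, seed: int,
                  items: Sequence[int] | None = None) -> BatchResult:
    """Cue every stored sign and word once in the mixed buffer."""
    exp = ProductionExperiment(config, seed)
    idx = list(items) if items is not None else list(range(len(exp.lexicon)))
    records = exp.run_items(idx)
    return BatchResult(records=records, aggregate=aggregate_labels([r.label for r in records]))


def run_sob_sequence(config: ExperimentConfig, items: Sequence[int],
                     inter_cue_interval: int, seed: int, T_max: int | None = None):
    """Cue several items one after another within a single trial.

    Returns one TrialRecord per cued item, all scored on the same trajectory
    restricted to the window from its cue onset to the next item's onset (or
    the end of the run for the last item).
    """
    if not items:
        return []
    exp = ProductionExperiment(config, seed)
    cue_events = [(0, item, k * inter_cue_interval) for k, item in enumerate(items)]
    if T_max is None:
        T_max = int(config.protocol.get("T_max", 1500))
    res = exp.simulate(cue_events, n_trials=1, T_max=T_max)
    proto = exp.config.protocol
    records = []
    dt = exp.buf_params.dt
    for k, item_index in enumerate(items):
        it = exp.lexicon.items[item_index]
        t0 = int(round(k * inter_cue_interval / dt))
        t1 = int(round((k + 1) * inter_cue_interval / dt)) if k + 1 < len(items) else res["t_end"]
        utts = extract_utterances(
            res["m_buf"][t0:t1, 0, :],
            float(proto.get("theta_on", 0.5)),
            float(proto.get("theta_off", 0.35)),
            int(round(float(proto.get("d_min", 10)) / dt)),
        )
        label = classify_error(utts[:3], it.component_ids) if it.item_kind == "word" else None
        records.append(
            TrialRecord(
                item_index=item_index,
                item_kind=it.item_kind,
                target=tuple(it.component_ids),
                utterances=utts,
                label=label if label is not None else ErrorLabel("correct", None),
                n_utterances=len(utts),
            )
        )
    return records


# ----------------------------------------------------------------------
def run_free_latching(
    params: NetworkParams,
    p: int,
    seed: int,
    n_trials: int = 10,
    T_max: int = 1500,
    cue_strength: float = 1.0,
    cue_duration: int = 10,
    wm_ids: Sequence[int] | None = None,
    delta_theta: float = 0.0,
    cue_ids: Sequence[int] | None = None,
):
    """Free latching of a single network after one initial cue per trial.

    Used for the pattern-load regime scan and for working-memory kick
    experiments (``wm_ids`` selects the kicked patterns; each trial is cued
    with one of them unless ``cue_ids`` is given).  ``T_max`` and
    ``cue_duration`` are in time units (converted to steps via params.dt).
    Returns (patterns, overlap trajectories (steps, B, p)).
    """
    T_max = int(round(T_max / params.dt))
    cue_duration = int(round(cue_duration / params.dt))
    pats = generate_random_patterns(params.N, params.S, params.a, p,
                                    derive_rng(seed, "free_patterns"))
    conn = build_connectivity(params.N, params.N, params.C_m,
                              seed=derive_rng(seed, "free_connectivity"))
    kick = wm_kick_mask(pats, wm_ids) if wm_ids is not None else None
    net = PottsNetwork(params, store_autoassociative(pats, conn, params),
                       kick_mask=kick, delta_theta=delta_theta)
    state = net.null_state((n_trials,))

    rng = derive_rng(seed, "free_cues")
    if cue_ids is None:
        pool = list(wm_ids) if wm_ids is not None else list(range(p))
        cue_ids = rng.choice(pool, size=n_trials, replace=True)
    fields = np.stack(
        [cue_field(pats, int(c), cue_strength, params.S) for c in cue_ids]
    )

    from .analysis import overlap_matrix

    m = np.zeros((T_max, n_trials, p), dtype=np.float32)
    for t in range(T_max):
        h = net.fields(state.sigma)
        if t < cue_duration:
            h += fields
        net.step(state, h)
        m[t] = overlap_matrix(state.sigma, pats)
    return pats, m
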