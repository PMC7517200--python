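"""Potts network engine.

Each of the ``N`` units is a local patch with ``S`` active states plus a
quiescent state; its activation is a point on the (S+1)-simplex computed by a
softmax of the state-specific inputs ``r_ik`` against a unit-level threshold
``theta_i0 + U_eff``.  Memories are stored once in a simil-Hebbian tensor

    J_ij^kl = c_ij / (C_m a (1 - a/S)) * sum_mu (d(xi_i^mu,k) - a/S)(d(xi_j^mu,l) - a/S)

on a diluted connectivity (``C_m`` inputs per unit).  The dynamics couples

* the inputs            tau1   dr_ik/dt   = h_ik - theta_ik - r_ik
* fast/slow adaptation  tau2f  dthf_ik/dt = g2f  sigma_ik - thf_ik
                        tau2s  dths_ik/dt = (1-g2f) sigma_ik - ths_ik
* fast/slow inhibition  tauA   dthA_i/dt  = gA  sum_k sigma_ik - thA_i
                        tauB   dthB_i/dt  = (1-gA) sum_k sigma_ik - thB_i
* a dynamic threshold   tauU   dU^/dt     = (1/(a N_scope)) sum_i (1-sigma_i0) - U^

integrated by explicit Euler with the network-update as the unit of time
(dt=1 by default; the smallest time constant, tau_A=2, stays resolved).
The dynamic threshold can act buffer-wide or per unit cluster, and is the one
component switched off by the ``no_dynamic_threshold`` ablation.

All state arrays carry an arbitrary leading batch shape so that many
independent trials sharing the same weights are integrated in one vectorized
sweep; the heavy lifting is a single dense ``(B, N*S) @ (N*S, N*S)`` product
per network per step, kept in float32 (fields), while the simplex update is
done in float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .patterns import PatternSet

__all__ = [
    "NetworkParams",
    "Connectivity",
    "PottsWeights",
    "NetworkState",
    "PottsNetwork",
    "build_connectivity",
    "store_autoassociative",
    "pattern_kernel",
    "compute_field",
    "update_activations",
    "wm_kick_mask",
]


@dataclass
class NetworkParams:
    """All constants of one Potts network.

    ``tau2_fast``, ``tau2_slow`` and ``gamma2_fast`` may be scalars or
    per-(unit, state) arrays of shape (N, S) (used by the sign-buffer variant
    with heterogeneous adaptation).  ``tau_U`` defaults to ``tau_A``.
    """

    N: int
    S: int
    a: float
    C_m: int
    beta: float = 12.5
    U: float = 0.1
    w: float = 0.5
    tau1: float = 3.33
    tau2_fast: float | np.ndarray = 11.1
    tau2_slow: float | np.ndarray = 33.3
    gamma2_fast: float | np.ndarray = 0.5
    tau_A: float = 2.0
    tau_B: float = 1.0e6
    gamma_A: float = 0.0
    tau_U: float | None = None
    a_U: float | None = None  # dynamic-threshold normalization fraction (default: a)
    dt: float = 1.0
    dynamic_threshold: bool = False

    def __post_init__(self):
        for name in ("tau1", "tau_A", "tau_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if np.any(np.asarray(self.tau2_fast) <= 0) or np.any(np.asarray(self.tau2_slow) <= 0):
            raise ValueError("adaptation timescales must be positive")
        g2 = np.asarray(self.gamma2_fast)
        if np.any(g2 < 0) or np.any(g2 > 1) or not (0.0 <= self.gamma_A <= 1.0):
            raise ValueError("gamma2_fast and gamma_A must lie in [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.tau_U is None:
            self.tau_U = self.tau_A
        if self.a_U is None:
            self.a_U = self.a


@dataclass
class Connectivity:
    """Binary adjacency c[i, j] = 1 if pre-unit j feeds post-unit i."""

    c: np.ndarray  # (N_post, N_pre) bool

    @property
    def C_m(self) -> int:
        return int(self.c[0].sum())


def build_connectivity(
    N_post: int, N_pre: int, C_m: int, self_allowed: bool = False, seed=None
) -> Connectivity:
    """Each post-unit samples exactly C_m distinct pre-units uniformly."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    limit = N_pre if self_allowed else N_pre - 1
    if C_m > limit:
        raise ValueError(f"C_m={C_m} exceeds available pre-units ({limit})")
    c = np.zeros((N_post, N_pre), dtype=bool)
    for i in range(N_post):
        pool = np.arange(N_pre)
        if not self_allowed and i < N_pre:
            pool = np.delete(pool, i)
        c[i, rng.choice(pool, size=C_m, replace=False)] = True
    return Connectivity(c=c)


def pattern_kernel(patterns: PatternSet, S: int, a: float,
                   dtype=np.float32) -> np.ndarray:
    """Mean-subtracted indicator (d(xi_i^mu, k) - a/S) as a (p, N*S) matrix."""
    xi = patterns.states  # (p, N)
    p, N = xi.shape
    ks = np.arange(1, S + 1)
    V = (xi[:, :, None] == ks[None, None, :]).astype(dtype)
    V -= dtype(a / S)
    return V.reshape(p, N * S)


@dataclass
class PottsWeights:
    """Dense (N_post*S, N_pre*S) weight matrix including connectivity and norm."""

    W: np.ndarray  # float32
    N_post: int
    N_pre: int
    S: int


def _expand_mask(c: np.ndarray, S: int, out: np.ndarray) -> None:
    """Multiply out (N_post*S, N_pre*S) in place by the unit-level adjacency."""
    n_post, n_pre = c.shape
    out4 = out.reshape(n_post, S, n_pre, S)
    out4 *= c[:, None, :, None]


def store_autoassociative(
    patterns: PatternSet, conn: Connectivity, params: NetworkParams
) -> PottsWeights:
    """Hebbian storage of all patterns on the diluted connectivity."""
    S, a, C_m = params.S, params.a, params.C_m
    V = pattern_kernel(patterns, S, a)  # (p, N*S)
    norm = np.float32(1.0 / (C_m * a * (1.0 - a / S)))
    W = (V.T @ V) * norm
    _expand_mask(conn.c, S, W)
    return PottsWeights(W=W, N_post=params.N, N_pre=params.N, S=S)


def update_activations(r, theta0_total, U_eff, beta) -> np.ndarray:
    """Softmax over the S active states and the quiescent option.

    ``r``: (..., N, S) inputs; ``theta0_total``: (..., N) unit-level inhibition
    (theta_A + theta_B); ``U_eff``: scalar or (..., N) effective threshold.
    Returns sigma (..., N, S+1) with the quiescent component in column 0.
    Max-subtraction keeps the exponentials finite for any beta.
    """
    r = np.asarray(r, dtype=np.float64)
    thr = np.asarray(theta0_total, dtype=np.float64) + U_eff  # (..., N)
    x = np.concatenate([thr[..., None], r], axis=-1) * beta
    x -= x.max(axis=-1, keepdims=True)
    np.exp(x, out=x)
    x /= x.sum(axis=-1, keepdims=True)
    return x


def compute_field(
    sigma: np.ndarray,
    weights: PottsWeights,
    params: NetworkParams,
    hetero: Optional["object"] = None,
    source_sigma: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Recurrent field h_ik plus local feedback (and optional hetero input).

    ``sigma``: (..., N, S+1).  The local feedback term ``w (sigma_ik - mean_k)``
    is mean-subtracted over active states only.
    """
    act = sigma[..., 1:]
    lead = act.shape[:-2]
    flat = act.reshape(*lead, weights.N_post * weights.S).astype(np.float32)
    h = (flat @ weights.W.T).astype(np.float64).reshape(*lead, weights.N_post, weights.S)
    h += params.w * (act - act.mean(axis=-1, keepdims=True))
    if hetero is not None:
        from .coupling import compute_hetero_field

        h += compute_hetero_field(hetero, source_sigma)
    return h


def wm_kick_mask(patterns: PatternSet, wm_ids) -> np.ndarray:
    """(N, S) boolean mask of (unit, state) pairs active in >= 1 WM pattern."""
    wm_ids = list(wm_ids)
    if len(wm_ids) < 1:
        raise ValueError("working-memory set must contain at least one pattern")
    xi = patterns.states[wm_ids]  # (M, N)
    ks = np.arange(1, patterns.S + 1)
    return ((xi[:, :, None] == ks[None, None, :]).any(axis=0))


@dataclass
class NetworkState:
    """All dynamical variables, with an arbitrary leading batch shape."""

    sigma: np.ndarray      # (..., N, S+1)
    r: np.ndarray          # (..., N, S)
    theta_fast: np.ndarray  # (..., N, S)
    theta_slow: np.ndarray  # (..., N, S)
    theta_A: np.ndarray    # (..., N)
    theta_B: np.ndarray    # (..., N)
    U_hat: np.ndarray      # (..., n_scopes)

    @classmethod
    def null(cls, params: NetworkParams, batch_shape=(), n_scopes: int = 1,
             eps: float = 1e-3, theta_B0: float = 0.0) -> "NetworkState":
        """Global null state: sigma_i0 = 1-eps, active components eps/S.

        The inputs r are initialized at the (negative) level consistent with
        that quiescent activation under the softmax, rather than at zero, so
        a freshly created network relaxes smoothly toward its resting state
        instead of emitting a spurious burst of activity on the first update.

        ``theta_B0`` preloads the slow unit-level inhibition uniformly: the
        trial then starts from a globally inhibited (refractory) state whose
        threshold decays on the tau_B timescale, so externally driven
        patterns ignite strictly in the order of their drive strengths.
        """
        N, S = params.N, params.S
        sigma = np.zeros(batch_shape + (N, S + 1))
        sigma[..., 0] = 1.0 - eps
        sigma[..., 1:] = eps / S
        r0 = params.U + np.log(eps / (S * (1.0 - eps))) / params.beta
        zNS = np.zeros(batch_shape + (N, S))
        zN = np.zeros(batch_shape + (N,))
        return cls(
            sigma=sigma,
            r=zNS + r0,
            theta_fast=zNS.copy(),
            theta_slow=zNS.copy(),
            theta_A=zN.copy(),
            theta_B=zN + theta_B0,
            U_hat=np.zeros(batch_shape + (n_scopes,)),
        )

    def copy(self) -> "NetworkState":
        return NetworkState(*(getattr(self, f).copy() for f in (
            "sigma", "r", "theta_fast", "theta_slow", "theta_A", "theta_B", "U_hat")))


class PottsNetwork:
    """One network: weights + params + inhibition scopes + optional WM kick."""

    def __init__(
        self,
        params: NetworkParams,
        weights: PottsWeights,
        cluster_ids: np.ndarray | None = None,
        cluster_sizes: np.ndarray | None = None,
        kick_mask: np.ndarray | None = None,
        delta_theta: float = 0.0,
    ):
        self.params = params
        self.weights = weights
        if cluster_ids is None:
            self.cluster_ids = np.zeros(params.N, dtype=np.int64)
            self.cluster_sizes = np.array([params.N], dtype=np.float64)
        else:
            self.cluster_ids = np.asarray(cluster_ids, dtype=np.int64)
            self.cluster_sizes = np.asarray(cluster_sizes, dtype=np.float64)
        self.n_scopes = len(self.cluster_sizes)
        self.kick_mask = kick_mask
        self.delta_theta = delta_theta
        # one-hot scope membership for the U^ drive, (n_scopes, N)
        self._scope_onehot = (
            self.cluster_ids[None, :] == np.arange(self.n_scopes)[:, None]
        ).astype(np.float64)

    def null_state(self, batch_shape=(), theta_B0: float = 0.0) -> NetworkState:
        return NetworkState.null(self.params, batch_shape, n_scopes=self.n_scopes,
                                 theta_B0=theta_B0)

    def fields(self, sigma: np.ndarray) -> np.ndarray:
        return compute_field(sigma, self.weights, self.params)

    def step(self, state: NetworkState, h: np.ndarray) -> None:
        """One explicit-Euler update, in place.  ``h`` is the full field."""
        p = self.params
        dt = p.dt
        sig_act = state.sigma[..., 1:]
        sig_tot = sig_act.sum(axis=-1)  # (..., N)

        # adaptation (state-specific thresholds), optionally with the WM kick
        drive_f = np.asarray(p.gamma2_fast) * sig_act
        drive_s = (1.0 - np.asarray(p.gamma2_fast)) * sig_act
        if self.kick_mask is not None and self.delta_theta != 0.0:
            kick = self.delta_theta * self.kick_mask
            drive_f = drive_f - np.asarray(p.gamma2_fast) * kick
            drive_s = drive_s - (1.0 - np.asarray(p.gamma2_fast)) * kick
        state.theta_fast += (dt / np.asarray(p.tau2_fast)) * (drive_f - state.theta_fast)
        state.theta_slow += (dt / np.asarray(p.tau2_slow)) * (drive_s - state.theta_slow)

        # unit-level fast/slow inhibition
        state.theta_A += (dt / p.tau_A) * (p.gamma_A * sig_tot - state.theta_A)
        state.theta_B += (dt / p.tau_B) * ((1.0 - p.gamma_A) * sig_tot - state.theta_B)

        # dynamic threshold, one component per inhibition scope
        if p.dynamic_threshold:
            active = 1.0 - state.sigma[..., 0]  # (..., N)
            drive = active @ self._scope_onehot.T  # (..., n_scopes)
            drive /= p.a_U * self.cluster_sizes
            state.U_hat += (dt / p.tau_U) * (drive - state.U_hat)

        # inputs and the simplex update
        state.r += (dt / p.tau1) * (h - (state.theta_fast + state.theta_slow) - state.r)
        U_eff = p.U + (state.U_hat[..., self.cluster_ids] if p.dynamic_threshold else 0.0)
        state.sigma = update_activations(
            state.r, state.theta_A + state.theta_B, U_eff, p.beta
        )
        if not np.all(np.isfinite(state.sigma)):
            raise FloatingPointError("network state became non-finite")
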