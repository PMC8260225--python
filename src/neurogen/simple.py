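"""Simplified binary winner-take-all network and its toy neurogenesis runs.

One unit per cluster, Heaviside transfer, and implicit inhibition: every
unit inhibits every other through a fixed recurrent weight w_rec < 0,

    tau_m dnu_i/dt = -nu_i + H(I_i - b_i),
    I_i = w_i . x + sum_{k != i} R_ik nu_k .

Rates relax from zero to a binary fixed point.  Because within a constant
Heaviside configuration the dynamics are linear, the relaxation is
integrated *exactly* event-by-event: each rate decays exponentially toward
its current binary target, and the next threshold crossing time is solved
in closed form.  A forward-Euler integrator is available as a cross-check.

The toy neurogenesis paradigm pretrains two mature units on clusters 1-2 of
the equidistant dataset, freezes them, then adds a newborn unit with zero
weights whose maturation mirrors the full model: excitatory lateral input
and no output during the early phase (with a linear threshold ramp from
b_birth to the mature threshold), then a sign switch and reciprocal
inhibition in the late phase.  Whether the newborn ends up selective for
the novel cluster depends only on the cluster spacing xi relative to
xi_thresh = sqrt(||w||/b - 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import ClusterSpec, PatternSet, build_dataset
from .plasticity import PlasticityConfig, hebbian_update

logger = logging.getLogger(__name__)

__all__ = [
    "SimpleNetConfig",
    "SimpleTrajectory",
    "OscillationError",
    "simple_converge",
    "similarity_threshold",
    "max_recurrent_weight",
    "pretrain_mature_pair",
    "run_simple_neurogenesis",
    "run_sequential_growth",
]


class OscillationError(RuntimeError):
    """The binary relaxation cycled without reaching a fixed point."""

    def __init__(self, message: str, trace):
        super().__init__(message)
        self.trace = trace


@dataclass
class SimpleNetConfig:
    """Parameters of the simplified network (one unit per cluster)."""

    w_rec: float = -1.2        # recurrent inhibition between mature units
    b_mature: float = 1.2      # mature firing threshold
    b_birth: float = 0.9       # newborn threshold at birth
    ramp_len: int = 12000      # presentations over which b rises to mature
    tau_m: float = 20.0        # ms
    dt: float = 1.0            # Euler step, ms (euler method only)
    plasticity: PlasticityConfig = field(
        default_factory=PlasticityConfig.simple)
    final_window: int = 500    # trailing presentations averaged for reports

    def __post_init__(self) -> None:
        if self.w_rec >= 0:
            raise ValueError("w_rec must be negative (inhibition)")
        if not self.b_birth < self.b_mature:
            raise ValueError("b_birth must be below b_mature")
        if not -self.w_rec > self.b_birth:
            raise ValueError(
                "need -w_rec > b_birth so lateral excitation can activate "
                "a newborn unit")


# -- rate relaxation ---------------------------------------------------------

_MAX_EVENTS = 10_000


def _converge_exact(i_ff: np.ndarray, b: np.ndarray, R: np.ndarray,
                    ) -> np.ndarray:
    """Event-driven exact relaxation of the Heaviside rate dynamics.

    Time is measured in units of tau_m.  Within a region where the binary
    configuration s = H(I - b) is constant, nu(t) = s + (nu0 - s) e^-t and
    I_i(t) = c_i + d_i e^-t with c = i_ff + R s, d = R (nu0 - s); the next
    threshold crossing solves I_i(t) = b_i in closed form.
    """
    n = len(i_ff)
    nu = np.zeros(n)
    trace = []
    for _ in range(_MAX_EVENTS):
        s = (i_ff + R @ nu - b > 0).astype(float)   # H(0) = 0
        trace.append(s.copy())
        c = i_ff + R @ s
        d = R @ (nu - s)
        # crossing: e^-t = (b - c)/d, need ratio in (0, 1) => t > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (b - c) / d
        valid = (d != 0) & (ratio > 0.0) & (ratio < 1.0 - 1e-12)
        if not valid.any():
            # no further crossing: nu -> s is the fixed point
            return s
        # smallest positive time = largest ratio; overshoot by a tiny dt so
        # the crossing unit lands strictly past its threshold and the same
        # event cannot re-trigger
        t_next = -np.log(np.max(ratio[valid])) + 1e-9
        nu = s + (nu - s) * np.exp(-t_next)
    raise OscillationError(
        "binary relaxation exceeded the event budget without settling",
        np.array(trace))


def _converge_euler(i_ff: np.ndarray, b: np.ndarray, R: np.ndarray,
                    tau_m: float, dt: float, tol: float = 1e-9,
                    max_steps: int = 2_000_000) -> np.ndarray:
    """Forward-Euler reference integrator for the Heaviside dynamics."""
    nu = np.zeros(len(i_ff))
    for _ in range(max_steps):
        target = (i_ff + R @ nu - b > 0).astype(float)
        dnu = (dt / tau_m) * (-nu + target)
        nu = nu + dnu
        if np.max(np.abs(dnu)) < tol * dt / tau_m:
            return target if np.allclose(nu, target, atol=1e-6) else nu
    raise OscillationError("Euler relaxation did not converge", nu)


def simple_converge(W: np.ndarray, b: np.ndarray, recurrent: np.ndarray,
                    pattern: np.ndarray, method: str = "exact",
                    tau_m: float = 20.0, dt: float = 1.0) -> np.ndarray:
    """Relax the simplified network on one pattern; returns the binary rates.

    ``recurrent[i, k]`` is the weight from unit k onto unit i (zero
    diagonal).  Rates start at zero; the fixed point is binary because the
    Heaviside transfer admits only 0/1 self-consistent rates.
    """
    i_ff = np.asarray(W) @ np.asarray(pattern, dtype=float)
    b = np.broadcast_to(np.asarray(b, dtype=float), i_ff.shape)
    R = np.asarray(recurrent, dtype=float)
    if method == "exact":
        return _converge_exact(i_ff, b, R)
    if method == "euler":
        return _converge_euler(i_ff, b, R, tau_m, dt)
    raise ValueError(f"unknown method {method!r}")


# -- closed-form parameter relations ----------------------------------------

def similarity_threshold(norm: float, b: float) -> float:
    """Spacing xi below which two clusters co-activate the same unit.

    A unit whose weight vector (norm ``norm``) points at one cluster center
    receives ~ norm/(1+xi^2) from the other cluster; it fires iff that
    exceeds its threshold b, giving xi_thresh = sqrt(norm/b - 1).  Returns
    0 (with a warning) when norm <= b, where no similar regime exists.
    """
    if b <= 0 or norm <= 0:
        raise ValueError("norm and b must be positive")
    if norm <= b:
        warnings.warn("norm <= b: no similar regime (xi_thresh = 0)",
                      stacklevel=2)
        return 0.0
    return float(np.sqrt(norm / b - 1.0))


def max_recurrent_weight(norm: float, b: float, xi_range) -> float:
    """Upper bound on w_rec for single-winner competition.

    The recurrent weight must satisfy w_rec < b - max_xi norm/(1+xi^2) so
    that a unit driven by a *different* cluster stays below threshold while
    the winner is active.
    """
    xi = np.atleast_1d(np.asarray(xi_range, dtype=float))
    return float(b - np.max(norm / (1.0 + xi**2)))


# -- toy neurogenesis --------------------------------------------------------

@dataclass
class SimpleTrajectory:
    """Per-presentation record of the newborn unit's receptive field."""

    norms: np.ndarray            # ||w_newborn|| after each presentation
    phis: np.ndarray             # angle to the novel center, degrees
    phase_split: int             # index where the late phase starts
    W: np.ndarray                # final weights, (K_units, N_EC)
    case: str                    # "similar" | "distinct"
    final_window: int
    W_early: np.ndarray | None = None   # weights at the end of the early phase

    @property
    def final_phi(self) -> float:
        """Trailing-window average angle at the end of the late phase."""
        return float(np.mean(self.phis[-self.final_window:]))

    @property
    def final_norm(self) -> float:
        return float(np.mean(self.norms[-self.final_window:]))

    @property
    def end_of_early_phi(self) -> float:
        lo = max(self.phase_split - self.final_window, 0)
        return float(np.mean(self.phis[lo:self.phase_split]))

    @property
    def end_of_early_norm(self) -> float:
        lo = max(self.phase_split - self.final_window, 0)
        return float(np.mean(self.norms[lo:self.phase_split]))


def _pretrain_pair(train: PatternSet, clusters, cfg: SimpleNetConfig,
                   rng: np.random.Generator, epochs: int = 1) -> np.ndarray:
    """Initialize two mature units at training patterns (scaled to the norm
    ceiling) and train them on the two pretraining clusters."""
    upper = cfg.plasticity.gamma / cfg.plasticity.beta   # 1.5 for defaults
    sub = [train.X[train.labels == c] for c in clusters]
    W = np.stack([s[rng.integers(len(s))] * upper for s in sub])
    b = np.full(2, cfg.b_mature)
    R = cfg.w_rec * (1 - np.eye(2))
    X = np.vstack(sub)
    for _ in range(epochs):
        for idx in rng.permutation(len(X)):
            nu = simple_converge(W, b, R, X[idx])
            W = hebbian_update(W, X[idx], nu, cfg.plasticity)
    return W


def pretrain_mature_pair(train: PatternSet, cfg: SimpleNetConfig | None = None,
                         clusters=(0, 1), seed: int = 0, epochs: int = 1,
                         ) -> tuple[np.ndarray, float]:
    """Pretrain two mature units on two clusters; returns (W, mean norm).

    With tightly concentrated clusters the converged rows point at the
    cluster centers with norm gamma/beta times the mean resultant length of
    the cluster (about 1.49 for kappa = 1e4 in 128 dimensions).
    """
    cfg = cfg or SimpleNetConfig()
    rng = np.random.default_rng([3, seed])
    W = _pretrain_pair(train, clusters, cfg, rng, epochs)
    return W, float(np.linalg.norm(W, axis=1).mean())


def run_simple_neurogenesis(train: PatternSet, cfg: SimpleNetConfig | None = None,
                            novel_cluster: int = 2, clusters=(0, 1),
                            seed: int = 0, pretrain_epochs: int = 1,
                            eta_newborn: float | None = None,
                            ) -> SimpleTrajectory:
    """Full toy neurogenesis paradigm on the equidistant dataset.

    Pretrain two mature units, freeze them, add a zero-weight newborn unit,
    run one epoch over all three clusters with excitatory lateral input and
    a linear threshold ramp (early phase), switch the lateral input sign and
    wire reciprocal inhibition (late phase), and run one more epoch.
    Records the newborn weight norm and its angle to the novel-cluster
    center after every presentation.
    """
    cfg = cfg or SimpleNetConfig()
    if train.spec is None:
        raise ValueError("train set must carry its ClusterSpec (novel center)")
    rng = np.random.default_rng([3, seed])

    W_mature = _pretrain_pair(train, clusters, cfg, rng, pretrain_epochs)
    # center of mass of the novel cluster: the average of the novel stimuli
    novel_center = train.X[train.labels == novel_cluster].mean(axis=0)
    novel_center = novel_center / np.linalg.norm(novel_center)

    used = list(clusters) + [novel_cluster]
    X = np.vstack([train.X[train.labels == c] for c in used])

    W = np.vstack([W_mature, np.zeros(train.n_features)])
    nb = 2                                           # newborn row index
    plast = cfg.plasticity if eta_newborn is None else PlasticityConfig.simple(
        eta=eta_newborn)

    # early phase: mature units inhibit each other; mature -> newborn is
    # excitatory (GABA depolarizing); newborn -> mature absent
    R_early = cfg.w_rec * (1 - np.eye(3))
    R_early[nb, :] = -cfg.w_rec
    R_early[:, nb] = 0.0
    R_early[nb, nb] = 0.0
    R_late = cfg.w_rec * (1 - np.eye(3))

    norms, phis = [], []
    presented = 0

    def b_newborn() -> float:
        ramp = min(presented / cfg.ramp_len, 1.0)
        return cfg.b_birth + ramp * (cfg.b_mature - cfg.b_birth)

    for phase, R in (("early", R_early), ("late", R_late)):
        for idx in rng.permutation(len(X)):
            b = np.array([cfg.b_mature, cfg.b_mature, b_newborn()])
            nu = simple_converge(W, b, R, X[idx])
            if nu[nb] > plast.theta:
                W[nb] = hebbian_update(W[nb], X[idx], nu[nb], plast)
            presented += 1
            n = np.linalg.norm(W[nb])
            norms.append(n)
            cosphi = (W[nb] @ novel_center / n) if n > 0 else 0.0
            phis.append(np.degrees(np.arccos(np.clip(cosphi, -1.0, 1.0))))
        if phase == "early":
            phase_split = presented
            W_early = W.copy()

    case = ("similar" if train.spec.xi < similarity_threshold(
        cfg.plasticity.gamma / cfg.plasticity.beta, cfg.b_mature)
        else "distinct")
    return SimpleTrajectory(np.array(norms), np.array(phis), phase_split,
                            W, case, cfg.final_window, W_early)


def run_sequential_growth(spec: ClusterSpec, mode: str = "neurogenesis",
                          init_norm: float = 0.1, seed: int = 0,
                          cfg: SimpleNetConfig | None = None,
                          ) -> np.ndarray:
    """Grow the network one cluster at a time; returns the final weights.

    ``mode="neurogenesis"``: each added unit starts at zero weights and goes
    through the two-phase maturation (one epoch cooperative with threshold
    ramp, one epoch competitive), after which it is frozen.
    ``mode="rand_init"``: each added unit starts at a random direction with
    norm ``init_norm``, is fully integrated immediately (mature threshold,
    inhibitory coupling), and all added units stay plastic for two epochs
    per stage.
    """
    if mode not in ("neurogenesis", "rand_init"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = cfg or SimpleNetConfig()
    rng = np.random.default_rng([4, seed])
    train, _ = build_dataset(spec)

    W = _pretrain_pair(train, (0, 1), cfg, rng)
    for k in range(2, spec.K):
        X = train.X[train.labels <= k]
        if mode == "neurogenesis":
            W = np.vstack([W, np.zeros(spec.n_ec)])
            nb = k
            n_units = k + 1
            R_early = cfg.w_rec * (1 - np.eye(n_units))
            R_early[nb, :] = -cfg.w_rec
            R_early[:, nb] = 0.0
            R_early[nb, nb] = 0.0
            R_late = cfg.w_rec * (1 - np.eye(n_units))
            presented = 0
            for R in (R_early, R_late):
                for idx in rng.permutation(len(X)):
                    ramp = min(presented / cfg.ramp_len, 1.0)
                    b = np.full(n_units, cfg.b_mature)
                    b[nb] = cfg.b_birth + ramp * (cfg.b_mature - cfg.b_birth)
                    nu = simple_converge(W, b, R, X[idx])
                    if nu[nb] > cfg.plasticity.theta:
                        W[nb] = hebbian_update(W[nb], X[idx], nu[nb],
                                               cfg.plasticity)
                    presented += 1
        else:
            direction = rng.uniform(size=spec.n_ec)
            direction /= np.linalg.norm(direction)
            W = np.vstack([W, init_norm * direction])
            n_units = k + 1
            R = cfg.w_rec * (1 - np.eye(n_units))
            b = np.full(n_units, cfg.b_mature)
            plastic = np.arange(2, n_units)          # added units stay plastic
            for _ in range(2):
                for idx in rng.permutation(len(X)):
                    nu = simple_converge(W, b, R, X[idx])
                    W[plastic] = hebbian_update(W[plastic], X[idx],
                                                nu[plastic], cfg.plasticity)
    return W
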