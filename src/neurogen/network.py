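"""Rate dynamics of the dentate-gyrus circuit.

Granule cells (DGCs) receive feedforward drive from EC input cells and
recurrent inhibition from a pool of interneurons.  For each presented
pattern the coupled rate equations

    tau_m   dnu_i/dt  = -nu_i  + tanh([I_i - b_i]+ / L)
    tau_inh dnuI_k/dt = -nuI_k + [I^I_k - p* N_DGC]+

are integrated (forward Euler, both populations initialized at zero) until
the rates settle to a fixed point.  I_i sums feedforward input W x and
interneuron input W_EI nuI; I^I_k sums DGC input W_IE nu.  Rates are
unit-free with nu = 1 corresponding to 10 Hz; the subtractive term
p* N_DGC in the interneuron drive enforces sparse DGC activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "MaturationStage",
    "NetworkConfig",
    "NetworkState",
    "RateResponse",
    "ConvergenceError",
    "init_network",
    "converge_rates",
    "batch_rates",
    "activity_stats",
]


class MaturationStage(str, Enum):
    """Plasticity/wiring stage of a granule cell."""

    MATURE_FIXED = "mature_fixed"       # eta = 0, frozen weights
    MATURE_PLASTIC = "mature_plastic"   # eta > 0
    NEWBORN_EARLY = "newborn_early"     # excitatory GABA, b = 0, no IE output
    NEWBORN_LATE = "newborn_late"       # inhibitory GABA, IE output, adaptive b


class ConvergenceError(RuntimeError):
    """Rate dynamics failed to reach a fixed point within T_max."""

    def __init__(self, message: str, response: "RateResponse"):
        super().__init__(message)
        self.response = response


@dataclass
class NetworkConfig:
    """Sizes, connectivity and dynamics of the biologically plausible net."""

    n_ec: int = 144
    n_dgc: int = 100
    n_inh: int = 25
    p_ie: float = 0.9          # DGC -> interneuron connection probability
    p_ei: float = 0.9          # interneuron -> DGC connection probability
    w_ie: float = 1.0
    w_ei_magnitude: float | None = None   # default 1/(p_ei * n_inh)
    tau_m: float = 20.0        # ms
    tau_inh: float = 2.0       # ms
    L: float = 0.5             # f-I curve smoothness
    p_star: float = 0.1        # sparsity parameter
    dt: float = 0.1            # Euler step, ms
    tol: float = 1e-6          # fixed-point precision (on |dnu/dt|)
    t_max_factor: float = 2000.0   # T_max = t_max_factor * tau_m

    def __post_init__(self) -> None:
        if not (0 <= self.p_ie <= 1 and 0 <= self.p_ei <= 1):
            raise ValueError("connection probabilities must lie in [0,1]")
        if min(self.tau_m, self.tau_inh, self.dt, self.L) <= 0:
            raise ValueError("tau_m, tau_inh, dt and L must be positive")

    @property
    def w_ei(self) -> float:
        """Magnitude of the interneuron->DGC weight (sign set by stage)."""
        if self.w_ei_magnitude is not None:
            return self.w_ei_magnitude
        if self.n_inh == 0 or self.p_ei == 0:
            return 0.0
        return 1.0 / (self.p_ei * self.n_inh)


@dataclass
class NetworkState:
    """Mutable synaptic state of the circuit.

    ``W`` is the non-negative N_DGC x N_EC feedforward matrix; ``w_ei`` the
    signed interneuron->DGC matrix living on the immutable ``mask_ei``;
    ``w_ie`` the DGC->interneuron matrix on ``mask_ie`` (zeroed columns for
    early-phase newborns); ``b`` per-cell thresholds; ``stage`` per-cell
    maturation stages.
    """

    W: np.ndarray
    w_ei: np.ndarray
    w_ie: np.ndarray
    mask_ei: np.ndarray
    mask_ie: np.ndarray
    b: np.ndarray
    stage: list
    rng: np.random.Generator = field(repr=False, default=None)

    def validate(self) -> None:
        if np.any(self.W < 0):
            raise ValueError("feedforward weights must be non-negative")
        for i, s in enumerate(self.stage):
            if s is MaturationStage.NEWBORN_EARLY and self.w_ie[:, i].any():
                raise ValueError(
                    f"early-phase newborn {i} must have zero output "
                    "to interneurons")

    def copy(self) -> "NetworkState":
        return NetworkState(self.W.copy(), self.w_ei.copy(),
                            self.w_ie.copy(), self.mask_ei, self.mask_ie,
                            self.b.copy(), list(self.stage), self.rng)


@dataclass
class RateResponse:
    """Converged rates for one pattern plus convergence metadata."""

    nu: np.ndarray          # DGC rates, 0 <= nu < 1 (1 = 10 Hz)
    nu_inh: np.ndarray      # interneuron rates, >= 0
    t: float                # simulated time to convergence, ms
    converged: bool
    residual: float         # max |dnu/dt| at exit


def init_network(config: NetworkConfig, seed: int | np.random.Generator,
                 ) -> NetworkState:
    """Random adult-stage initialization.

    Feedforward rows are Uniform(0,1) draws L2-normalized to 1 (fair
    competition between cells); connectivity masks are Bernoulli(p_ie) /
    Bernoulli(p_ei); inhibition starts in the mature (negative) regime;
    thresholds start at 0; all cells start as mature_plastic.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    W = rng.uniform(size=(config.n_dgc, config.n_ec))
    W /= np.linalg.norm(W, axis=1, keepdims=True)
    mask_ei = rng.uniform(size=(config.n_dgc, config.n_inh)) < config.p_ei
    mask_ie = rng.uniform(size=(config.n_inh, config.n_dgc)) < config.p_ie
    w_ei = np.where(mask_ei, -config.w_ei, 0.0)
    w_ie = np.where(mask_ie, config.w_ie, 0.0)
    b = np.zeros(config.n_dgc)
    stage = [MaturationStage.MATURE_PLASTIC] * config.n_dgc
    return NetworkState(W, w_ei, w_ie, mask_ei, mask_ie, b, stage, rng)


def converge_rates(state: NetworkState, pattern: np.ndarray,
                   config: NetworkConfig,
                   raise_on_failure: bool = True) -> RateResponse:
    """Integrate the coupled rate equations to their fixed point.

    Both populations start at rate zero.  Convergence is declared when the
    largest rate derivative magnitude drops below ``config.tol`` (i.e. the
    per-step change is below tol*dt/tau).  Exceeding T_max raises
    :class:`ConvergenceError` carrying the last state unless
    ``raise_on_failure`` is false.
    """
    pattern = np.asarray(pattern, dtype=float)
    i_ff = state.W @ pattern                       # constant during relaxation
    nu = np.zeros(len(state.W))
    nu_inh = np.zeros(state.w_ie.shape[0])
    dt, tau_m, tau_inh = config.dt, config.tau_m, config.tau_inh
    n_steps = int(config.t_max_factor * tau_m / dt)
    thresh_inh = config.p_star * len(nu)

    residual = np.inf
    for step in range(1, n_steps + 1):
        drive = np.tanh(np.maximum(i_ff + state.w_ei @ nu_inh - state.b, 0.0)
                        / config.L)
        drive_inh = np.maximum(state.w_ie @ nu - thresh_inh, 0.0)
        dnu = (-nu + drive) / tau_m
        dnu_inh = (-nu_inh + drive_inh) / tau_inh
        nu = nu + dt * dnu
        nu_inh = nu_inh + dt * dnu_inh
        residual = max(np.max(np.abs(dnu), initial=0.0),
                       np.max(np.abs(dnu_inh), initial=0.0))
        if residual < config.tol:
            return RateResponse(nu, nu_inh, step * dt, True, residual)

    resp = RateResponse(nu, nu_inh, n_steps * dt, False, residual)
    if raise_on_failure:
        raise ConvergenceError(
            f"rates did not converge within T_max = {n_steps * dt} ms "
            f"(residual {residual:.3g})", resp)
    return resp


def batch_rates(state: NetworkState, X: np.ndarray,
                config: NetworkConfig) -> np.ndarray:
    """Converged DGC rates for each row of X, as a (P, N_DGC) matrix."""
    return np.stack([converge_rates(state, x, config).nu for x in X])


def activity_stats(response: RateResponse,
                   silent_thresh: float = 0.1,
                   high_thresh: float = 0.1) -> tuple[float, float]:
    """Fractions of silent (< 1 Hz) and highly active (> 1 Hz) cells.

    Rates are unit-free with 1 = 10 Hz, so the 1 Hz boundary is nu = 0.1.
    """
    nu = response.nu
    return (float(np.mean(nu < silent_thresh)),
            float(np.mean(nu > high_thresh)))
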