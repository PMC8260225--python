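"""Three-term Hebbian/heterosynaptic plasticity and threshold adaptation.

After the rates have converged for one pattern, each plastic cell i updates
its feedforward weight row by

    dw_ij = eta * ( gamma * x_j * nu_i * [nu_i - theta]+        (LTP)
                  - alpha * x_j * nu_i * [theta - nu_i]+        (LTD)
                  - beta * w_ij * [nu_i - theta]+ * nu_i**3 )   (heterosynaptic)

with weights hard-bounded below at zero.  The first two terms are a
rate-threshold (BCM-like) Hebbian pair: potentiation above the postsynaptic
threshold theta, depression below it.  The third, heterosynaptic term
depresses *all* synapses of a strongly firing cell supra-linearly in its
rate, which bounds the weight-vector norm without explicit upper bounds:
at a clamped rate nu > theta the row converges to gamma*x/(beta*nu^2).

The relative LTP/LTD strengths derive from theta: gamma = gamma0 - theta
and alpha = alpha0 / theta^3 (keeping LTD commensurate with LTP near
nu = theta; an explicit override is provided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlasticityConfig",
    "hebbian_update",
    "threshold_update",
    "expected_weight_vector",
    "weight_norm_bounds",
]


@dataclass
class PlasticityConfig:
    """Plasticity-rule constants.

    Defaults are the biologically plausible network's values; the simplified
    winner-take-all network uses ``simple()``.
    """

    eta: float = 0.01        # learning rate
    eta_b: float = 0.01      # threshold learning rate
    theta: float = 0.15      # LTD/LTP transition rate
    alpha0: float = 0.05
    gamma0: float = 10.0
    beta: float = 1.0
    nu0: float = 0.2         # reference rate for threshold adaptation
    alpha_override: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ValueError(f"theta must be in (0,1), got {self.theta}")
        if self.gamma <= 0:
            raise ValueError("gamma = gamma0 - theta must be positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    @property
    def gamma(self) -> float:
        """LTP strength gamma = gamma0 - theta."""
        return self.gamma0 - self.theta

    @property
    def alpha(self) -> float:
        """LTD strength alpha = alpha0 / theta^3 (unless overridden)."""
        if self.alpha_override is not None:
            return self.alpha_override
        return self.alpha0 / self.theta**3

    @classmethod
    def simple(cls, eta: float = 0.01) -> "PlasticityConfig":
        """Parameters of the simplified (binary winner-take-all) network."""
        return cls(eta=eta, theta=0.15, alpha0=0.03, gamma0=1.65, beta=1.0)


def hebbian_update(w_row: np.ndarray, x: np.ndarray, nu: float,
                   cfg: PlasticityConfig) -> np.ndarray:
    """Apply one plasticity step to a weight row; returns the new row.

    Supports a batch of rows: ``w_row`` of shape (M, N) with ``nu`` of
    shape (M,) updates M cells against the same pattern.
    """
    w = np.asarray(w_row, dtype=float)
    x = np.asarray(x, dtype=float)
    nu = np.asarray(nu, dtype=float)
    ltp = np.maximum(nu - cfg.theta, 0.0)
    ltd = np.maximum(cfg.theta - nu, 0.0)
    if w.ndim == 2:
        hom = (cfg.gamma * ltp - cfg.alpha * ltd) * nu
        dw = cfg.eta * (np.outer(hom, x) - cfg.beta * w * (ltp * nu**3)[:, None])
    else:
        dw = cfg.eta * ((cfg.gamma * ltp - cfg.alpha * ltd) * nu * x
                        - cfg.beta * w * ltp * nu**3)
    return np.maximum(w + dw, 0.0)


def threshold_update(b, nu, cfg: PlasticityConfig):
    """Adapt the firing threshold: b' = b + eta_b (nu - nu0).

    Mimics the loss of intrinsic excitability of maturing cells: a cell
    firing above the reference rate nu0 raises its threshold.
    """
    return b + cfg.eta_b * (np.asarray(nu) - cfg.nu0)


def expected_weight_vector(rates: np.ndarray, patterns: np.ndarray,
                           cfg: PlasticityConfig) -> np.ndarray:
    """Analytic fixed point of the weight row over a frozen winning set.

    For a cell winning (nu > theta) the patterns in its winning set C, the
    converged row is the G1/G2-weighted average

        w = (gamma/beta) * <G1(nu) x>_C / <G2(nu)>_C,

    with G1(nu) = (nu - theta) nu and G2(nu) = (nu - theta) nu^3.
    """
    rates = np.asarray(rates, dtype=float)
    patterns = np.asarray(patterns, dtype=float)
    if rates.size == 0:
        raise ValueError("empty winning set")
    if np.any(rates <= cfg.theta):
        raise ValueError("all rates in the winning set must exceed theta")
    g1 = (rates - cfg.theta) * rates
    g2 = (rates - cfg.theta) * rates**3
    return (cfg.gamma / cfg.beta) * (g1 @ patterns / len(rates)) / g2.mean()


def weight_norm_bounds(cfg: PlasticityConfig, nu_min: float, nu_max: float,
                       mean_cos: float = 1.0) -> tuple[float, float, float]:
    """Bounds on the converged weight-row norm.

    Returns ``(lower, upper_tight, upper_loose)`` where
    upper_loose = gamma/(beta theta^2), upper_tight = gamma/(beta nu_min^2)
    and lower = gamma/(beta nu_max^2) * mean_cos, with ``mean_cos`` the mean
    cosine between the weight row and its winning patterns.
    """
    if not cfg.theta < nu_min <= nu_max <= 1.0:
        raise ValueError("need theta < nu_min <= nu_max <= 1")
    g_over_b = cfg.gamma / cfg.beta
    upper_loose = g_over_b / cfg.theta**2
    upper_tight = g_over_b / nu_min**2
    lower = g_over_b / nu_max**2 * mean_cos
    return lower, upper_tight, upper_loose
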