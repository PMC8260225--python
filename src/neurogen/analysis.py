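"""Population-level analysis: discriminant axes, dimensionality, geometry.

Three independent views of what the circuit learns:

* pairwise Fisher linear-discriminant axes of the granule-cell population
  activity, used to visualize how well a novel class separates from the
  pretrained ones;
* the participation ratio PR = Tr(C)^2 / Tr(C^2) of a pattern ensemble's
  covariance C — an effective dimensionality that interpolates between 1
  (rank-one data) and the ambient dimension (isotropic data);
* the closed-form geometry of the newborn unit's weight vector at the end
  of the cooperative phase, which predicts whether a novel cluster can be
  acquired: for *similar* clusters the weight vector ends near the centroid
  of all clusters (small angle phi to the novel center), for *distinct*
  clusters near the midpoint of the pretrained pair (large phi).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .network import NetworkConfig, NetworkState, converge_rates
from .datasets import pairwise_center_angle

logger = logging.getLogger(__name__)

__all__ = [
    "FisherAxes",
    "GeometryResult",
    "fisher_axes",
    "participation_ratio",
    "analytic_early_geometry",
    "quasi_orthogonality",
]


@dataclass
class FisherAxes:
    """Per class-pair discriminant axes with a common projection origin."""

    pairs: list                      # [(class_m, class_n), ...]
    axes: np.ndarray                 # (n_pairs, N_DGC), unit rows
    origins: np.ndarray              # per-axis offset: pool mean projection

    def project(self, activities: np.ndarray) -> np.ndarray:
        """Per-axis coordinates of each activity vector, origin-centred."""
        return np.asarray(activities) @ self.axes.T - self.origins


def fisher_axes(activities: np.ndarray, labels: np.ndarray, pairs,
                regularize: bool = True) -> FisherAxes:
    """Fisher linear-discriminant axis for each class pair.

    For classes (m, n) the axis maximizes J(w) = w^T S_B w / w^T S_W w with
    S_B the between-class scatter of the two means and S_W the sum of the
    two within-class covariances; the optimum is the leading eigenvector of
    S_W^-1 S_B.  Near-singular S_W is ridge-regularized by
    eps = 1e-8 Tr(S_W)/dim (logged).  The origin of each axis is set so
    that the mean projection of the full training pool is zero.
    """
    activities = np.asarray(activities, dtype=float)
    labels = np.asarray(labels)
    dim = activities.shape[1]
    axes, origins = [], []
    for m, n in pairs:
        A_m, A_n = activities[labels == m], activities[labels == n]
        if len(A_m) < 2 or len(A_n) < 2:
            raise ValueError(f"need >= 2 patterns per class for pair ({m},{n})")
        mu_m, mu_n = A_m.mean(axis=0), A_n.mean(axis=0)
        S_w = np.cov(A_m, rowvar=False) + np.cov(A_n, rowvar=False)
        cond = np.linalg.cond(S_w)
        if cond > 1e10:
            if not regularize:
                raise np.linalg.LinAlgError(
                    f"S_W is near-singular (cond={cond:.3g}) and "
                    "regularization is disabled")
            eps = 1e-8 * np.trace(S_w) / dim
            eps = eps if eps > 0 else 1e-12
            logger.info("regularizing S_W for pair (%s, %s): eps=%.3g",
                        m, n, eps)
            S_w = S_w + eps * np.eye(dim)
        # rank-one S_B: leading eigenvector of S_W^-1 S_B is S_W^-1 (mu_m-mu_n)
        axis = linalg.solve(S_w, mu_m - mu_n, assume_a="pos")
        axis /= np.linalg.norm(axis)
        axes.append(axis)
        origins.append(float(activities.mean(axis=0) @ axis))
    return FisherAxes(list(pairs), np.array(axes), np.array(origins))


def participation_ratio(X: np.ndarray) -> float:
    """Effective dimensionality PR = Tr(C)^2 / Tr(C^2) of the rows of X."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to estimate a covariance")
    Xc = X - X.mean(axis=0)
    # Tr(C) and Tr(C^2) via the Gram route to avoid forming a D x D matrix
    # when D is large: Tr(C) = sum of squares / (n-1), Tr(C^2) = ||Xc^T Xc||_F^2
    n = X.shape[0] - 1
    tr_c = np.sum(Xc**2) / n
    if tr_c == 0:
        raise ValueError("zero-variance data has no participation ratio")
    G = (Xc.T @ Xc if X.shape[1] <= X.shape[0] else Xc @ Xc.T) / n
    tr_c2 = np.sum(G**2)
    return float(tr_c**2 / tr_c2)


@dataclass
class GeometryResult:
    """Closed-form early-phase geometry of the newborn weight vector."""

    case: str            # "similar" | "distinct"
    omega_deg: float     # pairwise center angle
    z: float             # half-chord between projected centers
    y: float             # in-triangle segment (circumradius / median)
    norm: float          # expected newborn weight norm, end of early phase
    phi_deg: float       # angle to the novel-cluster center, degrees


def analytic_early_geometry(xi: float, mature_norm: float,
                            case: str) -> GeometryResult:
    """Predict the newborn weight vector at the end of the early phase.

    All cluster centers sit on a sphere of radius ``mature_norm`` (the
    converged mature weight norm) with pairwise angle Omega given by xi.

    *similar*: the newborn vector points at the centroid of the equilateral
    triangle of all three projected centers.  With half-chord
    z = r sin(Omega/2), the circumradius is y = z / cos(pi/6), so
    norm = sqrt(r^2 - y^2) and phi = arccos(norm / r).

    *distinct*: the newborn vector points at the midpoint of the two
    pretrained centers: norm = r cos(Omega/2).  The distance from that
    midpoint to the novel vertex is the triangle median y = z / tan(pi/6),
    and phi follows from the law of cosines on (norm, r, y).
    """
    if mature_norm <= 0:
        raise ValueError("mature_norm must be positive")
    if not 0 < xi < 1:
        raise ValueError(f"xi must lie in (0, 1), got {xi}")
    r = mature_norm
    omega = np.radians(pairwise_center_angle(xi))
    z = r * np.sin(omega / 2)
    if case == "similar":
        y = z / np.cos(np.pi / 6)
        norm = np.sqrt(r**2 - y**2)
        phi = np.arccos(norm / r)
    elif case == "distinct":
        norm = r * np.cos(omega / 2)
        y = z / np.tan(np.pi / 6)
        phi = np.arccos((norm**2 + r**2 - y**2) / (2 * norm * r))
    else:
        raise ValueError(f"case must be 'similar' or 'distinct', got {case!r}")
    return GeometryResult(case, float(np.degrees(omega)), float(z), float(y),
                          float(norm), float(np.degrees(phi)))


def quasi_orthogonality(state: NetworkState, pattern: np.ndarray, unit: int,
                        config: NetworkConfig) -> bool:
    """True iff the pattern cannot activate the unit at the fixed point.

    A pattern is quasi-orthogonal to a unit's weight vector when the
    stationary total input (feedforward plus converged interneuron input)
    stays below the unit's threshold.  With no inhibition and b -> 0 this
    reduces to w . x <= 0, ordinary orthogonality for non-negative vectors.
    """
    resp = converge_rates(state, pattern, config)
    total_input = state.W[unit] @ np.asarray(pattern) \
        + state.w_ei[unit] @ resp.nu_inh
    return bool(total_input < state.b[unit]) or (
        total_input == state.b[unit] and state.b[unit] == 0)
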