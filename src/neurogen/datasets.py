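"""Clustered input patterns on the unit hypersphere.

The model's entorhinal-cortex (EC) input is a non-negative activity vector
normalized to unit L2 norm (feedforward inhibition implements the
normalization implicitly).  The synthetic benchmark places ``K`` equidistant
cluster centers on the positive quadrant of the hypersphere — Walsh patterns
shifted along the diagonal — and scatters unit-norm patterns around each
center with a von Mises–Fisher (vMF) distribution of concentration ``kappa``.

The spacing parameter ``xi`` (|xi| < 1) controls the pairwise angle between
centers: cos(Omega) = 1/(1+xi^2), so Omega ranges from 0 (xi=0) to 60 degrees
(xi=1).  Pairwise cluster similarity is s = 1 - xi.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSpec",
    "PatternSet",
    "make_walsh_centers",
    "pairwise_center_angle",
    "sample_vmf_cluster",
    "build_dataset",
    "normalize_external_patterns",
    "save_patternset",
    "load_patternset",
]

# Fixed offsets deriving the train/test RNG streams from the base seed, so
# test patterns are unchanged when n_train changes.
_TRAIN_STREAM = 0
_TEST_STREAM = 1

# Maximum rejection-sampler attempts per sample before raising.
_MAX_REJECTION_ATTEMPTS = 10**6


@dataclass
class ClusterSpec:
    """Specification of the equidistant-cluster dataset.

    Parameters
    ----------
    K : int
        Number of clusters (>= 2).  Input dimension is ``N_EC = 2**K``
        (the Walsh square waves underlying the centers require a
        power-of-two dimension; K=7 gives the standard 128 input cells).
    xi : float
        Center spacing parameter, |xi| < 1.  Similarity is ``s = 1 - xi``.
    kappa : float
        vMF concentration (> 0).  Large kappa gives tight clusters; the
        kappa -> 0 limit is uniform sampling on the sphere.
    n_train, n_test : int
        Patterns per cluster in the train and test splits.
    seed : int
        Base RNG seed; train and test use disjoint child streams.
    """

    K: int
    xi: float
    kappa: float = 1e4
    n_train: int = 6000
    n_test: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.K <= 20:
            raise ValueError(f"need 2 <= K <= 20 clusters, got {self.K}")
        if not abs(self.xi) < 1:
            raise ValueError(f"|xi| must be < 1, got {self.xi}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")

    @property
    def similarity(self) -> float:
        """Pairwise cluster similarity s = 1 - xi."""
        return 1.0 - self.xi

    @property
    def n_ec(self) -> int:
        """Input dimension N_EC = 2**K."""
        return 2**self.K

    @property
    def c0(self) -> float:
        """Normalization constant sqrt(N_EC (1 + xi^2))."""
        return float(np.sqrt(self.n_ec * (1.0 + self.xi**2)))

    @property
    def centers(self) -> np.ndarray:
        """The K unit-norm Walsh cluster centers (K x N_EC)."""
        return make_walsh_centers(self)

    @property
    def omega_deg(self) -> float:
        """Pairwise angle between centers, degrees."""
        return pairwise_center_angle(self.xi)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "xi": self.xi,
            "kappa": self.kappa,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "seed": self.seed,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "ClusterSpec":
        return cls(**yaml.safe_load(text))


@dataclass
class PatternSet:
    """A matrix of unit-norm input patterns with integer class labels."""

    X: np.ndarray
    labels: np.ndarray
    provenance: str = "synthetic"
    spec: ClusterSpec | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix of patterns")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("labels length must match number of patterns")
        norms = np.linalg.norm(self.X, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("every pattern row must have unit L2 norm")

    @property
    def n_patterns(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, classes) -> "PatternSet":
        """Restrict to patterns whose label is in ``classes``."""
        mask = np.isin(self.labels, np.asarray(classes))
        return PatternSet(self.X[mask], self.labels[mask],
                          provenance=self.provenance, spec=self.spec)


def make_walsh_centers(spec: ClusterSpec) -> np.ndarray:
    """Construct the K equidistant unit cluster centers.

    Center k has blocks of length ``2^k`` alternating between (1+xi)/c0 and
    (1-xi)/c0 ... concretely, component j of center k is
    (1 + xi * sign_kj)/c0 where sign_kj is the Walsh-type square wave of
    period 2^(k+1).  All centers lie in the positive quadrant, have unit
    norm, and every pair has dot product 1/(1+xi^2).
    """
    K, xi, c0 = spec.K, spec.xi, spec.c0
    n = spec.n_ec
    j = np.arange(n)
    centers = np.empty((K, n))
    for k in range(K):
        # square wave: +1 on the first half of each period, -1 on the second
        block = 2**k
        sign = np.where((j // block) % 2 == 0, 1.0, -1.0)
        centers[k] = (1.0 + xi * sign) / c0
    return centers


def pairwise_center_angle(xi: float) -> float:
    """Angle Omega (degrees) between any two cluster centers.

    cos(Omega) = 1/(1 + xi^2); Omega reaches its maximum of 60 degrees in
    the limit xi -> 1.
    """
    if not abs(xi) <= 1:
        raise ValueError(f"|xi| must be <= 1, got {xi}")
    return float(np.degrees(np.arccos(1.0 / (1.0 + xi**2))))


def _vmf_radial_samples(n: int, dim: int, kappa: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw n samples of the radial component a of a vMF distribution.

    Wood-style rejection sampler: with N = dim,
    b = (N-1)/(sqrt(4 kappa^2 + (N-1)^2) + 2 kappa), psi = (1-b)/(1+b),
    c = kappa psi + (N-1) ln(1 - psi^2); a candidate
    a = (1 - (1+b) z)/(1 - (1-b) z) with z ~ Beta((N-1)/2, (N-1)/2) is kept
    when kappa a + (N-1) ln(1 - psi a) - c >= ln(u), u ~ U[0,1].
    """
    N = dim
    b = (N - 1) / (np.sqrt(4 * kappa**2 + (N - 1) ** 2) + 2 * kappa)
    psi = (1 - b) / (1 + b)
    c = kappa * psi + (N - 1) * np.log(1 - psi**2)

    out = np.empty(n)
    got = 0
    attempts = 0
    while got < n:
        m = max(n - got, 16)
        attempts += m
        if attempts > _MAX_REJECTION_ATTEMPTS * n:
            raise RuntimeError(
                "vMF rejection sampler exceeded the attempt budget; "
                f"kappa={kappa} may be malformed")
        z = rng.beta((N - 1) / 2, (N - 1) / 2, size=m)
        a = (1 - (1 + b) * z) / (1 - (1 - b) * z)
        u = rng.uniform(size=m)
        keep = kappa * a + (N - 1) * np.log(1 - psi * a) - c >= np.log(u)
        acc = a[keep]
        take = min(len(acc), n - got)
        out[got:got + take] = acc[:take]
        got += take
    return out


def sample_vmf_cluster(center: np.ndarray, kappa: float, n: int,
                       seed: int | np.random.Generator) -> np.ndarray:
    """Sample ``n`` unit vectors from a vMF distribution around ``center``.

    Each sample is sqrt(1 - a^2) zeta + a center, where a is the radial
    component from the rejection sampler and zeta is a uniformly random unit
    vector orthogonal to the center; samples are re-normalized to unit norm
    to absorb floating-point drift.
    """
    center = np.asarray(center, dtype=float)
    if not np.isclose(np.linalg.norm(center), 1.0, atol=1e-9):
        raise ValueError("cluster center must have unit L2 norm")
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    if n < 1:
        raise ValueError(f"need n >= 1 samples, got {n}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    dim = center.size
    a = _vmf_radial_samples(n, dim, kappa, rng)

    # tangent directions: gaussian, projected orthogonal to center, normalized
    g = rng.standard_normal((n, dim))
    g -= np.outer(g @ center, center)
    zeta = g / np.linalg.norm(g, axis=1, keepdims=True)

    x = np.sqrt(1 - a[:, None] ** 2) * zeta + a[:, None] * center
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(x < 0):
        logger.warning(
            "vMF samples contain negative components (kappa=%.3g is small); "
            "EC rates are nominally non-negative", kappa)
    return x


def build_dataset(spec: ClusterSpec) -> tuple[PatternSet, PatternSet]:
    """Generate the labeled train/test pattern sets for ``spec``.

    Train and test splits use disjoint RNG streams derived from the base
    seed, so regenerating with a different ``n_train`` leaves the test
    patterns untouched.
    """
    centers = make_walsh_centers(spec)
    sets = []
    for stream, n_per in ((_TRAIN_STREAM, spec.n_train),
                          (_TEST_STREAM, spec.n_test)):
        rng = np.random.default_rng([stream, spec.seed])
        X = np.empty((spec.K * n_per, spec.n_ec))
        labels = np.repeat(np.arange(spec.K), n_per)
        for k in range(spec.K):
            X[k * n_per:(k + 1) * n_per] = sample_vmf_cluster(
                centers[k], spec.kappa, n_per, rng)
        sets.append(PatternSet(X, labels, provenance="synthetic", spec=spec))
    return sets[0], sets[1]


def normalize_external_patterns(raw: np.ndarray,
                                downsample_to: int | None = None,
                                ) -> PatternSet:
    """Adapt an external non-negative image/pattern matrix to unit norm.

    ``raw`` is (P, N) or (P, H, W); square images may optionally be
    downsampled to ``downsample_to`` x ``downsample_to`` pixels by block
    averaging before rows are L2-normalized.  All-zero rows are rejected.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("external patterns must be non-negative")
    if raw.ndim == 3:
        if downsample_to is not None:
            p, h, w = raw.shape
            if h != w or h % downsample_to:
                raise ValueError(
                    f"cannot block-average {h}x{w} images to "
                    f"{downsample_to}x{downsample_to}")
            f = h // downsample_to
            raw = raw.reshape(p, downsample_to, f, downsample_to, f)
            raw = raw.mean(axis=(2, 4))
        raw = raw.reshape(raw.shape[0], -1)
    elif downsample_to is not None:
        raise ValueError("downsampling requires image-shaped (P, H, W) input")

    norms = np.linalg.norm(raw, axis=1)
    if np.any(norms == 0):
        raise ValueError("external patterns contain an all-zero row")
    X = raw / norms[:, None]
    return PatternSet(X, np.zeros(len(X), dtype=int), provenance="external")


def save_patternset(path, patterns: PatternSet) -> None:
    """Save a PatternSet to HDF5 (matrix, labels, spec metadata)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=patterns.X)
        f.create_dataset("labels", data=patterns.labels)
        f.attrs["provenance"] = patterns.provenance
        if patterns.spec is not None:
            f.attrs["spec_yaml"] = patterns.spec.to_yaml()


def load_patternset(path) -> PatternSet:
    """Load a PatternSet previously written by :func:`save_patternset`."""
    import h5py

    with h5py.File(path, "r") as f:
        spec = None
        if "spec_yaml" in f.attrs:
            spec = ClusterSpec.from_yaml(str(f.attrs["spec_yaml"]))
        return PatternSet(f["X"][()], f["labels"][()],
                          provenance=str(f.attrs.get("provenance", "external")),
                          spec=spec)
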