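"""Supervised linear readout on top of converged granule-cell activities.

A single layer of readout units with a rectified-tanh transfer
g(x) = tanh(2 [x]+) is trained by stochastic gradient descent on the
quadratic loss against one-hot labels (classification) or against the input
pattern itself (autoencoder-style reconstruction).  The readout never
backpropagates into the granule-cell network: activities are computed once
per pattern and cached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReadoutModel",
    "g_transfer",
    "train_readout",
    "classification_performance",
    "reconstruction_error",
]


def g_transfer(x: np.ndarray) -> np.ndarray:
    """Rectified hyperbolic tangent g(x) = tanh(2 [x]+)."""
    return np.tanh(2.0 * np.maximum(x, 0.0))


def _g_prime(x: np.ndarray) -> np.ndarray:
    """g'(x) = 2 (1 - tanh^2(2 [x]+)), the update factor of the SGD rule."""
    return 2.0 * (1.0 - g_transfer(x) ** 2)


@dataclass
class ReadoutModel:
    """Trained readout weights, (N_RO x N_DGC)."""

    W_ro: np.ndarray
    classes: np.ndarray | None = None   # class of each readout unit

    def activities(self, dgc_activities: np.ndarray) -> np.ndarray:
        """Readout rates g(W_ro nu) for a (P, N_DGC) activity matrix."""
        return g_transfer(np.asarray(dgc_activities) @ self.W_ro.T)


def train_readout(activities: np.ndarray, targets: np.ndarray,
                  seed: int = 0, eta: float = 0.01, epochs: int = 100,
                  sigma: float = 0.1, labels_are_classes: bool = True,
                  ) -> ReadoutModel:
    """Fit the readout by SGD on the quadratic loss.

    ``targets`` is either a length-P integer label vector (one readout unit
    per class, one-hot targets) or a (P, N_RO) matrix of real-valued targets
    (e.g. the input patterns, for the autoencoder readout).  Weights start
    at sigma * U(0,1); each epoch presents every pattern once in an order
    reshuffled from a dedicated seed; the per-pattern update is

        dW_k = eta (L_k - nu_k^RO) g'(I_k^RO) nu .
    """
    activities = np.asarray(activities, dtype=float)
    rng = np.random.default_rng([5, seed])
    n_patterns, n_dgc = activities.shape

    classes = None
    if labels_are_classes and np.asarray(targets).ndim == 1:
        labels = np.asarray(targets, dtype=int)
        classes = np.unique(labels)
        T = (labels[:, None] == classes[None, :]).astype(float)
    else:
        T = np.asarray(targets, dtype=float)
        if T.shape[0] != n_patterns:
            raise ValueError("targets must have one row per pattern")

    W = sigma * rng.uniform(size=(T.shape[1], n_dgc))
    for _ in range(epochs):
        for mu in rng.permutation(n_patterns):
            nu = activities[mu]
            I = W @ nu
            err = T[mu] - g_transfer(I)
            W += eta * np.outer(err * _g_prime(I), nu)
    return ReadoutModel(W, classes)


def classification_performance(model: ReadoutModel, activities: np.ndarray,
                               labels: np.ndarray) -> float:
    """Percentage of patterns whose most active readout unit is correct.

    Argmax ties resolve to the lowest class index and count as
    classifications.
    """
    if model.classes is None:
        raise ValueError("model was not trained with class labels")
    labels = np.asarray(labels, dtype=int)
    unknown = np.setdiff1d(labels, model.classes)
    if unknown.size:
        raise ValueError(f"labels {unknown.tolist()} outside the class set")
    out = model.activities(activities)
    predicted = model.classes[np.argmax(out, axis=1)]
    return 100.0 * float(np.mean(predicted == labels))


def reconstruction_error(model: ReadoutModel, activities: np.ndarray,
                         patterns: np.ndarray) -> float:
    """Mean squared distance between patterns and their reconstructions."""
    patterns = np.asarray(patterns, dtype=float)
    recon = model.activities(activities)
    if recon.shape != patterns.shape:
        raise ValueError(
            f"reconstruction shape {recon.shape} does not match patterns "
            f"{patterns.shape}")
    return float(np.mean(np.sum((patterns - recon) ** 2, axis=1)))
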