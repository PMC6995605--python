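"""k-means discretization of feature space into microstates.

Conformations from all trajectories are pooled for fitting, but frame
assignments are kept per trajectory so that downstream transition counting
never crosses a trajectory boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .features import FeatureMatrix

__all__ = ["Microstates", "kmeans_fit", "assign"]


@dataclass
class Microstates:
    """Fitted microstate clustering.

    ``assignments`` holds one label sequence per input trajectory, in the
    order the trajectories were supplied.
    """

    centers: np.ndarray               # (k, d)
    inertia: float
    assignments: list[np.ndarray]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("non-finite cluster centers")
        if self.inertia < 0:
            raise ValueError("inertia must be non-negative")
        k = self.centers.shape[0]
        for a in self.assignments:
            if a.size and (a.min() < 0 or a.max() >= k):
                raise ValueError("labels outside [0, k)")

    @property
    def k(self) -> int:
        return self.centers.shape[0]


def _pool(features: FeatureMatrix | list[FeatureMatrix]) -> tuple[np.ndarray, list[int]]:
    if isinstance(features, FeatureMatrix):
        features = [features]
    lengths = [f.n_frames for f in features]
    return np.vstack([f.values for f in features]), lengths


def kmeans_fit(
    features: FeatureMatrix | list[FeatureMatrix],
    k: int = 200,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> Microstates:
    """Lloyd's k-means with k-means++ seeding, best of ``n_init`` restarts.

    The default k = 200 is the standard operating point for microstate
    MSMs of a single protein domain. Deterministic for a fixed seed; empty
    clusters are re-seeded at far points rather than dropped (scikit-learn's
    relocation policy), so exactly k centers are always returned.
    """
    X, lengths = _pool(features)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of frames ({X.shape[0]})")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(X)
    labels = np.asarray(km.labels_, dtype=np.int64)
    splits = np.cumsum(lengths)[:-1]
    return Microstates(
        centers=km.cluster_centers_,
        inertia=float(km.inertia_),
        assignments=[a.copy() for a in np.split(labels, splits)],
    )


def assign(features: FeatureMatrix | np.ndarray, states: Microstates) -> np.ndarray:
    """Nearest-center (Euclidean) microstate label per frame.

    Ties are broken toward the lowest center index.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.ndim != 2 or X.shape[1] != states.centers.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1] if X.ndim == 2 else X.shape} does not "
            f"match center dimension {states.centers.shape[1]}"
        )
    # direct differences (not the inner-product expansion) so exactly
    # equidistant frames tie exactly and argmin's first-index rule applies
    from scipy.spatial.distance import cdist

    d2 = cdist(X, states.centers, metric="sqeuclidean")
    return np.argmin(d2, axis=1).astype(np.int64)
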