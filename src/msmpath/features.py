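"""Feature representation for conformational clustering.

Pairwise Cα distances are the geometric features (rotation/translation
invariant by construction); PCA reduces them to the leading components of
structural variation before k-means discretization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from .structure import Trajectory, _resolve_mask

__all__ = ["FeatureMatrix", "PCAModel", "pairwise_ca_distances", "fit_pca"]


@dataclass
class FeatureMatrix:
    """frames × features array with per-column descriptors.

    Descriptors are ``(i, j)`` particle-index pairs for distance features
    or ``("PC", k)`` for principal components.
    """

    values: np.ndarray
    descriptors: list[tuple]
    centered: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("feature matrix must be 2-D (frames x features)")
        if not np.all(np.isfinite(v)):
            bad = np.nonzero(~np.all(np.isfinite(v), axis=1))[0]
            raise ValueError(f"non-finite features in frames {bad[:5].tolist()}")
        if len(self.descriptors) != v.shape[1]:
            raise ValueError("descriptor count must equal column count")
        self.values = v

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def pairwise_ca_distances(
    traj: Trajectory,
    mask: np.ndarray | None = None,
    stride_pairs: int = 1,
) -> FeatureMatrix:
    """All-pairs inter-particle distances per frame, in Angstrom.

    For n selected particles the matrix has n(n−1)/2 columns ordered
    lexicographically in (i, j), i < j (indices into the selection).
    ``stride_pairs = k`` restricts to every k-th selected particle before
    forming pairs, for large systems.
    """
    idx = _resolve_mask(mask, traj.n_particles)
    if stride_pairs > 1:
        idx = idx[::stride_pairs]
    if idx.size < 2:
        raise ValueError("need at least 2 particles for distance features")
    coords = traj.coordinates[:, idx, :]
    ii, jj = np.triu_indices(idx.size, k=1)
    diff = coords[:, ii, :] - coords[:, jj, :]
    d = np.sqrt(np.sum(diff**2, axis=-1))
    descriptors = [(int(idx[a]), int(idx[b])) for a, b in zip(ii, jj)]
    return FeatureMatrix(values=d, descriptors=descriptors)


@dataclass
class PCAModel:
    """Fitted PCA: mean, orthonormal components (rows), variance fractions."""

    mean: np.ndarray
    components: np.ndarray            # (n_components, n_features)
    explained_variance_ratio: np.ndarray

    def transform(self, features: FeatureMatrix | np.ndarray) -> FeatureMatrix:
        X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
        Y = (X - self.mean) @ self.components.T
        return FeatureMatrix(
            values=Y,
            descriptors=[("PC", k) for k in range(self.components.shape[0])],
            centered=True,
        )

    def inverse_transform(self, projected: FeatureMatrix | np.ndarray) -> np.ndarray:
        Y = projected.values if isinstance(projected, FeatureMatrix) else np.asarray(projected)
        return Y @ self.components + self.mean


def fit_pca(
    features: FeatureMatrix,
    n_components: int | None = None,
    variance_target: float = 0.90,
    max_components: int = 10,
) -> PCAModel:
    """PCA on mean-centered (not variance-scaled) features.

    With ``n_components=None`` the smallest count explaining at least
    ``variance_target`` of the variance is used, capped at
    ``max_components`` — a reproducible data-driven default.
    """
    X = features.values
    rank = min(X.shape[0] - 1 if X.shape[0] > 1 else 1, X.shape[1])
    if n_components is not None:
        if n_components < 1 or n_components > min(X.shape):
            raise ValueError(
                f"n_components must be in [1, {min(X.shape)}] "
                f"(achievable rank {rank})"
            )
        k = n_components
    else:
        k = min(max_components, rank)
    sk = _SKPCA(n_components=k, svd_solver="auto", random_state=0)
    sk.fit(X)
    if n_components is None:
        cum = np.cumsum(sk.explained_variance_ratio_)
        k_eff = int(np.searchsorted(cum, variance_target) + 1)
        k_eff = min(k_eff, k)
        return PCAModel(
            mean=sk.mean_,
            components=sk.components_[:k_eff],
            explained_variance_ratio=sk.explained_variance_ratio_[:k_eff],
        )
    return PCAModel(
        mean=sk.mean_,
        components=sk.components_,
        explained_variance_ratio=sk.explained_variance_ratio_,
    )
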