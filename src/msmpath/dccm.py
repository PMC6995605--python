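"""Dynamical cross-correlation matrix (DCCM) of Cα displacement vectors.

The correlation coefficient between the motions of particles i and j is

    C_ij = ⟨Δr_i · Δr_j⟩ / [⟨Δr_i · Δr_i⟩ ⟨Δr_j · Δr_j⟩]^1/2,

with Δr the displacement about the mean position and ⟨…⟩ the trajectory
average. Positive C_ij means the residues move in the same direction,
negative values anti-correlated motion. Correlations use the full 3-D
vector dot product. State-conditional maps (frames of one macrostate,
re-aligned to their own mean) expose how coupling changes between
conformational states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import (
    DisplacementField,
    Trajectory,
    displacement_field,
    superpose_trajectory,
)

__all__ = ["DCCMatrix", "dcc_matrix", "state_conditional_dccm"]


@dataclass
class DCCMatrix:
    """Symmetric per-particle-pair correlation coefficients in [−1, 1].

    Particles with zero fluctuation have no defined correlation; their
    rows/columns are NaN and flagged in ``undefined`` instead of letting
    NaN propagate silently.
    """

    values: np.ndarray                 # (n, n)
    particle_index: np.ndarray
    undefined: np.ndarray              # (n,) bool
    subset: str = "all frames"

    def __post_init__(self) -> None:
        V = self.values
        ok = ~self.undefined
        sub = V[np.ix_(ok, ok)]
        if sub.size:
            if np.abs(sub - sub.T).max() > 1e-10:
                raise ValueError("DCC matrix must be symmetric")
            if np.abs(np.diag(sub) - 1.0).max() > 1e-10:
                raise ValueError("DCC diagonal must be 1 for fluctuating particles")
            if sub.min() < -1 - 1e-10 or sub.max() > 1 + 1e-10:
                raise ValueError("DCC entries must lie in [-1, 1]")


def dcc_matrix(fld: DisplacementField, subset: str = "all frames") -> DCCMatrix:
    """DCCM from a mean-free displacement field."""
    d = fld.values
    if d.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    n_frames = d.shape[0]
    G = np.einsum("tix,tjx->ij", d, d) / n_frames       # ⟨Δr_i · Δr_j⟩
    var = np.diag(G).copy()
    undefined = var <= 0
    denom = np.sqrt(np.where(undefined, 1.0, var))
    C = G / denom[:, None] / denom[None, :]
    C[undefined, :] = np.nan
    C[:, undefined] = np.nan
    ok = ~undefined
    C[np.ix_(ok, ok)] = np.clip(C[np.ix_(ok, ok)], -1.0, 1.0)
    C = 0.5 * (C + C.T)                                  # exact symmetry
    n = C.shape[0]
    C[np.arange(n), np.arange(n)] = np.where(undefined, np.nan, 1.0)
    return DCCMatrix(values=C, particle_index=fld.particle_index, undefined=undefined, subset=subset)


def state_conditional_dccm(
    traj: Trajectory,
    frame_subset: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    subset_name: str | None = None,
) -> DCCMatrix:
    """DCCM of a frame subset, superposed to the subset's own mean structure.

    Conditioning on (for example) the frames assigned to one macrostate
    and re-aligning within the subset avoids inheriting global-alignment
    artifacts from other states.
    """
    if frame_subset is None:
        frame_subset = np.arange(traj.n_frames)
    frame_subset = np.asarray(frame_subset)
    if frame_subset.dtype == bool:
        frame_subset = np.nonzero(frame_subset)[0]
    if frame_subset.size < 2:
        raise ValueError("frame subset must contain at least 2 frames")
    sub = Trajectory(traj.coordinates[frame_subset], traj.frame_interval, traj.particle_labels)
    aligned = superpose_trajectory(sub, mask=mask)
    mean_structure = aligned.coordinates.mean(axis=0)
    aligned = superpose_trajectory(aligned, reference=mean_structure, mask=mask)
    fld = displacement_field(aligned, mask=mask)
    name = subset_name or f"{frame_subset.size} selected frames"
    return dcc_matrix(fld, subset=name)
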