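"""Rigid-body superposition and per-frame / per-particle structural metrics.

Implements the classical observables of trajectory analysis: least-squares
(Kabsch) superposition, RMSD time series, RMSF over a frame window, radius
of gyration, and mean-referenced displacement fields (the input of the
dynamical cross-correlation matrix). All computations are mass-uniform:
the analysis operates on Cα-level coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "DisplacementField",
    "superpose",
    "superpose_trajectory",
    "rmsd",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
    "displacement_field",
]


@dataclass
class Trajectory:
    """Coordinate trajectory: frames × particles × 3, in Angstrom.

    ``particle_labels`` carries residue numbers (1-based, PDB convention)
    when the trajectory comes from a structure; synthetic trajectories use
    sequential labels.
    """

    coordinates: np.ndarray
    frame_interval: float = 1.0          # ns
    particle_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError(f"coordinates must be (frames, particles, 3), got {c.shape}")
        if c.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if not np.all(np.isfinite(c)):
            raise ValueError("coordinates contain non-finite values")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.coordinates = c
        if self.particle_labels is None:
            self.particle_labels = np.arange(1, c.shape[1] + 1)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[1]

    def select_residues(self, first: int, last: int) -> np.ndarray:
        """Index mask for an inclusive residue-number range (e.g. 10–124)."""
        labels = np.asarray(self.particle_labels)
        mask = np.nonzero((labels >= first) & (labels <= last))[0]
        if mask.size == 0:
            raise ValueError(f"no particles with residue numbers in [{first}, {last}]")
        return mask


def _resolve_mask(mask: np.ndarray | None, n_particles: int) -> np.ndarray:
    if mask is None:
        return np.arange(n_particles)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        mask = np.nonzero(mask)[0]
    if mask.size == 0:
        raise ValueError("empty selection mask")
    if mask.min() < 0 or mask.max() >= n_particles:
        raise ValueError("mask indices outside particle range")
    return mask


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def _kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation mapping centered P onto centered Q.

    Closed-form via the 3×3 SVD of the covariance, with the determinant
    correction so reflections are never returned.
    """
    H = P.T @ Q
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of one frame onto a reference.

    The transform is fitted on ``mask`` (>= 3 non-collinear particles) and
    applied to all particles of ``mobile``.

    Returns
    -------
    (transformed, rotation, translation) with
    ``transformed = (mobile - com_mobile) @ R.T + com_reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = _resolve_mask(mask, mobile.shape[0])
    if idx.size < 3:
        raise ValueError("superposition mask must select at least 3 particles")
    P = mobile[idx]
    Q = reference[idx]
    mu_p = P.mean(axis=0)
    mu_q = Q.mean(axis=0)
    Pc, Qc = P - mu_p, Q - mu_q
    # rank check: collinear (or coincident) selections leave the rotation
    # about the degenerate axis undetermined
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2:
        raise ValueError(
            "degenerate selection: fit particles are collinear (covariance rank < 2), "
            "the optimal rotation is not unique"
        )
    R = _kabsch_rotation(Pc, Qc)
    transformed = (mobile - mu_p) @ R.T + mu_q
    translation = mu_q - mu_p @ R.T
    return transformed, R, translation


def superpose_trajectory(
    traj: Trajectory,
    reference: np.ndarray | None = None,
    mask: np.ndarray | None = None,
) -> Trajectory:
    """Superpose every frame onto ``reference`` (default: the first frame)."""
    ref = traj.coordinates[0] if reference is None else np.asarray(reference, dtype=float)
    out = np.empty_like(traj.coordinates)
    for t in range(traj.n_frames):
        out[t], _, _ = superpose(traj.coordinates[t], ref, mask)
    return Trajectory(out, traj.frame_interval, traj.particle_labels)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD between two equal-shape frames (no fitting)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    superpose_frames: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) to a reference, after per-frame superposition.

    Both the rigid-body fit and the deviation are evaluated on ``mask``
    (default: all particles), matching Cα-selection analyses.
    """
    ref = traj.coordinates[0] if reference is None else np.asarray(reference, dtype=float)
    idx = _resolve_mask(mask, traj.n_particles)
    out = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        frame = traj.coordinates[t]
        if superpose_frames:
            frame, _, _ = superpose(frame, ref, idx)
        out[t] = rmsd(frame[idx], ref[idx])
    return out


def rmsf(
    traj: Trajectory,
    mask: np.ndarray | None = None,
    window: tuple[int, int] | None = None,
    align: str = "mean",
) -> np.ndarray:
    """Per-particle root-mean-square fluctuation over a frame window.

    Frames are first superposed: with ``align='mean'`` (default) onto the
    window-mean structure (frames are aligned to the first frame, the mean
    is formed, and all frames re-aligned to it once); with ``align='first'``
    onto the first window frame. Fluctuations are then taken about the
    per-particle mean position.
    """
    idx = _resolve_mask(mask, traj.n_particles)
    lo, hi = (0, traj.n_frames) if window is None else window
    coords = traj.coordinates[lo:hi, idx, :]
    if coords.shape[0] < 2:
        raise ValueError("RMSF window must contain at least 2 frames")
    sub = Trajectory(coords, traj.frame_interval)
    aligned = superpose_trajectory(sub).coordinates
    if align == "mean":
        mean_structure = aligned.mean(axis=0)
        sub2 = Trajectory(aligned, traj.frame_interval)
        aligned = superpose_trajectory(sub2, reference=mean_structure).coordinates
    elif align != "first":
        raise ValueError("align must be 'mean' or 'first'")
    mean_pos = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean_pos) ** 2, axis=-1), axis=0))


def radius_of_gyration(traj: Trajectory, mask: np.ndarray | None = None) -> np.ndarray:
    """Mass-uniform radius of gyration per frame (Angstrom)."""
    idx = _resolve_mask(mask, traj.n_particles)
    coords = traj.coordinates[:, idx, :]
    com = coords.mean(axis=1, keepdims=True)
    return np.sqrt(np.mean(np.sum((coords - com) ** 2, axis=-1), axis=1))


@dataclass
class DisplacementField:
    """Per-frame, per-particle displacements about the mean position.

    ``values[t, i]`` = r_i(t) − ⟨r_i⟩, so the time mean vanishes per
    particle by construction. Frames must be superposed to a common
    reference before the field is built; otherwise rigid-body motion
    contaminates the correlations computed from it.
    """

    values: np.ndarray               # (frames, particles, 3)
    particle_index: np.ndarray = field(default=None)  # original particle indices

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] < 2:
            raise ValueError("displacement field needs >= 2 frames of (particles, 3) vectors")
        mean_norm = np.abs(v.mean(axis=0)).max()
        if mean_norm > 1e-9:
            raise ValueError(f"displacement field not mean-free (max |mean| = {mean_norm:.3g})")
        self.values = v
        if self.particle_index is None:
            self.particle_index = np.arange(v.shape[1])


def displacement_field(traj: Trajectory, mask: np.ndarray | None = None) -> DisplacementField:
    """Δr_i(t) = r_i(t) − ⟨r_i⟩ on the selected particles.

    The trajectory is assumed already superposed to a common reference.
    """
    if traj.n_frames < 2:
        raise ValueError("displacement field requires at least 2 frames")
    idx = _resolve_mask(mask, traj.n_particles)
    coords = traj.coordinates[:, idx, :]
    delta = coords - coords.mean(axis=0, keepdims=True)
    return DisplacementField(values=delta, particle_index=idx)
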