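"""Kinetic coarse-graining: PCCA+ lumping and macrostate-level observables.

PCCA+ (Perron Cluster Cluster Analysis) assigns each microstate a fuzzy
membership in a small number of metastable macrostates using the dominant
right eigenvectors of a reversible transition matrix: in the space spanned
by the top m eigenvectors the microstates lie (approximately) inside a
simplex whose vertices are the pure metastable states, and memberships are
the barycentric coordinates with respect to those vertices (inner-simplex
algorithm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix
from .msm import TransitionModel

__all__ = [
    "MacrostateLumping",
    "pcca_plus",
    "macrostate_populations",
    "macrostate_dtrajs",
    "representative_frames",
    "FreeEnergySurface",
    "free_energy_surface",
]


@dataclass
class MacrostateLumping:
    """Fuzzy and crisp assignment of microstates to macrostates.

    ``memberships[i, a]`` is the degree to which microstate ``i`` belongs
    to macrostate ``a`` (rows sum to 1); ``crisp_map[i]`` is the argmax.
    ``populations`` are macrostate equilibrium probabilities, i.e. sums of
    the microstate stationary distribution under the crisp map.
    """

    memberships: np.ndarray            # (n_micro, n_macro)
    crisp_map: np.ndarray              # (n_micro,) int
    populations: np.ndarray            # (n_macro,)
    active_set: np.ndarray             # original microstate labels

    def __post_init__(self) -> None:
        M = self.memberships
        if np.any(M < -1e-10):
            raise ValueError("negative memberships")
        if np.abs(M.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("membership rows must sum to 1")
        if not np.array_equal(self.crisp_map, np.argmax(M, axis=1)):
            raise ValueError("crisp_map inconsistent with memberships")
        if abs(self.populations.sum() - 1.0) > 1e-10:
            raise ValueError("macrostate populations must sum to 1")

    @property
    def n_macrostates(self) -> int:
        return self.memberships.shape[1]


def _inner_simplex_vertices(X: np.ndarray) -> np.ndarray:
    """Indices of m rows of X spanning the largest simplex (Weber's scheme).

    First vertex: the row farthest from the row-mean; subsequent vertices:
    the row with the largest residual after projecting out the directions
    of the vertices already chosen.
    """
    n, m = X.shape
    vertices = np.empty(m, dtype=np.int64)
    vertices[0] = int(np.argmax(np.linalg.norm(X, axis=1)))
    # shift the first vertex to the origin, then greedily take the row with
    # the largest residual norm, projecting out each chosen direction
    R = X - X[vertices[0]]
    for k in range(1, m):
        norms = np.linalg.norm(R, axis=1)
        vertices[k] = int(np.argmax(norms))
        if norms[vertices[k]] < 1e-14:
            # degenerate: remaining rows coincide; pick any unused row
            used = set(vertices[: k + 1].tolist())
            vertices[k] = next(i for i in range(n) if i not in used)
            continue
        u = R[vertices[k]] / norms[vertices[k]]
        R = R - np.outer(R @ u, u)
    return vertices


def pcca_plus(model: TransitionModel, n_macrostates: int) -> MacrostateLumping:
    """PCCA+ lumping of a reversible transition model into macrostates.

    Requires a reversible model (real spectrum). Memberships are computed
    as barycentric coordinates in the top-``n_macrostates`` eigenvector
    space, clipped at zero and renormalized; the crisp map is the argmax.
    """
    if not model.reversible:
        raise ValueError(
            "PCCA+ requires a reversible transition model (real spectrum); "
            "estimate with reversible=True"
        )
    m = n_macrostates
    if m < 2:
        raise ValueError("n_macrostates must be >= 2")
    if m > model.n_states:
        raise ValueError("n_macrostates cannot exceed the number of microstates")
    lam = np.real(model.eigenvalues)
    if m < model.n_states and lam[m] > 1.0 - 1e-12 and np.isclose(lam[m], lam[m - 1]):
        warnings.warn(
            "eigenvalue at the cut is degenerate with the included block; "
            "macrostate count may be ill-determined", stacklevel=2,
        )
    X = np.real(model.right_eigenvectors[:, :m]).copy()
    X[:, 0] = 1.0                              # exact constant first column
    vertices = _inner_simplex_vertices(X)
    A = np.linalg.inv(X[vertices])
    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    chi = chi / chi.sum(axis=1, keepdims=True)
    crisp = np.argmax(chi, axis=1)
    present = np.unique(crisp)
    if present.size < m:
        raise ValueError(
            f"PCCA+ produced only {present.size} non-empty macrostates out of {m}; "
            "the spectrum has no metastable gap at this count"
        )
    pops = np.zeros(m)
    np.add.at(pops, crisp, model.stationary)
    return MacrostateLumping(
        memberships=chi,
        crisp_map=crisp,
        populations=pops,
        active_set=model.active_set,
    )


def macrostate_populations(
    lumping: MacrostateLumping,
    model: TransitionModel,
    fuzzy: bool = False,
) -> np.ndarray:
    """Equilibrium probability per macrostate: Π_A = Σ_{i∈A} π_i.

    ``fuzzy=True`` weights π by the fuzzy memberships instead of the
    crisp map.
    """
    if lumping.memberships.shape[0] != model.n_states:
        raise ValueError("lumping and model disagree on microstate count")
    if fuzzy:
        return model.stationary @ lumping.memberships
    pops = np.zeros(lumping.n_macrostates)
    np.add.at(pops, lumping.crisp_map, model.stationary)
    return pops


def macrostate_dtrajs(lumping: MacrostateLumping, dtrajs) -> list[np.ndarray]:
    """Map microstate label sequences to macrostate label sequences.

    Frames in microstates outside the active set get label −1.
    """
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    n_labels = int(max(d.max() for d in dtrajs)) + 1
    lookup = np.full(max(n_labels, int(lumping.active_set.max()) + 1), -1, dtype=np.int64)
    lookup[lumping.active_set] = lumping.crisp_map
    return [lookup[np.asarray(d, dtype=np.int64)] for d in dtrajs]


def representative_frames(
    lumping: MacrostateLumping,
    dtrajs,
    features: FeatureMatrix | np.ndarray,
    model: TransitionModel,
    n_samples: int = 100,
    seed: int | None = None,
) -> dict[int, dict]:
    """Sample conformations per macrostate and pick a medoid representative.

    For each macrostate: a uniform random sample (without replacement,
    clamped to the available count with a warning) of the frames whose
    microstate maps to it, plus the frame nearest to the macrostate's
    population-weighted feature mean ("medoid", the representative
    structure). Returns ``{macrostate: {"frames", "medoid"}}`` with global
    frame indices into the concatenated trajectories. Macrostates with no
    assigned frames are reported with empty entries.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    macro = np.concatenate(macrostate_dtrajs(lumping, dtrajs))
    if macro.shape[0] != X.shape[0]:
        raise ValueError("features and discrete trajectories disagree on frame count")
    micro = np.concatenate(
        [np.asarray(d) for d in (dtrajs if not isinstance(dtrajs, np.ndarray) else [dtrajs])]
    )
    rng = np.random.default_rng(seed)
    # per-frame stationary weight: pi(microstate) / count(microstate)
    counts = np.bincount(micro, minlength=int(lumping.active_set.max()) + 1).astype(float)
    pi_full = np.zeros_like(counts)
    pi_full[lumping.active_set] = model.stationary
    with np.errstate(invalid="ignore", divide="ignore"):
        frame_w = np.where(counts[micro] > 0, pi_full[micro] / counts[micro], 0.0)
    out: dict[int, dict] = {}
    for a in range(lumping.n_macrostates):
        members = np.nonzero(macro == a)[0]
        if members.size == 0:
            warnings.warn(f"macrostate {a} has no assigned frames", stacklevel=2)
            out[a] = {"frames": np.array([], dtype=np.int64), "medoid": None}
            continue
        take = n_samples
        if take > members.size:
            warnings.warn(
                f"macrostate {a}: requested {n_samples} samples, only "
                f"{members.size} frames available; returning all", stacklevel=2,
            )
            take = members.size
        sample = rng.choice(members, size=take, replace=False)
        w = frame_w[members]
        w = w / w.sum() if w.sum() > 0 else np.full(members.size, 1.0 / members.size)
        center = w @ X[members]
        medoid = members[int(np.argmin(np.linalg.norm(X[members] - center, axis=1)))]
        out[a] = {"frames": np.sort(sample), "medoid": int(medoid)}
    return out


# ---------------------------------------------------------------------------
# Free-energy surfaces
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    """2-D free-energy surface F = −ln p over a coordinate grid, in kT.

    The gauge is fixed so the minimum over populated bins is 0; empty bins
    are masked (``populated == False``) rather than set to infinity.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray            # (nx, ny), NaN on empty bins
    populations: np.ndarray            # (nx, ny) probability mass
    populated: np.ndarray              # bool mask
    macrostate_locations: np.ndarray | None = None   # (n_macro, 2) weighted centroids


def free_energy_surface(
    projected: np.ndarray,
    weights: np.ndarray | None = None,
    bins: int | tuple[int, int] = 40,
    macrostate_labels: np.ndarray | None = None,
) -> FreeEnergySurface:
    """Boltzmann inversion of a weighted 2-D histogram: F_bin = −ln(p_bin).

    ``projected`` is (frames, 2) — typically the first two PCs. ``weights``
    are per-frame stationary weights (π(microstate)/count(microstate)) so
    the surface reflects equilibrium rather than raw sampling; ``None``
    gives the raw histogram. With ``macrostate_labels`` (per frame, −1 to
    skip) the weighted centroid of each macrostate is recorded, mirroring
    the usual "average location of each macrostate" annotation.
    """
    P = np.asarray(projected, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("projected coordinates must be (frames, 2)")
    if np.isscalar(bins):
        bins = (int(bins), int(bins))
    if bins[0] < 2 or bins[1] < 2:
        raise ValueError("need at least 2 bins per axis")
    w = np.ones(P.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    H, xe, ye = np.histogram2d(P[:, 0], P[:, 1], bins=bins, weights=w)
    p = H / H.sum()
    populated = p > 0
    if populated.sum() <= 1:
        warnings.warn("all frames fall in a single bin; surface is flat", stacklevel=2)
    F = np.full_like(p, np.nan)
    with np.errstate(divide="ignore"):
        F[populated] = -np.log(p[populated])
    F[populated] -= np.nanmin(F[populated])
    locations = None
    if macrostate_labels is not None:
        labels = np.asarray(macrostate_labels)
        n_macro = int(labels.max()) + 1
        locations = np.full((n_macro, 2), np.nan)
        for a in range(n_macro):
            sel = labels == a
            if sel.any():
                ws = w[sel] / w[sel].sum()
                locations[a] = ws @ P[sel]
    return FreeEnergySurface(
        x_edges=xe, y_edges=ye, free_energy=F,
        populations=p, populated=populated,
        macrostate_locations=locations,
    )
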