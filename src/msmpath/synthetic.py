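"""Synthetic trajectory generators with analytic kinetic ground truth.

Every downstream stage of the pipeline (featurization, clustering, MSM
estimation, lumping, TPT) is exercised against data whose kinetics are
known exactly: discrete trajectories sampled from an explicit transition
matrix, and continuous paths from overdamped Langevin dynamics on a
multi-well potential whose Boltzmann weights are available by quadrature.
A low-dimensional path can then be embedded as a 3-D multi-particle
"structure" trajectory so that the geometric feature pipeline sees input
with the same shape as real molecular data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

__all__ = [
    "GroundTruthChain",
    "PotentialSpec",
    "EmbeddedTrajectory",
    "sample_markov_chain",
    "simulate_brownian",
    "embed_path_as_structure",
    "double_well_spec",
]


# ---------------------------------------------------------------------------
# Ground-truth Markov chain
# ---------------------------------------------------------------------------

def _validate_stochastic(T: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {T.shape}")
    if np.any(T < 0):
        raise ValueError("transition matrix has negative entries")
    rowsums = T.sum(axis=1)
    if not np.allclose(rowsums, 1.0, atol=1e-10):
        raise ValueError(f"rows must sum to 1 (max deviation {np.abs(rowsums - 1).max():.3g})")
    return T


def _stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Left eigenvector of eigenvalue 1, normalized to a probability vector."""
    w, vl = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(vl[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass(frozen=True)
class GroundTruthChain:
    """A known discrete-time Markov chain used as a generating model.

    Parameters
    ----------
    transition_matrix
        Row-stochastic square matrix ``T``; ``T[i, j]`` is the probability
        of jumping from state ``i`` to state ``j`` in one step.
    lag_unit
        Physical time per chain step (arbitrary units, default 1.0).
    """

    transition_matrix: np.ndarray
    lag_unit: float = 1.0
    stationary: np.ndarray = field(init=False, repr=False)
    eigenvalues: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        T = _validate_stochastic(self.transition_matrix)
        object.__setattr__(self, "transition_matrix", T)
        pi = _stationary_distribution(T)
        if not np.allclose(pi @ T, pi, atol=1e-10):
            raise ValueError("stationary vector does not satisfy pi T = pi")
        w = np.linalg.eigvals(T)
        # report a real spectrum sorted descending; complex parts only arise
        # for non-reversible chains and are reported by real part
        w = np.sort_complex(w)[::-1].real
        object.__setattr__(self, "stationary", pi)
        object.__setattr__(self, "eigenvalues", w)

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def implied_timescales(self) -> np.ndarray:
        """Analytic relaxation timescales −lag_unit/ln λ_i for i ≥ 2."""
        lam = self.eigenvalues[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            ts = -self.lag_unit / np.log(lam)
        ts[lam <= 0] = np.nan
        ts[np.isclose(lam, 1.0)] = np.inf
        return ts

    def occupancy_std(self, n_steps: int) -> np.ndarray:
        """Analytic standard error of empirical state occupancies.

        For ``n_steps`` correlated samples of the chain at equilibrium,
        Var(freq_i) ≈ [π_i(1−π_i) + 2 Σ_{k≥1} (π_i (Tᵏ)_{ii} − π_i²)] / n —
        the multinomial variance inflated by the chain's integrated
        autocorrelation. The series is summed until the increments are
        negligible.
        """
        T = self.transition_matrix
        pi = self.stationary
        var = pi * (1.0 - pi)
        Tk = T.copy()
        for _ in range(100 * T.shape[0] + 1000):
            term = pi * np.diag(Tk) - pi**2
            var = var + 2.0 * term
            if np.abs(term).max() < 1e-12 * np.abs(var).max():
                break
            Tk = Tk @ T
        return np.sqrt(np.maximum(var, 0.0) / n_steps)


def sample_markov_chain(
    chain: GroundTruthChain | np.ndarray,
    n_steps: int,
    start: int = 0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Sample a state sequence of length ``n_steps`` from a Markov chain.

    Transitions are drawn row-wise from the chain's transition matrix with
    a seeded generator, so the output is bitwise reproducible per seed.
    """
    if not isinstance(chain, GroundTruthChain):
        chain = GroundTruthChain(np.asarray(chain, dtype=float))
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    n = chain.n_states
    if not 0 <= start < n:
        raise ValueError(f"start state {start} outside [0, {n})")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(chain.transition_matrix, axis=1)
    cum[:, -1] = 1.0  # guard against rounding in searchsorted
    u = rng.random(n_steps - 1)
    out = np.empty(n_steps, dtype=np.int64)
    s = start
    out[0] = s
    for t in range(1, n_steps):
        s = int(np.searchsorted(cum[s], u[t - 1], side="right"))
        out[t] = s
    return out


# ---------------------------------------------------------------------------
# Brownian dynamics on an analytic multi-well potential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PotentialSpec:
    """Multi-well potential: Gaussian wells on a quadratic confining background.

    ``U(x) = 0.5 * k_background * |x|^2 − Σ_m depth_m * exp(−|x−c_m|² / (2 w_m²))``

    Energies are in kT units, lengths in the (arbitrary) length unit of the
    latent space. The Gaussian-well form keeps the gradient closed-form and
    makes Boltzmann basin weights computable by quadrature, which the tests
    use as an independent oracle.
    """

    well_centers: np.ndarray          # (n_wells, dim)
    well_depths: np.ndarray           # (n_wells,), kT
    well_widths: np.ndarray           # (n_wells,), length
    k_background: float = 2.0         # kT / length^2
    diffusion_coefficient: float = 1.0
    kT: float = 1.0

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.well_centers, dtype=float))
        if c.shape[0] < 1:
            raise ValueError("at least one well required")
        d = np.asarray(self.well_depths, dtype=float)
        w = np.asarray(self.well_widths, dtype=float)
        if d.shape[0] != c.shape[0] or w.shape[0] != c.shape[0]:
            raise ValueError("well_centers, well_depths, well_widths must agree in length")
        if np.any(w <= 0):
            raise ValueError("well widths must be positive")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be positive")
        object.__setattr__(self, "well_centers", c)
        object.__setattr__(self, "well_depths", d)
        object.__setattr__(self, "well_widths", w)

    @property
    def dim(self) -> int:
        return self.well_centers.shape[1]

    def energy(self, x: np.ndarray) -> np.ndarray:
        """U(x) in kT units; x has shape (..., dim)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        u = 0.5 * self.k_background * np.sum(x**2, axis=-1)
        for c, d, w in zip(self.well_centers, self.well_depths, self.well_widths):
            r2 = np.sum((x - c) ** 2, axis=-1)
            u = u - d * np.exp(-r2 / (2.0 * w**2))
        return u

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = self.k_background * x
        for c, d, w in zip(self.well_centers, self.well_depths, self.well_widths):
            diff = x - c
            r2 = np.sum(diff**2, axis=-1, keepdims=True)
            g = g + (d / w**2) * diff * np.exp(-r2 / (2.0 * w**2))
        return g

    def max_gradient_bound(self) -> float:
        """Upper bound on |∇U| over the region containing the wells."""
        g_wells = float(np.sum(self.well_depths / self.well_widths) * np.exp(-0.5))
        extent = float(np.max(np.linalg.norm(self.well_centers, axis=1), initial=0.0))
        reach = extent + 3.0 * float(np.max(self.well_widths))
        return self.k_background * reach + g_wells

    def min_well_spacing(self) -> float:
        c = self.well_centers
        if c.shape[0] < 2:
            return float(2.0 * np.max(self.well_widths))
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        return float(d[np.triu_indices(c.shape[0], 1)].min())

    def basin_weights(self) -> np.ndarray:
        """Exact Boltzmann weight of each well's basin by quadrature (1-D only).

        Basins are separated at the midpoints between adjacent well centers.
        """
        if self.dim != 1:
            raise NotImplementedError("quadrature basin weights implemented for 1-D potentials")
        centers = np.sort(self.well_centers[:, 0])
        order = np.argsort(self.well_centers[:, 0])
        edges = np.concatenate(
            [[-np.inf], 0.5 * (centers[1:] + centers[:-1]), [np.inf]]
        )
        weights = np.empty(len(centers))
        for i in range(len(centers)):
            lo = edges[i] if np.isfinite(edges[i]) else centers[i] - 30.0
            hi = edges[i + 1] if np.isfinite(edges[i + 1]) else centers[i] + 30.0
            weights[i], _ = integrate.quad(
                lambda x: np.exp(-self.energy([[x]])[0] / self.kT), lo, hi, limit=200
            )
        out = np.empty_like(weights)
        out[order] = weights  # back to the spec's well order
        return out / out.sum()


def double_well_spec(delta_kT: float = 1.0) -> PotentialSpec:
    """The package's standard 1-D double well with basin free-energy gap ``delta_kT``.

    Wells at x = ±1.5, widths 0.5, shallow-well depth 5.5 kT on a quadratic
    background k = 2 kT: barrier ≈ 3 kT above the shallow well, giving
    interbasin relaxation of order 10² frame intervals at the default
    dt = 0.01 / stride 10 sampling. ``delta_kT`` is the *free-energy*
    difference between the basins: the Gaussian depth offset is calibrated
    by quadrature so the Boltzmann basin weights are exactly
    e^delta_kT : 1 (a raw depth offset would be biased by the wells'
    unequal curvatures).
    """
    from scipy.optimize import brentq

    centers = np.array([[-1.5], [1.5]])
    widths = np.array([0.5, 0.5])
    base_depth = 5.5

    def gap(extra: float) -> float:
        spec = PotentialSpec(
            well_centers=centers,
            well_depths=np.array([base_depth, base_depth + extra]),
            well_widths=widths,
            k_background=2.0,
        )
        w = spec.basin_weights()
        return float(np.log(w[1] / w[0])) - delta_kT

    if abs(delta_kT) < 1e-12:
        extra = 0.0
    else:
        lo, hi = sorted((0.0, 2.0 * delta_kT + np.sign(delta_kT)))
        extra = brentq(gap, lo, hi, xtol=1e-10)
    return PotentialSpec(
        well_centers=centers,
        well_depths=np.array([base_depth, base_depth + extra]),
        well_widths=widths,
        k_background=2.0,
    )


def simulate_brownian(
    potential: PotentialSpec,
    n_steps: int,
    dt: float = 0.01,
    x0: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
    stride: int = 1,
    domain_bound: float = 50.0,
) -> np.ndarray:
    """Overdamped Langevin (Euler–Maruyama) path on an analytic potential.

    dx = −(D/kT) ∇U dt + sqrt(2 D dt) ξ,  ξ ~ N(0, I).

    Returns the path strided to every ``stride``-th step, shape
    (n_steps // stride, dim). Stationary occupancies converge to the
    Boltzmann weights of ``potential``.

    Raises
    ------
    ValueError
        If ``dt`` violates the drift stability criterion
        dt · max|∇U| · D/kT < 0.1 · (minimum well spacing), or if the path
        leaves ``domain_bound`` (diverging integration).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    D, kT = potential.diffusion_coefficient, potential.kT
    max_drift = dt * potential.max_gradient_bound() * D / kT
    limit = 0.1 * potential.min_well_spacing()
    if max_drift >= limit:
        raise ValueError(
            f"dt={dt} unstable: per-step drift bound {max_drift:.3g} exceeds "
            f"0.1 x well spacing = {limit:.3g}; reduce dt"
        )
    rng = np.random.default_rng(seed)
    dim = potential.dim
    x = np.zeros(dim) if x0 is None else np.asarray(x0, dtype=float).reshape(dim)
    amp = np.sqrt(2.0 * D * dt)
    cD = D * dt / kT
    n_out = n_steps // stride
    out = np.empty((n_out, dim))
    noise = rng.standard_normal((n_steps, dim))
    j = 0
    for t in range(n_steps):
        x = x - cD * potential.gradient(x) + amp * noise[t]
        if (t + 1) % stride == 0:
            out[j] = x
            j += 1
    if not np.all(np.isfinite(out)) or np.max(np.abs(out), initial=0.0) > domain_bound:
        raise ValueError(
            "Brownian path diverged beyond the domain bound; the Euler-Maruyama "
            "step dt is too large for this potential's gradients"
        )
    return out


def basin_labels(potential: PotentialSpec, path: np.ndarray) -> np.ndarray:
    """Ground-truth basin label per frame: index of the nearest well center."""
    path = np.atleast_2d(path)
    d = np.linalg.norm(path[:, None, :] - potential.well_centers[None, :, :], axis=-1)
    return np.argmin(d, axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# Embedding a latent path as a multi-particle 3-D trajectory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbeddedTrajectory:
    """A synthetic 3-D trajectory with per-frame ground-truth basin labels."""

    coordinates: np.ndarray            # (frames, particles, 3), Angstrom
    frame_interval: float              # ns
    latent_state_labels: np.ndarray    # (frames,) int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if self.latent_state_labels.shape[0] != self.coordinates.shape[0]:
            raise ValueError("one label per frame required")


def random_template(n_particles: int, seed: int | None = None, box: float = 20.0) -> np.ndarray:
    """Random reference coordinates (Angstrom) for embedding tests."""
    rng = np.random.default_rng(seed)
    return rng.uniform(-box / 2, box / 2, size=(n_particles, 3))


def embed_path_as_structure(
    path: np.ndarray,
    template: np.ndarray,
    labels: np.ndarray | None = None,
    amplitude: float = 2.0,
    noise_sigma: float = 0.1,
    frame_interval: float = 0.1,
    seed: int | np.random.Generator | None = None,
) -> EmbeddedTrajectory:
    """Embed a low-dimensional latent path into particle coordinates.

    Each latent coordinate drives displacement of all particles along a
    fixed random orthonormal mode of the template (translation-free), plus
    isotropic Gaussian noise of ``noise_sigma`` Angstrom. By construction
    the pairwise-distance features downstream carry the latent signal, and
    PCA of those features recovers the path.

    Parameters
    ----------
    path : (frames, d) or (frames,) latent coordinates.
    template : (particles, 3) reference coordinates; >= 4 particles.
    amplitude : Angstrom of particle displacement per latent unit.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim == 1:
        path = path[:, None]
    template = np.asarray(template, dtype=float)
    if template.ndim != 2 or template.shape[1] != 3:
        raise ValueError("template must have shape (particles, 3)")
    n_particles = template.shape[0]
    if n_particles < 4:
        raise ValueError("template must have at least 4 particles")
    d_latent = path.shape[1]
    if 3 * n_particles - 3 < d_latent:
        raise ValueError(
            f"{n_particles} particles cannot carry {d_latent} independent modes"
        )
    rng = np.random.default_rng(seed)
    # random modes, centered (no net translation), then orthonormalized
    raw = rng.standard_normal((d_latent, n_particles, 3))
    raw -= raw.mean(axis=1, keepdims=True)
    flat = raw.reshape(d_latent, -1)
    q, _ = np.linalg.qr(flat.T)
    modes = q.T[:d_latent].reshape(d_latent, n_particles, 3)

    disp = amplitude * np.einsum("td,dpx->tpx", path, modes)
    coords = template[None, :, :] + disp
    if noise_sigma > 0:
        coords = coords + noise_sigma * rng.standard_normal(coords.shape)
    if labels is None:
        labels = np.zeros(path.shape[0], dtype=np.int64)
    return EmbeddedTrajectory(
        coordinates=coords,
        frame_interval=frame_interval,
        latent_state_labels=np.asarray(labels, dtype=np.int64),
    )
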