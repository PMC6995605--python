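"""Markov state model estimation and validation.

A discrete trajectory over microstates is summarized by transition counts
at a lag time τ; the row-stochastic transition matrix T(τ) estimated from
those counts propagates state populations through the master equation

    P(nτ) = [T(τ)]ⁿ P(0).

The relaxation timescale implied by the i-th eigenvalue is

    t_i(τ) = −τ / ln λ_i(τ),

which must be flat in τ for a Markovian model; the Chapman–Kolmogorov test
T(nτ) ≈ [T(τ)]ⁿ checks the same property on the eigenvectors by comparing
model-predicted multi-step staying probabilities of state groups against
direct re-estimation at lag nτ.

The default estimator is the detailed-balance-constrained (reversible)
maximum-likelihood estimator, the standard choice for systems sampled at
equilibrium; plain row-normalization is available for oracle checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "CountMatrix",
    "TransitionModel",
    "CKReport",
    "count_transitions",
    "estimate_transition_matrix",
    "implied_timescales",
    "its_scan",
    "ck_test",
    "propagate",
    "estimate_msm",
]


# ---------------------------------------------------------------------------
# Transition counting
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    counts: np.ndarray                 # (k, k) nonnegative
    lag: int                           # frames
    mode: str                          # "sliding" | "strided"
    active_set: np.ndarray             # indices of the largest strongly connected component

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]

    def active_counts(self) -> np.ndarray:
        return self.counts[np.ix_(self.active_set, self.active_set)]


def _as_dtraj_list(dtrajs) -> list[np.ndarray]:
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    return [np.asarray(d, dtype=np.int64) for d in dtrajs]


def _largest_connected_set(C: np.ndarray) -> np.ndarray:
    """Largest strongly connected component of the transition-count graph."""
    graph = csr_matrix((C > 0).astype(np.int8))
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    # among components, pick the one with the most counts (ties: most states)
    best, best_key = 0, (-1.0, -1)
    for c in range(n_comp):
        members = np.nonzero(labels == c)[0]
        key = (C[np.ix_(members, members)].sum(), members.size)
        if key > best_key:
            best, best_key = c, key
    return np.nonzero(labels == best)[0]


def count_transitions(dtrajs, lag: int, mode: str = "sliding", n_states: int | None = None) -> CountMatrix:
    """Count observed (s(t), s(t+lag)) transitions, never across trajectories.

    ``sliding`` counts every frame pair at offset ``lag``; ``strided``
    counts only pairs starting at t = 0, lag, 2·lag, … (statistically
    independent transitions).
    """
    dtrajs = _as_dtraj_list(dtrajs)
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    if mode not in ("sliding", "strided"):
        raise ValueError("mode must be 'sliding' or 'strided'")
    if not any(len(d) > lag for d in dtrajs):
        raise ValueError(f"lag {lag} is >= every trajectory length; no transitions to count")
    k = n_states if n_states is not None else int(max(d.max() for d in dtrajs)) + 1
    C = np.zeros((k, k), dtype=np.int64)
    for d in dtrajs:
        if len(d) <= lag:
            continue
        src = d[:-lag]
        dst = d[lag:]
        if mode == "strided":
            src = src[::lag]
            dst = dst[::lag]
        np.add.at(C, (src, dst), 1)
    return CountMatrix(counts=C, lag=lag, mode=mode, active_set=_largest_connected_set(C))


# ---------------------------------------------------------------------------
# Transition-matrix estimation
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """Row-stochastic transition matrix on the active set, with spectrum.

    ``active_set`` maps the model's state indices back to the original
    microstate labels. ``lag_time`` is the lag in physical units
    (lag frames × frame interval).
    """

    T: np.ndarray
    lag: int                           # frames
    lag_time: float                    # physical units (ns)
    stationary: np.ndarray
    eigenvalues: np.ndarray            # descending by modulus; real for reversible
    right_eigenvectors: np.ndarray     # columns
    left_eigenvectors: np.ndarray      # columns (π-weighted for reversible)
    reversible: bool
    active_set: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = self.T.shape[0]
        if self.active_set is None:
            self.active_set = np.arange(n)
        rows = self.T.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-10:
            raise ValueError("transition matrix rows must sum to 1 within 1e-10")
        if abs(self.eigenvalues[0] - 1.0) > 1e-8:
            raise ValueError("leading eigenvalue must be 1")
        if np.any(self.stationary < -1e-12) or abs(self.stationary.sum() - 1.0) > 1e-10:
            raise ValueError("stationary vector must be a probability distribution")
        if np.abs(self.stationary @ self.T - self.stationary).max() > 1e-8:
            raise ValueError("stationary vector does not satisfy pi T = pi")
        if self.reversible:
            flux = self.stationary[:, None] * self.T
            if np.abs(flux - flux.T).max() > 1e-8:
                raise ValueError("reversible model violates detailed balance")

    @property
    def n_states(self) -> int:
        return self.T.shape[0]


def _reversible_mle(C: np.ndarray, tol: float = 1e-12, max_iter: int = 10000) -> tuple[np.ndarray, np.ndarray]:
    """Detailed-balance-constrained MLE by the standard fixed-point iteration.

    Iterates x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j) on the symmetric
    unnormalized flux x; at the fixed point T_ij = x_ij / x_i maximizes the
    likelihood subject to π_i T_ij = π_j T_ji, with π = x_i / Σ x.
    """
    C = np.asarray(C, dtype=float)
    c_row = C.sum(axis=1)
    Cs = C + C.T
    x = Cs.copy()
    x_row = x.sum(axis=1)
    for _ in range(max_iter):
        q = c_row / x_row                       # (k,)
        denom = q[:, None] + q[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            x_new = np.where(Cs > 0, Cs / denom, 0.0)
        x_new_row = x_new.sum(axis=1)
        delta = np.abs(x_new / x_new.sum() - x / x.sum()).max()
        x, x_row = x_new, x_new_row
        if delta < tol:
            break
    T = x / x_row[:, None]
    pi = x_row / x_row.sum()
    return T, pi


def _spectrum_reversible(T: np.ndarray, pi: np.ndarray):
    """Real spectrum via the π-symmetrized matrix D^1/2 T D^-1/2."""
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] * T) / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)                        # enforce exact symmetry
    w, V = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    right = V / sqrt_pi[:, None]               # ψ_i = D^-1/2 v_i
    left = V * sqrt_pi[:, None]                # φ_i = D^1/2 v_i
    # sign convention: make the first eigenvector positive (it is constant)
    for i in range(V.shape[1]):
        j = np.argmax(np.abs(right[:, i]))
        if right[j, i] < 0:
            right[:, i] *= -1
            left[:, i] *= -1
    return w, right, left


def estimate_transition_matrix(
    counts: CountMatrix,
    reversible: bool = True,
    frame_interval: float = 1.0,
) -> TransitionModel:
    """Maximum-likelihood transition matrix on the largest connected set.

    ``reversible=True`` (default) imposes detailed balance; ``False`` is
    plain row-normalization of the counts.
    """
    active = counts.active_set
    if active.size == 0:
        raise ValueError("empty active set: no connected transitions")
    C = counts.active_counts().astype(float)
    if reversible:
        T, pi = _reversible_mle(C)
        w, right, left = _spectrum_reversible(T, pi)
        # clip tiny numerical overshoot of the Perron eigenvalue
        w[0] = 1.0
    else:
        T = C / C.sum(axis=1, keepdims=True)
        w_c, V = np.linalg.eig(T)
        order = np.lexsort((np.arange(len(w_c)), -np.abs(w_c)))
        # modulus-descending, but the stationary eigenvalue (closest to 1)
        # leads even when other unit-modulus (complex) eigenvalues exist
        order = list(order)
        lead = min(order, key=lambda i: abs(w_c[i] - 1.0))
        order.remove(lead)
        order = np.array([lead] + order)
        w_c = w_c[order]
        V = V[:, order]
        right = V
        wl, Vl = np.linalg.eig(T.T)
        il = int(np.argmin(np.abs(wl - 1.0)))
        pi = np.abs(np.real(Vl[:, il]))
        pi = pi / pi.sum()
        left = Vl[:, np.lexsort((np.arange(len(wl)), -np.abs(wl)))]
        w = w_c if np.iscomplexobj(w_c) and np.abs(w_c.imag).max() > 1e-12 else w_c.real
    dropped = counts.n_states - active.size
    if dropped:
        warnings.warn(
            f"{dropped} microstate(s) outside the largest connected set were dropped",
            stacklevel=2,
        )
    return TransitionModel(
        T=T,
        lag=counts.lag,
        lag_time=counts.lag * frame_interval,
        stationary=pi,
        eigenvalues=w,
        right_eigenvectors=np.asarray(right),
        left_eigenvectors=np.asarray(left),
        reversible=reversible,
        active_set=active,
    )


def estimate_msm(
    dtrajs,
    lag: int,
    reversible: bool = True,
    mode: str = "sliding",
    frame_interval: float = 1.0,
    n_states: int | None = None,
) -> TransitionModel:
    """Convenience: count transitions and estimate in one call."""
    counts = count_transitions(dtrajs, lag=lag, mode=mode, n_states=n_states)
    return estimate_transition_matrix(counts, reversible=reversible, frame_interval=frame_interval)


def propagate(model: TransitionModel, p0: np.ndarray, n: int) -> np.ndarray:
    """Master-equation propagation P(nτ) = P(0) [T(τ)]ⁿ (row-vector form)."""
    p = np.asarray(p0, dtype=float)
    if p.shape != (model.n_states,):
        raise ValueError("population vector shape mismatch")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-10:
        raise ValueError("p0 must be a probability distribution")
    return p @ np.linalg.matrix_power(model.T, n)


# ---------------------------------------------------------------------------
# Implied timescales
# ---------------------------------------------------------------------------

def implied_timescales(model: TransitionModel, n_timescales: int | None = None):
    """Relaxation timescales t_i = −τ / ln λ_{i+1}, in physical units.

    Eigenvalues are taken in modulus-descending order after the stationary
    eigenvalue. λ = 1 maps to +inf; λ ≤ 0 or complex eigenvalues have no
    real relaxation time at this lag and are returned as NaN with the
    ``undefined`` flag set.

    Returns
    -------
    (timescales, undefined) : arrays of length ``n_timescales``.
    """
    if n_timescales is None:
        n_timescales = model.n_states - 1
    if n_timescales >= model.n_states:
        raise ValueError("n_timescales must be < number of states")
    lam = model.eigenvalues[1 : n_timescales + 1]
    ts = np.full(len(lam), np.nan)
    undefined = np.zeros(len(lam), dtype=bool)
    for i, l in enumerate(lam):
        if np.iscomplexobj(lam) and abs(np.imag(l)) > 1e-12:
            undefined[i] = True
            continue
        l = float(np.real(l))
        if np.isclose(l, 1.0, atol=1e-12):
            ts[i] = np.inf
        elif l <= 0:
            undefined[i] = True
        else:
            ts[i] = -model.lag_time / np.log(l)
    return ts, undefined


def its_scan(
    dtrajs,
    lags,
    n_timescales: int = 4,
    reversible: bool = True,
    frame_interval: float = 1.0,
    n_states: int | None = None,
) -> pd.DataFrame:
    """Implied timescales as a function of lag time (one row per lag).

    Estimation errors at individual lags are recorded (NaN row + warning)
    without aborting the scan. Columns ``t2, t3, …`` are in physical units.
    A flat curve across lags is the Markovian signature; the ``plateau``
    helper flags lags where successive relative changes fall below 10%,
    but lag selection is always explicit, never automatic.
    """
    rows = []
    for lag in lags:
        try:
            model = estimate_msm(
                dtrajs, lag=lag, reversible=reversible,
                frame_interval=frame_interval, n_states=n_states,
            )
            nt = min(n_timescales, model.n_states - 1)
            ts, _ = implied_timescales(model, nt)
            ts = np.concatenate([ts, np.full(n_timescales - nt, np.nan)])
        except ValueError as err:
            warnings.warn(f"lag {lag}: estimation failed ({err})", stacklevel=2)
            ts = np.full(n_timescales, np.nan)
        rows.append([lag, lag * frame_interval, *ts])
    cols = ["lag_frames", "lag_time", *[f"t{i+2}" for i in range(n_timescales)]]
    return pd.DataFrame(rows, columns=cols)


def its_plateau(table: pd.DataFrame, rel_tol: float = 0.10) -> np.ndarray:
    """Lags whose slowest timescale changed < rel_tol from the previous lag."""
    t2 = table["t2"].to_numpy()
    lags = table["lag_frames"].to_numpy()
    rel = np.abs(np.diff(t2)) / np.abs(t2[:-1])
    return lags[1:][rel < rel_tol]


# ---------------------------------------------------------------------------
# Chapman–Kolmogorov test
# ---------------------------------------------------------------------------

@dataclass
class CKReport:
    """Estimated vs model-predicted staying probabilities per state group.

    For each group A and step multiple n: ``predicted[A][n]`` is the
    staying probability of A under [T(τ)]ⁿ, ``estimated[A][n]`` the same
    quantity from a direct re-estimation at lag nτ, with a multinomial
    standard error. ``missing`` marks points where data ran out.
    """

    steps: np.ndarray                  # the n values
    set_labels: list
    predicted: np.ndarray              # (n_sets, n_points)
    estimated: np.ndarray              # (n_sets, n_points), NaN where missing
    std_err: np.ndarray                # (n_sets, n_points)
    missing: np.ndarray                # bool

    def max_zscore(self) -> float:
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(self.predicted - self.estimated) / self.std_err
        return float(np.nanmax(z))

    def violations(self, n_sigma: float = 3.0) -> list[tuple]:
        """(set_label, n, z) for points where |pred − est| > n_sigma · SE."""
        out = []
        for a, label in enumerate(self.set_labels):
            for p, n in enumerate(self.steps):
                if self.missing[a, p] or self.std_err[a, p] == 0:
                    continue
                z = abs(self.predicted[a, p] - self.estimated[a, p]) / self.std_err[a, p]
                if z > n_sigma:
                    out.append((label, int(n), float(z)))
        return out


def _staying_probability(T: np.ndarray, pi: np.ndarray, members: np.ndarray) -> float:
    """π-weighted probability of remaining in the member set after one step."""
    w = pi[members]
    w = w / w.sum()
    return float(w @ T[np.ix_(members, members)].sum(axis=1))


def ck_test(
    dtrajs,
    model: TransitionModel,
    sets: list[np.ndarray] | None = None,
    n_steps: int = 5,
    mode: str = "sliding",
) -> CKReport:
    """Chapman–Kolmogorov test: T(nτ) vs [T(τ)]ⁿ on state groups.

    ``sets`` are groups of *original* microstate labels (default: one
    singleton group per state — only sensible for small models). The
    predicted curve aggregates powers of the model's T; the estimated
    curve re-estimates a matrix at lag nτ from the data (non-reversible
    row normalization, so the estimate is independent of the model's
    estimator) and aggregates it with the model's stationary weights.
    Standard errors are multinomial: sqrt(p(1−p)/N) with N the number of
    counted transitions leaving the group at lag nτ.
    """
    dtrajs = _as_dtraj_list(dtrajs)
    if sets is None:
        sets = [np.array([s]) for s in model.active_set]
    set_in_active = []
    index_of = {s: i for i, s in enumerate(model.active_set)}
    for group in sets:
        members = np.array([index_of[s] for s in np.atleast_1d(group) if s in index_of])
        if members.size == 0:
            raise ValueError(f"state group {group} has no members in the active set")
        set_in_active.append(members)

    steps = np.arange(1, n_steps + 1)
    n_sets = len(sets)
    predicted = np.full((n_sets, n_steps), np.nan)
    estimated = np.full((n_sets, n_steps), np.nan)
    std_err = np.full((n_sets, n_steps), np.nan)
    missing = np.zeros((n_sets, n_steps), dtype=bool)

    Tn = np.eye(model.n_states)
    for p, n in enumerate(steps):
        Tn = Tn @ model.T
        for a, members in enumerate(set_in_active):
            predicted[a, p] = _staying_probability(Tn, model.stationary, members)
        lag_n = model.lag * int(n)
        if not any(len(d) > lag_n for d in dtrajs):
            missing[:, p] = True
            continue
        counts_n = count_transitions(dtrajs, lag=lag_n, mode=mode)
        C = counts_n.counts.astype(float)
        for a, members in enumerate(set_in_active):
            orig = model.active_set[members]
            orig = orig[orig < C.shape[0]]
            row = C[orig, :]
            N = row.sum()
            if N == 0:
                missing[a, p] = True
                continue
            # π-weighted aggregation of the empirical lag-nτ matrix
            w = model.stationary[members]
            w = w / w.sum()
            with np.errstate(invalid="ignore", divide="ignore"):
                stay_rows = np.where(
                    row.sum(axis=1) > 0,
                    row[:, orig].sum(axis=1) / row.sum(axis=1),
                    0.0,
                )
            p_est = float(w @ stay_rows)
            estimated[a, p] = p_est
            std_err[a, p] = np.sqrt(max(p_est * (1 - p_est), 1e-30) / N)
    return CKReport(
        steps=steps,
        set_labels=[np.atleast_1d(g).tolist() for g in sets],
        predicted=predicted,
        estimated=estimated,
        std_err=std_err,
        missing=missing,
    )
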