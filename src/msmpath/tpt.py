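"""Transition path theory: committors, reactive flux, pathway decomposition.

Given a transition model, a source set A and a sink set B, the forward
committor q⁺_i is the probability that a trajectory at state i reaches B
before A; the reactive flux f_ij = π_i q⁻_i T_ij q⁺_j measures the
equilibrium probability current of A→B reactive trajectories through each
edge. Net fluxes are coarse-grained onto macrostates and decomposed into
individual pathways by iterative bottleneck (max–min capacity) removal,
yielding the percentage each pathway contributes to the total A→B flux.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve as _solve

from .lumping import MacrostateLumping
from .msm import TransitionModel

__all__ = [
    "TPTResult",
    "committor",
    "reactive_flux",
    "coarse_grain_flux",
    "decompose_pathways",
    "transition_pathways",
]


def _as_set(states, n: int, name: str) -> np.ndarray:
    s = np.unique(np.atleast_1d(np.asarray(states, dtype=np.int64)))
    if s.size == 0:
        raise ValueError(f"{name} set is empty")
    if s.min() < 0 or s.max() >= n:
        raise ValueError(f"{name} set contains states outside [0, {n})")
    return s


def committor(
    model: TransitionModel,
    A,
    B,
    backward: bool = False,
) -> np.ndarray:
    """Forward (or backward) committor by direct linear solve.

    Forward: q⁺ = 0 on A, 1 on B, and on intermediates I the harmonic
    condition (I − T_II) q_I = T_IB·1. Backward uses the time-reversed
    matrix T̃_ij = π_j T_ji / π_i with the roles of A and B swapped; for
    reversible models q⁻ = 1 − q⁺.
    """
    n = model.n_states
    A = _as_set(A, n, "A")
    B = _as_set(B, n, "B")
    if np.intersect1d(A, B).size:
        raise ValueError("A and B must be disjoint")
    T = model.T
    if backward:
        pi = model.stationary
        T = (T.T * pi[None, :]) / pi[:, None]   # T̃_ij = π_j T_ji / π_i
        A, B = B, A                             # hit A (in original roles) first
    q = np.zeros(n)
    q[B] = 1.0
    inter = np.setdiff1d(np.arange(n), np.concatenate([A, B]))
    if inter.size == 0:
        # boundary values only (after any role swap), nothing to solve
        warnings.warn("A and B cover all states; committor is trivial", stacklevel=2)
        return q
    M = np.eye(inter.size) - T[np.ix_(inter, inter)]
    rhs = T[np.ix_(inter, B)].sum(axis=1)
    try:
        q[inter] = _solve(M, rhs)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"committor system is singular: {err}") from err
    q = np.clip(q, 0.0, 1.0)
    if backward:
        # q currently solves the reversed-chain forward problem = q⁻ of the original
        return q
    return q


@dataclass
class TPTResult:
    """Reactive-flux analysis between a source set A and sink set B."""

    A: np.ndarray
    B: np.ndarray
    forward_committor: np.ndarray
    backward_committor: np.ndarray
    gross_flux: np.ndarray             # f_ij = π_i q⁻_i T_ij q⁺_j, zero diagonal
    net_flux: np.ndarray               # f⁺_ij = max(0, f_ij − f_ji)
    total_flux: float

    def conservation_error(self) -> float:
        """Max |inflow − outflow| of net flux over intermediate states."""
        inter = np.setdiff1d(
            np.arange(self.net_flux.shape[0]), np.concatenate([self.A, self.B])
        )
        if inter.size == 0:
            return 0.0
        imbalance = self.net_flux.sum(axis=0) - self.net_flux.sum(axis=1)
        return float(np.abs(imbalance[inter]).max())


def reactive_flux(model: TransitionModel, A, B) -> TPTResult:
    """Net reactive A→B flux network and total flux.

    Total flux is the net flux leaving A: F = Σ_{i∈A, j∉A} f⁺_ij.
    """
    n = model.n_states
    A = _as_set(A, n, "A")
    B = _as_set(B, n, "B")
    qp = committor(model, A, B)
    if model.reversible:
        qm = 1.0 - qp
    else:
        qm = committor(model, A, B, backward=True)
    pi = model.stationary
    f = (pi * qm)[:, None] * model.T * qp[None, :]
    np.fill_diagonal(f, 0.0)
    # no flux into A or out of B is reactive
    f[:, A] = 0.0
    f[B, :] = 0.0
    net = np.maximum(f - f.T, 0.0)
    notA = np.setdiff1d(np.arange(n), A)
    total = float(net[np.ix_(A, notA)].sum())
    return TPTResult(
        A=A, B=B, forward_committor=qp, backward_committor=qm,
        gross_flux=f, net_flux=net, total_flux=total,
    )


def coarse_grain_flux(flux: TPTResult, lumping: MacrostateLumping) -> tuple[np.ndarray, int, int]:
    """Lump the microstate net-flux network onto macrostates.

    A and B must each lie inside a single macrostate; the macro network is
    the sum of micro net fluxes between lumped sets, re-antisymmetrized to
    a net macro flux.

    Returns (macro_net_flux, macro_A, macro_B).
    """
    crisp = lumping.crisp_map
    if crisp.shape[0] != flux.net_flux.shape[0]:
        raise ValueError("lumping does not cover the flux network's states")
    m = lumping.n_macrostates
    macros_A = np.unique(crisp[flux.A])
    macros_B = np.unique(crisp[flux.B])
    if macros_A.size > 1:
        raise ValueError(f"source set A straddles macrostates {macros_A.tolist()}")
    if macros_B.size > 1:
        raise ValueError(f"sink set B straddles macrostates {macros_B.tolist()}")
    M = np.zeros((crisp.shape[0], m))
    M[np.arange(crisp.shape[0]), crisp] = 1.0
    F = M.T @ flux.net_flux @ M
    np.fill_diagonal(F, 0.0)
    F = np.maximum(F - F.T, 0.0)
    return F, int(macros_A[0]), int(macros_B[0])


def _widest_path(F: np.ndarray, a: int, b: int) -> list[int] | None:
    """Max-bottleneck a→b path; lexicographically smallest among ties."""
    n = F.shape[0]
    width = np.full(n, -np.inf)
    width[a] = np.inf
    prev = np.full(n, -1)
    visited = np.zeros(n, dtype=bool)
    for _ in range(n):
        # among unvisited, take max width; tie-break by lowest index
        cand = np.where(visited, -np.inf, width)
        u = int(np.argmax(cand))
        if cand[u] == -np.inf:
            break
        visited[u] = True
        if u == b:
            break
        for v in range(n):
            if F[u, v] > 0 and not visited[v]:
                w = min(width[u], F[u, v])
                if w > width[v]:
                    width[v] = w
                    prev[v] = u
    if width[b] <= 0 or not np.isfinite(width[b]):
        return None
    path = [b]
    while path[-1] != a:
        path.append(int(prev[path[-1]]))
    return path[::-1]


def decompose_pathways(
    net_flux: np.ndarray,
    A: int,
    B: int,
    total_flux: float | None = None,
    max_paths: int = 100,
    tol: float = 1e-12,
) -> list[dict]:
    """Greedy bottleneck decomposition of a conserved net-flux network.

    Repeatedly find the strongest A→B path (maximum minimum-edge
    capacity), record it with its bottleneck flux, subtract that flux
    along the path, and continue until no path carries more than
    ``tol`` × total flux. Each entry has ``path`` (state sequence),
    ``flux`` and ``fraction`` (of the total A→B flux). Fractions sum to 1
    when the decomposition exhausts the network; residual cyclic flux
    below tolerance is reported in the trailing ``remainder`` entry of the
    last dict.
    """
    F = np.array(net_flux, dtype=float)
    if F.ndim != 2 or F.shape[0] != F.shape[1]:
        raise ValueError("net_flux must be square")
    if total_flux is None:
        total_flux = float(F[A, :].sum() - F[:, A].sum())
    if total_flux <= 0:
        raise ValueError("total flux must be positive to decompose pathways")
    out: list[dict] = []
    for _ in range(max_paths):
        path = _widest_path(F, A, B)
        if path is None:
            break
        edges = list(zip(path[:-1], path[1:]))
        bottleneck = min(F[u, v] for u, v in edges)
        if bottleneck <= tol * total_flux:
            break
        for u, v in edges:
            F[u, v] -= bottleneck
        out.append({
            "path": path,
            "flux": float(bottleneck),
            "fraction": float(bottleneck / total_flux),
        })
    if out:
        out[-1]["remainder"] = float(max(F.sum(), 0.0))
    return out


def transition_pathways(
    model: TransitionModel,
    lumping: MacrostateLumping,
    source_macro: int | None = None,
    sink_macro: int | None = None,
    max_paths: int = 100,
) -> dict:
    """Full coarse-grained TPT between two macrostates.

    Defaults mirror the usual misfolding setup: the least-populated
    macrostate as source (near-native) and the most-populated as sink
    (misfolded). Returns the TPTResult, the macro flux network, and the
    pathway table with percentages of total flux.
    """
    pops = lumping.populations
    a = int(np.argmin(pops)) if source_macro is None else int(source_macro)
    b = int(np.argmax(pops)) if sink_macro is None else int(sink_macro)
    if a == b:
        raise ValueError("source and sink macrostates coincide")
    A = np.nonzero(lumping.crisp_map == a)[0]
    B = np.nonzero(lumping.crisp_map == b)[0]
    flux = reactive_flux(model, A, B)
    macro_F, ma, mb = coarse_grain_flux(flux, lumping)
    macro_total = float(macro_F[ma, :].sum() - macro_F[:, ma].sum())
    paths = decompose_pathways(macro_F, ma, mb, total_flux=macro_total, max_paths=max_paths)
    for p in paths:
        p["percent"] = 100.0 * p["fraction"]
    return {
        "tpt": flux,
        "macro_net_flux": macro_F,
        "macro_total_flux": macro_total,
        "source": ma,
        "sink": mb,
        "pathways": paths,
    }
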