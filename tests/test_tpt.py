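"""Transition path theory: committors, flux, coarse-graining, pathways."""

from itertools import permutations

import numpy as np
import pytest

from msmpath import (
    coarse_grain_flux,
    committor,
    decompose_pathways,
    pcca_plus,
    reactive_flux,
    sample_markov_chain,
    transition_pathways,
)
from msmpath.msm import CountMatrix, estimate_transition_matrix


def model_from_matrix(T, scale=1e9, reversible=True):
    C = CountMatrix(np.asarray(np.asarray(T) * scale, dtype=np.int64),
                    1, "sliding", np.arange(len(T)))
    return estimate_transition_matrix(C, reversible=reversible)


@pytest.fixture
def chain3_symmetric():
    return model_from_matrix([[0.5, 0.5, 0.0], [0.25, 0.5, 0.25], [0.0, 0.5, 0.5]])


@pytest.fixture
def chain3_biased():
    # middle state: to A with 0.2, stay 0.4, to B with 0.4
    return model_from_matrix([[0.5, 0.5, 0.0], [0.2, 0.4, 0.4], [0.0, 0.5, 0.5]])


class TestCommittor:
    def test_boundary_conditions(self, chain3_symmetric):
        q = committor(chain3_symmetric, [0], [2])
        assert q[0] == 0.0 and q[2] == 1.0

    def test_symmetric_chain_midpoint(self, chain3_symmetric):
        q = committor(chain3_symmetric, [0], [2])
        assert q[1] == pytest.approx(0.5, abs=1e-10)

    def test_biased_middle_state(self, chain3_biased):
        """Hand solution: q(1) = 0.2*0 + 0.4*q(1) + 0.4*1 => q(1) = 2/3."""
        q = committor(chain3_biased, [0], [2])
        assert q[1] == pytest.approx(2 / 3, abs=1e-9)

    def test_backward_committor_reversible_identity(self, chain3_biased):
        qp = committor(chain3_biased, [0], [2])
        qm = committor(chain3_biased, [0], [2], backward=True)
        assert np.allclose(qm, 1.0 - qp, atol=1e-10)

    def test_overlapping_sets_rejected(self, chain3_symmetric):
        with pytest.raises(ValueError, match="disjoint"):
            committor(chain3_symmetric, [0, 1], [1, 2])

    def test_five_state_linear_solve_oracle(self):
        """Committor on a random reversible 5-state chain matches a
        from-scratch dense solve of the boundary-value problem."""
        rng = np.random.default_rng(0)
        C = CountMatrix(rng.integers(1, 40, (5, 5)), 1, "sliding", np.arange(5))
        m = estimate_transition_matrix(C, reversible=True)
        q = committor(m, [0], [4])
        # independent oracle: solve full system with rows replaced
        M = np.eye(5) - m.T
        M[0] = 0.0
        M[0, 0] = 1.0
        M[4] = 0.0
        M[4, 4] = 1.0
        rhs = np.zeros(5)
        rhs[4] = 1.0
        expected = np.linalg.solve(M, rhs)
        assert np.allclose(q, expected, atol=1e-9)


class TestReactiveFlux:
    def test_flux_conservation_at_intermediates(self, chain3_biased):
        r = reactive_flux(chain3_biased, [0], [2])
        assert r.conservation_error() < 1e-10

    def test_conservation_on_random_chains(self):
        rng = np.random.default_rng(1)
        for _ in range(3):
            C = CountMatrix(rng.integers(1, 30, (6, 6)), 1, "sliding", np.arange(6))
            m = estimate_transition_matrix(C, reversible=True)
            r = reactive_flux(m, [0], [5])
            assert r.conservation_error() < 1e-10

    def test_total_flux_matches_trajectory_counting(self, chain3_symmetric):
        """F_total equals the long-run rate of A->B reactive crossings."""
        r = reactive_flux(chain3_symmetric, [0], [2])
        T = chain3_symmetric.T
        s = sample_markov_chain(T, 1_000_000, seed=17)
        count, armed = 0, s[0] == 0
        for v in s[1:]:
            if v == 0:
                armed = True
            elif v == 2 and armed:
                count += 1
                armed = False
        rate = count / (len(s) - 1)
        se = np.sqrt(count) / (len(s) - 1)
        assert abs(rate - r.total_flux) <= 3 * se

    def test_committor_zero_gives_zero_flux(self, chain3_symmetric):
        r = reactive_flux(chain3_symmetric, [0], [2])
        # manually zero the committor: no reactive current
        f = (chain3_symmetric.stationary * 0)[:, None] * chain3_symmetric.T
        assert np.all(f == 0)


class TestCoarseGraining:
    def test_identity_lumping_preserves_network(self):
        rng = np.random.default_rng(2)
        C = CountMatrix(rng.integers(1, 30, (4, 4)), 1, "sliding", np.arange(4))
        m = estimate_transition_matrix(C, reversible=True)
        r = reactive_flux(m, [0], [3])
        lump = pcca_plus(m, 4)
        F, a, b = coarse_grain_flux(r, lump)
        perm = lump.crisp_map
        expected = np.zeros_like(F)
        for i in range(4):
            for j in range(4):
                expected[perm[i], perm[j]] += r.net_flux[i, j]
        expected = np.maximum(expected - expected.T, 0)
        assert np.allclose(F, expected, atol=1e-15)

    def test_all_intermediates_in_one_macrostate(self):
        T = np.array([
            [0.8, 0.1, 0.1, 0.0],
            [0.1, 0.8, 0.05, 0.05],
            [0.1, 0.05, 0.8, 0.05],
            [0.0, 0.1, 0.1, 0.8],
        ])
        m = model_from_matrix(T)
        r = reactive_flux(m, [0], [3])

        from msmpath.lumping import MacrostateLumping

        chi = np.array([[1, 0, 0], [0, 1, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        crisp = np.argmax(chi, axis=1)
        pops = np.zeros(3)
        np.add.at(pops, crisp, m.stationary)
        lump = MacrostateLumping(chi, crisp, pops, np.arange(4))
        F, a, b = coarse_grain_flux(r, lump)
        paths = decompose_pathways(F, a, b)
        assert len(paths) == 1
        assert paths[0]["path"] == [0, 1, 2]
        assert paths[0]["flux"] == pytest.approx(r.total_flux, abs=1e-10)

    def test_straddling_source_rejected(self):
        rng = np.random.default_rng(3)
        C = CountMatrix(rng.integers(1, 30, (4, 4)), 1, "sliding", np.arange(4))
        m = estimate_transition_matrix(C, reversible=True)
        r = reactive_flux(m, [0, 1], [3])
        lump = pcca_plus(m, 4)  # identity: A = {0,1} spans two macrostates
        with pytest.raises(ValueError, match="straddles"):
            coarse_grain_flux(r, lump)


def brute_force_decomposition(F, a, b):
    """Independent greedy oracle: enumerate all simple paths, then repeatedly
    remove the one with the largest bottleneck (lexicographic tie-break)."""
    n = F.shape[0]
    F = F.copy()

    def simple_paths(u, target, visited):
        if u == target:
            yield [u]
            return
        for v in range(n):
            if F[u, v] > 0 and v not in visited:
                for rest in simple_paths(v, target, visited | {v}):
                    yield [u] + rest

    out = []
    while True:
        best, best_width = None, 0.0
        for p in sorted(simple_paths(a, b, {a})):
            w = min(F[u, v] for u, v in zip(p[:-1], p[1:]))
            if w > best_width + 1e-15:
                best, best_width = p, w
        if best is None or best_width <= 1e-12:
            break
        for u, v in zip(best[:-1], best[1:]):
            F[u, v] -= best_width
        out.append((best, best_width))
    return out


class TestPathwayDecomposition:
    def test_single_chain(self):
        F = np.zeros((3, 3))
        F[0, 1] = F[1, 2] = 0.4
        paths = decompose_pathways(F, 0, 2)
        assert len(paths) == 1
        assert paths[0]["path"] == [0, 1, 2]
        assert paths[0]["fraction"] == pytest.approx(1.0, abs=1e-12)

    def test_two_equal_parallel_branches(self):
        F = np.zeros((4, 4))
        F[0, 1] = F[1, 3] = 0.3
        F[0, 2] = F[2, 3] = 0.3
        paths = decompose_pathways(F, 0, 3)
        assert len(paths) == 2
        assert all(p["fraction"] == pytest.approx(0.5, abs=1e-12) for p in paths)
        # lexicographic tie-break: path through node 1 first
        assert paths[0]["path"] == [0, 1, 3]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_on_random_conserved_networks(self, seed):
        """Greedy bottleneck fractions match an independently implemented
        exhaustive simple-path enumeration on 5-node conserved networks."""
        rng = np.random.default_rng(seed)
        C = CountMatrix(rng.integers(1, 40, (5, 5)), 1, "sliding", np.arange(5))
        m = estimate_transition_matrix(C, reversible=True)
        r = reactive_flux(m, [0], [4])
        paths = decompose_pathways(r.net_flux, 0, 4, total_flux=r.total_flux)
        oracle = brute_force_decomposition(r.net_flux, 0, 4)
        assert len(paths) == len(oracle)
        for p, (op, ow) in zip(paths, oracle):
            assert p["path"] == op
            assert p["flux"] == pytest.approx(ow, rel=1e-9)
        assert sum(p["fraction"] for p in paths) == pytest.approx(1.0, abs=1e-9)

    def test_fractions_in_unit_interval(self):
        rng = np.random.default_rng(5)
        C = CountMatrix(rng.integers(1, 40, (6, 6)), 1, "sliding", np.arange(6))
        m = estimate_transition_matrix(C, reversible=True)
        r = reactive_flux(m, [0], [5])
        paths = decompose_pathways(r.net_flux, 0, 5, total_flux=r.total_flux)
        for p in paths:
            assert 0.0 <= p["fraction"] <= 1.0 + 1e-9


def test_transition_pathways_end_to_end():
    """Macro-level decomposition conserves the microscopic total flux."""
    rng = np.random.default_rng(6)
    # metastable 6-state chain: three 2-state blocks weakly coupled
    T = np.full((6, 6), 0.005)
    for b in range(3):
        i = 2 * b
        T[i, i] = T[i + 1, i + 1] = 0.8
        T[i, i + 1] = T[i + 1, i] = 0.17
    T = T / T.sum(axis=1, keepdims=True)
    m = model_from_matrix(T)
    lump = pcca_plus(m, 3)
    # blocks are symmetric, so name source and sink explicitly
    res = transition_pathways(m, lump, source_macro=0, sink_macro=2)
    frac = sum(p["fraction"] for p in res["pathways"])
    assert frac == pytest.approx(1.0, abs=1e-6)
    assert res["macro_total_flux"] > 0
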