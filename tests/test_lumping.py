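"""PCCA+ lumping, macrostate populations, representatives, free-energy surfaces."""

import numpy as np
import pytest

from msmpath import (
    free_energy_surface,
    macrostate_populations,
    pcca_plus,
    representative_frames,
)
from msmpath.lumping import macrostate_dtrajs
from msmpath.msm import CountMatrix, estimate_transition_matrix


def model_from_matrix(T, scale=1e9, reversible=True):
    C = CountMatrix(np.asarray(np.asarray(T) * scale, dtype=np.int64),
                    1, "sliding", np.arange(len(T)))
    return estimate_transition_matrix(C, reversible=reversible)


def nearly_block_chain(eps=0.01, intra=0.1):
    T = np.array([
        [1 - intra - eps, intra, eps, 0.0],
        [intra, 1 - intra - eps, 0.0, eps],
        [eps, 0.0, 1 - intra - eps, intra],
        [0.0, eps, intra, 1 - intra - eps],
    ])
    return model_from_matrix(T)


class TestPCCAPlus:
    def test_decoupled_blocks_lumped_exactly(self):
        # two 2-state blocks bridged by a vanishing coupling (keeps the
        # chain connected without moving the eigenvector sign structure)
        m = nearly_block_chain(eps=1e-9)
        lump = pcca_plus(m, 2)
        assert lump.crisp_map[0] == lump.crisp_map[1]
        assert lump.crisp_map[2] == lump.crisp_map[3]
        assert lump.crisp_map[0] != lump.crisp_map[2]

    def test_weakly_coupled_blocks_match_eigenvector_signs(self):
        m = nearly_block_chain(eps=0.01, intra=0.1)
        lump = pcca_plus(m, 2)
        psi2 = m.right_eigenvectors[:, 1]
        signs = psi2 > 0
        # lumping must equal the sign partition of the slowest eigenvector
        assert (
            np.array_equal(lump.crisp_map == lump.crisp_map[0], signs == signs[0])
        )

    def test_identity_lumping(self):
        m = nearly_block_chain(eps=0.02, intra=0.15)
        lump = pcca_plus(m, 4)
        assert sorted(lump.crisp_map.tolist()) == [0, 1, 2, 3]
        # memberships approximate a permutation matrix
        assert np.allclose(np.sort(lump.memberships, axis=1)[:, -1], 1.0, atol=1e-6)

    def test_memberships_row_stochastic(self):
        rng = np.random.default_rng(0)
        C = CountMatrix(rng.integers(1, 80, (8, 8)), 1, "sliding", np.arange(8))
        m = estimate_transition_matrix(C, reversible=True)
        lump = pcca_plus(m, 3)
        assert np.allclose(lump.memberships.sum(axis=1), 1.0, atol=1e-8)
        assert lump.memberships.min() >= -1e-10

    def test_permutation_invariance(self):
        """Relabelling microstates permutes the lumping accordingly."""
        m = nearly_block_chain(eps=0.01)
        lump = pcca_plus(m, 2)
        perm = np.array([2, 0, 3, 1])
        T = m.T[np.ix_(perm, perm)]
        m2 = model_from_matrix(T)
        lump2 = pcca_plus(m2, 2)
        part1 = lump.crisp_map[perm] == lump.crisp_map[perm][0]
        part2 = lump2.crisp_map == lump2.crisp_map[0]
        assert np.array_equal(part1, part2)

    def test_nonreversible_model_rejected(self):
        T = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        m = model_from_matrix(T, reversible=False)
        with pytest.raises(ValueError, match="reversible"):
            pcca_plus(m, 2)

    def test_too_few_macrostates_rejected(self):
        m = nearly_block_chain()
        with pytest.raises(ValueError, match=">= 2"):
            pcca_plus(m, 1)


class TestMacrostatePopulations:
    def test_identity_lumping_preserves_pi(self):
        m = model_from_matrix([[0.9, 0.1], [0.2, 0.8]])
        lump = pcca_plus(m, 2)
        pops = macrostate_populations(lump, m)
        assert np.allclose(np.sort(pops), np.sort(m.stationary), atol=1e-9)
        assert np.allclose(np.sort(pops), [1 / 3, 2 / 3], atol=1e-6)

    def test_populations_sum_to_one(self):
        m = nearly_block_chain()
        lump = pcca_plus(m, 2)
        assert macrostate_populations(lump, m).sum() == pytest.approx(1.0, abs=1e-12)
        assert macrostate_populations(lump, m, fuzzy=True).sum() == pytest.approx(1.0, abs=1e-9)


class TestRepresentativeFrames:
    def test_sampling_and_clamping(self):
        m = nearly_block_chain(eps=0.05, intra=0.2)
        rng = np.random.default_rng(1)
        dtraj = rng.integers(0, 4, 200)
        X = rng.standard_normal((200, 2))
        lump = pcca_plus(m, 2)
        reps = representative_frames(lump, [dtraj], X, m, n_samples=10, seed=0)
        for a, entry in reps.items():
            assert len(entry["frames"]) == 10
            assert entry["medoid"] is not None
        with pytest.warns(UserWarning, match="available"):
            reps = representative_frames(lump, [dtraj], X, m, n_samples=10_000, seed=0)
        total = sum(len(e["frames"]) for e in reps.values())
        assert total == 200

    def test_medoid_recovers_gaussian_center(self):
        """Medoid of a single-Gaussian state lies near the generating mean."""
        m = model_from_matrix([[0.95, 0.05], [0.05, 0.95]])
        rng = np.random.default_rng(2)
        n = 2000
        dtraj = rng.integers(0, 2, n)
        mu = np.array([3.0, -1.0])
        X = np.where(dtraj[:, None] == 0, mu, -mu) + 0.5 * rng.standard_normal((n, 2))
        lump = pcca_plus(m, 2)
        reps = representative_frames(lump, [dtraj], X, m, n_samples=5, seed=3)
        for a, entry in reps.items():
            med = X[entry["medoid"]]
            target = mu if dtraj[entry["medoid"]] == 0 else -mu
            assert np.linalg.norm(med - target) < 3 * 0.5 / np.sqrt(1) + 0.2


class TestFreeEnergySurface:
    def test_uniform_two_bins_flat(self):
        pts = np.array([[0.25, 0.5], [0.75, 0.5]] * 100)
        fes = free_energy_surface(pts, bins=(2, 2))
        F = fes.free_energy[fes.populated]
        assert np.allclose(F, 0.0, atol=1e-12)

    def test_four_to_one_population_ratio(self):
        """Bin populations (0.8, 0.2) give dF = ln 4."""
        pts = np.concatenate([np.tile([[0.25, 0.5]], (80, 1)), np.tile([[0.75, 0.5]], (20, 1))])
        fes = free_energy_surface(pts, bins=(2, 2))
        F = np.sort(fes.free_energy[fes.populated])
        assert F[0] == 0.0
        assert F[1] == pytest.approx(np.log(4.0), abs=1e-12)

    def test_duplicating_frames_leaves_surface_unchanged(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((500, 2))
        f1 = free_energy_surface(pts, bins=5)
        f2 = free_energy_surface(np.vstack([pts, pts]), bins=5)
        assert np.allclose(
            np.nan_to_num(f1.free_energy), np.nan_to_num(f2.free_energy), atol=1e-12
        )

    def test_harmonic_well_quadratic_profile(self):
        """-ln p of Gaussian samples is quadratic with curvature 1/(2 sigma^2)."""
        rng = np.random.default_rng(4)
        sigma = 0.7
        pts = np.c_[sigma * rng.standard_normal(200_000), np.zeros(200_000)]
        fes = free_energy_surface(pts, bins=(41, 2))
        centers = 0.5 * (fes.x_edges[:-1] + fes.x_edges[1:])
        F = np.nanmin(fes.free_energy, axis=1)
        sel = np.abs(centers) < 2 * sigma
        coeff = np.polyfit(centers[sel], F[sel], 2)[0]
        assert coeff == pytest.approx(1.0 / (2 * sigma**2), rel=0.1)

    def test_weights_reshape_surface(self):
        pts = np.concatenate([np.tile([[0.25, 0.5]], (50, 1)), np.tile([[0.75, 0.5]], (50, 1))])
        w = np.concatenate([np.full(50, 4.0), np.full(50, 1.0)])
        fes = free_energy_surface(pts, weights=w, bins=(2, 2))
        F = np.sort(fes.free_energy[fes.populated])
        assert F[1] == pytest.approx(np.log(4.0), abs=1e-12)

    def test_single_bin_warns(self):
        pts = np.tile([[0.5, 0.5]], (10, 1))
        with pytest.warns(UserWarning, match="single bin"):
            free_energy_surface(pts, bins=(2, 2))


def test_macrostate_dtrajs_maps_and_flags():
    m = nearly_block_chain()
    lump = pcca_plus(m, 2)
    d = np.array([0, 1, 2, 3, 0])
    out = macrostate_dtrajs(lump, [d])[0]
    assert np.array_equal(out, lump.crisp_map[d])
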