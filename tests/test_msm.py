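"""Transition counting, MSM estimation, implied timescales, CK validation."""

import numpy as np
import pytest

from msmpath import (
    GroundTruthChain,
    ck_test,
    count_transitions,
    estimate_msm,
    estimate_transition_matrix,
    implied_timescales,
    its_scan,
    propagate,
    sample_markov_chain,
)
from msmpath.msm import CountMatrix


def model_from_matrix(T, reversible=True, scale=1e9):
    """Build a TransitionModel whose T matches a given matrix (via huge counts)."""
    C = CountMatrix(
        counts=np.asarray(np.asarray(T) * scale, dtype=np.int64),
        lag=1, mode="sliding", active_set=np.arange(len(T)),
    )
    return estimate_transition_matrix(C, reversible=reversible)


class TestCounting:
    def test_alternating_sequence_lag1(self):
        cm = count_transitions([np.array([0, 1, 0, 1])], lag=1)
        expected = np.array([[0, 2], [1, 0]])
        assert np.array_equal(cm.counts, expected)

    def test_alternating_sequence_lag2(self):
        cm = count_transitions([np.array([0, 1, 0, 1])], lag=2)
        assert np.array_equal(cm.counts, np.array([[1, 0], [0, 1]]))

    def test_no_counting_across_trajectory_boundary(self):
        cm = count_transitions([np.array([0, 1]), np.array([1, 0])], lag=1)
        assert np.array_equal(cm.counts, np.array([[0, 1], [1, 0]]))

    def test_strided_mode_counts_independent_pairs(self):
        cm = count_transitions([np.array([0, 0, 1, 1, 0])], lag=2, mode="strided")
        # pairs at t=0 and t=2 only: (0,1), (1,0)
        assert cm.counts.sum() == 2
        assert cm.counts[0, 1] == 1 and cm.counts[1, 0] == 1

    def test_lag_too_long_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            count_transitions([np.array([0, 1])], lag=5)


class TestEstimation:
    def test_symmetric_counts_row_normalize(self):
        C = CountMatrix(np.array([[8, 2], [2, 8]]), 1, "sliding", np.arange(2))
        for rev in (True, False):
            m = estimate_transition_matrix(C, reversible=rev)
            assert np.allclose(m.T, [[0.8, 0.2], [0.2, 0.8]], atol=1e-10)

    def test_stationary_distribution_by_power_iteration(self):
        """pi of [[.9,.1],[.2,.8]] is (2/3, 1/3) — checked against an
        independent power iteration."""
        m = model_from_matrix([[0.9, 0.1], [0.2, 0.8]], reversible=False)
        p = np.array([1.0, 0.0])
        for _ in range(500):
            p = p @ m.T
        assert np.allclose(m.stationary, p, atol=1e-10)
        assert np.allclose(m.stationary, [2 / 3, 1 / 3], atol=1e-9)

    def test_reversible_estimate_satisfies_detailed_balance(self):
        rng = np.random.default_rng(0)
        C = CountMatrix(rng.integers(1, 50, size=(5, 5)), 1, "sliding", np.arange(5))
        m = estimate_transition_matrix(C, reversible=True)
        flux = m.stationary[:, None] * m.T
        assert np.abs(flux - flux.T).max() < 1e-8

    def test_reversible_mle_recovers_reversible_truth(self):
        """For detailed-balanced counts the reversible MLE equals row
        normalization (independent closed form)."""
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        pi = np.array([2 / 3, 1 / 3])
        counts = (1e8 * pi[:, None] * T).astype(np.int64)  # balanced counts
        C = CountMatrix(counts, 1, "sliding", np.arange(2))
        m = estimate_transition_matrix(C, reversible=True)
        assert np.allclose(m.T, T, atol=1e-6)

    def test_disconnected_states_dropped(self):
        d = np.array([0, 1, 0, 1, 0, 1, 2])  # state 2 never returns
        with pytest.warns(UserWarning, match="dropped"):
            m = estimate_msm(d, lag=1)
        assert m.n_states == 2
        assert set(m.active_set) == {0, 1}

    def test_spectral_reconstruction(self):
        rng = np.random.default_rng(1)
        C = CountMatrix(rng.integers(5, 60, size=(6, 6)), 1, "sliding", np.arange(6))
        m = estimate_transition_matrix(C, reversible=True)
        recon = sum(
            lam * np.outer(m.right_eigenvectors[:, i], m.left_eigenvectors[:, i])
            for i, lam in enumerate(m.eigenvalues)
        )
        assert np.abs(recon - m.T).max() < 1e-8


class TestImpliedTimescales:
    def test_identity_chain_infinite(self):
        m = model_from_matrix(np.eye(2) * 0.9999999999 + 0.0000000001 * np.ones((2, 2)) / 2)
        ts, undef = implied_timescales(m, 1)
        assert ts[0] > 1e8 or np.isinf(ts[0])

    def test_two_state_trace_oracle(self):
        """lambda_2 of a 2x2 stochastic matrix is trace - 1."""
        m = model_from_matrix([[0.9, 0.1], [0.2, 0.8]])
        lam2 = 0.9 + 0.8 - 1.0
        ts, undef = implied_timescales(m, 1)
        assert not undef[0]
        assert ts[0] == pytest.approx(-1.0 / np.log(lam2), rel=1e-6)
        assert ts[0] == pytest.approx(2.804, abs=0.01)

    def test_instant_mixing_flagged(self):
        m = model_from_matrix([[0.5, 0.5], [0.5, 0.5]])
        ts, undef = implied_timescales(m, 1)
        assert undef[0]
        assert np.isnan(ts[0])

    def test_physical_units(self):
        m = model_from_matrix([[0.9, 0.1], [0.2, 0.8]])
        C = CountMatrix(np.array([[9, 1], [2, 8]]) * 10**6, 3, "sliding", np.arange(2))
        m3 = estimate_transition_matrix(C, frame_interval=0.5)
        ts, _ = implied_timescales(m3, 1)
        # lag 3 frames x 0.5 ns = 1.5 ns
        assert ts[0] == pytest.approx(-1.5 / np.log(0.7), rel=1e-6)


class TestITSScan:
    def test_markovian_data_flat(self, chain4):
        d = sample_markov_chain(chain4, 100_000, seed=21)
        table = its_scan(d, lags=[1, 2, 4, 8], n_timescales=2)
        analytic = chain4.implied_timescales()[0]
        assert np.allclose(table["t2"], analytic, rtol=0.15)

    def test_single_lag_consistency(self, chain4):
        d = sample_markov_chain(chain4, 50_000, seed=22)
        table = its_scan(d, lags=[3], n_timescales=2)
        m = estimate_msm(d, lag=3)
        ts, _ = implied_timescales(m, 2)
        assert np.allclose(table.iloc[0][["t2", "t3"]].to_numpy(dtype=float), ts)

    def test_hidden_state_data_its_rises_with_lag(self):
        """A 2-state observation of a 3-state chain is non-Markovian: its
        apparent timescale grows toward the true t2 as the lag increases."""
        T = np.array([[0.9, 0.1, 0.0], [0.1, 0.8, 0.1], [0.0, 0.02, 0.98]])
        truth = GroundTruthChain(T)
        s = sample_markov_chain(truth, 200_000, seed=23)
        obs = np.where(s == 0, 0, 1)
        table = its_scan(obs, lags=[1, 2, 5, 10, 20, 40], n_timescales=1)
        t2 = table["t2"].to_numpy()
        assert t2[1] > t2[0] and t2[3] > t2[1]
        # approaches the generating chain's slowest timescale from below
        analytic = truth.implied_timescales()[0]
        assert t2[0] < 0.8 * analytic
        assert t2[-1] == pytest.approx(analytic, rel=0.25)


class TestPropagation:
    def test_mass_conserved(self):
        m = model_from_matrix([[0.9, 0.05, 0.05], [0.1, 0.8, 0.1], [0.02, 0.08, 0.9]])
        p0 = np.array([1.0, 0.0, 0.0])
        for n in (1, 10, 100, 1000):
            p = propagate(m, p0, n)
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p >= -1e-15)

    def test_converges_to_stationary(self):
        m = model_from_matrix([[0.9, 0.1], [0.2, 0.8]])
        p = propagate(m, np.array([1.0, 0.0]), 500)
        assert np.allclose(p, m.stationary, atol=1e-10)


class TestChapmanKolmogorov:
    def test_markovian_self_consistency(self, chain4):
        d = sample_markov_chain(chain4, 100_000, seed=24)
        m = estimate_msm(d, lag=1)
        rep = ck_test(d, m, sets=[[0], [1], [2], [3]], n_steps=10)
        assert rep.max_zscore() <= 3.0
        assert not rep.violations()

    def test_n1_predicted_equals_model(self, chain4):
        d = sample_markov_chain(chain4, 20_000, seed=25)
        m = estimate_msm(d, lag=2)
        sets = [[0, 1], [2, 3]]
        rep = ck_test(d, m, sets=sets, n_steps=3)
        from msmpath.msm import _staying_probability

        for a, group in enumerate(sets):
            members = np.array([list(m.active_set).index(s) for s in group])
            assert rep.predicted[a, 0] == pytest.approx(
                _staying_probability(m.T, m.stationary, members), abs=1e-12
            )

    def test_non_markovian_observable_flagged(self):
        T = np.array([[0.9, 0.1, 0.0], [0.1, 0.8, 0.1], [0.0, 0.02, 0.98]])
        s = sample_markov_chain(T, 100_000, seed=26)
        obs = np.where(s == 0, 0, 1)
        m = estimate_msm(obs, lag=1)
        rep = ck_test(obs, m, sets=[[0], [1]], n_steps=8)
        assert len(rep.violations(3.0)) >= 1

    def test_missing_points_marked_not_fabricated(self):
        d = np.array([0, 1, 0, 1, 0, 1, 0, 1, 1, 0])
        m = estimate_msm(d, lag=2)
        rep = ck_test(d, m, sets=[[0], [1]], n_steps=8)
        assert rep.missing[:, -1].all()
        assert np.isnan(rep.estimated[:, -1]).all()
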