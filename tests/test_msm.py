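import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from msmkin import msm, synthetic
from msmkin.msm import DisconnectedError


class TestKCenters:
    def test_greedy_steps_on_1d_surrogate(self):
        pts = np.array([0.0, 1.0, 10.0, 11.0])
        res = msm.kcenters(4, lambda i: np.abs(pts - pts[i]), k=2)
        assert res.center_indices.tolist() == [0, 3]   # points 0 and 11
        assert res.assignments.tolist() == [0, 0, 1, 1]
        assert res.max_radius == pytest.approx(1.0)

    def test_k_equals_n_gives_zero_radius(self, rng):
        pts = rng.normal(size=6)
        res = msm.kcenters(6, lambda i: np.abs(pts - pts[i]), k=6)
        assert res.max_radius == pytest.approx(0.0)
        assert len(set(res.center_indices.tolist())) == 6

    def test_k_one_radius_is_max_distance_to_first_frame(self, rng):
        pts = rng.normal(size=9)
        res = msm.kcenters(9, lambda i: np.abs(pts - pts[i]), k=1)
        assert res.max_radius == pytest.approx(np.abs(pts - pts[0]).max())

    def test_k_larger_than_frames_rejected(self):
        with pytest.raises(ValueError):
            msm.kcenters(3, lambda i: np.zeros(3), k=4)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("k", [2, 3])
    def test_gonzalez_factor_two_guarantee(self, seed, k):
        """Greedy max radius is within 2x of the exhaustively optimal
        k-center radius on small instances."""
        pts = np.random.default_rng(seed).uniform(0, 10, size=(9, 2))
        res = msm.kcenters(9, lambda i: np.linalg.norm(pts - pts[i], axis=1), k)
        optimal = min(
            max(min(np.linalg.norm(pts[i] - pts[c]) for c in combo)
                for i in range(len(pts)))
            for combo in itertools.combinations(range(len(pts)), k))
        assert res.max_radius <= 2.0 * optimal + 1e-12


class TestTransitionCounting:
    @pytest.mark.parametrize("seq,lag,expected", [
        ([0, 0, 1, 1], 1, [[1, 1], [0, 1]]),
        ([0, 1, 0, 1, 0], 2, [[2, 0], [0, 1]]),
    ])
    def test_sliding_counts(self, seq, lag, expected):
        np.testing.assert_array_equal(
            msm.count_transitions([seq], lag), expected)

    def test_no_counting_across_replicas(self):
        c = msm.count_transitions([[0, 1], [0, 1]], 1)
        np.testing.assert_array_equal(c, [[0, 2], [0, 0]])

    def test_strided_counting_skips_overlap(self):
        c = msm.count_transitions([[0, 0, 1, 1, 0]], 2, sliding=False)
        np.testing.assert_array_equal(c, [[0, 1], [1, 0]])

    def test_lag_not_shorter_than_replica_rejected(self):
        with pytest.raises(ValueError):
            msm.count_transitions([[0, 1]], 2)


class TestReversibleMLE:
    def test_symmetric_counts_row_normalize(self):
        t, pi = msm.reversible_mle(np.array([[9, 1], [1, 9]]))
        np.testing.assert_allclose(t, [[0.9, 0.1], [0.1, 0.9]], atol=1e-9)
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-9)

    def test_matches_direct_likelihood_maximization(self):
        """Two-state reversible MLE against a numeric maximizer over the
        (p, q) = (T_01, T_10) parameterization (any 2-state chain satisfies
        detailed balance, so the constraint set is the full simplex pair)."""
        c = np.array([[8, 2], [1, 9]])
        t, pi = msm.reversible_mle(c)

        def neg_loglik(x):
            p, q = x
            tm = np.array([[1 - p, p], [q, 1 - q]])
            return -(c * np.log(tm)).sum()

        best = minimize(neg_loglik, x0=[0.3, 0.3],
                        bounds=[(1e-9, 1 - 1e-9)] * 2)
        np.testing.assert_allclose(t[0, 1], best.x[0], atol=1e-6)
        np.testing.assert_allclose(t[1, 0], best.x[1], atol=1e-6)
        # detailed balance of the returned matrix
        flow = pi[:, None] * t
        np.testing.assert_allclose(flow, flow.T, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_detailed_balance_on_random_counts(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.integers(1, 50, size=(5, 5))
        t, pi = msm.reversible_mle(c)
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-10)
        flow = pi[:, None] * t
        assert np.abs(flow - flow.T).max() < 1e-8

    def test_block_diagonal_counts_rejected_then_trimmed(self):
        c = np.array([[5, 1, 0], [1, 5, 0], [0, 0, 7]])
        with pytest.raises(DisconnectedError):
            msm.reversible_mle(c)
        # the high-level estimator trims to the largest connected set instead
        model = msm.estimate_msm([[0, 1, 0, 1, 0, 1], [2, 2, 2, 2]], 1)
        assert model.active_set.tolist() == [0, 1]

    def test_recovers_ground_truth_chain(self):
        """1e5 transitions from a known reversible chain: max row-wise L1
        error of the estimate <= 0.02."""
        t_true = synthetic.default_transition_matrix(0.9)
        seq = synthetic.sample_markov_chain(
            t_true, 100001, np.random.default_rng(7))
        model = msm.estimate_msm([seq], 1)
        order = np.argsort(model.active_set)
        assert model.n_states == 4
        err = np.abs(model.transition_matrix[np.ix_(order, order)]
                     - t_true).sum(axis=1).max()
        assert err <= 0.02


class TestImpliedTimescales:
    def test_infinite_data_limit_closed_form(self):
        """Counts proportional to pi_i T_ij for the symmetric 2-state chain
        with T_12 = 0.1 reproduce t_2 = -1/ln(0.8) frames exactly."""
        c = np.array([[450000, 50000], [50000, 450000]])
        t, pi = msm.reversible_mle(c)
        model = msm.MarkovStateModel(
            transition_matrix=t, stationary_distribution=pi,
            count_matrix=c, active_set=np.array([0, 1]),
            lag_frames=1, lag_ns=1.0)
        assert model.timescales(1)[0] == pytest.approx(-1.0 / np.log(0.8),
                                                       rel=1e-12)

    def test_lag_invariance_for_markovian_data(self):
        t_true = np.array([[0.9, 0.1], [0.1, 0.9]])
        seq = synthetic.sample_markov_chain(
            t_true, 100000, np.random.default_rng(3))
        scan = msm.implied_timescales([seq], [1, 2, 4], dt_ns=1.0, m=1)
        ts = scan.timescales_ns[:, 0]
        assert np.all(np.isfinite(ts))
        assert ts.max() / ts.min() < 1.1
        assert scan.is_flat()

    def test_never_leaving_a_state_yields_no_finite_timescale(self):
        scan = msm.implied_timescales([[0] * 50], [1, 2], m=1)
        assert np.isnan(scan.timescales_ns).all()


class TestChapmanKolmogorov:
    def test_multiple_one_residual_is_exactly_zero(self):
        seq = synthetic.sample_markov_chain(
            np.array([[0.9, 0.1], [0.1, 0.9]]), 5000,
            np.random.default_rng(0))
        res = msm.ck_test([seq], 1, [1], [[0], [1]], n_bootstrap=10)
        np.testing.assert_array_equal(res.residual, 0.0)

    def test_markovian_data_within_bands(self):
        t3 = np.array([[0.95, 0.04, 0.01], [0.04, 0.93, 0.03],
                       [0.01, 0.03, 0.96]])
        seqs = [synthetic.sample_markov_chain(
            t3, 20000, np.random.default_rng((5, r))) for r in range(5)]
        res = msm.ck_test(seqs, 1, [1, 2, 4, 8], [[0], [1], [2]], seed=1)
        assert res.within_band().all()

    def test_hidden_lumped_chain_violates(self):
        """Observing a 3-state chain through a 2-state lens with very
        different within-lump exit rates breaks the Chapman-Kolmogorov
        consistency: residuals must exceed the bootstrap band."""
        t_hidden = np.array([[0.68, 0.02, 0.30], [0.02, 0.97, 0.01],
                             [0.30, 0.01, 0.69]])
        lumps = np.array([0, 0, 1])
        obs = [lumps[synthetic.sample_markov_chain(
            t_hidden, 100000, np.random.default_rng((9, r)))]
            for r in range(2)]
        # analytic check that the construction is genuinely non-Markovian:
        # exact lumped persistence vs base-lag propagation differ strongly
        pi_h = np.array([1 / 3] * 3)
        pa = pi_h[:2] / pi_h[:2].sum()
        t4 = np.linalg.matrix_power(t_hidden, 4)
        exact = pa @ t4[:2, :2].sum(axis=1)
        t1_lumped = pa @ t_hidden[:2, :2].sum(axis=1)
        assert abs(exact - t1_lumped ** 4) > 0.03
        res = msm.ck_test(obs, 1, [1, 2, 4, 8], [[0], [1]], seed=2)
        assert (~res.within_band()).any()

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            msm.ck_test([[0, 1, 0, 1]], 1, [1], [[]])


class TestPCCA:
    @staticmethod
    def _block_chain(eps=0.02):
        t = np.full((4, 4), eps / 2)
        t[0, 1] = t[1, 0] = t[2, 3] = t[3, 2] = 0.98 - eps / 2
        np.fill_diagonal(t, 0.0)
        np.fill_diagonal(t, 1.0 - t.sum(axis=1))
        return t

    def test_recovers_planted_blocks(self):
        t = self._block_chain()
        pi = np.full(4, 0.25)
        lump = msm.pcca_macrostates(t, pi, 2)
        assert lump.labels[0] == lump.labels[1]
        assert lump.labels[2] == lump.labels[3]
        assert lump.labels[0] != lump.labels[2]
        np.testing.assert_allclose(lump.populations, [0.5, 0.5], atol=1e-12)

    def test_matches_exhaustive_metastability_maximization(self):
        """The planted 2-partition also maximizes the metastability (trace
        of the lumped transition matrix) over all 2-partitions."""
        t = self._block_chain()
        pi = np.full(4, 0.25)
        best_part, best_meta = None, -np.inf
        for bits in range(1, 8):    # nontrivial bipartitions of 4 states
            part = np.array([(bits >> i) & 1 for i in range(4)])
            if part.min() == part.max():
                continue
            meta = 0.0
            for lab in (0, 1):
                idx = np.flatnonzero(part == lab)
                w = pi[idx] / pi[idx].sum()
                meta += float(w @ t[np.ix_(idx, idx)].sum(axis=1))
            if meta > best_meta:
                best_meta, best_part = meta, part
        lump = msm.pcca_macrostates(t, pi, 2)
        assert np.all((lump.labels == lump.labels[0]) ==
                      (best_part == best_part[0]))

    def test_full_resolution_is_identity_partition(self):
        t, pi = msm.reversible_mle(np.array([[8, 1, 1], [1, 8, 1], [1, 1, 8]]))
        lump = msm.pcca_macrostates(t, pi, 3)
        assert sorted(lump.labels.tolist()) == [0, 1, 2]

    def test_single_basin_still_total(self):
        t, pi = msm.reversible_mle(np.array([[5, 5], [5, 5]]))
        lump = msm.pcca_macrostates(t, pi, 2)
        assert set(lump.labels.tolist()) == {0, 1}

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_blocks_across_noisy_replicates(self, seed):
        """Sampled counts from a two-block chain (block self-transition
        0.95) still lump to the planted blocks."""
        rng = np.random.default_rng(seed)
        t = self._block_chain(eps=0.05)
        seq = synthetic.sample_markov_chain(t, 20000, rng)
        model = msm.estimate_msm([seq], 1)
        assert model.n_states == 4
        lump = msm.pcca_macrostates(model.transition_matrix,
                                    model.stationary_distribution, 2)
        labels = lump.labels[np.argsort(model.active_set)]
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
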