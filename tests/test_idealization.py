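"""Idealization correctness: resampling arithmetic, Viterbi against an
exhaustive-enumeration oracle, EM monotonicity, and the derived channel
statistics."""

import itertools

import numpy as np
import pytest

from mcugate import idealization as ideal
from mcugate import synthetic as syn
from mcugate.records import SingleChannelRecording


def make_rec(samples, rate=1000.0):
    return SingleChannelRecording(
        samples=np.asarray(samples, dtype=float),
        sample_rate=rate,
        filter_cutoff=rate / 4,
        voltage=-120.0,
    )


def brute_force_viterbi(x, model):
    """Exhaustive best-path search over all K^T state sequences."""
    from scipy.stats import norm

    K, T = model.K, x.size
    best_lp, best_path = -np.inf, None
    log_b = norm.logpdf(x[:, None], model.means[None, :], model.sd[None, :])
    with np.errstate(divide="ignore"):
        log_trans = np.log(model.trans)
        log_init = np.log(model.init)
    for path in itertools.product(range(K), repeat=T):
        lp = log_init[path[0]] + log_b[0, path[0]]
        for t in range(1, T):
            lp += log_trans[path[t - 1], path[t]] + log_b[t, path[t]]
        if lp > best_lp:
            best_lp, best_path = lp, path
    return np.array(best_path)


def random_hmm(rng, K):
    means = np.sort(rng.uniform(-3, 1, K))
    trans = rng.dirichlet(np.full(K, 1.0), size=K)
    init = rng.dirichlet(np.full(K, 1.0))
    return ideal.HMMModel(means=means, sd=rng.uniform(0.2, 1.0), trans=trans, init=init)


class TestResample:
    def test_constant_trace_unchanged(self):
        rec = make_rec(np.full(100, -2.0), rate=50_000.0)
        out = ideal.resample(rec, 2_500.0)
        np.testing.assert_allclose(out.samples, -2.0)
        assert out.sample_rate == 2_500.0

    def test_same_rate_identity(self):
        rec = make_rec(np.arange(10.0))
        assert ideal.resample(rec, rec.sample_rate) is rec

    def test_alternating_blocks_average_to_zero(self):
        rec = make_rec(np.tile([1.0, -1.0], 50), rate=1000.0)
        out = ideal.resample(rec, 500.0)
        np.testing.assert_allclose(out.samples, 0.0)

    def test_non_integer_factor_rejected(self):
        rec = make_rec(np.arange(10.0), rate=1000.0)
        with pytest.raises(ValueError, match="not an integer"):
            ideal.resample(rec, 300.0)

    def test_trailing_partial_block_dropped(self):
        rec = make_rec(np.arange(11.0), rate=1000.0)
        out = ideal.resample(rec, 500.0)
        assert out.samples.size == 5


class TestViterbi:
    def test_matches_exhaustive_enumeration(self):
        """Decoded path identical to brute-force search on random small
        instances (spot sample; the full 200-instance sweep runs in the
        acceptance suite)."""
        rng = np.random.default_rng(123)
        for _ in range(25):
            K = int(rng.integers(2, 5))
            T = int(rng.integers(2, {2: 13, 3: 10, 4: 8}[K]))
            model = random_hmm(rng, K)
            x = rng.normal(0, 2, T)
            rec = make_rec(x)
            path = ideal.viterbi_idealize(rec, model).states
            np.testing.assert_array_equal(path, brute_force_viterbi(x, model))

    def test_noiseless_step_trace_exact(self):
        x = np.concatenate([np.zeros(20), np.full(15, -2.0), np.zeros(10)])
        model = ideal.HMMModel(
            means=[0.0, -2.0], sd=0.1,
            trans=[[0.95, 0.05], [0.05, 0.95]], init=[0.5, 0.5],
        )
        path = ideal.viterbi_idealize(make_rec(x), model).states
        np.testing.assert_array_equal(path, (x != 0).astype(int))

    def test_degenerate_model_rejected(self):
        model = ideal.HMMModel(
            means=[0.0, -2.0], sd=0.1,
            trans=[[0.95, 0.05], [0.05, 0.95]], init=[0.5, 0.5],
        )
        model.trans = np.zeros((2, 2))  # corrupt after validation
        with pytest.raises(ValueError, match="degenerate"):
            ideal.viterbi_idealize(make_rec(np.zeros(5)), model)


class TestBaumWelch:
    def test_single_state_trivial(self):
        x = np.random.default_rng(0).normal(-1.0, 0.3, 500)
        model, _ = ideal.baum_welch_fit(make_rec(x), K=1)
        assert model.means[0] == pytest.approx(x.mean())

    def test_loglik_non_decreasing(self):
        rng = np.random.default_rng(4)
        x = np.concatenate(
            [rng.normal(0, 0.2, 300), rng.normal(-2, 0.2, 200), rng.normal(0, 0.2, 300)]
        )
        _, traj = ideal.baum_welch_fit(make_rec(x), K=2, seed=1, max_iter=100)
        assert np.all(np.diff(traj) >= -1e-8)

    def test_posteriors_sum_to_one(self):
        from mcugate._kernels import backward_scaled, forward_scaled
        from mcugate.idealization import _gaussian_emissions

        rng = np.random.default_rng(9)
        x = rng.normal(-1, 0.5, 400)
        model = random_hmm(rng, 3)
        b = _gaussian_emissions(x, model.means, model.sd)
        alpha, c = forward_scaled(b, model.trans, model.init)
        beta = backward_scaled(b, model.trans, c)
        gamma = alpha * beta
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)

    def test_recovers_default_model_filtered_pipeline(self, short_wt_trace):
        """Amplitudes within 5 % through the full resample-and-fit
        pipeline on one simulated (filtered) trace."""
        model_true, rec, _ = short_wt_trace
        low = ideal.resample(rec, 2_500.0)
        fit, traj = ideal.baum_welch_fit(low, K=4, seed=0, max_iter=300)
        assert np.all(np.diff(traj) >= -1e-8)
        truth_means = model_true.level_currents
        assert abs(fit.means[0]) < 0.05
        np.testing.assert_allclose(fit.means[1:], truth_means[1:], rtol=0.05)

    def test_recovers_transition_matrix_unfiltered(self, gating_default):
        """Transition rows within 0.02 absolute of ground truth when
        emissions are conditionally independent (no acquisition filter):
        the Baum-Welch estimator itself, free of filter-smearing bias."""
        from dataclasses import replace

        # emission noise set to the level the filtered+decimated pipeline
        # reaches at 2.5 kHz (~0.13 pA)
        model_true = replace(
            gating_default.potentiated(105e6, "WT"), noise_sd=0.13
        )
        rec, _ = syn.simulate_single_channel(
            model_true, duration=60.0, sample_rate=2_500.0,
            filter_cutoff=None, seed=21,
        )
        fit, _ = ideal.baum_welch_fit(rec, K=4, seed=0, max_iter=300)
        trans_true = np.linalg.matrix_power(model_true.transition_matrix, 20)
        assert np.abs(fit.trans - trans_true).max() < 0.02
        np.testing.assert_allclose(fit.means[1:], model_true.level_currents[1:], rtol=0.05)


class TestChannelStats:
    def test_arithmetic(self):
        model = ideal.HMMModel(
            means=[0.0, -2.0], sd=0.1,
            trans=[[0.9, 0.1], [0.1, 0.9]], init=[0.5, 0.5],
        )
        states = np.array([0] * 7 + [1] * 3)
        st = ideal.channel_stats(ideal.IdealizedTrace(states, 2500.0), model)
        assert st.p_open == pytest.approx(0.3)
        assert st.i_avg == pytest.approx(-0.6)

    def test_all_closed_path(self):
        model = ideal.HMMModel(
            means=[0.0, -2.0], sd=0.1,
            trans=[[0.9, 0.1], [0.1, 0.9]], init=[0.5, 0.5],
        )
        st = ideal.channel_stats(ideal.IdealizedTrace(np.zeros(10, int), 2500.0), model)
        assert st.p_open == 0.0 and st.i_avg == 0.0

    def test_i_avg_equals_reconstructed_trace_mean(self, short_wt_trace):
        _, rec, _ = short_wt_trace
        model, idealized, st = ideal.idealize_recording(rec, seed=0)
        recon = model.means[idealized.states]
        assert st.i_avg == pytest.approx(recon.mean(), abs=1e-12)

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            ideal.IdealizedTrace(np.array([], dtype=int), 2500.0)


class TestCompareGenotypes:
    def _stats(self, po, amp=-2.0):
        occ = np.array([1 - po, po])
        return ideal.ChannelStats(
            amplitudes=np.array([0.0, amp]), occupancy=occ,
            p_open=po, i_avg=float(occ @ [0.0, amp]),
        )

    def test_identical_groups_ratio_one_p_one(self):
        g = {"WT": [self._stats(0.5)] * 3, "KO": [self._stats(0.5)] * 3}
        cmp = ideal.compare_genotypes(g)
        assert cmp.ratio_of_means == 1.0
        assert cmp.p_value == pytest.approx(1.0)

    def test_t_statistic_matches_textbook_formula(self):
        a, b = [0.5, 0.6, 0.55], [0.2, 0.25, 0.22]
        g = {"WT": [self._stats(v) for v in a], "KO": [self._stats(v) for v in b]}
        cmp = ideal.compare_genotypes(g)
        # pooled-variance two-sample t
        na, nb = 3, 3
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t_hand = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert cmp.t_statistic == pytest.approx(t_hand)
        assert cmp.ratio_of_means == pytest.approx(np.mean(a) / np.mean(b))

    def test_small_group_rejected(self):
        g = {"WT": [self._stats(0.5)], "KO": [self._stats(0.2), self._stats(0.2)]}
        with pytest.raises(ValueError, match="at least 2"):
            ideal.compare_genotypes(g)
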