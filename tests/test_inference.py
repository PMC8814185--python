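"""Resampling inference: bootstrap, sign-permutation clusters, FDR, reliability."""

from itertools import product

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from chromadecode import inference as inf
from chromadecode.decoder import CVConfig
from chromadecode.preprocess import preprocess_pipeline
from chromadecode.problems import polarity_problems
from chromadecode.simulate import SimulationConfig, simulate_subject

POL_ID_PINK = next(p for p in polarity_problems() if p.id == "pol_id_pink")


class TestPeakTime:
    def test_unique_max(self):
        t = np.arange(0.0, 50.0, 5.0)
        curve = np.zeros(10)
        curve[4] = 1.0  # bin starting 20 ms
        assert inf.peak_time(curve, t, (0, 50)) == 20.0

    def test_flat_curve_ties_to_window_start(self):
        t = np.arange(0.0, 50.0, 5.0)
        assert inf.peak_time(np.full(10, 0.6), t, (10, 40)) == 10.0

    def test_two_equal_maxima_earliest_wins(self):
        t = np.arange(0.0, 600.0, 5.0)
        curve = np.full(120, 0.5)
        curve[t == 100.0] = 0.9
        curve[t == 300.0] = 0.9
        assert inf.peak_time(curve, t, (0, 600)) == 100.0

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            inf.peak_time(np.ones(5), np.arange(5.0), (10, 20))


class TestBootstrapCurves:
    def test_identical_subjects_zero_width(self):
        t = np.arange(0.0, 40.0, 5.0)
        curve = np.linspace(0.5, 0.9, 8)
        boot = inf.bootstrap_curves(np.tile(curve, (5, 1)), t, n_boot=200, seed=0)
        np.testing.assert_allclose(boot.ci_low, boot.ci_high)
        assert len(set(boot.peak_time_samples)) == 1

    def test_two_subjects_means_come_from_three_multisets(self):
        t = np.arange(0.0, 20.0, 5.0)
        a = np.array([0.5, 0.6, 0.7, 0.8])
        b = np.array([0.9, 0.8, 0.7, 0.6])
        boot = inf.bootstrap_curves(np.stack([a, b]), t, n_boot=500, seed=1)
        expected = {tuple(a), tuple(b), tuple((a + b) / 2)}
        rng_means = {tuple(np.round(m, 12)) for m in _resampled_means(np.stack([a, b]), 500, 1)}
        assert rng_means <= {tuple(np.round(np.array(e), 12)) for e in expected}
        # grand mean converges to the subject mean
        np.testing.assert_allclose(boot.mean_curve, (a + b) / 2, atol=0.02)

    def test_seed_determinism(self):
        t = np.arange(0.0, 20.0, 5.0)
        curves = np.random.default_rng(3).uniform(0.4, 0.9, size=(6, 4))
        b1 = inf.bootstrap_curves(curves, t, n_boot=100, seed=5)
        b2 = inf.bootstrap_curves(curves, t, n_boot=100, seed=5)
        np.testing.assert_array_equal(b1.peak_time_samples, b2.peak_time_samples)

    def test_mean_converges_to_subject_mean(self):
        rng = np.random.default_rng(7)
        curves = rng.uniform(0.4, 0.9, size=(10, 12))
        t = np.arange(0.0, 60.0, 5.0)
        boot = inf.bootstrap_curves(curves, t, n_boot=10_000, seed=2)
        subject_mean = curves.mean(axis=0)
        mc_se = curves.std(axis=0).max() / np.sqrt(10) / np.sqrt(10_000) * 3
        assert np.all(np.abs(boot.mean_curve - subject_mean) < 3 * curves.std(axis=0).max() / np.sqrt(10 * 10_000) + 1e-3)
        assert mc_se < 0.01


def _resampled_means(curves, n_boot, seed):
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, curves.shape[0], size=(n_boot, curves.shape[0]))
    return curves[draws].mean(axis=1)


class TestComparePeakTimes:
    def _summary(self, peaks):
        peaks = np.asarray(peaks, dtype=float)
        t = np.arange(0.0, 300.0, 5.0)
        return inf.BootstrapSummary(
            mean_curve=np.zeros(60), ci_low=np.zeros(60), ci_high=np.zeros(60),
            peak_time_samples=peaks, bin_start_times=t, n_boot=len(peaks),
        )

    def test_three_of_thousand(self):
        a = self._summary([110.0] * 997 + [100.0] * 3)
        b = self._summary([105.0] * 1000)
        cmp = inf.compare_peak_times(a, b)
        assert cmp.pvalue == pytest.approx(0.003)

    def test_all_later_reports_below_resolution(self):
        a = self._summary([120.0] * 1000)
        b = self._summary([100.0] * 1000)
        cmp = inf.compare_peak_times(a, b)
        assert cmp.pvalue == 0.0
        assert cmp.pvalue_text == "p < 0.001"

    def test_same_distribution_p_near_half(self):
        rng = np.random.default_rng(0)
        a = self._summary(rng.normal(100, 10, 1000))
        b = self._summary(rng.normal(100, 10, 1000))
        assert 0.4 < inf.compare_peak_times(a, b).pvalue < 0.6

    def test_mismatched_boot_counts_raise(self):
        with pytest.raises(ValueError):
            inf.compare_peak_times(self._summary([1.0] * 10), self._summary([1.0] * 20))


# ---------------------------------------------------------------------------
# exact enumeration oracle for the sign-permutation cluster test


def _exact_signperm_oracle(curves, chance, cdt, alpha):
    """Brute-force exact test: all sign assignments, explicit loops."""
    E = np.asarray(curves, dtype=float) - chance
    n, n_bins = E.shape
    assignments = list(product([1.0, -1.0], repeat=n))
    perm_means = [np.mean([s * e for s, e in zip(signs, E)], axis=0) for signs in assignments]
    obs = E.mean(axis=0)
    P = len(assignments)

    def pointwise_p(target):
        return np.array(
            [sum(pm[b] >= target[b] for pm in perm_means) / P for b in range(n_bins)]
        )

    def clusters_of(mask):
        out, cur = [], []
        for i, m in enumerate(mask):
            if m:
                cur.append(i)
            elif cur:
                out.append(cur)
                cur = []
        if cur:
            out.append(cur)
        return out

    p_obs = pointwise_p(obs)
    obs_clusters = clusters_of(p_obs < cdt)
    max_masses = []
    for pm in perm_means:
        pp = pointwise_p(pm)
        cl = clusters_of(pp < cdt)
        max_masses.append(max((sum(pm[i] for i in c) for c in cl), default=0.0))
    results = []
    for c in obs_clusters:
        mass = sum(obs[i] for i in c)
        pc = sum(mm >= mass for mm in max_masses) / P
        results.append((c, mass, pc))
    sig = np.zeros(n_bins, dtype=bool)
    for c, mass, pc in results:
        if pc < alpha:
            sig[list(c)] = True
    return p_obs, results, sig


class TestSignPermClusterTest:
    def test_exhaustive_enumeration_matches_exact_oracle(self):
        rng = np.random.default_rng(11)
        curves = 0.5 + rng.normal(0.0, 0.05, size=(5, 20))
        curves[:, 6:12] += 0.15  # a real localized effect
        mask = inf.signperm_cluster_test(
            curves, n_perm=32, cdt=0.05, alpha=0.05, seed=0,
            bin_start_times=np.arange(0.0, 100.0, 5.0),
        )
        assert mask.exact
        p_obs, results, sig = _exact_signperm_oracle(curves, 0.5, 0.05, 0.05)
        np.testing.assert_allclose(mask.pointwise_p, p_obs)
        assert len(mask.clusters) == len(results)
        for cl, (cells, mass, pc) in zip(mask.clusters, results):
            assert list(cl.cells) == cells
            assert cl.mass == pytest.approx(mass)
            assert cl.pvalue == pytest.approx(pc)
        np.testing.assert_array_equal(mask.significant, sig)

    def test_single_localized_effect_yields_one_cluster(self):
        rng = np.random.default_rng(2)
        curves = 0.5 + rng.normal(0.0, 0.01, size=(8, 40))
        curves[:, 15:25] += 0.3
        mask = inf.signperm_cluster_test(
            curves, n_perm=256, cdt=0.01, alpha=0.05, seed=1,
            bin_start_times=np.arange(0.0, 200.0, 5.0),
        )
        sig_clusters = [c for c in mask.clusters if c.pvalue < 0.05]
        assert len(sig_clusters) == 1
        assert set(range(15, 25)) <= set(sig_clusters[0].cells.tolist())

    def test_2d_matrix_clusters(self):
        rng = np.random.default_rng(3)
        mats = 0.5 + rng.normal(0.0, 0.01, size=(8, 12, 12))
        mats[:, 4:8, 4:8] += 0.3
        mask = inf.signperm_cluster_test(mats, n_perm=200, cdt=0.01, alpha=0.05, seed=0)
        assert mask.significant.shape == (12, 12)
        assert mask.significant[5, 5]
        assert not mask.significant[0, 11]

    def test_low_perm_count_warns(self):
        curves = 0.5 + np.random.default_rng(0).normal(0, 0.02, (12, 10))
        with pytest.warns(UserWarning, match="coarse"):
            inf.signperm_cluster_test(curves, n_perm=50, seed=0)


class TestOnsetAndCounts:
    def _mask(self, sig, t0=0.0):
        sig = np.asarray(sig, dtype=bool)
        return inf.SignificanceMask(
            significant=sig, clusters=[], alpha=0.05, cluster_defining_p=0.01,
            bin_start_times=t0 + 5.0 * np.arange(len(sig)),
        )

    def test_onset_at_first_long_run(self):
        sig = np.zeros(30, dtype=bool)
        sig[13:] = True
        assert inf.onset_time(self._mask(sig)) == 65.0

    def test_isolated_triples_give_none(self):
        sig = np.zeros(30, dtype=bool)
        sig[3:6] = True
        sig[10:13] = True
        assert inf.onset_time(self._mask(sig)) is None

    def test_four_bin_run_pattern(self):
        sig = np.zeros(60, dtype=bool)
        sig[52:56] = True
        assert inf.onset_time(self._mask(sig)) == 260.0

    def test_prestimulus_runs_ignored(self):
        sig = np.zeros(30, dtype=bool)
        sig[0:6] = True  # run entirely before 0 ms
        mask = self._mask(sig, t0=-50.0)
        assert inf.onset_time(mask) is None

    def test_significant_bin_count(self):
        sig = np.zeros(60, dtype=bool)
        assert inf.significant_bin_count(self._mask(sig)) == 0
        sig[5:47] = True
        assert inf.significant_bin_count(self._mask(sig)) == 42


def test_bh_fdr_matches_textbook_step_up():
    """Step-up rule on p=(0.001, 0.02, 0.04, 0.2) at q=0.05: the largest k
    with p_(k) <= k*q/m is 2, so exactly the two smallest pass."""
    pvals = np.array([0.001, 0.02, 0.04, 0.2])
    reject = multipletests(pvals, alpha=0.05, method="fdr_bh")[0]
    np.testing.assert_array_equal(reject, [True, True, False, False])


@pytest.fixture(scope="module")
def null_cv():
    return CVConfig(n_splits=4, trials_per_split=4, n_runs=3, n_selected_sensors=8, seed=5)


class TestWithinSubjectNull:
    def test_strong_signal_reported_near_latency(self, null_cv):
        """FDR-corrected shuffle nulls flag >= 4 consecutive bins around the
        implanted latency; the add-one p-values never leave (0, 1]."""
        cfg = SimulationConfig(
            n_subjects=1, n_sensors=16, n_trials_per_condition=48,
            epoch_window=(-50.0, 150.0), noise_sd=80.0, seed=21,
        )
        binned = preprocess_pipeline(simulate_subject(cfg, 0), n_per_condition=48)
        cv = null_cv.with_(trials_per_split=12, n_runs=5)
        res = inf.within_subject_null_test(binned, POL_ID_PINK, cv, n_null=800, seed=0)
        t = res.bin_start_times
        window = (t >= 95) & (t < 115)
        assert res.reported[window].all()
        assert res.reported.sum() >= 4
        assert np.all(res.pvalues >= 1 / 801) and np.all(res.pvalues <= 1.0)

    def test_null_signal_reports_nothing(self, null_cv):
        cfg = SimulationConfig(
            n_subjects=1, n_sensors=16, n_trials_per_condition=16,
            epoch_window=(-50.0, 200.0),
            amp_polarity_shared=0.0, amp_polarity_hue_specific=0.0,
            amp_hue_shared=0.0, amp_hue_polarity_specific=0.0,
            beta_LM=0.0, beta_S=0.0, seed=22,
        )
        binned = preprocess_pipeline(simulate_subject(cfg, 0), n_per_condition=16)
        res = inf.within_subject_null_test(binned, POL_ID_PINK, null_cv, n_null=200, seed=1)
        assert res.reported.sum() == 0


class TestTestRetest:
    def test_noiseless_signal_fully_reliable(self):
        cfg = SimulationConfig(
            n_subjects=1, n_sensors=12, n_trials_per_condition=40,
            epoch_window=(-50.0, 200.0), noise_sd=0.0, seed=31,
        )
        binned = preprocess_pipeline(simulate_subject(cfg, 0), n_per_condition=40)
        cv = CVConfig(n_splits=2, trials_per_split=5, n_runs=2, n_selected_sensors=6, seed=0)
        table = inf.test_retest(binned, POL_ID_PINK, cv, fractions=(0.25, 0.5), n_rep=2, seed=0)
        assert (table["correlation"] > 0.99).all()

    def test_pure_noise_unreliable(self):
        cfg = SimulationConfig(
            n_subjects=1, n_sensors=12, n_trials_per_condition=40,
            epoch_window=(-50.0, 200.0),
            amp_polarity_shared=0.0, amp_polarity_hue_specific=0.0,
            amp_hue_shared=0.0, amp_hue_polarity_specific=0.0,
            beta_LM=0.0, beta_S=0.0, seed=32,
        )
        binned = preprocess_pipeline(simulate_subject(cfg, 0), n_per_condition=40)
        cv = CVConfig(n_splits=2, trials_per_split=5, n_runs=2, n_selected_sensors=6, seed=0)
        table = inf.test_retest(binned, POL_ID_PINK, cv, fractions=(0.25, 0.5), n_rep=4, seed=0)
        assert abs(table["correlation"].mean()) < 0.35

    def test_overlapping_fractions_rejected(self, tiny_binned, cv_small):
        with pytest.raises(ValueError):
            inf.test_retest(tiny_binned[0], POL_ID_PINK, cv_small, fractions=(0.6,))


class TestDerivativeSpearman:
    def test_self_correlation_is_one(self):
        t = np.arange(0.0, 200.0, 5.0)
        curve = 0.5 + 0.3 * np.sin(t / 30.0)
        rho, _ = inf.derivative_spearman(curve, curve, t, start=0.0)
        assert rho == pytest.approx(1.0)

    def test_mirrored_curve_is_minus_one(self):
        t = np.arange(0.0, 200.0, 5.0)
        curve = 0.5 + 0.3 * np.sin(t / 30.0)
        rho, _ = inf.derivative_spearman(curve, 1.0 - curve, t, start=0.0)
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_rank_pattern(self):
        t = np.arange(0.0, 30.0, 5.0)
        a = np.array([0.0, 1.0, 3.0, 6.0, 10.0, 15.0])  # diffs 1,2,3,4,5
        b = np.array([0.0, 5.0, 9.0, 12.0, 14.0, 15.0])  # diffs 5,4,3,2,1
        rho, _ = inf.derivative_spearman(a, b, t, start=0.0, duration=30.0)
        assert rho == pytest.approx(-1.0)

    def test_short_window_rejected(self):
        t = np.arange(0.0, 200.0, 5.0)
        with pytest.raises(ValueError):
            inf.derivative_spearman(np.ones(40), np.ones(40), t, start=0.0, duration=10.0)


class TestSubjectConsistency:
    def test_identical_curves_rho_one(self):
        t = np.arange(0.0, 100.0, 5.0)
        curve = 0.5 + 0.3 * np.sin(t / 20.0)
        rho = inf.subject_consistency(np.tile(curve, (5, 1)), t, n_boot=50, window=(0, 100), seed=0)
        np.testing.assert_allclose(rho, 1.0)

    def test_independent_noise_rho_near_zero(self):
        rng = np.random.default_rng(4)
        curves = 0.5 + rng.normal(0.0, 0.05, size=(6, 40))
        t = np.arange(0.0, 200.0, 5.0)
        rho = inf.subject_consistency(curves, t, n_boot=100, window=(0, 200), seed=0)
        assert np.all(np.abs(rho) < 0.35)

    def test_snr_monotone_trend(self):
        """Stronger shared structure across subjects raises consistency."""
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 200.0, 5.0)
        template = 0.5 + 0.3 * np.exp(-((t - 100.0) ** 2) / 800.0)
        means = []
        for snr in (0.2, 2.0):
            curves = template[None, :] * snr + rng.normal(0.0, 0.05, size=(6, 40))
            rho = inf.subject_consistency(curves, t, n_boot=100, window=(0, 200), seed=1)
            means.append(rho.mean())
        assert means[1] > means[0]
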