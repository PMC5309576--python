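"""Bland-Altman, repeated-measures LOA, Wald tests, power, diagnostics."""

import numpy as np
import pytest
from scipy import stats

import tidalcompare as tc
from tidalcompare.agreement import DiffSample


def sample_from_diffs(d, subject=None):
    d = np.asarray(d, dtype=float)
    return DiffSample(np.zeros_like(d), d, subject=subject)


class TestBlandAltman:
    def test_identity_gives_zero_bias_and_loa(self):
        x = np.array([3.0, 4.0, 5.0, 6.0])
        res = tc.bland_altman(DiffSample(x, x))
        assert res.bias == 0.0
        assert res.loa_lower == res.loa_upper == 0.0

    def test_constant_input_r_is_nan_safe(self):
        x = np.full(5, 2.0)
        res = tc.bland_altman(DiffSample(x, x))
        assert np.isnan(res.pearson_r)

    def test_unit_sd_differences_give_multiplier_loa(self):
        # differences {-1, 0, 1}: mean 0, sample SD 1 -> LOA = +/-1.96
        res = tc.bland_altman(sample_from_diffs([-1.0, 0.0, 1.0]))
        assert res.bias == 0.0
        assert res.sd == 1.0
        assert res.loa_upper == 1.96
        assert res.loa_lower == -1.96

    def test_perfect_linear_pair_r_is_one(self):
        res = tc.bland_altman(DiffSample(np.array([10.0, 20.0]), np.array([10.0, 20.0])))
        assert res.pearson_r == pytest.approx(1.0)

    def test_constant_offset_bias_zero_width(self):
        x = np.array([1.0, 2.0, 3.0])
        res = tc.bland_altman(DiffSample(x, x + 0.7))
        assert res.bias == pytest.approx(0.7)
        assert res.loa_upper - res.loa_lower == pytest.approx(0.0, abs=1e-12)

    def test_loa_widen_with_noise(self, rng):
        x = rng.normal(size=400)
        widths = []
        for s in [0.0, 0.5, 1.0, 2.0]:
            res = tc.bland_altman(DiffSample(x, x + rng.normal(0, s + 1e-9, 400)))
            widths.append(res.loa_upper - res.loa_lower)
        assert widths == sorted(widths)

    def test_too_few_observations(self):
        with pytest.raises(tc.DataError):
            tc.bland_altman(sample_from_diffs([1.0]))


class TestPercentDiff:
    def test_printed_scale(self):
        pct, _ = tc.percent_diff(
            DiffSample(np.array([2.0, 2.0]), np.array([2.2, 2.0]))
        )
        np.testing.assert_allclose(pct, [10.0, 0.0])

    def test_worked_value(self):
        pct, _ = tc.percent_diff(
            DiffSample(np.array([1.17, 1.0]), np.array([1.2251, 1.0]))
        )
        assert pct[0] == pytest.approx(4.71, abs=0.005)

    def test_zero_reference_rejected(self):
        with pytest.raises(tc.DataError):
            tc.percent_diff(DiffSample(np.array([0.0, 1.0]), np.array([1.0, 1.0])))


class TestRepeatedMeasuresLOA:
    def test_equal_subject_distributions_match_pooled(self, rng):
        # sigma_b = 0: RM LOA within 2% of pooled Bland-Altman LOA
        d = rng.normal(0.1, 1.0, size=600)
        subj = np.repeat(np.arange(30), 20)
        s = sample_from_diffs(d, subject=subj)
        rm = tc.loa_repeated(s)
        ba = tc.bland_altman(s)
        width_rm = rm.loa_upper - rm.loa_lower
        width_ba = ba.loa_upper - ba.loa_lower
        assert width_rm == pytest.approx(width_ba, rel=0.02)
        assert rm.bias == pytest.approx(ba.bias, abs=1e-12)

    def test_variance_components_recovered(self):
        # 50 subjects x 20 breaths, sigma_b = 0.5, sigma_w = 1.0; a seeded
        # Monte-Carlo draw (the between-subject component is estimated from
        # only 50 effects, so its sampling error dominates the tolerance)
        rng = np.random.default_rng(2)
        k, m = 50, 20
        subj = np.repeat(np.arange(k), m)
        d = rng.normal(0, 0.5, k).repeat(m) + rng.normal(0, 1.0, k * m)
        rm = tc.loa_repeated(sample_from_diffs(d, subject=subj))
        assert rm.sigma2_between == pytest.approx(0.25, rel=0.15)
        assert rm.sigma2_within == pytest.approx(1.0, rel=0.15)

    def test_identical_differences_zero_width(self):
        subj = np.repeat([0, 1, 2], 4)
        rm = tc.loa_repeated(sample_from_diffs(np.full(12, 0.3), subject=subj))
        assert rm.bias == pytest.approx(0.3)
        assert rm.loa_upper - rm.loa_lower == pytest.approx(0.0, abs=1e-12)

    def test_single_subject_falls_back_to_pooled(self, rng):
        d = rng.normal(size=10)
        rm = tc.loa_repeated(sample_from_diffs(d, subject=np.zeros(10)))
        ba = tc.bland_altman(sample_from_diffs(d))
        assert rm.fallback_simple
        assert rm.loa_upper == pytest.approx(ba.loa_upper)

    def test_one_breath_per_subject_equals_simple(self, rng):
        d = rng.normal(size=25)
        rm = tc.loa_repeated(sample_from_diffs(d, subject=np.arange(25)))
        ba = tc.bland_altman(sample_from_diffs(d))
        assert rm.loa_lower == pytest.approx(ba.loa_lower)
        assert rm.loa_upper == pytest.approx(ba.loa_upper)

    def test_against_mixed_model_oracle(self, rng):
        # independent route: random-intercept ML fit (statsmodels MixedLM)
        import statsmodels.api as sm

        k, m = 25, 12
        subj = np.repeat(np.arange(k), m)
        d = rng.normal(0, 0.6, k).repeat(m) + rng.normal(0, 1.0, k * m)
        rm = tc.loa_repeated(sample_from_diffs(d, subject=subj))
        fit = sm.MixedLM(d, np.ones_like(d), groups=subj).fit(reml=True)
        sd_ml = float(np.sqrt(np.asarray(fit.cov_re)[0, 0] + fit.scale))
        assert rm.bias == pytest.approx(float(np.asarray(fit.fe_params)[0]), abs=0.02)
        assert rm.sd_total == pytest.approx(sd_ml, rel=0.05)

    def test_heavy_tailed_coverage_is_conservative(self, rng):
        # strongly peaked symmetric differences (rare large outliers, most
        # mass near zero, kurtosis >> 3 as in real breath-difference data):
        # the rare outliers inflate the SD so the LOA sit further apart than
        # the true 95% quantiles and coverage is conservative
        n = 20_000
        outlier = rng.random(n) < 0.04
        d = np.where(outlier, rng.normal(0, 3.0, n), rng.normal(0, 0.2, n))
        from scipy import stats

        assert stats.kurtosis(d, fisher=False) > 3
        subj = np.repeat(np.arange(100), n // 100)
        rm = tc.loa_repeated(sample_from_diffs(d, subject=subj))
        coverage = np.mean((d >= rm.loa_lower) & (d <= rm.loa_upper))
        assert coverage >= 0.95


class TestWaldTest:
    def test_same_group_gives_p_one(self, rng):
        d = rng.normal(size=30)
        g = tc.bland_altman(sample_from_diffs(d))
        res = tc.wald_loa_equality(g, g)
        assert res.p_lower == 1.0 and res.p_upper == 1.0

    def test_type_i_error_calibrated(self):
        # 1000 null simulations: per-limit rejection rate within [0.03, 0.07]
        rng = np.random.default_rng(1234)
        n = 40
        rej_lower = rej_upper = 0
        n_sim = 1000
        for _ in range(n_sim):
            g1 = tc.bland_altman(sample_from_diffs(rng.normal(size=n)))
            g2 = tc.bland_altman(sample_from_diffs(rng.normal(size=n)))
            w = tc.wald_loa_equality(g1, g2)
            rej_lower += w.p_lower < 0.05
            rej_upper += w.p_upper < 0.05
        assert 0.03 <= rej_lower / n_sim <= 0.07
        assert 0.03 <= rej_upper / n_sim <= 0.07

    def test_widely_separated_limits_reject(self, rng):
        g1 = tc.bland_altman(sample_from_diffs(rng.normal(0, 1, 50)))
        g2 = tc.bland_altman(sample_from_diffs(rng.normal(0, 6, 50)))
        res = tc.wald_loa_equality(g1, g2)
        assert res.p_upper < 0.001 and res.p_lower < 0.001

    def test_degenerate_zero_variance_rejected(self):
        g = tc.bland_altman(sample_from_diffs([0.5, 0.5, 0.5]))
        with pytest.raises(tc.DataError):
            tc.wald_loa_equality(g, g)


class TestDetectableChange:
    def test_monotone_in_sample_size(self, rng):
        d = rng.normal(size=400)
        small = tc.bland_altman(sample_from_diffs(d[:40]))
        large = tc.bland_altman(sample_from_diffs(d))
        base = tc.bland_altman(sample_from_diffs(rng.normal(size=40)))
        d_small = tc.detectable_loa_change(base, small).delta_min
        d_large = tc.detectable_loa_change(base, large).delta_min
        assert d_large < d_small

    def test_empirical_power_at_delta_min(self):
        # shift the second group's bias by the returned minimum detectable
        # change (a bias shift moves a limit without altering the limit SEs
        # the post-hoc analysis conditions on): power must be near 0.80
        rng = np.random.default_rng(99)
        n, sigma = 40, 1.0
        g_ref = tc.bland_altman(sample_from_diffs(rng.normal(0, sigma, n)))
        delta = tc.detectable_loa_change(g_ref, g_ref).delta_min
        hits = 0
        n_sim = 600
        for _ in range(n_sim):
            g1 = tc.bland_altman(sample_from_diffs(rng.normal(0, sigma, n)))
            g2 = tc.bland_altman(sample_from_diffs(delta + rng.normal(0, sigma, n)))
            hits += tc.wald_loa_equality(g1, g2).p_upper < 0.05
        assert 0.70 <= hits / n_sim <= 0.90

    def test_invalid_power_rejected(self, rng):
        g = tc.bland_altman(sample_from_diffs(rng.normal(size=10)))
        with pytest.raises(tc.DataError):
            tc.detectable_loa_change(g, g, power=1.5)


class TestDiagnostics:
    def test_normal_sample_kurtosis_near_three(self, rng):
        d = rng.normal(size=100_000)
        diag = tc.distribution_diagnostics(sample_from_diffs(d))
        assert diag.kurtosis == pytest.approx(3.0, abs=0.2)

    def test_laplace_kurtosis_near_six(self, rng):
        d = rng.laplace(size=200_000)
        diag = tc.distribution_diagnostics(sample_from_diffs(d))
        assert diag.kurtosis == pytest.approx(6.0, abs=0.5)

    def test_log_retest_skipped_for_negative_values(self, rng):
        ref = rng.uniform(1, 2, 50)
        test = ref + rng.normal(0, 0.1, 50)
        test[0] = -0.5
        diag = tc.distribution_diagnostics(DiffSample(ref, test))
        assert not diag.log_retested
        assert "non-positive" in diag.log_skip_reason

    def test_log_retest_runs_for_positive_pairs(self, rng):
        ref = rng.uniform(1, 2, 200)
        test = ref * rng.lognormal(0, 0.05, 200)
        diag = tc.distribution_diagnostics(DiffSample(ref, test))
        assert diag.log_retested
        assert np.isfinite(diag.log_kurtosis)

    def test_constant_sample_rejected(self):
        with pytest.raises(tc.DataError):
            tc.distribution_diagnostics(sample_from_diffs(np.full(10, 1.0)))


def test_bland_altman_plot_writes_file(tmp_path, rng):
    ref = rng.uniform(10, 20, 30)
    sample = DiffSample(ref, ref + rng.normal(0, 0.5, 30), parameter="RR")
    res = tc.bland_altman(sample)
    path = tmp_path / "ba.png"
    tc.bland_altman_plot(sample, res, str(path))
    assert path.stat().st_size > 0
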