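import numpy as np
import pytest
import scipy.stats

from urchinwalk import (
    ancova_entropy,
    gls_heteroscedastic,
    levene_test,
    lm_treatment,
)
from urchinwalk.errors import InsufficientDataError

# Frozen fixture for the heteroscedastic GLS: 12 "control" + 9 "predator"
# values with a strong variance contrast.  Expected values computed with
# R nlme::gls(y ~ g, weights = varIdent(form = ~1|g), method = "ML") and
# anova() against the intercept-only fit (R 4.3.3, nlme 3.1-168).
GLS_A = [0.9725, 0.9086, 0.7697, 0.6583, 0.6745, 0.2737,
         0.7601, 0.6306, 0.784, 0.7921, 0.9632, 0.6507]
GLS_B = [0.9597, 1.0335, 0.9066, 0.9429, 0.944, 0.8647,
         0.962, 0.8727, 1.0207]
GLS_R_CHI2 = 9.8878720234
GLS_R_P = 0.001663716551
GLS_R_AIC = -25.8413212251
GLS_R_SD_CONTROL = 0.1794514
GLS_R_SD_RATIO = 0.3064774

# Frozen ANCOVA fixture; expected sequential F/p from R anova(lm(...)).
ANC_SLOPE = [0.813, 0.949, 0.888, 0.613, 0.65, 0.937, 0.503, 0.911, 0.899,
             0.734, 0.895, 0.892, 0.888, 0.917, 0.926, 0.933, 0.999, 0.969]
ANC_H = [1.3085, 1.1371, 1.1806, 1.8684, 1.6779, 1.346, 2.1134, 1.3378,
         1.0798, 1.6142, 1.1832, 1.208, 1.018, 1.0921, 1.0158, 1.0235,
         1.1291, 0.9589]
ANC_G = ["control"] * 10 + ["predator"] * 8
ANC_R_F = [60.2510182951, 83.1508122490, 1.8046697139]
ANC_R_P = [1.942480885e-06, 2.892135257e-07, 0.2005204719]


class TestLevene:
    def test_identical_groups_statistic_zero(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        stat, p = levene_test(vals, ["a"] * 3 + ["b"] * 3)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_singleton_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            levene_test([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_power_against_ninefold_variance(self, rng):
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            x = np.concatenate([rng.normal(0, 1, 200), rng.normal(0, 3, 200)])
            g = ["a"] * 200 + ["b"] * 200
            _, p = levene_test(x, g)
            rejections += p < 0.01
        assert rejections / n_rep >= 0.95

    def test_type_one_error_calibrated(self, rng):
        n_rep = 5000
        ps = np.empty(n_rep)
        for i in range(n_rep):
            x = rng.normal(0, 1, 40)
            ps[i] = levene_test(x, ["a"] * 20 + ["b"] * 20)[1]
        assert np.mean(ps < 0.05) == pytest.approx(0.05, abs=0.015)


class TestLmTreatment:
    def test_identical_groups(self):
        m = lm_treatment([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        eff = m.effects[0]
        assert eff.statistic == pytest.approx(0.0, abs=1e-12)
        assert eff.p_value == pytest.approx(1.0)
        assert m.n_per_group == {"a": 3, "b": 3}

    def test_separated_groups(self, rng):
        y = np.concatenate([rng.normal(0, 1e-4, 4), 1 + rng.normal(0, 1e-4, 4)])
        m = lm_treatment(y, ["a"] * 4 + ["b"] * 4)
        assert m.effects[0].p_value < 1e-8

    def test_f_equals_squared_pooled_t(self, rng):
        """Algebraic identity on random datasets."""
        for _ in range(200):
            na, nb = rng.integers(3, 30, 2)
            ya = rng.normal(0, 1, na)
            yb = rng.normal(rng.normal(), 1, nb)
            m = lm_treatment(
                np.concatenate([ya, yb]), ["a"] * na + ["b"] * nb
            )
            t, p = scipy.stats.ttest_ind(ya, yb, equal_var=True)
            assert m.effects[0].statistic == pytest.approx(t**2, rel=1e-8)
            assert m.effects[0].p_value == pytest.approx(p, rel=1e-8)

    def test_residual_df(self):
        m = lm_treatment(list(range(10)), ["a"] * 5 + ["b"] * 5)
        resid = [e for e in m.effects if e.term == "residuals"][0]
        assert resid.df == 8

    def test_shift_and_scale_invariance(self, rng):
        y = rng.normal(0, 1, 20)
        g = ["a"] * 12 + ["b"] * 8
        f0 = lm_treatment(y, g).effects[0].statistic
        f1 = lm_treatment(5.0 * y + 3.0, g).effects[0].statistic
        assert f0 == pytest.approx(f1, rel=1e-9)


class TestGlsHeteroscedastic:
    def test_matches_r_nlme_oracle(self):
        m = gls_heteroscedastic(
            GLS_A + GLS_B, ["control"] * 12 + ["predator"] * 9
        )
        eff = m.effects[0]
        assert eff.statistic_name == "chi2"
        assert eff.statistic == pytest.approx(GLS_R_CHI2, abs=1e-8)
        assert eff.p_value == pytest.approx(GLS_R_P, rel=1e-6)
        assert m.aic == pytest.approx(GLS_R_AIC, abs=1e-8)
        assert m.group_sds["control"] == pytest.approx(GLS_R_SD_CONTROL, abs=1e-6)
        assert m.group_sd_ratio == pytest.approx(GLS_R_SD_RATIO, abs=1e-6)

    def test_identical_groups_chi2_zero(self):
        vals = [1.0, 2.0, 3.0, 4.0] * 2
        m = gls_heteroscedastic(vals, ["a"] * 4 + ["b"] * 4)
        assert m.effects[0].statistic == pytest.approx(0.0, abs=1e-10)
        assert m.effects[0].p_value == pytest.approx(1.0)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            gls_heteroscedastic([1, 1, 1, 1, 2, 3], ["a"] * 3 + ["b"] * 3)

    def test_agrees_with_lm_under_equal_variance(self, rng):
        """LRT chi2 tracks the homoscedastic LM's decision when variances match."""
        agree = 0
        n_rep = 300
        for _ in range(n_rep):
            y = np.concatenate([rng.normal(0, 1, 25), rng.normal(0.4, 1, 25)])
            g = ["a"] * 25 + ["b"] * 25
            p_gls = gls_heteroscedastic(y, g).effects[0].p_value
            p_lm = lm_treatment(y, g).effects[0].p_value
            agree += (p_gls < 0.05) == (p_lm < 0.05)
        assert agree / n_rep >= 0.95

    def test_power_at_study_like_effect(self, rng):
        """N(0.75, 0.15^2) n=29 vs N(0.95, 0.05^2) n=21: near-certain detection."""
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            y = np.concatenate(
                [rng.normal(0.75, 0.15, 29), rng.normal(0.95, 0.05, 21)]
            )
            g = ["control"] * 29 + ["predator"] * 21
            rejections += gls_heteroscedastic(y, g).effects[0].p_value < 0.01
        assert rejections / n_rep >= 0.90

    def test_aic_prefers_heteroscedastic_fit_under_sd_ratio_3(self, rng):
        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            y = np.concatenate([rng.normal(0, 1, 25), rng.normal(0, 3, 25)])
            m = gls_heteroscedastic(y, ["a"] * 25 + ["b"] * 25)
            wins += m.aic < m.extra["aic_homoscedastic"]
        assert wins / n_rep >= 0.90

    def test_wald_option_close_to_lrt(self, rng):
        y = np.concatenate([rng.normal(0.7, 0.15, 29), rng.normal(0.95, 0.05, 21)])
        g = ["a"] * 29 + ["b"] * 21
        lrt = gls_heteroscedastic(y, g, test="lrt").effects[0]
        wald = gls_heteroscedastic(y, g, test="wald").effects[0]
        # both tests agree on this clear-cut effect and are the same order
        assert lrt.p_value < 0.001 and wald.p_value < 0.001
        assert 1 / 3 < wald.statistic / lrt.statistic < 3

    def test_shift_scale_invariance(self, rng):
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 2, 10)])
        g = ["a"] * 10 + ["b"] * 10
        a = gls_heteroscedastic(y, g).effects[0].statistic
        b = gls_heteroscedastic(4.0 * y - 2.0, g).effects[0].statistic
        assert a == pytest.approx(b, rel=1e-8)


class TestAncovaEntropy:
    def test_matches_r_sequential_anova(self):
        m = ancova_entropy(ANC_H, ANC_SLOPE, ANC_G)
        stats = [e.statistic for e in m.effects[:3]]
        ps = [e.p_value for e in m.effects[:3]]
        np.testing.assert_allclose(stats, ANC_R_F, rtol=1e-8)
        np.testing.assert_allclose(ps, ANC_R_P, rtol=1e-6)
        resid = [e for e in m.effects if e.term == "residuals"][0]
        assert resid.df == len(ANC_H) - 4

    def test_deterministic_linear_dependence(self):
        slope = np.array([0.5, 0.6, 0.7, 0.8, 0.55, 0.65, 0.75, 0.85])
        entropy = 2.0 - slope
        g = ["a", "a", "a", "a", "b", "b", "b", "b"]
        m = ancova_entropy(entropy, slope, g)
        by_term = {e.term: e for e in m.effects}
        assert by_term["slope"].p_value < 1e-10
        # residuals of the full fit are pure rounding noise; the interaction
        # explains none of the response beyond that noise
        assert by_term["treatment:slope"].p_value > 0.05

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            ancova_entropy([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4], ["a", "a", "b", "b"])

    def test_constant_slope_within_both_groups_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ancova_entropy(
                list(range(8)), [0.5] * 4 + [0.9] * 4, ["a"] * 4 + ["b"] * 4
            )

    def test_null_p_values_uniform(self, rng):
        """All three sequential tests are calibrated when entropy is noise."""
        n_rep = 400
        ps = np.empty((n_rep, 3))
        for i in range(n_rep):
            slope = np.concatenate([rng.uniform(0.5, 1, 25), rng.uniform(0.5, 1, 25)])
            entropy = rng.normal(0, 1, 50)
            g = ["a"] * 25 + ["b"] * 25
            m = ancova_entropy(entropy, slope, g)
            ps[i] = [e.p_value for e in m.effects[:3]]
        for j in range(3):
            assert scipy.stats.kstest(ps[:, j], "uniform").pvalue > 0.01

    def test_power_with_group_offset_and_slope_relation(self, rng):
        n_rep, hits_t, hits_s = 100, 0, 0
        for _ in range(n_rep):
            slope = np.concatenate([rng.uniform(0.5, 1, 25), rng.uniform(0.8, 1, 25)])
            g = ["a"] * 25 + ["b"] * 25
            offset = np.where(np.array(g) == "b", -0.25, 0.0)
            entropy = 3.0 - 1.5 * slope + offset + rng.normal(0, 0.15, 50)
            m = ancova_entropy(entropy, slope, g)
            by_term = {e.term: e for e in m.effects}
            hits_t += by_term["treatment"].p_value < 0.05
            hits_s += by_term["slope"].p_value < 0.05
        assert hits_t / n_rep >= 0.90
        assert hits_s / n_rep >= 0.90
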