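"""Association models, Firth fallback, fixed-effects meta-analysis, metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.special import expit

from penetrax.stats import (
    StratifiedEffect,
    fit_carrier_model,
    fit_gps_model_by_stratum,
    firth_logistic,
    interaction_test,
    logistic_fit,
    meta_fixed,
    performance_metrics,
    tertile_or,
)


def _labels(y):
    return np.where(y == 1, "case", "control").astype(object)


class TestCarrierModel:
    def test_2x2_closed_form_odds_ratio(self):
        # carrier-cases a=10, carrier-controls b=90, noncarrier c=1, d=99:
        # OR = (10*99)/(90*1) = 11.0
        carrier = np.array([1] * 100 + [0] * 100)
        y = np.array([1] * 10 + [0] * 90 + [1] * 1 + [0] * 99)
        eff = fit_carrier_model(_labels(y), carrier)
        assert eff.or_ == pytest.approx(11.0, rel=1e-4)
        assert eff.n_cases == 10 and eff.n_controls == 90

    def test_recovers_planted_log_or(self):
        rng = np.random.default_rng(0)
        n = 30_000
        carrier = (rng.random(n) < 0.02).astype(float)
        beta = np.log(5.0)
        y = (rng.random(n) < expit(-3.0 + beta * carrier)).astype(int)
        eff = fit_carrier_model(_labels(y), carrier)
        assert abs(eff.log_or - beta) < 2 * eff.se

    def test_null_coverage_over_replicates(self):
        rng = np.random.default_rng(1)
        covered = 0
        for _ in range(100):
            carrier = (rng.random(2000) < 0.1).astype(float)
            y = (rng.random(2000) < 0.2).astype(int)
            eff = fit_carrier_model(_labels(y), carrier)
            lo, hi = eff.ci
            covered += lo <= 1.0 <= hi
        assert covered >= 94

    def test_separation_falls_back_to_firth(self):
        carrier = np.array([1] * 20 + [0] * 80)
        y = np.array([1] * 20 + [0] * 80)  # complete separation
        with pytest.warns(UserWarning, match="Firth"):
            eff = fit_carrier_model(_labels(y), carrier)
        assert eff.method == "firth"
        assert np.isfinite(eff.log_or) and np.isfinite(eff.se)


class TestFirth:
    def test_matches_ml_when_data_are_well_behaved(self):
        rng = np.random.default_rng(2)
        n = 5000
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.5 + 0.8 * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        bf, _ = firth_logistic(y, X)
        coef, *_ = logistic_fit(y, X, term_names=["const", "x"])
        assert bf[1] == pytest.approx(coef["x"], abs=0.01)


class TestGpsByStratum:
    def test_recovery_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        n = 40_000
        g = rng.normal(size=n)
        carrier = (rng.random(n) < 0.05).astype(bool)
        beta = np.log(1.7)
        y = (rng.random(n) < expit(-2.5 + beta * g + 1.0 * carrier)).astype(int)
        out = fit_gps_model_by_stratum(_labels(y), g, carrier)
        assert abs(out["noncarrier"].log_or - beta) < 2.5 * out["noncarrier"].se
        # doubling the score scale leaves the per-SD estimate unchanged
        out2 = fit_gps_model_by_stratum(_labels(y), 2.0 * g, carrier)
        assert out2["noncarrier"].log_or == pytest.approx(
            out["noncarrier"].log_or, rel=1e-6)

    def test_shuffled_scores_give_null(self):
        rng = np.random.default_rng(4)
        n = 20_000
        g = rng.normal(size=n)
        carrier = (rng.random(n) < 0.05).astype(bool)
        y = (rng.random(n) < expit(-2.0 + 0.6 * g)).astype(int)
        g_perm = rng.permutation(g)
        out = fit_gps_model_by_stratum(_labels(y), g_perm, carrier)
        lo, hi = out["noncarrier"].ci
        assert lo <= 1.0 <= hi


class TestTertileOr:
    def _sim(self, rng, n=60_000, bc=np.log(8), bg=np.log(1.8)):
        g = rng.normal(size=n)
        carrier = (rng.random(n) < 0.02).astype(bool)
        y = (rng.random(n) < expit(-3.2 + bc * carrier + bg * g)).astype(int)
        tert = 1 + (g > np.quantile(g, 1 / 3)) + (g > np.quantile(g, 2 / 3))
        return y, tert.astype(int), carrier

    def test_reference_row_is_exactly_one(self):
        rng = np.random.default_rng(5)
        y, tert, carrier = self._sim(rng)
        effs = tertile_or(_labels(y), tert, carrier)
        ref = [e for e in effs if e.stratum == "noncarrier_T2"][0]
        assert ref.or_ == 1.0 and ref.extra.get("reference")

    def test_planted_monotone_gradient(self):
        rng = np.random.default_rng(6)
        y, tert, carrier = self._sim(rng)
        effs = {e.stratum: e for e in tertile_or(_labels(y), tert, carrier)}
        assert (effs["carrier_T1"].log_or < effs["carrier_T2"].log_or
                < effs["carrier_T3"].log_or)
        assert (effs["noncarrier_T1"].log_or < 0 < effs["noncarrier_T3"].log_or)

    def test_null_gradient_when_score_has_no_effect(self):
        rng = np.random.default_rng(7)
        y, tert, carrier = self._sim(rng, bg=0.0)
        effs = {e.stratum: e for e in tertile_or(_labels(y), tert, carrier)}
        for a, b in [("carrier_T1", "carrier_T2"), ("carrier_T2", "carrier_T3")]:
            diff = abs(effs[a].log_or - effs[b].log_or)
            pooled = np.hypot(effs[a].se, effs[b].se)
            assert diff < 3 * pooled

    def test_empty_carrier_tertile_reported_as_na(self):
        rng = np.random.default_rng(8)
        y, tert, carrier = self._sim(rng, n=3000)
        # force an empty carrier tertile
        carrier = carrier & (tert != 1)
        effs = {e.stratum: e for e in tertile_or(_labels(y), tert, carrier)}
        assert np.isnan(effs["carrier_T1"].log_or)
        assert effs["carrier_T1"].extra.get("empty")

    def test_empty_reference_is_error(self):
        y = np.array([1, 0, 1, 0])
        tert = np.array([1, 1, 3, 3])
        with pytest.raises(ValueError, match="reference stratum"):
            tertile_or(_labels(y), tert, np.zeros(4, bool))


class TestInteraction:
    def test_estimates_equal_planted_conditional_effects(self):
        rng = np.random.default_rng(9)
        n = 60_000
        g = rng.normal(size=n)
        carrier = (rng.random(n) < 0.05).astype(bool)
        bc, bg = np.log(5), np.log(1.6)
        y = (rng.random(n) < expit(-3.0 + bc * carrier + bg * g)).astype(int)
        out = interaction_test(_labels(y), g, carrier)
        assert abs(out["carrier_log_or"] - bc) < 2.5 * out["carrier_se"]
        assert abs(out["gps_log_or"] - bg) < 2.5 * out["gps_se"]
        assert out["interaction_p"] > 0.001

    def test_power_against_planted_interaction(self):
        rng = np.random.default_rng(10)
        n = 60_000
        g = rng.normal(size=n)
        carrier = (rng.random(n) < 0.2).astype(bool)
        y = (rng.random(n) < expit(
            -2.0 + 0.7 * carrier + 0.4 * g + np.log(1.5) * carrier * g)).astype(int)
        out = interaction_test(_labels(y), g, carrier)
        assert out["interaction_p"] < 0.05
        assert abs(out["interaction_log_or"] - np.log(1.5)) < \
            2.5 * out["interaction_se"]


class TestMetaFixed:
    def _eff(self, b, se, cohort=""):
        return StratifiedEffect("s", b, se, 0.5, cohort=cohort)

    def test_hand_inverse_variance_oracle(self):
        # w1=1/0.0113^2, w2=1/0.0146^2 -> pooled 0.49372..., OR ~ 1.64
        m = meta_fixed([self._eff(0.5878, 0.0113), self._eff(0.3365, 0.0146)])
        w1, w2 = 0.0113**-2, 0.0146**-2
        expected = (0.5878 * w1 + 0.3365 * w2) / (w1 + w2)
        assert m.log_or == pytest.approx(expected, abs=1e-10)
        assert m.se == pytest.approx((w1 + w2) ** -0.5, abs=1e-10)
        assert m.or_ == pytest.approx(1.64, abs=0.005)

    def test_single_cohort_identity(self):
        m = meta_fixed([self._eff(0.3, 0.1)])
        assert m.log_or == pytest.approx(0.3) and m.se == pytest.approx(0.1)

    def test_equal_estimates_shrink_se(self):
        m = meta_fixed([self._eff(0.5, 0.2), self._eff(0.5, 0.2)])
        assert m.log_or == pytest.approx(0.5)
        assert m.se == pytest.approx(0.2 / np.sqrt(2))

    @settings(deadline=None, max_examples=50)
    @given(
        betas=hst.lists(hst.floats(-2, 2), min_size=2, max_size=5),
        seed=hst.integers(0, 100),
    )
    def test_pooled_between_bounds_and_order_invariant(self, betas, seed):
        rng = np.random.default_rng(seed)
        ses = rng.uniform(0.05, 0.5, size=len(betas))
        effs = [self._eff(b, s) for b, s in zip(betas, ses)]
        m = meta_fixed(effs)
        assert min(betas) - 1e-12 <= m.log_or <= max(betas) + 1e-12
        m2 = meta_fixed(effs[::-1])
        assert m2.log_or == pytest.approx(m.log_or, abs=1e-12)

    def test_infinite_se_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped"):
            m = meta_fixed([self._eff(0.3, 0.1), self._eff(5.0, np.inf)])
        assert m.log_or == pytest.approx(0.3)

    def test_no_usable_inputs_is_error(self):
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            meta_fixed([self._eff(0.3, np.nan)])


class TestCovariateInvariance:
    def test_affine_relabeling_of_covariates_leaves_or_unchanged(self):
        rng = np.random.default_rng(11)
        n = 20_000
        age = rng.uniform(40, 70, size=n)
        carrier = (rng.random(n) < 0.05).astype(float)
        y = (rng.random(n) < expit(-3 + 1.2 * carrier + 0.02 * (age - 55))).astype(int)
        cov1 = pd.DataFrame({"age": age})
        cov2 = pd.DataFrame({"age": (age - 50.0) / 10.0})
        e1 = fit_carrier_model(_labels(y), carrier, cov1)
        e2 = fit_carrier_model(_labels(y), carrier, cov2)
        assert e1.log_or == pytest.approx(e2.log_or, abs=1e-6)


class TestPerformanceMetrics:
    def test_null_score(self):
        rng = np.random.default_rng(12)
        y = (rng.random(20_000) < 0.3).astype(int)
        s = rng.normal(size=20_000)
        out = performance_metrics(_labels(y), s)
        assert out["auroc_crude"] == pytest.approx(0.5, abs=0.02)
        assert out["incremental_r2"] == pytest.approx(0.0, abs=0.005)

    def test_perfect_separation_gives_auroc_one(self):
        y = np.array([1] * 50 + [0] * 50)
        s = np.concatenate([np.random.default_rng(13).uniform(1, 2, 50),
                            np.random.default_rng(14).uniform(-2, -1, 50)])
        out = performance_metrics(_labels(y), s)
        assert out["auroc_crude"] == 1.0

    def test_matches_binormal_approximation(self):
        # score ~ N(delta,1) in cases vs N(0,1) in controls:
        # AUROC = Phi(delta/sqrt(2))
        from scipy.stats import norm
        rng = np.random.default_rng(15)
        delta = 1.0
        s = np.concatenate([rng.normal(delta, 1, 5000), rng.normal(0, 1, 5000)])
        y = np.array([1] * 5000 + [0] * 5000)
        out = performance_metrics(_labels(y), s)
        assert out["auroc_crude"] == pytest.approx(norm.cdf(delta / np.sqrt(2)),
                                                   abs=0.01)

    def test_one_class_labels_error(self):
        with pytest.raises(ValueError):
            performance_metrics(_labels(np.ones(10)), np.zeros(10))
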