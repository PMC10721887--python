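"""Polygenic scoring, P+T selection, ancestry calibration, tertiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from penetrax.gps import (
    ancestry_adjust,
    apol1_adjust_standardize,
    apol1_risk_genotype,
    assign_tertiles,
    pt_clump,
    score,
)


def _weights(ids, w, allele="T"):
    return pd.DataFrame({"variant_id": ids, "effect_allele": allele, "weight": w})


class TestScore:
    def test_weighted_sum_arithmetic(self):
        d = np.array([[0, 1, 2]])
        w = _weights(["a", "b", "c"], [0.1, -0.2, 0.3])
        assert score(d, w, ["a", "b", "c"])[0] == pytest.approx(0.4)

    def test_all_zero_weights(self):
        d = np.array([[2, 2], [0, 1]])
        out = score(d, _weights(["a", "b"], [0.0, 0.0]), ["a", "b"])
        assert np.allclose(out, 0.0)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(50, 10))
        ids = [f"v{i}" for i in range(10)]
        w = rng.normal(size=10)
        s1 = score(d, _weights(ids, w), ids)
        s3 = score(d, _weights(ids, 3 * w), ids)
        assert np.allclose(s3, 3 * s1)

    def test_effect_allele_flip_preserves_rank_order(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(100, 8))
        ids = [f"v{i}" for i in range(8)]
        w = rng.normal(size=8)
        base = score(d, _weights(ids, w), ids, dosage_alt_alleles=["T"] * 8)
        # flipping the stated effect allele flips dosage to 2-d; negating the
        # weight restores the same ranking (score shifts by a constant)
        flipped = score(d, _weights(ids, -w, allele="G"), ids,
                        dosage_alt_alleles=["T"] * 8)
        assert sps.spearmanr(base, flipped).statistic == pytest.approx(1.0)

    def test_missing_dosage_contributes_zero_in_sum_mode(self):
        d = np.array([[-1, 2]])
        out = score(d, _weights(["a", "b"], [5.0, 1.0]), ["a", "b"])
        assert out[0] == pytest.approx(2.0)

    def test_majority_unmatched_is_error(self):
        d = np.zeros((2, 1))
        w = _weights(["a", "x", "y"], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="unmatched"):
            score(d, w, ["a"])

    def test_duplicate_weight_ids_rejected(self):
        w = _weights(["a", "a"], [1.0, 2.0])
        with pytest.raises(ValueError, match="duplicate"):
            score(np.zeros((1, 1)), w, ["a"])


class TestPtClump:
    def test_correlated_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(2)
        a = rng.binomial(2, 0.5, size=500).astype(float)
        dos = np.column_stack([a, a, rng.binomial(2, 0.5, size=500)])
        ss = pd.DataFrame({"variant_id": ["a", "b", "c"], "effect_allele": "T",
                           "beta": [0.5, 0.4, 0.3], "p": [1e-8, 1e-4, 1e-3]})
        out = pt_clump(ss, dos, ["a", "b", "c"])
        assert list(out["variant_id"]) == ["a", "c"]
        assert list(out["weight"]) == [0.5, 0.3]  # discovery betas unchanged

    def test_all_above_p_threshold_gives_empty_table(self):
        dos = np.random.default_rng(3).binomial(2, 0.5, size=(100, 2)).astype(float)
        ss = pd.DataFrame({"variant_id": ["a", "b"], "effect_allele": "T",
                           "beta": [0.5, 0.4], "p": [0.5, 0.9]})
        assert len(pt_clump(ss, dos, ["a", "b"])) == 0

    def test_brute_force_r2_audit_on_selected_set(self):
        rng = np.random.default_rng(4)
        n, m = 1500, 40
        z = rng.standard_normal((n, m))
        for j in range(1, m):
            z[:, j] = 0.7 * z[:, j - 1] + np.sqrt(1 - 0.49) * z[:, j]
        dos = (z < 0).astype(float) + (rng.standard_normal((n, m)) < 0)
        ids = [f"v{j}" for j in range(m)]
        ss = pd.DataFrame({"variant_id": ids, "effect_allele": "T",
                           "beta": rng.normal(size=m),
                           "p": rng.uniform(0, 0.03, size=m)})
        out = pt_clump(ss, dos, ids, r2_max=0.2, window=m)
        cols = [ids.index(v) for v in out["variant_id"]]
        x = dos[:, cols] - dos[:, cols].mean(axis=0)
        sd = x.std(axis=0)
        r = (x.T @ x) / n / np.outer(sd, sd)
        off = r[~np.eye(len(cols), dtype=bool)]
        assert (off**2 <= 0.2 + 1e-12).all()


class TestAncestryAdjust:
    def _two_group(self, rng, n_per=2000, shift=3.0):
        pcs = np.vstack([rng.normal(-2, 0.2, size=(n_per, 1)),
                         rng.normal(2, 0.2, size=(n_per, 1))])
        pcs = np.column_stack([pcs, rng.normal(size=(2 * n_per, 1))])
        raw = rng.normal(size=2 * n_per) + shift * (pcs[:, 0] > 0)
        return raw, pcs

    def test_group_means_aligned_after_adjustment(self):
        rng = np.random.default_rng(5)
        ref_raw, ref_pcs = self._two_group(rng)
        raw, pcs = self._two_group(rng)
        adj = ancestry_adjust(raw, ref_raw, ref_pcs, pcs, n_pcs=2)
        g = pcs[:, 0] > 0
        assert abs(adj[g].mean() - adj[~g].mean()) < 0.05

    def test_reference_adjusted_to_standard_scale(self):
        rng = np.random.default_rng(6)
        ref_raw, ref_pcs = self._two_group(rng)
        adj = ancestry_adjust(ref_raw, ref_raw, ref_pcs, ref_pcs, n_pcs=2)
        assert abs(adj.mean()) < 0.05
        assert adj.std() == pytest.approx(1.0, abs=0.1)
        for g in (ref_pcs[:, 0] > 0, ref_pcs[:, 0] <= 0):
            assert abs(adj[g].mean()) < 0.06
            assert adj[g].std() == pytest.approx(1.0, abs=0.1)

    def test_uninformative_pcs_reduce_to_global_standardization(self):
        rng = np.random.default_rng(7)
        raw = rng.normal(5, 2, size=1000)
        pcs = rng.normal(size=(1000, 2))  # carry no score information
        adj = ancestry_adjust(raw, raw, pcs, pcs, n_pcs=2)
        expected = (raw - raw.mean()) / raw.std()
        # the variance model adds estimation wiggle but no systematic change
        assert np.corrcoef(adj, expected)[0, 1] > 0.99
        assert abs(adj.mean()) < 0.05 and abs(adj.std() - 1.0) < 0.1

    def test_small_reference_is_error(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="too small"):
            ancestry_adjust(rng.normal(size=10), rng.normal(size=50),
                            rng.normal(size=(50, 10)), rng.normal(size=(10, 10)),
                            n_pcs=10)


class TestApol1:
    @pytest.mark.parametrize(
        "g1,g2,expected",
        [(2, 0, 1), (0, 2, 1), (1, 1, 1), (1, 0, 0), (0, 1, 0), (0, 0, 0)],
    )
    def test_recessive_risk_genotype_definition(self, g1, g2, expected):
        assert apol1_risk_genotype([g1], [g2])[0] == expected

    def test_residualization_removes_association(self):
        rng = np.random.default_rng(9)
        n = 50_000
        ind = (rng.random(n) < 0.1).astype(float)
        adjusted = rng.normal(size=n) + 0.8 * ind
        out = apol1_adjust_standardize(adjusted, ind)
        r = np.corrcoef(out["standardized"], ind)[0, 1]
        assert abs(r) < 0.01

    def test_missing_indicator_treated_as_zero_with_warning(self):
        rng = np.random.default_rng(10)
        ind = np.array([1.0, np.nan, 0.0, 0.0, np.nan, 1.0] * 2)
        with pytest.warns(UserWarning, match="APOL1"):
            out = apol1_adjust_standardize(rng.normal(size=12), ind)
        assert set(out["apol1_indicator"]) <= {0, 1}

    def test_standardized_output_is_mean_zero_sd_one(self):
        rng = np.random.default_rng(11)
        out = apol1_adjust_standardize(rng.normal(3, 5, size=1000),
                                       np.zeros(1000), mode="none")
        assert abs(out["standardized"].mean()) < 1e-9
        assert out["standardized"].std(ddof=0) == pytest.approx(1.0)


class TestTertiles:
    def test_cut_points_match_analytic_normal_tertiles(self):
        rng = np.random.default_rng(12)
        s = rng.standard_normal(100_000)
        t = assign_tertiles(s)
        # empirical cut points must approximate +-0.4307 (normal tertiles)
        assert s[t == 1].max() == pytest.approx(-0.4307, abs=0.02)
        assert s[t == 3].min() == pytest.approx(0.4307, abs=0.02)
        counts = np.bincount(t)[1:]
        assert counts.max() - counts.min() <= 2

    def test_three_distinct_values_one_per_tertile(self):
        assert list(assign_tertiles(np.array([5.0, -1.0, 2.0]))) == [3, 1, 2]

    def test_partition_exact(self):
        rng = np.random.default_rng(13)
        t = assign_tertiles(rng.normal(size=1000))
        assert set(t) == {1, 2, 3}

    def test_degenerate_constant_scores_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            assign_tertiles(np.ones(10))

    def test_carrier_labels_come_from_cohort_wide_cuts(self, small_pipeline):
        # carriers' tertiles must be assigned on the same cohort-wide scale,
        # not carrier-only percentiles: carrier tertile counts are unbalanced
        res = small_pipeline.cohorts["cohort1"]
        scores = res.scores
        carrier = res.carriers["dominant_carrier"].to_numpy()
        all_t = assign_tertiles(scores["standardized"].to_numpy())
        assert np.array_equal(all_t, scores["tertile"].to_numpy())
        assert np.array_equal(all_t[carrier], scores["tertile"].to_numpy()[carrier])
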