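"""Qualifying-variant classification and carrier calling."""

import numpy as np
import pandas as pd
import pytest

from conftest import base_annotation, toy_rare
from penetrax.qv import (
    call_carriers,
    carrier_prevalence,
    classify,
    is_deleterious_missense,
    is_plof,
    penetrance,
)


class TestIsPlof:
    @pytest.mark.parametrize(
        "consequence,expected",
        [
            ("stop_gained", True),
            ("frameshift", True),
            ("stop_lost", True),
            ("start_lost", True),
            ("splice_acceptor", True),
            ("splice_donor", True),
            ("essential_splice", True),
            ("splice_region", False),  # non-essential splice is not LOF
            ("missense", False),
            ("synonymous", False),
        ],
    )
    def test_consequence_set(self, consequence, expected):
        assert is_plof(consequence) is expected


class TestDeleteriousMissense:
    def _df(self, **kw):
        return pd.DataFrame([base_annotation(**kw)])

    def test_unanimous_and_high_revel(self):
        kw = {c: "damaging" for c in
              ("sift", "polyphen2_hdiv", "polyphen2_hvar", "lrt", "mutation_taster")}
        assert is_deleterious_missense(self._df(revel=0.80, **kw))[0]

    def test_four_of_five_fails_consensus(self):
        kw = {c: "damaging" for c in
              ("sift", "polyphen2_hdiv", "polyphen2_hvar", "lrt")}
        assert not is_deleterious_missense(
            self._df(revel=0.80, mutation_taster="tolerated", **kw))[0]

    def test_revel_boundary_is_strict(self):
        kw = {c: "damaging" for c in
              ("sift", "polyphen2_hdiv", "polyphen2_hvar", "lrt", "mutation_taster")}
        assert not is_deleterious_missense(self._df(revel=0.70, **kw))[0]

    def test_missing_scores_fail_conservatively(self):
        kw = {c: "damaging" for c in
              ("sift", "polyphen2_hdiv", "polyphen2_hvar", "lrt")}
        assert not is_deleterious_missense(
            self._df(revel=np.nan, mutation_taster="damaging", **kw))[0]
        assert not is_deleterious_missense(
            self._df(revel=0.9, mutation_taster="missing", **kw))[0]


DAMAGING = {c: "damaging" for c in
            ("sift", "polyphen2_hdiv", "polyphen2_hvar", "lrt", "mutation_taster")}


class TestClassify:
    def _models(self, row):
        annot = pd.DataFrame([row])
        return {m: bool(classify(annot, m)["qualifying"][0]) for m in ("M1", "M2", "M3")}

    def test_asserted_p_low_revel_in_m1_m2_not_m3(self):
        # the clinically asserted missense with poor in-silico support shows
        # why M3 need not contain M1
        row = base_annotation(clinvar_assertion="P", clinvar_n_submitters=2,
                              revel=0.2)
        assert self._models(row) == {"M1": True, "M2": True, "M3": False}

    def test_lp_three_submitters_is_m2_only(self):
        row = base_annotation(clinvar_assertion="LP", clinvar_n_submitters=3,
                              revel=0.2)
        assert self._models(row) == {"M1": False, "M2": True, "M3": False}

    def test_plof_with_varsome_lb_vetoed_everywhere(self):
        row = base_annotation(consequence="stop_gained", revel=np.nan,
                              varsome_assertion="LB")
        assert self._models(row) == {"M1": False, "M2": False, "M3": False}

    def test_single_submitter_excluded(self):
        row = base_annotation(clinvar_assertion="P", clinvar_n_submitters=1)
        assert self._models(row) == {"M1": False, "M2": False, "M3": False}

    def test_conflict_excluded(self):
        row = base_annotation(clinvar_assertion="P", clinvar_n_submitters=3,
                              clinvar_conflict_flag=True)
        assert self._models(row) == {"M1": False, "M2": False, "M3": False}

    def test_deleterious_missense_is_m3_only(self):
        row = base_annotation(revel=0.85, **DAMAGING)
        assert self._models(row) == {"M1": False, "M2": False, "M3": True}

    def test_plof_in_all_models(self):
        row = base_annotation(consequence="splice_donor", revel=np.nan)
        assert self._models(row) == {"M1": True, "M2": True, "M3": True}

    def test_varsome_vus_never_vetoes(self):
        row = base_annotation(clinvar_assertion="P", clinvar_n_submitters=2,
                              varsome_assertion="VUS")
        assert self._models(row)["M1"] is True

    def test_unknown_assertion_vocabulary_is_error(self):
        row = base_annotation(clinvar_assertion="Pathogenic")
        with pytest.raises(ValueError, match="assertion"):
            classify(pd.DataFrame([row]), "M1")

    def test_m1_subset_of_m2_on_generated_annotations(self, small_study):
        annot = small_study.cohorts["cohort1"].annotation
        m1 = set(classify(annot, "M1").query("qualifying")["variant_id"])
        m2 = set(classify(annot, "M2").query("qualifying")["variant_id"])
        assert m1 <= m2
        assert len(m1) < len(m2)

    def test_matches_generated_truth_exactly(self, small_study):
        var = small_study.truth_variants
        annot = small_study.cohorts["cohort1"].annotation
        for model in ("M1", "M2", "M3"):
            got = classify(annot, model)["qualifying"].to_numpy()
            want = var[f"qv_{model.lower()}"].to_numpy()
            assert np.array_equal(got, want)


class TestCallCarriers:
    def _qv(self, ids):
        return pd.DataFrame({"variant_id": ids, "qualifying": True, "qv_model": "M1"})

    def test_single_het_is_dominant_only(self):
        rare = toy_rare([[1, 0], [0, 0]], genes=["PKD1", "PKD1"], sex=["F", "F"])
        out = call_carriers(self._qv(["v0", "v1"]), rare)
        assert bool(out["dominant_carrier"][0]) and not bool(out["recessive_genotype"][0])
        assert not out["dominant_carrier"][1]

    def test_compound_het_female_col4a3(self):
        rare = toy_rare([[1, 1]], genes=["COL4A3", "COL4A3"], sex=["F"])
        out = call_carriers(self._qv(["v0", "v1"]), rare)
        assert bool(out["recessive_genotype"][0])
        assert out["zygosity"][0] == "comp_het"

    def test_two_hets_in_different_genes_not_compound(self):
        rare = toy_rare([[1, 1]], genes=["COL4A3", "COL4A4"], sex=["F"])
        out = call_carriers(self._qv(["v0", "v1"]), rare)
        assert not bool(out["recessive_genotype"][0])

    def test_male_col4a5_hemizygote(self):
        rare = toy_rare([[2], [0]], genes=["COL4A5"], chroms=["X"], sex=["M", "F"])
        out = call_carriers(self._qv(["v0"]), rare)
        assert bool(out["recessive_genotype"][0])
        assert out["zygosity"][0] == "hemi"

    def test_homozygote_any_gene(self):
        rare = toy_rare([[2]], genes=["PKD2"], sex=["F"])
        out = call_carriers(self._qv(["v0"]), rare)
        assert bool(out["recessive_genotype"][0])
        assert out["zygosity"][0] == "hom"

    def test_male_het_x_warned_and_flagged(self):
        rare = toy_rare([[1]], genes=["COL4A5"], chroms=["X"], sex=["M"])
        with pytest.warns(UserWarning, match="heterozygous X"):
            out = call_carriers(self._qv(["v0"]), rare)
        assert bool(out["dominant_carrier"][0])
        assert bool(out["male_het_x_flag"][0])

    def test_recessive_implies_dominant(self, small_pipeline):
        for res in small_pipeline.cohorts.values():
            c = res.carriers
            assert not (c["recessive_genotype"] & ~c["dominant_carrier"]).any()

    def test_carrier_counts_nondecreasing_m1_to_m2(self, small_study):
        from penetrax.filtering import filter_variants
        cohort = small_study.cohorts["cohort1"]
        masked, surviving, _ = filter_variants(
            cohort.rare, cohort.annotation,
            thresholds=small_study.config.maf_thresholds)
        counts = {}
        for model in ("M1", "M2"):
            qv = classify(surviving, model)
            out = call_carriers(qv, masked)
            counts[model] = int(out["dominant_carrier"].sum())
        assert counts["M1"] <= counts["M2"]

    def test_planted_in_cis_pair_called_compound(self, small_study):
        # unphased genotypes cannot distinguish in-cis pairs: the planted one
        # must be (incorrectly but by documented design) called compound het
        from penetrax.filtering import filter_variants
        cohort = small_study.cohorts["cohort1"]
        masked, surviving, _ = filter_variants(
            cohort.rare, cohort.annotation,
            thresholds=small_study.config.maf_thresholds)
        qv = classify(surviving, "M3")
        qv = qv[qv["gene"].isin(["COL4A3", "COL4A4", "COL4A5"])]
        out = call_carriers(qv, masked)
        cis_id = cohort.truth.loc[cohort.truth["in_cis_pair"], "participant_id"].iloc[0]
        row = out.loc[out["participant_id"] == cis_id].iloc[0]
        assert bool(row["recessive_genotype"])


class TestPenetrance:
    def test_pooled_carrier_count_arithmetic(self):
        # 41 carrier-cases and 81 carrier-controls pooled across cohorts
        carrier = np.ones(122, dtype=bool)
        status = np.array([1.0] * 41 + [0.0] * 81)
        out = penetrance(carrier, status)
        assert out["penetrance"] == pytest.approx(41 / 122, abs=1e-12)
        assert out["penetrance"] == pytest.approx(0.336, abs=0.001)
        lo, hi = out["ci"]
        assert lo < 41 / 122 < hi

    def test_zero_cases(self):
        out = penetrance(np.ones(10, bool), np.zeros(10))
        assert out["penetrance"] == 0.0

    def test_zero_carriers_undefined(self):
        out = penetrance(np.zeros(5, bool), np.ones(5))
        assert np.isnan(out["penetrance"])
        assert "undefined" in out["note"]

    def test_excluded_participants_ignored(self):
        carrier = np.ones(4, bool)
        status = np.array([1.0, 0.0, np.nan, np.nan])
        assert penetrance(carrier, status)["penetrance"] == 0.5

    def test_recovers_planted_penetrance_within_binomial_3sigma(self, small_pipeline):
        res = small_pipeline.cohorts["cohort1"]
        truth = small_pipeline.study.cohorts["cohort1"].truth
        carrier = truth["carrier_adpkd_m1"].to_numpy()
        status = truth["label"].map({"case": 1.0, "control": 0.0}).to_numpy()
        true_pen = np.nansum(status[carrier]) / np.isfinite(status[carrier]).sum()
        est = res.penetrance["penetrance"]
        n = res.penetrance["n_carriers"]
        sigma = np.sqrt(true_pen * (1 - true_pen) / n)
        assert abs(est - true_pen) <= 3 * sigma + 1e-9


class TestCarrierPrevalence:
    def test_reported_count_arithmetic(self):
        assert carrier_prevalence(34, 98_622) == pytest.approx(0.034, abs=0.0005)
        assert carrier_prevalence(1435, 469_835) == pytest.approx(0.31, abs=0.005)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            carrier_prevalence(5, 0)
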