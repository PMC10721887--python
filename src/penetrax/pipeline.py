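"""End-to-end orchestration: simulate -> filter -> classify -> phenotype ->
ancestry -> polygenic score -> association statistics -> PheWAS.

Each stage's outputs are kept on a :class:`PipelineResult`; a JSON manifest
records the seed, stage completion, and content hashes of the statistics
tables so a rerun with the same configuration and seed is verifiably
identical.  Covariate conventions follow the analysis they serve: the
carrier / per-SD / interaction CKD models adjust for age, sex, diabetes,
batch and four ancestry PCs; the tertile figures and the PheWAS adjust for
age, sex, batch and their own PC count (four and five respectively), without
diabetes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ancestry as anc
from . import gps as gpsmod
from . import phewas as phw
from . import qv as qvmod
from . import stats as st
from .filtering import filter_variants
from .phenotyping import PhenotypingConfig, assign_case_control, derive_covariates
from .simulate import SimConfig, SimulatedStudy, simulate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "qv", "phenotype", "ancestry", "gps", "assoc", "phewas")


@dataclass
class RunConfig:
    """Model choices, covariate conventions, and stage toggles for one run."""

    sim: SimConfig = field(default_factory=SimConfig)
    qv_model: str = "M1"
    inheritance: str = "dominant"  # or "recessive"
    equation: str = "2009"
    gene_set: str | None = None  # defaults to sim.analysis_gene_set
    n_pcs_projection: int = 10
    n_pcs_assoc: int = 4
    n_pcs_phewas: int = 5
    kinship_threshold: float = 0.0442
    # kinship exclusion is off by default: the KING estimator needs thousands
    # of pruned variants for its noise to sit safely below the 0.0442
    # threshold, and the simulated cohorts are unrelated by construction.
    # Set kinship_max_n above the cohort size to enable the stage.
    kinship_max_n: int = 0
    apol1_mode: str = "residualize"
    phewas_min_cases: int = 20
    stages: tuple = STAGES

    def validate(self):
        if self.qv_model not in qvmod.QV_MODELS:
            raise ValueError(f"unknown QV model {self.qv_model!r}")
        if self.inheritance not in ("dominant", "recessive"):
            raise ValueError("inheritance must be dominant or recessive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        self.sim.validate()
        return self


@dataclass
class CohortResult:
    name: str
    filter_report: object = None
    surviving_annotation: pd.DataFrame | None = None
    qv_table: pd.DataFrame | None = None
    carriers: pd.DataFrame | None = None
    labels: pd.DataFrame | None = None
    covariates: pd.DataFrame | None = None
    pcs: np.ndarray | None = None
    ancestry_calls: pd.DataFrame | None = None
    scores: pd.DataFrame | None = None
    carrier_effect: object = None
    gps_effects: dict = field(default_factory=dict)
    tertile_effects: list = field(default_factory=list)
    interaction: dict = field(default_factory=dict)
    performance: dict = field(default_factory=dict)
    penetrance: dict = field(default_factory=dict)
    phewas: pd.DataFrame | None = None


@dataclass
class PipelineResult:
    config: RunConfig
    study: SimulatedStudy
    cohorts: dict
    meta: dict = field(default_factory=dict)
    meta_phewas: pd.DataFrame | None = None
    phewas_threshold: float = np.nan
    manifest: dict = field(default_factory=dict)


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False, float_format="%.10g").encode()
    ).hexdigest()[:16]


def _assoc_covariates(cov: pd.DataFrame, pcs: np.ndarray, n_pcs: int,
                      include_diabetes: bool) -> pd.DataFrame:
    out = pd.DataFrame({
        "age": cov["age"].to_numpy(),
        "sex_male": cov["sex_male"].to_numpy(dtype=float),
        "batch": cov["batch"].astype(object).to_numpy(),
    })
    if include_diabetes:
        out["diabetes"] = cov["diabetes"].to_numpy(dtype=float)
    for k in range(min(n_pcs, pcs.shape[1])):
        out[f"PC{k + 1}"] = pcs[:, k]
    return out


def run_pipeline(
    config: RunConfig | None = None,
    study: SimulatedStudy | None = None,
    outdir: str | None = None,
) -> PipelineResult:
    """Run the requested stages end to end.

    ``study`` may be supplied (e.g. reloaded from disk) to skip simulation;
    otherwise it is generated from ``config.sim``.  When ``outdir`` is given,
    statistics tables and the manifest are written there.
    """
    config = (config or RunConfig()).validate()
    gene_set = config.gene_set or config.sim.analysis_gene_set
    manifest: dict = {"seed": config.sim.seed, "stages_completed": [],
                      "hashes": {}, "qv_model": config.qv_model,
                      "gene_set": gene_set, "inheritance": config.inheritance}

    def _done(stage):
        manifest["stages_completed"].append(stage)

    try:
        if study is None:
            if "simulate" not in config.stages:
                raise ValueError("no study supplied and simulate stage disabled")
            study = simulate_cohort(config.sim)
        _done("simulate")

        results = {name: CohortResult(name=name) for name in study.cohorts}

        # reference panel scored once with the shared weights
        panel_raw = gpsmod.score(
            study.panel_dosages, study.weights, study.panel_variant_ids)

        for name, cohort in study.cohorts.items():
            res = results[name]
            sex = cohort.phenotypes["sex"].to_numpy()

            if "filter" in config.stages:
                masked, surviving, report = filter_variants(
                    cohort.rare, cohort.annotation,
                    thresholds=config.sim.maf_thresholds)
                res.filter_report = report
                res.surviving_annotation = surviving
                _cohort_rare = masked
                _done(f"filter:{name}")
            else:
                _cohort_rare, surviving = cohort.rare, cohort.annotation

            if "qv" in config.stages:
                qv_table = qvmod.classify(surviving, config.qv_model)
                in_set = qv_table["gene"].isin(
                    dict(adpkd=("PKD1", "PKD2"),
                         col4a=("COL4A3", "COL4A4", "COL4A5"))[gene_set])
                res.qv_table = qv_table
                res.carriers = qvmod.call_carriers(
                    qv_table.loc[in_set], _cohort_rare, sex=sex,
                    model=config.qv_model)
                _done(f"qv:{name}")

            if "phenotype" in config.stages:
                res.labels = assign_case_control(
                    cohort.phenotypes, PhenotypingConfig(equation=config.equation))
                res.covariates = derive_covariates(cohort.phenotypes)
                _done(f"phenotype:{name}")

            if "ancestry" in config.stages:
                kept = anc.ld_prune(cohort.dosages)
                _, pcs, projector = anc.project_pcs(
                    study.panel_dosages[:, kept], cohort.dosages[:, kept],
                    n_pcs=config.n_pcs_projection)
                ref_pcs = projector.reference_pcs_
                calls, acc = anc.classify_ancestry(
                    ref_pcs, study.panel_labels, pcs, seed=config.sim.seed)
                res.pcs = pcs
                res.ancestry_calls = calls
                res.ancestry_calls.attrs["heldout_accuracy"] = acc
                n = len(cohort.phenotypes)
                if n <= config.kinship_max_n:
                    pairs = anc.king_kinship(
                        cohort.dosages[:, kept],
                        cohort.phenotypes["participant_id"].to_numpy(),
                        min_kinship=config.kinship_threshold)
                    res.ancestry_calls.attrs["kept_after_kinship"] = anc.exclude_related(
                        pairs, config.kinship_threshold,
                        cohort.phenotypes["participant_id"].to_numpy())
                else:
                    logger.info("kinship skipped for %s (n=%d > kinship_max_n=%d)",
                                name, n, config.kinship_max_n)
                res._gps_inputs = (projector, kept)  # type: ignore[attr-defined]
                _done(f"ancestry:{name}")

            if "gps" in config.stages:
                projector, kept = res._gps_inputs  # type: ignore[attr-defined]
                raw = gpsmod.score(cohort.dosages, study.weights,
                                   cohort.dosage_variant_ids)
                ref_pcs_full = projector.reference_pcs_
                adjusted = gpsmod.ancestry_adjust(
                    raw, panel_raw, ref_pcs_full, res.pcs,
                    n_pcs=config.n_pcs_projection)
                apol1 = gpsmod.apol1_risk_genotype(
                    cohort.phenotypes["apol1_g1"], cohort.phenotypes["apol1_g2"])
                res.scores = gpsmod.apol1_adjust_standardize(
                    adjusted, apol1, mode=config.apol1_mode)
                res.scores.insert(0, "participant_id",
                                  cohort.phenotypes["participant_id"].to_numpy())
                res.scores.insert(1, "raw", raw)
                _done(f"gps:{name}")

        if "assoc" in config.stages:
            for name, cohort in study.cohorts.items():
                res = results[name]
                carrier = (
                    res.carriers["dominant_carrier"]
                    if config.inheritance == "dominant"
                    else res.carriers["recessive_genotype"]
                ).to_numpy()
                labels = res.labels["label"].to_numpy()
                scores = res.scores["standardized"].to_numpy()
                tert = res.scores["tertile"].to_numpy()
                cov_full = _assoc_covariates(res.covariates, res.pcs,
                                             config.n_pcs_assoc, True)
                cov_fig = _assoc_covariates(res.covariates, res.pcs,
                                            config.n_pcs_assoc, False)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res.carrier_effect = st.fit_carrier_model(
                        labels, carrier, cov_full, cohort=name)
                    res.gps_effects = st.fit_gps_model_by_stratum(
                        labels, scores, carrier, cov_full, cohort=name)
                    res.tertile_effects = st.tertile_or(
                        labels, tert, carrier, cov_fig, cohort=name)
                    res.interaction = st.interaction_test(
                        labels, scores, carrier, cov_full, cohort=name)
                    res.performance = st.performance_metrics(labels, scores, cov_full)
                status = pd.Series(labels).map({"case": 1.0, "control": 0.0}).to_numpy()
                res.penetrance = qvmod.penetrance(carrier, status)
            _meta_all(results, manifest)
            _done("assoc")
        meta = manifest.pop("_meta", {})

        phewas_threshold = np.nan
        meta_phewas_df = None
        if "phewas" in config.stages:
            per_cohort = []
            for name, cohort in study.cohorts.items():
                res = results[name]
                matrix, pc_meta = phw.map_codes(
                    cohort.phenotypes["icd9_codes"], study.phecode_map)
                carrier = (
                    res.carriers["dominant_carrier"]
                    if config.inheritance == "dominant"
                    else res.carriers["recessive_genotype"]
                ).to_numpy()
                cov = _assoc_covariates(res.covariates, res.pcs,
                                        config.n_pcs_phewas, False)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res.phewas = phw.run_phewas(
                        matrix, carrier, cov, min_cases=config.phewas_min_cases,
                        cohort=name)
                per_cohort.append(res.phewas)
            meta_phewas_df, phewas_threshold = phw.meta_phewas(
                per_cohort, phecode_meta=pc_meta)
            manifest["hashes"]["meta_phewas"] = _hash_df(meta_phewas_df)
            _done("phewas")

    except Exception as exc:
        stage = manifest["stages_completed"][-1] if manifest["stages_completed"] else "start"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    manifest["n_stages"] = len({s.split(":")[0] for s in manifest["stages_completed"]})
    result = PipelineResult(config=config, study=study, cohorts=results,
                            meta=meta, meta_phewas=meta_phewas_df,
                            phewas_threshold=phewas_threshold, manifest=manifest)
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _meta_all(results: dict, manifest: dict):
    """Fixed-effects meta-analysis of every per-cohort estimate."""
    meta: dict = {}
    cohorts = list(results.values())
    meta["carrier"] = st.meta_fixed([r.carrier_effect for r in cohorts])
    for stratum in ("carrier", "noncarrier"):
        meta[f"gps_per_sd_{stratum}"] = st.meta_fixed(
            [r.gps_effects[stratum] for r in cohorts])
    tertile_meta = {}
    for i, name in enumerate(st.TERTILE_STRATA):
        if name == "noncarrier_T2":
            continue
        effs = [r.tertile_effects[i] for r in cohorts
                if np.isfinite(r.tertile_effects[i].log_or)]
        if effs:
            tertile_meta[name] = st.meta_fixed(effs)
    meta["tertiles"] = tertile_meta
    meta["interaction"] = st.meta_fixed([
        st.StratifiedEffect("interaction", r.interaction["interaction_log_or"],
                            r.interaction["interaction_se"],
                            r.interaction["interaction_p"], cohort=r.name)
        for r in cohorts])
    meta["joint_carrier"] = st.meta_fixed([
        st.StratifiedEffect("joint_carrier", r.interaction["carrier_log_or"],
                            r.interaction["carrier_se"], np.nan, cohort=r.name)
        for r in cohorts])
    meta["joint_gps"] = st.meta_fixed([
        st.StratifiedEffect("joint_gps", r.interaction["gps_log_or"],
                            r.interaction["gps_se"], np.nan, cohort=r.name)
        for r in cohorts])
    manifest["_meta"] = meta


def effects_table(result: PipelineResult) -> pd.DataFrame:
    """Forest-plot-ready table: per-cohort and meta ORs for every stratum."""
    rows = []
    for name, res in result.cohorts.items():
        if res.carrier_effect is not None:
            rows.append(res.carrier_effect.to_dict())
        for eff in res.gps_effects.values():
            rows.append(eff.to_dict())
        for eff in res.tertile_effects:
            rows.append(eff.to_dict())
    for key, m in result.meta.items():
        if key == "tertiles":
            for stratum, mm in m.items():
                rows.append({"stratum": stratum, "cohort": "meta",
                             "log_or": mm.log_or, "or": mm.or_, "se": mm.se,
                             "ci_low": mm.ci[0], "ci_high": mm.ci[1], "p": mm.p})
        else:
            rows.append({"stratum": key, "cohort": "meta", "log_or": m.log_or,
                         "or": m.or_, "se": m.se, "ci_low": m.ci[0],
                         "ci_high": m.ci[1], "p": m.p})
    return pd.DataFrame(rows)


def _write_outputs(result: PipelineResult, outdir: str):
    os.makedirs(outdir, exist_ok=True)
    table = effects_table(result)
    table.to_csv(os.path.join(outdir, "association_effects.tsv"), sep="\t",
                 index=False, float_format="%.10g")
    result.manifest["hashes"]["association_effects"] = _hash_df(table)
    if result.meta_phewas is not None:
        result.meta_phewas.to_csv(os.path.join(outdir, "meta_phewas.tsv"),
                                  sep="\t", index=False, float_format="%.10g")
    for name, res in result.cohorts.items():
        if res.labels is not None:
            res.labels.to_csv(os.path.join(outdir, f"labels_{name}.tsv"),
                              sep="\t", index=False, float_format="%.10g")
        if res.scores is not None:
            res.scores.to_csv(os.path.join(outdir, f"scores_{name}.tsv"),
                              sep="\t", index=False, float_format="%.10g")
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
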