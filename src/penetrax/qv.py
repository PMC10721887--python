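"""Qualifying-variant (QV) classification and carrier calling.

Three nested-in-spirit models define qualifying variants among QC-passing
rare variants:

* M1 (most stringent): pLOF, plus variants asserted Pathogenic (P) by at
  least two independent ClinVar submitters without conflicts.
* M2: pLOF, plus P or Likely Pathogenic (LP) under the same submitter rules.
* M3: pLOF, plus deleterious missense (REVEL > 0.70 and all five in-silico
  predictors damaging).

A Benign/Likely-Benign assertion from either ClinVar or Varsome vetoes a
variant from every model.  M1 ⊆ M2 always; M3 need not contain M1 (a
clinically asserted P missense with a low REVEL score is in M1/M2 only).

Carrier calling is per participant per model: dominant carriage is >= 1
alternate QV allele; recessive genotypes are homozygous-alternate QVs,
compound (>= 2 distinct heterozygous QVs in one of COL4A3/COL4A4; unphased,
so in-cis pairs are possible false positives), or hemizygous male COL4A5 QVs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .filtering import RareGenotypes
from .genes import (
    ASSERTION_VOCABULARY,
    PLOF_CONSEQUENCES,
    PREDICTOR_COLUMNS,
    REVEL_THRESHOLD,
)

__all__ = [
    "QV_MODELS",
    "is_plof",
    "is_deleterious_missense",
    "classify",
    "call_carriers",
    "penetrance",
    "carrier_prevalence",
]

QV_MODELS = ("M1", "M2", "M3")

#: genes in which two distinct heterozygous QVs are called a compound
#: heterozygote; COL4A5 recessive calls go through male hemizygosity instead.
COMPOUND_HET_GENES = ("COL4A3", "COL4A4")
HEMIZYGOUS_GENE = "COL4A5"


def is_plof(consequence) -> np.ndarray | bool:
    """Predicted loss-of-function: stop-gain, frameshift, stop-lost,
    start-lost, essential splice."""
    arr = np.asarray(consequence, dtype=object)
    out = np.isin(arr, list(PLOF_CONSEQUENCES))
    return out if out.shape else bool(out)


def is_deleterious_missense(annotation: pd.DataFrame) -> np.ndarray:
    """Missense with REVEL > 0.70 (strict) and unanimous 'damaging' verdicts
    from all five predictors.  Missing REVEL or predictor verdicts fail the
    test (conservative)."""
    missense = annotation["consequence"].to_numpy(dtype=object) == "missense"
    revel = pd.to_numeric(annotation["revel"], errors="coerce").to_numpy(dtype=float)
    revel_ok = np.where(np.isnan(revel), False, revel > REVEL_THRESHOLD)
    consensus = np.ones(len(annotation), dtype=bool)
    for col in PREDICTOR_COLUMNS:
        verdict = annotation[col].astype(object).to_numpy()
        consensus &= np.array([str(v) == "damaging" for v in verdict])
    return missense & revel_ok & consensus


def _check_assertions(annotation: pd.DataFrame):
    for col in ("clinvar_assertion", "varsome_assertion"):
        vals = set(annotation[col].fillna("none").astype(str))
        bad = vals - set(ASSERTION_VOCABULARY)
        if bad:
            raise ValueError(f"unknown assertion value(s) in {col}: {sorted(bad)}")


def classify(annotation: pd.DataFrame, model: str) -> pd.DataFrame:
    """Classify QC-passing variants under one QV model.

    Returns the annotation with boolean ``qualifying`` plus a ``qv_reason``
    column ('plof', 'clinvar', 'deleterious_missense', or '').
    """
    if model not in QV_MODELS:
        raise ValueError(f"unknown QV model: {model!r}")
    _check_assertions(annotation)

    clinvar = annotation["clinvar_assertion"].fillna("none").astype(str).to_numpy()
    varsome = annotation["varsome_assertion"].fillna("none").astype(str).to_numpy()
    n_sub = pd.to_numeric(annotation["clinvar_n_submitters"], errors="coerce").fillna(0)
    n_sub = n_sub.to_numpy(dtype=int)
    conflict = annotation["clinvar_conflict_flag"].fillna(False).astype(bool).to_numpy()

    benign_veto = np.isin(clinvar, ("B", "LB")) | np.isin(varsome, ("B", "LB"))
    plof = is_plof(annotation["consequence"])
    clinvar_solid = (n_sub >= 2) & ~conflict

    if model == "M1":
        asserted = (clinvar == "P") & clinvar_solid
        qualifying = (plof | asserted) & ~benign_veto
        reason_assert = asserted
        reason_dm = np.zeros(len(annotation), dtype=bool)
    elif model == "M2":
        asserted = np.isin(clinvar, ("P", "LP")) & clinvar_solid
        qualifying = (plof | asserted) & ~benign_veto
        reason_assert = asserted
        reason_dm = np.zeros(len(annotation), dtype=bool)
    else:  # M3
        dm = is_deleterious_missense(annotation)
        qualifying = (plof | dm) & ~benign_veto
        reason_assert = np.zeros(len(annotation), dtype=bool)
        reason_dm = dm

    reason = np.full(len(annotation), "", dtype=object)
    reason[qualifying & reason_dm] = "deleterious_missense"
    reason[qualifying & reason_assert] = "clinvar"
    reason[qualifying & plof] = "plof"

    out = annotation.copy()
    out["qualifying"] = qualifying
    out["qv_reason"] = reason
    out["qv_model"] = model
    return out


@dataclass
class CarrierCall:
    participant_id: object
    model: str
    dominant_carrier: bool
    recessive_genotype: bool
    supporting_variants: tuple
    zygosity: str  # '', 'het', 'hom', 'comp_het', 'hemi'


def call_carriers(
    qv_annotation: pd.DataFrame,
    rare: RareGenotypes,
    sex: np.ndarray | None = None,
    model: str | None = None,
) -> pd.DataFrame:
    """Per-participant dominant and recessive carrier status for one QV set.

    ``qv_annotation`` is the output of :func:`classify` (rows with
    ``qualifying`` True are used).  ``sex`` defaults to the genotype
    container's sex array and is required when X-linked QVs are present.
    """
    model = model or (qv_annotation["qv_model"].iloc[0] if len(qv_annotation) else "M1")
    qv = qv_annotation.loc[qv_annotation.get("qualifying", True)]
    sex = rare.sex if sex is None else np.asarray(sex)

    sub = rare.subset_variants(qv["variant_id"])
    genes = sub.variants["gene"].to_numpy(dtype=object)
    chroms = sub.variants["chrom"].to_numpy(dtype=object)
    vids = sub.variant_ids
    gt = np.maximum(sub.gt, 0)  # missing counts as reference

    n = len(rare.samples)
    male = (
        np.array([str(s).upper().startswith("M") for s in sex])
        if sex is not None
        else np.zeros(n, dtype=bool)
    )
    if (chroms == "X").any() and sex is None:
        raise ValueError("sex is required to call X-chromosome carriers")

    x_cols = chroms == "X"
    if x_cols.any():
        het_x = (gt[:, x_cols] == 1) & male[:, None]
        if het_x.any():
            warnings.warn(
                f"{int(het_x.any(axis=1).sum())} male heterozygous X call(s); "
                "treated as carriers and flagged"
            )

    dominant = (gt > 0).any(axis=1)
    hom_any = (gt == 2) & ~((chroms == "X")[None, :] & male[:, None])
    hom = hom_any.any(axis=1)

    comp_het = np.zeros(n, dtype=bool)
    for gene in COMPOUND_HET_GENES:
        cols = genes == gene
        if cols.any():
            comp_het |= (gt[:, cols] > 0).sum(axis=1) >= 2

    hemi_cols = (genes == HEMIZYGOUS_GENE) & (chroms == "X")
    hemi = male & (gt[:, hemi_cols] > 0).any(axis=1) if hemi_cols.any() else np.zeros(n, bool)

    recessive = hom | comp_het | hemi
    zyg = np.full(n, "", dtype=object)
    zyg[dominant] = "het"
    zyg[comp_het] = "comp_het"
    zyg[hom] = "hom"
    zyg[hemi] = "hemi"
    flag_het_x = np.zeros(n, dtype=bool)
    if x_cols.any():
        flag_het_x = ((gt[:, x_cols] == 1) & male[:, None]).any(axis=1)

    carrier_cols = gt > 0
    support = [tuple(vids[row]) for row in carrier_cols]

    return pd.DataFrame(
        {
            "participant_id": rare.samples,
            "model": model,
            "dominant_carrier": dominant,
            "recessive_genotype": recessive,
            "zygosity": zyg,
            "supporting_variants": support,
            "male_het_x_flag": flag_het_x,
        }
    )


def carrier_prevalence(n_carriers: int, n_total: int) -> float:
    """Carrier prevalence as a percentage of the cohort."""
    if n_total <= 0 or n_carriers < 0 or n_carriers > n_total:
        raise ValueError("invalid carrier / cohort counts")
    return 100.0 * n_carriers / n_total


def penetrance(
    carrier: np.ndarray, case_status: np.ndarray, alpha: float = 0.05
) -> dict:
    """P(disease | carrier): cases / (cases + controls) among carriers, with an
    exact (Clopper-Pearson) binomial confidence interval.

    ``case_status`` entries outside {0,1} (e.g. NaN for excluded participants)
    are ignored.
    """
    carrier = np.asarray(carrier, dtype=bool)
    status = np.asarray(case_status, dtype=float)
    usable = np.isfinite(status) & np.isin(status, (0.0, 1.0))
    k = int(status[carrier & usable].sum())
    n = int((carrier & usable).sum())
    if n == 0:
        return {"penetrance": np.nan, "n_carriers": 0, "ci": (np.nan, np.nan),
                "note": "undefined: zero carriers"}
    lo = sps.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = sps.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return {
        "penetrance": k / n,
        "n_carriers": n,
        "n_carrier_cases": k,
        "ci": (float(lo), float(hi)),
    }
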