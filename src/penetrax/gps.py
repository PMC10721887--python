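"""Genome-wide polygenic score (GPS): weighted-sum scoring, optional P+T
(pruning-and-thresholding) model building, ancestry calibration against a
labeled reference, APOL1 adjustment, standardization, and tertile assignment.

Ancestry calibration follows the two-stage reference-fit procedure: the raw
score is regressed on reference principal components to remove the
PC-predicted mean, then the log squared residual is regressed on the same PCs
to normalize the PC-predicted variance; cohort samples are transformed with
the reference fits only.  The APOL1 high-risk genotype (two risk alleles:
G1/G1, G2/G2 or G1/G2) is residualized out of the calibrated score before the
final standardization.  Tertiles are cut on the cohort-wide standardized
distribution so carrier and noncarrier strata share one scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "score",
    "pt_clump",
    "AncestryAdjuster",
    "ancestry_adjust",
    "apol1_risk_genotype",
    "apol1_adjust_standardize",
    "assign_tertiles",
]


def score(
    dosages: np.ndarray,
    weights: pd.DataFrame,
    dosage_variant_ids,
    dosage_alt_alleles=None,
    missing_mode: str = "sum",
) -> np.ndarray:
    """Raw score per participant: sum_m w_m * dosage_im ('--score sum' semantics).

    ``weights`` columns: variant_id, effect_allele, weight.  If
    ``dosage_alt_alleles`` is given, weights whose effect allele is the
    non-counted allele are applied to the flipped dosage (2 - d).  Missing
    dosages (coded -1) contribute 0 under 'sum' mode, or the variant's mean
    dosage under 'mean' mode.
    """
    if weights["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in weights table")
    if not np.all(np.isfinite(weights["weight"].to_numpy(dtype=float))):
        raise ValueError("non-finite weights")

    ids = list(dosage_variant_ids)
    pos = {v: i for i, v in enumerate(ids)}
    matched = weights.loc[weights["variant_id"].isin(pos)]
    n_unmatched = len(weights) - len(matched)
    if n_unmatched:
        if n_unmatched > 0.5 * len(weights):
            raise ValueError(
                f"{n_unmatched}/{len(weights)} weight variants unmatched in dosages"
            )
        warnings.warn(f"{n_unmatched} weight variant(s) unmatched in dosages")

    cols = np.array([pos[v] for v in matched["variant_id"]])
    w = matched["weight"].to_numpy(dtype=float)
    d = np.asarray(dosages, dtype=np.float64)[:, cols]

    if dosage_alt_alleles is not None:
        alts = np.asarray(list(dosage_alt_alleles), dtype=object)[cols]
        flip = alts != matched["effect_allele"].to_numpy(dtype=object)
        d[:, flip] = np.where(d[:, flip] >= 0, 2.0 - d[:, flip], d[:, flip])

    missing = d < 0
    if missing_mode == "sum":
        d = np.where(missing, 0.0, d)
    elif missing_mode == "mean":
        col_mean = np.where(
            missing.all(axis=0), 0.0,
            np.nanmean(np.where(missing, np.nan, d), axis=0),
        )
        d = np.where(missing, col_mean[None, :], d)
    else:
        raise ValueError(f"unknown missing_mode: {missing_mode!r}")
    return d @ w


def pt_clump(
    sumstats: pd.DataFrame,
    dosages: np.ndarray,
    dosage_variant_ids,
    r2_max: float = 0.2,
    p_max: float = 0.03,
    window: int = 500,
) -> pd.DataFrame:
    """P+T selection: greedy by ascending p-value; a variant is selected only
    if its r^2 with every already-selected variant within ``window`` positions
    (input variant order) is <= ``r2_max``.  Weights are the discovery betas,
    unchanged.

    ``sumstats`` columns: variant_id, effect_allele, beta, p.
    Returns a weights table (variant_id, effect_allele, weight, p).
    """
    ids = list(dosage_variant_ids)
    pos = {v: i for i, v in enumerate(ids)}
    ss = sumstats.loc[sumstats["p"] <= p_max]
    ss = ss.loc[ss["variant_id"].isin(pos)]
    ss = ss.sort_values(["p", "variant_id"], kind="mergesort")

    x = np.asarray(dosages, dtype=np.float64)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)

    selected: list[int] = []
    keep_rows = []
    for row in ss.itertuples(index=False):
        j = pos[row.variant_id]
        if sd[j] == 0:
            continue
        ok = True
        for i in selected:
            if abs(i - j) > window:
                continue
            denom = sd[i] * sd[j] * len(x)
            r = (x[:, i] @ x[:, j]) / denom if denom > 0 else 0.0
            if r * r > r2_max:
                ok = False
                break
        if ok:
            selected.append(j)
            keep_rows.append(row)

    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in keep_rows],
            "effect_allele": [r.effect_allele for r in keep_rows],
            "weight": [r.beta for r in keep_rows],
            "p": [r.p for r in keep_rows],
        }
    )


def _design(pcs: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(pcs)), pcs])


@dataclass
class AncestryAdjuster:
    """Reference-fitted mean/variance calibration of the raw score on PCs."""

    n_pcs: int = 10
    strategy: str = "mean_variance"  # or "mean_only"

    def fit(self, ref_raw: np.ndarray, ref_pcs: np.ndarray) -> "AncestryAdjuster":
        ref_pcs = np.asarray(ref_pcs)[:, : self.n_pcs]
        if len(ref_raw) < 10 * self.n_pcs:
            raise ValueError(
                f"reference of {len(ref_raw)} is too small for {self.n_pcs} PCs "
                "(need >= 10 x n_pcs)"
            )
        x = _design(ref_pcs)
        self.mean_coef_, *_ = np.linalg.lstsq(x, np.asarray(ref_raw, float), rcond=None)
        resid = ref_raw - x @ self.mean_coef_
        if self.strategy == "mean_variance":
            logsq = np.log(resid**2 + 1e-12)
            self.var_coef_, *_ = np.linalg.lstsq(x, logsq, rcond=None)
            # E[log chi2_1] = digamma(1/2) + log 2 ~ -1.27036; correct so the
            # predicted sd is unbiased for a normal residual
            self.var_offset_ = 1.2703628454614782
        else:
            self.var_coef_ = None
            self.resid_sd_ = float(resid.std())
        return self

    def transform(self, raw: np.ndarray, pcs: np.ndarray) -> np.ndarray:
        x = _design(np.asarray(pcs)[:, : self.n_pcs])
        centered = np.asarray(raw, float) - x @ self.mean_coef_
        if self.var_coef_ is None:
            return centered / self.resid_sd_
        sd = np.exp(0.5 * (x @ self.var_coef_ + self.var_offset_))
        return centered / np.maximum(sd, 1e-12)


def ancestry_adjust(
    raw: np.ndarray,
    ref_raw: np.ndarray,
    ref_pcs: np.ndarray,
    cohort_pcs: np.ndarray,
    n_pcs: int = 10,
    strategy: str = "mean_variance",
) -> np.ndarray:
    """Calibrate cohort raw scores using reference-only mean/variance fits."""
    adj = AncestryAdjuster(n_pcs=n_pcs, strategy=strategy).fit(ref_raw, ref_pcs)
    return adj.transform(raw, cohort_pcs)


def apol1_risk_genotype(g1_alleles, g2_alleles) -> np.ndarray:
    """Recessive APOL1 high-risk genotype: two risk alleles in any combination
    (G1/G1, G2/G2, or G1/G2)."""
    g1 = np.nan_to_num(np.asarray(g1_alleles, dtype=float), nan=0.0)
    g2 = np.nan_to_num(np.asarray(g2_alleles, dtype=float), nan=0.0)
    return ((g1 + g2) >= 2).astype(int)


def apol1_adjust_standardize(
    adjusted: np.ndarray,
    apol1_indicator: np.ndarray,
    mode: str = "residualize",
) -> pd.DataFrame:
    """Remove the APOL1 risk-genotype association from the calibrated score,
    standardize, and assign cohort-wide tertiles.

    ``mode='residualize'`` (default) regresses the score on the indicator and
    keeps the residual; ``mode='none'`` skips the APOL1 step.  Missing
    indicator values are treated as 0 with a logged count.
    """
    adjusted = np.asarray(adjusted, dtype=float)
    ind = np.asarray(apol1_indicator, dtype=float)
    n_missing = int((~np.isfinite(ind)).sum())
    if n_missing:
        warnings.warn(f"{n_missing} missing APOL1 indicator(s) treated as 0")
        ind = np.nan_to_num(ind, nan=0.0)

    if mode == "residualize":
        x = np.column_stack([np.ones(len(ind)), ind])
        coef, *_ = np.linalg.lstsq(x, adjusted, rcond=None)
        resid = adjusted - x @ coef
    elif mode == "none":
        resid = adjusted - adjusted.mean()
    else:
        raise ValueError(f"unknown APOL1 adjustment mode: {mode!r}")

    sd = resid.std()
    if sd == 0:
        raise ValueError("degenerate (constant) score distribution")
    std = resid / sd
    return pd.DataFrame(
        {
            "ancestry_adjusted": adjusted,
            "standardized": std,
            "apol1_indicator": ind.astype(int),
            "tertile": assign_tertiles(std),
        }
    )


def assign_tertiles(standardized: np.ndarray) -> np.ndarray:
    """Tertile labels 1/2/3 from the cohort-wide empirical 33.3/66.7
    percentiles (linear-midpoint interpolation at ties)."""
    s = np.asarray(standardized, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 participants for tertiles")
    if s.std() == 0:
        raise ValueError("degenerate (constant) scores: tertiles undefined")
    q1, q2 = np.quantile(s, [1.0 / 3.0, 2.0 / 3.0], method="midpoint")
    return (1 + (s > q1).astype(int) + (s > q2).astype(int)).astype(int)
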