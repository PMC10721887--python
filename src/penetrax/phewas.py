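"""Phecode-based phenome-wide association study (PheWAS).

ICD-9 codes are mapped to phecodes via an input map; a participant is a case
for a phecode with >= 2 code occurrences mapping to it, a control with zero
occurrences of any code in the phecode's exclusion range, and missing
otherwise.  Each phecode is tested by logistic regression of case status on
carrier genotype plus covariates, per cohort; cohorts are pooled by
fixed-effects meta-analysis, with a Bonferroni phenome-wide threshold of
0.05 divided by the number of phecodes tested.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .stats import StratifiedEffect, logistic_fit, meta_fixed, _covariate_matrix, _prepare

__all__ = ["map_codes", "run_phewas", "meta_phewas", "bonferroni_threshold"]

logger = logging.getLogger(__name__)


def _parse_range(cell) -> tuple[float, float] | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return None
    s = str(cell)
    if "-" in s:
        lo, hi = s.split("-", 1)
        return float(lo), float(hi)
    return float(s), float(s)


def map_codes(
    icd_codes: pd.Series,
    phecode_map: pd.DataFrame,
    min_occurrences: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map per-participant ICD-9 multisets to a phecode case/control matrix.

    ``icd_codes``: one semicolon-separated string (or list) per participant;
    repeated codes count as repeated occurrences.
    ``phecode_map`` columns: phecode, icd9, exclusion_range, system_group
    (and optionally label).

    Returns (matrix, metadata): matrix is participants x phecodes with 1.0 =
    case (>= ``min_occurrences`` occurrences), 0.0 = control (no occurrence
    of any code in the exclusion range), NaN = missing.  Unmapped codes are
    counted and logged, never dropped silently.
    """
    code_to_phecodes: dict[str, list[float]] = {}
    for row in phecode_map.itertuples(index=False):
        code_to_phecodes.setdefault(str(row.icd9), []).append(float(row.phecode))

    phecodes = np.array(sorted(phecode_map["phecode"].astype(float).unique()))
    pc_pos = {p: i for i, p in enumerate(phecodes)}

    meta_rows = []
    for p in phecodes:
        rows = phecode_map.loc[phecode_map["phecode"].astype(float) == p]
        rng = _parse_range(rows["exclusion_range"].iloc[0]) or (p, p)
        meta_rows.append(
            {
                "phecode": p,
                "system_group": rows["system_group"].iloc[0],
                "label": rows["label"].iloc[0] if "label" in rows else "",
                "exclusion_low": rng[0],
                "exclusion_high": rng[1],
            }
        )
    meta = pd.DataFrame(meta_rows)

    n = len(icd_codes)
    counts = np.zeros((n, len(phecodes)), dtype=np.int32)
    n_unmapped = 0
    for i, cell in enumerate(icd_codes):
        if isinstance(cell, (list, tuple)):
            codes = [str(c) for c in cell]
        elif cell is None or (isinstance(cell, float) and np.isnan(cell)):
            codes = []
        else:
            codes = [c.strip() for c in str(cell).split(";") if c.strip()]
        for code in codes:
            hit = code_to_phecodes.get(code)
            if hit is None:
                n_unmapped += 1
                continue
            for p in hit:
                counts[i, pc_pos[p]] += 1
    if n_unmapped:
        logger.info("map_codes: %d ICD code occurrence(s) had no phecode mapping", n_unmapped)

    matrix = np.full((n, len(phecodes)), np.nan)
    matrix[counts >= min_occurrences] = 1.0
    # controls: zero occurrences of any phecode within the exclusion range
    for j, p in enumerate(phecodes):
        lo = meta.loc[j, "exclusion_low"]
        hi = meta.loc[j, "exclusion_high"]
        in_range = (phecodes >= lo) & (phecodes <= hi)
        range_counts = counts[:, in_range].sum(axis=1)
        is_control = (range_counts == 0) & ~(counts[:, j] >= min_occurrences)
        matrix[is_control, j] = 0.0

    mat = pd.DataFrame(matrix, columns=[f"{p:g}" for p in phecodes], index=icd_codes.index)
    mat.attrs["n_unmapped"] = n_unmapped
    return mat, meta


def run_phewas(
    phecode_matrix: pd.DataFrame,
    carrier: np.ndarray,
    covariates: pd.DataFrame | None = None,
    min_cases: int = 20,
    cohort: str = "",
) -> pd.DataFrame:
    """Per-phecode logistic regression (dominant carrier coding).

    Phecodes with fewer than ``min_cases`` cases, no carriers among usable
    participants, or non-convergent fits are reported with a skip/flag
    reason rather than dropped silently.
    """
    carrier = np.asarray(carrier, dtype=float)
    rows = []
    for pc in phecode_matrix.columns:
        y_raw = phecode_matrix[pc].to_numpy(dtype=float)
        usable = np.isfinite(y_raw)
        y = y_raw[usable]
        n_cases = int((y == 1).sum())
        base = {
            "phecode": pc,
            "cohort": cohort,
            "n_cases": n_cases,
            "n_controls": int((y == 0).sum()),
        }
        if n_cases < min_cases:
            rows.append({**base, "log_or": np.nan, "se": np.nan, "p": np.nan,
                         "skip_reason": f"fewer than {min_cases} cases"})
            continue
        car = carrier[usable]
        if car.sum() == 0 or (car == 0).sum() == 0:
            rows.append({**base, "log_or": np.nan, "se": np.nan, "p": np.nan,
                         "skip_reason": "no carrier variation"})
            continue
        X = _covariate_matrix(
            None if covariates is None else covariates.loc[usable].reset_index(drop=True),
            int(usable.sum()),
        )
        X.insert(1, "carrier", car)
        try:
            coef, se, p, method = logistic_fit(y, X)
        except Exception as exc:  # non-convergent fit: flagged, excluded from meta
            rows.append({**base, "log_or": np.nan, "se": np.nan, "p": np.nan,
                         "skip_reason": f"fit failed: {exc}"})
            continue
        rows.append({**base, "log_or": float(coef["carrier"]), "se": float(se["carrier"]),
                     "p": float(p["carrier"]), "skip_reason": "", "method": method})
    return pd.DataFrame(rows)


def bonferroni_threshold(n_phecodes_tested: int, alpha: float = 0.05) -> float:
    """Phenome-wide significance threshold: alpha / number of phecodes tested."""
    if n_phecodes_tested <= 0:
        raise ValueError("need a positive number of tested phecodes")
    return alpha / n_phecodes_tested


def meta_phewas(
    cohort_results: list[pd.DataFrame],
    phecode_meta: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Fixed-effects meta-analysis across cohorts per phecode.

    Returns (results, threshold); results rows carry the pooled OR/CI/p, the
    effect direction, total cases, and a significance flag at the Bonferroni
    threshold of ``alpha`` / #phecodes tested (those with >= 1 usable cohort
    estimate).
    """
    all_pc = sorted(set().union(*[set(r["phecode"]) for r in cohort_results]))
    rows = []
    for pc in all_pc:
        effects = []
        n_cases = 0
        for res in cohort_results:
            sub = res.loc[res["phecode"] == pc]
            if len(sub) == 0:
                continue
            r = sub.iloc[0]
            n_cases += int(r["n_cases"])
            if np.isfinite(r["log_or"]) and np.isfinite(r["se"]) and r["se"] > 0:
                effects.append(
                    StratifiedEffect(str(pc), float(r["log_or"]), float(r["se"]),
                                     float(r["p"]), cohort=str(r["cohort"]))
                )
        if not effects:
            rows.append({"phecode": pc, "log_or": np.nan, "se": np.nan, "p": np.nan,
                         "or": np.nan, "n_cases": n_cases, "tested": False})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = meta_fixed(effects)
        rows.append({
            "phecode": pc, "log_or": m.log_or, "se": m.se, "p": m.p, "or": m.or_,
            "ci_low": m.ci[0], "ci_high": m.ci[1],
            "direction": "up" if m.log_or > 0 else "down",
            "n_cases": n_cases, "n_cohorts": len(effects), "tested": True,
        })
    out = pd.DataFrame(rows)
    n_tested = int(out["tested"].sum())
    threshold = bonferroni_threshold(max(n_tested, 1), alpha)
    out["significant"] = out["p"] < threshold
    if phecode_meta is not None:
        meta_idx = phecode_meta.copy()
        meta_idx["phecode"] = meta_idx["phecode"].astype(float).map("{:g}".format)
        out = out.merge(
            meta_idx[["phecode", "system_group"] + (["label"] if "label" in meta_idx else [])],
            on="phecode", how="left",
        )
        out = out.sort_values(["system_group", "phecode"], kind="mergesort").reset_index(drop=True)
    return out, threshold
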