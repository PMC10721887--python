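"""CKD e-phenotyping: eGFR estimation and case/control/excluded assignment.

Cases have eGFR < 60 ml/min/1.73m2 or renal replacement therapy (RRT);
controls have eGFR > 90 and no CKD billing code; the 60-90 band is excluded
to limit misclassification from age-related eGFR decline.  Two creatinine
based CKD-EPI estimating equations are supported: the 2009 equation (with an
explicit Black race indicator) and the race-free 2021 equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "egfr_2009",
    "egfr_2021",
    "invert_egfr_2009",
    "assign_case_control",
    "derive_covariates",
    "PhenotypingConfig",
]

# 2009 CKD-EPI: 141 * min(Scr/k,1)^a * max(Scr/k,1)^-1.209 * 0.993^age
#               * 1.018 [female] * 1.159 [Black]
_K_2009 = {"F": 0.7, "M": 0.9}
_A_2009 = {"F": -0.329, "M": -0.411}

# 2021 CKD-EPI (race-free): 142 * min(Scr/k,1)^a * max(Scr/k,1)^-1.200
#               * 0.9938^age * 1.012 [female]
_K_2021 = {"F": 0.7, "M": 0.9}
_A_2021 = {"F": -0.241, "M": -0.302}

#: default billing codes whose presence disqualifies a high-eGFR participant
#: from the control group (chronic kidney disease, ESRD, dialysis, transplant;
#: ICD-9-style).  The validated e-phenotype uses a longer curated list; this
#: default is configurable.
DEFAULT_CKD_CODES = ("585", "586", "V42.0", "V45.11", "V56")

#: diabetes (type I or II) defining codes, matched as prefixes.
DEFAULT_DIABETES_CODES = ("250", "E10", "E11")


def _sex_arrays(sex, k_map, a_map):
    sex = np.asarray(sex, dtype=object)
    female = np.asarray([str(s).upper().startswith("F") for s in sex.ravel()]).reshape(sex.shape)
    k = np.where(female, k_map["F"], k_map["M"])
    a = np.where(female, a_map["F"], a_map["M"])
    return female, k, a


def egfr_2009(creatinine, age, sex, black_indicator=False):
    """2009 CKD-EPI estimated GFR (ml/min/1.73 m2).

    Parameters
    ----------
    creatinine : serum creatinine in mg/dL (scalar or array), > 0.
    age : years, > 0.
    sex : 'F'/'M' (or 'female'/'male').
    black_indicator : explicit race-coefficient indicator; never inferred.
    """
    scr = np.asarray(creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("creatinine and age must be positive")
    female, k, a = _sex_arrays(sex, _K_2009, _A_2009)
    ratio = scr / k
    out = (
        141.0
        * np.minimum(ratio, 1.0) ** a
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age
        * np.where(female, 1.018, 1.0)
        * np.where(np.asarray(black_indicator, dtype=bool), 1.159, 1.0)
    )
    return out if out.shape else float(out)


def egfr_2021(creatinine, age, sex):
    """2021 race-free CKD-EPI estimated GFR (ml/min/1.73 m2)."""
    scr = np.asarray(creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("creatinine and age must be positive")
    female, k, a = _sex_arrays(sex, _K_2021, _A_2021)
    ratio = scr / k
    out = (
        142.0
        * np.minimum(ratio, 1.0) ** a
        * np.maximum(ratio, 1.0) ** -1.200
        * 0.9938 ** age
        * np.where(female, 1.012, 1.0)
    )
    return out if out.shape else float(out)


def invert_egfr_2009(target_egfr, age, sex, black_indicator=False):
    """Serum creatinine (mg/dL) that yields ``target_egfr`` under the 2009 equation.

    The equation is piecewise in Scr around the sex-specific knot kappa and
    strictly decreasing in Scr, so the inverse is closed-form.
    """
    g = np.asarray(target_egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(g <= 0) or np.any(age <= 0):
        raise ValueError("target eGFR and age must be positive")
    female, k, a = _sex_arrays(sex, _K_2009, _A_2009)
    base = (
        141.0
        * 0.993 ** age
        * np.where(female, 1.018, 1.0)
        * np.where(np.asarray(black_indicator, dtype=bool), 1.159, 1.0)
    )
    # g = base * (scr/k)^e with e = -1.209 when g < base (scr above knot),
    # e = a when g >= base.
    exponent = np.where(g < base, -1.209, a)
    scr = k * (g / base) ** (1.0 / exponent)
    return scr if scr.shape else float(scr)


@dataclass
class PhenotypingConfig:
    """Code lists and equation choice for case/control assignment."""

    equation: str = "2009"  # "2009" | "2021"
    ckd_codes: tuple[str, ...] = DEFAULT_CKD_CODES
    diabetes_codes: tuple[str, ...] = DEFAULT_DIABETES_CODES
    case_egfr: float = 60.0
    control_egfr: float = 90.0
    creatinine_aggregate: str = "median"
    extra: dict = field(default_factory=dict)


def _split_codes(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    s = str(cell).strip()
    if not s:
        return []
    return [c.strip() for c in s.split(";") if c.strip()]


def _has_prefix(codes: list[str], prefixes) -> bool:
    return any(code.startswith(p) for code in codes for p in prefixes)


def _aggregate_creatinine(cell, how: str):
    """Phenotype tables may carry several creatinine draws per person
    (semicolon-separated); aggregate deterministically (median by default)."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return np.nan
    if isinstance(cell, (int, float)):
        return float(cell)
    parts = [p for p in str(cell).split(";") if p.strip()]
    if not parts:
        return np.nan
    vals = np.array([float(p) for p in parts])
    if how == "median":
        return float(np.median(vals))
    if how == "mean":
        return float(np.mean(vals))
    if how == "last":
        return float(vals[-1])
    if how == "first":
        return float(vals[0])
    raise ValueError(f"unknown creatinine aggregate: {how!r}")


def assign_case_control(
    phenotypes: pd.DataFrame, config: PhenotypingConfig | None = None
) -> pd.DataFrame:
    """Assign each participant exactly one of {case, control, excluded}.

    Rules, in order: RRT -> case; no usable creatinine -> excluded;
    eGFR < 60 -> case; eGFR > 90 with no CKD billing code -> control;
    everyone else (60-90 band, or high eGFR with CKD codes) -> excluded.

    Returns a DataFrame indexed like ``phenotypes`` with columns
    ``label``, ``egfr``, ``equation``.
    """
    cfg = config or PhenotypingConfig()
    if cfg.equation not in ("2009", "2021"):
        raise ValueError(f"unknown equation: {cfg.equation!r}")

    scr = np.array(
        [
            _aggregate_creatinine(c, cfg.creatinine_aggregate)
            for c in phenotypes["creatinine_mg_dl"]
        ]
    )
    age = phenotypes["age"].to_numpy(dtype=float)
    sex = phenotypes["sex"].to_numpy()
    have_scr = np.isfinite(scr) & (scr > 0)

    egfr = np.full(len(phenotypes), np.nan)
    if have_scr.any():
        if cfg.equation == "2009":
            black = (
                phenotypes["black_indicator"].to_numpy(dtype=bool)
                if "black_indicator" in phenotypes
                else np.zeros(len(phenotypes), dtype=bool)
            )
            egfr[have_scr] = egfr_2009(
                scr[have_scr], age[have_scr], sex[have_scr], black[have_scr]
            )
        else:
            egfr[have_scr] = egfr_2021(scr[have_scr], age[have_scr], sex[have_scr])

    rrt = (
        phenotypes["rrt_flag"].to_numpy(dtype=bool)
        if "rrt_flag" in phenotypes
        else np.zeros(len(phenotypes), dtype=bool)
    )
    ckd_code = np.array(
        [_has_prefix(_split_codes(c), cfg.ckd_codes) for c in phenotypes["icd9_codes"]]
    ) if "icd9_codes" in phenotypes else np.zeros(len(phenotypes), dtype=bool)

    label = np.full(len(phenotypes), "excluded", dtype=object)
    label[rrt] = "case"
    usable = ~rrt & have_scr
    label[usable & (egfr < cfg.case_egfr)] = "case"
    label[usable & (egfr > cfg.control_egfr) & ~ckd_code] = "control"
    # the 60-90 band, high-eGFR participants with CKD codes, and participants
    # without creatinine or RRT remain "excluded"

    return pd.DataFrame(
        {
            "participant_id": phenotypes["participant_id"].to_numpy(),
            "label": label,
            "egfr": egfr,
            "equation": f"CKD-EPI-{cfg.equation}",
        },
        index=phenotypes.index,
    )


def derive_covariates(
    phenotypes: pd.DataFrame, diabetes_codes=DEFAULT_DIABETES_CODES
) -> pd.DataFrame:
    """Model covariates: age, sex (1=male), diabetes flag from ICD codes, batch."""
    if not diabetes_codes:
        raise ValueError("diabetes code list must be non-empty")
    col = "diabetes_codes" if "diabetes_codes" in phenotypes else "icd9_codes"
    diabetes = np.array(
        [_has_prefix(_split_codes(c), diabetes_codes) for c in phenotypes[col]]
    )
    sex_male = np.array(
        [str(s).upper().startswith("M") for s in phenotypes["sex"]], dtype=int
    )
    return pd.DataFrame(
        {
            "participant_id": phenotypes["participant_id"].to_numpy(),
            "age": phenotypes["age"].to_numpy(dtype=float),
            "sex_male": sex_male,
            "diabetes": diabetes.astype(int),
            "batch": phenotypes["batch"].to_numpy(),
        },
        index=phenotypes.index,
    )
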