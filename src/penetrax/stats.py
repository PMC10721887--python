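"""Association statistics for carrier-stratified penetrance analysis.

Per cohort: logistic regression of CKD case status on carrier status, on the
standardized polygenic score within carrier strata, on a six-level
carrier-by-tertile factor (reference: noncarrier middle tertile), and a
carrier-by-score interaction model.  Cohort estimates are pooled by
inverse-variance fixed-effects meta-analysis.  Wald inference throughout,
matching the OR (95% CI) reporting style; a Firth-type penalized fit is the
automatic fallback for sparse or separated strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

import statsmodels.api as sm

__all__ = [
    "StratifiedEffect",
    "MetaResult",
    "logistic_fit",
    "firth_logistic",
    "fit_carrier_model",
    "fit_gps_model_by_stratum",
    "tertile_or",
    "interaction_test",
    "meta_fixed",
    "performance_metrics",
]

Z95 = sps.norm.ppf(0.975)


@dataclass
class StratifiedEffect:
    """An odds ratio with Wald CI/SE/p for one stratum in one cohort."""

    stratum: str
    log_or: float
    se: float
    p: float
    cohort: str = ""
    n_cases: int = 0
    n_controls: int = 0
    method: str = "ml"
    extra: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return float(np.exp(self.log_or))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.log_or - Z95 * self.se)),
            float(np.exp(self.log_or + Z95 * self.se)),
        )

    def to_dict(self) -> dict:
        lo, hi = self.ci
        return {
            "stratum": self.stratum,
            "cohort": self.cohort,
            "log_or": self.log_or,
            "or": self.or_,
            "se": self.se,
            "ci_low": lo,
            "ci_high": hi,
            "p": self.p,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "method": self.method,
        }


@dataclass
class MetaResult:
    """Inverse-variance fixed-effects pooled estimate."""

    log_or: float
    se: float
    p: float
    inputs: list = field(default_factory=list)
    q_statistic: float = np.nan
    i2: float = np.nan

    @property
    def or_(self) -> float:
        return float(np.exp(self.log_or))

    @property
    def ci(self) -> tuple[float, float]:
        return (
            float(np.exp(self.log_or - Z95 * self.se)),
            float(np.exp(self.log_or + Z95 * self.se)),
        )


def _detect_separation(y, x_col) -> bool:
    """Complete or quasi-complete separation of a binary predictor column."""
    vals = np.unique(x_col)
    if len(vals) > 2:
        return False
    for v in vals:
        yy = y[x_col == v]
        if len(yy) and (yy.min() == yy.max()):
            return True
    return False


def firth_logistic(y: np.ndarray, X: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth-penalized logistic regression (Jeffreys-prior bias reduction).

    Newton iterations on the modified score U*(b) = X'(y - p + h(1/2 - p)),
    h the hat diagonal.  Returns (coefficients, standard errors).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XW = X * w[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score_vec = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score_vec
        # dampen huge steps for stability
        if np.abs(step).max() > 5:
            step = step * (5 / np.abs(step).max())
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    info = X.T @ (X * (p * (1 - p))[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


def logistic_fit(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    term_names=None,
    allow_firth: bool = True,
):
    """ML logistic fit with automatic Firth fallback on separation or sparse
    binary cells.  Returns (coef Series, se Series, p Series, method)."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        names = list(term_names) if term_names is not None else [
            f"x{i}" for i in range(Xm.shape[1])
        ]
    y = np.asarray(y, dtype=float)

    needs_firth = False
    if allow_firth:
        for j in range(Xm.shape[1]):
            col = Xm[:, j]
            if len(np.unique(col)) == 2 and _detect_separation(y, col):
                needs_firth = True
                break
    method = "ml"
    if not needs_firth:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, Xm).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 50):
                needs_firth = True
            else:
                coef, se = res.params, res.bse
        except Exception:
            needs_firth = True
    if needs_firth:
        if not allow_firth:
            raise RuntimeError("separation detected and Firth fallback disabled")
        warnings.warn("separation or unstable fit: falling back to Firth penalization")
        coef, se = firth_logistic(y, Xm)
        method = "firth"
    z = coef / se
    p = 2 * sps.norm.sf(np.abs(z))
    return (
        pd.Series(coef, index=names),
        pd.Series(se, index=names),
        pd.Series(p, index=names),
        method,
    )


def _covariate_matrix(covariates: pd.DataFrame | None, n: int) -> pd.DataFrame:
    """Intercept + covariates; categorical 'batch'-like columns are dummy
    coded (first level dropped)."""
    cols = {"const": np.ones(n)}
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype == object or str(col.dtype).startswith("category"):
                dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
                for d in dummies.columns:
                    cols[d] = dummies[d].to_numpy()
            else:
                cols[name] = col.to_numpy(dtype=float)
    return pd.DataFrame(cols)


def _prepare(labels: pd.Series | np.ndarray):
    """Map case/control labels to 1/0; excluded (anything else / NaN) dropped."""
    lab = pd.Series(np.asarray(labels, dtype=object))
    y = lab.map({"case": 1.0, "control": 0.0, 1: 1.0, 0: 0.0, 1.0: 1.0, 0.0: 0.0})
    mask = y.notna().to_numpy()
    return y.to_numpy(dtype=float), mask


def fit_carrier_model(
    labels,
    carrier: np.ndarray,
    covariates: pd.DataFrame | None = None,
    cohort: str = "",
    extra_predictors: pd.DataFrame | None = None,
) -> StratifiedEffect:
    """Carrier vs noncarrier CKD odds ratio, adjusted for the covariate set."""
    y, mask = _prepare(labels)
    carrier = np.asarray(carrier, dtype=float)
    X = _covariate_matrix(covariates, len(carrier))
    X.insert(1, "carrier", carrier)
    if extra_predictors is not None:
        for c in extra_predictors.columns:
            X[c] = extra_predictors[c].to_numpy(dtype=float)
    Xs, ys = X.loc[mask], y[mask]
    coef, se, p, method = logistic_fit(ys, Xs)
    cur = carrier[mask]
    return StratifiedEffect(
        stratum="carrier_vs_noncarrier",
        log_or=float(coef["carrier"]),
        se=float(se["carrier"]),
        p=float(p["carrier"]),
        cohort=cohort,
        n_cases=int(((ys == 1) & (cur == 1)).sum()),
        n_controls=int(((ys == 0) & (cur == 1)).sum()),
        method=method,
        extra={"coef": coef.to_dict()},
    )


def fit_gps_model_by_stratum(
    labels,
    scores: np.ndarray,
    carrier: np.ndarray,
    covariates: pd.DataFrame | None = None,
    cohort: str = "",
    per_sd_of_controls: bool = True,
) -> dict[str, StratifiedEffect]:
    """Per-SD GPS odds ratio fitted separately in carriers and noncarriers.

    The per-SD scale is the control-group score SD (computed over the whole
    cohort's controls), so both strata share the same unit.
    """
    y, mask = _prepare(labels)
    scores = np.asarray(scores, dtype=float)
    carrier = np.asarray(carrier, dtype=bool)
    sd = scores[mask & (y == 0)].std() if per_sd_of_controls else scores[mask].std()
    scaled = scores / sd

    out = {}
    for name, sel in (("carrier", carrier), ("noncarrier", ~carrier)):
        sub = mask & sel
        X = _covariate_matrix(
            None if covariates is None else covariates.loc[sub].reset_index(drop=True),
            int(sub.sum()),
        )
        X.insert(1, "gps", scaled[sub])
        ys = y[sub]
        n_cases = int((ys == 1).sum())
        eff_extra = {}
        if n_cases < 10:
            eff_extra["low_power"] = True
        coef, se, p, method = logistic_fit(ys, X)
        out[name] = StratifiedEffect(
            stratum=f"gps_per_sd_{name}",
            log_or=float(coef["gps"]),
            se=float(se["gps"]),
            p=float(p["gps"]),
            cohort=cohort,
            n_cases=n_cases,
            n_controls=int((ys == 0).sum()),
            method=method,
            extra=eff_extra,
        )
    return out


TERTILE_STRATA = (
    "noncarrier_T1",
    "noncarrier_T2",
    "noncarrier_T3",
    "carrier_T1",
    "carrier_T2",
    "carrier_T3",
)


def tertile_or(
    labels,
    tertiles: np.ndarray,
    carrier: np.ndarray,
    covariates: pd.DataFrame | None = None,
    cohort: str = "",
) -> list[StratifiedEffect]:
    """One logistic fit with a six-level carrier-by-tertile factor; reference
    is the noncarrier middle tertile (OR = 1 by construction).  Empty carrier
    tertiles are reported as NA rows, never dropped silently."""
    y, mask = _prepare(labels)
    tert = np.asarray(tertiles, dtype=int)
    carrier = np.asarray(carrier, dtype=bool)
    stratum = np.array(
        [f"{'carrier' if c else 'noncarrier'}_T{t}" for c, t in zip(carrier, tert)],
        dtype=object,
    )
    present = [s for s in TERTILE_STRATA if (mask & (stratum == s)).any()]
    if "noncarrier_T2" not in present:
        raise ValueError("reference stratum (noncarrier middle tertile) is empty")

    dummy_strata = [s for s in present if s != "noncarrier_T2"]
    X = _covariate_matrix(covariates, len(stratum))
    for s in dummy_strata:
        X[s] = (stratum == s).astype(float)
    Xs, ys = X.loc[mask], y[mask]
    coef, se, p, method = logistic_fit(ys, Xs)

    effects = []
    for s in TERTILE_STRATA:
        sel = mask & (stratum == s)
        n_cases = int(y[sel].sum()) if sel.any() else 0
        n_controls = int((y[sel] == 0).sum()) if sel.any() else 0
        if s == "noncarrier_T2":
            eff = StratifiedEffect(s, 0.0, 0.0, 1.0, cohort, n_cases, n_controls,
                                   method, {"reference": True})
        elif s in dummy_strata:
            eff = StratifiedEffect(
                s, float(coef[s]), float(se[s]), float(p[s]), cohort,
                n_cases, n_controls, method,
            )
        else:
            eff = StratifiedEffect(s, np.nan, np.nan, np.nan, cohort, 0, 0,
                                   method, {"empty": True})
        effects.append(eff)
    return effects


def interaction_test(
    labels,
    scores: np.ndarray,
    carrier: np.ndarray,
    covariates: pd.DataFrame | None = None,
    cohort: str = "",
) -> dict:
    """GPS-by-carrier interaction: main effects plus product term; Wald p for
    the product coefficient.  Also returns the main-effect estimates from the
    joint model (which equal the conditional effects when the interaction is
    null)."""
    y, mask = _prepare(labels)
    scores = np.asarray(scores, dtype=float)
    carrier = np.asarray(carrier, dtype=float)
    X = _covariate_matrix(covariates, len(carrier))
    X.insert(1, "carrier", carrier)
    X.insert(2, "gps", scores)
    X.insert(3, "carrier_x_gps", carrier * scores)
    coef, se, p, method = logistic_fit(y[mask] if mask.all() else y[mask], X.loc[mask])
    return {
        "interaction_log_or": float(coef["carrier_x_gps"]),
        "interaction_se": float(se["carrier_x_gps"]),
        "interaction_p": float(p["carrier_x_gps"]),
        "carrier_log_or": float(coef["carrier"]),
        "carrier_se": float(se["carrier"]),
        "gps_log_or": float(coef["gps"]),
        "gps_se": float(se["gps"]),
        "method": method,
        "cohort": cohort,
    }


def meta_fixed(effects: list[StratifiedEffect]) -> MetaResult:
    """Inverse-variance fixed-effects pooling on the log-OR scale."""
    usable = [e for e in effects if np.isfinite(e.log_or) and np.isfinite(e.se) and e.se > 0]
    dropped = len(effects) - len(usable)
    if dropped:
        warnings.warn(f"dropped {dropped} effect(s) with non-finite SE from meta-analysis")
    if not usable:
        raise ValueError("no usable cohort estimates for meta-analysis")
    b = np.array([e.log_or for e in usable])
    w = np.array([1.0 / e.se**2 for e in usable])
    pooled = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    q = float((w * (b - pooled) ** 2).sum())
    dfree = len(usable) - 1
    i2 = float(max(0.0, (q - dfree) / q)) if q > 0 and dfree > 0 else 0.0
    p = float(2 * sps.norm.sf(abs(pooled / se)))
    return MetaResult(pooled, se, p, inputs=[e.to_dict() for e in usable],
                      q_statistic=q, i2=i2)


def _nagelkerke_r2(y: np.ndarray, p_full: np.ndarray) -> float:
    n = len(y)
    p0 = y.mean()
    ll_null = np.sum(y * np.log(p0) + (1 - y) * np.log(1 - p0))
    eps = 1e-12
    ll_full = np.sum(y * np.log(p_full + eps) + (1 - y) * np.log(1 - p_full + eps))
    cox_snell = 1 - np.exp(2 * (ll_null - ll_full) / n)
    max_r2 = 1 - np.exp(2 * ll_null / n)
    return float(cox_snell / max_r2)


def performance_metrics(
    labels,
    scores: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """AUROC of the full model (score + covariates), crude AUROC of the score
    alone, and incremental Nagelkerke pseudo-R^2 (full minus covariates-only).

    AUROC CI by the Hanley-McNeil approximation.
    """
    y, mask = _prepare(labels)
    y = y[mask]
    if len(np.unique(y)) < 2:
        raise ValueError("need both cases and controls for performance metrics")
    scores = np.asarray(scores, dtype=float)[mask]
    covs = None if covariates is None else covariates.loc[mask].reset_index(drop=True)

    X_full = _covariate_matrix(covs, len(y))
    X_full.insert(1, "gps", scores)
    coef = logistic_fit(y, X_full)[0]
    p_full = 1 / (1 + np.exp(-(X_full.to_numpy(float) @ coef.to_numpy())))

    X_cov = _covariate_matrix(covs, len(y))
    coef_cov = logistic_fit(y, X_cov)[0]
    p_cov = 1 / (1 + np.exp(-(X_cov.to_numpy(float) @ coef_cov.to_numpy())))

    auc_full = float(roc_auc_score(y, p_full))
    auc_crude = float(roc_auc_score(y, scores))

    n1, n0 = int(y.sum()), int((y == 0).sum())

    def _hm_ci(a):
        q1 = a / (2 - a)
        q2 = 2 * a**2 / (1 + a)
        var = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
        half = Z95 * np.sqrt(max(var, 0))
        return (max(0.0, a - half), min(1.0, a + half))

    return {
        "auroc_full": auc_full,
        "auroc_full_ci": _hm_ci(auc_full),
        "auroc_crude": auc_crude,
        "auroc_crude_ci": _hm_ci(auc_crude),
        "r2_full": _nagelkerke_r2(y, p_full),
        "r2_covariates": _nagelkerke_r2(y, p_cov),
        "incremental_r2": _nagelkerke_r2(y, p_full) - _nagelkerke_r2(y, p_cov),
        "n_cases": n1,
        "n_controls": n0,
    }
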