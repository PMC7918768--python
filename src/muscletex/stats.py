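"""Statistical layer: group comparisons, adjusted regressions, stepwise
selection, and Bonferroni marking.

The analysis design mirrors a covariate-adjusted feature screen followed by
stepwise model building:

* per texture feature, an ordinary least squares model of strength (MVIC)
  on {sex, side, age, BMI, feature}, using both sides' rows stacked
  (side-matched: left feature values pair with left strength) and reporting
  the feature term's p-value and the model's adjusted R^2;
* SPSS-style stepwise selection over a candidate list: forward entry of
  the smallest-p candidate while p < p_enter, backward removal of any
  included term with p > p_remove, deterministic tie-break by candidate
  order, full audit log.

Term p-values are two-sided t-tests, identical to the single-df F-test
(F = t^2).  Two rows per subject are treated as independent observations
with a side covariate; an optional cluster-robust mode (clustering on
subject) is available for sensitivity analysis.

Coding conventions (fixed so coefficient signs are reproducible):
sex female = 0 / male = 1; side left = 0 / right = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

ADJUSTMENT_COVARIATES = ("sex_male", "side_right", "age", "bmi")


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int


@dataclass
class RegressionResult:
    """One fitted OLS model: coefficients, SEs, term p-values, fit stats."""

    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    r2: float
    r2_adj: float
    n: int
    n_predictors: int
    p_model: float

    @classmethod
    def from_fit(cls, fit, n_predictors: int) -> "RegressionResult":
        ci = fit.conf_int()
        return cls(
            params=dict(fit.params),
            bse=dict(fit.bse),
            pvalues=dict(fit.pvalues),
            conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in ci.index},
            r2=float(fit.rsquared),
            r2_adj=float(fit.rsquared_adj),
            n=int(fit.nobs),
            n_predictors=n_predictors,
            p_model=float(fit.f_pvalue) if n_predictors > 0 else float("nan"),
        )


@dataclass
class StepwiseResult:
    log: list[dict]
    selected: list[str]
    final: RegressionResult


def encode_design(tbl: pd.DataFrame) -> pd.DataFrame:
    """Add numeric sex/side codes (female=0/male=1, left=0/right=1)."""
    out = tbl.copy()
    if "sex" in out.columns and "sex_male" not in out.columns:
        out["sex_male"] = (out["sex"].astype(str).str.upper() == "M").astype(float)
    if "side" in out.columns and "side_right" not in out.columns:
        out["side_right"] = (out["side"].astype(str).str.lower() == "right").astype(
            float
        )
    return out


def unpaired_ttest(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> TTestResult:
    """Two-sided unpaired t-test; pooled variance by default (Welch optional)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(
        t=float(t),
        p=float(p),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_a=a.size,
        n_b=b.size,
    )


def fit_ols(
    tbl: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    cluster_by: str | None = None,
) -> RegressionResult:
    """OLS of ``outcome`` on ``predictors`` plus intercept.

    ``cluster_by`` switches to cluster-robust (sandwich) standard errors
    grouped on the named column (e.g. ``subject_id``).
    """
    y = tbl[outcome].to_numpy(dtype=np.float64)
    X = pd.DataFrame({"const": np.ones(len(tbl))})
    for name in predictors:
        X[name] = tbl[name].to_numpy(dtype=np.float64)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    model = sm.OLS(y, X)
    if cluster_by is not None:
        fit = model.fit(
            cov_type="cluster", cov_kwds={"groups": tbl[cluster_by].to_numpy()}
        )
    else:
        fit = model.fit()
    return RegressionResult.from_fit(fit, n_predictors=len(predictors))


def adjusted_single_feature_regression(
    tbl: pd.DataFrame,
    outcome: str,
    feature: str,
    cluster_by: str | None = None,
) -> RegressionResult:
    """OLS of MVIC on {sex, side, age, BMI, feature}, both sides stacked."""
    tbl = encode_design(tbl)
    predictors = list(ADJUSTMENT_COVARIATES) + [feature]
    return fit_ols(tbl, outcome, predictors, cluster_by=cluster_by)


def stepwise_regression(
    tbl: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 200,
) -> StepwiseResult:
    """Forward entry / backward removal stepwise OLS over ``candidates``.

    At each step the excluded candidate whose term p-value (when added to
    the current model) is smallest enters if p < ``p_enter``; then included
    terms with p > ``p_remove`` are removed worst-first.  Ties break by
    candidate-list order, making the procedure fully deterministic.  An
    empty final model is a valid result.
    """
    tbl = encode_design(tbl)
    selected: list[str] = []
    log: list[dict] = []
    step = 0
    while step < max_steps:
        changed = False
        # forward entry
        best_name, best_p = None, np.inf
        for name in candidates:
            if name in selected:
                continue
            try:
                res = fit_ols(tbl, outcome, selected + [name])
            except ValueError:
                continue  # collinear candidate cannot enter
            p = res.pvalues[name]
            if p < best_p:
                best_name, best_p = name, p
        if best_name is not None and best_p < p_enter:
            selected.append(best_name)
            step += 1
            log.append(
                {"step": step, "action": "add", "term": best_name, "p": best_p}
            )
            changed = True
        # backward removal
        while selected:
            res = fit_ols(tbl, outcome, selected)
            worst_name, worst_p = None, -np.inf
            for name in selected:
                p = res.pvalues[name]
                if p > worst_p:
                    worst_name, worst_p = name, p
            if worst_p > p_remove:
                selected.remove(worst_name)  # type: ignore[arg-type]
                step += 1
                log.append(
                    {"step": step, "action": "remove", "term": worst_name,
                     "p": worst_p}
                )
                changed = True
            else:
                break
        if not changed:
            break
    final = fit_ols(tbl, outcome, selected)
    return StepwiseResult(log=log, selected=list(selected), final=final)


def bonferroni_flags(
    p_values: np.ndarray, m: int = 12, alpha: float = 0.05
) -> np.ndarray:
    """Flag p-values significant after Bonferroni correction (p < alpha/m).

    The default m = 12 corresponds to screening mean PDFF plus 11 texture
    features against one strength outcome.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    p = np.asarray(p_values, dtype=np.float64)
    return p < alpha / m


def ks_normality(values: np.ndarray) -> tuple[float, float]:
    """Kolmogorov-Smirnov check against a fitted Normal (pass-through utility).

    Parameters are estimated from the sample, so the p-value is approximate
    (anti-conservative); provided as a convenience screen only.
    """
    values = np.asarray(values, dtype=np.float64)
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample")
    stat, p = sps.kstest((values - values.mean()) / sd, "norm")
    return float(stat), float(p)
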