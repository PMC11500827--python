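"""Cohort-level statistics relating movement features to arm impairment.

Subjects are split at UEFM 30 and 50 into severe (group 1, no hand
function), moderate (group 2, hand function but little daily hand use) and
mild (group 3, regular hand use).  Each feature gets a simple OLS
regression against UEFM, a one-way ANOVA across groups, and unpaired
t-tests with pooled-SD Cohen's D for four contrasts (1v2, 2v3, 1v23,
12v3).  A multivariate OLS model of UEFM is then selected by backward
elimination with the minimum-AIC rule, after prefiltering features whose
simple correlation with UEFM is not significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

UEFM_CUTS = (30, 50)

CONTRASTS = {          # lower (more impaired) side first
    "1v2": ((1,), (2,)),
    "2v3": ((2,), (3,)),
    "1v23": ((1,), (2, 3)),
    "12v3": ((1, 2), (3,)),
}


def assign_groups(uefm: np.ndarray) -> np.ndarray:
    """Impairment group per subject: 1 if UEFM < 30, 2 if 30 <= UEFM < 50,
    3 if UEFM >= 50."""
    uefm = np.asarray(uefm, dtype=float)
    if np.any((uefm < 0) | (uefm > 66)):
        raise ValueError("UEFM scores must be in [0, 66]")
    return np.where(uefm < UEFM_CUTS[0], 1,
                    np.where(uefm < UEFM_CUTS[1], 2, 3)).astype(int)


def cohen_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD Cohen's D, signed as mean(b) - mean(a).

    By the module's contrast convention ``a`` is the more-impaired side,
    so a positive D means the feature is larger in the less-impaired group.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        return float("nan")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else float("inf")
    return float((b.mean() - a.mean()) / np.sqrt(sp2))


def feature_table(features: pd.DataFrame, uefm: np.ndarray,
                  groups: np.ndarray | None = None) -> pd.DataFrame:
    """Per-feature association table: Pearson r and p vs UEFM, R^2,
    Cohen's D (+ t-test p) for the four group contrasts, one-way ANOVA.

    Non-finite feature values (e.g. infinite ratio sentinels) are excluded
    per feature.  Contrasts lacking 2+ subjects per side come out NaN.
    """
    uefm = np.asarray(uefm, dtype=float)
    if groups is None:
        groups = assign_groups(uefm)
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        ok = np.isfinite(x)
        row = {"feature": name, "n": int(ok.sum())}
        if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(uefm[ok]) > 0:
            r, p = stats.pearsonr(x[ok], uefm[ok])
            row |= {"pearson_r": r, "p_value": p, "r_squared": r * r}
        else:
            row |= {"pearson_r": np.nan, "p_value": np.nan,
                    "r_squared": np.nan}
        by_group = {g: x[ok & (groups == g)] for g in (1, 2, 3)}
        for cname, (lo, hi) in CONTRASTS.items():
            a = np.concatenate([by_group[g] for g in lo])
            b = np.concatenate([by_group[g] for g in hi])
            d = cohen_d(a, b)
            if a.size >= 2 and b.size >= 2:
                _, tp = stats.ttest_ind(a, b, equal_var=True)
            else:
                tp = np.nan
            row |= {f"cohen_d_{cname}": d, f"abs_d_{cname}": abs(d),
                    f"t_p_{cname}": tp}
        if all(v.size >= 2 for v in by_group.values()):
            F, ap = stats.f_oneway(*by_group.values())
            row |= {"anova_F": float(F), "anova_p": float(ap)}
        else:
            row |= {"anova_F": np.nan, "anova_p": np.nan}
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1 / (1 - R_i^2) per variable, where R_i^2
    comes from regressing variable i on the others (with intercept).

    Perfect collinearity yields an infinite sentinel; values >= 5 signal
    problematic multicollinearity.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 variables")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("VIF needs more observations than variables")
    out = {}
    arr = X.to_numpy(dtype=float)
    for i, name in enumerate(X.columns):
        y = arr[:, i]
        others = np.delete(arr, i, axis=1)
        design = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid ** 2)) / tss if tss > 0 else 1.0
        out[name] = float("inf") if 1.0 - r2 < 1e-10 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class EliminationStep:
    variables: list[str]
    p_values: dict[str, float]     # slope p-values
    aic: float
    delta_aic: float = float("nan")


@dataclass
class EliminationTrace:
    steps: list[EliminationStep]
    prefiltered_out: dict[str, float]     # feature -> simple-correlation p
    selected_variables: list[str] = field(default_factory=list)
    selected_step: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"step": i, "n_variables": len(s.variables),
             "variables": "+".join(s.variables), "aic": s.aic,
             "delta_aic": s.delta_aic,
             "substantial_support": s.delta_aic < 2.0}
            for i, s in enumerate(self.steps)])


def _gaussian_aic(result) -> float:
    """AIC = 2k - 2 ln L with k counting intercept, slopes and the residual
    variance (statsmodels' OLS aic + 2; the offset cannot alter ranking)."""
    k = result.df_model + 2  # slopes + intercept + sigma^2
    return float(2 * k - 2 * result.llf)


def backward_eliminate(X: pd.DataFrame, uefm: np.ndarray,
                       prefilter_alpha: float = 0.05) -> EliminationTrace:
    """Minimum-AIC backward elimination of an OLS model predicting UEFM.

    Features whose simple Pearson correlation with UEFM has p >=
    ``prefilter_alpha`` are dropped first.  Then the highest-p coefficient
    is removed one step at a time down to a single variable, and the step
    with minimal AIC is selected (delta AIC < 2 marks models with
    substantial empirical support).
    """
    y = np.asarray(uefm, dtype=float)
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > number of variables + 1")
    ok_rows = np.isfinite(X.to_numpy(float)).all(axis=1)
    X = X.loc[ok_rows]
    y = y[ok_rows]
    prefiltered = {}
    kept = []
    for name in X.columns:
        x = X[name].to_numpy(float)
        if np.std(x) == 0:
            prefiltered[name] = float("nan")
            continue
        _, p = stats.pearsonr(x, y)
        if p >= prefilter_alpha:
            prefiltered[name] = float(p)
        else:
            kept.append(name)
    steps: list[EliminationStep] = []
    variables = list(kept)
    while variables:
        design = sm.add_constant(X[variables])
        res = sm.OLS(y, design).fit()
        pvals = {v: float(res.pvalues[v]) for v in variables}
        steps.append(EliminationStep(variables=list(variables),
                                     p_values=pvals, aic=_gaussian_aic(res)))
        if len(variables) == 1:
            break
        variables.remove(max(pvals, key=pvals.get))
    trace = EliminationTrace(steps=steps, prefiltered_out=prefiltered)
    if steps:
        aics = np.array([s.aic for s in steps])
        best = int(np.argmin(aics))
        for s in steps:
            s.delta_aic = float(s.aic - aics[best])
        trace.selected_step = best
        trace.selected_variables = list(steps[best].variables)
    return trace
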