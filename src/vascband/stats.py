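"""Core statistics: univariate logistic fits, z-scoring, VIF, AUC and DeLong.

The DeLong machinery (placement values, structural components, paired AUC
comparison) is implemented here directly; model fitting goes through
statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "UnivariateResult",
    "DeLongComparison",
    "univariate_lr",
    "odds_change_percent",
    "zscore",
    "vif_values",
    "vif_filter",
    "auc_mann_whitney",
    "delong_variance",
    "auc_delong_ci",
    "delong_test",
    "wilson_interval",
]


# ---------------------------------------------------------------- univariate


@dataclass
class UnivariateResult:
    """Unstandardized per-unit logistic slope for one feature."""

    feature: str
    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float
    mean_malignant: float
    sd_malignant: float
    mean_benign: float
    sd_benign: float
    separable: bool = False


def univariate_lr(x: pd.Series | np.ndarray, y: np.ndarray, name: str | None = None) -> UnivariateResult:
    """Maximum-likelihood intercept+slope logistic fit of y on one feature.

    The coefficient is per unit of the raw (unstandardized) feature with a
    Wald 95% CI.  Complete separation is flagged rather than allowed to
    diverge silently.
    """
    name = name or getattr(x, "name", "x")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature contains non-finite values")
    design = sm.add_constant(x)
    separable = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception:
            # complete separation: a light ridge keeps the estimate finite
            separable = True
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-4, L1_wt=0.0
            )
    beta = float(fit.params[1])
    try:
        bse = np.asarray(fit.bse, dtype=float)
        se = float(bse[1]) if np.all(np.isfinite(bse)) else np.inf
    except Exception:
        se = np.inf
    if not np.isfinite(se) or se > 1e3 * max(1.0, abs(beta)):
        separable = True
    if separable:
        warnings.warn(f"possible complete separation for feature {name!r}", stacklevel=2)
    p = float(fit.pvalues[1]) if np.isfinite(se) else np.nan
    m, b = x[y == 1], x[y == 0]
    return UnivariateResult(
        feature=name,
        coefficient=beta,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        p_value=p,
        mean_malignant=float(m.mean()),
        sd_malignant=float(m.std(ddof=1)),
        mean_benign=float(b.mean()),
        sd_benign=float(b.std(ddof=1)),
        separable=separable,
    )


def odds_change_percent(beta: float) -> float:
    """Percent change in odds per unit increase: negative slopes are reported
    as the percent decrease 100*(1 - e^beta), positive as the increase
    100*(e^beta - 1)."""
    if beta < 0:
        return 100.0 * (1.0 - np.exp(beta))
    return 100.0 * (np.exp(beta) - 1.0)


# ------------------------------------------------------------------ z-score


def zscore(
    table: pd.DataFrame, columns: list[str] | None = None, ddof: int = 1
) -> pd.DataFrame:
    """Standardize numeric columns to mean 0, SD 1 (sample SD by default).

    Constant columns are dropped with a warning.  Non-numeric and excluded
    columns pass through untouched.
    """
    out = table.copy()
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    for c in columns:
        sd = out[c].std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"dropping constant column {c!r}", stacklevel=2)
            out = out.drop(columns=[c])
            continue
        out[c] = (out[c] - out[c].mean()) / sd
    return out


# ---------------------------------------------------------------------- VIF


def vif_values(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R^2_j) per column (intercept included
    in each auxiliary regression)."""
    vifs = {}
    arr = X.to_numpy(dtype=float)
    arr = arr - arr.mean(axis=0)  # centring improves lstsq conditioning
    n = len(X)
    for j, col in enumerate(X.columns):
        others = np.delete(arr, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        target = arr[:, j]
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        resid = target - design @ coef
        ss_res = float(resid @ resid)
        ss_tot = float((target**2).sum())
        if ss_tot == 0:
            vifs[col] = np.inf
            continue
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
        vifs[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vifs)


def vif_filter(X: pd.DataFrame, features: list[str] | None = None, threshold: float = 5.0) -> list[str]:
    """Iteratively drop the highest-VIF feature until all VIFs <= threshold.

    Ties (including several infinite VIFs from exact collinearity) are broken
    lexicographically so the result is deterministic.
    """
    kept = list(features if features is not None else X.columns)
    while len(kept) >= 2:
        vifs = vif_values(X[kept])
        worst = vifs.max()
        if worst <= threshold:
            break
        candidates = sorted(vifs.index[vifs == worst])
        kept.remove(candidates[0])
    return kept


# ------------------------------------------------------------- AUC / DeLong


def auc_mann_whitney(y: np.ndarray, pred: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic (ties count 1/2)."""
    y = np.asarray(y, dtype=int)
    pred = np.asarray(pred, dtype=float)
    pos = pred[y == 1]
    neg = pred[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes to compute an AUC")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (len(pos) * len(neg)))


def _placements(y: np.ndarray, pred: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the per-subject structural components (placement values)."""
    pos = pred[y == 1]
    neg = pred[y == 0]
    m, n = len(pos), len(neg)
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v_pos = (all_ranks[:m] - pos_ranks) / n  # P(pred_neg < pos_i), ties halved
    v_neg = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v_pos.mean())
    return auc, v_pos, v_neg


def delong_variance(y: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong sampling variance for one prediction vector."""
    y = np.asarray(y, dtype=int)
    pred = np.asarray(pred, dtype=float)
    auc, v_pos, v_neg = _placements(y, pred)
    var = v_pos.var(ddof=1) / len(v_pos) + v_neg.var(ddof=1) / len(v_neg)
    return auc, float(var)


def auc_delong_ci(y: np.ndarray, pred: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """(AUC, low, high): DeLong normal-approximation CI clipped to [0, 1]."""
    auc, var = delong_variance(y, pred)
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return auc, float(max(0.0, auc - half)), float(min(1.0, auc + half))


@dataclass
class DeLongComparison:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p_value: float
    degenerate: bool = False


def delong_test(pred_a: np.ndarray, pred_b: np.ndarray, y: np.ndarray) -> DeLongComparison:
    """Paired DeLong test for the difference of two correlated AUCs.

    Both prediction vectors must score the same subjects.  Ties are handled
    by midranks; fully degenerate inputs (no variance in the paired
    difference) return p = 1 with a warning.
    """
    y = np.asarray(y, dtype=int)
    pred_a = np.asarray(pred_a, dtype=float)
    pred_b = np.asarray(pred_b, dtype=float)
    if pred_a.shape != pred_b.shape or pred_a.shape != y.shape:
        raise ValueError("paired predictions and labels must have equal length")
    auc_a, va_pos, va_neg = _placements(y, pred_a)
    auc_b, vb_pos, vb_neg = _placements(y, pred_b)
    m, n = len(va_pos), len(va_neg)
    s_pos = np.cov(np.stack([va_pos, vb_pos]), ddof=1)
    s_neg = np.cov(np.stack([va_neg, vb_neg]), ddof=1)
    var = (
        s_pos[0, 0] / m + s_neg[0, 0] / n
        + s_pos[1, 1] / m + s_neg[1, 1] / n
        - 2 * (s_pos[0, 1] / m + s_neg[0, 1] / n)
    )
    delta = auc_a - auc_b
    if var <= 1e-16:
        if abs(delta) > 1e-12:
            raise ValueError("zero DeLong variance with non-zero AUC difference")
        warnings.warn("degenerate DeLong comparison (identical rankings); p = 1", stacklevel=2)
        return DeLongComparison(auc_a, auc_b, 0.0, 0.0, 1.0, degenerate=True)
    z = delta / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return DeLongComparison(auc_a, auc_b, float(delta), float(z), float(min(p, 1.0)))


def wilson_interval(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo, hi = proportion_confint(successes, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)
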