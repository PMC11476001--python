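"""Multivariate malignancy models: selection cascade, CV evaluation, families.

:class:`MalignancyLogit` is the full modelling recipe as one sklearn-style
classifier: LASSO selection (CV-tuned penalty) -> VIF filter (threshold 5.0)
-> one-in-ten forward stepwise -> maximum-likelihood logistic fit.
``fit_and_evaluate`` wraps it in stratified k-fold cross-validation, pooling
the out-of-fold predicted probabilities for the reported AUC (DeLong CI) and
accuracy at the 0.5 threshold (Wilson CI); the coefficients and Wald
p-values come from a full-data refit.  ``run_model_families`` runs the whole
grid of compartment x band models plus the six integrative families and the
pairwise DeLong comparison matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .selection import ForwardStepwiseSelector, LassoLogisticSelector, VIFFilter
from .stats import auc_delong_ci, delong_test, wilson_interval, zscore

__all__ = [
    "MalignancyLogit",
    "ModelReport",
    "fit_and_evaluate",
    "run_model_families",
    "candidate_sets",
    "filter_cohort",
    "BAND_FEATURES",
    "DEMOGRAPHICS",
    "NODULE_CHARACTERISTICS",
]

BANDS = (5, 10, 15)
BAND_FEATURES = [
    f"{comp}{d}_{metric}"
    for comp in ("artery", "vein")
    for d in BANDS
    for metric in ("count", "volume", "tortuosity")
]
DEMOGRAPHICS = ["age", "gender", "smoking_status", "pack_years", "BMI"]
NODULE_CHARACTERISTICS = [
    "tumor_volume",
    "tumor_density",
    "tumor_mean_diameter",
    "tumor_max_diameter",
    "tumor_surface_area",
    "tumor_irregularity",
    "tumor_cal_volume",
    "tumor_cavitiy_ratio",
    "tumor_ground_glass_ratio",
    "tumor_fat_ratio",
    "solidness",
    "tumor_AgatstonCal",
]


def _fit_logit(y: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Logistic MLE with a ridge fallback under complete separation.

    Returns (params, p_values); the fallback keeps coefficients finite and
    reports NaN p-values (Wald inference is meaningless at separation).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            params = np.asarray(fit.params, dtype=float)
            if np.all(np.isfinite(params)) and np.all(np.isfinite(fit.bse)):
                return params, np.asarray(fit.pvalues, dtype=float)
        except Exception:
            pass
        fit = sm.GLM(y, design, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-4, L1_wt=0.0
        )
    params = np.asarray(fit.params, dtype=float)
    return params, np.full(len(params), np.nan)


class MalignancyLogit(ClassifierMixin, BaseEstimator):
    """LASSO -> VIF -> stepwise -> logistic regression as one classifier.

    Expects standardized features.  Fitted attributes: ``selected_features_``
    (the surviving feature names), ``coef_`` / ``intercept_`` (final
    maximum-likelihood fit), ``pvalues_`` (Wald), ``significant_``
    (p < 0.05).  If the LASSO stage empties the candidate set the model
    degrades to the intercept-only prevalence predictor.
    """

    def __init__(
        self,
        cv: int = 10,
        vif_threshold: float = 5.0,
        cap: int | None = None,
        n_penalties: int = 30,
        random_state: int = 0,
    ):
        self.cv = cv
        self.vif_threshold = vif_threshold
        self.cap = cap
        self.n_penalties = n_penalties
        self.random_state = random_state

    def fit(self, X, y):
        X_arr = validate_data(self, X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        names = np.asarray(
            self.feature_names_in_
            if hasattr(self, "feature_names_in_")
            else [str(i) for i in range(X_arr.shape[1])]
        )
        frame = pd.DataFrame(X_arr, columns=names)

        selected = list(names)
        lasso = LassoLogisticSelector(
            cv=self.cv, n_penalties=self.n_penalties, random_state=self.random_state
        )
        lasso.fit(frame[selected], y)
        selected = lasso.selected_features_
        self.lasso_C_ = lasso.C_
        if len(selected) >= 2:
            selected = VIFFilter(self.vif_threshold).fit(frame[selected], y).selected_features_
        if selected:
            stepwise = ForwardStepwiseSelector(cap=self.cap).fit(frame[selected], y)
            selected = stepwise.selected_features_

        self.selected_features_ = selected
        if selected:
            design = sm.add_constant(frame[selected].to_numpy())
            params, pvals = _fit_logit(y, design)
            self.intercept_ = float(params[0])
            self.coef_ = params[1:]
            self.pvalues_ = dict(zip(selected, pvals[1:]))
        else:
            warnings.warn("no features survived selection; intercept-only model", stacklevel=2)
            prevalence = y.mean()
            self.intercept_ = float(np.log(prevalence / (1 - prevalence)))
            self.coef_ = np.zeros(0)
            self.pvalues_ = {}
        self.significant_ = [f for f, p in self.pvalues_.items() if p < 0.05]
        self._support = np.isin(names, selected)
        return self

    def decision_function(self, X):
        check_is_fitted(self)
        X_arr = validate_data(self, X, dtype=float, reset=False)
        return self.intercept_ + X_arr[:, self._support] @ self.coef_

    def predict_proba(self, X):
        logit = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-logit))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


@dataclass
class ModelReport:
    """Everything reported for one model family on one cohort."""

    name: str
    candidates: list[str]
    selected: list[str]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    auc: float
    auc_ci: tuple[float, float]
    accuracy: float
    accuracy_ci: tuple[float, float]
    n_folds: int
    n_subjects: int
    seed: int
    oof_pred: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("oof_pred")
        return d


def fit_and_evaluate(
    table: pd.DataFrame,
    features: list[str],
    y: np.ndarray | str = "malignant",
    k_folds: int = 10,
    seed: int = 0,
    name: str = "model",
    select: bool = True,
    nested: bool = False,
    threshold: float = 0.5,
) -> ModelReport:
    """Cross-validated evaluation of the full modelling recipe.

    Selection (when enabled) runs once on the full data; the stratified
    k-fold loop refits the final logistic model per fold and pools the
    out-of-fold probabilities for the AUC (DeLong 95% CI) and the accuracy at
    the classification threshold (Wilson 95% CI).

    ``nested=True`` instead re-runs the entire selection cascade inside every
    training fold, which removes the selection optimism of the default and
    gives honestly calibrated out-of-fold predictions (the reported
    ``selected`` list still comes from the full-data cascade).
    """
    if isinstance(y, str):
        y = table[y].to_numpy()
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k_folds:
        raise ValueError(
            f"cohort too small for {k_folds}-fold stratified CV: minority class has "
            f"{counts.min()} subjects (need >= {k_folds})"
        )
    X = table[features]
    model = MalignancyLogit(cv=k_folds, random_state=seed)
    if select:
        model.fit(X, y)
        final = model.selected_features_
    else:
        final = list(features)

    oof = np.empty(len(y), dtype=float)
    folds = StratifiedKFold(k_folds, shuffle=True, random_state=seed)
    for train, test in folds.split(X, y):
        if select and nested:
            # fold-internal selection; a coarser penalty grid and 5 inner folds
            # keep the nested loop tractable without affecting its lack of bias
            fold_model = MalignancyLogit(
                cv=min(k_folds, 5), n_penalties=15, random_state=seed
            ).fit(X.iloc[train], y[train])
            oof[test] = (
                fold_model.predict_proba(X.iloc[test])[:, 1]
                if fold_model.selected_features_
                else y.mean()
            )
        elif final:
            design = sm.add_constant(X.iloc[train][final].to_numpy(), has_constant="add")
            params, _ = _fit_logit(y[train], design)
            test_design = sm.add_constant(X.iloc[test][final].to_numpy(), has_constant="add")
            oof[test] = 1.0 / (1.0 + np.exp(-(test_design @ params)))
        else:
            # intercept-only: covariate-free prediction; fold-specific
            # prevalences would only inject artificial rank structure
            oof[test] = y.mean()

    if final:
        design = sm.add_constant(X[final].to_numpy())
        params, pvals = _fit_logit(y, design)
        coefficients = dict(zip(final, params[1:]))
        p_values = dict(zip(final, pvals[1:]))
    else:
        coefficients, p_values = {}, {}

    if np.ptp(oof) < 1e-12:
        auc, lo, hi = 0.5, 0.5, 0.5  # constant predictor: chance by definition
    else:
        auc, lo, hi = auc_delong_ci(y, oof)
    correct = int(((oof >= threshold).astype(int) == y).sum())
    acc_lo, acc_hi = wilson_interval(correct, len(y))
    return ModelReport(
        name=name,
        candidates=list(features),
        selected=final,
        coefficients=coefficients,
        p_values=p_values,
        auc=auc,
        auc_ci=(lo, hi),
        accuracy=correct / len(y),
        accuracy_ci=(acc_lo, acc_hi),
        n_folds=k_folds,
        n_subjects=len(y),
        seed=seed,
        oof_pred=oof,
    )


def candidate_sets(bands: tuple[int, ...] = BANDS) -> dict[str, list[str]]:
    """Candidate feature sets for every model family.

    The compartment x band grid (Artery5 ... VesselAll) plus the six
    integrative families (demographics, macro-vasculature, CT-derived nodule,
    and their unions).
    """
    sets: dict[str, list[str]] = {}
    metrics = ("count", "volume", "tortuosity")
    for d in bands:
        sets[f"Artery{d}"] = [f"artery{d}_{m}" for m in metrics]
        sets[f"Vein{d}"] = [f"vein{d}_{m}" for m in metrics]
        sets[f"Vessel{d}"] = sets[f"Artery{d}"] + sets[f"Vein{d}"]
    sets["ArteryAll"] = [f for f in BAND_FEATURES if f.startswith("artery")]
    sets["VeinAll"] = [f for f in BAND_FEATURES if f.startswith("vein")]
    sets["VesselAll"] = list(BAND_FEATURES)
    sets["Demographics"] = list(DEMOGRAPHICS)
    sets["MacroVasc"] = list(BAND_FEATURES)
    sets["Nodule"] = list(NODULE_CHARACTERISTICS)
    sets["MacroVasc+Demographics"] = list(BAND_FEATURES) + DEMOGRAPHICS
    sets["MacroVasc+Nodule"] = list(BAND_FEATURES) + NODULE_CHARACTERISTICS
    sets["Composite"] = list(BAND_FEATURES) + DEMOGRAPHICS + NODULE_CHARACTERISTICS
    return sets


def filter_cohort(table: pd.DataFrame, cohort: str) -> pd.DataFrame:
    """'all' or the clinically challenging '8-20' mm mean-diameter subset."""
    if cohort == "all":
        return table
    if cohort == "8-20":
        d = table["tumor_mean_diameter"]
        return table[(d >= 8.0) & (d <= 20.0)].reset_index(drop=True)
    raise ValueError(f"unknown cohort {cohort!r} (expected 'all' or '8-20')")


def run_model_families(
    table: pd.DataFrame,
    cohort: str = "all",
    seed: int = 0,
    families: list[str] | None = None,
    k_folds: int | None = None,
    nested: bool = False,
) -> tuple[dict[str, ModelReport], pd.DataFrame]:
    """Run the model families on one cohort and DeLong-compare their AUCs.

    Features are z-scored within the analyzed cohort before selection.  The
    fold count defaults to 10 for the full cohort and 5 for the 8-20 mm
    subset.  Returns the per-family reports and the matrix of pairwise
    DeLong p-values on the pooled out-of-fold predictions.
    """
    sub = filter_cohort(table, cohort)
    if k_folds is None:
        k_folds = 10 if cohort == "all" else 5
    y = sub["malignant"].to_numpy()
    sets = candidate_sets()
    if families is not None:
        sets = {k: v for k, v in sets.items() if k in families}
    all_feats = sorted({f for fs in sets.values() for f in fs if f in sub.columns})
    standardized = zscore(sub[all_feats + ["malignant"]], columns=all_feats)

    reports: dict[str, ModelReport] = {}
    for fam, feats in sets.items():
        feats = [f for f in feats if f in standardized.columns]
        if not feats:
            continue
        reports[fam] = fit_and_evaluate(
            standardized, feats, y, k_folds=k_folds, seed=seed, name=fam, nested=nested
        )
    names = list(reports)
    pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmp = delong_test(reports[a].oof_pred, reports[b].oof_pred, y)
            pmat.loc[a, b] = pmat.loc[b, a] = cmp.p_value
    return reports, pmat


def reports_to_frame(reports: dict[str, ModelReport]) -> pd.DataFrame:
    rows = []
    for r in reports.values():
        rows.append(
            {
                "model": r.name,
                "selected": ";".join(r.selected),
                "coefficients": json.dumps({k: round(v, 4) for k, v in r.coefficients.items()}),
                "p_values": json.dumps({k: round(v, 5) for k, v in r.p_values.items()}),
                "auc": r.auc,
                "auc_ci_low": r.auc_ci[0],
                "auc_ci_high": r.auc_ci[1],
                "accuracy": r.accuracy,
                "accuracy_ci_low": r.accuracy_ci[0],
                "accuracy_ci_high": r.accuracy_ci[1],
                "n_folds": r.n_folds,
                "n_subjects": r.n_subjects,
            }
        )
    return pd.DataFrame(rows)
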