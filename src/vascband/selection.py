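"""Feature-selection estimators for the malignancy models.

scikit-learn-style transformers implementing the selection cascade used for
every multivariate model: L1 (LASSO) logistic selection with cross-validated
penalty choice, iterative variance-inflation-factor filtering, and one-in-ten
forward stepwise selection by AIC.  Each composes with sklearn pipelines; the
module-level functions are thin wrappers.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data

from .stats import vif_filter as _vif_filter

logger = logging.getLogger("vascband.selection")

__all__ = [
    "LassoLogisticSelector",
    "VIFFilter",
    "ForwardStepwiseSelector",
    "lasso_select",
    "forward_stepwise",
]


class LassoLogisticSelector(SelectorMixin, BaseEstimator):
    """Select features with non-zero L1-penalized logistic coefficients.

    The penalty is chosen on a log-spaced path by minimizing mean
    cross-validated deviance (stratified k-fold, seeded); features whose
    coefficients the optimal penalty shrinks exactly to zero are dropped.
    Inputs are expected standardized.

    Parameters
    ----------
    cv : int
        Folds for the penalty search (10 for the full cohort, 5 for small
        subsets).
    n_penalties : int
        Points on the log-spaced inverse-penalty path.
    random_state : int
        Seed for the fold shuffle; fixing it makes selection deterministic.
    """

    def __init__(
        self,
        cv: int = 10,
        n_penalties: int = 30,
        c_range: tuple[float, float] = (1e-3, 1e2),
        random_state: int = 0,
    ):
        self.cv = cv
        self.n_penalties = n_penalties
        self.c_range = c_range
        self.random_state = random_state

    def fit(self, X, y):
        X_arr = validate_data(self, X, dtype=float)
        y = np.asarray(y, dtype=int)
        folds = StratifiedKFold(self.cv, shuffle=True, random_state=self.random_state)
        model = LogisticRegressionCV(
            Cs=np.logspace(*np.log10(self.c_range), self.n_penalties),
            cv=folds,
            l1_ratios=(1.0,),
            solver="liblinear",
            scoring="neg_log_loss",
            refit=True,
            random_state=self.random_state,
            use_legacy_attributes=False,
        )
        model.fit(X_arr, y)
        self.C_ = float(np.ravel(model.C_)[0])
        self.coef_ = model.coef_[0]
        self.support_ = np.abs(self.coef_) > 1e-8
        logger.debug(
            "lasso: C=%.4g, kept %d/%d features", self.C_, int(self.support_.sum()),
            len(self.support_),
        )
        if not self.support_.any():
            warnings.warn("LASSO shrank every coefficient to zero", stacklevel=2)
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    @property
    def selected_features_(self) -> list[str]:
        check_is_fitted(self)
        if hasattr(self, "feature_names_in_"):
            return list(np.asarray(self.feature_names_in_)[self.support_])
        return [str(i) for i in np.flatnonzero(self.support_)]


class VIFFilter(SelectorMixin, BaseEstimator):
    """Iteratively drop the highest-VIF feature while any VIF > threshold."""

    def __init__(self, threshold: float = 5.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        X_arr = validate_data(self, X, dtype=float)
        names = (
            list(self.feature_names_in_)
            if hasattr(self, "feature_names_in_")
            else [str(i) for i in range(X_arr.shape[1])]
        )
        frame = pd.DataFrame(X_arr, columns=names)
        kept = _vif_filter(frame, threshold=self.threshold) if len(names) >= 2 else names
        dropped = [n for n in names if n not in kept]
        if dropped:
            logger.debug("vif filter dropped: %s", dropped)
        self.support_ = np.array([n in kept for n in names])
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    @property
    def selected_features_(self) -> list[str]:
        check_is_fitted(self)
        if hasattr(self, "feature_names_in_"):
            return list(np.asarray(self.feature_names_in_)[self.support_])
        return [str(i) for i in np.flatnonzero(self.support_)]


class ForwardStepwiseSelector(SelectorMixin, BaseEstimator):
    """Greedy forward selection by AIC, capped by the one-in-ten rule.

    If the candidate count already satisfies ``cap`` (floor(events/10) by
    default, where events is the minority-class count) the step is skipped
    entirely; otherwise features are added greedily while the AIC improves,
    never exceeding the cap.
    """

    def __init__(self, cap: int | None = None):
        self.cap = cap

    def fit(self, X, y):
        X_arr = validate_data(self, X, dtype=float)
        y = np.asarray(y, dtype=int)
        events = int(min((y == 1).sum(), (y == 0).sum()))
        cap = self.cap if self.cap is not None else max(1, events // 10)
        self.cap_ = cap
        p = X_arr.shape[1]
        if p <= cap:
            self.support_ = np.ones(p, dtype=bool)
            return self

        def aic_of(cols: list[int]) -> float:
            design = sm.add_constant(X_arr[:, cols]) if cols else np.ones((len(y), 1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
                except Exception:
                    return np.inf  # separation: never preferred
            return float(fit.aic)

        chosen: list[int] = []
        current = aic_of(chosen)
        remaining = list(range(p))
        while remaining and len(chosen) < cap:
            scores = [(aic_of(chosen + [j]), j) for j in remaining]
            best_aic, best_j = min(scores)
            if best_aic >= current:
                break
            chosen.append(best_j)
            remaining.remove(best_j)
            current = best_aic
        logger.debug("stepwise trace (cap %d): chose columns %s", cap, chosen)
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[chosen] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    @property
    def selected_features_(self) -> list[str]:
        check_is_fitted(self)
        if hasattr(self, "feature_names_in_"):
            return list(np.asarray(self.feature_names_in_)[self.support_])
        return [str(i) for i in np.flatnonzero(self.support_)]


def lasso_select(
    table: pd.DataFrame,
    candidates: list[str],
    y: np.ndarray | str = "malignant",
    k_folds: int = 10,
    seed: int = 0,
) -> list[str]:
    """Features with non-zero CV-tuned LASSO logistic coefficients."""
    if isinstance(y, str):
        y = table[y].to_numpy()
    sel = LassoLogisticSelector(cv=k_folds, random_state=seed).fit(table[candidates], y)
    return sel.selected_features_


def forward_stepwise(
    table: pd.DataFrame,
    features: list[str],
    y: np.ndarray | str = "malignant",
    cap: int | None = None,
) -> list[str]:
    """One-in-ten-capped greedy AIC forward selection (wrapper)."""
    if isinstance(y, str):
        y = table[y].to_numpy()
    sel = ForwardStepwiseSelector(cap=cap).fit(table[features], y)
    return sel.selected_features_
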