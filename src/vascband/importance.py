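"""Feature-importance survey: permutation importance and Shapley values.

Importance is assessed with two complementary attribution methods across
three classifiers — logistic regression, a linear-kernel SVM (C = 1.0), and
an MLP (one hidden layer of 100 units, constant learning rate 0.001) — and
the six resulting score columns are each min-max normalized to [0, 1] and
averaged into a single ranking.

Shapley values are exact here: the closed form ``phi_j = w_j (x_j - b_j)``
for linear decision functions, and full enumeration over all 2^p feature
coalitions with background-mean imputation otherwise (p <= 20 enforced).
Both satisfy local accuracy (the attributions of a sample sum to
``f(x) - f(background)``) by construction.
"""

from __future__ import annotations

import warnings
from math import comb

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "train_explainer_models",
    "permutation_importance",
    "shapley_linear",
    "shapley_enumeration",
    "shapley_values",
    "aggregate_importance",
    "importance_survey",
    "MAX_ENUMERATION_FEATURES",
]

MAX_ENUMERATION_FEATURES = 20


def train_explainer_models(
    X: pd.DataFrame | np.ndarray, y: np.ndarray, seed: int = 0, max_iter: int = 2000
) -> dict:
    """Fit the three explainer classifiers on standardized features.

    Returns ``{"LR": ..., "SVM": ..., "MLP": ...}``; a ``converged_`` flag is
    attached to the MLP (non-convergence at the iteration cap warns and
    flags, it does not raise).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    lr = LogisticRegression(C=np.inf, max_iter=max_iter).fit(X, y)
    svm = SVC(kernel="linear", C=1.0, random_state=seed).fit(X, y)
    mlp = MLPClassifier(
        hidden_layer_sizes=(100,),
        learning_rate="constant",
        learning_rate_init=0.001,
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        mlp.fit(X, y)
    mlp.converged_ = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if not mlp.converged_:
        warnings.warn("MLP did not converge within the iteration cap", stacklevel=2)
    return {"LR": lr, "SVM": svm, "MLP": mlp}


def permutation_importance(
    model, X, y, n_repeats: int = 50, seed: int = 0
) -> np.ndarray:
    """Mean AUC drop when one feature column is shuffled (seeded)."""
    result = _sk_permutation_importance(
        model, np.asarray(X, dtype=float), np.asarray(y, dtype=int),
        scoring="roc_auc", n_repeats=n_repeats, random_state=seed,
    )
    return result.importances_mean


def _decision_weights(model) -> tuple[np.ndarray, float]:
    return np.asarray(model.coef_, dtype=float).ravel(), float(np.ravel(model.intercept_)[0])


def shapley_linear(model, X: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Exact Shapley attributions of a linear decision function."""
    w, _ = _decision_weights(model)
    return (np.asarray(X, dtype=float) - np.asarray(background, dtype=float)) * w


def _coalition_structure(p: int) -> dict:
    """Membership masks, per-feature subset indices, and Shapley weights for
    dimension p (cached: the structure is sample-independent)."""
    n_subsets = 1 << p
    subset_ids = np.arange(n_subsets, dtype=np.int64)
    masks = ((subset_ids[:, None] >> np.arange(p)) & 1).astype(bool)
    sizes = masks.sum(axis=1)
    # weight for adding a feature to a subset of the given size
    add_weight = np.array([1.0 / (p * comb(p - 1, s)) for s in range(p)])
    without = np.empty((p, n_subsets // 2), dtype=np.int64)
    weights = np.empty((p, n_subsets // 2))
    for j in range(p):
        wj = subset_ids[(subset_ids >> j) & 1 == 0]
        without[j] = wj
        weights[j] = add_weight[sizes[wj]]
    return {"masks": masks, "without": without, "weights": weights}


_structure_cache: dict[int, dict] = {}


def shapley_enumeration(
    f, X: np.ndarray, background: np.ndarray
) -> np.ndarray:
    """Exact Shapley values by enumerating all 2^p feature coalitions.

    ``f`` maps an (m, p) array to m scalar outputs.  Absent features are
    imputed with the background point.  Exact but exponential: p <= 20.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.asarray(background, dtype=float)
    n, p = X.shape
    if p > MAX_ENUMERATION_FEATURES:
        raise ValueError(
            f"exact enumeration supports at most {MAX_ENUMERATION_FEATURES} features "
            f"(got {p}); restrict the feature set or use the linear closed form"
        )
    if p not in _structure_cache:
        if len(_structure_cache) > 4:
            _structure_cache.clear()
        _structure_cache[p] = _coalition_structure(p)
    struct = _structure_cache[p]
    masks, without, weights = struct["masks"], struct["without"], struct["weights"]

    phi = np.zeros((n, p))
    bits = 1 << np.arange(p, dtype=np.int64)
    for i in range(n):
        coalitions = np.where(masks, X[i], background)
        fvals = np.asarray(f(coalitions), dtype=float)
        for j in range(p):
            wj = without[j]
            phi[i, j] = weights[j] @ (fvals[wj + bits[j]] - fvals[wj])
    return phi


def _model_output(model):
    """Scalar output the attributions explain, always on the decision scale:
    the margin for linear models, the log-odds for probabilistic classifiers.

    Using the probability scale instead would squash the attributions of a
    dominant feature on confidently classified samples (sigmoid saturation)
    while leaving noise-feature wiggles uncompressed, distorting mean-|phi|
    rankings relative to the margin-scale linear columns.
    """
    if hasattr(model, "decision_function") and hasattr(model, "coef_"):
        return lambda Z: model.decision_function(Z)

    def log_odds(Z):
        p = np.clip(model.predict_proba(Z)[:, 1], 1e-12, 1 - 1e-12)
        return np.log(p / (1 - p))

    return log_odds


def shapley_values(
    model, X: np.ndarray, background: np.ndarray | None = None
) -> np.ndarray:
    """Per-sample per-feature exact Shapley attributions for a classifier.

    Linear models use the closed form; anything else full enumeration.  The
    background defaults to the feature means of ``X``.
    """
    X = np.asarray(X, dtype=float)
    if background is None:
        background = X.mean(axis=0)
    if hasattr(model, "coef_") and np.asarray(model.coef_).ndim <= 2:
        return shapley_linear(model, X, background)
    return shapley_enumeration(_model_output(model), X, background)


def aggregate_importance(raw_scores: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize each score column to [0, 1] and rank by the mean.

    A constant column carries no ranking information and is set to zero with
    a warning.  Output adds an ``average`` column and sorts descending by it
    (feature name breaks ties, so the table is deterministic).
    """
    if len(raw_scores) < 2:
        raise ValueError("need at least 2 features to rank")
    out = raw_scores.copy().astype(float)
    for col in out.columns:
        lo, hi = out[col].min(), out[col].max()
        if hi - lo < 1e-15:
            warnings.warn(f"constant importance column {col!r}; set to zero", stacklevel=2)
            out[col] = 0.0
        else:
            out[col] = (out[col] - lo) / (hi - lo)
    out["average"] = out.mean(axis=1)
    return out.sort_index().sort_values("average", ascending=False, kind="stable")


def importance_survey(
    table: pd.DataFrame,
    features: list[str],
    y: np.ndarray | str = "malignant",
    seed: int = 0,
    n_repeats: int = 50,
    shap_samples: int | None = 32,
) -> pd.DataFrame:
    """The full six-column importance table for one feature set.

    Trains the three explainer classifiers, computes permutation importance
    (AUC drop on the training table) and mean |Shapley| per feature for each,
    normalizes all six columns to [0, 1], and averages.  ``shap_samples``
    subsamples rows for the enumeration-based MLP attributions (seeded); the
    linear closed forms always use every row.
    """
    if isinstance(y, str):
        y = table[y].to_numpy()
    y = np.asarray(y, dtype=int)
    X = table[features].to_numpy(dtype=float)
    models = train_explainer_models(X, y, seed=seed)
    background = X.mean(axis=0)
    rng = np.random.default_rng(seed)

    raw = {}
    for label, model in models.items():
        raw[f"PI_{label}"] = permutation_importance(model, X, y, n_repeats=n_repeats, seed=seed)
        if hasattr(model, "coef_"):
            phi = shapley_linear(model, X, background)
        else:
            rows = X
            if shap_samples is not None and shap_samples < len(X):
                rows = X[rng.choice(len(X), shap_samples, replace=False)]
            phi = shapley_enumeration(_model_output(model), rows, background)
        raw[f"SHAP_{label}"] = np.abs(phi).mean(axis=0)
    frame = pd.DataFrame(raw, index=pd.Index(features, name="feature"))
    return aggregate_importance(frame)
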