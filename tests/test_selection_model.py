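"""Selection cascade and model pipeline behaviour."""

import warnings

import numpy as np
import pandas as pd
import pytest

from vascband.cohort import simulate_logit_cohort
from vascband.model import (
    MalignancyLogit,
    candidate_sets,
    filter_cohort,
    fit_and_evaluate,
    run_model_families,
)
from vascband.selection import (
    ForwardStepwiseSelector,
    LassoLogisticSelector,
    forward_stepwise,
    lasso_select,
)
from vascband.stats import zscore


def _toy(n, rng, p_noise=9, beta=1.5):
    X = rng.normal(size=(n, p_noise + 1))
    logit = beta * X[:, 0]
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
    cols = ["signal"] + [f"noise{i}" for i in range(p_noise)]
    return pd.DataFrame(X, columns=cols), y


class TestLassoSelection:
    def test_recovers_true_feature_across_seeds(self):
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            df, y = _toy(500, rng)
            sel = lasso_select(df, list(df.columns), y, k_folds=10, seed=seed)
            hits += "signal" in sel
        assert hits / n_runs >= 0.95

    def test_overwhelming_penalty_empties_selection(self, rng):
        df, y = _toy(200, rng)
        sel = LassoLogisticSelector(cv=5, n_penalties=2, c_range=(1e-8, 1e-7), random_state=0)
        with pytest.warns(UserWarning, match="zero"):
            sel.fit(df, y)
        assert sel.selected_features_ == []

    def test_duplicated_informative_feature_never_yields_noise_only(self):
        hits = 0
        n_runs = 30
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            df, y = _toy(500, rng, p_noise=8)
            df["signal_dup"] = df["signal"] + rng.normal(0, 1e-6, len(df))
            sel = lasso_select(df, list(df.columns), y, k_folds=10, seed=seed)
            hits += ("signal" in sel) or ("signal_dup" in sel)
        assert hits / n_runs >= 0.95


class TestForwardStepwise:
    def test_one_in_ten_cap_from_events(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(148, 8)), columns=[f"f{i}" for i in range(8)])
        y = np.zeros(148, int)
        y[:69] = 1  # 69 events -> cap 6
        sel = ForwardStepwiseSelector().fit(X, y)
        assert sel.cap_ == 6
        assert len(sel.selected_features_) <= 6

    def test_single_candidate_passes_through(self, rng):
        df, y = _toy(100, rng, p_noise=0)
        assert forward_stepwise(df, ["signal"], y) == ["signal"]

    def test_strong_feature_beats_null_under_cap_one(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(500, 2))
            ylogit = 1.5 * X[:, 0]
            y = (rng.uniform(size=500) < 1 / (1 + np.exp(-ylogit))).astype(int)
            df = pd.DataFrame(X, columns=["strong", "null"])
            assert_sel = forward_stepwise(df, ["strong", "null"], y, cap=1)
            hits += assert_sel == ["strong"]
        assert hits >= 95


class TestFitAndEvaluate:
    def test_perfectly_separated_features_reach_unit_auc(self):
        n = 100
        y = np.repeat([0, 1], n // 2)
        df = pd.DataFrame({"f": np.concatenate([np.linspace(-3, -1, 50), np.linspace(1, 3, 50)])})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = fit_and_evaluate(df, ["f"], y, k_folds=5, seed=0, select=False)
        assert rep.auc == 1.0

    def test_label_independent_feature_near_chance(self, rng):
        df = pd.DataFrame({"f": rng.normal(size=400)})
        y = rng.integers(0, 2, 400)
        rep = fit_and_evaluate(df, ["f"], y, k_folds=10, seed=0, select=False)
        assert rep.auc == pytest.approx(0.5, abs=0.1)

    def test_too_small_cohort_rejected(self, rng):
        df = pd.DataFrame({"f": rng.normal(size=16)})
        y = np.repeat([0, 1], 8)
        with pytest.raises(ValueError, match="too small"):
            fit_and_evaluate(df, ["f"], y, k_folds=10, seed=0)

    def test_reports_are_seed_deterministic(self):
        df = simulate_logit_cohort(300, {"artery5_count": 1.0}, seed=7)
        a = fit_and_evaluate(df, ["artery5_count", "vein5_count"], df.malignant.to_numpy(), 5, seed=3)
        b = fit_and_evaluate(df, ["artery5_count", "vein5_count"], df.malignant.to_numpy(), 5, seed=3)
        assert a.to_dict() == b.to_dict()
        np.testing.assert_array_equal(a.oof_pred, b.oof_pred)


class TestModelFamilies:
    def test_candidate_set_definitions(self):
        sets = candidate_sets()
        assert sets["Artery5"] == ["artery5_count", "artery5_volume", "artery5_tortuosity"]
        assert set(sets["Artery5"]) <= set(sets["Vessel5"])
        assert set(sets["MacroVasc"]) <= set(sets["Composite"])
        assert len(sets["VesselAll"]) == 18

    def test_subset_filter_selects_by_mean_diameter(self):
        df = pd.DataFrame({"tumor_mean_diameter": [5.0, 8.0, 14.0, 20.0, 25.0]})
        sub = filter_cohort(df, "8-20")
        assert list(sub.tumor_mean_diameter) == [8.0, 14.0, 20.0]
        with pytest.raises(ValueError, match="unknown cohort"):
            filter_cohort(df, "5-10")

    def test_single_signal_recovered_in_artery_and_vessel_models(self):
        df = simulate_logit_cohort(1200, {"artery5_count": 1.0}, seed=21)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports, pmat = run_model_families(df, "all", seed=2, families=["Artery5", "Vessel5"])
        for name in ("Artery5", "Vessel5"):
            assert "artery5_count" in reports[name].selected
        a, v = reports["Artery5"], reports["Vessel5"]
        assert a.auc_ci[0] <= v.auc <= a.auc_ci[1]
        assert pmat.loc["Artery5", "Vessel5"] == pmat.loc["Vessel5", "Artery5"]

    def test_standardized_coefficient_recovery(self):
        """A +1 SD-unit log-odds effect is recovered within 0.15 at n = 2000."""
        df = simulate_logit_cohort(2000, {"artery5_count": 1.0}, seed=5)
        z = zscore(df[["artery5_count", "malignant"]], columns=["artery5_count"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MalignancyLogit(cv=10, random_state=0).fit(
                z[["artery5_count"]], df.malignant.to_numpy()
            )
        assert model.coef_[0] == pytest.approx(1.0, abs=0.15)

    def test_sklearn_contract(self):
        from sklearn.base import clone

        m = MalignancyLogit(cv=5, random_state=3)
        params = m.get_params()
        assert params["cv"] == 5
        m2 = clone(m).set_params(cv=7)
        assert m2.get_params()["cv"] == 7
        df = simulate_logit_cohort(200, {"artery5_count": 1.2}, seed=1)
        z = zscore(df[["artery5_count", "vein5_count", "malignant"]],
                   columns=["artery5_count", "vein5_count"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m2.fit(z[["artery5_count", "vein5_count"]], df.malignant.to_numpy())
        proba = m2.predict_proba(z[["artery5_count", "vein5_count"]])
        assert proba.shape == (200, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
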