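"""Statistical primitives against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from vascband.stats import (
    auc_delong_ci,
    auc_mann_whitney,
    delong_test,
    delong_variance,
    odds_change_percent,
    univariate_lr,
    vif_filter,
    vif_values,
    zscore,
)


class TestUnivariateLogit:
    def test_mle_matches_grid_search_oracle(self):
        """Six-point fit equals a fine 2-parameter likelihood grid search."""
        x = np.array([0.0, 1.0, 2.0, 1.0, 2.0, 3.0])
        y = np.array([0, 0, 0, 1, 1, 1])

        def nll(b0, b1):
            eta = b0 + b1 * x
            return np.sum(np.log1p(np.exp(eta)) - y * eta)

        b0s = np.linspace(-6, 2, 401)
        b1s = np.linspace(-1, 4, 501)
        grid = np.array([[nll(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(grid.argmin(), grid.shape)
        # refine around the coarse optimum
        b0s2 = np.linspace(b0s[i] - 0.05, b0s[i] + 0.05, 201)
        b1s2 = np.linspace(b1s[j] - 0.05, b1s[j] + 0.05, 201)
        grid2 = np.array([[nll(b0, b1) for b1 in b1s2] for b0 in b0s2])
        i2, j2 = np.unravel_index(grid2.argmin(), grid2.shape)

        res = univariate_lr(x, y)
        assert res.coefficient == pytest.approx(b1s2[j2], abs=1e-3)

    def test_age_coefficient_worked_example(self):
        """A slope of -0.12 per year is an 11.3% drop in odds per year."""
        assert odds_change_percent(-0.12) == pytest.approx(11.3, abs=0.05)
        assert round(odds_change_percent(-0.12), 1) == 11.3

    def test_uninformative_feature_gives_null_slope(self, rng):
        x = np.tile(rng.normal(size=50), 2)
        y = np.repeat([0, 1], 50)
        res = univariate_lr(x, y)
        assert abs(res.coefficient) < 1e-6
        assert res.p_value > 0.99

    def test_complete_separation_flagged_not_divergent(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = np.concatenate([np.zeros(10, int), np.ones(10, int)])
        with pytest.warns(UserWarning, match="separation"):
            res = univariate_lr(x, y)
        assert res.separable

    def test_ci_contains_coefficient(self, rng):
        x = rng.normal(size=200)
        y = (rng.uniform(size=200) < 1 / (1 + np.exp(-x))).astype(int)
        res = univariate_lr(x, y)
        assert res.ci_low <= res.coefficient <= res.ci_high
        assert 0 < res.p_value <= 1


class TestZScore:
    def test_sample_sd_convention_closed_form(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out = zscore(df)
        np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])  # sd(ddof=1) = 1

    def test_population_sd_convention_closed_form(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out = zscore(df, ddof=0)
        np.testing.assert_allclose(out["a"], [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_idempotent_and_moments(self, rng):
        df = pd.DataFrame({"a": rng.normal(3, 7, 500)})
        once = zscore(df)
        assert once["a"].mean() == pytest.approx(0.0, abs=1e-10)
        assert once["a"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(zscore(once)["a"], once["a"], atol=1e-10)

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = zscore(df)
        assert "b" not in out.columns


class TestAUC:
    def test_matches_pair_counting_oracle_on_random_instances(self, rng):
        """AUC equals the normalized Mann-Whitney count on 100 instances."""
        from sklearn.metrics import roc_auc_score

        for _ in range(100):
            y = rng.integers(0, 2, 20)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            pred = rng.choice(np.linspace(0, 1, 7), size=20)  # ties likely
            pos, neg = pred[y == 1], pred[y == 0]
            oracle = (
                (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
            ) / (len(pos) * len(neg))
            ours = auc_mann_whitney(y, pred)
            assert ours == pytest.approx(oracle, abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(y, pred), abs=1e-12)

    def test_perfect_ranking_gives_unit_auc(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        assert auc_mann_whitney(y, np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])) == 1.0

    def test_delong_auc_equals_mann_whitney(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        pred = rng.normal(size=40)
        auc, _ = delong_variance(y, pred)
        assert auc == pytest.approx(auc_mann_whitney(y, pred), abs=1e-12)


class TestDeLong:
    def test_identical_predictions_give_p_one(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        pred = rng.normal(size=30)
        with pytest.warns(UserWarning, match="degenerate"):
            cmp = delong_test(pred, pred, y)
        assert cmp.delta == 0.0 and cmp.p_value == 1.0

    def test_antisymmetric_in_model_order(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        a, b = rng.normal(size=60), rng.normal(size=60)
        ab, ba = delong_test(a, b, y), delong_test(b, a, y)
        assert ab.z == pytest.approx(-ba.z, abs=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)

    def test_variance_close_to_subject_bootstrap(self, rng):
        y = rng.integers(0, 2, 200)
        pred = rng.normal(size=200) + 0.8 * y
        _, var = delong_variance(y, pred)
        boots = []
        for _ in range(600):
            idx = rng.integers(0, 200, 200)
            if len(np.unique(y[idx])) < 2:
                continue
            boots.append(auc_mann_whitney(y[idx], pred[idx]))
        assert np.sqrt(var) == pytest.approx(np.std(boots), rel=0.15)

    def test_ci_sanity_and_clipping(self, rng):
        y = np.repeat([0, 1], 25)
        pred = np.concatenate([rng.normal(0, 1, 25), rng.normal(3, 1, 25)])
        auc, lo, hi = auc_delong_ci(y, pred)
        assert 0 <= lo <= auc <= hi <= 1


class TestVIF:
    def test_orthogonal_features_all_unity(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame(
            {
                "a": np.cos(2 * np.pi * t / n),
                "b": np.sin(2 * np.pi * t / n),
                "c": np.cos(4 * np.pi * t / n),
            }
        )
        vifs = vif_values(X)
        np.testing.assert_allclose(vifs, 1.0, atol=1e-9)
        assert vif_filter(X) == ["a", "b", "c"]

    def test_exact_duplicate_dropped_deterministically(self, rng):
        x = rng.normal(size=100)
        X = pd.DataFrame({"x1": x, "x2": x, "y_noise": rng.normal(size=100)})
        kept = vif_filter(X)
        assert kept == ["x2", "y_noise"]  # lexicographically first of the tie dropped

    def test_matches_correlation_inverse_oracle(self, rng):
        """VIFs equal the diagonal of the inverse correlation matrix."""
        rho = 0.6
        cov = np.full((3, 3), rho) + (1 - rho) * np.eye(3)
        X = rng.multivariate_normal(np.zeros(3), cov, size=4000)
        frame = pd.DataFrame(X, columns=["a", "b", "c"])
        corr = np.corrcoef(X, rowvar=False)
        oracle = np.diag(np.linalg.inv(corr))
        np.testing.assert_allclose(vif_values(frame).to_numpy(), oracle, atol=1e-6)
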