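"""MLPE mixed model: likelihood, fitting, selection rules and tables."""

import itertools
from types import SimpleNamespace

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from lgflow import (
    MLPERegressor,
    between_variable_selection,
    fit_mlpe,
    model_table,
    significance_over_distance,
    within_variable_selection,
)
from lgflow.matrices import PairwiseMatrix
from lgflow.mlpe import MLPEError


def all_pairs(k):
    return np.array(list(itertools.combinations(range(k), 2)))


def simulate(k, beta0, beta1, sigma_u, sigma_e, rng, x=None):
    pairs = all_pairs(k)
    n = len(pairs)
    if x is None:
        x = rng.standard_normal(n)
    u = rng.normal(0, sigma_u, k)
    y = (
        beta0
        + beta1 * x
        + u[pairs[:, 0]]
        + u[pairs[:, 1]]
        + rng.normal(0, sigma_e, n)
    )
    return x, y, pairs


def matrix_from_condensed(k, vals, statistic):
    return PairwiseMatrix.from_condensed(
        [f"g{i}" for i in range(k)], vals, statistic
    )


class TestMLPERegressor:
    def test_zero_group_variance_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        x, y, pairs = simulate(15, 0.1, 0.5, sigma_u=0.0, sigma_e=0.05, rng=rng)
        m = MLPERegressor(standardize=False).fit(x, y, pairs=pairs)
        ols = np.polyfit(x, y, 1)[0]
        assert m.coef_[0] == pytest.approx(ols, abs=1e-6)
        assert m.sigma_u2_ <= 1e-6

    def test_loglik_matches_dense_mvn_oracle(self):
        rng = np.random.default_rng(1)
        k = 8
        x, y, pairs = simulate(k, 0.2, 0.4, sigma_u=0.1, sigma_e=0.05, rng=rng)
        m = MLPERegressor(standardize=False).fit(x, y, pairs=pairs)
        n = len(y)
        Z = np.zeros((n, k))
        for row, (a, b) in enumerate(pairs):
            Z[row, a] = Z[row, b] = 1.0
        cov = m.sigma_u2_ * Z @ Z.T + m.sigma2_ * np.eye(n)
        mean = m.intercept_ + m.coef_[0] * x
        oracle = multivariate_normal(mean, cov).logpdf(y)
        assert m.loglik_ == pytest.approx(oracle, abs=1e-6)

    def test_aic_formula_wiring(self):
        rng = np.random.default_rng(2)
        x, y, pairs = simulate(10, 0.0, 0.3, 0.05, 0.05, rng)
        m = MLPERegressor().fit(x, y, pairs=pairs)
        assert m.n_params_ == 4  # intercept + slope + two variances
        assert m.aic_ == pytest.approx(-2 * m.loglik_ + 2 * m.n_params_)
        assert m.aicc_ == pytest.approx(
            m.aic_
            + 2 * m.n_params_ * (m.n_params_ + 1) / (m.n_pairs_ - m.n_params_ - 1)
        )
        assert m.aicc_ > m.aic_

    def test_parameter_recovery_quick(self):
        rng = np.random.default_rng(3)
        hits = 0
        reps = 20
        for _ in range(reps):
            x, y, pairs = simulate(40, 0.1, 0.5, 0.02, 0.02, rng)
            m = MLPERegressor().fit(x, y, pairs=pairs)
            slope = m.coef_[0] / np.std(x)  # back to raw scale
            if abs(slope - 0.5) < 0.1:
                hits += 1
        assert hits >= int(0.9 * reps)

    def test_variance_components_nonnegative(self):
        rng = np.random.default_rng(4)
        x, y, pairs = simulate(12, 0.0, 0.0, 0.1, 0.01, rng)
        m = MLPERegressor().fit(x, y, pairs=pairs)
        assert m.sigma_u2_ >= 0 and m.sigma2_ > 0

    def test_reml_loglik_differs_from_ml(self):
        rng = np.random.default_rng(5)
        x, y, pairs = simulate(10, 0.0, 0.3, 0.1, 0.05, rng)
        ml = MLPERegressor(method="ML").fit(x, y, pairs=pairs)
        reml = MLPERegressor(method="REML").fit(x, y, pairs=pairs)
        assert ml.loglik_ != pytest.approx(reml.loglik_, abs=1e-3)

    def test_predict_uses_fixed_effects_only(self):
        rng = np.random.default_rng(6)
        x, y, pairs = simulate(10, 1.0, 2.0, 0.0, 1e-8, rng)
        m = MLPERegressor(standardize=False).fit(x, y, pairs=pairs)
        np.testing.assert_allclose(
            m.predict(x), m.intercept_ + m.coef_[0] * x, atol=1e-12
        )

    def test_too_few_groups_rejected(self):
        with pytest.raises(MLPEError, match="three"):
            MLPERegressor().fit(
                np.array([1.0]), np.array([1.0]), pairs=np.array([[0, 1]])
            )

    def test_sklearn_params_roundtrip(self):
        m = MLPERegressor(method="REML", standardize=False)
        assert MLPERegressor(**m.get_params()).method == "REML"


class TestModelTable:
    def fake(self, aicc, loglik=0.0):
        return SimpleNamespace(aicc=aicc, loglik=loglik)

    def test_equal_models_split_weight(self):
        t = model_table({"a": self.fake(10.0), "b": self.fake(10.0)})
        np.testing.assert_allclose(t["weight"], [0.5, 0.5])

    def test_delta_two_weights(self):
        t = model_table({"a": self.fake(10.0), "b": self.fake(12.0)})
        assert t["weight"].iloc[0] == pytest.approx(0.7311, abs=1e-3)
        assert t["weight"].iloc[1] == pytest.approx(0.2689, abs=1e-3)

    def test_single_model_weight_one(self):
        t = model_table({"a": self.fake(3.0)})
        assert t["weight"].iloc[0] == pytest.approx(1.0)

    def test_sorted_and_normalized(self):
        t = model_table(
            {"a": self.fake(5.0), "b": self.fake(1.0), "c": self.fake(9.0)}
        )
        assert list(t["surface"]) == ["b", "a", "c"]
        assert t["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (t["cum_weight"].diff().dropna() >= -1e-12).all()


class TestSignificanceRule:
    def build_matrices(self, k, rng, effect, collinear=False):
        pairs = all_pairs(k)
        n = len(pairs)
        dist = rng.uniform(1, 5, n)
        rd = dist.copy() if collinear else rng.uniform(1, 5, n)
        u = rng.normal(0, 0.01, k)
        y = (
            0.1
            + effect * (rd - rd.mean()) / rd.std()
            + u[pairs[:, 0]]
            + u[pairs[:, 1]]
            + rng.normal(0, 0.01, n)
        )
        return (
            matrix_from_condensed(k, np.clip(y, 0, 1), "gst_prime"),
            matrix_from_condensed(k, rd, "resistance"),
            matrix_from_condensed(k, dist, "geo_null"),
        )

    def test_strong_decorrelated_effect_is_significant(self):
        rng = np.random.default_rng(7)
        y, rd, dist = self.build_matrices(15, rng, effect=0.1)
        dec = significance_over_distance(y, rd, dist)
        assert dec.significant and not dec.collinear

    def test_pure_distance_signal_not_significant(self):
        rng = np.random.default_rng(8)
        pairs = all_pairs(15)
        n = len(pairs)
        dist = rng.uniform(1, 5, n)
        rd = rng.uniform(1, 5, n)  # unrelated to y
        y = 0.1 + 0.05 * (dist - dist.mean()) / dist.std() + rng.normal(0, 0.01, n)
        dec = significance_over_distance(
            matrix_from_condensed(15, np.clip(y, 0, 1), "gst_prime"),
            matrix_from_condensed(15, rd, "resistance"),
            matrix_from_condensed(15, dist, "geo_null"),
        )
        assert not dec.significant

    def test_collinear_predictor_flagged(self):
        rng = np.random.default_rng(9)
        y, rd, dist = self.build_matrices(10, rng, effect=0.1, collinear=True)
        dec = significance_over_distance(y, rd, dist)
        assert dec.collinear and not dec.significant

    def test_decision_invariant_to_predictor_rescaling(self):
        rng = np.random.default_rng(10)
        y, rd, dist = self.build_matrices(15, rng, effect=0.1)
        dec1 = significance_over_distance(y, rd, dist)
        rd_scaled = PairwiseMatrix(
            rd.labels, rd.values * 1000.0, "resistance"
        )
        dec2 = significance_over_distance(y, rd_scaled, dist)
        assert dec1.significant == dec2.significant
        assert dec1.fit_single.slopes[0] == pytest.approx(
            dec2.fit_single.slopes[0], abs=1e-8
        )


class TestSelectionProcedures:
    def test_within_variable_recovers_true_candidate(self):
        rng = np.random.default_rng(11)
        k = 15
        pairs = all_pairs(k)
        n = len(pairs)
        truth = rng.uniform(1, 5, n)
        decoys = {f"v_{t}_5": rng.uniform(1, 5, n) for t in (1, 3)}
        dist = rng.uniform(1, 5, n)
        y = 0.1 + 0.08 * (truth - truth.mean()) / truth.std() + rng.normal(0, 0.01, n)
        candidates = {
            "v_2_5": matrix_from_condensed(k, truth, "resistance"),
            **{
                lab: matrix_from_condensed(k, v, "resistance")
                for lab, v in decoys.items()
            },
        }
        res = within_variable_selection(
            matrix_from_condensed(k, np.clip(y, 0, 1), "gst_prime"),
            candidates,
            matrix_from_condensed(k, dist, "geo_null"),
        )
        assert res.best_label == "v_2_5"
        assert res.delta_aic_vs_distance > 0
        assert res.decision.significant
        assert set(res.null_correlations) == set(candidates)

    def test_tie_break_by_label_order(self):
        rng = np.random.default_rng(12)
        k = 10
        n = len(all_pairs(k))
        vals = rng.uniform(1, 5, n)
        y = np.clip(0.1 + 0.02 * vals + rng.normal(0, 0.01, n), 0, 1)
        same = {lab: matrix_from_condensed(k, vals, "resistance")
                for lab in ("b_cand", "a_cand")}
        res = within_variable_selection(
            matrix_from_condensed(k, y, "gst_prime"),
            same,
            matrix_from_condensed(k, rng.uniform(1, 5, n), "geo_null"),
        )
        assert res.best_label == "a_cand"

    def test_between_variable_table_includes_distance_row(self):
        rng = np.random.default_rng(13)
        k = 12
        n = len(all_pairs(k))
        truth = rng.uniform(1, 5, n)
        y = np.clip(0.1 + 0.1 * (truth - truth.mean()) / truth.std()
                    + rng.normal(0, 0.01, n), 0, 1)
        table = between_variable_selection(
            matrix_from_condensed(k, y, "gst_prime"),
            {
                "habitat": matrix_from_condensed(k, truth, "resistance"),
                "noise": matrix_from_condensed(
                    k, rng.uniform(1, 5, n), "resistance"
                ),
            },
            matrix_from_condensed(k, rng.uniform(1, 5, n), "geo_null"),
        )
        assert "distance" in set(table["surface"])
        assert table["surface"].iloc[0] == "habitat"
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-9)


class TestFitMLPEWrapper:
    def test_nonfinite_pairs_excluded(self):
        rng = np.random.default_rng(14)
        k = 8
        n = len(all_pairs(k))
        rd = rng.uniform(1, 5, n)
        rd[0] = np.inf  # a disconnected pair
        y = np.clip(rng.uniform(0, 0.3, n), 0, 1)
        fit = fit_mlpe(
            matrix_from_condensed(k, y, "gst_prime"),
            [matrix_from_condensed(k, rd, "resistance")],
        )
        assert fit.model.n_pairs_ == n - 1

    def test_serialization_roundtrip(self):
        rng = np.random.default_rng(15)
        x, y, pairs = simulate(8, 0.1, 0.3, 0.02, 0.02, rng)
        k = 8
        fit = fit_mlpe(
            matrix_from_condensed(k, np.clip(y, 0, 1), "gst_prime"),
            [matrix_from_condensed(k, x - x.min() + 1, "resistance")],
            names=["rd"],
        )
        d = fit.to_dict()
        assert d["predictors"] == ["rd"]
        assert d["n_pairs"] == len(y)
        assert np.isfinite(d["aicc"])
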