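import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutualnet.traitmodels import fit_all_subsets, fit_trait_models, transform_and_check


class TestTransform:
    def test_log10_applied(self):
        frame = pd.DataFrame({"strength": [10.0, 100.0]})
        out, _ = transform_and_check(frame)
        assert out["strength"].tolist() == [1.0, 2.0]

    def test_explicit_offset(self):
        frame = pd.DataFrame({"dprime": [0.0, 0.1]})
        out, _ = transform_and_check(frame, offset=1e-3)
        assert out.loc[0, "dprime"] == pytest.approx(np.log10(1e-3))

    def test_auto_offset_is_half_smallest_positive(self):
        frame = pd.DataFrame({"dprime": [0.0, 0.2, 0.4]})
        out, _ = transform_and_check(frame)
        assert out.loc[0, "dprime"] == pytest.approx(np.log10(0.1))

    def test_zero_without_offset_names_the_variable(self):
        frame = pd.DataFrame({"dprime": [0.0, 0.2]}, index=["B1", "B2"])
        with pytest.raises(ValueError, match="dprime.*B1"):
            transform_and_check(frame, offset=None)

    def test_categorical_columns_pass_through(self):
        frame = pd.DataFrame({"fruit_color": [1, 2], "sugar": [10.0, 100.0]})
        out, diags = transform_and_check(frame)
        assert out["fruit_color"].tolist() == [1, 2]
        assert "fruit_color" not in diags.index
        assert "sugar" in diags.index

    def test_diagnostics_report_ks(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"x": np.exp(rng.normal(size=60))})
        _, diags = transform_and_check(frame)
        assert 0.0 <= diags.loc["x", "ks_p"] <= 1.0


class TestFitAllSubsets:
    def test_noiseless_line_recovered_exactly(self):
        x = np.arange(1.0, 7.0)
        frame = pd.DataFrame({"y": 2.0 * x, "x": x})
        res = fit_all_subsets(frame, "y", ["x"])
        assert res.coefficients.loc["x", "estimate"] == pytest.approx(2.0, abs=1e-6)
        best = res.models.iloc[0]
        assert best["predictors"] == "x"
        assert best["weight"] == pytest.approx(1.0, abs=1e-6)

    def test_aic_weights_match_hand_computation(self):
        # 5-point toy set, two candidate models: intercept-only and slope
        frame = pd.DataFrame({"y": [1.1, 1.9, 3.2, 3.9, 5.1], "x": [1, 2, 3, 4, 5]})
        res = fit_all_subsets(frame, "y", ["x"])
        n = 5

        def hand_aic(y, X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = ((y - X @ beta) ** 2).sum()
            k = X.shape[1] + 1  # + residual variance
            return n * np.log(rss / n) + 2 * k + n * np.log(2 * np.pi) + n

        y = frame["y"].to_numpy()
        aic0 = hand_aic(y, np.ones((n, 1)))
        aic1 = hand_aic(y, np.column_stack([np.ones(n), frame["x"]]))
        table = res.models.set_index("predictors")
        assert table.loc["(intercept)", "aic"] == pytest.approx(aic0)
        assert table.loc["x", "aic"] == pytest.approx(aic1)
        delta = aic0 - aic1
        w1 = 1.0 / (1.0 + np.exp(-0.5 * delta))
        assert table.loc["x", "weight"] == pytest.approx(w1)
        assert res.models["weight"].sum() == pytest.approx(1.0)
        assert res.models.iloc[0]["delta_aic"] == 0.0

    def test_single_candidate_reduces_to_ols(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        frame = pd.DataFrame({"y": 1.5 * x + rng.normal(0, 0.3, 12), "x": x})
        res = fit_all_subsets(frame, "y", [])
        # only the intercept-only model exists
        assert len(res.models) == 1
        assert res.coefficients.loc["Intercept", "estimate"] == pytest.approx(
            frame["y"].mean()
        )

    def test_null_predictors_rarely_significant(self):
        """Type-I behavior: pure-noise predictors exceed p=0.05 almost always."""
        rng = np.random.default_rng(42)
        n, reps = 50, 100
        false_hits = 0
        total = 0
        for _ in range(reps):
            frame = pd.DataFrame(
                {
                    "y": rng.normal(size=n),
                    "a": rng.normal(size=n),
                    "b": rng.normal(size=n),
                }
            )
            res = fit_all_subsets(frame, "y", ["a", "b"])
            for term in ("a", "b"):
                total += 1
                if res.coefficients.loc[term, "p"] <= 0.05:
                    false_hits += 1
        assert false_hits / total <= 0.10

    def test_conditional_averaging_differs_and_is_larger(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        frame = pd.DataFrame({"y": 0.5 * x + rng.normal(0, 1.0, 15), "x": x})
        full = fit_all_subsets(frame, "y", ["x"], average="full")
        cond = fit_all_subsets(frame, "y", ["x"], average="conditional")
        b_full = full.coefficients.loc["x", "estimate"]
        b_cond = cond.coefficients.loc["x", "estimate"]
        assert abs(b_cond) > abs(b_full)  # shrinkage toward 0 only in full mode

    def test_too_many_predictors_rejected(self):
        frame = pd.DataFrame(np.random.default_rng(0).normal(size=(12, 10)))
        frame.columns = [f"x{i}" for i in range(9)] + ["y"]
        with pytest.raises(ValueError, match="8 predictors"):
            fit_all_subsets(frame, "y", [f"x{i}" for i in range(9)])


class TestFitTraitModels:
    def test_joins_and_fits_per_response(self):
        rng = np.random.default_rng(5)
        idx = [f"B{i}" for i in range(12)]
        metrics = pd.DataFrame(
            {
                "degree": rng.integers(1, 10, 12),
                "strength": rng.uniform(0.1, 3.0, 12),
                "dprime": rng.uniform(0.01, 0.9, 12),
            },
            index=idx,
        )
        traits = pd.DataFrame({"body_mass": rng.uniform(10, 80, 12)}, index=idx)
        out = fit_trait_models(metrics, traits)
        assert set(out) == {"degree", "strength", "dprime"}
        for res in out.values():
            assert "body_mass" in res.coefficients.index

    def test_disjoint_tables_error(self):
        metrics = pd.DataFrame({"degree": [1]}, index=["B1"])
        traits = pd.DataFrame({"body_mass": [10.0]}, index=["X9"])
        with pytest.raises(ValueError, match="no species shared"):
            fit_trait_models(metrics, traits)
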