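"""Tests for the 2D-QSAR OLS fit and the R² improvement metric."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from troqsar import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidInputError,
    MOAClass,
    NotFittedError,
    QSARModel,
    evaluate_record,
    fit_linear_qsar,
    improvement_percent,
    predict,
)

from conftest import normal_equations

# Normal-equations oracle values for the 10 unique fixture records whose
# *printed* class is narcosis (tripropyl phosphate excluded, the repeated
# diethyl phthalate row deduplicated), frozen from the closed-form solve.
PRINTED_NARCOSIS_ORACLE = {
    "slope": -0.57149914512769,
    "intercept": 2.6080104129557875,
    "r_squared": 0.879556684415486,
}


def printed_narcosis_xy(table2):
    seen = set()
    xs, ys = [], []
    for rec in table2:
        if rec.cas in seen or rec.extra["printed_moa"] is not MOAClass.NARCOSIS:
            continue
        seen.add(rec.cas)
        xs.append(rec.log_kow)
        ys.append(rec.endpoints.resolved_log_lc50())
    return xs, ys


class TestFitLinearQsar:
    def test_collinear_points_exact(self):
        model = fit_linear_qsar([0, 1, 2], [1, 2, 3])
        assert model.slope == pytest.approx(1.0, abs=1e-12)
        assert model.intercept == pytest.approx(1.0, abs=1e-12)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert model.sdep == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_response_defines_r2_zero(self):
        with pytest.warns(UserWarning, match="zero variance"):
            model = fit_linear_qsar([0, 1], [5, 5])
        assert model.slope == pytest.approx(0.0, abs=1e-12)
        assert model.r_squared == 0.0
        assert "ZERO_VARIANCE_RESPONSE" in model.warnings

    def test_small_sample_warning_flag(self):
        model = fit_linear_qsar([0, 1, 2], [1.0, 1.9, 3.2])
        assert "SMALL_SAMPLE" in model.warnings
        big = fit_linear_qsar(range(6), [0, 1, 2, 3, 4, 5.5])
        assert "SMALL_SAMPLE" not in big.warnings

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            fit_linear_qsar([1.0], [2.0])
        with pytest.raises(DegenerateDesignError):
            fit_linear_qsar([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(InvalidInputError):
            fit_linear_qsar([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(InvalidInputError):
            fit_linear_qsar([1.0, float("nan")], [1.0, 2.0])

    def test_residuals_sum_to_zero_and_r2_equals_squared_correlation(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(-5, 5, 20)
        y = 1.5 - 0.7 * x + rng.normal(0, 0.5, 20)
        model = fit_linear_qsar(x, y)
        assert sum(model.residuals) == pytest.approx(0.0, abs=1e-9)
        fitted = model.intercept + model.slope * x
        corr = np.corrcoef(y, fitted)[0, 1]
        assert model.r_squared == pytest.approx(corr**2, abs=1e-10)

    def test_fixture_printed_narcosis_fit_matches_oracle(self, table2):
        xs, ys = printed_narcosis_xy(table2)
        assert len(xs) == 10
        model = fit_linear_qsar(xs, ys)
        slope, intercept, r2, sdep = normal_equations(xs, ys)
        assert model.slope == pytest.approx(slope, abs=1e-10)
        assert model.intercept == pytest.approx(intercept, abs=1e-10)
        assert model.r_squared == pytest.approx(r2, abs=1e-10)
        assert model.sdep == pytest.approx(sdep, abs=1e-10)
        # frozen regression values
        assert model.slope == pytest.approx(PRINTED_NARCOSIS_ORACLE["slope"], abs=1e-9)
        assert model.intercept == pytest.approx(
            PRINTED_NARCOSIS_ORACLE["intercept"], abs=1e-9
        )
        assert model.r_squared == pytest.approx(
            PRINTED_NARCOSIS_ORACLE["r_squared"], abs=1e-9
        )

    def test_random_fits_match_normal_equations(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 51))
            x = rng.uniform(-10, 10, n)
            y = rng.uniform(-10, 10, n)
            if np.ptp(x) == 0:
                continue
            model = fit_linear_qsar(x, y)
            slope, intercept, r2, sdep = normal_equations(x, y)
            assert np.isclose(model.slope, slope, rtol=1e-10, atol=1e-10)
            assert np.isclose(model.intercept, intercept, rtol=1e-10, atol=1e-10)
            assert np.isclose(model.r_squared, r2, rtol=1e-10, atol=1e-10)
            assert np.isclose(model.sdep, sdep, rtol=1e-10, atol=1e-10)

    @given(shift=st.floats(min_value=-100, max_value=100, allow_nan=False))
    @settings(max_examples=50, derandomize=True)
    def test_shift_equivariance(self, shift):
        x = np.arange(8.0)
        y = np.array([0.3, 1.2, 1.8, 3.1, 3.9, 5.2, 5.8, 7.1])
        base = fit_linear_qsar(x, y)
        shifted = fit_linear_qsar(x, y + shift)
        assert shifted.slope == pytest.approx(base.slope, abs=1e-10)
        assert shifted.intercept == pytest.approx(base.intercept + shift, abs=1e-8)
        assert shifted.r_squared == pytest.approx(base.r_squared, abs=1e-10)
        assert shifted.sdep == pytest.approx(base.sdep, abs=1e-10)


class TestPredict:
    def test_line_evaluation(self):
        model = fit_linear_qsar([0, 1, 2], [0, 1, 2])
        assert predict(model, 2.5) == pytest.approx(2.5, abs=1e-12)
        assert model.predict(2.5) == pytest.approx(2.5, abs=1e-12)

    def test_passes_through_centroid(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 9, 15)
        y = 2.0 - 0.5 * x + rng.normal(0, 0.3, 15)
        model = fit_linear_qsar(x, y)
        assert predict(model, float(x.mean())) == pytest.approx(
            float(y.mean()), abs=1e-9
        )

    def test_fixture_line_at_log_kow_4_70(self, table2):
        xs, ys = printed_narcosis_xy(table2)
        model = fit_linear_qsar(xs, ys)
        slope, intercept, _, _ = normal_equations(xs, ys)
        assert predict(model, 4.70) == pytest.approx(intercept + slope * 4.70, abs=1e-10)

    def test_errors(self):
        model = fit_linear_qsar([0, 1], [0, 1])
        with pytest.raises(NotFittedError):
            predict("not a model", 1.0)
        with pytest.raises(InvalidInputError):
            predict(model, float("inf"))


class TestImprovementPercent:
    def test_worked_pair_both_conventions(self):
        result = improvement_percent(0.74, 0.81)
        assert round(result.pct_improved_denominator, 2) == 8.64
        assert round(result.pct_initial_denominator, 2) == 9.46

    def test_invariant_definitions(self):
        result = improvement_percent(0.5, 0.8)
        assert result.pct_initial_denominator == pytest.approx(
            (0.8 - 0.5) / 0.5 * 100, abs=1e-9
        )
        assert result.pct_improved_denominator == pytest.approx(
            (0.8 - 0.5) / 0.8 * 100, abs=1e-9
        )

    @pytest.mark.parametrize("r", [0.1, 0.5, 1.0])
    def test_equal_inputs_give_zero(self, r):
        result = improvement_percent(r, r)
        assert result.pct_initial_denominator == 0.0
        assert result.pct_improved_denominator == 0.0

    def test_domain_errors(self):
        with pytest.raises(InvalidInputError):
            improvement_percent(0.0, 0.5)
        with pytest.raises(InvalidInputError):
            improvement_percent(-0.1, 0.5)
        with pytest.raises(InvalidInputError):
            improvement_percent(0.5, 1.5)

    @given(
        a=st.floats(min_value=0.01, max_value=1.0, allow_nan=False),
        b=st.floats(min_value=0.01, max_value=1.0, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_positive_iff_improved(self, a, b):
        result = improvement_percent(a, b)
        assert (result.pct_initial_denominator > 0) == (b > a)
        assert (result.pct_improved_denominator > 0) == (b > a)


class TestModelSerialization:
    def test_json_roundtrip(self):
        model = fit_linear_qsar([0, 1, 2, 3, 4], [2.0, 1.4, 1.1, 0.4, 0.1])
        restored = QSARModel.from_json(model.to_json())
        assert restored.slope == model.slope
        assert restored.intercept == model.intercept
        assert restored.r_squared == model.r_squared
        assert restored.sdep == model.sdep
        assert restored.n == model.n
        payload = json.loads(model.to_json())
        assert set(payload) == {"slope", "intercept", "r_squared", "sdep", "n", "warnings"}
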