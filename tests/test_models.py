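"""TCP model behaviour: midpoints, monotonicity, saturation, routing.

Frozen expected values were computed independently with arbitrary-precision
arithmetic (sympy) from the closed forms, not with the package.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sbrtlc.lq import FractionScheme, P110, P120, RadiobiologyParams, bed, eqd2, isocenter_scheme
from sbrtlc.models import (
    GUCKEN_PARAMS,
    SANTIAGO_PARAMS,
    LogisticTcpParams,
    MartelParams,
    ModelContractError,
    ModelLibrary,
    OhriParams,
    PlanContext,
    TaiParams,
    gucken_tcp,
    logistic_tcp,
    martel_tcp,
    ohri_tcp,
    predict,
    santiago_tcp,
    tai_lc,
)

bed_grid = st.floats(min_value=-200.0, max_value=500.0, allow_nan=False)


class TestLogistic:
    @pytest.mark.parametrize(
        "params",
        [LogisticTcpParams(0.0, 31.0), GUCKEN_PARAMS, SANTIAGO_PARAMS],
        ids=["ohri", "gucken", "santiago"],
    )
    def test_midpoint_is_half(self, params):
        assert logistic_tcp(params.tcd50, params) == 0.5

    def test_frozen_value_against_precision_oracle(self):
        # sympy: exp(116.5/80)/(1+exp(116.5/80))
        assert logistic_tcp(115.5, GUCKEN_PARAMS) == pytest.approx(
            0.81095845190260504417, abs=1e-14
        )

    def test_saturation_without_overflow(self):
        assert logistic_tcp(1e4, GUCKEN_PARAMS) == 1.0
        assert logistic_tcp(-1e4, GUCKEN_PARAMS) == pytest.approx(0.0, abs=1e-50)
        assert logistic_tcp(1e9, LogisticTcpParams(0.0, 1e-3)) == 1.0

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            LogisticTcpParams(0.0, 0.0)
        with pytest.raises(ValueError):
            LogisticTcpParams(0.0, -31.0)

    @given(x=bed_grid)
    @settings(max_examples=200, derandomize=True)
    def test_point_symmetry_about_midpoint(self, x):
        for params in (GUCKEN_PARAMS, SANTIAGO_PARAMS, LogisticTcpParams(0.0, 31.0)):
            left = logistic_tcp(x, params)
            right = logistic_tcp(2 * params.tcd50 - x, params)
            assert left + right == pytest.approx(1.0, abs=1e-12)


class TestMartel:
    def test_midpoint_and_zero_dose(self):
        assert martel_tcp(72.0) == pytest.approx(0.5, abs=1e-15)
        assert martel_tcp(0.0) == 0.0

    def test_frozen_value_against_precision_oracle(self):
        # sympy: 1/(1 + (72/96.25)**8)
        assert martel_tcp(96.25) == pytest.approx(0.91070413015376782100, abs=1e-13)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            martel_tcp(-1.0)

    @given(d=st.floats(min_value=1.0, max_value=300.0), eps=st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=100, derandomize=True)
    def test_strictly_increasing(self, d, eps):
        assert martel_tcp(d + eps) > martel_tcp(d)

    def test_both_forms_cross_half_at_d50(self):
        exp_form = MartelParams(form="exponential-logistic")
        assert martel_tcp(72.0, exp_form) == pytest.approx(0.5, abs=1e-15)
        # the two parametrizations agree at the midpoint, not globally
        assert martel_tcp(100.0, exp_form) != martel_tcp(100.0)


class TestOhri:
    def test_midpoint_when_size_penalty_cancels(self):
        assert ohri_tcp(0.0, 0.0) == 0.5
        for diameter in (0.5, 2.5, 4.0):
            assert ohri_tcp(10.0 * diameter, diameter) == pytest.approx(0.5, abs=1e-15)

    def test_frozen_value_cohort_mean_diameter(self):
        # BED 100 Gy, diameter 2.5 cm -> logistic(75; 0, 31); sympy oracle
        assert ohri_tcp(100.0, 2.5) == pytest.approx(0.91829134963450250991, abs=1e-14)

    def test_decreasing_in_diameter(self):
        doses = np.linspace(60, 150, 10)
        for dose in doses:
            assert ohri_tcp(dose, 3.5) < ohri_tcp(dose, 1.5)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            ohri_tcp(100.0, -0.1)


class TestGuckenSantiago:
    def test_midpoints(self):
        assert gucken_tcp(-1.0) == 0.5
        assert santiago_tcp(-60.2) == 0.5

    def test_gucken_at_zero_bed(self):
        # sympy: expit(1/80)
        assert gucken_tcp(0.0) == pytest.approx(0.50312495931053160616, abs=1e-14)

    @given(lo=st.floats(min_value=0.0, max_value=400.0), delta=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_dose(self, lo, delta):
        assert gucken_tcp(lo + delta) > gucken_tcp(lo)
        assert santiago_tcp(lo + delta) > santiago_tcp(lo)

    def test_three_year_curves_nearly_coincide_in_clinical_range(self):
        """Dense scan: the two 3-year models differ by ≤ 3 percentage points
        for isocenter BED10 anywhere in 100–180 Gy."""
        grid = np.linspace(100.0, 180.0, 8001)
        diff = np.abs([gucken_tcp(x) - santiago_tcp(x) for x in grid])
        assert diff.max() <= 0.03


class TestTai:
    def test_midpoints_per_horizon(self):
        params = TaiParams()
        assert tai_lc(params.midpoint(2), 2, params) == 0.5
        assert tai_lc(params.midpoint(3), 3, params) == 0.5

    def test_later_horizon_never_predicts_more_control(self):
        params = TaiParams()
        for dose in np.linspace(0.0, 400.0, 401):
            assert tai_lc(dose, 3, params) <= tai_lc(dose, 2, params)

    @given(lo=st.floats(min_value=0.0, max_value=300.0), delta=st.floats(min_value=0.5, max_value=100.0))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_dose(self, lo, delta):
        for horizon in (2, 3):
            assert tai_lc(lo + delta, horizon) > tai_lc(lo, horizon)

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ModelContractError):
            tai_lc(100.0, 5)

    def test_missing_parameter_set_names_the_source_fit(self):
        params = TaiParams(k=45.0, tcd50_by_horizon={2: -15.0})
        with pytest.raises(ModelContractError, match="Model Fit II"):
            tai_lc(100.0, 3, params)

    def test_regressing_midpoint_rejected(self):
        with pytest.raises(ValueError):
            TaiParams(tcd50_by_horizon={2: 10.0, 3: -5.0})


class TestPredictRouting:
    @pytest.fixture
    def library(self):
        return ModelLibrary()

    @pytest.mark.parametrize("scheme", ["1x30", "3x15", "4x12", "3x18", "5x10"])
    def test_ohri_is_normalization_invariant(self, library, scheme):
        prescription = FractionScheme.from_string(scheme)
        low = predict("Ohri", PlanContext(prescription, 1.10, diameter=2.5), library)
        high = predict("Ohri", PlanContext(prescription, 1.20, diameter=2.5), library)
        assert low == high

    @pytest.mark.parametrize("model", ["Martel", "Gucken", "Santiago", "Tai2y", "Tai3y"])
    def test_isocenter_models_increase_with_normalization(self, library, model):
        prescription = FractionScheme(5, 10.0)
        low = predict(model, PlanContext(prescription, 1.10, diameter=2.5), library)
        high = predict(model, PlanContext(prescription, 1.20, diameter=2.5), library)
        assert high > low

    def test_predict_matches_hand_chained_calls(self, library):
        prescription = FractionScheme(5, 10.0)
        context = PlanContext(prescription, 1.10, diameter=2.5)
        iso = isocenter_scheme(prescription, 1.10)
        rb = RadiobiologyParams()
        assert predict("Martel", context, library) == martel_tcp(eqd2(iso, rb), library.martel)
        assert predict("Gucken", context, library) == gucken_tcp(bed(iso, rb))
        assert predict("Santiago", context, library) == santiago_tcp(bed(iso, rb))
        assert predict("Tai2y", context, library) == tai_lc(bed(iso, rb), 2, library.tai)
        assert predict("Ohri", context, library) == ohri_tcp(bed(prescription, rb), 2.5, library.ohri)

    def test_horizon_contract_enforced(self, library):
        context = PlanContext(FractionScheme(5, 10.0), 1.10, diameter=2.5)
        with pytest.raises(ModelContractError):
            predict("Martel", context, library, horizon=3)
        with pytest.raises(ModelContractError):
            predict("Gucken", context, library, horizon=2)

    def test_ohri_without_diameter_rejected(self, library):
        with pytest.raises(ValueError):
            predict("Ohri", PlanContext(FractionScheme(5, 10.0), 1.10), library)

    def test_outputs_are_probabilities_even_at_extreme_bed(self, library):
        context = PlanContext(FractionScheme(1, 300.0), 1.20, diameter=2.5)
        for model in ("Martel", "Ohri", "Gucken", "Santiago", "Tai2y", "Tai3y"):
            value = predict(model, context, library)
            assert 0.0 <= value <= 1.0 and math.isfinite(value)
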