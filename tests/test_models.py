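"""Closed-form pupil models and adaptation-field conversions."""

import math

import numpy as np
import pytest

from pupilbench.models import (
    REFERENCE_AGE_YEARS,
    FieldGeometry,
    InvalidGeometryError,
    MissingParameterError,
    ViewingConditions,
    field_to_deg2,
    predict_diameter,
    watson_yellott_dsdw,
)

WIDE_CIRCLE = FieldGeometry(
    "circular", (53.13,), "circle_area", allow_flat_large_field=True
)


def wy_conditions(luminance, age, eyes=2, field=WIDE_CIRCLE):
    return ViewingConditions(luminance, field=field, age_years=age, eyes=eyes)


class TestFieldConversion:
    def test_rectangular_product(self):
        f = FieldGeometry(
            "rectangular", (10.0, 20.0), "product", allow_flat_large_field=True
        )
        with pytest.warns(UserWarning):
            assert field_to_deg2(f) == pytest.approx(200.0)

    def test_circle_area(self):
        with pytest.warns(UserWarning):
            f = FieldGeometry(
                "circular", (53.13,), "circle_area", allow_flat_large_field=True
            )
            assert field_to_deg2(f) == pytest.approx(
                math.pi / 4.0 * 53.13**2, rel=1e-12
            )
        assert field_to_deg2(WIDE_CIRCLE) == pytest.approx(2217.0, abs=0.1)

    def test_spherical_cap(self):
        # direct high-precision evaluation of 6566π(1 − cos(Dπ/360))
        f = FieldGeometry("circular", (53.1,), "spherical_cap")
        expected = 6566.0 * math.pi * (1.0 - math.cos(53.1 * math.pi / 360.0))
        assert field_to_deg2(f) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2175.3, abs=0.5)

    @pytest.mark.parametrize("d_deg", [0.01, 0.1, 1.0, 5.0, 9.9])
    def test_cap_equals_flat_circle_in_small_angle_limit(self, d_deg):
        cap = field_to_deg2(FieldGeometry("circular", (d_deg,), "spherical_cap"))
        flat = field_to_deg2(FieldGeometry("circular", (d_deg,), "circle_area"))
        assert cap / flat == pytest.approx(1.0, rel=0.01)

    def test_legacy_toolbox_warns(self):
        f = FieldGeometry("circular", (10.0,), "legacy_toolbox")
        with pytest.warns(UserWarning, match="pitfall"):
            assert field_to_deg2(f) == pytest.approx(5.0 * math.pi)

    def test_large_field_requires_cap_or_override(self):
        f = FieldGeometry("circular", (30.0,), "circle_area")
        with pytest.raises(InvalidGeometryError, match="spherical-cap"):
            field_to_deg2(f)
        # the cap itself never complains
        field_to_deg2(FieldGeometry("circular", (30.0,), "spherical_cap"))

    @pytest.mark.parametrize("bad", [0.0, -1.0, 180.0, 200.0])
    def test_invalid_angles_rejected(self, bad):
        with pytest.raises(InvalidGeometryError):
            FieldGeometry("circular", (bad,), "circle_area")

    def test_rectangular_equivalent_diameter_conserves_area(self):
        f = FieldGeometry("rectangular", (3.0, 12.0), "circle_area")
        assert field_to_deg2(f) == pytest.approx(36.0, rel=1e-12)


class TestWorkedExamples:
    """The printed benchmark predictions (tolerance 0.002 mm covers the
    source's inconsistent presentation rounding)."""

    @pytest.mark.parametrize(
        "model, luminance, expected",
        [
            ("crawford", 100.0, 3.007),
            ("crawford", 99.8, 3.006),
            ("de_groot_gebhard", 100.0, 3.182),
            ("de_groot_gebhard", 99.8, 3.182),
        ],
    )
    def test_luminance_only_models(self, model, luminance, expected):
        pred = predict_diameter(model, ViewingConditions(luminance))
        assert pred.diameter_mm == pytest.approx(expected, abs=0.002)

    @pytest.mark.parametrize(
        "luminance, age, expected",
        [
            (100.0, 22.2, 3.019),
            (99.8, 21.95, 3.022),
            (100.0, 33.0, 2.942),
            (99.8, 33.0, 2.943),
        ],
    )
    def test_watson_yellott(self, luminance, age, expected):
        pred = predict_diameter("watson_yellott", wy_conditions(luminance, age))
        assert pred.diameter_mm == pytest.approx(expected, abs=0.002)
        assert pred.intermediate_dsdw_mm is not None

    def test_moon_spencer_unit_luminance(self):
        # tanh(0) = 0
        assert predict_diameter(
            "moon_spencer", ViewingConditions(1.0)
        ).diameter_mm == pytest.approx(4.9)

    def test_holladay_dark_limit(self):
        d = predict_diameter("holladay", ViewingConditions(1e-12)).diameter_mm
        assert d == pytest.approx(7.0, abs=1e-4)

    def test_blackie_howland_unit_luminance(self):
        assert predict_diameter(
            "blackie_howland", ViewingConditions(1.0)
        ).diameter_mm == pytest.approx(5.697)

    def test_blackie_howland_warns_outside_validity(self):
        with pytest.warns(UserWarning, match="10 cd"):
            predict_diameter("blackie_howland", ViewingConditions(100.0))

    def test_reference_age_recovers_dsdw(self):
        cond = wy_conditions(100.0, REFERENCE_AGE_YEARS)
        pred = predict_diameter("watson_yellott", cond)
        assert pred.diameter_mm == pytest.approx(pred.intermediate_dsdw_mm, rel=1e-14)


class TestParameterValidation:
    def test_field_required(self):
        for model in ("stanley_davies", "barten", "watson_yellott"):
            with pytest.raises(MissingParameterError):
                predict_diameter(model, ViewingConditions(100.0, age_years=30, eyes=2))

    def test_age_and_eyes_required_for_unified_model(self):
        with pytest.raises(MissingParameterError):
            predict_diameter(
                "watson_yellott", ViewingConditions(100.0, field=WIDE_CIRCLE, eyes=2)
            )
        with pytest.raises(MissingParameterError):
            predict_diameter(
                "watson_yellott",
                ViewingConditions(100.0, field=WIDE_CIRCLE, age_years=30),
            )

    def test_nonpositive_luminance_rejected(self):
        with pytest.raises(ValueError):
            ViewingConditions(0.0)

    def test_age_range(self):
        with pytest.raises(ValueError):
            ViewingConditions(100.0, age_years=12.0)
        with pytest.warns(UserWarning, match="17"):
            ViewingConditions(100.0, age_years=88.0)

    def test_unknown_model(self):
        with pytest.raises(KeyError):
            predict_diameter("bouma", ViewingConditions(100.0))


class TestInvariants:
    LUMINANCES = np.logspace(-2, 4, 200)

    @pytest.mark.parametrize(
        "model", ["holladay", "crawford", "moon_spencer", "de_groot_gebhard",
                  "stanley_davies", "barten", "blackie_howland"]
    )
    def test_strictly_decreasing_in_luminance(self, model):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = [
                predict_diameter(
                    model, ViewingConditions(L, field=WIDE_CIRCLE)
                ).diameter_mm
                for L in self.LUMINANCES
            ]
        assert np.all(np.diff(d) < 0)

    @pytest.mark.parametrize("age", [17.0, 40.0, 83.0])
    def test_watson_yellott_decreasing_for_all_ages(self, age):
        d = [
            predict_diameter(
                "watson_yellott", wy_conditions(L, age)
            ).diameter_mm
            for L in self.LUMINANCES
        ]
        assert np.all(np.diff(d) < 0)

    def test_output_bounds_over_wide_grid(self):
        fields = [
            FieldGeometry("circular", (d,), "spherical_cap") for d in (1.0, 10.0, 120.0)
        ]
        for L in np.logspace(-4, 6, 60):
            assert 2.8 < predict_diameter(
                "crawford", ViewingConditions(L)
            ).diameter_mm < 7.2
            assert 1.9 < predict_diameter(
                "moon_spencer", ViewingConditions(L)
            ).diameter_mm < 7.9
            for f in fields:
                cond = ViewingConditions(L, field=f, age_years=40, eyes=1)
                sd = predict_diameter("stanley_davies", cond).diameter_mm
                dsdw = watson_yellott_dsdw(cond)
                assert 2.0 < sd <= 7.75
                assert 2.0 < dsdw <= 7.75

    def test_stanley_davies_equals_dsdw_binocular(self):
        for L in (0.5, 10.0, 1000.0):
            cond = ViewingConditions(L, field=WIDE_CIRCLE, age_years=30, eyes=2)
            sd = predict_diameter("stanley_davies", cond).diameter_mm
            assert watson_yellott_dsdw(cond) == pytest.approx(sd, rel=1e-14)

    def test_monocular_factor_dims_effective_flux(self):
        mono = wy_conditions(100.0, 30.0, eyes=1)
        equivalent = wy_conditions(10.0, 30.0, eyes=2)
        assert watson_yellott_dsdw(mono) == pytest.approx(
            watson_yellott_dsdw(equivalent), rel=1e-14
        )

    def test_age_sensitivity_changes_sign_at_critical_dsdw(self):
        critical = 0.02132 / 0.009562  # ≈ 2.2296 mm

        def age_slope(L):
            lo = predict_diameter("watson_yellott", wy_conditions(L, 20.0)).diameter_mm
            hi = predict_diameter("watson_yellott", wy_conditions(L, 60.0)).diameter_mm
            return hi - lo

        small_dsdw = wy_conditions(1e6, 40.0)  # very high flux → small pupil
        large_dsdw = wy_conditions(1.0, 40.0)
        assert watson_yellott_dsdw(small_dsdw) < critical < watson_yellott_dsdw(large_dsdw)
        assert age_slope(1e6) < 0 < age_slope(1.0) or age_slope(1e6) > 0 > age_slope(1.0)
        # sensitivity grows with age above critical flux, shrinks below
        assert age_slope(1.0) < 0  # large pupils shrink with age
        assert age_slope(1e6) > 0  # small (senile-miosis floor) pupils grow
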