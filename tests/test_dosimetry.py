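import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from uvact import dosimetry as dm


def make_field(values, coords=(-1.0, 0.0, 1.0)):
    xx, yy = np.meshgrid(coords, coords)
    return dm.IrradianceField(
        xx.ravel(), yy.ravel(), np.asarray(values, float).ravel(),
        np.ones(len(coords) ** 2, bool),
    )


class TestDose:
    @pytest.mark.parametrize(
        "irr,t,expected",
        [(1.0, 4.0, 4.0), (2.5, 0.0, 0.0), (0.5, 8.0, 4.0)],
    )
    def test_examples(self, irr, t, expected):
        assert dm.dose(irr, t) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            dm.dose(-1.0, 1.0)
        with pytest.raises(ValueError):
            dm.dose(1.0, -1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        e=st.floats(0, 100, allow_nan=False),
        t=st.floats(0, 1000, allow_nan=False),
        c=st.floats(0.01, 100, allow_nan=False),
    )
    def test_bilinearity(self, e, t, c):
        assert dm.dose(c * e, t) == pytest.approx(c * dm.dose(e, t), rel=1e-12)
        assert dm.dose(e, c * t) == pytest.approx(c * dm.dose(e, t), rel=1e-12)


class TestTimingCorrections:
    LAG_TABLE = ((2.0, 0.1), (2.4, 0.2), (3.0, 0.4))

    def test_zero_lag_is_identity(self):
        led = dm.LedSpec("U280", 281.3, time_lag_s=0.0)
        assert dm.effective_exposure_time(10.0, led) == 10.0

    def test_lag_table_lookup_adds(self):
        led = dm.LedSpec("U280", 281.3, time_lag_s=self.LAG_TABLE, drive_current_a=2.4)
        assert dm.effective_exposure_time(10.0, led) == pytest.approx(10.2)
        assert dm.effective_exposure_time(0.0, led) == pytest.approx(0.2)

    def test_lag_interpolates_between_currents(self):
        led = dm.LedSpec("U280", 281.3, time_lag_s=self.LAG_TABLE, drive_current_a=2.2)
        assert dm.effective_exposure_time(0.0, led) == pytest.approx(0.15)

    def test_current_outside_table_names_range(self):
        led = dm.LedSpec("U280", 281.3, time_lag_s=self.LAG_TABLE, drive_current_a=5.0)
        with pytest.raises(ValueError, match=r"\[2.0, 3.0\]"):
            dm.effective_exposure_time(10.0, led)

    @pytest.mark.parametrize(
        "dose,frac,t,tref,expected",
        [
            (4.0, 0.0, 5.0, 2.0, 4.0),
            (2.0, 0.03, 2.0, 2.0, 2.06),
            (4.0, 0.03, 4.0, 2.0, 4.06),  # surplus fixed at the 2 s calibration
        ],
    )
    def test_overshoot_is_fixed_surplus(self, dose, frac, t, tref, expected):
        assert dm.overshoot_corrected_dose(dose, frac, t, tref) == pytest.approx(expected)

    def test_exposure_record_consistency(self):
        led = dm.LedSpec("U280", 281.3, time_lag_s=0.2)
        rec = dm.ExposureRecord.from_timer(led, 4.0, 1.0)
        assert rec.effective_time_s == pytest.approx(4.2)
        assert rec.dose_mj_cm2 == pytest.approx(4.2)
        with pytest.raises(ValueError):
            dm.ExposureRecord(led, 4.0, 4.2, 1.0, 5.0)


class TestWaterFactor:
    def test_transparent_limit(self):
        assert dm.water_factor(0.0, 0.1) == 1.0

    def test_thin_layer_value(self):
        # absorbance from 97.6 % transmission over a 1 mm path
        a = dm.transmittance_to_absorbance(97.6, 0.1)
        assert dm.water_factor(a, 0.1) == pytest.approx(0.9879, abs=1e-4)

    def test_unit_optical_depth_closed_form(self):
        # a*l = 1: WF = (1 - 0.1) / ln 10
        assert dm.water_factor(10.0, 0.1) == pytest.approx(0.9 / math.log(10), rel=1e-12)

    def test_depth_must_be_positive(self):
        with pytest.raises(ValueError):
            dm.water_factor(0.1, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(a=st.floats(0.0, 30.0), l=st.floats(0.01, 1.0))
    def test_matches_depth_averaged_transmission(self, a, l):
        oracle, _ = quad(lambda z: 10.0 ** (-a * z), 0.0, l)
        assert dm.water_factor(a, l) == pytest.approx(oracle / l, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(0.01, 20.0), l=st.floats(0.01, 1.0), bump=st.floats(0.01, 5.0))
    def test_monotone_in_absorbance_and_depth(self, a, l, bump):
        wf = dm.water_factor(a, l)
        assert dm.water_factor(a + bump, l) <= wf + 1e-12
        assert dm.water_factor(a, l + bump) <= wf + 1e-12
        assert wf <= 1.0

    def test_spectrum_weighted_average(self):
        a = (0.1, 1.0)
        w = (0.5, 0.5)
        expected = 0.5 * dm.water_factor(0.1, 0.1) + 0.5 * dm.water_factor(1.0, 0.1)
        assert dm.water_factor_weighted(a, w, 0.1) == pytest.approx(expected, rel=1e-12)


class TestDivergenceAndDepth:
    @pytest.mark.parametrize(
        "wd,depth,expected",
        [(10.0, 0.1, 0.990), (10.0, 0.6, 0.943), (10.0, 0.0, 1.0)],
    )
    def test_printed_values(self, wd, depth, expected):
        assert round(dm.divergence_factor(wd, depth), 3) == expected

    def test_far_source_limit(self):
        assert dm.divergence_factor(1e6, 0.6) == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            dm.divergence_factor(0.0, 0.1)

    @pytest.mark.parametrize(
        "volume,expected_cm,nominal",
        [(1.0, 0.1039, 0.1), (6.0, 0.6236, 0.6), (0.962, 0.1000, 0.1)],
    )
    def test_depth_from_volume(self, volume, expected_cm, nominal):
        depth = dm.depth_from_volume(volume, 35.0)
        assert depth == pytest.approx(expected_cm, abs=5e-5)
        assert round(depth, 1) == nominal


class TestFieldStatistics:
    def test_uniform_field(self):
        field = make_field(np.ones(9))
        assert dm.petri_factor(field, "center") == 1.0
        assert dm.petri_factor(field, "max") == 1.0
        assert dm.coefficient_of_variation(field) == 0.0

    def test_center_peaked_grid(self):
        vals = np.full(9, 0.8)
        vals[4] = 1.0  # center node of the 3x3 grid
        field = make_field(vals)
        expected = (0.8 * 8 + 1.0) / 9
        assert dm.petri_factor(field, "center") == pytest.approx(expected, rel=1e-12)
        assert dm.petri_factor(field, "max") == pytest.approx(expected, rel=1e-12)

    def test_pf_max_bounded_by_one(self):
        rng = np.random.default_rng(0)
        field = make_field(rng.uniform(0.5, 1.5, 9))
        assert dm.petri_factor(field, "max") <= 1.0

    def test_two_node_cv_uses_sample_sd(self):
        field = dm.IrradianceField(
            np.array([0.0, 1.0]), np.zeros(2), np.array([1.0, 3.0]), np.ones(2, bool)
        )
        assert dm.coefficient_of_variation(field) == pytest.approx(
            100 * math.sqrt(2) / 2, rel=1e-12
        )

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(0.01, 100.0))
    def test_cv_scale_invariant(self, scale):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.5, 1.5, 9)
        cv1 = dm.coefficient_of_variation(make_field(vals))
        cv2 = dm.coefficient_of_variation(make_field(vals * scale))
        assert cv1 == pytest.approx(cv2, rel=1e-9)

    def test_degenerate_grid_rejected(self):
        field = dm.IrradianceField(
            np.array([0.0]), np.array([0.0]), np.array([1.0]), np.ones(1, bool)
        )
        with pytest.raises(ValueError):
            dm.coefficient_of_variation(field)

    def test_even_grid_center_tie_breaks_low(self):
        coords = (-1.5, -0.5, 0.5, 1.5)
        xx, yy = np.meshgrid(coords, coords)
        vals = np.arange(16.0)
        field = dm.IrradianceField(xx.ravel(), yy.ravel(), vals, np.ones(16, bool))
        i = field.center_index()
        assert (field.x_mm[i], field.y_mm[i]) == (-0.5, -0.5)


class TestFresnelAndReflection:
    def normal_incidence(self, n1, n2):
        return ((n1 - n2) / (n1 + n2)) ** 2

    def test_index_matched_zero(self):
        assert dm.fresnel_reflectance(1.33, 1.33, 37.0) == pytest.approx(0.0, abs=1e-15)

    def test_normal_incidence_closed_form(self):
        for n2 in (1.33, 1.4, 2.0):
            assert dm.fresnel_reflectance(1.0, n2, 0.0) == pytest.approx(
                self.normal_incidence(1.0, n2), abs=1e-12
            )

    def test_air_water_20_degrees_small_loss(self):
        # independent oracle: explicit s/p coefficients via Snell's law
        n1, n2, theta = 1.0, 1.33, math.radians(20.0)
        tt = math.asin(n1 * math.sin(theta) / n2)
        rs = (n1 * math.cos(theta) - n2 * math.cos(tt)) / (
            n1 * math.cos(theta) + n2 * math.cos(tt)
        )
        rp = (n2 * math.cos(theta) - n1 * math.cos(tt)) / (
            n2 * math.cos(theta) + n1 * math.cos(tt)
        )
        oracle = 0.5 * (rs**2 + rp**2)
        got = dm.fresnel_reflectance(1.0, 1.33, 20.0)
        assert got == pytest.approx(oracle, abs=1e-12)
        assert got < 0.021  # beam loss stays within ~2 % inside a 20 degree cone

    @settings(derandomize=True, max_examples=100)
    @given(n2=st.floats(1.0, 2.5), angle=st.floats(0.0, 89.9))
    def test_reflectance_in_unit_interval(self, n2, angle):
        r = dm.fresnel_reflectance(1.0, n2, angle)
        assert 0.0 <= r <= 1.0

    def test_total_internal_reflection(self):
        assert dm.fresnel_reflectance(1.5, 1.0, 60.0) == 1.0

    def test_reflection_factor_normal_beam(self):
        optics = dm.SampleOptics(0.1, 0.1)
        dist = dm.AngularDistribution((0.0,), (1.0,))
        rf = dm.reflection_factor(dist, optics)
        assert round(rf, 3) == 0.980
        assert 0.97 <= rf <= 0.98

    def test_reflection_factor_index_matched(self):
        optics = dm.SampleOptics(0.1, 0.1, refractive_index=1.0)
        dist = dm.AngularDistribution((0.0,), (1.0,))
        assert dm.reflection_factor(dist, optics) == pytest.approx(1.0, abs=1e-15)

    def test_reflection_factor_weighted_split(self):
        optics = dm.SampleOptics(0.1, 0.1)
        dist = dm.AngularDistribution((0.0, 20.0), (0.5, 0.5))
        r0 = dm.fresnel_reflectance(1.0, 1.33, 0.0)
        r20 = dm.fresnel_reflectance(1.0, 1.33, 20.0)
        assert dm.reflection_factor(dist, optics) == pytest.approx(
            1 - (r0 + r20) / 2, rel=1e-12
        )

    def test_beam_fraction_within(self):
        on_axis = dm.AngularDistribution((0.0,), (1.0,))
        assert dm.beam_fraction_within(on_axis, 20.0) == 1.0
        split = dm.AngularDistribution((10.0, 30.0), (0.5, 0.5))
        assert dm.beam_fraction_within(split, 20.0) == pytest.approx(0.5)
        assert dm.beam_fraction_within(split, 90.0) == pytest.approx(1.0)
        assert dm.beam_fraction_within(split, 25.0) <= dm.beam_fraction_within(split, 35.0)


class TestTransmittanceConversion:
    @pytest.mark.parametrize(
        "t_percent,path,expected",
        [(100.0, 0.1, 0.0), (97.6, 0.1, 0.1055), (17.5, 0.1, 7.570)],
    )
    def test_examples(self, t_percent, path, expected):
        assert dm.transmittance_to_absorbance(t_percent, path) == pytest.approx(
            expected, abs=5e-4
        )

    def test_nonpositive_transmittance_rejected(self):
        with pytest.raises(ValueError):
            dm.transmittance_to_absorbance(0.0, 0.1)


class TestValidityGates:
    def factors(self, wf, df, cv):
        return dm.CorrectionFactors(
            wf=wf, df=df, pf_center=0.985, pf_max=0.984, rf=0.975, cv_percent=cv
        )

    def test_bench_factors_pass(self):
        report = dm.validate_exposure(self.factors(0.985, 0.990, 2.23))
        assert report.all_pass

    def test_opaque_sample_fails_wf_gate_only(self):
        report = dm.validate_exposure(self.factors(0.715, 0.990, 2.23))
        assert not report.wf_pass
        assert report.df_pass and report.cv_pass
        assert not report.all_pass

    def test_gates_are_inclusive(self):
        report = dm.validate_exposure(self.factors(0.9, 0.94, 6.7))
        assert report.all_pass

    def test_corrected_dose_mode_multiplies(self):
        f = self.factors(0.985, 0.990, 2.23)
        expected = 4.0 * 0.985 * 0.990 * 0.984 * 0.975
        assert dm.corrected_dose(4.0, f) == pytest.approx(expected, rel=1e-12)


class TestDomainTypes:
    def test_sample_optics_volume_consistency(self):
        dm.SampleOptics(0.1, 0.104, volume_ml=1.0)  # consistent within rounding
        with pytest.raises(ValueError, match="inconsistent"):
            dm.SampleOptics(0.1, 0.6, volume_ml=1.0)

    def test_angular_distribution_must_normalize(self):
        with pytest.raises(ValueError):
            dm.AngularDistribution((0.0, 10.0), (0.5, 0.6))
        with pytest.raises(ValueError):
            dm.AngularDistribution((10.0, 10.0), (0.5, 0.5))

    def test_led_spec_invariants(self):
        with pytest.raises(ValueError):
            dm.LedSpec("bad", 150.0)
        with pytest.raises(ValueError):
            dm.LedSpec("U280", 281.3, overshoot_fraction=0.5)
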