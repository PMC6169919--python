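"""Stress-intensity chain: crack angle, geometry factor, K, events, LEFM."""

import json
import math
from importlib import resources

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import femurtough as ft
from femurtough.errors import (
    EventDetectionError,
    GeometryError,
    InputError,
    RangeError,
)
from femurtough.fracture import MPA_SQRT_MM_TO_MPA_SQRT_M, EventDetectionConfig
from femurtough.simulate import PlantedRCurve, gen_bend_test


class TestHalfCrackAngle:
    def test_zero_extension_returns_initial_angle(self, section, notch):
        assert ft.half_crack_angle(notch, 0.0, section) == notch.initial_half_angle

    def test_arc_formula_at_mean_radius(self):
        sec = ft.CrossSection.from_mean_and_thickness(0.8, 0.2)
        nt = ft.NotchGeometry(initial_half_angle=0.6, notch_depth=0.65)
        assert ft.half_crack_angle(nt, 0.08, sec) == pytest.approx(0.7, abs=1e-12)

    def test_outer_surface_mapping_hook(self):
        sec = ft.CrossSection.from_mean_and_thickness(0.8, 0.2)
        nt = ft.NotchGeometry(initial_half_angle=0.5, notch_depth=0.65)
        theta = ft.half_crack_angle(nt, 0.09, sec, radius_mode="outer")
        assert theta == pytest.approx(0.5 + 0.09 / 0.9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 0.15), min_size=2, max_size=10))
    def test_monotone_in_extension(self, increments):
        sec = ft.CrossSection(0.9, 0.65)
        nt = ft.NotchGeometry(initial_half_angle=0.5, notch_depth=0.6)
        da = np.cumsum(increments)
        thetas = [ft.half_crack_angle(nt, d, sec) for d in da]
        assert np.all(np.diff(thetas) >= 0)

    def test_negative_extension_rejected(self, section, notch):
        with pytest.raises(InputError):
            ft.half_crack_angle(notch, -0.01, section)

    def test_overshoot_clips_with_warning(self, section, notch):
        with pytest.warns(UserWarning, match="clipped"):
            theta = ft.half_crack_angle(notch, 10.0, section)
        assert theta < math.pi


class TestGeometryFactor:
    def test_vanishing_crack_limit(self):
        assert ft.geometry_factor(1e-9, 3.1) == pytest.approx(1.0, abs=1e-6)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        theta=st.floats(0.05, math.pi / 2 - 0.05),
        dtheta=st.floats(0.01, 0.5),
        ratio=st.floats(2.5, 20.0),
    )
    def test_monotone_in_angle_and_at_least_one(self, theta, dtheta, ratio):
        lo = ft.geometry_factor(theta, ratio)
        hi = ft.geometry_factor(theta + dtheta, ratio)
        assert hi > lo >= 1.0

    def test_matches_table_at_grid_points(self):
        raw = json.loads(
            resources.files("femurtough.data")
            .joinpath("geometry_factor_table.json")
            .read_text()
        )
        coeffs = np.asarray(raw["angle_coefficients"])
        exps = np.asarray(raw["angle_exponents"])
        theta = 0.5
        for ratio, a_b in raw["ab_table"]:
            expected = 1.0 + a_b * np.sum(coeffs * (theta / math.pi) ** exps)
            assert ft.geometry_factor(theta, ratio) == pytest.approx(expected, rel=1e-12)

    def test_interpolation_is_continuous_between_levels(self):
        # midway between tabulated ratios 3.0 and 3.5
        f_mid = ft.geometry_factor(0.7, 3.25)
        f_lo = ft.geometry_factor(0.7, 3.0)
        f_hi = ft.geometry_factor(0.7, 3.5)
        assert f_lo < f_mid < f_hi
        assert f_mid == pytest.approx(0.5 * (f_lo + f_hi), rel=1e-12)

    @pytest.mark.parametrize(
        "theta,ratio", [(0.0, 3.0), (math.pi, 3.0), (0.5, 2.0), (0.5, 25.0)]
    )
    def test_out_of_window_raises_named_range_error(self, theta, ratio):
        with pytest.raises(RangeError, match="supported window"):
            ft.geometry_factor(theta, ratio)


class TestStressIntensity:
    def test_zero_load_gives_zero_k(self, section):
        assert ft.stress_intensity(0.0, 8.0, section, 0.5, 1.2) == 0.0

    def test_hand_computed_reference_value(self):
        # sigma_b = 20/(pi*0.64*0.2) = 49.74 MPa; sqrt(pi*0.0008*0.5) m^0.5
        sec = ft.CrossSection.from_mean_and_thickness(0.8, 0.2)
        k = ft.stress_intensity(10.0, 8.0, sec, 0.5, 1.0)
        assert k == pytest.approx(1.763, abs=2e-3)

    def test_linear_in_load(self, section):
        k1 = ft.stress_intensity(7.3, 8.0, section, 0.6, 1.3)
        k2 = ft.stress_intensity(14.6, 8.0, section, 0.6, 1.3)
        assert k2 == pytest.approx(2 * k1, rel=1e-14)

    def test_unit_self_consistency_with_si_computation(self, section):
        """N/mm internal units and a direct SI evaluation agree to 1e-9."""
        p, s, theta, fb = 12.0, 8.0, 0.55, 1.25
        k_pkg = ft.stress_intensity(p, s, section, theta, fb)
        # direct SI: lengths in m, stress in Pa, K in Pa*sqrt(m)
        r_m, t = section.mean_radius * 1e-3, section.wall_thickness * 1e-3
        sigma_pa = (p * s * 1e-3 / 4.0) / (math.pi * r_m**2 * t)
        k_si = fb * sigma_pa * math.sqrt(math.pi * r_m * theta) / 1e6
        assert k_pkg == pytest.approx(k_si, rel=1e-9)

    def test_non_finite_input_rejected(self, section):
        with pytest.raises(InputError):
            ft.stress_intensity(float("nan"), 8.0, section, 0.5, 1.0)
        with pytest.raises(InputError):
            ft.stress_intensity(-1.0, 8.0, section, 0.5, 1.0)

    def test_conversion_constant(self):
        assert MPA_SQRT_MM_TO_MPA_SQRT_M == pytest.approx(0.031622776, rel=1e-7)


class TestDetectEvents:
    def test_recovers_planted_event_frames(self, bend_record):
        record, truth = bend_record
        ev = ft.detect_events(record)
        assert ev.initiation_index == truth["initiation_index"]
        assert ev.peak_index == truth["peak_index"]
        assert ev.instability_index == truth["instability_index"]

    def test_ordering_invariant(self, bend_record):
        record, _ = bend_record
        ev = ft.detect_events(record)
        assert ev.initiation_index <= ev.peak_index <= ev.instability_index

    def test_no_crack_extension_raises(self, bend_record):
        record, _ = bend_record
        record.delta_a = np.zeros_like(record.delta_a)
        with pytest.raises(EventDetectionError, match="no initiation"):
            ft.detect_events(record)

    def test_all_zero_load_raises(self, bend_record):
        record, _ = bend_record
        record.load = np.zeros_like(record.load)
        with pytest.raises(InputError):
            ft.detect_events(record)

    def test_invariant_under_uniform_time_rescaling(self, bend_record):
        record, _ = bend_record
        ev0 = ft.detect_events(record)
        scaled = ft.BendTestRecord(
            time=record.time * 3.7,
            load=record.load,
            displacement=record.displacement,
            frame_time=record.frame_time * 3.7,
            delta_a=record.delta_a,
            span=record.span,
        )
        assert ft.detect_events(scaled) == ev0


class TestToughnessTriplet:
    def test_forward_inverse_closure(self, bend_record, section, notch):
        record, truth = bend_record
        res = ft.toughness_triplet(record, notch, section)
        assert res.K_init == pytest.approx(truth["K_init"], rel=1e-6)
        assert res.K_pl == pytest.approx(truth["K_pl"], rel=1e-6)
        assert res.K_inst == pytest.approx(truth["K_inst"], rel=1e-6)

    def test_load_scaling_doubles_all_k(self, bend_record, section, notch):
        record, _ = bend_record
        base = ft.toughness_triplet(record, notch, section)
        doubled = ft.BendTestRecord(
            time=record.time,
            load=record.load * 2.0,
            displacement=record.displacement,
            frame_time=record.frame_time,
            delta_a=record.delta_a,
            span=record.span,
        )
        res = ft.toughness_triplet(doubled, notch, section)
        for ev in ("initiation", "peak", "instability"):
            assert res.K[ev] == pytest.approx(2 * base.K[ev], rel=1e-12)

    def test_theta_ordering_invariant(self, bend_record, section, notch):
        record, _ = bend_record
        res = ft.toughness_triplet(record, notch, section)
        assert (
            res.theta["initiation"] <= res.theta["peak"] <= res.theta["instability"]
        )

    def test_sham_calibrated_cohort_recovers_5p5_mean(self, section, notch):
        """Bend tests planted from the Sham K_inst distribution average ~5.5."""
        rng = np.random.default_rng(42)
        k_inst_draws = rng.normal(5.5, 0.14 * 5.5, 30)
        recovered = []
        for k in k_inst_draws:
            planted = PlantedRCurve(k=(0.55 * k, 0.91 * k, k))
            record, _ = gen_bend_test(section=section, notch=notch, planted=planted)
            res = ft.toughness_triplet(record, notch, section)
            recovered.append(res.K_inst)
        assert np.mean(recovered) == pytest.approx(np.mean(k_inst_draws), rel=1e-9)
        assert np.mean(recovered) == pytest.approx(5.5, rel=0.10)


class TestPlasticZoneAndLefm:
    def test_zero_k_gives_zero_radius(self):
        assert ft.plastic_zone_radius(0.0, 160.0) == 0.0

    def test_reference_value_at_3mpa(self):
        # (3/160)^2 / (6 pi) m = 18.65 um
        assert ft.plastic_zone_radius(3.0, 160.0) == pytest.approx(0.01865, abs=2e-4)

    def test_quadratic_scaling_in_k(self):
        assert ft.plastic_zone_radius(6.0, 160.0) == pytest.approx(
            4 * ft.plastic_zone_radius(3.0, 160.0), rel=1e-12
        )

    def test_plane_stress_is_three_times_larger(self):
        assert ft.plastic_zone_radius(3.0, 160.0, mode="plane_stress") == pytest.approx(
            3 * ft.plastic_zone_radius(3.0, 160.0), rel=1e-12
        )

    def test_nonpositive_yield_rejected(self):
        with pytest.raises(InputError):
            ft.plastic_zone_radius(3.0, 0.0)

    def test_small_k_valid_large_k_invalid(self):
        sec = ft.CrossSection.from_mean_and_thickness(0.8, 0.2)
        assert ft.lefm_validity(1.0, sec)["valid"]
        assert not ft.lefm_validity(6.0, sec)["valid"]

    def test_infinite_yield_always_valid(self):
        sec = ft.CrossSection.from_mean_and_thickness(0.8, 0.2)
        assert ft.lefm_validity(100.0, sec, yield_strength=1e12)["valid"]

    def test_ratio_always_reported(self):
        sec = ft.CrossSection.from_mean_and_thickness(0.8, 0.2)
        out = ft.lefm_validity(6.0, sec)
        assert out["ratio"] == pytest.approx(
            ft.plastic_zone_radius(6.0, 160.0) / 0.2, rel=1e-12
        )


class TestFractureAngle:
    def test_transverse_fracture_is_zero_degrees(self):
        assert ft.fracture_angle((0.0, 0.0), (0.0, 1.0)) == pytest.approx(0.0)

    def test_diagonal_is_45_degrees(self):
        assert ft.fracture_angle((0.0, 0.0), (1.0, 1.0)) == pytest.approx(45.0)

    def test_devitalized_range_example(self):
        assert ft.fracture_angle((0.0, 0.0), (0.2, 1.0)) == pytest.approx(11.31, abs=0.01)

    def test_coincident_points_rejected(self):
        with pytest.raises(InputError, match="undefined"):
            ft.fracture_angle((1.0, 2.0), (1.0, 2.0))

    def test_bounded_between_0_and_90(self):
        assert ft.fracture_angle((0.0, 0.0), (5.0, 0.0)) == pytest.approx(90.0)


class TestRecordValidation:
    def test_long_duration_warns_not_errors(self):
        t = np.linspace(0, 100, 50)
        with pytest.warns(UserWarning, match="60 s"):
            ft.BendTestRecord(
                time=t,
                load=np.linspace(0, 10, 50),
                displacement=t * 0.001,
                frame_time=np.array([0.0, 50.0]),
                delta_a=np.array([0.0, 0.1]),
            )

    def test_decreasing_crack_extension_rejected(self):
        with pytest.raises(InputError, match="non-decreasing"):
            ft.BendTestRecord(
                time=np.array([0.0, 1.0, 2.0]),
                load=np.array([0.0, 5.0, 8.0]),
                displacement=np.array([0.0, 0.01, 0.02]),
                frame_time=np.array([0.0, 1.0, 2.0]),
                delta_a=np.array([0.0, 0.2, 0.1]),
            )

    def test_unreachable_planted_peak_raises(self, section, notch):
        # peak K far below initiation K cannot put the load maximum at the
        # planted peak frame
        with pytest.raises(GeometryError, match="peak"):
            gen_bend_test(
                section=section,
                notch=notch,
                planted=PlantedRCurve(delta_a=(0.011, 0.15, 0.35), k=(5.0, 2.0, 2.1)),
            )
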