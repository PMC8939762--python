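"""Raster scan planning, coverage accounting, and G-code round trips."""

import numpy as np
import pytest

from fuskit.exceptions import GCodeError, InvalidParameterError
from fuskit.scan import (
    ScanPlan,
    build_plan,
    coverage_stats,
    export_gcode,
    laser_offset_transform,
    parse_gcode,
    plan_timing,
    plane_grid,
    route_length,
    serpentine_route,
)


def brute_force_count(diameter, spacing, convention):
    """O(N^2) lattice filter, independent of the vectorized implementation."""
    radius = diameter / 2.0
    count = 0
    n = int(np.ceil(radius / spacing)) + 1
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            if convention == "centered":
                x, y = i * spacing, j * spacing
            elif convention == "half-offset":
                x, y = (i + 0.5) * spacing, (j + 0.5) * spacing
            else:
                x, y = (i + 0.5) * spacing, j * spacing
            if x * x + y * y <= radius * radius + 1e-12:
                count += 1
    return count


class TestPlaneGrid:
    @pytest.mark.parametrize("convention,expected",
                             [("centered", 197), ("half-offset", 208)])
    def test_treatment_circle_spot_counts(self, convention, expected):
        # 4.8 mm circle, 0.3 mm pitch: i^2 + j^2 <= 16^2 lattice filter.
        spots = plane_grid(4.8, 0.3, convention)
        assert len(spots) == expected
        assert len(spots) == brute_force_count(4.8, 0.3, convention)

    @pytest.mark.parametrize("convention", ["centered", "half-offset", "rows-offset"])
    @pytest.mark.parametrize("diameter,spacing", [(4.8, 0.3), (2.0, 0.35), (1.0, 0.2)])
    def test_matches_brute_force_enumeration(self, convention, diameter, spacing):
        assert len(plane_grid(diameter, spacing, convention)) == brute_force_count(
            diameter, spacing, convention
        )

    def test_all_spots_inside_circle(self):
        spots = plane_grid(4.8, 0.3)
        assert np.all(np.hypot(spots[:, 0], spots[:, 1]) <= 2.4 + 1e-9)

    def test_degenerate_single_spot(self):
        assert len(plane_grid(0.3, 0.3)) == 1
        with pytest.warns(UserWarning, match="single-spot"):
            spots = plane_grid(0.2, 0.3)
        assert len(spots) == 1

    def test_invalid_convention_rejected(self):
        with pytest.raises(InvalidParameterError, match="convention"):
            plane_grid(4.8, 0.3, "hexagonal")


class TestSerpentineRoute:
    def test_unit_square_route_length(self):
        spots = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        route = serpentine_route(spots)
        assert route_length(route) == pytest.approx(3.0)

    def test_route_is_permutation_of_spots(self):
        spots = plane_grid(4.8, 0.3)
        route = serpentine_route(spots)
        assert sorted(map(tuple, route)) == sorted(map(tuple, spots))

    def test_alternate_rows_reverse_direction(self):
        route = serpentine_route(plane_grid(1.2, 0.3))
        rows = {}
        for x, y in route:
            rows.setdefault(round(y, 6), []).append(x)
        xs = [v for _, v in sorted(rows.items(), reverse=True)]
        assert xs[0] == sorted(xs[0]) and xs[1] == sorted(xs[1], reverse=True)

    def test_treatment_route_length_within_oracle_bounds(self):
        # Lower bound: N-1 nearest-neighbour moves; upper bound adds the
        # worst-case diagonal row transitions computed explicitly.
        route = serpentine_route(plane_grid(4.8, 0.3))
        length = route_length(route)
        assert 61.0 <= length <= 67.0
        n = len(route)
        assert length >= (n - 1) * 0.3 - 1e-9

    def test_length_invariant_under_reversal(self):
        route = serpentine_route(plane_grid(2.4, 0.3))
        assert route_length(route[::-1]) == pytest.approx(route_length(route))


class TestPlanTiming:
    def test_protocol_duration_matches_stated_time(self):
        # 204 dwell stops/plane, 6 planes, 0.4 s dwell, 2 mm/s -> ~11.5 min.
        plan = build_plan()
        timing = plan_timing(plan, spots_per_plane_override=204)
        assert timing["total_min"] == pytest.approx(11.5, rel=0.05)

    def test_two_spot_plan(self):
        plan = ScanPlan(
            circle_diameter_mm=1.0, spacing_mm=0.3, grid_convention="centered",
            route=np.array([[0.0, 0.0], [0.3, 0.0]]), n_planes=1,
            z_spacing_mm=0.0, dwell_s=0.4, travel_speed_mm_s=2.0,
        )
        assert plan_timing(plan)["total_s"] == pytest.approx(0.95)

    def test_zero_spot_override(self):
        plan = build_plan(n_planes=1)
        timing = plan_timing(plan, spots_per_plane_override=0)
        assert timing["dwell_per_plane_s"] == 0.0

    def test_timing_invariant_under_route_reversal(self):
        plan = build_plan()
        reversed_plan = ScanPlan(
            **{**plan.__dict__, "route": plan.route[::-1].copy()}
        )
        assert plan_timing(reversed_plan)["total_s"] == pytest.approx(
            plan_timing(plan)["total_s"]
        )


def brute_force_voxel_fraction(plan, focal_diameter_um, cell=0.010):
    """3-D voxel union oracle for the treated fraction of a small plan."""
    radius = focal_diameter_um * 1e-3 / 2.0
    h = plan.z_spacing_mm
    height = (plan.n_planes - 1) * plan.z_spacing_mm
    big_r = plan.circle_diameter_mm / 2.0
    lim = big_r + radius
    xs = np.arange(-lim, lim, cell) + cell / 2
    zs = np.arange(-h / 2, height + h / 2, cell) + cell / 2
    z_planes = -plan.z_planes_mm() if plan.z_order == "top-down" else plan.z_planes_mm()
    treated = 0
    for z in zs:
        mask = np.zeros((len(xs), len(xs)), dtype=bool)
        if any(abs(z - zp) <= h / 2 for zp in z_planes):
            for x0, y0 in plan.route:
                mask |= (xs[:, None] - x0) ** 2 + (xs[None, :] - y0) ** 2 <= radius**2
        treated += mask.sum()
    total = np.pi * big_r**2 * height
    return treated * cell**3 / total


class TestCoverage:
    def test_matches_voxel_oracle_on_small_plan(self):
        plan = build_plan(circle_diameter_mm=1.2, spacing_mm=0.3, n_planes=3)
        stats = coverage_stats(plan, focal_diameter_um=200.0)
        oracle = brute_force_voxel_fraction(plan, 200.0)
        assert stats.treated_fraction == pytest.approx(oracle, rel=0.03)

    def test_treatment_plan_fraction_small(self):
        # The nominal protocol treats only ~a tenth of the target cylinder.
        stats = coverage_stats(build_plan())
        assert 0.08 < stats.treated_fraction < 0.14
        assert stats.treated_fraction < stats.scanned_fraction < 1.0

    def test_single_spot_volume_order(self):
        # One focal cylinder d=104 um, h=0.5 mm -> ~4.25e-3 mm^3.
        plan = build_plan(n_planes=1)
        stats = coverage_stats(plan, focal_diameter_um=104.0, spot_height_mm=0.5)
        assert stats.spot_volume_mm3 == pytest.approx(4.25e-3, rel=0.01)

    def test_fractions_monotone_in_focal_diameter(self):
        plan = build_plan(circle_diameter_mm=2.4, n_planes=2)
        fractions = [
            coverage_stats(plan, focal_diameter_um=d).treated_fraction
            for d in (80.0, 104.0, 150.0)
        ]
        assert fractions == sorted(fractions)

    def test_treated_never_exceeds_scanned(self):
        for d_um in (80.0, 150.0):
            stats = coverage_stats(build_plan(circle_diameter_mm=2.4, n_planes=2),
                                   focal_diameter_um=d_um)
            assert stats.treated_volume_mm3 <= stats.scanned_volume_mm3


class TestGCode:
    def test_roundtrip_is_exact(self):
        plan = build_plan(z_start_mm=5.0)
        text = export_gcode(plan)
        parsed = parse_gcode(text)
        assert np.array_equal(parsed.route, np.round(plan.route, 3))
        assert parsed.dwell_s == plan.dwell_s
        assert parsed.travel_speed_mm_s == pytest.approx(plan.travel_speed_mm_s)
        assert parsed.n_planes == plan.n_planes
        assert parsed.z_spacing_mm == pytest.approx(plan.z_spacing_mm)
        # And the re-export is byte-identical (fixed point).
        assert export_gcode(parsed) == text

    def test_single_spot_program_shape(self):
        plan = ScanPlan(
            circle_diameter_mm=0.3, spacing_mm=0.3, grid_convention="centered",
            route=np.array([[0.0, 0.0]]), n_planes=1, z_spacing_mm=0.0,
            dwell_s=0.4, travel_speed_mm_s=2.0,
        )
        text = export_gcode(plan)
        assert text.count("G4 P400") == 1
        assert text.count("X") == 1

    def test_dwell_word_count_equals_spot_count(self):
        plan = build_plan()
        text = export_gcode(plan)
        assert text.count("G4 P400") == plan.spots_per_plane * plan.n_planes

    def test_unsupported_word_rejected_with_line_number(self):
        with pytest.raises(GCodeError, match="line 3"):
            parse_gcode("G21\nG90\nG2 X1 Y1 I0 J1\n")


class TestPlanJson:
    def test_roundtrip(self):
        plan = build_plan(z_start_mm=4.6)
        restored = ScanPlan.from_json(plan.to_json())
        assert np.allclose(restored.route, plan.route)
        assert restored.n_planes == plan.n_planes
        assert restored.dwell_s == plan.dwell_s
        assert restored.grid_convention == plan.grid_convention
        assert np.allclose(restored.z_planes_mm(), plan.z_planes_mm())


class TestLaserOffset:
    def test_zero_offset_identity(self):
        spots = plane_grid(1.2, 0.3)
        assert np.array_equal(laser_offset_transform(spots, (0.0, 0.0)), spots)

    def test_translate_untranslate_identity(self):
        spots = plane_grid(1.2, 0.3)
        moved = laser_offset_transform(spots, (1.7, -0.4))
        back = laser_offset_transform(moved, (-1.7, 0.4))
        assert np.allclose(back, spots)

    def test_centroid_shifts_by_offset(self):
        spots = plane_grid(2.4, 0.3)
        moved = laser_offset_transform(spots, (1.0, 2.0))
        assert np.allclose(moved.mean(axis=0) - spots.mean(axis=0), [1.0, 2.0])
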