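import math

import numpy as np
import pytest
from shapely.geometry import box

import stemmorph as sm
from oracles import eye_max_internal_angle, in_wedge
from stemmorph.vision import RELATION_BETWEEN, RELATION_BEYOND, RELATION_NONE


def make_eye(aperture=0.2, depth=0.4, extent=0.2, n=1.4, center=(0, 0), tilt=0.0):
    return sm.EyeGeometry(lens_center=center, lens_normal=(0, 1),
                          lens_aperture=aperture, retina_depth=depth,
                          retina_extent=extent, refractive_index=n, tilt=tilt)


WINDOW = box(-10, -10, 10, 10)


class TestSnell:
    def test_normal_incidence(self):
        assert sm.snell_external_angle(0.0, 1.4) == 0.0

    def test_no_refraction_at_unity(self):
        assert sm.snell_external_angle(math.radians(30), 1.0) == pytest.approx(
            math.radians(30))

    def test_30deg_at_1p4(self):
        # arcsin(1.4 * sin 30 deg) = arcsin(0.7)
        assert math.degrees(sm.snell_external_angle(math.radians(30), 1.4)) \
            == pytest.approx(math.degrees(math.asin(0.7)), abs=1e-9)

    def test_saturates_at_grazing(self):
        assert sm.snell_external_angle(math.radians(60), 1.4) == pytest.approx(
            math.pi / 2)

    def test_negative_angle_rejected(self):
        with pytest.raises(sm.ParameterError):
            sm.snell_external_angle(-0.1, 1.4)

    @pytest.mark.parametrize("theta", [0.1, 0.3, 0.6, 1.0])
    def test_monotone_in_n(self, theta):
        angles = [sm.snell_external_angle(theta, n)
                  for n in (1.0, 1.1, 1.2, 1.4, 1.6)]
        assert all(b >= a for a, b in zip(angles, angles[1:]))
        assert angles[0] == pytest.approx(theta)


class TestEyeFieldOfView:
    def test_geometric_half_angle_closed_form(self):
        f = sm.eye_field_of_view(make_eye(0.2, 0.4, 0.2), "geometric", WINDOW)
        assert math.degrees(f.half_angle) == pytest.approx(
            math.degrees(math.atan(0.5)), abs=1e-9)  # arctan(0.2/0.4)

    def test_refractive_widens(self):
        g = sm.eye_field_of_view(make_eye(), "geometric", WINDOW)
        r = sm.eye_field_of_view(make_eye(), "refractive", WINDOW)
        expected = math.asin(1.4 * math.sin(g.half_angle))
        assert r.half_angle == pytest.approx(expected, abs=1e-9)
        assert r.half_angle > g.half_angle

    def test_unity_index_equals_geometric(self):
        g = sm.eye_field_of_view(make_eye(n=1.0), "geometric", WINDOW)
        r = sm.eye_field_of_view(make_eye(n=1.0), "refractive", WINDOW)
        assert r.half_angle == pytest.approx(g.half_angle, abs=1e-12)
        assert r.polygon.symmetric_difference(g.polygon).area < 1e-9

    @pytest.mark.parametrize("aperture,depth,extent",
                             [(0.2, 0.4, 0.2), (0.3, 0.3, 0.3),
                              (0.32, 0.7, 0.135), (0.1, 1.0, 0.5)])
    def test_matches_dense_ray_sampling(self, aperture, depth, extent):
        f = sm.eye_field_of_view(make_eye(aperture, depth, extent),
                                 "geometric", WINDOW)
        oracle = eye_max_internal_angle(aperture, depth, extent)
        assert abs(math.degrees(f.half_angle) - math.degrees(oracle)) < 0.1

    def test_external_half_angle_monotone_in_n(self):
        angles = [sm.eye_field_of_view(make_eye(n=n), "refractive", WINDOW).half_angle
                  for n in (1.0, 1.2, 1.4, 1.6)]
        assert all(b >= a for a, b in zip(angles, angles[1:]))

    def test_tilt_produces_asymmetric_rays(self):
        f = sm.eye_field_of_view(make_eye(tilt=0.3), "geometric", WINDOW)
        a_minus = math.atan2(*f.boundary_rays[0][::-1])
        a_plus = math.atan2(*f.boundary_rays[1][::-1])
        # angles relative to +y are not mirror images
        assert abs((math.pi / 2 - a_plus) + (math.pi / 2 - a_minus)) > 0.05

    def test_untilted_rays_symmetric_about_normal(self):
        f = sm.eye_field_of_view(make_eye(), "geometric", WINDOW)
        d_minus, d_plus = f.boundary_rays
        np.testing.assert_allclose(d_minus[0], -d_plus[0], atol=1e-12)
        np.testing.assert_allclose(d_minus[1], d_plus[1], atol=1e-12)

    def test_zero_depth_rejected(self):
        with pytest.raises(sm.ParameterError):
            make_eye(depth=0.0)


class TestBinocularOverlap:
    def test_parallel_eyes_onset_closed_form(self):
        """Apex separation 1, tan(half-angle) 0.5 -> onset at 1.0."""
        half = math.atan(0.5)
        left = sm.view_field_from_apex((-0.5, 0), (0, 1), half, WINDOW)
        right = sm.view_field_from_apex((0.5, 0), (0, 1), half, WINDOW)
        b = sm.binocular_overlap(left, right)
        assert b.onset_distance == pytest.approx(1.0, rel=1e-6)

    def test_onset_against_rasterized_ray_oracle(self):
        half = math.atan(0.5)
        left = sm.view_field_from_apex((-0.5, 0), (0, 1), half, WINDOW)
        right = sm.view_field_from_apex((0.5, 0), (0, 1), half, WINDOW)
        b = sm.binocular_overlap(left, right)
        ys = np.arange(0.0, 3.0, 1e-3)
        pts = np.column_stack([np.zeros_like(ys), ys])
        both = (in_wedge(pts, (-0.5, 0), (0, 1), half)
                & in_wedge(pts, (0.5, 0), (0, 1), half))
        oracle_onset = ys[both][0]
        assert abs(b.onset_distance - oracle_onset) / oracle_onset < 0.01

    def test_coincident_eyes_self_intersection(self):
        f = sm.view_field_from_apex((0, 0), (0, 1), 0.4, WINDOW)
        b = sm.binocular_overlap(f, f)
        assert b.region.symmetric_difference(f.polygon).area < 1e-9

    def test_outward_facing_eyes_no_overlap(self):
        left = sm.view_field_from_apex((-0.5, 0), (-1, 0), 0.3, WINDOW)
        right = sm.view_field_from_apex((0.5, 0), (1, 0), 0.3, WINDOW)
        b = sm.binocular_overlap(left, right)
        assert b.region.is_empty
        assert b.onset_distance is None

    def test_region_contained_in_monocular_fields(self):
        left = sm.eye_field_of_view(make_eye(center=(-0.7, 0)), "refractive", WINDOW)
        right = sm.eye_field_of_view(make_eye(center=(0.7, 0)), "refractive", WINDOW)
        b = sm.binocular_overlap(left, right)
        assert b.region.area > 0
        for mono in (left, right):
            assert b.region.difference(mono.polygon).area < 1e-9

    def test_mirror_symmetry(self):
        from shapely.affinity import scale as mirror
        left = sm.eye_field_of_view(make_eye(center=(-0.7, 0)), "geometric", WINDOW)
        right = sm.eye_field_of_view(make_eye(center=(0.7, 0)), "geometric", WINDOW)
        b = sm.binocular_overlap(left, right)
        mirrored = mirror(b.region, xfact=-1, yfact=1, origin=(0, 0))
        assert b.region.hausdorff_distance(mirrored) < 1e-6


class TestStyletZone:
    def _layout(self, span, length):
        lay = sm.gen_layout("flat_short")
        from dataclasses import replace
        return replace(lay, stylet_span_angle=span, stylet_length=length)

    def test_half_disc_area(self):
        zone = sm.stylet_zone(self._layout(math.pi, 1.0))
        assert zone.area == pytest.approx(math.pi / 2, rel=0.005)

    def test_sector_area_formula(self):
        zone = sm.stylet_zone(self._layout(math.pi / 3, 3.0))
        assert zone.area == pytest.approx(9 * math.pi / 6, rel=0.005)

    def test_deterministic(self):
        lay = self._layout(math.pi / 2, 1.5)
        z1, z2 = sm.stylet_zone(lay), sm.stylet_zone(lay)
        assert z1.equals(z2)

    def test_zero_length_rejected(self):
        with pytest.raises(sm.ParameterError):
            self._layout(math.pi / 2, 0.0)


class TestClassifyOverlap:
    def test_empty_region_none(self):
        b = sm.BinocularField(region=__import__("shapely").geometry.Polygon(),
                              onset_distance=None)
        zone = sm.stylet_zone(sm.gen_layout("flat_short"))
        assert sm.classify_overlap(b, zone) == (RELATION_NONE, 0.0)

    def test_near_overlap_between_stylets(self):
        lay = sm.gen_layout("flat_short")
        zone = sm.stylet_zone(lay)
        half = math.atan(0.5)
        f = sm.view_field_from_apex((0, 0.5), (0, 1), half, WINDOW)
        b = sm.binocular_overlap(f, f)
        rel, area = sm.classify_overlap(b, zone)
        assert rel == RELATION_BETWEEN and area > 0

    def test_distant_overlap_beyond_stylets(self):
        lay = sm.gen_layout("flat_short")   # stylet reach 1.5
        zone = sm.stylet_zone(lay)
        f = sm.view_field_from_apex((0, 3.0), (0, 1), 0.3, WINDOW)
        b = sm.binocular_overlap(f, f)
        rel, area = sm.classify_overlap(b, zone)
        assert rel == RELATION_BEYOND and area == 0.0


@pytest.fixture(scope="module")
def results():
    res = sm.evaluate_scenarios(sm.gen_layout("flat_short"))
    return {(r.scenario, r.mode): r for r in res}


class TestScenarios:
    def test_flat_short_feasible_overlap_between_stylets(self, results):
        r = results[("flat_short", "refractive")]
        assert r.feasible and r.relation == RELATION_BETWEEN
        assert results[("flat_short", "geometric")].relation == RELATION_BETWEEN

    def test_tapering_long_moves_within_range_under_refraction(self, results):
        assert results[("tapering_long", "geometric")].relation == RELATION_BEYOND
        assert results[("tapering_long", "refractive")].relation == RELATION_BETWEEN

    def test_long_clipped_infeasible(self, results):
        assert results[("long_clipped", "geometric")].feasible is False
        assert results[("long_clipped", "refractive")].feasible is False

    def test_tilted_far_or_absent(self, results):
        for mode in ("geometric", "refractive"):
            assert results[("tilted", mode)].relation in (RELATION_NONE,
                                                          RELATION_BEYOND)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(sm.ParameterError):
            sm.evaluate_scenarios(sm.gen_layout("flat_short"), scenarios=["bogus"])

    def test_mirror_symmetric_binocular_region(self, results):
        from shapely.affinity import scale as mirror
        region = results[("flat_short", "geometric")].binocular.region
        mirrored = mirror(region, xfact=-1, yfact=1, origin=(0, 0))
        head_width = 2.0
        assert region.hausdorff_distance(mirrored) < 1e-6 * head_width

    def test_widening_retina_never_shrinks_overlap(self):
        """Larger retina extent widens the field, so the binocular region
        can only grow (seeded parameter sweep)."""
        rng = np.random.default_rng(12)
        lay = sm.gen_layout("flat_short")
        for _ in range(5):
            depth = rng.uniform(0.3, 0.8)
            aperture = rng.uniform(0.1, 0.3)
            areas = []
            for extent in np.linspace(0.05, 0.4, 6):
                from dataclasses import replace
                right = replace(lay.right_eye, retina_depth=depth,
                                lens_aperture=aperture, retina_extent=extent)
                left = right.mirrored()
                w = lay.default_window()
                lf = sm.eye_field_of_view(left, "geometric", w)
                rf = sm.eye_field_of_view(right, "geometric", w)
                areas.append(sm.binocular_overlap(lf, rf).region.area)
            assert all(b >= a - 1e-9 for a, b in zip(areas, areas[1:]))
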