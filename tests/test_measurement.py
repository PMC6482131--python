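"""Landmark planes, cross-sections, maximal diameters, dilatation field."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aortrack import (
    AnnotationError,
    Centerline,
    CrossSection,
    GeometryError,
    SchemaError,
    build_landmarks,
    cross_section,
    diameter_curve,
    dilatation_field,
    init_tube_mesh,
    max_diameter,
    measure_pair,
    subdivide,
)
from aortrack.errors import BoundaryIntersectionError, OutOfRangeError
from aortrack.phantom import LANDMARK_NAMES


def _straight_centerline(length=100.0, n=101):
    return Centerline(np.stack([
        np.zeros(n), np.zeros(n), np.linspace(0.0, length, n)], axis=1))


def _cylinder_mesh(radius=15.0, length=100.0, compensate=True):
    """Analytic cylinder surface whose subdivided mesh radius is ``radius``."""
    mesh = init_tube_mesh(_straight_centerline(length), radius=radius,
                          vertices_per_ring=32)
    if compensate:
        shrink = np.linalg.norm(mesh.near_limit_positions()[0][:2]) / radius
        mesh.control_vertices[:, :2] /= shrink
    return subdivide(mesh, 2)


def _annotations(centerline, jitter=None):
    from aortrack.phantom import LANDMARK_FRACTIONS

    rng = np.random.default_rng(0)
    ann = {}
    for name, frac in LANDMARK_FRACTIONS.items():
        p = centerline.point_at(frac * centerline.total_length)
        if jitter is not None:
            p = p + rng.uniform(-jitter, jitter, 3)
        ann[name] = p
    return ann


class TestBuildLandmarks:
    def test_on_centerline_annotation_is_projection_fixed_point(self):
        cl = _straight_centerline()
        ann = _annotations(cl)
        lm = build_landmarks(ann, cl)
        for name, e in lm:
            assert np.allclose(e["point"], ann[name], atol=1.0)
            assert np.allclose(e["normal"], (0, 0, 1), atol=1e-9)

    def test_shuffled_input_order_is_normalized(self):
        cl = _straight_centerline()
        ann = _annotations(cl)
        shuffled = {k: ann[k] for k in reversed(list(ann))}
        a = build_landmarks(ann, cl)
        b = build_landmarks(shuffled, cl)
        assert list(a.entries) == list(b.entries) == list(LANDMARK_NAMES)
        for name in a.entries:
            assert a.arc_length(name) == b.arc_length(name)

    def test_missing_and_unknown_names_rejected(self):
        cl = _straight_centerline()
        ann = _annotations(cl)
        incomplete = {k: v for k, v in ann.items() if k != "MAA"}
        with pytest.raises(SchemaError):
            build_landmarks(incomplete, cl)
        with pytest.raises(SchemaError):
            build_landmarks({**ann, "APEX": ann["STJ"]}, cl)

    def test_annotation_too_far_names_landmark(self):
        cl = _straight_centerline()
        ann = _annotations(cl)
        ann["DIST"] = ann["DIST"] + np.array([50.0, 0.0, 0.0])
        with pytest.raises(AnnotationError, match="DIST"):
            build_landmarks(ann, cl)

    def test_phantom_landmarks_recovered_within_2mm(self, default_phantom,
                                                    baseline_state):
        _, _, _, truth = default_phantom
        cl = baseline_state["centerline"]
        ann = {k: v["point"] for k, v in truth.landmarks.items()}
        lm = build_landmarks(ann, cl)
        for name, e in lm:
            # compare plane anchor against the true landmark position
            assert np.linalg.norm(e["point"] - truth.landmarks[name]["point"]) < 2.0


class TestCrossSection:
    def test_perpendicular_section_is_circle(self):
        mesh = _cylinder_mesh(radius=15.0)
        sec = cross_section(mesh, (0.0, 0.0, 50.0), (0.0, 0.0, 1.0))
        r = np.linalg.norm(sec.polygon[:, :2], axis=1)
        assert np.max(np.abs(r - 15.0)) < 0.1
        assert sec.area == pytest.approx(np.pi * 15.0 ** 2, rel=0.01)
        assert sec.max_diameter_mm == pytest.approx(30.0, rel=0.01)

    @pytest.mark.parametrize("tilt_deg", [30.0, 60.0, 75.0])
    def test_tilted_plane_major_axis_law(self, tilt_deg):
        mesh = _cylinder_mesh(radius=15.0, length=160.0)
        t = np.radians(tilt_deg)
        normal = (np.sin(t), 0.0, np.cos(t))
        sec = cross_section(mesh, (0.0, 0.0, 80.0), normal)
        assert sec.max_diameter_mm == pytest.approx(30.0 / np.cos(t), rel=0.01)

    def test_plane_beyond_tube_raises_out_of_range(self):
        mesh = _cylinder_mesh()
        with pytest.raises(OutOfRangeError):
            cross_section(mesh, (0.0, 0.0, 500.0), (0.0, 0.0, 1.0))

    def test_plane_through_boundary_ring_raises(self):
        mesh = _cylinder_mesh(length=100.0)
        with pytest.raises(BoundaryIntersectionError):
            # steep plane through the tube end crosses the open boundary
            cross_section(mesh, (0.0, 0.0, 99.0), (np.sin(1.2), 0.0, np.cos(1.2)))

    def test_polygon_ordered_ccw_about_normal(self):
        mesh = _cylinder_mesh()
        sec = cross_section(mesh, (0.0, 0.0, 50.0), (0.0, 0.0, 1.0))
        ang = np.unwrap(np.arctan2(sec.polygon[:, 1], sec.polygon[:, 0]))
        # CCW about +z in a right-handed frame: angles increase
        assert ang[-1] > ang[0]


class TestMaxDiameter:
    def test_unit_square_diagonal(self):
        poly = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        sec = CrossSection(polygon=poly, normal=(0, 0, 1))
        assert max_diameter(sec) == pytest.approx(np.sqrt(2.0))
        assert sec.diameter_endpoints is not None

    def test_regular_64gon(self):
        ang = 2 * np.pi * np.arange(64) / 64
        poly = np.stack([7.0 * np.cos(ang), 7.0 * np.sin(ang),
                         np.zeros(64)], axis=1)
        sec = CrossSection(polygon=poly, normal=(0, 0, 1))
        assert max_diameter(sec) == pytest.approx(14.0, rel=0.002)

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        ang = np.sort(rng.uniform(0, 2 * np.pi, n))
        rad = rng.uniform(2.0, 20.0, n)
        poly = np.stack([rad * np.cos(ang), rad * np.sin(ang),
                         np.zeros(n)], axis=1)
        sec = CrossSection(polygon=poly, normal=(0, 0, 1))
        d = max_diameter(sec)
        brute = 0.0
        for i in range(n):
            brute = max(brute, np.max(
                np.linalg.norm(poly[i] - poly[i + 1:], axis=1), initial=0.0))
        assert d == brute

    def test_collinear_polygon_rejected(self):
        poly = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        sec = CrossSection(polygon=poly, normal=(0, 0, 1))
        with pytest.raises(GeometryError):
            max_diameter(sec)


class TestMeasurePair:
    def test_identical_meshes_zero_difference(self, baseline_state):
        cl = baseline_state["centerline"]
        mesh = baseline_state["mesh"]
        lm = build_landmarks(_annotations(cl), cl)
        rep = measure_pair(mesh, mesh, lm)
        assert len(rep.rows) == 7
        assert np.allclose(rep.rows["difference_mm"], 0.0)

    def test_swapping_meshes_negates_differences(self, default_phantom,
                                                 baseline_state):
        from aortrack import generate_followup, segment_followup, uniform_dilation

        spec, grid, _, _ = default_phantom
        cl = baseline_state["centerline"]
        mesh_b = baseline_state["mesh"]
        fvol, _ = generate_followup(spec, uniform_dilation(2.0), None,
                                    noise_seed=33, grid=grid)
        mesh_f = segment_followup(fvol, mesh_b, cl)
        lm = build_landmarks(_annotations(cl), cl)
        fwd = measure_pair(mesh_b, mesh_f, lm).rows["difference_mm"].to_numpy()
        rev = measure_pair(mesh_f, mesh_b, lm).rows["difference_mm"].to_numpy()
        assert np.array_equal(fwd, -rev)

    def test_failed_landmark_recorded_not_fatal(self):
        mesh = _cylinder_mesh(length=100.0)
        short = _cylinder_mesh(length=40.0)
        cl = _straight_centerline(100.0)
        lm = build_landmarks(_annotations(cl), cl)
        rep = measure_pair(mesh, short, lm)
        assert len(rep.rows) == 7
        failed = rep.rows[rep.rows["followup_mm"].isna()]
        assert len(failed) > 0
        assert failed["note"].str.contains("followup").all()


class TestDiameterCurve:
    def test_constant_radius_curve_flat(self):
        mesh = _cylinder_mesh(radius=12.0)
        s, d = diameter_curve(mesh, _straight_centerline(), step=5.0)
        assert len(s) > 10
        assert np.max(np.abs(d - 24.0)) < 0.5

    def test_tapering_tube_slope_matches_profile(self):
        from conftest import straight_tube_spec
        from aortrack import GridSpec, generate_baseline, segment_baseline

        spec = straight_tube_spec(radius=15.0, taper_to=10.0, length=120.0,
                                  blur_sigma=0.6)
        grid = GridSpec.fit(spec, spacing=1.0)
        vol, truth = generate_baseline(spec, grid)
        mesh = segment_baseline(vol, truth.centerline.resampled())
        s, d = diameter_curve(mesh, truth.centerline, step=2.0)
        core = (s > 15) & (s < 105)
        slope = np.polyfit(s[core], d[core], 1)[0]
        true_slope = 2.0 * (10.0 - 15.0) / 120.0
        assert slope == pytest.approx(true_slope, rel=0.05)

    def test_step_larger_than_tube_still_samples(self):
        mesh = _cylinder_mesh()
        s, d = diameter_curve(mesh, _straight_centerline(), step=500.0)
        assert len(s) >= 1

    def test_arc_relative_to_stj(self):
        mesh = _cylinder_mesh()
        cl = _straight_centerline()
        lm = build_landmarks(_annotations(cl), cl)
        s, _ = diameter_curve(mesh, cl, step=5.0, landmarks=lm)
        assert s.min() < 0.0 < s.max()  # origin shifted to the STJ plane


class TestDilatationField:
    def test_identical_meshes_zero_field(self, baseline_state):
        mesh = baseline_state["mesh"]
        field = dilatation_field(mesh, mesh)
        assert np.nanmax(np.abs(field)) < 1e-9

    def test_uniform_radius_dilation_doubles_in_diameter(self):
        a = _cylinder_mesh(radius=10.0)
        b = _cylinder_mesh(radius=15.0)
        field = dilatation_field(a, b)
        K = a.ring_size
        assert np.allclose(field[K:-K], 10.0, atol=0.2)
        assert a.vertex_scalar is not None  # stored as the mesh scalar channel

    def test_localized_dilation_support(self, default_phantom, baseline_state):
        from aortrack import generate_followup, localized_dilation, segment_followup

        spec, grid, _, truth = default_phantom
        cl = baseline_state["centerline"]
        mesh_b = baseline_state["mesh"]
        s0 = truth.landmarks["DESC"]["arc_length"]
        fvol, _ = generate_followup(spec, localized_dilation(s0, 40.0, 5.0),
                                    None, noise_seed=44, grid=grid)
        mesh_f = segment_followup(fvol, mesh_b, cl)
        field = dilatation_field(mesh_b, mesh_f)
        ring_field = field.reshape(mesh_b.n_rings, mesh_b.ring_size)[:, 0]
        arcs = mesh_b.ring_arc_lengths
        far = np.abs(arcs - cl.project(truth.centerline.point_at(s0))) > 45.0
        near = np.abs(arcs - cl.project(truth.centerline.point_at(s0))) < 15.0
        assert np.nanmax(np.abs(ring_field[far])) < 1.5
        assert np.nanmean(ring_field[near]) > 7.0
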