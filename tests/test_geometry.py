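"""Parametric eye geometry: meridian profiles, loft, fixtures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tonofem import geometry as G


class TestOcularParams:
    def test_defaults_are_printed_dimensions(self, params):
        assert params.corneal_anterior_radius == 7.75
        assert params.corneal_central_thickness == 0.52
        assert params.scleral_thickness == 0.317
        assert params.junction_angle("nasal") == 173.9

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"corneal_anterior_radius": -1.0},
            {"corneal_central_thickness": 0.7, "corneal_peripheral_thickness": 0.6},
            {"junction_angle_nasal": 150.0},
            {"junction_angle_nasal": 181.0},
            {"axial_length": 5.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            G.OcularGeometryParams(**kwargs)


class TestMeridianProfile:
    @pytest.mark.parametrize(
        "quadrant,angle",
        [("superior", 178.1), ("inferior", 177.7), ("nasal", 173.9),
         ("temporal", 177.0)],
    )
    def test_junction_angle_matches_table(self, params, quadrant, angle):
        prof = G.build_meridian_profile(params, quadrant)
        assert prof.measured_junction_angle_deg() == pytest.approx(angle, abs=0.1)

    def test_wall_thickness_endpoints(self, params):
        """Central 0.52 mm at the apex, 0.67 mm at the limbus, scleral
        0.317 mm beyond the junction band."""
        for q in G.QUADRANTS:
            prof = G.build_meridian_profile(params, q)
            t = prof.thickness(np.array([0.0, G.U_CORNEA_END, 0.9]))
            assert t[0] == pytest.approx(0.52, abs=1e-12)
            assert t[1] == pytest.approx(0.67, abs=1e-12)
            assert t[2] == pytest.approx(0.317, abs=1e-12)

    def test_thickness_field_bounds(self, params):
        """Wall thickness stays within [scleral, peripheral-corneal]."""
        prof = G.build_meridian_profile(params, "nasal")
        t = prof.thickness(np.linspace(0, 1, 500))
        assert t.min() >= 0.317 - 1e-12
        assert t.max() <= 0.67 + 1e-12

    def test_tangent_case_no_kink(self):
        """All angles at 180 deg: tangent-continuous profile, with the
        outer polyline curvature never changing sign."""
        p = G.OcularGeometryParams(
            junction_angle_superior=180.0, junction_angle_inferior=180.0,
            junction_angle_nasal=180.0, junction_angle_temporal=180.0,
        )
        prof = G.build_meridian_profile(p, "nasal")
        assert prof.measured_junction_angle_deg() == pytest.approx(180.0, abs=1e-9)
        # discrete curvature of the outer polyline: turning angle per vertex
        pts = prof.outer
        v = np.diff(pts, axis=0)
        cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
        turning = cross[np.abs(cross) > 1e-14]
        assert np.all(turning < 0) or np.all(turning > 0)

    def test_inner_polyline_strictly_inside(self, params):
        prof = G.build_meridian_profile(params, "temporal")
        gap = np.linalg.norm(prof.outer - prof.inner, axis=1)
        assert gap.min() > 0.25  # at least the scleral thickness, roughly

    def test_infeasible_closure_raises_with_quadrant(self):
        """A grossly incompatible axial length cannot be closed."""
        with pytest.raises(G.GeometricInfeasibilityError, match="nasal"):
            p = G.OcularGeometryParams(axial_length=16.0)
            G.build_meridian_profile(p, "nasal")

    def test_apex_and_pole_on_axis(self, params):
        prof = G.build_meridian_profile(params, "superior")
        assert prof.outer[0] == pytest.approx([0.0, 0.0])
        assert prof.outer[-1] == pytest.approx([params.axial_length, 0.0])

    def test_choroid_flag_thickens_sclera(self):
        p = G.OcularGeometryParams(include_choroid_in_wall=True)
        prof = G.build_meridian_profile(p, "nasal")
        t = prof.thickness(np.array([0.9]))
        assert t[0] == pytest.approx(0.317 + 0.298, abs=1e-12)


class TestLoft:
    def test_key_azimuths_reproduce_profile_angles(self, eye_shell):
        for q, az in G.QUADRANT_AZIMUTH_DEG.items():
            got = eye_shell.junction_exterior_angle_deg(
                np.radians([az]))[0]
            want = eye_shell.profiles[q].junction_angle_deg
            assert got == pytest.approx(want, abs=5e-3)

    def test_junction_angle_continuous_within_envelope(self, eye_shell):
        """Dense azimuth ring: the lofted junction angle varies smoothly
        and stays near the envelope of the four printed values."""
        th = np.linspace(0.0, 2 * math.pi, 721)
        ang = eye_shell.junction_exterior_angle_deg(th)
        assert np.all(np.isfinite(ang))
        assert ang.min() > 173.9 - 0.5
        assert ang.max() < 178.1 + 0.5
        assert np.abs(np.diff(ang)).max() < 0.2  # no jumps

    def test_identical_profiles_give_surface_of_revolution(self, params):
        prof = G.build_meridian_profile(params, "nasal")
        shell = G.loft_eye_surface({q: prof for q in G.QUADRANTS})
        u = np.linspace(0.05, 0.95, 40)
        base = shell.outer_point3(u, np.zeros_like(u))
        for az in (0.7, 2.0, 4.5):
            pts = shell.outer_point3(u, np.full_like(u, az))
            r_base = np.hypot(base[:, 1], base[:, 2])
            r_pts = np.hypot(pts[:, 1], pts[:, 2])
            np.testing.assert_allclose(pts[:, 0], base[:, 0], atol=1e-9)
            np.testing.assert_allclose(r_pts, r_base, atol=1e-9)

    def test_axisymmetric_when_angles_equal(self):
        p = G.OcularGeometryParams(
            junction_angle_superior=177.0, junction_angle_inferior=177.0,
            junction_angle_nasal=177.0, junction_angle_temporal=177.0,
        )
        shell = G.build_eye_shell(p)
        u = np.linspace(0.0, 1.0, 30)
        ref = shell.outer_point3(u, np.zeros_like(u))
        r_ref = np.hypot(ref[:, 1], ref[:, 2])
        for az in np.linspace(0.3, 6.0, 7):
            pts = shell.outer_point3(u, np.full_like(u, az))
            np.testing.assert_allclose(
                np.hypot(pts[:, 1], pts[:, 2]), r_ref, atol=1e-9
            )

    def test_watertight_triangulations(self, eye_shell):
        for surface in ("outer", "inner"):
            m = eye_shell.to_trimesh(48, 48, surface=surface)
            assert m.is_watertight

    def test_missing_profile_rejected(self, params):
        prof = G.build_meridian_profile(params, "nasal")
        with pytest.raises(ValueError, match="superior"):
            G.loft_eye_surface({"nasal": prof})


class TestSphereFixture:
    def test_scleral_dimensions_sphere(self):
        sp = G.make_sphere_fixture(11.2, 0.317)
        u = np.linspace(0, 1, 50)
        pts = sp.outer_point3(u, np.zeros_like(u))
        r = np.linalg.norm(pts - [11.2 + 0.317 / 2, 0, 0], axis=1)
        np.testing.assert_allclose(r, 11.2 + 0.317 / 2, atol=1e-9)

    def test_volume_closed_form(self):
        sp = G.make_sphere_fixture(10.0, 1.0)
        m = sp.to_trimesh(96, 96)
        assert m.is_watertight
        vol_ref = 4.0 / 3.0 * math.pi * 10.5**3
        assert abs(m.volume - vol_ref) / vol_ref < 0.005

    def test_azimuthal_slices_identical(self):
        sp = G.make_sphere_fixture(8.0, 0.5)
        u = np.linspace(0, 1, 25)
        ref = sp.outer_point3(u, np.zeros_like(u))
        pts = sp.outer_point3(u, np.full_like(u, 1.9))
        np.testing.assert_allclose(
            np.hypot(pts[:, 1], pts[:, 2]),
            np.hypot(ref[:, 1], ref[:, 2]), atol=1e-12,
        )

    def test_thickness_must_be_thin(self):
        with pytest.raises(ValueError):
            G.make_sphere_fixture(1.0, 2.0)


class TestBlockFixture:
    def test_tagged_faces(self):
        b = G.make_block_fixture(20.0, 20.0)
        assert len(b.tagged_faces) == 6
        assert b.contact_face == "top"

    def test_halfspace_validity_scale(self):
        b = G.make_block_fixture(20.0, 20.0)
        assert b.is_halfspace_valid(G.ProbeSpec(diameter=1.7))
        assert not b.is_halfspace_valid(G.ProbeSpec(diameter=5.0))

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            G.make_block_fixture(0.0, 20.0)


class TestProbeSpec:
    def test_presets(self):
        assert G.PROBE_PRESETS["standard"].diameter == 1.7
        assert G.PROBE_PRESETS["goldmann"].diameter == 3.06
        assert G.PROBE_PRESETS["validation"].diameter == 2.0

    def test_fillet_bounds(self):
        with pytest.raises(ValueError):
            G.ProbeSpec(diameter=1.7, edge_fillet_radius=1.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    angle=st.floats(min_value=170.0, max_value=180.0),
    rc=st.floats(min_value=7.0, max_value=8.5),
)
def test_profile_construction_robust_over_plausible_anatomy(angle, rc):
    """Any anatomically plausible junction angle and corneal radius yields
    a valid profile with the requested kink."""
    p = G.OcularGeometryParams(
        corneal_anterior_radius=rc,
        junction_angle_nasal=angle,
    )
    prof = G.build_meridian_profile(p, "nasal")
    assert prof.measured_junction_angle_deg() == pytest.approx(angle, abs=0.1)
    assert prof.s_total > 25.0
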