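"""Guide generation: patch selection, extrusion, boolean edits, seating ICP."""

import numpy as np
import pytest

from arguide.guide_design import (FitResult, SeedOffSurfaceError, add_cone_fiducials,
                                  add_marker_holder, add_screw_holes, build_guide,
                                  extract_bone_fragment, fit_guide, select_contact_region)
from arguide.mesh import MeshQuery, make_box, make_icosphere
from arguide.transforms import RigidTransform, rotation_from_axis_angle

from conftest import grid_patch


class TestContactRegion:
    def test_saturation_returns_whole_surface(self, sphere30):
        patch = select_contact_region(sphere30, [0, 0, 30], radius=1000.0)
        assert patch.n_faces == sphere30.n_faces

    def test_spherical_cap_area(self, sphere30):
        """Geodesic radius r on a sphere of radius R: area 2 pi R^2 (1 - cos r/R)."""
        r = 15.0
        patch = select_contact_region(sphere30, [0, 0, 30], radius=r)
        exact = 2 * np.pi * 30.0**2 * (1 - np.cos(r / 30.0))
        assert abs(patch.area() - exact) / exact < 0.05

    def test_patch_connected_and_contains_seed(self, small_phantom):
        bone = small_phantom.bone
        seed = bone.vertices[np.argmax(bone.vertices[:, 2])]
        patch = select_contact_region(bone, seed, radius=15.0)
        assert len(np.unique(patch.face_connected_components())) == 1
        d, _, _, _ = MeshQuery(patch).closest(seed[None])
        assert d[0] < 1e-6

    def test_seed_off_surface(self, sphere30):
        with pytest.raises(SeedOffSurfaceError):
            select_contact_region(sphere30, [0, 0, 60], radius=10.0)


class TestBuildGuide:
    def test_zero_thickness_rejected(self, flat_patch):
        with pytest.raises(ValueError):
            build_guide(flat_patch, 0.0)

    def test_prism_volume(self, flat_patch):
        """20x20 planar patch extruded 3 mm: a 1200 mm^3 prism."""
        g = build_guide(flat_patch, 3.0)
        assert g.body.is_watertight()
        assert abs(g.body.volume() - 1200.0) / 1200.0 < 0.10

    def test_inner_surface_reproduces_bone(self, sphere30):
        """Mean distance from the guide's inner surface to the bone < 0.2 mm."""
        patch = select_contact_region(sphere30, [0, 0, 30], radius=12.0)
        g = build_guide(patch, 3.0)
        q = MeshQuery(sphere30)
        d = np.abs(q.signed_distance(g.contact_patch.vertices))
        assert d.mean() < 0.2
        assert g.body.is_watertight()

    def test_curved_patch_watertight(self):
        curved = grid_patch(10.0, 21, z_fn=lambda x, y: 0.02 * (x**2 - y**2))
        g = build_guide(curved, 2.0)
        assert g.body.is_watertight()


class TestScrewHoles:
    def test_no_axes_identity(self, flat_patch):
        g = build_guide(flat_patch, 3.0)
        assert add_screw_holes(g, []) is g

    def test_two_through_holes_cylinder_volume(self, flat_patch):
        g = build_guide(flat_patch, 3.0)
        axes = [(np.array([5.0, 5.0, -1.0]), np.array([0.0, 0.0, 1.0])),
                (np.array([-5.0, -5.0, -1.0]), np.array([0.0, 0.0, 1.0]))]
        g2 = add_screw_holes(g, axes, diameter=5.0, pitch=0.3)
        removed = g.body.volume() - g2.body.volume()
        exact = 2 * np.pi * 2.5**2 * 3.0
        assert abs(removed - exact) / exact < 0.15
        assert g2.body.is_watertight()
        assert len(g2.screw_axes) == 2
        assert np.isclose(g2.screw_axes[0][2], 5.0)

    def test_axis_outside_is_noop(self, flat_patch):
        g = build_guide(flat_patch, 3.0)
        axes = [(np.array([500.0, 500.0, 0.0]), np.array([0.0, 0.0, 1.0]))]
        g2 = add_screw_holes(g, axes, pitch=0.4)
        assert abs(g2.body.volume() - g.body.volume()) / g.body.volume() < 0.02


class TestConeFiducials:
    def test_no_points_identity(self, plate):
        assert add_cone_fiducials(plate, np.zeros((0, 3))) is plate

    def test_cone_depth_and_apex(self, plate):
        """Ø4 x 3 mm pocket: apex lands at point - 3*normal within 0.1 mm."""
        point = np.array([[0.0, 0.0, 1.5]])  # on the top face
        out = add_cone_fiducials(plate, point, diameter=4.0, depth=3.0, pitch=0.12)
        assert out.is_watertight()
        apex_pred = np.array([0.0, 0.0, 1.5 - 3.0])
        d, _, _, _ = MeshQuery(out).closest(apex_pred[None])
        assert d[0] < 0.1
        near_axis = out.vertices[np.linalg.norm(out.vertices[:, :2], axis=1) < 0.3]
        depth = 1.5 - near_axis[:, 2].min()
        assert abs(depth - 3.0) < 0.1

    def test_off_surface_points_listed(self, plate):
        with pytest.raises(ValueError, match="indices \\[1\\]"):
            add_cone_fiducials(plate, np.array([[0, 0, 1.5], [0, 0, 30.0]]))


class TestMarkerHolder:
    @pytest.fixture()
    def guide(self, flat_patch):
        return build_guide(flat_patch, 3.0)

    def test_pose_stored_bit_exact(self, guide, rng):
        R = rotation_from_axis_angle(rng.standard_normal(3), 0.3)
        pose = RigidTransform(R, np.array([1.0, -2.0, 40.0]), "guide", "marker")
        g2 = add_marker_holder(guide, pose)
        assert g2.holder_pose is pose

    def test_cube_does_not_collide_with_socket(self, guide):
        pose = RigidTransform(np.eye(3), np.array([0.0, 0.0, 3.0 + 2.5 + 15.0 + 1.0]),
                              "guide", "marker")
        g2 = add_marker_holder(guide, pose)
        cube = make_box([30.0, 30.0, 30.0], center=pose.translation)
        q = MeshQuery(g2.body)
        pts, _ = cube.sample_surface(3000, np.random.default_rng(0))
        # the marker surface must stay outside the printed socket walls
        assert (q.signed_distance(pts) > -0.05).all()

    def test_collision_with_patch_rejected(self):
        # wide patch; socket walls pass through the patch plane
        wide = build_guide(grid_patch(25.0, 41), 3.0)
        pose = RigidTransform(np.eye(3), np.array([0.0, 0.0, 14.0]), "guide", "marker")
        with pytest.raises(ValueError, match="collides"):
            add_marker_holder(wide, pose)


class TestBoneFragment:
    def test_huge_margin_whole_bone(self, sphere30):
        patch = select_contact_region(sphere30, [0, 0, 30], radius=10.0)
        frag = extract_bone_fragment(sphere30, patch, margin=1000.0, pitch=2.0)
        assert abs(frag.volume() - sphere30.volume()) / sphere30.volume() < 0.10

    def test_containment_properties(self, small_phantom):
        ph = small_phantom
        patch = ph.guide.contact_patch
        frag = extract_bone_fragment(ph.bone, patch, margin=8.0, pitch=1.0)
        assert frag.is_watertight()
        lo_b, hi_b = ph.bone.bounds()
        lo_f, hi_f = frag.bounds()
        assert (lo_f >= lo_b - 1.0).all() and (hi_f <= hi_b + 1.0).all()
        # every patch vertex lies in (on) the fragment solid
        q = MeshQuery(frag)
        assert (q.signed_distance(patch.vertices) < 1.0).all()
        assert frag.volume() < ph.bone.volume()

    def test_disjoint_patch_errors(self, sphere30):
        far_patch = grid_patch(5.0, 7).translated([500.0, 0, 0])
        with pytest.raises(ValueError):
            extract_bone_fragment(sphere30, far_patch, margin=2.0, pitch=2.0)


class TestFitGuide:
    def test_seated_pose_zero_residual(self, small_phantom):
        ph = small_phantom
        fit = fit_guide(ph.guide, ph.bone, ph.seating_truth)
        assert fit.rms_mm < 1e-9
        assert np.linalg.norm(fit.pose.translation) < 0.05
        assert fit.converged

    def test_recovers_small_displacement(self, small_phantom):
        """Known small rigid offset is undone to within 0.1 mm / 0.1 deg."""
        ph = small_phantom
        dR = rotation_from_axis_angle([0.3, 1.0, 0.2], np.radians(1.0))
        init = RigidTransform(dR, np.array([0.5, -0.4, 0.6]), "anatomy", "guide")
        fit = fit_guide(ph.guide, ph.bone, init)
        assert np.linalg.norm(fit.pose.translation) < 0.1
        assert fit.pose.rotation_angle_deg() < 0.1
        assert fit.rms_mm < 0.05

    def test_result_unpacks(self, small_phantom):
        ph = small_phantom
        pose, rms = fit_guide(ph.guide, ph.bone)
        assert isinstance(pose, RigidTransform)
        assert rms >= 0.0
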