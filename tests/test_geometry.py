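"""Plane construction and mesh-surgery operations."""
import numpy as np
import pytest
import trimesh

import craniospring.geometry as G
import craniospring.morphometrics as M
from craniospring.errors import (ConfigurationError, DegenerateGeometryError,
                                 EmptyResultError, OffsetError,
                                 SeparationError)
from craniospring.types import OsteotomySpec, Plane, TriSurface


def sphere(radius=50.0, subdivisions=4):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriSurface.from_trimesh(m)


class TestFitBasePlane:
    def test_coplanar_points_give_z_plane(self):
        p = G.fit_base_plane([0, 0, 0], [-60, -90, 0], [60, -90, 0])
        assert np.allclose(p.normal, [0, 0, 1])
        assert abs(p.signed_distance(np.array([[5.0, 5.0, 0.0]]))[0]) < 1e-9

    def test_exact_interpolation_of_random_triples(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            pts = rng.normal(0, 60, (3, 3))
            # cross-product construction oracle
            n_ref = np.cross(pts[1] - pts[0], pts[2] - pts[0])
            if np.linalg.norm(n_ref) < 1e-3:
                continue
            plane = G.fit_base_plane(*pts)
            assert np.abs(plane.signed_distance(pts)).max() < 1e-9
            n_ref /= np.linalg.norm(n_ref)
            assert min(np.linalg.norm(plane.normal - n_ref),
                       np.linalg.norm(plane.normal + n_ref)) < 1e-9

    def test_collinear_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            G.fit_base_plane([0, 0, 0], [1, 1, 1], [2, 2, 2])


class TestCutByPlane:
    def test_hemisphere_area(self):
        cut = G.cut_by_plane(sphere(1.0), Plane([0, 0, 0], [0, 0, 1]))
        assert cut.area() == pytest.approx(2 * np.pi, rel=0.01)

    def test_noop_when_entirely_on_kept_side(self):
        s = sphere(10.0)
        out = G.cut_by_plane(s, Plane([0, 0, -100], [0, 0, 1]))
        assert out.n_vertices == s.n_vertices

    def test_ellipsoid_cut_area_matches_quadrature_oracle(self):
        a, b, c = 60.0, 40.0, 50.0
        m = trimesh.creation.icosphere(subdivisions=5, radius=1.0)
        v = np.asarray(m.vertices) * [a, b, c]
        surf = TriSurface(v, np.asarray(m.faces))
        z0 = 10.0
        cut = G.cut_by_plane(surf, Plane([0, 0, z0], [0, 0, 1]))
        # dense-quadrature oracle on the parametric ellipsoid above z0
        th = np.linspace(0, np.arccos(z0 / c), 2000)
        ph = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        TH, PH = np.meshgrid(th, ph, indexing="ij")
        x = a * np.sin(TH) * np.cos(PH)
        y = b * np.sin(TH) * np.sin(PH)
        z = c * np.cos(TH)
        # |r_theta x r_phi| on the parametric grid
        xt = a * np.cos(TH) * np.cos(PH)
        yt = b * np.cos(TH) * np.sin(PH)
        zt = -c * np.sin(TH)
        xp = -a * np.sin(TH) * np.sin(PH)
        yp = b * np.sin(TH) * np.cos(PH)
        zp = np.zeros_like(PH)
        cr = np.stack([yt * zp - zt * yp, zt * xp - xt * zp,
                       xt * yp - yt * xp])
        integrand = np.linalg.norm(cr, axis=0)
        area_ref = np.trapezoid(integrand.sum(axis=1) * (ph[1] - ph[0]), th)
        assert cut.area() == pytest.approx(area_ref, rel=0.01)
        del x, y, z

    def test_area_conservation(self):
        s = sphere(50.0)
        plane = Plane([0, 0, 13.0], [0.2, -0.3, 0.93])
        kept = G.cut_by_plane(s, plane, "positive")
        rest = G.cut_by_plane(s, plane, "negative")
        assert kept.area() + rest.area() == pytest.approx(s.area(), rel=1e-3)

    def test_commutes_with_rigid_transform(self):
        s = sphere(40.0, subdivisions=3)
        plane = Plane([0, 5, 3], [0.1, 0.2, 0.97])
        T = trimesh.transformations.rotation_matrix(0.7, [0.3, 1, 0.2],
                                                    [4, 5, 6])
        a = G.cut_by_plane(s, plane).transformed(T)
        b = G.cut_by_plane(s.transformed(T), plane.transformed(T))
        assert a.n_vertices == b.n_vertices
        da = np.sort(np.linalg.norm(a.vertices, axis=1))
        db = np.sort(np.linalg.norm(b.vertices, axis=1))
        assert np.abs(da - db).max() < 1e-6

    def test_empty_result_raises(self):
        with pytest.raises(EmptyResultError):
            G.cut_by_plane(sphere(10.0), Plane([0, 0, 100], [0, 0, 1]))


class TestOffsetInward:
    def test_sphere_shrinks_by_distance(self):
        out = G.offset_inward(sphere(50.0), 2.8)
        r = np.linalg.norm(out.vertices, axis=1)
        assert np.abs(r - 47.2).max() < 0.1

    def test_zero_distance_is_identity(self):
        s = sphere(30.0, 3)
        out = G.offset_inward(s, 0.0)
        assert np.array_equal(out.vertices, s.vertices)

    def test_phantom_offset_distance_via_nearest_oracle(self, coarse_head):
        head, _ = coarse_head
        out = G.offset_inward(head, 2.8)
        d = M.nearest_surface_distance(out.vertices, head)
        assert np.abs(d - 2.8).max() < 0.15

    def test_collapse_raises(self):
        with pytest.raises(OffsetError):
            G.offset_inward(sphere(5.0, 3), 10.0)


class TestCloseHoles:
    def test_single_hole_closed_watertight(self):
        s = sphere(20.0, 3)
        surf = TriSurface(s.vertices, s.faces[1:])   # one triangular hole
        out = G.close_holes(surf)
        assert out.to_trimesh().is_watertight

    def test_closed_mesh_unchanged(self):
        s = sphere(20.0, 3)
        out = G.close_holes(s)
        assert out.n_faces == s.n_faces

    def test_phantom_gaps_filled_except_base_rim(self, coarse_head):
        head, landmarks = coarse_head
        base = G.fit_base_plane(landmarks["nasion"],
                                landmarks["tragion_left"],
                                landmarks["tragion_right"])
        cut = G.cut_by_plane(head, base)
        # punch three synthetic suture gaps well above the rim
        cen = cut.face_centroids()
        h = base.signed_distance(cen)
        keep = np.ones(cut.n_faces, dtype=bool)
        rng = np.random.default_rng(3)
        high = np.flatnonzero(h > 30)
        for seed_face in rng.choice(high, 3, replace=False):
            d = np.linalg.norm(cen - cen[seed_face], axis=1)
            keep &= d > 6.0
        holed = TriSurface(cut.vertices, cut.faces[keep])
        n_loops_before = len(holed.boundary_loops())
        assert n_loops_before >= 4            # 3 gaps + base rim
        out = G.close_holes(holed, keep_open_plane=base)
        loops = out.boundary_loops()
        assert len(loops) == 1                # only the rim remains
        assert out.is_edge_manifold()


class TestSeparateInnerOuter:
    @staticmethod
    def _bridged_shells(r_out=50.0, r_in=47.5):
        outer = trimesh.creation.icosphere(subdivisions=4, radius=r_out)
        inner = trimesh.creation.icosphere(subdivisions=4, radius=r_in)
        keep_o = np.asarray(outer.vertices)[:, 2] > -1e-9
        keep_i = np.asarray(inner.vertices)[:, 2] > -1e-9
        fo = outer.faces[keep_o[outer.faces].all(axis=1)]
        fi = inner.faces[keep_i[inner.faces].all(axis=1)]
        v = np.vstack([outer.vertices, inner.vertices])
        f = np.vstack([fo, fi + len(outer.vertices)])
        return TriSurface(v, f)

    def test_concentric_hemispheres(self):
        shell = self._bridged_shells()
        inner, outer = G.separate_inner_outer(shell,
                                              Plane([0, 0, 0], [0, 0, 1]),
                                              rim_band=6.0)
        r_i = np.linalg.norm(inner.vertices - shell.vertices.mean(axis=0),
                             axis=1).mean()
        r_o = np.linalg.norm(outer.vertices - shell.vertices.mean(axis=0),
                             axis=1).mean()
        assert r_o > r_i
        assert r_o == pytest.approx(50.0, abs=1.5)
        assert r_i == pytest.approx(47.5, abs=1.5)
        assert inner.n_faces + outer.n_faces <= shell.n_faces

    def test_single_surface_raises(self):
        s = sphere(30.0, 3)
        with pytest.raises(SeparationError):
            G.separate_inner_outer(s, Plane([0, 0, -40], [0, 0, 1]))


class TestSuturePlanes:
    @staticmethod
    def _frame():
        frame = G.make_frame([0, 60, 0], [-45, 0, 0], [45, 0, 0])
        frame.A = np.array([0.0, 75.0, 0.0])
        frame.P = np.array([0.0, -75.0, 0.0])
        return frame

    def test_right_angle_is_perpendicular_through_midpoint(self):
        frame = self._frame()
        coronal, _ = G.suture_planes(frame, 90.0, 68.0, 0.5, 0.25)
        assert abs(abs(coronal.normal @ frame.ap_direction) - 1) < 1e-9
        assert np.linalg.norm(np.asarray(frame.B)
                              - 0.5 * (frame.A + frame.P)) < 1e-9

    def test_foot_point_arithmetic(self):
        frame = G.make_frame([0, 60, 0], [-45, 0, 0], [45, 0, 0])
        frame.A = np.array([0.0, 150.0, 0.0])
        frame.P = np.array([0.0, 0.0, 0.0])
        G.suture_planes(frame, 83.0, 68.0, 0.30, 0.25)
        assert np.linalg.norm(frame.B - frame.A) == pytest.approx(45.0)
        assert np.linalg.norm(frame.L - frame.P) == pytest.approx(37.5)

    def test_plane_contains_configured_angle(self):
        frame = self._frame()
        coronal, lambdoid = G.suture_planes(frame, 83.0, 68.0, 0.30, 0.25)
        u = frame.base_plane.normal
        a_hat = frame.ap_direction
        for plane, ang, sign in ((coronal, 83.0, 1), (lambdoid, 68.0, -1)):
            trace = np.cos(np.radians(ang)) * sign * a_hat \
                + np.sin(np.radians(ang)) * u
            assert abs(plane.normal @ trace) < 1e-9

    def test_converging_planes_raise_below_vertex(self):
        frame = self._frame()
        with pytest.raises(ConfigurationError):
            # traces leaning toward each other cross low over a short gap
            G.suture_planes(frame, 120.0, 120.0, 0.45, 0.45, max_height=80.0)

    def test_invalid_fractions_raise(self):
        frame = self._frame()
        with pytest.raises(ConfigurationError):
            G.suture_planes(frame, 83.0, 68.0, 0.8, 0.25)


class TestCarveOsteotomies:
    def test_notch_sets_present_and_disjoint(self, coarse_model):
        ns = coarse_model.notch_sets
        assert set(ns) == {"anterior_left", "anterior_right",
                           "posterior_left", "posterior_right"}
        seen = set()
        for idx in ns.values():
            assert len(idx) > 0
            assert not (seen & set(idx.tolist()))
            seen |= set(idx.tolist())

    def test_gap_boundary_on_kerf_planes(self, coarse_model):
        model = coarse_model
        m = model.frame.midline_plane.normal
        vlat = (model.shell.vertices - model.frame.midline_plane.point) @ m
        h = model.frame.base_plane.signed_distance(model.shell.vertices)
        boundary = G._boundary_vertices(model.shell)
        spec = OsteotomySpec()
        gap = boundary & (np.abs(np.abs(vlat) - spec.lateral_offset)
                          < spec.kerf) & (h > 10)
        assert gap.sum() > 10
        # all gap-boundary vertices sit within the kerf of a cut line
        assert (np.abs(np.abs(vlat[gap]) - spec.lateral_offset)
                <= 0.5 * spec.kerf + 1e-6).all()

    def test_zero_kerf_raises(self):
        with pytest.raises(ConfigurationError):
            OsteotomySpec(kerf=0.0)

    def test_two_extra_boundary_loops(self, coarse_head):
        from craniospring import PopulationParams, build_s_model
        head, landmarks = coarse_head
        model = build_s_model(head, landmarks, PopulationParams())
        # pre-carve split model has 1 loop (rim); carved has 3
        assert len(model.shell.boundary_loops()) == 3

    def test_cut_outside_parietal_raises(self, coarse_head):
        from craniospring import PopulationParams, build_s_model
        from craniospring.errors import PipelineError
        head, landmarks = coarse_head
        bad = OsteotomySpec(anterior_extent=0.05, posterior_extent=0.95)
        with pytest.raises(PipelineError, match="parietal"):
            build_s_model(head, landmarks, PopulationParams(), bad)


class TestQuality:
    def test_shell_has_no_slivers(self, coarse_model):
        sh = coarse_model.shell
        tri = sh.vertices[sh.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        l2 = sum(np.linalg.norm(tri[:, (i + 1) % 3] - tri[:, i], axis=1)**2
                 for i in range(3))
        q = 4 * np.sqrt(3) * areas / l2
        assert q.min() > 0.03
        assert sh.is_edge_manifold()


class TestUniformScale:
    def test_scales_about_centroid(self):
        s = sphere(50.0, 3)
        out = G.uniform_scale(s, 1.1)
        r = np.linalg.norm(out.vertices - out.vertices.mean(axis=0), axis=1)
        assert r.mean() == pytest.approx(55.0, rel=1e-3)

    def test_identity(self):
        s = sphere(50.0, 3)
        out = G.uniform_scale(s, 1.0)
        assert np.allclose(out.vertices, s.vertices)
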