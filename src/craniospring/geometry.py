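"""Landmark-based plane construction and triangle-mesh surgery.

All the geometric carpentry used to turn a head-surface scan into a
simulation-ready skull shell: exact plane fits through landmark triples,
mesh/plane cutting with triangle splitting, inward surface offsetting,
boundary-loop hole filling, inner/outer skull-table separation, tilted
suture-plane construction and parasagittal osteotomy carving.

Plane cutting and connected-component queries delegate to :mod:`trimesh`;
the anatomical constructions are this package's own.
"""
from __future__ import annotations

from collections import defaultdict

import numpy as np
import trimesh
import trimesh.intersections

from .errors import (ConfigurationError, DegenerateGeometryError,
                     EmptyResultError, OffsetError, SeparationError,
                     TopologyError)
from .types import GEOM_TOL, AnatomicalFrame, OsteotomySpec, Plane, TriSurface

REGIONS = ("frontal", "coronal_suture", "parietal", "lambdoid_suture",
           "occipital")

NOTCH_KEYS = ("anterior_left", "anterior_right",
              "posterior_left", "posterior_right")


# ---------------------------------------------------------------------------
# planes and frames
# ---------------------------------------------------------------------------

def fit_base_plane(nasion, tragion_left, tragion_right) -> Plane:
    """Exact plane through nasion and both tragions.

    The normal is oriented toward the cranial vertex: with the nasion
    anterior and the tragions posterolateral, ``(tl - n) x (tr - n)`` points
    upward out of the skull base.
    """
    n = np.asarray(nasion, dtype=float)
    tl = np.asarray(tragion_left, dtype=float)
    tr = np.asarray(tragion_right, dtype=float)
    cross = np.cross(tl - n, tr - n)
    norm = np.linalg.norm(cross)
    scale = max(np.linalg.norm(tl - n), np.linalg.norm(tr - n), 1.0)
    if norm < 1e-9 * scale * scale:
        raise DegenerateGeometryError(
            "nasion/tragion landmarks are collinear or coincident")
    return Plane(point=n, normal=cross / norm)


def make_frame(nasion, tragion_left, tragion_right,
               bregma=None, lambda_pt=None) -> AnatomicalFrame:
    """Anatomical frame from the three base landmarks.

    The midline (sagittal symmetry) plane passes through the nasion,
    contains the base-plane normal, and its normal points toward the left
    tragion.  A/P and the suture feet are filled in later from the mesh.
    """
    base = fit_base_plane(nasion, tragion_left, tragion_right)
    n = np.asarray(nasion, dtype=float)
    tl = np.asarray(tragion_left, dtype=float)
    tr = np.asarray(tragion_right, dtype=float)
    tmid = 0.5 * (tl + tr)
    ap_guess = n - tmid
    ap_guess = ap_guess - (ap_guess @ base.normal) * base.normal
    if np.linalg.norm(ap_guess) < 1e-9:
        raise DegenerateGeometryError("nasion coincides with tragion midpoint")
    lateral = np.cross(base.normal, ap_guess / np.linalg.norm(ap_guess))
    if (tl - n) @ lateral < 0:
        lateral = -lateral
    midline = Plane(point=n, normal=lateral)
    return AnatomicalFrame(nasion=n, tragion_left=tl, tragion_right=tr,
                           base_plane=base, midline_plane=midline,
                           bregma=None if bregma is None else np.asarray(bregma, float),
                           lambda_pt=None if lambda_pt is None else np.asarray(lambda_pt, float))


# ---------------------------------------------------------------------------
# mesh surgery
# ---------------------------------------------------------------------------

def cut_by_plane(mesh: TriSurface, plane: Plane, keep: str = "positive",
                 ) -> TriSurface:
    """Cut a mesh with a plane, keeping one side.

    Triangles straddling the plane are split so the open boundary lies
    exactly on the plane.  ``keep`` is ``"positive"`` (along the normal) or
    ``"negative"``.  Face labels do not survive a cut (cut before
    labelling); a mesh entirely on the kept side is returned unchanged.
    """
    if keep not in ("positive", "negative"):
        raise ConfigurationError(f"keep must be 'positive'/'negative', got {keep!r}")
    p = plane if keep == "positive" else plane.flipped()
    sd = p.signed_distance(mesh.vertices)
    if sd.min() >= -GEOM_TOL:
        return mesh.copy()
    if sd.max() <= GEOM_TOL:
        raise EmptyResultError("cut removed the whole mesh")
    sliced = trimesh.intersections.slice_mesh_plane(
        mesh.to_trimesh(), plane_normal=p.normal, plane_origin=p.point,
        cap=False)
    if sliced is None or len(sliced.faces) == 0:
        raise EmptyResultError("cut removed the whole mesh")
    # the slicer emits one cut vertex per incident face; weld duplicates
    out = _weld(TriSurface.from_trimesh(sliced))
    return _drop_degenerate(out)


def _weld(mesh: TriSurface, tol: float = 1e-6) -> TriSurface:
    """Merge vertices coincident within ``tol`` (snap-to-grid keying)."""
    key = np.round(mesh.vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True,
                                  return_inverse=True)
    faces = inverse[mesh.faces]
    vl = None if mesh.vertex_labels is None else mesh.vertex_labels[first]
    return TriSurface(mesh.vertices[first], faces, vl, mesh.face_labels)


def _drop_degenerate(mesh: TriSurface, area_tol: float = 1e-10) -> TriSurface:
    a, b, c = (mesh.vertices[mesh.faces[:, i]] for i in range(3))
    areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    keep = areas > area_tol
    if keep.all():
        return mesh
    fl = None if mesh.face_labels is None else mesh.face_labels[keep]
    return TriSurface(mesh.vertices, mesh.faces[keep], mesh.vertex_labels, fl)


def ensure_outward_normals(mesh: TriSurface) -> TriSurface:
    """Flip winding if a closed mesh has negative signed volume."""
    tm = mesh.to_trimesh()
    if tm.is_watertight and tm.volume < 0:
        return TriSurface(mesh.vertices.copy(), mesh.faces[:, ::-1].copy(),
                          mesh.vertex_labels, mesh.face_labels)
    return mesh


def _smoothed_vertex_normals(mesh: TriSurface, iterations: int = 2) -> np.ndarray:
    tm = mesh.to_trimesh()
    normals = np.array(tm.vertex_normals, dtype=float)
    if iterations:
        adj = defaultdict(list)
        edges = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]],
                           mesh.faces[:, [2, 0]]])
        for a, b in edges:
            adj[int(a)].append(int(b))
            adj[int(b)].append(int(a))
        for _ in range(iterations):
            new = normals.copy()
            for v, nbrs in adj.items():
                new[v] = normals[v] + normals[nbrs].sum(axis=0)
            norms = np.linalg.norm(new, axis=1, keepdims=True)
            normals = new / np.maximum(norms, 1e-12)
    return normals


def offset_inward(mesh: TriSurface, distance: float) -> TriSurface:
    """Offset every vertex inward (against the outward normal) by ``distance``.

    Vertex normals are angle-weighted and lightly smoothed so the offset of
    a smooth convex surface stays within a small fraction of ``distance`` of
    the true parallel surface.  A zero distance is the identity.
    """
    if distance < 0:
        raise ConfigurationError("offset distance must be non-negative")
    if distance == 0:
        return mesh.copy()
    normals = _smoothed_vertex_normals(mesh)
    out = TriSurface(mesh.vertices - distance * normals, mesh.faces.copy(),
                     mesh.vertex_labels, mesh.face_labels)
    # collapse detection: face normals flipping against the originals, or a
    # closed surface turning inside-out (signed volume changing sign)
    def face_normals(m: TriSurface) -> np.ndarray:
        a, b, c = (m.vertices[m.faces[:, i]] for i in range(3))
        return np.cross(b - a, c - a)
    dots = np.einsum("ij,ij->i", face_normals(mesh), face_normals(out))
    if (dots <= 0).mean() > 0.01:
        raise OffsetError(
            f"offset of {distance} mm exceeds local feature size "
            f"({(dots <= 0).sum()} inverted faces)")
    tm_in = mesh.to_trimesh()
    if tm_in.is_watertight:
        v_in, v_out = tm_in.volume, out.to_trimesh().volume
        if v_in * v_out <= 0:
            raise OffsetError(
                f"offset of {distance} mm collapses the closed surface "
                f"(volume {v_in:.0f} -> {v_out:.0f} mm^3)")
    return out


def close_holes(mesh: TriSurface, keep_open_plane: Plane | None = None,
                keep_open_tol: float = 2.0) -> TriSurface:
    """Fill open boundary loops by centroid-fan triangulation.

    Loops whose vertices all lie within ``keep_open_tol`` mm of
    ``keep_open_plane`` (the base rim) are left open.  Winding of the fill
    triangles follows the surrounding surface.  Raises
    :class:`TopologyError` if the boundary is not a disjoint union of loops.
    """
    loops = mesh.boundary_loops()
    if not loops:
        return mesh.copy()
    directed = _directed_boundary_edges(mesh)
    vertices = [mesh.vertices]
    new_faces = []
    next_idx = mesh.n_vertices
    for loop in loops:
        if keep_open_plane is not None:
            d = np.abs(keep_open_plane.signed_distance(mesh.vertices[loop]))
            if (d < keep_open_tol).all():
                continue
        centroid = mesh.vertices[loop].mean(axis=0)
        vertices.append(centroid[None, :])
        loop_set = set(int(v) for v in loop)
        for a, b in directed:
            if a in loop_set and b in loop_set:
                new_faces.append([b, a, next_idx])
        next_idx += 1
    if not new_faces:
        return mesh.copy()
    v = np.vstack(vertices)
    f = np.vstack([mesh.faces, np.array(new_faces, dtype=np.int64)])
    fl = None
    if mesh.face_labels is not None:
        fl = np.concatenate([mesh.face_labels,
                             np.array(["fill"] * len(new_faces), dtype=object)])
    out = TriSurface(v, f, None, fl)
    if not out.is_edge_manifold():
        raise TopologyError("hole filling produced a non-manifold mesh")
    return out


def _directed_boundary_edges(mesh: TriSurface) -> set[tuple[int, int]]:
    """Directed edges that appear in exactly one face (no opposite twin)."""
    e = mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    fwd = set(map(tuple, e.tolist()))
    return {d for d in fwd if (d[1], d[0]) not in fwd}


def separate_inner_outer(closed_skull: TriSurface, base_plane: Plane,
                         rim_band: float | None = None,
                         ) -> tuple[TriSurface, TriSurface]:
    """Split a closed skull shell into inner and outer tables.

    The shell is closed except (possibly) at the base rim, where inner and
    outer surfaces are bridged.  Faces within ``rim_band`` mm of the base
    plane are peeled off; the two remaining connected components are
    classified by mean distance from the cavity centroid.
    """
    tm = closed_skull.to_trimesh()
    if rim_band is None:
        rim_band = max(2.0, 2.0 * float(tm.edges_unique_length.mean()))
    sd = np.abs(base_plane.signed_distance(closed_skull.vertices))
    face_min = sd[closed_skull.faces].min(axis=1)
    keep = face_min > rim_band
    if not keep.any():
        raise SeparationError("no faces left after removing the rim band")
    trimmed = trimesh.Trimesh(vertices=closed_skull.vertices,
                              faces=closed_skull.faces[keep], process=False)
    parts = trimmed.split(only_watertight=False)
    parts = [p for p in parts if len(p.faces) > 10]
    if len(parts) != 2:
        raise SeparationError(
            f"expected 2 connected components after rim removal, got {len(parts)}")
    centroid = closed_skull.vertices.mean(axis=0)
    radii = [float(np.linalg.norm(np.asarray(p.vertices) - centroid, axis=1).mean())
             for p in parts]
    outer_i = int(np.argmax(radii))
    outer = TriSurface.from_trimesh(parts[outer_i])
    inner = TriSurface.from_trimesh(parts[1 - outer_i])
    return inner, outer


# ---------------------------------------------------------------------------
# suture planes and regions
# ---------------------------------------------------------------------------

def suture_planes(frame: AnatomicalFrame, alpha: float, beta: float,
                  ab_frac: float, lp_frac: float,
                  max_height: float | None = None) -> tuple[Plane, Plane]:
    """Coronal and lambdoid suture planes from angles and AP fractions.

    The coronal plane passes through ``B = A + ab_frac (P - A)``,
    perpendicular to the midline plane, tilted so that in the midline the
    angle at B between the ray B->A and the cranial-going trace equals
    ``alpha``; the lambdoid plane mirrors this at ``L = P + lp_frac (A - P)``
    with angle ``beta`` against the ray L->P.  Coronal normal points
    anterior, lambdoid normal posterior.
    """
    if frame.A is None or frame.P is None:
        raise DegenerateGeometryError("frame must carry A/P points")
    if not (0 < alpha < 180 and 0 < beta < 180):
        raise ConfigurationError("suture angles must lie in (0, 180) degrees")
    if not (0 < ab_frac < 1 and 0 < lp_frac < 1) or ab_frac >= 1 - lp_frac:
        raise ConfigurationError(
            "suture fractions must satisfy 0 < ab_frac < 1 - lp_frac < 1")
    A, P = np.asarray(frame.A, float), np.asarray(frame.P, float)
    a_hat = frame.ap_direction            # posterior -> anterior
    u = frame.base_plane.normal           # cranial
    m = frame.midline_plane.normal        # lateral
    al, be = np.radians(alpha), np.radians(beta)
    B = A + ab_frac * (P - A)
    L = P + lp_frac * (A - P)
    t_cor = np.cos(al) * a_hat + np.sin(al) * u
    t_lam = -np.cos(be) * a_hat + np.sin(be) * u
    n_cor = np.cross(t_cor, m)
    if n_cor @ a_hat < 0:           # orient anterior
        n_cor = -n_cor
    n_lam = np.cross(m, t_lam)
    if n_lam @ a_hat > 0:           # orient posterior
        n_lam = -n_lam
    coronal = Plane(B, n_cor)
    lambdoid = Plane(L, n_lam)
    frame.B, frame.L = B, L
    if max_height is not None:
        apex = _trace_intersection_height(B, L, t_cor, t_lam, a_hat, u)
        if apex is not None and 0.0 < apex < max_height:
            raise ConfigurationError(
                f"suture planes intersect at height {apex:.1f} mm, below the "
                f"vertex ({max_height:.1f} mm); regions would be empty")
    return coronal, lambdoid


def _trace_intersection_height(B, L, t_cor, t_lam, a_hat, u):
    """Height above base of the traces' intersection, None if diverging."""
    # 2D coords in the midline plane: (s along a_hat, h along u)
    def to2d(v):
        return np.array([v @ a_hat, v @ u])
    b2, l2 = to2d(B), to2d(L)
    tc, tl2 = to2d(t_cor), to2d(t_lam)
    mat = np.column_stack([tc, -tl2])
    det = np.linalg.det(mat)
    if abs(det) < 1e-12:
        return None
    s, r = np.linalg.solve(mat, l2 - b2)
    if s <= 0 or r <= 0:
        return None
    return float((b2 + s * tc)[1])


def split_regions(mesh: TriSurface, coronal: Plane, lambdoid: Plane,
                  suture_width: float) -> TriSurface:
    """Split a skull shell into the five labelled regions.

    The two suture bands are the ribbons between the planes offset by
    half the suture width to either side; triangles straddling a band
    boundary are split so the bands have exact edges.
    """
    if suture_width <= 0:
        raise ConfigurationError("suture_width must be positive")
    w = 0.5 * suture_width
    parts: list[tuple[trimesh.Trimesh, str]] = []

    def _slice(m: trimesh.Trimesh, plane: Plane, sign: float) -> trimesh.Trimesh | None:
        if len(m.faces) == 0:
            return None
        normal = sign * plane.normal
        sd = (np.asarray(m.vertices) - plane.point) @ normal
        if sd.min() >= -GEOM_TOL:
            return m
        if sd.max() <= GEOM_TOL:
            return None
        out = trimesh.intersections.slice_mesh_plane(
            m, plane_normal=normal, plane_origin=plane.point, cap=False)
        return out if out is not None and len(out.faces) else None

    tm = mesh.to_trimesh()
    frontal = _slice(tm, coronal.offset(+w), +1.0)
    rest = _slice(tm, coronal.offset(+w), -1.0)
    band_c = _slice(rest, coronal.offset(-w), +1.0) if rest is not None else None
    rest2 = _slice(rest, coronal.offset(-w), -1.0) if rest is not None else None
    occipital = _slice(rest2, lambdoid.offset(+w), +1.0) if rest2 is not None else None
    rest3 = _slice(rest2, lambdoid.offset(+w), -1.0) if rest2 is not None else None
    band_l = _slice(rest3, lambdoid.offset(-w), +1.0) if rest3 is not None else None
    parietal = _slice(rest3, lambdoid.offset(-w), -1.0) if rest3 is not None else None
    for part, name in [(frontal, "frontal"), (band_c, "coronal_suture"),
                       (parietal, "parietal"), (band_l, "lambdoid_suture"),
                       (occipital, "occipital")]:
        if part is None or len(part.faces) == 0:
            raise ConfigurationError(f"region split produced an empty {name} region")
        parts.append((part, name))
    return _concat_merge(parts)


def _concat_merge(parts: list[tuple[trimesh.Trimesh, str]]) -> TriSurface:
    """Concatenate labelled parts, welding duplicated vertices exactly."""
    verts, faces, labels = [], [], []
    offset = 0
    for m, name in parts:
        verts.append(np.asarray(m.vertices, float))
        faces.append(np.asarray(m.faces, np.int64) + offset)
        labels.extend([name] * len(m.faces))
        offset += len(m.vertices)
    v = np.vstack(verts)
    f = np.vstack(faces)
    key = np.round(v / 1e-6).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True,
                                  return_inverse=True)
    v_out = v[first]
    f_out = inverse[f]
    out = TriSurface(v_out, f_out, face_labels=np.array(labels, dtype=object))
    return _drop_degenerate(out)


# ---------------------------------------------------------------------------
# osteotomies
# ---------------------------------------------------------------------------

def carve_osteotomies(model: TriSurface, frame: AnatomicalFrame,
                      spec: OsteotomySpec,
                      notch_size: float = 5.0) -> TriSurface:
    """Carve the two parasagittal osteotomy gaps and mark spring notches.

    The parietal region is sliced along the four kerf-boundary planes at
    +/- (lateral_offset +/- kerf/2) from the midline, so the gap's lateral
    edges are exact; strip faces between the AP extents are removed.  Four
    notch vertex sets are recorded in ``vertex_labels`` on the lateral gap
    boundaries at ``spec.notch_fractions`` of the cut length, keyed
    ``anterior_left/anterior_right/posterior_left/posterior_right``.
    """
    if model.face_labels is None:
        raise ConfigurationError("model must be region-labelled before carving")
    if frame.A is None or frame.P is None:
        raise DegenerateGeometryError("frame must carry A/P points")
    A, P = np.asarray(frame.A, float), np.asarray(frame.P, float)
    ap = P - A
    ap_len = float(np.linalg.norm(ap))
    m = frame.midline_plane.normal
    mid_pt = frame.midline_plane.point
    off, half_kerf = spec.lateral_offset, 0.5 * spec.kerf

    # any face crossing a kerf band inside the extent must be parietal
    vlat_all = (model.vertices - mid_pt) @ m
    flat = vlat_all[model.faces]
    cen_s = ((model.face_centroids() - A) @ ap) / ap_len**2
    in_extent = (cen_s > spec.anterior_extent) & (cen_s < spec.posterior_extent)
    any_band = np.zeros(model.n_faces, dtype=bool)
    for side in (+1.0, -1.0):
        lo, hi = side * off - half_kerf, side * off + half_kerf
        crosses = (flat.min(axis=1) < hi) & (flat.max(axis=1) > lo)
        sel = crosses & in_extent
        if not sel.any():
            raise ConfigurationError(
                "osteotomy band contains no faces; check lateral_offset/extents")
        if (model.face_labels[sel] != "parietal").any():
            bad = set(model.face_labels[sel]) - {"parietal"}
            raise ConfigurationError(
                f"osteotomy cut extends outside the parietal region into {sorted(bad)}")
        any_band |= sel

    # slice the parietal submesh along the four kerf-boundary planes
    par_sel = model.face_labels == "parietal"
    parts: list[tuple[trimesh.Trimesh, str]] = []
    for name in set(model.face_labels):
        if name == "parietal":
            continue
        sub = trimesh.Trimesh(vertices=model.vertices,
                              faces=model.faces[model.face_labels == name],
                              process=False)
        parts.append((sub, name))
    pieces = [trimesh.Trimesh(vertices=model.vertices,
                              faces=model.faces[par_sel], process=False)]
    for lat_plane in (-off - half_kerf, -off + half_kerf,
                      off - half_kerf, off + half_kerf):
        plane = Plane(mid_pt + lat_plane * m, m)
        new_pieces = []
        for piece in pieces:
            for sign in (+1.0, -1.0):
                sd = (np.asarray(piece.vertices) - plane.point) @ (sign * plane.normal)
                if sd.min() >= -GEOM_TOL:
                    new_pieces.append(piece)
                    continue
                if sd.max() <= GEOM_TOL:
                    continue
                cutp = trimesh.intersections.slice_mesh_plane(
                    piece, plane_normal=sign * plane.normal,
                    plane_origin=plane.point, cap=False)
                if cutp is not None and len(cutp.faces):
                    new_pieces.append(cutp)
        pieces = new_pieces
    for piece in pieces:
        cen = np.asarray(piece.triangles_center)
        lat_mid = float(((cen - mid_pt) @ m).mean())
        if abs(abs(lat_mid) - off) < half_kerf:     # a kerf strip
            s_vals = ((cen - A) @ ap) / ap_len**2
            keep = ~((s_vals > spec.anterior_extent)
                     & (s_vals < spec.posterior_extent))
            if keep.any():
                parts.append((trimesh.Trimesh(vertices=piece.vertices,
                                              faces=np.asarray(piece.faces)[keep],
                                              process=False), "parietal"))
        else:
            parts.append((piece, "parietal"))
    carved = _concat_merge(parts)
    carved = _heal_t_vertices(carved)
    carved = improve_quality(carved)
    carved = _prune_unused_vertices(carved)

    # notch markers on the lateral gap boundaries
    boundary_v = _boundary_vertices(carved)
    vl = np.array([""] * carved.n_vertices, dtype=object)
    vlat = (carved.vertices - mid_pt) @ m
    vs = ((carved.vertices - A) @ ap) / ap_len**2
    height = frame.base_plane.signed_distance(carved.vertices)
    hmax = float(height.max())
    cut_len = spec.posterior_extent - spec.anterior_extent
    left_sign = 1.0 if (frame.tragion_left - frame.nasion) @ m > 0 else -1.0
    for side in (+1.0, -1.0):
        side_name = "left" if side == left_sign else "right"
        lateral_side = (boundary_v & (vlat * side > off)
                        & (vlat * side < off + half_kerf + 1e-6)
                        & (height > 0.25 * hmax))
        for frac, pos_name in zip(spec.notch_fractions, ("anterior", "posterior")):
            s_target = spec.anterior_extent + frac * cut_len
            near = lateral_side & (np.abs(vs - s_target) * ap_len < notch_size)
            if not near.any():
                raise ConfigurationError(
                    f"no boundary vertices found for notch {pos_name}_{side_name}")
            vl[near] = f"notch_{pos_name}_{side_name}"
    carved.vertex_labels = vl
    return carved


def improve_quality(mesh: TriSurface, min_quality: float = 0.05,
                    max_passes: int = 6) -> TriSurface:
    """Collapse the short edges of sliver triangles left by plane slicing.

    Quality is the normalised radius ratio 4*sqrt(3)*A / sum(l^2) (1 for
    equilateral).  Collapses obey a link condition (no non-manifold pinch)
    and keep boundary geometry: an edge with one boundary endpoint
    collapses onto it, interior edges onto the midpoint; edges joining two
    boundary vertices collapse only if the edge itself is on the boundary.
    Labels survive; vertex labels merge (non-empty wins).
    """
    for _ in range(max_passes):
        tri = mesh.vertices[mesh.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        edge_vec = np.stack([tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 1],
                             tri[:, 0] - tri[:, 2]])
        l2 = (edge_vec**2).sum(axis=2)
        quality = 4 * np.sqrt(3.0) * areas / np.maximum(l2.sum(axis=0), 1e-30)
        bad = np.flatnonzero(quality < min_quality)
        if len(bad) == 0:
            return mesh
        # adjacency for the link condition
        from collections import defaultdict
        nbrs: dict[int, set[int]] = defaultdict(set)
        for f in mesh.faces:
            for i in range(3):
                a, b = int(f[i]), int(f[(i + 1) % 3])
                nbrs[a].add(b)
                nbrs[b].add(a)
        edges_sorted = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2),
                               axis=1)
        uniq, counts = np.unique(edges_sorted, axis=0, return_counts=True)
        boundary_edges = {tuple(e) for e in uniq[counts == 1]}
        is_boundary_v = _boundary_vertices(mesh)
        edge_faces: dict[tuple[int, int], list[int]] = defaultdict(list)
        for fi, f in enumerate(mesh.faces):
            for i in range(3):
                a, b = int(f[i]), int(f[(i + 1) % 3])
                edge_faces[(min(a, b), max(a, b))].append(fi)
        merged = np.arange(mesh.n_vertices)
        new_pos = mesh.vertices.copy()
        touched: set[int] = set()
        for fi in bad[np.argsort(quality[bad])]:
            f = mesh.faces[fi]
            if any(int(v) in touched for v in f):
                continue
            # shortest edge of this face
            ls = [l2[k, fi] for k in range(3)]
            k = int(np.argmin(ls))
            a, b = int(f[k]), int(f[(k + 1) % 3])
            key = (min(a, b), max(a, b))
            ba, bb = bool(is_boundary_v[a]), bool(is_boundary_v[b])
            if ba and bb and key not in boundary_edges:
                continue
            # link condition: shared neighbours must be the edge's wings
            wings = set()
            for fj in edge_faces[key]:
                wings.update(int(v) for v in mesh.faces[fj])
            wings -= {a, b}
            if nbrs[a] & nbrs[b] != wings:
                continue
            if ba and not bb:
                keep, drop = a, b
            elif bb and not ba:
                keep, drop = b, a
            else:
                keep, drop = a, b
                if not (ba and bb):
                    new_pos[keep] = 0.5 * (mesh.vertices[a] + mesh.vertices[b])
            merged[drop] = keep
            if (mesh.vertex_labels is not None
                    and not mesh.vertex_labels[keep]
                    and mesh.vertex_labels[drop]):
                mesh.vertex_labels[keep] = mesh.vertex_labels[drop]
            touched.update((a, b))
        if not touched:
            return mesh
        faces = merged[mesh.faces]
        ok = ((faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2])
              & (faces[:, 2] != faces[:, 0]))
        fl = None if mesh.face_labels is None else mesh.face_labels[ok]
        mesh = _prune_unused_vertices(
            TriSurface(new_pos, faces[ok], mesh.vertex_labels, fl))
        mesh = _drop_degenerate(mesh, area_tol=1e-8)
    return mesh


def _boundary_vertices(mesh: TriSurface) -> np.ndarray:
    """Boolean mask of vertices lying on a once-used (boundary) edge."""
    edges = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    mask[np.unique(uniq[counts == 1])] = True
    return mask


def _heal_t_vertices(mesh: TriSurface, tol: float = 1e-5,
                     max_rounds: int = 4) -> TriSurface:
    """Split faces whose boundary edge passes through another boundary vertex.

    Slicing one region along a plane that crosses a neighbouring region's
    border inserts vertices on the shared polyline on one side only;
    splitting the neighbouring face at that point restores watertight
    connectivity.
    """
    for _ in range(max_rounds):
        edges = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        uniq, inv, counts = np.unique(edges, axis=0, return_inverse=True,
                                      return_counts=True)
        b_edge_rows = np.flatnonzero(counts[inv] == 1)   # rows into edges
        if len(b_edge_rows) == 0:
            return mesh
        b_vertex_idx = np.unique(edges[b_edge_rows])
        from scipy.spatial import cKDTree
        tree = cKDTree(mesh.vertices[b_vertex_idx])
        new_faces = []
        replaced = np.zeros(mesh.n_faces, dtype=bool)
        new_labels = []
        for row in b_edge_rows:
            face_i, corner = divmod(int(row), 3)
            if replaced[face_i]:
                continue
            a, b = edges[row]
            pa, pb = mesh.vertices[a], mesh.vertices[b]
            d = pb - pa
            length = np.linalg.norm(d)
            if length < tol:
                continue
            mid = 0.5 * (pa + pb)
            cand = tree.query_ball_point(mid, r=0.5 * length + tol)
            split_at = None
            for ci in cand:
                t_idx = int(b_vertex_idx[ci])
                if t_idx in (int(a), int(b)):
                    continue
                pt = mesh.vertices[t_idx]
                u = (pt - pa) @ d / length**2
                if tol / length < u < 1 - tol / length:
                    if np.linalg.norm(pa + u * d - pt) < tol:
                        split_at = t_idx
                        break
            if split_at is None:
                continue
            f = mesh.faces[face_i]
            # rotate so the boundary edge is (f0, f1)
            for shift in range(3):
                g = np.roll(f, -shift)
                if {int(g[0]), int(g[1])} == {int(a), int(b)}:
                    break
            new_faces.append([g[0], split_at, g[2]])
            new_faces.append([split_at, g[1], g[2]])
            if mesh.face_labels is not None:
                new_labels.extend([mesh.face_labels[face_i]] * 2)
            replaced[face_i] = True
        if not new_faces:
            return mesh
        faces = np.vstack([mesh.faces[~replaced],
                           np.array(new_faces, dtype=np.int64)])
        fl = None
        if mesh.face_labels is not None:
            fl = np.concatenate([mesh.face_labels[~replaced],
                                 np.array(new_labels, dtype=object)])
        mesh = TriSurface(mesh.vertices, faces, mesh.vertex_labels, fl)
    return mesh


def _prune_unused_vertices(mesh: TriSurface) -> TriSurface:
    used = np.unique(mesh.faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    vl = None if mesh.vertex_labels is None else mesh.vertex_labels[used]
    return TriSurface(mesh.vertices[used], remap[mesh.faces], vl,
                      mesh.face_labels)


def notch_sets(model: TriSurface) -> dict[str, np.ndarray]:
    """Vertex-index sets of the four spring notches, keyed by NOTCH_KEYS."""
    if model.vertex_labels is None:
        return {}
    out = {}
    for key in NOTCH_KEYS:
        idx = np.flatnonzero(model.vertex_labels == f"notch_{key}")
        if len(idx):
            out[key] = idx
    return out


def uniform_scale(mesh: TriSurface, factor: float) -> TriSurface:
    """Uniform scaling about the mesh centroid (growth-adjustment utility)."""
    if factor <= 0:
        raise ConfigurationError("scale factor must be positive")
    c = mesh.vertices.mean(axis=0)
    return TriSurface(c + factor * (mesh.vertices - c), mesh.faces.copy(),
                      mesh.vertex_labels, mesh.face_labels)
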