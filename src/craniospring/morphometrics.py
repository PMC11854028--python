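"""Measurement operators.

Tissue thickness as local surface distance, suture-plane geometry (the
coronal angle alpha = A-B-Bregma, the lambdoid angle beta = P-L-Lambda and
the AB/AP, LP/AP fractions), population averaging, and the outcome metrics
BPD / OFD / cranial index.

Surface distance is unsigned nearest-point distance (point to triangle),
computed with a KD-tree candidate search plus exact point-triangle
projection.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .errors import (ConfigurationError, DegenerateGeometryError,
                     EmptyResultError)
from .types import (AnatomicalFrame, Plane, PopulationParams, ShapeMetrics,
                    SutureGeometry, ThicknessMap, TriSurface)

NOMINAL_SPRING_LENGTH = 60.0  # mm, fully open distractor


# ---------------------------------------------------------------------------
# nearest surface distance
# ---------------------------------------------------------------------------

def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distance from points ``p`` (n,3) to triangles ``tri`` (n,k,3,3).

    Vectorised closest-point-on-triangle (region classification via
    barycentric clamping).  Returns (n, k) distances.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    p = p[:, None, :]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    v = np.where(np.abs(denom) > 1e-30, vb / np.where(denom == 0, 1, denom), 0.0)
    w = np.where(np.abs(denom) > 1e-30, vc / np.where(denom == 0, 1, denom), 0.0)
    # interior projection
    closest = a + v[..., None] * ab + w[..., None] * ac
    # vertex regions
    closest = np.where((d1 <= 0)[..., None] & (d2 <= 0)[..., None], a, closest)
    closest = np.where((d3 >= 0)[..., None] & (d4 <= d3)[..., None], b, closest)
    closest = np.where((d6 >= 0)[..., None] & (d5 <= d6)[..., None], c, closest)
    # edge AB
    vab = d1 / np.where(d1 - d3 == 0, 1, d1 - d3)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(on_ab[..., None], a + np.clip(vab, 0, 1)[..., None] * ab,
                       closest)
    # edge AC
    wac = d2 / np.where(d2 - d6 == 0, 1, d2 - d6)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(on_ac[..., None], a + np.clip(wac, 0, 1)[..., None] * ac,
                       closest)
    # edge BC
    wbc = (d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, 1,
                               (d4 - d3) + (d5 - d6))
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest = np.where(on_bc[..., None],
                       b + np.clip(wbc, 0, 1)[..., None] * (c - b), closest)
    return np.linalg.norm(p - closest, axis=-1)


def nearest_surface_distance(points: np.ndarray, surface: TriSurface,
                             k: int = 12) -> np.ndarray:
    """Unsigned nearest distance from each point to the triangulated surface."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if surface.n_faces == 0:
        raise EmptyResultError("target surface has no faces")
    centroids = surface.face_centroids()
    tree = cKDTree(centroids)
    k = min(k, surface.n_faces)
    _, idx = tree.query(points, k=k)
    if k == 1:
        idx = idx[:, None]
    tri = surface.vertices[surface.faces[idx]]
    d = _point_triangle_distance(points, tri)
    return d.min(axis=1)


# ---------------------------------------------------------------------------
# thickness
# ---------------------------------------------------------------------------

def crop_plane_at_fraction(mesh: TriSurface, base_plane: Plane,
                           fraction: float) -> Plane:
    """Plane parallel to the base, raised by ``fraction`` of the mesh height."""
    if not 0.0 <= fraction < 1.0:
        raise ConfigurationError("crop fraction must lie in [0, 1)")
    h = base_plane.signed_distance(mesh.vertices)
    hmax = float(h.max())
    if hmax <= 0:
        raise DegenerateGeometryError("mesh lies entirely below the base plane")
    return base_plane.offset(fraction * hmax)


def thickness_between(surface_a: TriSurface, surface_b: TriSurface,
                      crop_plane: Plane) -> ThicknessMap:
    """Local surface distance from ``surface_a`` to ``surface_b``.

    Only vertices of ``surface_a`` above ``crop_plane`` enter the map (the
    crop excludes skull base and orbits from the statistics).
    """
    above = crop_plane.signed_distance(surface_a.vertices) > 0
    if not above.any():
        raise EmptyResultError("no vertices above the crop plane")
    idx = np.flatnonzero(above)
    d = nearest_surface_distance(surface_a.vertices[idx], surface_b)
    return ThicknessMap(distances=d, crop_plane=crop_plane, vertex_indices=idx)


# ---------------------------------------------------------------------------
# AP points and suture geometry
# ---------------------------------------------------------------------------

def find_ap_points(mesh: TriSurface, base_plane: Plane,
                   anterior_hint: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Most anterior (A) / posterior (P) points of the mesh in the base plane.

    ``anterior_hint`` is any vector with a positive component toward the
    front (the nasion minus the tragion midpoint).  Candidate points come
    from the mesh/plane section and from boundary vertices lying on the
    plane; A and P are the extremes along the in-plane anterior direction,
    projected exactly onto the plane.
    """
    hint = np.asarray(anterior_hint, dtype=float)
    a_dir = hint - (hint @ base_plane.normal) * base_plane.normal
    nrm = np.linalg.norm(a_dir)
    if nrm < 1e-9:
        raise DegenerateGeometryError("anterior hint is parallel to base normal")
    a_dir /= nrm
    candidates = []
    sd = base_plane.signed_distance(mesh.vertices)
    on_plane = np.abs(sd) < 1e-3
    if on_plane.any():
        candidates.append(mesh.vertices[on_plane])
    try:
        section = mesh.to_trimesh().section(plane_origin=base_plane.point,
                                            plane_normal=base_plane.normal)
        if section is not None and len(section.vertices):
            candidates.append(np.asarray(section.vertices, dtype=float))
    except Exception:
        pass
    if not candidates:
        # open rim slightly off the plane (e.g. after an inward offset):
        # fall back to the boundary vertices nearest the plane
        from .geometry import _boundary_vertices
        rim = _boundary_vertices(mesh)
        if rim.any():
            d = np.abs(sd[rim])
            near_rim = rim & (np.abs(sd) < max(5.0, 2.0 * d.min() + 1.0))
            if near_rim.any():
                candidates.append(mesh.vertices[near_rim])
    if not candidates:
        raise EmptyResultError("mesh section with the base plane is empty")
    pts = np.vstack(candidates)
    pts = pts - np.outer(base_plane.signed_distance(pts), base_plane.normal)
    t = pts @ a_dir
    return pts[int(np.argmax(t))], pts[int(np.argmin(t))]


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise DegenerateGeometryError("zero-length vector in angle computation")
    c = np.clip((u @ v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def measure_suture_geometry(frame: AnatomicalFrame) -> SutureGeometry:
    """Suture angles and fractions from a fully-populated frame.

    Requires A, P, bregma, lambda and the suture feet B, L on segment AP.
    alpha is the angle at B in triangle A-B-Bregma, beta the angle at L in
    P-L-Lambda.
    """
    for name in ("A", "P", "B", "L", "bregma", "lambda_pt"):
        if getattr(frame, name) is None:
            raise DegenerateGeometryError(f"frame is missing point {name}")
    A, P = np.asarray(frame.A, float), np.asarray(frame.P, float)
    B, L = np.asarray(frame.B, float), np.asarray(frame.L, float)
    ap = np.linalg.norm(P - A)
    if ap < 1e-9:
        raise DegenerateGeometryError("A and P coincide")
    alpha = _angle_deg(A - B, np.asarray(frame.bregma, float) - B)
    beta = _angle_deg(P - L, np.asarray(frame.lambda_pt, float) - L)
    return SutureGeometry(alpha=alpha, beta=beta,
                          ab_frac=float(np.linalg.norm(B - A) / ap),
                          lp_frac=float(np.linalg.norm(L - P) / ap))


def measure_suture_geometry_on_model(model: TriSurface,
                                     frame: AnatomicalFrame,
                                     midline_tol: float | None = None,
                                     ) -> SutureGeometry:
    """Measure suture geometry from a region-labelled skull model.

    Each suture band is reduced to its least-squares plane (SVD of the band
    face centroids); the feet B/L are the plane's intersections with segment
    AP, and bregma/lambda are taken as the topmost band vertices near the
    midline.  This is the measurement counterpart of the plane-based
    construction, usable on any labelled model.
    """
    if model.face_labels is None:
        raise ConfigurationError("model carries no region labels")
    if frame.A is None or frame.P is None:
        raise DegenerateGeometryError("frame must carry A/P points")
    A, P = np.asarray(frame.A, float), np.asarray(frame.P, float)
    ap = P - A
    ap_len = float(np.linalg.norm(ap))
    if midline_tol is None:
        tm = model.to_trimesh()
        midline_tol = 2.0 * float(tm.edges_unique_length.mean())
    feet: dict[str, np.ndarray] = {}
    tops: dict[str, np.ndarray] = {}
    for band in ("coronal_suture", "lambdoid_suture"):
        sel = model.face_labels == band
        if not sel.any():
            raise EmptyResultError(f"model has no {band} faces")
        cen = model.vertices[model.faces[sel]].mean(axis=1)
        c0 = cen.mean(axis=0)
        _, _, vh = np.linalg.svd(cen - c0, full_matrices=False)
        normal = vh[-1]
        denom = ap @ normal
        if abs(denom) < 1e-9:
            raise DegenerateGeometryError(f"{band} plane is parallel to AP")
        t = ((c0 - A) @ normal) / denom
        feet[band] = A + t * ap
        # topmost band vertex near the midline
        vids = np.unique(model.faces[sel])
        pts = model.vertices[vids]
        near = np.abs(frame.midline_plane.signed_distance(pts)) < midline_tol
        if not near.any():
            near = np.ones(len(pts), dtype=bool)
        h = frame.base_plane.signed_distance(pts[near])
        top = pts[near][int(np.argmax(h))]
        # project onto the fitted mid-plane: a band vertex sits anywhere in
        # the +/- width/2 ribbon, which would bias the angle at ~60 mm range
        tops[band] = top - ((top - c0) @ normal) * normal
    B, L = feet["coronal_suture"], feet["lambdoid_suture"]
    alpha = _angle_deg(A - B, tops["coronal_suture"] - B)
    beta = _angle_deg(P - L, tops["lambdoid_suture"] - L)
    frame.B, frame.L = B, L
    frame.bregma = tops["coronal_suture"]
    frame.lambda_pt = tops["lambdoid_suture"]
    return SutureGeometry(alpha=alpha, beta=beta,
                          ab_frac=float(np.linalg.norm(B - A) / ap_len),
                          lp_frac=float(np.linalg.norm(L - P) / ap_len))


def suture_band_width(model: TriSurface, band: str = "coronal_suture",
                      ) -> float:
    """Mean on-surface width of a suture band: band area / centreline length.

    The centreline length is estimated from the least-squares plane section
    through the band (the polyline of band-edge midpoints projected onto the
    fitted plane), implemented as the length of the band's intersection with
    its own fitted mid-plane.
    """
    if model.face_labels is None:
        raise ConfigurationError("model carries no region labels")
    sel = model.face_labels == band
    if not sel.any():
        raise EmptyResultError(f"model has no {band} faces")
    sub = TriSurface(model.vertices, model.faces[sel])
    area = sub.area()
    cen = sub.face_centroids()
    c0 = cen.mean(axis=0)
    _, _, vh = np.linalg.svd(cen - c0, full_matrices=False)
    normal = vh[-1]
    section = sub.to_trimesh().section(plane_origin=c0, plane_normal=normal)
    if section is None or len(section.vertices) == 0:
        raise EmptyResultError(f"cannot section the {band} band")
    length = float(sum(e.length(section.vertices) for e in section.entities))
    if length <= 0:
        raise EmptyResultError(f"degenerate {band} centreline")
    return area / length


# ---------------------------------------------------------------------------
# population averaging
# ---------------------------------------------------------------------------

@dataclass
class SubjectMeasurement:
    """One subject's thickness maps and suture geometry."""

    skin: ThicknessMap
    skull: ThicknessMap
    suture: SutureGeometry


def population_average(measurements: list[SubjectMeasurement],
                       suture_width: float = 2.0) -> PopulationParams:
    """Arithmetic mean (sd reported) of each measured field across subjects."""
    if not measurements:
        raise ConfigurationError("population_average requires >= 1 measurement")
    skin = np.array([m.skin.mean for m in measurements])
    skull = np.array([m.skull.mean for m in measurements])
    alpha = np.array([m.suture.alpha for m in measurements])
    beta = np.array([m.suture.beta for m in measurements])
    ab = np.array([m.suture.ab_frac for m in measurements])
    lp = np.array([m.suture.lp_frac for m in measurements])

    def sd(x: np.ndarray) -> float:
        return float(x.std(ddof=1)) if len(x) > 1 else 0.0

    return PopulationParams(
        skin_thickness=float(skin.mean()), skull_thickness=float(skull.mean()),
        suture=SutureGeometry(alpha=float(alpha.mean()), beta=float(beta.mean()),
                              ab_frac=float(ab.mean()), lp_frac=float(lp.mean())),
        suture_width=suture_width,
        skin_thickness_sd=sd(skin), skull_thickness_sd=sd(skull),
        alpha_sd=sd(alpha), beta_sd=sd(beta))


# ---------------------------------------------------------------------------
# outcome metrics
# ---------------------------------------------------------------------------

def shape_metrics(mesh: TriSurface, frame: AnatomicalFrame) -> ShapeMetrics:
    """BPD / OFD / CI of the supra-base-plane surface.

    OFD is the maximal extent along the AP direction, BPD the maximal
    extent along the midline-plane normal, both over vertices on or above
    the base plane.
    """
    sd = frame.base_plane.signed_distance(mesh.vertices)
    above = sd >= -1e-6
    if not above.any():
        raise EmptyResultError("mesh has no vertices above the base plane")
    v = mesh.vertices[above]
    a_dir = frame.ap_direction if frame.A is not None else None
    if a_dir is None:
        hint = frame.nasion - 0.5 * (frame.tragion_left + frame.tragion_right)
        a_dir = hint - (hint @ frame.base_plane.normal) * frame.base_plane.normal
        a_dir = a_dir / np.linalg.norm(a_dir)
    t_ap = v @ a_dir
    t_lat = v @ frame.midline_plane.normal
    return ShapeMetrics(BPD=float(t_lat.max() - t_lat.min()),
                        OFD=float(t_ap.max() - t_ap.min()))


def spring_opening_percent(opening: float,
                           nominal: float = NOMINAL_SPRING_LENGTH) -> float:
    """Opening as percent of the nominal (fully open) distractor length."""
    if nominal <= 0:
        raise ConfigurationError("nominal spring length must be positive")
    if opening < 0:
        raise ConfigurationError("spring opening must be non-negative")
    return 100.0 * opening / nominal


def spearman_rho(series_a, series_b) -> tuple[float, float]:
    """Spearman rank correlation with exact permutation p for small n.

    For n <= 9 the two-sided p-value enumerates all rank permutations;
    larger samples use the t-approximation.  Constant input raises
    :class:`ConfigurationError` (the correlation is undefined).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ConfigurationError("need two equal-length series of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConfigurationError("constant series: correlation undefined")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    n = len(a)
    rho = float(np.corrcoef(ra, rb)[0, 1])
    if n <= 9:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in permutations(range(n)):
            r = np.corrcoef(ra, rb[list(perm)])[0, 1]
            if abs(r) >= target:
                count += 1
            total += 1
        p = count / total
    else:
        p = float(stats.spearmanr(a, b).pvalue)
    return rho, p
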