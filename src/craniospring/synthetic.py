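"""Deterministic synthetic phantoms.

Scaphocephalic head surfaces (elongated, CI < 1 superellipsoids with
analytic landmarks), two-layer skin/skull phantoms with known thickness,
and small synthetic populations.  These stand in for patient scans, which
cannot be shipped: every downstream module is exercised against phantoms
whose ground truth is known by construction.
"""
from __future__ import annotations

import numpy as np
import trimesh
from scipy.optimize import brentq

from .errors import ConfigurationError
from .geometry import make_frame, suture_planes
from .types import AnatomicalFrame, PhantomSpec, SutureGeometry, TriSurface

#: lower half-axis of the phantom as a fraction of its height (how far the
#: closed surface continues below the widest cross-section)
LOWER_FRACTION = 0.55


def _half_axes(spec: PhantomSpec) -> tuple[float, float, float, float, float]:
    """(a lateral, b anterior-posterior, c_up, c_dn, z0 equator height)."""
    a = spec.bpd / 2.0
    b = spec.ofd / 2.0
    z0 = spec.bulge_frac * spec.height
    c_up = spec.height - z0
    c_dn = max(LOWER_FRACTION * spec.height, z0 + 0.1 * spec.height)
    return a, b, c_up, c_dn, z0


def _superellipsoid_radius(directions: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Radial distance (about the equator centre) along unit ``directions``.

    The equator — the widest cross-section, at the parietal-eminence level
    ``bulge_frac * height`` above the base plane — has half-axes
    (bpd/2, ofd/2); the upper half reaches the vertex, the lower half
    closes the surface below the base plane.
    """
    a, b, c_up, c_dn, _ = _half_axes(spec)
    p = spec.squareness
    d = np.asarray(directions, dtype=float)
    c = np.where(d[..., 2] >= 0, c_up, c_dn)
    val = (np.abs(d[..., 0] / a) ** p + np.abs(d[..., 1] / b) ** p
           + np.abs(d[..., 2] / c) ** p)
    return val ** (-1.0 / p)


def _subdivisions_for(spec: PhantomSpec) -> int:
    r_char = (spec.bpd / 2 + spec.ofd / 2 + spec.height) / 3.0
    # icosahedron edge on the unit sphere is ~1.05; halves per subdivision
    s = int(np.ceil(np.log2(max(1.05 * r_char / spec.mesh_resolution, 1e-6))))
    if s < 2:
        raise ConfigurationError(
            f"mesh resolution {spec.mesh_resolution} mm is too coarse for a "
            f"{r_char:.0f} mm head (< 50 faces)")
    return min(s, 7)


def generate_head(spec: PhantomSpec) -> tuple[TriSurface, dict[str, np.ndarray]]:
    """Closed superellipsoidal head surface plus analytic landmarks.

    The base (nasion-tragion) plane is z = 0; above it the surface has
    extents (ofd, bpd, height).  Landmarks: nasion at the anterior pole of
    the base section, tragions at the lateral poles (left = +x), bregma and
    lambda on the midline where the configured suture planes meet the
    surface.  Deterministic given the spec (the seed only drives optional
    vertex jitter).
    """
    base = trimesh.creation.icosphere(subdivisions=_subdivisions_for(spec),
                                      radius=1.0)
    if len(base.faces) < 50:
        raise ConfigurationError("mesh resolution too coarse (< 50 faces)")
    dirs = np.asarray(base.vertices, dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    # tilt the sampling sphere so no vertex ring coincides with the base
    # plane (an exact tangency makes the base cut's rim non-manifold);
    # the sampled analytic surface itself is unchanged
    ang = np.radians(2.0)
    rot = np.array([[1.0, 0.0, 0.0],
                    [0.0, np.cos(ang), -np.sin(ang)],
                    [0.0, np.sin(ang), np.cos(ang)]])
    dirs = dirs @ rot.T
    r = _superellipsoid_radius(dirs, spec)
    a, b, c_up, c_dn, z0 = _half_axes(spec)
    centre = np.array([0.0, 0.0, z0])
    vertices = centre + dirs * r[:, None]
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        vertices = vertices + rng.normal(0.0, spec.jitter, vertices.shape)
    mesh = TriSurface(vertices, np.asarray(base.faces, dtype=np.int64))

    # landmarks sit on the base plane z = 0, which cuts the lower half of
    # the superellipsoid `z0` below its equator
    shrink = (1.0 - (z0 / c_dn) ** spec.squareness) ** (1.0 / spec.squareness)
    y_n = b * shrink
    x_t = a * shrink
    # left = -x so that (tl - nasion) x (tr - nasion) points cranially (+z)
    landmarks = {
        "nasion": np.array([0.0, y_n, 0.0]),
        "tragion_left": np.array([-x_t, 0.0, 0.0]),
        "tragion_right": np.array([x_t, 0.0, 0.0]),
    }
    frame = make_frame(**{k: landmarks[k] for k in
                          ("nasion", "tragion_left", "tragion_right")})
    frame.A = np.array([0.0, y_n, 0.0])
    frame.P = np.array([0.0, -y_n, 0.0])
    coronal, lambdoid = suture_planes(frame, spec.suture.alpha,
                                      spec.suture.beta, spec.suture.ab_frac,
                                      spec.suture.lp_frac)
    landmarks["bregma"] = _trace_surface_point(frame.B, _cranial_trace(
        frame, spec.suture.alpha, anterior=True), spec)
    landmarks["lambda"] = _trace_surface_point(frame.L, _cranial_trace(
        frame, spec.suture.beta, anterior=False), spec)
    return mesh, landmarks


def _cranial_trace(frame: AnatomicalFrame, angle_deg: float,
                   anterior: bool) -> np.ndarray:
    """Unit direction of a suture plane's cranial-going midline trace."""
    ang = np.radians(angle_deg)
    a_hat = frame.ap_direction
    u = frame.base_plane.normal
    sign = 1.0 if anterior else -1.0
    return sign * np.cos(ang) * a_hat + np.sin(ang) * u


def _trace_surface_point(origin: np.ndarray, direction: np.ndarray,
                         spec: PhantomSpec) -> np.ndarray:
    """Where the ray origin + t * direction pierces the phantom surface."""
    _, _, _, _, z0 = _half_axes(spec)
    centre = np.array([0.0, 0.0, z0])

    def f(t: float) -> float:
        q = origin + t * direction - centre
        nrm = np.linalg.norm(q)
        if nrm < 1e-12:
            return -1.0
        return nrm - float(_superellipsoid_radius(q[None] / nrm, spec)[0])
    t_hi = 4.0 * (spec.ofd + spec.height)
    return origin + brentq(f, 1e-6, t_hi) * direction


def generate_two_layer(spec: PhantomSpec,
                       ) -> tuple[TriSurface, TriSurface, TriSurface]:
    """Skin surface plus skull outer/inner tables with known thicknesses.

    ``skull_outer`` is the skin offset inward by ``spec.skin_thickness``;
    ``skull_inner`` offsets further by ``spec.skull_thickness``, so the true
    layer thicknesses are known exactly by construction.
    """
    from .geometry import offset_inward
    skin, _ = generate_head(spec)
    skull_outer = offset_inward(skin, spec.skin_thickness)
    skull_inner = offset_inward(skull_outer, spec.skull_thickness)
    return skin, skull_outer, skull_inner


#: default sampling distributions, centred on the cohort averages
DEFAULT_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "ofd": (125.0, 5.0),
    "bpd": (96.0, 4.0),
    "height": (55.0, 3.0),
    "skin_thickness": (2.8, 0.4),
    "skull_thickness": (2.5, 0.4),
    "alpha": (83.0, 4.0),
    "beta": (68.0, 3.0),
    "ab_frac": (0.30, 0.02),
    "lp_frac": (0.25, 0.02),
}


def generate_population(n: int,
                        distributions: dict[str, tuple[float, float]] | None = None,
                        seed: int = 0) -> list[PhantomSpec]:
    """Draw ``n`` phantom specs from normal parameter distributions.

    ``distributions`` maps parameter name to (mean, sd); unspecified
    parameters use :data:`DEFAULT_DISTRIBUTIONS`.  Draws violating the
    spec invariants (e.g. bpd >= ofd) are rejected and redrawn.
    """
    if n < 1:
        raise ConfigurationError("population size must be >= 1")
    dists = dict(DEFAULT_DISTRIBUTIONS)
    if distributions:
        for key, val in distributions.items():
            if key not in dists:
                raise ConfigurationError(f"unknown population parameter {key!r}")
            mean, sd = val
            if sd < 0:
                raise ConfigurationError(f"negative sd for {key!r}")
            dists[key] = (float(mean), float(sd))
    rng = np.random.default_rng(seed)
    specs: list[PhantomSpec] = []
    for i in range(n):
        for _attempt in range(200):
            draw = {k: rng.normal(m, s) if s > 0 else m
                    for k, (m, s) in dists.items()}
            try:
                spec = PhantomSpec(
                    ofd=draw["ofd"], bpd=draw["bpd"], height=draw["height"],
                    skin_thickness=draw["skin_thickness"],
                    skull_thickness=draw["skull_thickness"],
                    suture=SutureGeometry(alpha=draw["alpha"], beta=draw["beta"],
                                          ab_frac=draw["ab_frac"],
                                          lp_frac=draw["lp_frac"]),
                    seed=seed + i)
            except ValueError:
                continue
            specs.append(spec)
            break
        else:
            raise ConfigurationError(
                "could not draw a valid phantom spec; check distribution bounds")
    return specs
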