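"""Core domain types.

Units are millimetres for all lengths and degrees for all angles at the API
surface; internal trigonometry uses radians.  The coordinate frame is the one
the landmark file is expressed in; meshes are assumed co-registered with it.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import trimesh

from .errors import DegenerateGeometryError, TopologyError

GEOM_TOL = 1e-6  # mm, geometric coincidence
DEGEN_EDGE = 1e-4  # mm, edges shorter than this are collapsed by cleanup

__all__ = [
    "GEOM_TOL",
    "TriSurface",
    "Plane",
    "AnatomicalFrame",
    "SutureGeometry",
    "PopulationParams",
    "ThicknessMap",
    "ShapeMetrics",
    "OsteotomySpec",
    "Material",
    "SpringElement",
    "PhantomSpec",
]


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError("zero-length vector cannot be normalised")
    return v / n


@dataclass
class TriSurface:
    """Indexed triangle mesh with optional per-vertex / per-face region tags.

    ``vertices`` is (n, 3) float64 in mm, ``faces`` (m, 3) int vertex
    triples.  Labels are string arrays aligned with vertices/faces; the empty
    string means "unlabelled".
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_labels: np.ndarray | None = None
    face_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise TopologyError("face index out of range")
        if self.vertex_labels is not None:
            self.vertex_labels = np.asarray(self.vertex_labels, dtype=object)
            if len(self.vertex_labels) != len(self.vertices):
                raise TopologyError("vertex_labels length mismatch")
        if self.face_labels is not None:
            self.face_labels = np.asarray(self.face_labels, dtype=object)
            if len(self.face_labels) != len(self.faces):
                raise TopologyError("face_labels length mismatch")

    # -- conversions -----------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        """Trimesh view; ``process=False`` so indices stay stable."""
        return trimesh.Trimesh(vertices=self.vertices.copy(),
                               faces=self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh,
                     face_labels: np.ndarray | None = None) -> "TriSurface":
        return cls(vertices=np.asarray(mesh.vertices, dtype=float),
                   faces=np.asarray(mesh.faces, dtype=np.int64),
                   face_labels=face_labels)

    # -- basic queries ---------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def area(self) -> float:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        return float(np.linalg.norm(np.cross(b - a, c - a), axis=1).sum() / 2.0)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def boundary_loops(self) -> list[np.ndarray]:
        """Closed vertex loops of boundary edges (edges used by one face)."""
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        boundary = uniq[counts == 1]
        if len(boundary) == 0:
            return []
        # walk the boundary edge graph
        from collections import defaultdict
        adj: dict[int, list[int]] = defaultdict(list)
        for a, b in boundary:
            adj[int(a)].append(int(b))
            adj[int(b)].append(int(a))
        for v, nbrs in adj.items():
            if len(nbrs) != 2:
                raise TopologyError(
                    f"boundary is not a disjoint union of loops at vertex {v}")
        seen: set[int] = set()
        loops = []
        for start in sorted(adj):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            prev, cur = None, start
            while True:
                nxt = [w for w in adj[cur] if w != prev]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                if cur == start:
                    break
                loop.append(cur)
                seen.add(cur)
            loops.append(np.array(loop, dtype=np.int64))
        return loops

    def is_edge_manifold(self) -> bool:
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool((counts <= 2).all())

    def transformed(self, matrix: np.ndarray) -> "TriSurface":
        """Apply a 4x4 homogeneous transform; labels carried over."""
        matrix = np.asarray(matrix, dtype=float)
        v = self.vertices @ matrix[:3, :3].T + matrix[:3, 3]
        return replace(self, vertices=v, faces=self.faces.copy())

    def copy(self) -> "TriSurface":
        return TriSurface(
            self.vertices.copy(), self.faces.copy(),
            None if self.vertex_labels is None else self.vertex_labels.copy(),
            None if self.face_labels is None else self.face_labels.copy())


@dataclass(frozen=True)
class Plane:
    """Oriented plane: point on plane + unit normal (positive side = kept)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", _unit(self.normal))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - self.point) @ self.normal

    def offset(self, distance: float) -> "Plane":
        """Parallel plane shifted ``distance`` along the normal."""
        return Plane(self.point + distance * self.normal, self.normal)

    def flipped(self) -> "Plane":
        return Plane(self.point, -self.normal)

    def transformed(self, matrix: np.ndarray) -> "Plane":
        matrix = np.asarray(matrix, dtype=float)
        return Plane(matrix[:3, :3] @ self.point + matrix[:3, 3],
                     matrix[:3, :3] @ self.normal)


@dataclass
class AnatomicalFrame:
    """Landmarks plus the derived planes and midline AP axis.

    ``base_plane`` passes through nasion and both tragions with normal toward
    the cranial vertex; ``midline_plane`` is the sagittal symmetry plane
    containing the AP segment.  A and P are the extreme points of the skull
    section in the base plane; B and L are the suture-plane feet on AP.
    """

    nasion: np.ndarray
    tragion_left: np.ndarray
    tragion_right: np.ndarray
    base_plane: Plane
    midline_plane: Plane
    bregma: np.ndarray | None = None
    lambda_pt: np.ndarray | None = None
    A: np.ndarray | None = None
    P: np.ndarray | None = None
    B: np.ndarray | None = None
    L: np.ndarray | None = None

    @property
    def ap_direction(self) -> np.ndarray:
        """Unit vector from P toward A (posterior -> anterior)."""
        if self.A is None or self.P is None:
            raise DegenerateGeometryError("A/P points not set on frame")
        return _unit(np.asarray(self.A) - np.asarray(self.P))

    @property
    def lateral_direction(self) -> np.ndarray:
        """Unit normal of the midline plane (left-right axis)."""
        return self.midline_plane.normal


@dataclass(frozen=True)
class SutureGeometry:
    """Coronal/lambdoid suture-plane parameters.

    ``alpha``: coronal point angle A-B-Bregma (deg); ``beta``: lambdoid point
    angle P-L-Lambda (deg); ``ab_frac`` = |AB|/|AP|; ``lp_frac`` = |LP|/|AP|.
    """

    alpha: float
    beta: float
    ab_frac: float
    lp_frac: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 180.0 and 0.0 < self.beta < 180.0):
            raise ValueError("suture angles must lie in (0, 180) degrees")
        if not (0.0 < self.ab_frac < 1.0 and 0.0 < self.lp_frac < 1.0):
            raise ValueError("suture fractions must lie in (0, 1)")


@dataclass(frozen=True)
class PopulationParams:
    """Population-averaged tissue and suture parameters for S-model building.

    Defaults are the cohort averages: skin 2.8 mm, skull 2.5 mm, coronal
    angle 83 deg, lambdoid angle 68 deg, 2 mm wide sutures.  The AB/LP
    fractions have no published population value; 0.30/0.25 are this
    package's defaults.
    """

    skin_thickness: float = 2.8
    skull_thickness: float = 2.5
    suture: SutureGeometry = field(
        default_factory=lambda: SutureGeometry(83.0, 68.0, 0.30, 0.25))
    suture_width: float = 2.0
    skin_thickness_sd: float = 0.4
    skull_thickness_sd: float = 0.4
    alpha_sd: float = 4.0
    beta_sd: float = 3.0

    def __post_init__(self) -> None:
        # skin offset of zero is allowed (skull surface == cut head surface)
        if self.skin_thickness < 0:
            raise ValueError("skin_thickness must be non-negative")
        for name in ("skull_thickness", "suture_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ThicknessMap:
    """Per-vertex surface-distance thickness above a crop plane."""

    distances: np.ndarray
    crop_plane: Plane
    vertex_indices: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if (self.distances < 0).any():
            raise ValueError("thickness distances must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    @property
    def sd(self) -> float:
        return float(self.distances.std(ddof=1)) if len(self.distances) > 1 else 0.0


@dataclass(frozen=True)
class ShapeMetrics:
    """Biparietal diameter, occipitofrontal diameter and cranial index."""

    BPD: float
    OFD: float

    def __post_init__(self) -> None:
        if self.BPD <= 0 or self.OFD <= 0:
            raise ValueError("BPD and OFD must be positive")

    @property
    def CI(self) -> float:
        return self.BPD / self.OFD


@dataclass(frozen=True)
class OsteotomySpec:
    """Parasagittal osteotomy geometry and notch placement.

    Two cuts parallel to the midline at ``lateral_offset`` mm, of width
    ``kerf`` mm, running from ``anterior_extent`` to ``posterior_extent``
    (fractions of AP measured from A).  ``notch_fractions`` place the
    anterior/posterior spring notches along each cut.  Defaults are this
    package's, chosen to resemble published surgical figures.
    """

    lateral_offset: float = 25.0
    kerf: float = 1.0
    anterior_extent: float = 0.30
    posterior_extent: float = 0.80
    notch_fractions: tuple[float, float] = (0.25, 0.75)

    def __post_init__(self) -> None:
        from .errors import ConfigurationError
        if self.kerf <= 0:
            raise ConfigurationError("osteotomy kerf must be positive")
        if not (0.0 < self.anterior_extent < self.posterior_extent < 1.0):
            raise ConfigurationError("osteotomy extents must satisfy 0 < ant < post < 1")
        for f in self.notch_fractions:
            if not 0.0 < f < 1.0:
                raise ConfigurationError("notch fractions must lie in (0, 1)")
        if self.lateral_offset <= 0:
            raise ConfigurationError("lateral_offset must be positive")


@dataclass(frozen=True)
class Material:
    """Isotropic shell material with optional Prony shear relaxation.

    ``prony_terms`` is a tuple of (g_i, tau_i): relative moduli and
    relaxation times (s) with sum(g_i) < 1; the long-term modulus is
    E * (1 - sum g_i).  Relaxation is applied to the modulus uniformly
    (Poisson ratio held constant).
    """

    youngs_modulus: float
    poisson: float
    prony_terms: tuple[tuple[float, float], ...] = ()
    density: float | None = None

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 <= self.poisson < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        gsum = sum(g for g, _ in self.prony_terms)
        if gsum >= 1.0:
            raise ValueError("sum of Prony moduli must be < 1")
        if any(tau <= 0 for _, tau in self.prony_terms):
            raise ValueError("Prony relaxation times must be positive")

    @property
    def long_term_modulus(self) -> float:
        return self.youngs_modulus * (1.0 - sum(g for g, _ in self.prony_terms))


@dataclass
class SpringElement:
    """Linear compression spring between two shell nodes.

    Pushes the nodes apart with force ``stiffness * (free_length - opening)``
    clamped at zero (the distractor cannot pull).
    """

    model_id: str
    stiffness: float
    node_a: int
    node_b: int
    free_length: float = 60.0

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError("spring stiffness must be positive")
        if self.free_length <= 0:
            raise ValueError("spring free length must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic scaphocephalic head phantom.

    ``ofd``/``bpd``/``height`` are the extents (mm) of the supra-base-plane
    head; scaphocephaly requires bpd < ofd (CI < 1).  ``squareness`` is the
    superellipsoid exponent (2 = ellipsoid; >2 boxier, more head-like).
    """

    ofd: float = 125.0
    bpd: float = 96.0
    height: float = 55.0
    skin_thickness: float = 2.8
    skull_thickness: float = 2.5
    suture: SutureGeometry = field(
        default_factory=lambda: SutureGeometry(83.0, 68.0, 0.30, 0.25))
    mesh_resolution: float = 4.0
    squareness: float = 2.4
    #: height of the widest cross-section (parietal eminence level) above
    #: the nasion-tragion plane, as a fraction of `height`
    bulge_frac: float = 0.35
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.bpd < self.ofd:
            raise ValueError("scaphocephalic phantom requires bpd < ofd")
        for name in ("ofd", "bpd", "height", "mesh_resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("skin_thickness", "skull_thickness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.bulge_frac < 0.8:
            raise ValueError("bulge_frac must lie in [0, 0.8)")
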