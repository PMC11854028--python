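"""Assembly of simulation-ready skull models.

``build_s_model`` realises the surface-scan ("S model") recipe: cut the
head surface at the nasion-tragion plane, offset it inward by the
population-average skin thickness, place coronal/lambdoid suture planes
from the population angles and AP fractions, split into five regions,
carve the parasagittal osteotomies and mark the spring notches.
``ingest_ct_model`` wraps a pre-segmented skull surface (with optional
uniform growth scaling) into the same structure.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import geometry, morphometrics
from .errors import ConfigurationError, PipelineError
from .types import (AnatomicalFrame, OsteotomySpec, Plane, PopulationParams,
                    SpringElement, TriSurface)

#: spring stiffness (N/mm) per model; placeholder calibration constants of
#: this package (published sources give only the ordering by wire diameter,
#: reproduced here via the d^4 scaling of coil stiffness)
SPRING_STIFFNESS: dict[str, float] = {"S10": 0.15, "S12": 0.31, "S14": 0.58}

SPRING_FREE_LENGTH = 60.0  # mm, nominal fully-open size


@dataclass
class SkullModel:
    """Labelled shell ready for FE assembly.

    ``shell`` carries face labels in the five regions (plus the osteotomy
    gaps as missing faces) and notch vertex labels; ``thickness`` is the
    homogeneous shell thickness; ``springs`` is filled by
    :func:`attach_springs`.
    """

    shell: TriSurface
    thickness: float
    frame: AnatomicalFrame
    notch_sets: dict[str, np.ndarray]
    provenance: str = "S"
    springs: list[SpringElement] = field(default_factory=list)
    spring_models: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ConfigurationError("shell thickness must be positive")
        if self.provenance not in ("S", "CT"):
            raise ConfigurationError("provenance must be 'S' or 'CT'")


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return False
    return _Ctx()


def build_s_model(head_surface: TriSurface, landmarks: dict,
                  pop: PopulationParams,
                  spec: OsteotomySpec | None = None) -> SkullModel:
    """Build the S model from a head surface and base landmarks.

    ``landmarks`` needs nasion and both tragions (bregma/lambda are not
    required: suture placement comes from the population parameters).
    """
    if spec is None:
        spec = OsteotomySpec()
    for key in ("nasion", "tragion_left", "tragion_right"):
        if key not in landmarks:
            raise ConfigurationError(f"landmark {key!r} is required")
    with _stage("frame"):
        frame = geometry.make_frame(landmarks["nasion"],
                                    landmarks["tragion_left"],
                                    landmarks["tragion_right"])
    with _stage("base_cut"):
        head_cut = geometry.cut_by_plane(head_surface, frame.base_plane,
                                         keep="positive")
    with _stage("skin_offset"):
        skull_surface = geometry.offset_inward(head_cut, pop.skin_thickness)
    with _stage("ap_points"):
        hint = frame.nasion - 0.5 * (frame.tragion_left + frame.tragion_right)
        frame.A, frame.P = morphometrics.find_ap_points(
            skull_surface, frame.base_plane, hint)
    with _stage("suture_planes"):
        height = float(frame.base_plane.signed_distance(
            skull_surface.vertices).max())
        coronal, lambdoid = geometry.suture_planes(
            frame, pop.suture.alpha, pop.suture.beta, pop.suture.ab_frac,
            pop.suture.lp_frac, max_height=height)
    with _stage("region_split"):
        labelled = geometry.split_regions(skull_surface, coronal, lambdoid,
                                          pop.suture_width)
    with _stage("osteotomies"):
        carved = geometry.carve_osteotomies(labelled, frame, spec)
    model = SkullModel(shell=carved, thickness=pop.skull_thickness,
                       frame=frame, notch_sets=geometry.notch_sets(carved),
                       provenance="S")
    _sanity_check_ci(model)
    return model


def ingest_ct_model(skull_outer: TriSurface, landmarks: dict,
                    scale_factor: float = 1.0,
                    spec: OsteotomySpec | None = None,
                    pop: PopulationParams | None = None) -> SkullModel:
    """Wrap a pre-segmented, pre-cut skull surface into a SkullModel.

    The mesh is scaled uniformly about its centroid by ``scale_factor``
    (growth adjustment between scan and surgery; the factor is an input).
    If bregma/lambda landmarks are present, the suture planes are anchored
    through them (population angles give the tilt); otherwise population
    planes are used outright, requiring ``pop``.
    """
    if spec is None:
        spec = OsteotomySpec()
    if pop is None:
        pop = PopulationParams()
    for key in ("nasion", "tragion_left", "tragion_right"):
        if key not in landmarks:
            raise ConfigurationError(f"landmark {key!r} is required")
    with _stage("scale"):
        scaled = geometry.uniform_scale(skull_outer, scale_factor)
    with _stage("frame"):
        lm = {k: np.asarray(v, float) for k, v in landmarks.items()}
        if scale_factor != 1.0:
            c = skull_outer.vertices.mean(axis=0)
            lm = {k: c + scale_factor * (v - c) for k, v in lm.items()}
        frame = geometry.make_frame(lm["nasion"], lm["tragion_left"],
                                    lm["tragion_right"])
        frame.bregma = lm.get("bregma")
        frame.lambda_pt = lm.get("lambda")
    with _stage("base_cut"):
        cut = geometry.cut_by_plane(scaled, frame.base_plane, keep="positive")
    with _stage("ap_points"):
        hint = frame.nasion - 0.5 * (frame.tragion_left + frame.tragion_right)
        frame.A, frame.P = morphometrics.find_ap_points(cut, frame.base_plane,
                                                        hint)
    with _stage("suture_planes"):
        height = float(frame.base_plane.signed_distance(cut.vertices).max())
        if frame.bregma is not None and frame.lambda_pt is not None:
            coronal, lambdoid = _planes_through_landmarks(frame, pop)
        else:
            coronal, lambdoid = geometry.suture_planes(
                frame, pop.suture.alpha, pop.suture.beta, pop.suture.ab_frac,
                pop.suture.lp_frac, max_height=height)
    with _stage("region_split"):
        labelled = geometry.split_regions(cut, coronal, lambdoid,
                                          pop.suture_width)
    with _stage("osteotomies"):
        carved = geometry.carve_osteotomies(labelled, frame, spec)
    model = SkullModel(shell=carved, thickness=pop.skull_thickness,
                       frame=frame, notch_sets=geometry.notch_sets(carved),
                       provenance="CT")
    _sanity_check_ci(model)
    return model


def _planes_through_landmarks(frame: AnatomicalFrame,
                              pop: PopulationParams) -> tuple[Plane, Plane]:
    """Suture planes anchored at measured bregma/lambda, population tilt.

    The foot B (resp. L) is found by casting the trace of known angle back
    from the landmark to the AP line, so the plane passes through the
    landmark exactly.
    """
    a_hat = frame.ap_direction
    u = frame.base_plane.normal

    def foot(landmark: np.ndarray, angle_deg: float, anterior: bool) -> float:
        ang = np.radians(angle_deg)
        sign = 1.0 if anterior else -1.0
        trace = sign * np.cos(ang) * a_hat + np.sin(ang) * u
        h = float((landmark - frame.A) @ u)
        r = h / float(trace @ u)
        foot_pt = np.asarray(landmark, float) - r * trace
        # AP fraction of the foot, measured from A
        return float((foot_pt - frame.A) @ (frame.P - frame.A)
                     / np.linalg.norm(frame.P - frame.A) ** 2)

    ab = foot(frame.bregma, pop.suture.alpha, anterior=True)
    lp = 1.0 - foot(frame.lambda_pt, pop.suture.beta, anterior=False)
    if not (0.0 < ab < 1.0 - lp):
        raise ConfigurationError(
            f"landmark-anchored suture feet invalid (ab={ab:.3f}, lp={lp:.3f})")
    return geometry.suture_planes(frame, pop.suture.alpha, pop.suture.beta,
                                  ab, lp)


def _sanity_check_ci(model: SkullModel) -> None:
    try:
        metrics = morphometrics.shape_metrics(model.shell, model.frame)
    except Exception:
        return
    if not 0.4 < metrics.CI < 1.2:
        warnings.warn(f"built model has implausible CI = {metrics.CI:.2f}",
                      stacklevel=3)


def attach_springs(model: SkullModel,
                   spring_models: tuple[str, str] = ("S12", "S12"),
                   stiffness_table: dict[str, float] | None = None,
                   free_length: float = SPRING_FREE_LENGTH) -> SkullModel:
    """Attach anterior and posterior springs across the midline.

    Each spring connects the centroid nodes of the left/right notch sets of
    its pair (anterior or posterior); ``spring_models`` is (anterior,
    posterior) with IDs in S10/S12/S14.
    """
    table = SPRING_STIFFNESS if stiffness_table is None else stiffness_table
    for sid in spring_models:
        if sid not in table:
            raise ConfigurationError(
                f"unknown spring model {sid!r}; known: {sorted(table)}")
    springs = []
    for sid, position in zip(spring_models, ("anterior", "posterior")):
        nodes = []
        for side in ("left", "right"):
            key = f"{position}_{side}"
            idx = model.notch_sets.get(key)
            if idx is None or len(idx) == 0:
                raise ConfigurationError(f"notch set {key!r} is empty")
            pts = model.shell.vertices[idx]
            centroid = pts.mean(axis=0)
            nodes.append(int(idx[np.argmin(
                np.linalg.norm(pts - centroid, axis=1))]))
        springs.append(SpringElement(model_id=sid, stiffness=table[sid],
                                     node_a=nodes[0], node_b=nodes[1],
                                     free_length=free_length))
    model.springs = springs
    model.spring_models = tuple(spring_models)
    return model
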