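"""File formats, configuration and the pipeline driver.

Meshes travel as STL/PLY/OBJ (via trimesh); region labels, notch sets and
model metadata as sidecar JSON; landmarks as a small JSON dict in mm;
configuration as YAML.  ``run_pipeline`` chains the measure / build /
simulate / report stages and writes a deterministic JSON summary with a
provenance block (config hash, package version, seed).
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
import yaml

from .errors import ConfigurationError, MeshIOError, PipelineError
from .types import (Material, OsteotomySpec, PhantomSpec, PopulationParams,
                    SutureGeometry, TriSurface)

log = logging.getLogger("craniospring")

MESH_SUFFIXES = (".stl", ".ply", ".obj")

LANDMARK_KEYS = ("nasion", "tragion_left", "tragion_right")
OPTIONAL_LANDMARKS = ("bregma", "lambda")


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def read_mesh(path: str | Path) -> TriSurface:
    """Load an STL/PLY/OBJ triangle mesh (indices preserved, no processing)."""
    path = Path(path)
    if path.suffix.lower() not in MESH_SUFFIXES:
        raise MeshIOError(f"unsupported mesh format: {path}")
    if not path.exists() or path.stat().st_size == 0:
        raise MeshIOError(f"unreadable or empty mesh file: {path}")
    try:
        mesh = trimesh.load(path, force="mesh", process=False)
    except Exception as exc:
        raise MeshIOError(f"failed to read {path}: {exc}") from exc
    if mesh is None or len(getattr(mesh, "faces", ())) == 0:
        raise MeshIOError(f"no triangles in {path}")
    out = TriSurface.from_trimesh(mesh)
    labels = _sidecar_path(path)
    if labels.exists():
        _apply_labels(out, json.loads(labels.read_text()))
    return out


def write_mesh(mesh: TriSurface, path: str | Path) -> Path:
    """Write a mesh by extension; labels go to a JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() not in MESH_SUFFIXES:
        raise MeshIOError(f"unsupported mesh format: {path}")
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.to_trimesh().export(path)
    if mesh.face_labels is not None or mesh.vertex_labels is not None:
        _sidecar_path(path).write_text(json.dumps(_labels_dict(mesh)))
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.json")


def _labels_dict(mesh: TriSurface) -> dict:
    out: dict = {}
    if mesh.face_labels is not None:
        out["face_labels"] = {str(i): str(lbl) for i, lbl in
                              enumerate(mesh.face_labels) if lbl}
    if mesh.vertex_labels is not None:
        out["vertex_labels"] = {str(i): str(lbl) for i, lbl in
                                enumerate(mesh.vertex_labels) if lbl}
    return out


def _apply_labels(mesh: TriSurface, data: dict) -> None:
    if "face_labels" in data:
        fl = np.array([""] * mesh.n_faces, dtype=object)
        for k, v in data["face_labels"].items():
            fl[int(k)] = v
        mesh.face_labels = fl
    if "vertex_labels" in data:
        vl = np.array([""] * mesh.n_vertices, dtype=object)
        for k, v in data["vertex_labels"].items():
            vl[int(k)] = v
        mesh.vertex_labels = vl


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path: str | Path) -> dict[str, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise MeshIOError(f"landmark file not found: {path}")
    data = json.loads(path.read_text())
    out = {}
    for key in LANDMARK_KEYS:
        if key not in data:
            raise MeshIOError(f"landmark file {path} is missing {key!r}")
        out[key] = np.asarray(data[key], dtype=float)
        if out[key].shape != (3,):
            raise MeshIOError(f"landmark {key!r} must be [x, y, z] mm")
    for key in OPTIONAL_LANDMARKS:
        if key in data and data[key] is not None:
            out[key] = np.asarray(data[key], dtype=float)
    return out


def write_landmarks(landmarks: dict, path: str | Path,
                    frame_note: str = "model coordinates, mm") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {k: np.asarray(v, dtype=float).tolist()
               for k, v in landmarks.items()}
    payload["coordinate_frame"] = frame_note
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: Path = Path("craniospring_out")
    head_mesh: Path | None = None
    landmarks: Path | None = None
    phantom: PhantomSpec | None = None
    population: PopulationParams = field(default_factory=PopulationParams)
    osteotomy: OsteotomySpec = field(default_factory=OsteotomySpec)
    materials: dict[str, Material] | None = None
    spring_models: tuple[str, str] = ("S12", "S12")
    spring_stiffness: dict[str, float] | None = None
    schedule_n_log: int = 40
    schedule_t_end: float = 432000.0
    seed: int = 0

    def validate(self) -> None:
        if self.head_mesh is None and self.phantom is None:
            raise ConfigurationError(
                "config needs either head_mesh+landmarks paths or a "
                "phantom section")
        for p in (self.head_mesh, self.landmarks):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"referenced file missing: {p}")


_KNOWN_KEYS = {"outdir", "head_mesh", "landmarks", "phantom", "population",
               "osteotomy", "materials", "spring_models", "spring_stiffness",
               "schedule_n_log", "schedule_t_end", "seed"}


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig()
    if "outdir" in raw:
        cfg.outdir = Path(raw["outdir"])
    for key in ("head_mesh", "landmarks"):
        if raw.get(key):
            setattr(cfg, key, Path(raw[key]))
    if "phantom" in raw and raw["phantom"] is not None:
        ph = dict(raw["phantom"])
        if "suture" in ph:
            ph["suture"] = SutureGeometry(**ph["suture"])
        cfg.phantom = PhantomSpec(**ph)
    if "population" in raw and raw["population"] is not None:
        pp = dict(raw["population"])
        if "suture" in pp:
            pp["suture"] = SutureGeometry(**pp["suture"])
        cfg.population = PopulationParams(**pp)
    if "osteotomy" in raw and raw["osteotomy"] is not None:
        osteo = dict(raw["osteotomy"])
        if "notch_fractions" in osteo:
            osteo["notch_fractions"] = tuple(osteo["notch_fractions"])
        cfg.osteotomy = OsteotomySpec(**osteo)
    if "materials" in raw and raw["materials"] is not None:
        cfg.materials = {}
        for name, m in raw["materials"].items():
            m = dict(m)
            if "prony_terms" in m:
                m["prony_terms"] = tuple(tuple(t) for t in m["prony_terms"])
            cfg.materials[name] = Material(**m)
    if "spring_models" in raw:
        cfg.spring_models = tuple(raw["spring_models"])
        if len(cfg.spring_models) != 2:
            raise ConfigurationError("spring_models must list two IDs")
    if "spring_stiffness" in raw and raw["spring_stiffness"] is not None:
        cfg.spring_stiffness = {str(k): float(v)
                                for k, v in raw["spring_stiffness"].items()}
    for key in ("schedule_n_log", "seed"):
        if key in raw:
            setattr(cfg, key, int(raw[key]))
    if "schedule_t_end" in raw:
        cfg.schedule_t_end = float(raw["schedule_t_end"])
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the configuration for the provenance block."""
    def default(o):
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return o.__dict__
        if hasattr(o, "_asdict"):
            return o._asdict()
        return repr(o)
    blob = json.dumps(cfg, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

STAGES = ("measure", "build", "simulate", "report")


def run_pipeline(config: RunConfig,
                 stages: set[str] | None = None) -> tuple[int, dict]:
    """Run the requested stages; returns (exit status, artifact paths).

    Stage outputs land under ``config.outdir``; a failure stops the
    pipeline with nonzero status, keeping the artifacts produced so far.
    """
    from . import morphometrics
    from .fem_spring import assemble, extract_outputs, make_schedule, \
        solve_quasistatic
    from .model_builder import attach_springs, build_s_model
    from .synthetic import generate_head, generate_two_layer

    if stages is None:
        stages = set(STAGES)
    unknown = stages - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    if "simulate" in stages and "build" not in stages:
        raise ConfigurationError("stage 'simulate' requires stage 'build'")
    if "report" in stages and "simulate" not in stages:
        raise ConfigurationError("stage 'report' requires stage 'simulate'")
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    summary: dict = {"provenance": _provenance(config)}
    t_start = time.time()
    current = None
    try:
        current = "inputs"
        if config.phantom is not None:
            head, landmarks = generate_head(config.phantom)
        else:
            head = read_mesh(config.head_mesh)
            landmarks = read_landmarks(config.landmarks)

        if "measure" in stages:
            current = "measure"
            t0 = time.time()
            summary["measure"] = _measure_stage(config, out, artifacts)
            log.info("stage measure done in %.1f s", time.time() - t0)

        model = None
        if "build" in stages:
            current = "build"
            t0 = time.time()
            model = build_s_model(head, landmarks, config.population,
                                  config.osteotomy)
            model = attach_springs(model, config.spring_models,
                                   config.spring_stiffness)
            mesh_path = write_mesh(model.shell, out / "s_model.ply")
            meta = {
                "thickness": model.thickness,
                "provenance": model.provenance,
                "spring_models": list(model.spring_models),
                "notch_sets": {k: np.asarray(v).tolist()
                               for k, v in model.notch_sets.items()},
            }
            (out / "s_model.json").write_text(json.dumps(meta, indent=2,
                                                         sort_keys=True))
            artifacts["model_mesh"] = str(mesh_path)
            artifacts["model_meta"] = str(out / "s_model.json")
            sm = morphometrics.shape_metrics(model.shell, model.frame)
            summary["build"] = {"n_faces": model.shell.n_faces,
                                "PREOP": {"BPD": sm.BPD, "OFD": sm.OFD,
                                          "CI": sm.CI}}
            log.info("stage build done in %.1f s", time.time() - t0)

        solution = None
        if "simulate" in stages:
            current = "simulate"
            t0 = time.time()
            system = assemble(model, config.materials)
            schedule = make_schedule(config.schedule_t_end,
                                     n_log=config.schedule_n_log)
            solution = solve_quasistatic(system, model.springs, schedule)
            for name, mesh in solution.deformed.items():
                artifacts[f"deformed_{name}"] = str(
                    write_mesh(mesh, out / f"deformed_{name.lower()}.ply"))
            np.savetxt(out / "openings.csv",
                       np.column_stack([solution.times, solution.openings]),
                       delimiter=",", header="time_s,opening_mm_anterior,"
                       "opening_mm_posterior", comments="")
            artifacts["openings"] = str(out / "openings.csv")
            log.info("stage simulate done in %.1f s", time.time() - t0)

        if "report" in stages:
            current = "report"
            report = extract_outputs(solution, model.frame)
            summary["report"] = report
    except Exception as exc:
        log.error("pipeline stage %r failed: %s", current, exc)
        summary["error"] = {"stage": current, "message": str(exc)}
        _write_summary(summary, out, artifacts, t_start)
        return 1, artifacts
    _write_summary(summary, out, artifacts, t_start)
    return 0, artifacts


def _measure_stage(config: RunConfig, out: Path, artifacts: dict) -> dict:
    """Thickness + suture measurement on the two-layer phantom."""
    from . import morphometrics
    from .geometry import make_frame
    from .synthetic import generate_two_layer

    if config.phantom is None:
        raise PipelineError(
            "stage 'measure' needs a phantom section (two-layer ground "
            "truth); measuring patient scans requires skull inner/outer "
            "surfaces which this configuration does not reference")
    skin, outer, inner = generate_two_layer(config.phantom)
    from .synthetic import generate_head
    _, landmarks = generate_head(config.phantom)
    frame = make_frame(landmarks["nasion"], landmarks["tragion_left"],
                       landmarks["tragion_right"])
    crop = morphometrics.crop_plane_at_fraction(skin, frame.base_plane, 0.25)
    t_skin = morphometrics.thickness_between(skin, outer, crop)
    t_skull = morphometrics.thickness_between(outer, inner, crop)
    result = {"skin_thickness_mm": {"mean": t_skin.mean, "sd": t_skin.sd},
              "skull_thickness_mm": {"mean": t_skull.mean, "sd": t_skull.sd}}
    (out / "measurements.json").write_text(
        json.dumps(result, indent=2, sort_keys=True))
    artifacts["measurements"] = str(out / "measurements.json")
    return result


def _provenance(config: RunConfig) -> dict:
    from . import __version__
    return {"package": "craniospring", "version": __version__,
            "config_hash": config_hash(config), "seed": config.seed}


def _write_summary(summary: dict, out: Path, artifacts: dict,
                   t_start: float) -> None:
    summary["artifacts"] = {k: str(v) for k, v in sorted(artifacts.items())}
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float))
    log.info("pipeline finished in %.1f s; summary at %s",
             time.time() - t_start, out / "summary.json")
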