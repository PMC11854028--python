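"""Quasi-static viscoelastic shell FEM of spring expansion.

The labelled skull shell becomes an assembly of flat corotational
triangles (CST membrane + DKT bending, see :mod:`craniospring.shell`) with
homogeneous thickness; the base rim is fully clamped to mimic skull-base
tethering; springs are linear force elements pushing their attachment
nodes apart with ``k (L0 - d)`` clamped at zero.  Viscoelasticity is a
Prony series applied as uniform modulus relaxation with internal-variable
updates that are exact for piecewise-linear strain histories.  Geometric
nonlinearity is handled corotationally: each element's rigid rotation is
removed via its deformed frame, so the small-strain kernels remain valid
for large rotations of the bone flaps.

Openings are extracted at t = 1 s (POSTOP, the on-table elastic response;
spring force is ramped on over the first second) and t = 5 days (FU).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import (AssemblyError, ConfigurationError, ConstraintError,
                     CranioSpringError, NonConvergenceError, ReportError)
from .shell import shell_stiffness
from .types import AnatomicalFrame, Material, SpringElement, TriSurface
from . import morphometrics

POSTOP_TIME = 1.0          # s
FU_TIME = 432000.0         # s, 5 days

BONE_REGIONS = ("frontal", "parietal", "occipital")
SUTURE_REGIONS = ("coronal_suture", "lambdoid_suture")

#: default material table.  The elastic/viscoelastic constants are config
#: placeholders of this package (calibrated values live in device- and
#: cohort-specific prior work and are not public); users should pin their
#: own.  Ordering and structure: stiff mineralised bone, much softer
#: fibrous suture, single-term Prony relaxation for both.
DEFAULT_MATERIALS: dict[str, Material] = {
    "skull": Material(youngs_modulus=421.0, poisson=0.22,
                      prony_terms=((0.45, 2000.0),)),
    "suture": Material(youngs_modulus=8.0, poisson=0.45,
                       prony_terms=((0.60, 10000.0),)),
}


def material_for_region(region: str,
                        materials: dict[str, Material]) -> Material:
    """Resolve a region label to a material (exact key, then bone/suture)."""
    if region in materials:
        return materials[region]
    if region in BONE_REGIONS and "skull" in materials:
        return materials["skull"]
    if region in SUTURE_REGIONS and "suture" in materials:
        return materials["suture"]
    raise AssemblyError(f"no material for region {region!r}")


# ---------------------------------------------------------------------------
# system assembly
# ---------------------------------------------------------------------------

@dataclass
class FESystem:
    """Assembled shell system: geometry, element kernels, constraints."""

    nodes: np.ndarray             # (n, 3) undeformed coordinates
    elements: np.ndarray          # (m, 3) vertex triples
    frames0: np.ndarray           # (m, 3, 3) undeformed element frames
    local_xy: np.ndarray          # (m, 3, 2) local in-plane coordinates
    kloc: np.ndarray              # (m, 18, 18) instantaneous local stiffness
    g: np.ndarray                 # (m, T) Prony relative moduli (padded 0)
    tau: np.ndarray               # (m, T) relaxation times (padded 1)
    fixed: np.ndarray             # (6n,) boolean constrained-DOF mask
    thickness: float
    shell: TriSurface | None = None
    frame: AnatomicalFrame | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def ginf(self) -> np.ndarray:
        return 1.0 - self.g.sum(axis=1)

    @classmethod
    def from_arrays(cls, vertices: np.ndarray, faces: np.ndarray,
                    materials_per_face: list[Material] | Material,
                    thickness: float, fixed_nodes: np.ndarray,
                    shell: TriSurface | None = None,
                    frame: AnatomicalFrame | None = None) -> "FESystem":
        """Build a system from raw arrays (used by tests and toys too)."""
        vertices = np.asarray(vertices, dtype=float)
        faces = np.asarray(faces, dtype=np.int64)
        m = len(faces)
        if isinstance(materials_per_face, Material):
            materials_per_face = [materials_per_face] * m
        if len(materials_per_face) != m:
            raise AssemblyError("one material per face required")
        tri = vertices[faces]
        e1 = tri[:, 1] - tri[:, 0]
        n_vec = np.cross(e1, tri[:, 2] - tri[:, 0])
        areas2 = np.linalg.norm(n_vec, axis=1)
        if (areas2 < 1e-12).any():
            raise AssemblyError("degenerate (zero-area) element")
        e1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
        e3 = n_vec / areas2[:, None]
        e2 = np.cross(e3, e1)
        frames0 = np.stack([e1, e2, e3], axis=2)   # columns are axes
        d1 = tri[:, 1] - tri[:, 0]
        d2 = tri[:, 2] - tri[:, 0]
        local_xy = np.zeros((m, 3, 2))
        local_xy[:, 1, 0] = np.einsum("mi,mi->m", d1, e1)
        local_xy[:, 2, 0] = np.einsum("mi,mi->m", d2, e1)
        local_xy[:, 2, 1] = np.einsum("mi,mi->m", d2, e2)
        youngs = np.array([mat.youngs_modulus for mat in materials_per_face])
        poisson = np.array([mat.poisson for mat in materials_per_face])
        kloc = shell_stiffness(local_xy, youngs, poisson, thickness)
        nterms = max((len(mat.prony_terms) for mat in materials_per_face),
                     default=0)
        g = np.zeros((m, max(nterms, 1)))
        tau = np.ones((m, max(nterms, 1)))
        for i, mat in enumerate(materials_per_face):
            for j, (gj, tj) in enumerate(mat.prony_terms):
                g[i, j] = gj
                tau[i, j] = tj
        fixed = np.zeros(6 * len(vertices), dtype=bool)
        fixed_nodes = np.asarray(fixed_nodes, dtype=np.int64)
        for k in range(6):
            fixed[6 * fixed_nodes + k] = True
        if len(fixed_nodes) == 0:
            raise ConstraintError(
                "no constrained nodes: rigid-body modes are unconstrained")
        return cls(nodes=vertices, elements=faces, frames0=frames0,
                   local_xy=local_xy, kloc=kloc, g=g, tau=tau, fixed=fixed,
                   thickness=thickness, shell=shell, frame=frame)


def assemble(model, materials: dict[str, Material] | None = None,
             constraint_tol: float = 1.0) -> FESystem:
    """Assemble the FE system from a labelled :class:`SkullModel`.

    Every face label must resolve to a material (bone regions may share a
    single ``"skull"`` entry, suture bands a ``"suture"`` entry).  Nodes
    within ``constraint_tol`` mm of the base plane are fully clamped.
    """
    if materials is None:
        materials = DEFAULT_MATERIALS
    shell = model.shell
    if shell.face_labels is None:
        raise AssemblyError("shell has unlabeled faces (no face_labels)")
    mats = [material_for_region(str(lbl), materials)
            for lbl in shell.face_labels]
    # clamp the open base rim: boundary vertices nearest the base plane
    # (the rim may sit slightly off the plane after the inward offset)
    from .geometry import _boundary_vertices
    rim = _boundary_vertices(shell)
    sd = np.abs(model.frame.base_plane.signed_distance(shell.vertices))
    if rim.any():
        lo = float(sd[rim].min())
        fixed_nodes = np.flatnonzero(rim & (sd < lo + constraint_tol))
    else:
        fixed_nodes = np.flatnonzero(sd < constraint_tol)
    height = float(model.frame.base_plane.signed_distance(shell.vertices).max())
    fixed_nodes = fixed_nodes[sd[fixed_nodes] < 0.25 * height]
    if len(fixed_nodes) == 0:
        raise ConstraintError(
            "no nodes on the base plane: the shell cannot be tethered")
    return FESystem.from_arrays(shell.vertices, shell.faces, mats,
                                model.thickness, fixed_nodes, shell=shell,
                                frame=model.frame)


# ---------------------------------------------------------------------------
# springs
# ---------------------------------------------------------------------------

def spring_force(spring: SpringElement, opening: float) -> float:
    """Push-only linear spring force (N) at the given opening (mm)."""
    if opening < 0:
        raise ConfigurationError("spring opening must be non-negative")
    return max(0.0, spring.stiffness * (spring.free_length - opening))


# ---------------------------------------------------------------------------
# rotation utilities (vectorised)
# ---------------------------------------------------------------------------

def _exp_so3(theta: np.ndarray) -> np.ndarray:
    """Rodrigues exponential of stacked rotation vectors (n, 3)."""
    angle = np.linalg.norm(theta, axis=1)
    small = angle < 1e-12
    axis = np.where(small[:, None], 0.0,
                    theta / np.where(small, 1.0, angle)[:, None])
    K = np.zeros((len(theta), 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -axis[:, 2], axis[:, 1]
    K[:, 1, 0], K[:, 1, 2] = axis[:, 2], -axis[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -axis[:, 1], axis[:, 0]
    s = np.sin(angle)[:, None, None]
    c = (1 - np.cos(angle))[:, None, None]
    return np.eye(3) + s * K + c * (K @ K)


def _axial(R: np.ndarray) -> np.ndarray:
    """Rotation vector of stacked rotation matrices (valid below ~90 deg)."""
    w = 0.5 * np.stack([R[..., 2, 1] - R[..., 1, 2],
                        R[..., 0, 2] - R[..., 2, 0],
                        R[..., 1, 0] - R[..., 0, 1]], axis=-1)
    s = np.linalg.norm(w, axis=-1)
    s_c = np.clip(s, 0.0, 1.0 - 1e-12)
    scale = np.where(s > 1e-12, np.arcsin(s_c) / np.where(s > 1e-12, s, 1.0),
                     1.0)
    return w * scale[..., None]


# ---------------------------------------------------------------------------
# solution container
# ---------------------------------------------------------------------------

@dataclass
class ExpansionSolution:
    """Displacement and opening history plus deformed meshes."""

    times: np.ndarray                     # (n_t,)
    openings: np.ndarray                  # (n_t, n_springs) mm
    displacements: np.ndarray             # (n_t, n_nodes, 3) mm
    springs: list[SpringElement]
    system: FESystem
    deformed: dict[str, TriSurface] = field(default_factory=dict)
    #: per recorded time: sum of constrained-node reaction forces (n_t, 3),
    #: sum of applied spring forces (n_t, 3) and the force scale (n_t,)
    reaction_sums: np.ndarray | None = None
    applied_sums: np.ndarray | None = None
    force_scales: np.ndarray | None = None

    def opening_at(self, time: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - time)))
        if abs(self.times[i] - time) > 1e-6 * max(time, 1.0):
            raise ReportError(f"no solution snapshot at t = {time} s")
        return self.openings[i]

    def displacement_at(self, time: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - time)))
        if abs(self.times[i] - time) > 1e-6 * max(time, 1.0):
            raise ReportError(f"no solution snapshot at t = {time} s")
        return self.displacements[i]


def make_schedule(t_end: float = FU_TIME, ramp_steps: int = 4,
                  n_log: int = 40) -> np.ndarray:
    """Default time grid: ramp substeps to 1 s, then log-spaced to 5 days."""
    ramp = np.linspace(0.0, POSTOP_TIME, ramp_steps + 1)[1:]
    logpart = np.geomspace(POSTOP_TIME, t_end, n_log)[1:]
    return np.unique(np.concatenate([ramp, logpart]))


# ---------------------------------------------------------------------------
# quasi-static solver
# ---------------------------------------------------------------------------

class _Kinematics:
    """Per-iteration corotational state: frames, local displacements."""

    def __init__(self, system: FESystem):
        self.sys = system
        tri0 = system.nodes[system.elements]
        self.x0_local = np.concatenate(
            [system.local_xy, np.zeros((system.n_elements, 3, 1))], axis=2)
        del tri0

    def local_state(self, ut: np.ndarray, Rn: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray]:
        """Deformed frames Ed (m,3,3) and local DOF vectors ul (m,18)."""
        sysm = self.sys
        x = sysm.nodes + ut
        tri = x[sysm.elements]
        e1 = tri[:, 1] - tri[:, 0]
        nv = np.cross(e1, tri[:, 2] - tri[:, 0])
        nrm = np.linalg.norm(nv, axis=1)
        if (nrm < 1e-12).any():
            raise NonConvergenceError("element collapsed during iteration")
        e1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
        e3 = nv / nrm[:, None]
        e2 = np.cross(e3, e1)
        Ed = np.stack([e1, e2, e3], axis=2)
        # translational deformation: deformed local coords minus undeformed
        rel = tri - tri[:, 0:1, :]
        xl = np.einsum("mij,mnj->mni", Ed.transpose(0, 2, 1), rel)
        du = xl - self.x0_local
        # rotational deformation per node: Ed^T R_node E0
        Rn_el = Rn[sysm.elements]                      # (m, 3, 3, 3)
        Rdef = np.einsum("mij,mnjk,mkl->mnil",
                         Ed.transpose(0, 2, 1), Rn_el, sysm.frames0)
        th = _axial(Rdef)                              # (m, 3, 3)
        ul = np.concatenate([du, th], axis=2)          # (m, 3, 6)
        return Ed, ul.reshape(sysm.n_elements, 18)


def _spring_loads(springs: list[SpringElement], x: np.ndarray,
                  factor: float) -> tuple[np.ndarray, np.ndarray, list]:
    """External nodal forces, openings and tangent blocks for all springs."""
    n = len(x)
    f_ext = np.zeros((n, 6))
    openings = np.zeros(len(springs))
    blocks = []
    for si, spr in enumerate(springs):
        pa, pb = x[spr.node_a], x[spr.node_b]
        dvec = pb - pa
        d = float(np.linalg.norm(dvec))
        openings[si] = d
        if d < 1e-9:
            raise ConfigurationError("spring nodes coincide")
        dhat = dvec / d
        F = factor * spring_force(spr, d)
        f_ext[spr.node_b, :3] += F * dhat
        f_ext[spr.node_a, :3] -= F * dhat
        active = spr.free_length - d > 0
        kmag = factor * spr.stiffness if active else 0.0
        kb = (kmag * np.outer(dhat, dhat)
              - (F / d) * (np.eye(3) - np.outer(dhat, dhat)))
        blocks.append((spr.node_a, spr.node_b, kb))
    return f_ext, openings, blocks


def solve_quasistatic(system: FESystem, springs: list[SpringElement],
                      schedule: np.ndarray | None = None, *,
                      newton_tol: float = 1e-6, max_iter: int = 60,
                      crimped_opening: float = 25.0,
                      verbose: bool = False) -> ExpansionSolution:
    """March the viscoelastic equilibrium over the time schedule.

    At each step Newton iteration drives the residual (internal shell
    forces minus spring forces) below ``newton_tol`` times the applied
    spring force scale.  Spring force ramps linearly over [0, 1 s] so the
    t = 1 s snapshot is the full instantaneous elastic response.
    ``crimped_opening`` records the insertion opening; the initial notch
    separation may not be smaller.
    """
    if schedule is None:
        schedule = make_schedule()
    schedule = np.asarray(schedule, dtype=float)
    if (np.diff(schedule) <= 0).any() or schedule[0] <= 0:
        raise ConfigurationError("schedule must be strictly increasing, > 0")
    kin = _Kinematics(system)
    free = ~system.fixed
    n = system.n_nodes
    m = system.n_elements
    nterms = system.g.shape[1]

    ut = np.zeros((n, 3))
    Rn = np.tile(np.eye(3), (n, 1, 1))
    q_state = np.zeros((m, nterms, 18))
    ul_prev = np.zeros((m, 18))
    _, open0, _ = _spring_loads(springs, system.nodes, 0.0)
    if springs and (open0 < crimped_opening - 1e-9).any():
        raise ConfigurationError(
            f"notch separation {open0.min():.1f} mm is below the crimped "
            f"insertion opening {crimped_opening} mm")

    times_out = [0.0]
    openings_out = [open0.copy()]
    disp_out = [ut.copy()]
    reaction_out = [np.zeros(3)]
    applied_out = [np.zeros(3)]
    scale_out = [0.0]
    ginf = system.ginf

    dof_idx = (6 * system.elements[:, :, None]
               + np.arange(6)[None, None, :]).reshape(m, 18)

    def internal(Ed, ul, q_new):
        veff = ginf[:, None] * ul + (system.g[:, :, None]
                                     * (ul[:, None, :] - q_new)).sum(axis=1)
        f_loc = np.einsum("mij,mj->mi", system.kloc, veff)
        f_pairs = f_loc.reshape(m, 3, 2, 3)
        f_glob = np.einsum("mij,mnkj->mnki", Ed, f_pairs).reshape(m, 18)
        f_int = np.zeros(6 * n)
        np.add.at(f_int, dof_idx.ravel(), f_glob.ravel())
        return f_int

    def tangent(Ed, ceff, spring_blocks):
        # kloc is (m, 18, 18); per-node blocks of 6 DOFs = (trans 3, rot 3):
        # reshape to (m, node, pair, comp, node, pair, comp) and rotate the
        # component axes into the global frame
        kl = (system.kloc * ceff[:, None, None]).reshape(m, 3, 2, 3, 3, 2, 3)
        kg = np.einsum("mpi,makiblj,mqj->makpblq", Ed, kl, Ed)
        kg = kg.reshape(m, 18, 18)
        rows = np.repeat(dof_idx, 18, axis=1).ravel()
        cols = np.tile(dof_idx, (1, 18)).ravel()
        vals = kg.ravel()
        K = sp.coo_matrix((vals, (rows, cols)), shape=(6 * n, 6 * n))
        if spring_blocks:
            sr, sc, sv = [], [], []
            for (a, b, kb) in spring_blocks:
                for (i, j), sign in (((a, a), 1), ((b, b), 1),
                                     ((a, b), -1), ((b, a), -1)):
                    r3, c3 = np.meshgrid(6 * i + np.arange(3),
                                         6 * j + np.arange(3), indexing="ij")
                    sr.append(r3.ravel())
                    sc.append(c3.ravel())
                    sv.append(sign * kb.ravel())
            K = K + sp.coo_matrix((np.concatenate(sv),
                                   (np.concatenate(sr), np.concatenate(sc))),
                                  shape=(6 * n, 6 * n))
        return K.tocsc()[free][:, free]

    free_idx = np.flatnonzero(free)
    last_converged = None
    t_prev = 0.0
    for t_k in schedule:
        dt = t_k - t_prev
        factor = min(t_k / POSTOP_TIME, 1.0)
        alpha = np.exp(-dt / system.tau)                       # (m, T)
        gamma = 1.0 - (system.tau / dt) * (1.0 - alpha)
        ceff = ginf + (system.g * (1.0 - gamma)).sum(axis=1)   # (m,)

        def q_update(ul):
            return (alpha[:, :, None] * q_state
                    + ((1 - alpha) - gamma)[:, :, None] * ul_prev[:, None, :]
                    + gamma[:, :, None] * ul[:, None, :])

        def residual(ut_, Rn_):
            Ed, ul = kin.local_state(ut_, Rn_)
            q_new = q_update(ul)
            f_int = internal(Ed, ul, q_new)
            x = system.nodes + ut_
            f_ext, opens, blocks = _spring_loads(springs, x, factor)
            r = f_int - f_ext.ravel()
            scale = max(float(np.linalg.norm(f_ext[:, :3])), 1e-12)
            return r, Ed, ul, q_new, opens, blocks, scale

        r, Ed, ul, q_new, opens, blocks, scale = residual(ut, Rn)
        lu = None
        rnorm = np.linalg.norm(r[free_idx])
        it = 0
        bad_count = 0
        while rnorm > newton_tol * scale:
            if it >= max_iter:
                raise NonConvergenceError(
                    f"Newton failed at t = {t_k:.3g} s "
                    f"(|r| = {rnorm:.3g}, scale = {scale:.3g})",
                    last_converged_time=last_converged)
            if lu is None or it % 15 == 14:
                lu = splu(tangent(Ed, ceff, blocks))
            step = lu.solve(-r[free_idx])
            full = np.zeros(6 * n)
            full[free_idx] = step
            d_ut = full.reshape(n, 6)[:, :3]
            d_th = full.reshape(n, 6)[:, 3:]
            # full steps by default; backtrack only on blow-up (transient
            # residual growth is normal for the frozen modified tangent)
            lam = 1.0
            guard = 10.0 * rnorm + newton_tol * scale
            for _ in range(5):
                ut_try = ut + lam * d_ut
                Rn_try = _exp_so3(lam * d_th.reshape(-1, 3)).reshape(
                    n, 3, 3) @ Rn
                try:
                    out = residual(ut_try, Rn_try)
                except NonConvergenceError:
                    lam *= 0.25
                    continue
                if np.isfinite(out[0][free_idx]).all() and (
                        np.linalg.norm(out[0][free_idx]) < guard):
                    break
                lam *= 0.25
            else:
                raise NonConvergenceError(
                    f"Newton step keeps diverging at t = {t_k:.3g} s",
                    last_converged_time=last_converged)
            ut = ut_try
            Rn = Rn_try
            r, Ed, ul, q_new, opens, blocks, scale = out
            new_norm = np.linalg.norm(r[free_idx])
            if new_norm > rnorm:
                bad_count += 1
                if bad_count >= 3:      # persistently diverging: new tangent
                    lu = None
                    bad_count = 0
            else:
                bad_count = 0
            rnorm = new_norm
            it += 1
        if verbose:
            print(f"  t={t_k:10.3g}s  iters={it:3d}  |r|/scale="
                  f"{rnorm / max(scale, 1e-12):.2e}")
        q_state = q_new
        ul_prev = ul
        last_converged = t_k
        t_prev = t_k
        times_out.append(t_k)
        openings_out.append(opens.copy())
        disp_out.append(ut.copy())
        # reactions: residual at the constrained DOFs (f_int - f_ext there)
        f_ext_c, _, _ = _spring_loads(springs, system.nodes + ut, factor)
        r_nodes = r.reshape(n, 6)[:, :3]
        fixed_nodes_mask = system.fixed.reshape(n, 6)[:, 0]
        reaction_out.append(r_nodes[fixed_nodes_mask].sum(axis=0))
        applied_out.append(f_ext_c[~fixed_nodes_mask, :3].sum(axis=0))
        scale_out.append(scale)

    times = np.array(times_out)
    openings = np.array(openings_out)
    disp = np.array(disp_out)
    if springs and (np.diff(openings, axis=0) < -1e-4).any():
        raise CranioSpringError(
            "spring openings are not monotone over the schedule")
    solution = ExpansionSolution(times=times, openings=openings,
                                 displacements=disp, springs=springs,
                                 system=system,
                                 reaction_sums=np.array(reaction_out),
                                 applied_sums=np.array(applied_out),
                                 force_scales=np.array(scale_out))
    for name, t_named in (("POSTOP", POSTOP_TIME), ("FU", FU_TIME)):
        i = int(np.argmin(np.abs(times - t_named)))
        if abs(times[i] - t_named) <= 1e-6 * t_named and system.shell is not None:
            mesh = system.shell.copy()
            mesh.vertices = mesh.vertices + disp[i]
            solution.deformed[name] = mesh
    return solution


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def reaction_balance(solution: ExpansionSolution,
                     time: float) -> tuple[np.ndarray, np.ndarray, float]:
    """(sum of constrained reactions, sum of applied spring forces, scale).

    Global equilibrium demands the two vectors sum to zero; the Newton
    residual tolerance bounds the mismatch relative to the force scale.
    Values are recorded by the solver at each converged step.
    """
    if solution.reaction_sums is None:
        raise ReportError("solution carries no reaction records")
    i = int(np.argmin(np.abs(solution.times - time)))
    return (solution.reaction_sums[i], solution.applied_sums[i],
            float(solution.force_scales[i]))


def extract_outputs(solution: ExpansionSolution,
                    metrics_frame: AnatomicalFrame) -> dict:
    """Opening (mm and % of nominal) and BPD/OFD/CI at the named timepoints."""
    for name, t in (("POSTOP", POSTOP_TIME), ("FU", FU_TIME)):
        if name not in solution.deformed:
            raise ReportError(f"solution is missing the {name} timepoint")
    report: dict = {"springs": {}, "metrics": {}}
    labels = ["anterior", "posterior"] if len(solution.springs) == 2 else [
        f"spring_{i}" for i in range(len(solution.springs))]
    for si, (spr, lbl) in enumerate(zip(solution.springs, labels)):
        entry = {"model": spr.model_id, "opening_mm": {}, "opening_pct": {}}
        for name, t in (("POSTOP", POSTOP_TIME), ("FU", FU_TIME)):
            mm = float(solution.opening_at(t)[si])
            entry["opening_mm"][name] = mm
            entry["opening_pct"][name] = morphometrics.spring_opening_percent(
                mm, spr.free_length)
        report["springs"][lbl] = entry
    shell = solution.system.shell
    meshes = {"PREOP": shell}
    meshes.update(solution.deformed)
    for name, mesh in meshes.items():
        sm = morphometrics.shape_metrics(mesh, metrics_frame)
        report["metrics"][name] = {"BPD": sm.BPD, "OFD": sm.OFD, "CI": sm.CI}
    return report
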