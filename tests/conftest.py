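"""Shared fixtures: coarse phantoms and models built once per session."""
import numpy as np
import pytest

from craniospring import (OsteotomySpec, PhantomSpec, PopulationParams,
                          attach_springs, build_s_model)
from craniospring.synthetic import generate_head


@pytest.fixture(scope="session")
def coarse_spec():
    """Fast phantom (~8 mm edges) for geometry and builder unit tests."""
    return PhantomSpec(mesh_resolution=8.0)


@pytest.fixture(scope="session")
def coarse_head(coarse_spec):
    return generate_head(coarse_spec)


@pytest.fixture(scope="session")
def coarse_model(coarse_head):
    head, landmarks = coarse_head
    model = build_s_model(head, landmarks, PopulationParams(),
                          OsteotomySpec())
    return attach_springs(model, ("S12", "S12"))


@pytest.fixture(scope="session")
def default_spec():
    """The package-default study phantom (4 mm edges)."""
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_model(default_spec):
    head, landmarks = generate_head(default_spec)
    model = build_s_model(head, landmarks, PopulationParams(),
                          OsteotomySpec())
    return attach_springs(model, ("S12", "S12"))


def two_flap_toy(stiffness=0.02, nz=16, ny=4, length=40.0, width=8.0,
                 offset=25.0, youngs=400.0, thickness=2.5, prony=()):
    """Two vertical cantilever strips + one spring between their tips.

    Returns (system, [spring], beam parameters dict).  With Poisson 0 the
    strips follow Euler-Bernoulli beam theory, giving a closed-form 1-DOF
    oracle for the equilibrium opening.
    """
    from craniospring.fem_spring import FESystem
    from craniospring.types import Material, SpringElement

    def strip(xsign):
        zs = np.linspace(0, length, nz + 1)
        ys = np.linspace(-width / 2, width / 2, ny + 1)
        Z, Y = np.meshgrid(zs, ys, indexing="ij")
        v = np.column_stack([np.full(Z.size, xsign * offset), Y.ravel(),
                             Z.ravel()])
        f = []
        def nid(i, j):
            return i * (ny + 1) + j
        for i in range(nz):
            for j in range(ny):
                a, b, c, d = nid(i, j), nid(i, j + 1), nid(i + 1, j), \
                    nid(i + 1, j + 1)
                f += [[a, b, d], [a, d, c]]
        return v, np.array(f)

    v1, f1 = strip(-1)
    v2, f2 = strip(+1)
    verts = np.vstack([v1, v2])
    faces = np.vstack([f1, f2 + len(v1)])
    mat = Material(youngs_modulus=youngs, poisson=0.0, prony_terms=prony)
    fixed = np.flatnonzero(np.abs(verts[:, 2]) < 1e-9)
    system = FESystem.from_arrays(verts, faces, mat, thickness, fixed)
    tip1 = int(np.flatnonzero((np.abs(v1[:, 2] - length) < 1e-9)
                              & (np.abs(v1[:, 1]) < 1e-9))[0])
    tip2 = int(np.flatnonzero((np.abs(v2[:, 2] - length) < 1e-9)
                              & (np.abs(v2[:, 1]) < 1e-9))[0]) + len(v1)
    spring = SpringElement(model_id="S12", stiffness=stiffness,
                           node_a=tip1, node_b=tip2, free_length=60.0)
    params = dict(length=length, width=width, youngs=youngs,
                  thickness=thickness, d0=2 * offset, k=stiffness)
    return system, [spring], params


def flap_oracle_opening(params):
    """1-DOF energy-minimisation oracle for the two-flap toy."""
    from scipy.optimize import minimize_scalar
    L, w, E, t = (params["length"], params["width"], params["youngs"],
                  params["thickness"])
    inertia = w * t**3 / 12.0
    c = 3 * E * inertia / L**3          # cantilever tip stiffness
    k, d0 = params["k"], params["d0"]

    def energy(dl):
        return 2 * 0.5 * c * (dl / 2)**2 + 0.5 * k * (60.0 - (d0 + dl))**2

    res = minimize_scalar(energy, bounds=(0.0, 60.0 - d0), method="bounded")
    return d0 + res.x
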