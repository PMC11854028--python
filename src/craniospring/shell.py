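"""Flat triangular shell element kernels.

Membrane response is the constant-strain triangle (CST); bending is the
discrete-Kirchhoff triangle (DKT) of Batoz-Bathe-Ho, exactly integrated
with the three-midside-point rule (the DKT strain interpolation is linear
in the area coordinates, so the quadratic integrand is integrated
exactly).  A small drilling stiffness regularises the in-plane rotation.

All kernels are vectorised over an array of elements: inputs are stacked
local coordinates (n, 3) and material matrices, outputs stacked element
matrices.  Local DOF order per node is (ux, uy, uz=w, thx, thy, thz) with
thx/thy the right-handed rotations about the local x/y axes.
"""
from __future__ import annotations

import numpy as np

# Gauss points for exact integration of the quadratic DKT integrand
_GAUSS = np.array([[0.5, 0.0], [0.5, 0.5], [0.0, 0.5]])
_WEIGHT = 1.0 / 6.0

#: relative drilling stiffness (fraction of the peak bending diagonal)
DRILL_FACTOR = 1.0e-3


def cst_membrane(x: np.ndarray, y: np.ndarray, dm: np.ndarray) -> np.ndarray:
    """Stacked CST membrane stiffness (n, 6, 6).

    ``x``/``y`` are local node coordinates (n, 3); ``dm`` the membrane
    elasticity matrix t*C (n, 3, 3).  DOF order (u1, v1, u2, v2, u3, v3).
    """
    x23 = x[:, 1] - x[:, 2]
    x31 = x[:, 2] - x[:, 0]
    x12 = x[:, 0] - x[:, 1]
    y23 = y[:, 1] - y[:, 2]
    y31 = y[:, 2] - y[:, 0]
    y12 = y[:, 0] - y[:, 1]
    area2 = x31 * (-y12) - x12 * (-y31)  # 2A (signed); positive for ccw
    area2 = np.where(np.abs(area2) < 1e-30, 1e-30, area2)
    n = len(x)
    b = np.zeros((n, 3, 6))
    b[:, 0, 0], b[:, 0, 2], b[:, 0, 4] = y23, y31, y12
    b[:, 1, 1], b[:, 1, 3], b[:, 1, 5] = -x23, -x31, -x12
    b[:, 2, 0], b[:, 2, 2], b[:, 2, 4] = -x23, -x31, -x12
    b[:, 2, 1], b[:, 2, 3], b[:, 2, 5] = y23, y31, y12
    b = b / area2[:, None, None]
    area = 0.5 * np.abs(area2)
    return np.einsum("nji,njk,nkl,n->nil", b, dm, b, area)


def _dkt_h_derivs(xi: float, eta: float, p, q, t, r):
    """The four DKT shape-derivative vectors at one Gauss point.

    ``p, q, t, r`` are the side-geometry coefficient arrays keyed 4, 5, 6
    (sides 23, 31, 12); each entry is an array over elements.  Returns
    (Hx_xi, Hy_xi, Hx_eta, Hy_eta), each (n, 9).
    """
    p4, p5, p6 = p
    q4, q5, q6 = q
    t4, t5, t6 = t
    r4, r5, r6 = r
    n = len(p4)
    z = np.zeros(n)
    hx_xi = np.stack([
        p6 * (1 - 2 * xi) + (p5 - p6) * eta,
        q6 * (1 - 2 * xi) - (q5 + q6) * eta,
        -4 + 6 * (xi + eta) + r6 * (1 - 2 * xi) - eta * (r5 + r6),
        -p6 * (1 - 2 * xi) + eta * (p4 + p6),
        q6 * (1 - 2 * xi) - eta * (q6 - q4),
        -2 + 6 * xi + r6 * (1 - 2 * xi) + eta * (r4 - r6),
        -eta * (p5 + p4),
        eta * (q4 - q5),
        -eta * (r5 - r4)], axis=1)
    hy_xi = np.stack([
        t6 * (1 - 2 * xi) + eta * (t5 - t6),
        1 + r6 * (1 - 2 * xi) - eta * (r5 + r6),
        -q6 * (1 - 2 * xi) + eta * (q5 + q6),
        -t6 * (1 - 2 * xi) + eta * (t4 + t6),
        -1 + r6 * (1 - 2 * xi) + eta * (r4 - r6),
        -q6 * (1 - 2 * xi) - eta * (q4 - q6),
        -eta * (t4 + t5),
        eta * (r4 - r5),
        -eta * (q4 - q5)], axis=1)
    hx_eta = np.stack([
        -p5 * (1 - 2 * eta) - xi * (p6 - p5),
        q5 * (1 - 2 * eta) - xi * (q5 + q6),
        -4 + 6 * (xi + eta) + r5 * (1 - 2 * eta) - xi * (r5 + r6),
        xi * (p4 + p6),
        xi * (q4 - q6),
        -xi * (r6 - r4),
        p5 * (1 - 2 * eta) - xi * (p4 + p5),
        q5 * (1 - 2 * eta) + xi * (q4 - q5),
        -2 + 6 * eta + r5 * (1 - 2 * eta) + xi * (r4 - r5)], axis=1)
    hy_eta = np.stack([
        -t5 * (1 - 2 * eta) - xi * (t6 - t5),
        1 + r5 * (1 - 2 * eta) - xi * (r5 + r6),
        -q5 * (1 - 2 * eta) + xi * (q5 + q6),
        xi * (t4 + t6),
        xi * (r4 - r6),
        -xi * (q4 - q6),
        t5 * (1 - 2 * eta) - xi * (t4 + t5),
        -1 + r5 * (1 - 2 * eta) + xi * (r4 - r5),
        -q5 * (1 - 2 * eta) - xi * (q4 - q5)], axis=1)
    del z
    return hx_xi, hy_xi, hx_eta, hy_eta


def dkt_bending(x: np.ndarray, y: np.ndarray, db: np.ndarray) -> np.ndarray:
    """Stacked DKT bending stiffness (n, 9, 9).

    ``db`` is the plate rigidity matrix (t^3/12) C (n, 3, 3).  DOF order
    (w1, thx1, thy1, w2, ...) in the Batoz convention: thx is the rotation
    about x (= dw/dy for Kirchhoff), thy about y (= -dw/dx).
    """
    x23 = x[:, 1] - x[:, 2]
    x31 = x[:, 2] - x[:, 0]
    x12 = x[:, 0] - x[:, 1]
    y23 = y[:, 1] - y[:, 2]
    y31 = y[:, 2] - y[:, 0]
    y12 = y[:, 0] - y[:, 1]

    def side(xx, yy):
        l2 = xx**2 + yy**2
        return (-6 * xx / l2, 3 * xx * yy / l2, -6 * yy / l2, 3 * yy**2 / l2)

    p4, q4, t4, r4 = side(x23, y23)
    p5, q5, t5, r5 = side(x31, y31)
    p6, q6, t6, r6 = side(x12, y12)
    area2 = x31 * y12 - x12 * y31
    area2 = np.where(np.abs(area2) < 1e-30, 1e-30, area2)
    k = np.zeros((len(x), 9, 9))
    for xi, eta in _GAUSS:
        hx_xi, hy_xi, hx_eta, hy_eta = _dkt_h_derivs(
            xi, eta, (p4, p5, p6), (q4, q5, q6), (t4, t5, t6), (r4, r5, r6))
        b = np.empty((len(x), 3, 9))
        b[:, 0] = (y31[:, None] * hx_xi + y12[:, None] * hx_eta)
        b[:, 1] = (-x31[:, None] * hy_xi - x12[:, None] * hy_eta)
        b[:, 2] = (-x31[:, None] * hx_xi - x12[:, None] * hx_eta
                   + y31[:, None] * hy_xi + y12[:, None] * hy_eta)
        b /= area2[:, None, None]
        k += _WEIGHT * np.einsum("nji,njk,nkl->nil", b, db, b)
    return k * np.abs(area2)[:, None, None]


def elastic_matrices(youngs: np.ndarray, poisson: np.ndarray,
                     thickness: float) -> tuple[np.ndarray, np.ndarray]:
    """Membrane (t C) and bending (t^3/12 C) matrices per element."""
    e = np.asarray(youngs, dtype=float)
    nu = np.asarray(poisson, dtype=float)
    c = np.zeros((len(e), 3, 3))
    f = e / (1 - nu**2)
    c[:, 0, 0] = c[:, 1, 1] = f
    c[:, 0, 1] = c[:, 1, 0] = f * nu
    c[:, 2, 2] = f * (1 - nu) / 2
    return thickness * c, (thickness**3 / 12.0) * c


def shell_stiffness(local_xy: np.ndarray, youngs: np.ndarray,
                    poisson: np.ndarray, thickness: float) -> np.ndarray:
    """Stacked 18x18 local shell stiffness matrices.

    ``local_xy`` is (n, 3, 2): in-plane node coordinates in the element
    frame.  Per-node DOF order (ux, uy, w, thx, thy, thz); the drilling
    (thz) diagonal is a small fraction of the peak bending diagonal.
    """
    x = local_xy[:, :, 0]
    y = local_xy[:, :, 1]
    dm, db = elastic_matrices(youngs, poisson, thickness)
    km = cst_membrane(x, y, dm)
    kb = dkt_bending(x, y, db)
    n = len(x)
    k = np.zeros((n, 18, 18))
    mem_idx = np.array([0, 1, 6, 7, 12, 13])
    bend_idx = np.array([2, 3, 4, 8, 9, 10, 14, 15, 16])
    k[:, mem_idx[:, None], mem_idx[None, :]] += km
    k[:, bend_idx[:, None], bend_idx[None, :]] += kb
    drill = DRILL_FACTOR * kb.reshape(n, -1).max(axis=1)
    for d in (5, 11, 17):
        k[:, d, d] = drill
    return k
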