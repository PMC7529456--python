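"""Independent numerical oracles used by the test suite.

These deliberately avoid the solution paths of the package: energy
minimization instead of root finding for the axisymmetric equilibrium, a
global finite-difference collocation matrix instead of compound-matrix
shooting for the buckling determinant, and plain central differences for
derivative checks.
"""

import numpy as np
from scipy.optimize import minimize_scalar

from cordclose.buckling import _BaseState, _coefficient_matrix


def energy_minimum_radius(model, pressure_mmhg, T_act=0.0, v=1.0,
                          bracket_rel=(0.2, 2.5)):
    """Equilibrium inner radius by direct minimization of the total
    potential energy over the one remaining kinematic degree of freedom."""
    A = model.geometry.A

    def E(a):
        return model.total_potential_energy(a, pressure_mmhg, T_act=T_act, v=v)

    grid = np.linspace(bracket_rel[0] * A, bracket_rel[1] * A, 220)
    vals = [E(a) for a in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(E, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def fd_mode_determinant_sign(model, n, pressure_mmhg, T_act, v=1.0,
                             nodes_per_layer=220, state=None):
    """Sign (and log magnitude) of the determinant of the finite-difference
    collocation matrix of the incremental boundary-value problem.

    Midpoint (Crank-Nicolson) discretization of y' = M(r) y per layer, with
    the luminal follower-pressure rows and outer traction-free rows closing
    the square system.  A sign change in the loading parameter brackets a
    bifurcation, independently of the shooting integrator.
    """
    if state is None:
        state = model.solve(pressure_mmhg, T_act=T_act, v=v)
    base = _BaseState(model, state)
    P = state.pressure_kpa
    a, b, c = base.a, base.b, base.c
    grids = [np.linspace(a, b, nodes_per_layer),
             np.linspace(b, c, nodes_per_layer)]
    Ntot = 2 * nodes_per_layer  # interface node duplicated (continuity rows)
    dim = 4 * Ntot
    K = np.zeros((dim, dim))
    row = 0
    offset = 0
    for layer, rs in enumerate(grids):
        for i in range(len(rs) - 1):
            h = rs[i + 1] - rs[i]
            Mm = _coefficient_matrix(0.5 * (rs[i] + rs[i + 1]), base, n, layer)
            blk_i = -(np.eye(4) + 0.5 * h * Mm)
            blk_j = np.eye(4) - 0.5 * h * Mm
            K[row:row + 4, offset + 4 * i: offset + 4 * i + 4] = blk_i
            K[row:row + 4, offset + 4 * (i + 1): offset + 4 * (i + 1) + 4] = blk_j
            row += 4
        offset += 4 * len(rs)
    # interface continuity: last node of layer 0 == first node of layer 1
    i0 = 4 * (nodes_per_layer - 1)
    i1 = 4 * nodes_per_layer
    for k in range(4):
        K[row, i0 + k] = 1.0
        K[row, i1 + k] = -1.0
        row += 1
    # luminal follower pressure: Trr + P(U + nV)/a = 0 ; Trt + P(nU + V)/a = 0
    K[row, 0] = P / a
    K[row, 1] = n * P / a
    K[row, 2] = 1.0
    row += 1
    K[row, 0] = n * P / a
    K[row, 1] = P / a
    K[row, 3] = 1.0
    row += 1
    # outer surface traction-free
    K[row, dim - 2] = 1.0
    row += 1
    K[row, dim - 1] = 1.0
    row += 1
    assert row == dim
    sign, logdet = np.linalg.slogdet(K)
    return sign, logdet


def central_difference(f, x, h):
    return (f(x + h) - f(x - h)) / (2.0 * h)
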