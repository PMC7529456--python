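"""Linear stability of the loaded bilayer tube: contraction-induced folding.

Circumferential folding of the compressed inner layer is detected by a
small-on-large (incremental) bifurcation analysis of the axisymmetric base
state.  Perturbations are plane strain at fixed axial stretch,

    u_r = U(r) cos(n theta),   u_theta = V(r) sin(n theta),

with incompressible increments.  Writing the incremental nominal stress
with instantaneous moduli ``A0`` and the base-state Lagrange multiplier
``p(r)``, the incremental equilibrium equations reduce to a linear 4x4
first-order system in the state vector ``y = (U, V, Trr, Trt)`` where
``Trr cos(n t)`` and ``Trt sin(n t)`` are the radial-face incremental
traction components.  The system is integrated from the lumen (follower-
pressure boundary condition) through both layers (displacement and traction
continuous at the interface) to the adventitial surface; vanishing of the
2x2 determinant of the outer traction components of two independent
solutions signals a nontrivial folded equilibrium.  The smallest active
stress at which the determinant crosses zero is the critical contractile
stress for mode ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .constitutive import ActiveTone, LayerMaterial, wall_derivatives
from .equilibrium import BilayerVesselModel, LoadedState

__all__ = [
    "BucklingResult",
    "EllipticityLossError",
    "incremental_moduli",
    "mode_determinant",
    "critical_active_stress",
    "fold_sweep",
    "plateau_mode",
]


class EllipticityLossError(RuntimeError):
    """The incremental problem is ill-posed: the in-plane shear modulus of
    the actively stressed material is non-positive somewhere in the wall, so
    short-wavelength (material, not structural) instability precedes any
    global fold and the bifurcation determinant is undefined."""


@dataclass
class BucklingResult:
    """Critical active stress for one circumferential fold number."""

    n: int
    v: float
    pressure_mmhg: float
    T_act_crit: float  # kPa; NaN if not found
    converged: bool
    status: str  # "converged" | "no-crossing" | "closure-without-buckling"
    T_act_grid: np.ndarray = None
    determinants: np.ndarray = None


# ---------------------------------------------------------------------------
# instantaneous moduli
# ---------------------------------------------------------------------------


def incremental_moduli(
    lambda_r,
    lambda_theta,
    lambda_z,
    material: LayerMaterial,
    tone: ActiveTone | None = None,
    active_stiffness: bool = True,
    formulation: str = "principal",
):
    """In-plane instantaneous (small-on-large) moduli at a deformed state.

    Returns a dict of the principal-axis components ``A0_rrrr, A0_tttt,
    A0_rrtt, A0_rtrt, A0_trtr, A0_rttr`` (kPa) for plane-strain increments
    at fixed axial stretch, plus ``sigma_aniso``, a circumferential extra
    stress entering the assembled system as a structural shear term on the
    theta face (zero in the principal formulation).

    Two formulations of the shear response are available, reflecting a
    genuinely open modelling choice for fiber-reinforced, actively stressed
    tissue (they coincide for the isotropic matrix):

    * ``"principal"`` (default): the layer energy, including fiber terms
      and the active stretch potential, is treated as a function of the
      principal stretches and the classical quotient formulas give the
      shear moduli.  This is the formulation customary in tube-buckling
      analyses of arteries with smooth-muscle tone.
    * ``"structural"``: quotient formulas are applied to the neo-Hookean
      matrix only (where they are exact), while fibers and active muscle
      convect with the deformation as one-dimensional tension elements,
      contributing a circumferential stiffness ``lt^2 Wtt_aniso`` and the
      structural term ``sigma_aniso u_r,theta``; the shear response is then
      always elliptic.
    """
    lr = np.asarray(lambda_r, dtype=float)
    lt = np.asarray(lambda_theta, dtype=float)
    lr, lt = np.broadcast_arrays(lr, lt)
    mu = material.mu
    if formulation == "principal":
        # nudge coincident stretches (quotient formulas are 0/0 there)
        close = np.abs(lr**2 - lt**2) < 1e-7 * (lr**2 + lt**2)
        lr = np.where(close, lr * (1.0 + 1e-5), lr)
        lt = np.where(close, lt * (1.0 - 1e-5), lt)
        d = wall_derivatives(lr, lt, lambda_z, material, tone=tone,
                             active_stiffness=active_stiffness)
        Wr, Wt = d["Wr"], d["Wt"]
        denom = lr**2 - lt**2
        num = lr * Wr - lt * Wt
        return {
            "A0_rrrr": lr**2 * d["Wrr"],
            "A0_tttt": lt**2 * d["Wtt"],
            "A0_rrtt": lr * lt * d["Wrt"],
            "A0_rtrt": num * lr**2 / denom,
            "A0_trtr": num * lt**2 / denom,
            "A0_rttr": (lt * Wr - lr * Wt) * lr * lt / denom,
            "sigma_aniso": np.zeros_like(lr),
        }
    if formulation == "structural":
        full = wall_derivatives(lr, lt, lambda_z, material, tone=tone,
                                active_stiffness=active_stiffness)
        # isotropic parts: Wr = mu*lr, Wt_iso = mu*lt, Wrr = Wtt_iso = mu
        Wt_aniso = full["Wt"] - mu * lt
        Wtt_aniso = full["Wtt"] - mu
        return {
            "A0_rrrr": lr**2 * mu,
            "A0_tttt": lt**2 * (mu + Wtt_aniso),
            "A0_rrtt": lr * lt * full["Wrt"],
            "A0_rtrt": mu * lr**2,
            "A0_trtr": mu * lt**2,
            "A0_rttr": np.zeros_like(lr),
            "sigma_aniso": lt * Wt_aniso,
        }
    raise ValueError(f"unknown formulation {formulation!r}")


# ---------------------------------------------------------------------------
# base-state wrapper
# ---------------------------------------------------------------------------


class _BaseState:
    """Radial fields of a solved axisymmetric state, evaluable at any r."""

    def __init__(self, model: BilayerVesselModel, state: LoadedState,
                 active_stiffness: bool = True, formulation: str = "principal"):
        self.model = model
        self.state = state
        self.active_stiffness = active_stiffness
        self.formulation = formulation
        g = model.geometry
        self.lz = g.lambda_z
        self.a, self.b, self.c = state.a, state.b, state.c_out
        self._srr = []
        for layer in (0, 1):
            sel = state.layer == layer
            self._srr.append(CubicSpline(state.r[sel], state.sigma_rr[sel]))
        self._refs = ((g.A, g.B), (g.B, g.C))
        self._edges = ((self.a, self.b), (self.b, self.c))

    def layer_of(self, r: float) -> int:
        return 0 if r <= self.b else 1

    def fields(self, r, layer: int):
        """lt, lr, p and moduli at deformed radius r inside the given layer."""
        model, st = self.model, self.state
        g = model.geometry
        Rlo = self._refs[layer][0]
        rlo = self._edges[layer][0]
        jac = st.v if layer == 0 else 1.0
        R = np.sqrt(Rlo**2 + self.lz * (np.asarray(r, float) ** 2 - rlo**2) / jac)
        lt = r / R
        lr = jac * R / (self.lz * r)
        mat = model.materials[layer]
        tone = None
        if st.T_act > 0.0 and model.contractile[layer]:
            tone = model.tone.with_magnitude(st.T_act)
        mod = incremental_moduli(lr, lt, self.lz, mat, tone=tone,
                                 active_stiffness=self.active_stiffness,
                                 formulation=self.formulation)
        # multiplier from sigma_rr = lr*Wr - p (radial stress has no active part)
        Wr = wall_derivatives(lr, lt, self.lz, mat)["Wr"]
        p = lr * Wr - self._srr[layer](r)
        return lt, lr, p, mod


# ---------------------------------------------------------------------------
# incremental ODE system and determinant
# ---------------------------------------------------------------------------


def _coefficient_matrix(r, base: _BaseState, n: int, layer: int) -> np.ndarray:
    """Matrix M(r) of the linear system y' = M y, y = (U, V, Trr, Trt)."""
    lt, lr, p, mod = base.fields(r, layer)
    alpha = mod["A0_rtrt"]
    beta = mod["A0_rttr"] + p
    # convected fibers/active add their theta-stress to the theta-face shear
    gamma = mod["A0_trtr"] + mod["sigma_aniso"]
    k1 = mod["A0_rrrr"] + p
    k2 = mod["A0_tttt"] + p
    c12 = mod["A0_rrtt"]

    M = np.zeros((4, 4))
    # U' = -(U + nV)/r
    M[0, 0] = -1.0 / r
    M[0, 1] = -n / r
    # V' = [Trt + beta (nU + V)/r] / alpha
    M[1, 0] = beta * n / (alpha * r)
    M[1, 1] = beta / (alpha * r)
    M[1, 3] = 1.0 / alpha
    # eliminating the incremental pressure via Trr:
    #   Ttt = (c12 - k1) U' + (k2 - c12)(U + nV)/r + Trr
    #   Ttr = -gamma (nU + V)/r + beta V'
    q = (k1 - c12 + k2 - c12) / r  # coefficient of (U + nV)/r in Ttt
    Ttt_row = np.array([q, n * q, 1.0, 0.0])
    Ttr_row = np.array(
        [-gamma * n / r + beta * M[1, 0],
         -gamma / r + beta * M[1, 1],
         0.0,
         beta * M[1, 3]]
    )
    # Trr' = -(Trr - Ttt + n Ttr)/r
    M[2] = (Ttt_row - n * Ttr_row) / r
    M[2, 2] -= 1.0 / r
    # Trt' = (n Ttt - Trt - Ttr)/r
    M[3] = (n * Ttt_row - Ttr_row) / r
    M[3, 3] -= 1.0 / r
    return M


_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


def _compound_rhs(s, w, base: _BaseState, n: int, layer: int):
    """Second-compound system for the wedge of two solutions, in s = ln r.

    Evolving the six 2x2 minors of the solution pair avoids the numerical
    cancellation of near-parallel solutions at high mode numbers; the
    logarithmic radial coordinate keeps the coefficients O(n) even for
    strongly contracted lumens.
    """
    r = np.exp(s)
    M = r * _coefficient_matrix(r, base, n, layer)
    Phi = np.zeros((4, 4))
    for k, (i, j) in enumerate(_PAIRS):
        Phi[i, j] = w[k]
        Phi[j, i] = -w[k]
    dPhi = M @ Phi + Phi @ M.T
    return [dPhi[i, j] for i, j in _PAIRS]


def mode_determinant(
    model: BilayerVesselModel,
    n: int,
    pressure_mmhg: float,
    T_act: float,
    v: float = 1.0,
    state: LoadedState | None = None,
    active_stiffness: bool = True,
    formulation: str = "principal",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Boundary-condition determinant for fold mode ``n`` (dimensionless).

    Two independent solutions satisfying the luminal follower-pressure
    condition are propagated to the outer surface; the returned value is the
    determinant of their traction components there, normalized so that its
    zeros (bifurcation points) are scale-invariant.  Raises if the base
    state is occluded.
    """
    if n < 1:
        raise ValueError("mode number must be >= 1")
    if state is None:
        state = model.solve(pressure_mmhg, T_act=T_act, v=v)
    if state.occluded or state.a <= 0.0:
        raise RuntimeError("base state is occluded; no patent tube to perturb")
    base = _BaseState(model, state, active_stiffness=active_stiffness,
                      formulation=formulation)
    P = state.pressure_kpa
    a, b, c = base.a, base.b, base.c
    # the ODE divides by the shear modulus A0_rtrt; a sign change inside a
    # layer is an interior singularity (short-wavelength material
    # instability) at which the fold determinant is undefined
    for layer, (rlo, rhi) in ((0, (a, b)), (1, (b, c))):
        rs = np.linspace(rlo, rhi, 80)
        _, _, _, mod = base.fields(rs, layer)
        al = mod["A0_rtrt"]
        if np.min(al) <= 0.0 < np.max(al):
            raise EllipticityLossError(
                f"in-plane shear modulus changes sign within layer {layer}"
            )
    # luminal BC: Trr = P U' = -P (U + nV)/a ; Trt = -P (nU + V)/a
    y1 = np.array([1.0, 0.0, -P / a, -n * P / a])
    y2 = np.array([0.0, 1.0, -n * P / a, -P / a])
    w = np.array([y1[i] * y2[j] - y1[j] * y2[i] for i, j in _PAIRS])
    w /= np.linalg.norm(w)
    for layer, (rlo, rhi) in ((0, (a, b)), (1, (b, c))):
        sol = solve_ivp(
            _compound_rhs, (np.log(rlo), np.log(rhi)), w, args=(base, n, layer),
            method="RK45", rtol=rtol, atol=atol, dense_output=False,
        )
        if not sol.success:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"incremental integration failed: {sol.message}")
        w = sol.y[:, -1]
        w = w / np.linalg.norm(w)  # positive rescaling keeps the sign
    # nondimensionalize: tractions are O(mu/r) per unit displacement in
    # kPa/um units, so rescale the traction slots before normalizing to
    # keep the reported determinant O(1) away from bifurcation
    s = max(m.mu for m in model.materials) / (0.5 * (a + c))
    scale = {0: 1.0, 1: 1.0, 2: 1.0 / s, 3: 1.0 / s}
    w = np.array([wk * scale[i] * scale[j] for wk, (i, j) in zip(w, _PAIRS)])
    w /= np.linalg.norm(w)
    # minor built from the two traction rows = boundary determinant
    return float(w[_PAIRS.index((2, 3))])


# ---------------------------------------------------------------------------
# critical stress search
# ---------------------------------------------------------------------------


def critical_active_stress(
    model: BilayerVesselModel,
    n: int,
    v: float,
    pressure_mmhg: float,
    search: tuple[float, float] = (1.0, 500.0),
    coarse_step: float = 10.0,
    xtol: float = 0.1,
    active_stiffness: bool = True,
    formulation: str = "principal",
    _state_cache: dict | None = None,
) -> BucklingResult:
    """Smallest active stress at which mode ``n`` admits a folded solution.

    Scans the determinant over a coarse active-stress grid and refines the
    first sign change by bisection to ``xtol`` (kPa).  If the base state
    occludes before any sign change the result is flagged
    "closure-without-buckling"; if the whole range is scanned without a
    crossing, "no-crossing".
    """
    if n < 2:
        raise ValueError("buckling modes require n >= 2")
    cache = _state_cache if _state_cache is not None else {}

    def get_state(T):
        key = round(float(T), 6)
        if key not in cache:
            cache[key] = model.solve(pressure_mmhg, T_act=T, v=v)
        return cache[key]

    def det_at(T):
        return mode_determinant(
            model, n, pressure_mmhg, T, v=v, state=get_state(T),
            active_stiffness=active_stiffness, formulation=formulation,
        )

    def locate(T1, T2, d1, d2, a1, a2, min_step=1.0):
        """Zero of the determinant inside (T1, T2), restricted to a
        continuous base-state branch.

        The pressure-radius relation can fold during strong contraction
        (snap-through); a determinant sign flip caused by the base state
        jumping branches is not a bifurcation, so intervals are subdivided
        until either the sign change is localized on a continuous segment
        or the jump is isolated and skipped.
        """
        continuous = abs(a1 - a2) <= 0.2 * max(a1, a2)
        if continuous:
            return brentq(det_at, T1, T2, xtol=xtol)
        if T2 - T1 < min_step:
            return None  # branch jump, not a zero
        Tm = 0.5 * (T1 + T2)
        stm = get_state(Tm)
        if stm.occluded:
            return None
        try:
            dm = det_at(Tm)
        except EllipticityLossError:
            return None
        if np.sign(d1) != np.sign(dm):
            res = locate(T1, Tm, d1, dm, a1, stm.a, min_step)
            if res is not None:
                return res
        if np.sign(dm) != np.sign(d2):
            return locate(Tm, T2, dm, d2, stm.a, a2, min_step)
        return None

    grid = np.arange(search[0], search[1] + 0.5 * coarse_step, coarse_step)
    dets, Ts = [], []
    status = "no-crossing"
    T_crit = None
    prev = None  # (T, det, a)
    for T in grid:
        st = get_state(T)
        if st.occluded:
            status = "closure-without-buckling"
            break
        try:
            d = det_at(T)
        except EllipticityLossError:
            status = "ellipticity-loss"
            break
        Ts.append(T)
        dets.append(d)
        if prev is not None and np.sign(d) != np.sign(prev[1]):
            T_crit = locate(prev[0], T, prev[1], d, prev[2], st.a)
            if T_crit is not None:
                break
        prev = (T, d, st.a)
    Ts, dets = np.asarray(Ts), np.asarray(dets)
    if T_crit is None:
        return BucklingResult(n=n, v=v, pressure_mmhg=pressure_mmhg,
                              T_act_crit=np.nan, converged=False, status=status,
                              T_act_grid=Ts, determinants=dets)
    return BucklingResult(n=n, v=v, pressure_mmhg=pressure_mmhg,
                          T_act_crit=float(T_crit), converged=True,
                          status="converged", T_act_grid=Ts, determinants=dets)


def plateau_mode(n_values: Sequence[int], T_crit: Sequence[float],
                 threshold: float = 0.05):
    """Smallest mode whose critical stress drops by less than ``threshold``
    (relative) from n to n+1; None if the curve never flattens."""
    n_values = np.asarray(n_values)
    T_crit = np.asarray(T_crit, dtype=float)
    order = np.argsort(n_values)
    n_values, T_crit = n_values[order], T_crit[order]
    for i in range(len(n_values) - 1):
        if n_values[i + 1] != n_values[i] + 1:
            continue
        if not (np.isfinite(T_crit[i]) and np.isfinite(T_crit[i + 1])):
            continue
        drop = (T_crit[i] - T_crit[i + 1]) / T_crit[i]
        if drop < threshold:
            return int(n_values[i])
    return None


def fold_sweep(
    model: BilayerVesselModel,
    n_values: Sequence[int],
    v_list: Sequence[float],
    pressure_mmhg: float,
    plateau_threshold: float = 0.05,
    **kwargs,
):
    """Critical stress over a grid of fold numbers and swelling levels.

    Returns ``(table, plateau)``: a tidy DataFrame of per-(n, v) results and
    a dict mapping each v to its plateau mode (or None).  Per-cell failures
    are recorded and the sweep continues.
    """
    rows = []
    plateau: dict[float, int | None] = {}
    for v in v_list:
        cache: dict = {}
        crit = []
        for n in n_values:
            try:
                res = critical_active_stress(
                    model, int(n), v, pressure_mmhg, _state_cache=cache, **kwargs
                )
                tc, status = res.T_act_crit, res.status
            except Exception as exc:  # pragma: no cover - per-cell robustness
                tc, status = np.nan, f"error: {exc}"
            crit.append(tc)
            rows.append({
                "n": int(n), "v": v, "P_mmHg": pressure_mmhg,
                "T_act_crit_kPa": tc,
                "converged": np.isfinite(tc), "status": status,
            })
        plateau[v] = plateau_mode(list(n_values), crit, plateau_threshold)
    return pd.DataFrame(rows), plateau
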