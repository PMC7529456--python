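"""Finite-deformation equilibrium of the pressurized, contracting bilayer tube.

The loaded configuration is a cylinder at fixed axial stretch ``lz`` whose
deformation is fully parametrized by the loaded inner radius ``a``: the
inner (GAG-rich) layer deforms isochorically *after* swelling to ``v``
times its reference volume, the outer layer is strictly incompressible, so

    inner  (A <= R <= B):  r^2 = a^2 + v (R^2 - A^2) / lz
    outer  (B <= R <= C):  r^2 = b^2 + (R^2 - B^2) / lz,   b = r(B)

with circumferential stretch ``lt = r/R`` and radial stretch
``lr = dr/dR`` (``v R/(lz r)`` inner, ``R/(lz r)`` outer).  Radial
equilibrium of the axisymmetric state integrates to

    P = int_a^c (sigma_tt - sigma_rr) / r dr

where the circumferential stress includes the active smooth-muscle stress
in contractile layers.  Solving this scalar relation for ``a`` at given
luminal pressure yields the loaded state; sweeping the active stress
magnitude produces lumen-closure curves.

Pressures are mmHg at the public API (converted internally to kPa),
radii um, stresses kPa, axial force mN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson
from scipy.optimize import brentq

from .constitutive import (
    MMHG_TO_KPA,
    ActiveTone,
    LayerMaterial,
    VesselGeometry,
    active_stress,
    passive_extra_stress,
)
from .params import VesselParameters

__all__ = [
    "LoadedState",
    "ClosureCurve",
    "BilayerVesselModel",
    "radius_map",
    "luminal_pressure",
    "solve_inner_radius",
    "closure_sweep",
    "swelling_crossover",
]


class InfeasibleGeometryError(ValueError):
    """Raised when the prescribed deformation map produces negative radii."""


# ---------------------------------------------------------------------------
# kinematic map
# ---------------------------------------------------------------------------


def radius_map(a: float, geometry: VesselGeometry, v: float = 1.0,
               lambda_z: float | None = None):
    """Deformed radius r(R) for loaded inner radius ``a``.

    Returns a callable evaluating r at reference radii in [A, C]; the
    interface maps to ``b = r(B)``.
    """
    if a < 0.0:
        raise InfeasibleGeometryError("inner radius must be non-negative")
    lz = geometry.lambda_z if lambda_z is None else lambda_z
    A, B = geometry.A, geometry.B

    def r_of_R(R):
        R = np.asarray(R, dtype=float)
        b2 = a**2 + v * (B**2 - A**2) / lz
        inner = R <= B
        r2 = np.where(
            inner,
            a**2 + v * (np.minimum(R, B) ** 2 - A**2) / lz,
            b2 + (np.maximum(R, B) ** 2 - B**2) / lz,
        )
        if np.any(r2 < 0.0):
            raise InfeasibleGeometryError("deformation map yields negative r^2")
        return np.sqrt(r2)

    return r_of_R


# ---------------------------------------------------------------------------
# loaded state container
# ---------------------------------------------------------------------------


@dataclass
class LoadedState:
    """Solved axisymmetric configuration of the bilayered vessel.

    Radial profiles are sampled on a per-layer grid in the reference radius;
    stresses are total Cauchy stresses (Lagrange multiplier included, active
    stress included in the circumferential component of contractile layers).
    """

    a: float
    b: float
    c_out: float
    pressure_mmhg: float
    lambda_z: float
    T_act: float
    v: float
    occluded: bool = False
    r: np.ndarray = field(default=None, repr=False)
    R: np.ndarray = field(default=None, repr=False)
    layer: np.ndarray = field(default=None, repr=False)  # 0 inner, 1 outer
    lambda_r: np.ndarray = field(default=None, repr=False)
    lambda_t: np.ndarray = field(default=None, repr=False)
    sigma_rr: np.ndarray = field(default=None, repr=False)
    sigma_tt: np.ndarray = field(default=None, repr=False)
    sigma_zz: np.ndarray = field(default=None, repr=False)
    f_axial: float = np.nan
    mean_sigma_tt_inner: float = np.nan
    mean_sigma_tt_outer: float = np.nan

    @property
    def outer_diameter(self) -> float:
        return 2.0 * self.c_out

    @property
    def pressure_kpa(self) -> float:
        return self.pressure_mmhg * MMHG_TO_KPA


@dataclass
class ClosureCurve:
    """Normalized inner radius versus active stress at fixed pressure and swelling."""

    v: float
    pressure_mmhg: float
    T_act: np.ndarray
    a: np.ndarray
    a_normalized: np.ndarray
    outer_diameter: np.ndarray
    mean_sigma_tt_inner: np.ndarray
    mean_sigma_tt_outer: np.ndarray
    f_axial: np.ndarray
    occluded: np.ndarray

    @property
    def max_slope(self) -> float:
        """Largest magnitude of d(a/a0)/dT_act along the curve (per kPa)."""
        slopes = np.gradient(self.a_normalized, self.T_act)
        return float(np.nanmax(np.abs(slopes)))

    @property
    def transition_T_act(self) -> float:
        """Active stress at the steepest point of the closure curve (kPa)."""
        slopes = np.gradient(self.a_normalized, self.T_act)
        return float(self.T_act[np.nanargmax(np.abs(slopes))])

    def plateau_reached(self, tol_per_kpa: float = 1e-3) -> bool:
        """True if |da/dT_act| at the end of the grid is below tol (um/kPa)."""
        slopes = np.gradient(self.a, self.T_act)
        return bool(abs(slopes[-1]) < tol_per_kpa)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "v": self.v,
                "P_mmHg": self.pressure_mmhg,
                "T_act_kPa": self.T_act,
                "a_um": self.a,
                "a_normalized": self.a_normalized,
                "outer_diameter_um": self.outer_diameter,
                "mean_sigma_theta_inner_kPa": self.mean_sigma_tt_inner,
                "mean_sigma_theta_outer_kPa": self.mean_sigma_tt_outer,
                "f_axial_mN": self.f_axial,
                "occluded": self.occluded,
            }
        )


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class BilayerVesselModel:
    """Thick-walled bilayered vessel under pressure, axial stretch, swelling
    and smooth-muscle contraction.

    Parameters
    ----------
    params : VesselParameters
        Geometry, per-layer passive materials and smooth-muscle tone window.
    contractile_layers : tuple of {"inner", "outer"}
        Layers generating active circumferential stress (default outer only).
    nodes_per_layer : int
        Gauss-Legendre quadrature nodes per layer for the radial integrals.
    """

    #: bracket for the loaded inner radius, in units of the unloaded radius A
    A_BRACKET = (1e-3, 3.0)

    def __init__(self, params: VesselParameters,
                 contractile_layers: tuple[str, ...] = ("outer",),
                 nodes_per_layer: int = 200):
        self.params = params
        self.geometry = params.geometry
        self.materials = (params.inner, params.outer)
        self.tone = params.tone
        self.contractile = (
            "inner" in contractile_layers,
            "outer" in contractile_layers,
        )
        self.nodes_per_layer = int(nodes_per_layer)
        g = self.geometry
        self._bounds = ((g.A, g.B), (g.B, g.C))
        x, w = np.polynomial.legendre.leggauss(self.nodes_per_layer)
        self._gauss = (x, w)

    @classmethod
    def uniform_wall(cls, params: VesselParameters, **kw) -> "BilayerVesselModel":
        """Single-material comparator: outer-layer material and contractility
        throughout the wall (no GAG-rich inner specialization)."""
        uni = VesselParameters(
            geometry=params.geometry, inner=params.outer, outer=params.outer,
            tone=params.tone,
        )
        kw.setdefault("contractile_layers", ("inner", "outer"))
        return cls(uni, **kw)

    # -- kinematics ---------------------------------------------------------

    def _layer_nodes(self, layer: int):
        """Gauss nodes/weights mapped to the layer's reference-radius span."""
        lo, hi = self._bounds[layer]
        x, w = self._gauss
        R = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
        return R, 0.5 * (hi - lo) * w

    def _layer_kinematics(self, a, v: float, layer: int, R: np.ndarray):
        """lt, lr, r at reference radii R for loaded inner radius a (vectorized).

        ``a`` may be an array; results broadcast to shape (np.size(a), R.size).
        """
        g = self.geometry
        lz = g.lambda_z
        a = np.atleast_1d(np.asarray(a, dtype=float))[:, None]
        if layer == 0:
            r2 = a**2 + v * (R**2 - g.A**2) / lz
            jac = v
        else:
            b2 = a**2 + v * (g.B**2 - g.A**2) / lz
            r2 = b2 + (R**2 - g.B**2) / lz
            jac = 1.0
        r = np.sqrt(r2)
        lt = r / R
        lr = jac * R / (lz * r)
        return lt, lr, r

    def interface_radius(self, a, v: float):
        g = self.geometry
        return np.sqrt(np.asarray(a, dtype=float) ** 2 + v * (g.B**2 - g.A**2) / g.lambda_z)

    def outer_radius(self, a, v: float):
        g = self.geometry
        b2 = np.asarray(a, dtype=float) ** 2 + v * (g.B**2 - g.A**2) / g.lambda_z
        return np.sqrt(b2 + (g.C**2 - g.B**2) / g.lambda_z)

    def inner_radius_from_outer(self, c_out, v: float):
        """Invert the deformation map: loaded inner radius from outer radius."""
        g = self.geometry
        b2 = np.asarray(c_out, dtype=float) ** 2 - (g.C**2 - g.B**2) / g.lambda_z
        a2 = b2 - v * (g.B**2 - g.A**2) / g.lambda_z
        a2 = np.asarray(a2)
        if np.any(a2 < 0.0):
            raise InfeasibleGeometryError("outer radius implies negative lumen")
        return np.sqrt(a2)

    # -- equilibrium integrals ----------------------------------------------

    def _total_stresses(self, lt, lr, layer: int, T_act: float):
        """Extra Cauchy stresses (radial, circumferential incl. active, axial)."""
        lz = self.geometry.lambda_z
        srr, stt, szz = passive_extra_stress(lr, lt, lz, self.materials[layer])
        if T_act > 0.0 and self.contractile[layer]:
            stt = stt + active_stress(lt, self.tone.with_magnitude(T_act))
        return np.broadcast_arrays(srr, stt, szz)

    def pressure_and_force(self, a, T_act: float = 0.0, v: float = 1.0):
        """Luminal pressure (kPa) and transducer axial force (mN) at inner
        radius ``a`` (scalar or array)."""
        a_arr = np.atleast_1d(np.asarray(a, dtype=float))
        P = np.zeros(a_arr.shape)
        f = np.zeros(a_arr.shape)
        for layer in (0, 1):
            R, w = self._layer_nodes(layer)
            lt, lr, r = self._layer_kinematics(a_arr, v, layer, R)
            srr, stt, szz = self._total_stresses(lt, lr, layer, T_act)
            # dr = lr dR maps the quadrature to the deformed annulus
            P += ((stt - srr) / r * lr) @ w
            f += ((2.0 * szz - stt - srr) * r * lr) @ w
        f *= np.pi * 1e-6  # kPa*um^2 -> mN
        if np.isscalar(a) or np.ndim(a) == 0:
            return float(P[0]), float(f[0])
        return P, f

    def luminal_pressure(self, a, T_act: float = 0.0, v: float = 1.0):
        """Equilibrium luminal pressure (kPa) supporting inner radius ``a``."""
        return self.pressure_and_force(a, T_act=T_act, v=v)[0]

    # -- solving -------------------------------------------------------------

    def solve(self, pressure_mmhg: float, T_act: float = 0.0, v: float = 1.0,
              profile_nodes: int = 201) -> LoadedState:
        """Solve for the loaded configuration at given pressure, tone and swelling.

        If the pressure-radius relation admits several equilibria (possible
        during strong contraction), the largest-radius root is returned: it
        is the configuration reached quasi-statically from the patent state
        under pressure control.
        """
        if pressure_mmhg < 0.0:
            raise ValueError("pressure must be non-negative")
        P_target = pressure_mmhg * MMHG_TO_KPA
        A = self.geometry.A
        lo, hi = self.A_BRACKET
        a_grid = np.geomspace(lo * A, hi * A, 241)
        g_vals = self.pressure_and_force(a_grid, T_act=T_act, v=v)[0] - P_target
        sign = np.sign(g_vals)
        idx = np.nonzero(np.diff(sign) != 0)[0]
        if idx.size == 0:
            # no equilibrium with a patent lumen: occluded state
            return self._occluded_state(pressure_mmhg, T_act, v)
        i = idx[-1]  # largest-radius root = patent branch
        a_root = brentq(
            lambda aa: self.luminal_pressure(aa, T_act=T_act, v=v) - P_target,
            a_grid[i], a_grid[i + 1], xtol=1e-8 * A, rtol=1e-12,
        )
        return self._assemble_state(a_root, pressure_mmhg, T_act, v, profile_nodes)

    def _occluded_state(self, pressure_mmhg, T_act, v) -> LoadedState:
        g = self.geometry
        return LoadedState(
            a=0.0, b=float(self.interface_radius(0.0, v)),
            c_out=float(self.outer_radius(0.0, v)),
            pressure_mmhg=pressure_mmhg, lambda_z=g.lambda_z,
            T_act=T_act, v=v, occluded=True,
        )

    def _assemble_state(self, a, pressure_mmhg, T_act, v,
                        profile_nodes: int = 201) -> LoadedState:
        """Build the full LoadedState (profiles, axial force, layer means)."""
        g = self.geometry
        P_kpa = pressure_mmhg * MMHG_TO_KPA
        R_all, r_all, lay_all = [], [], []
        lt_all, lr_all, drr_all = [], [], []
        for layer in (0, 1):
            lo, hi = self._bounds[layer]
            R = np.linspace(lo, hi, profile_nodes)
            lt, lr, r = self._layer_kinematics(a, v, layer, R)
            lt, lr, r = lt[0], lr[0], r[0]
            srr, stt, szz = self._total_stresses(lt, lr, layer, T_act)
            R_all.append(R)
            r_all.append(r)
            lay_all.append(np.full(R.shape, layer))
            lt_all.append(lt)
            lr_all.append(lr)
            drr_all.append(np.column_stack([srr, stt, szz]))
        R_all = np.concatenate(R_all)
        r_all = np.concatenate(r_all)
        layer_id = np.concatenate(lay_all)
        lt_all = np.concatenate(lt_all)
        lr_all = np.concatenate(lr_all)
        extra = np.vstack(drr_all)
        srr_x, stt_x, szz_x = extra.T
        # integrate radial equilibrium inner -> outer for sigma_rr;
        # per layer (the interface point is duplicated), continuous across it
        integrand = (stt_x - srr_x) / r_all
        sigma_rr = np.empty_like(r_all)
        offset = -P_kpa
        for layer in (0, 1):
            sel = layer_id == layer
            cum = np.concatenate(
                [[0.0], cumulative_simpson(integrand[sel], x=r_all[sel])]
            )
            sigma_rr[sel] = offset + cum
            offset = sigma_rr[sel][-1]
        sigma_tt = sigma_rr + (stt_x - srr_x)
        sigma_zz = sigma_rr + (szz_x - srr_x)
        _, f_ax = self.pressure_and_force(a, T_act=T_act, v=v)
        inner = layer_id == 0
        state = LoadedState(
            a=float(a), b=float(self.interface_radius(a, v)),
            c_out=float(self.outer_radius(a, v)),
            pressure_mmhg=pressure_mmhg, lambda_z=g.lambda_z, T_act=T_act, v=v,
            occluded=bool(a < 1e-2 * g.A),
            r=r_all, R=R_all, layer=layer_id,
            lambda_r=lr_all, lambda_t=lt_all,
            sigma_rr=sigma_rr, sigma_tt=sigma_tt, sigma_zz=sigma_zz,
            f_axial=float(f_ax),
            mean_sigma_tt_inner=_area_mean(sigma_tt[inner], r_all[inner]),
            mean_sigma_tt_outer=_area_mean(sigma_tt[~inner], r_all[~inner]),
        )
        return state

    # -- sweeps ---------------------------------------------------------------

    def closure_curve(self, pressure_mmhg: float, T_act_grid, v: float = 1.0) -> ClosureCurve:
        """Inner radius versus active stress at fixed pressure and swelling,
        normalized by the passive (T_act = 0) radius at the same (P, v)."""
        T_act_grid = np.asarray(T_act_grid, dtype=float)
        if T_act_grid.ndim != 1 or np.any(np.diff(T_act_grid) <= 0):
            raise ValueError("T_act grid must be 1-D strictly increasing")
        n = T_act_grid.size
        a = np.full(n, np.nan)
        d_out = np.full(n, np.nan)
        ms_in = np.full(n, np.nan)
        ms_out = np.full(n, np.nan)
        f_ax = np.full(n, np.nan)
        occ = np.zeros(n, dtype=bool)
        for i, T in enumerate(T_act_grid):
            try:
                st = self.solve(pressure_mmhg, T_act=T, v=v)
            except Exception:
                occ[i] = True
                continue
            a[i] = st.a
            d_out[i] = st.outer_diameter
            ms_in[i] = st.mean_sigma_tt_inner
            ms_out[i] = st.mean_sigma_tt_outer
            f_ax[i] = st.f_axial
            occ[i] = st.occluded
        a0 = self.solve(pressure_mmhg, T_act=0.0, v=v).a
        return ClosureCurve(
            v=v, pressure_mmhg=pressure_mmhg, T_act=T_act_grid, a=a,
            a_normalized=a / a0, outer_diameter=d_out,
            mean_sigma_tt_inner=ms_in, mean_sigma_tt_outer=ms_out,
            f_axial=f_ax, occluded=occ,
        )

    def closure_sweep(self, pressure_mmhg: float, T_act_grid, v_list) -> list[ClosureCurve]:
        return [self.closure_curve(pressure_mmhg, T_act_grid, v=v) for v in v_list]

    def swelling_crossover(self, pressure_mmhg: float, v_low: float, v_high: float,
                           T_act_grid=None, xtol: float = 1e-3):
        """Active stress at which the inner-radius curves for two swelling
        levels cross (kPa), or None if no crossing occurs on the grid.

        Below the crossover a less swollen inner layer gives the *larger*
        lumen; above it, the smaller one.
        """
        if not v_low < v_high:
            raise ValueError("require v_low < v_high")
        if T_act_grid is None:
            T_act_grid = np.linspace(0.0, 150.0, 76)
        T_act_grid = np.asarray(T_act_grid, dtype=float)

        def diff(T):
            a_lo = self.solve(pressure_mmhg, T_act=T, v=v_low).a
            a_hi = self.solve(pressure_mmhg, T_act=T, v=v_high).a
            return a_lo - a_hi

        d = np.array([diff(T) for T in T_act_grid])
        sign = np.sign(d)
        idx = np.nonzero(np.diff(sign) != 0)[0]
        if idx.size == 0:
            return None
        i = idx[0]
        return float(brentq(diff, T_act_grid[i], T_act_grid[i + 1], xtol=xtol))

    # -- energy (used by independent verification) ----------------------------

    def total_potential_energy(self, a: float, pressure_mmhg: float,
                               T_act: float = 0.0, v: float = 1.0) -> float:
        """Total potential energy per unit reference length (kPa*um^2).

        Strain energy of both layers (inner weighted by the swelling ratio,
        active contraction entering through its stretch potential) minus the
        work of the luminal pressure.  Stationary exactly at equilibrium.
        """
        from .constitutive import active_pseudo_energy, strain_energy

        lz = self.geometry.lambda_z
        P_kpa = pressure_mmhg * MMHG_TO_KPA
        E = 0.0
        for layer, weight in ((0, v), (1, 1.0)):
            R, w = self._layer_nodes(layer)
            lt, lr, _ = self._layer_kinematics(a, v, layer, R)
            lt, lr = lt[0], lr[0]
            W = strain_energy(lr, lt, lz, self.materials[layer])
            if T_act > 0.0 and self.contractile[layer]:
                W = W + active_pseudo_energy(lt, self.tone.with_magnitude(T_act))
            E += weight * 2.0 * np.pi * np.dot(W * R, w)
        E -= P_kpa * np.pi * a**2 * lz
        return float(E)


def _area_mean(sigma, r):
    """Cross-section area-weighted mean of a radial stress profile."""
    num = np.trapezoid(sigma * r, r)
    den = np.trapezoid(r, r)
    return float(num / den)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def luminal_pressure(a, params: VesselParameters, T_act: float = 0.0,
                     v: float = 1.0, **kw):
    """Luminal pressure (kPa) supporting inner radius ``a`` (um)."""
    return BilayerVesselModel(params, **kw).luminal_pressure(a, T_act=T_act, v=v)


def solve_inner_radius(pressure_mmhg: float, params: VesselParameters,
                       T_act: float = 0.0, v: float = 1.0, **kw) -> LoadedState:
    """Solve the loaded configuration at given pressure (mmHg)."""
    return BilayerVesselModel(params, **kw).solve(pressure_mmhg, T_act=T_act, v=v)


def closure_sweep(params: VesselParameters, pressure_mmhg: float, T_act_grid,
                  v_list, **kw) -> list[ClosureCurve]:
    return BilayerVesselModel(params, **kw).closure_sweep(pressure_mmhg, T_act_grid, v_list)


def swelling_crossover(params: VesselParameters, pressure_mmhg: float,
                       v_low: float, v_high: float, T_act_grid=None, **kw):
    return BilayerVesselModel(params, **kw).swelling_crossover(
        pressure_mmhg, v_low, v_high, T_act_grid=T_act_grid
    )
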