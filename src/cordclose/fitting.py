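"""Passive parameter estimation from biaxial pressure-diameter / force-length
data, and calibration of the active tone magnitude from contraction data.

`PassiveBiaxialModel` follows the familiar model/results pattern: construct
it from a `BiaxialProtocolData` table, call :meth:`fit`, and inspect the
returned `PassiveFitResults` (parameter estimates, standard errors from the
Gauss-Newton approximation, residuals, `summary()`).

The forward model evaluates, for each measured configuration (axial
stretch, outer diameter), the luminal pressure and transducer axial force
that equilibrate the bilayered wall; the regression minimizes weighted
squared residuals of pressure and force jointly.  Fitting uses the
measured geometry directly, so no root-finding is needed inside the
objective.  Estimated parameters are those of the outer-layer four-fiber
constitutive model (the inner GAG layer modulus is not identifiable from
passive distension and is held fixed).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from functools import lru_cache

from .constitutive import (
    MMHG_TO_KPA,
    ActiveTone,
    FiberFamily,
    LayerMaterial,
    VesselGeometry,
    passive_extra_stress,
)
from .equilibrium import BilayerVesselModel, InfeasibleGeometryError
from .params import VesselParameters

__all__ = [
    "BiaxialProtocolData",
    "PassiveBiaxialModel",
    "PassiveFitResults",
    "predict_protocol",
    "fit_passive",
    "fit_active_tone",
]

#: fitted parameter names, in vector order
PARAM_NAMES = ("mu2", "c1_axial", "c2_axial", "c1_circ", "c2_circ",
               "c1_diag", "c2_diag", "eta_diag")

DEFAULT_BOUNDS = {
    "mu2": (1e-4, 1e3),
    "c1_axial": (1e-4, 1e3),
    "c2_axial": (1e-3, 50.0),
    "c1_circ": (1e-4, 1e3),
    "c2_circ": (1e-3, 50.0),
    "c1_diag": (1e-4, 1e3),
    "c2_diag": (1e-3, 50.0),
    "eta_diag": (1.0, 89.0),
}

_REQUIRED_COLUMNS = ("vessel_id", "protocol_id", "protocol_type", "lambda_z",
                     "pressure_mmHg", "outer_diameter_um", "axial_force_mN")


@dataclass
class BiaxialProtocolData:
    """Tidy table of passive biaxial test records plus vessel metadata.

    Columns: vessel_id, protocol_id, protocol_type ('pd' pressure-diameter
    at fixed axial stretch | 'fl' force-length at fixed pressure),
    lambda_z, pressure_mmHg, outer_diameter_um, axial_force_mN.
    """

    records: pd.DataFrame
    geometry: VesselGeometry
    vessel_type: str = "artery"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(_REQUIRED_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        df = self.records
        if (df["outer_diameter_um"] <= 0).any():
            raise ValueError("diameters must be positive")
        if (df["pressure_mmHg"] < 0).any():
            raise ValueError("pressures must be non-negative")
        if df["lambda_z"].nunique() < 2:
            raise ValueError(
                "at least two distinct axial stretches are required for identifiability"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_protocols(self) -> int:
        return self.records["protocol_id"].nunique()

    def to_csv(self, path: str | Path) -> None:
        """Write the table with vessel metadata in '#'-prefixed header lines."""
        g = self.geometry
        header = {
            "A_um": g.A, "B_um": g.B, "C_um": g.C,
            "lambda_z_in_vivo": g.lambda_z,
            "vessel_type": self.vessel_type,
            **self.meta,
        }
        with open(path, "w") as fh:
            for k, val in header.items():
                fh.write(f"# {k}: {val}\n")
            self.records.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BiaxialProtocolData":
        meta: dict = {}
        lines = Path(path).read_text().splitlines(keepends=True)
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                k, _, val = line[1:].partition(":")
                meta[k.strip()] = val.strip()
                body_start = i + 1
            else:
                break
        records = pd.read_csv(io.StringIO("".join(lines[body_start:])))
        geometry = VesselGeometry(
            A=float(meta.pop("A_um")), B=float(meta.pop("B_um")),
            C=float(meta.pop("C_um")),
            lambda_z=float(meta.pop("lambda_z_in_vivo", 1.0)),
        )
        vessel_type = meta.pop("vessel_type", "artery")
        return cls(records=records, geometry=geometry,
                   vessel_type=vessel_type, meta=meta)


# ---------------------------------------------------------------------------
# forward model (vectorized over protocol points)
# ---------------------------------------------------------------------------


def _materials_from_vector(x, mu1: float) -> tuple[LayerMaterial, LayerMaterial]:
    mu2, c11, c21, c12, c22, c1d, c2d, eta = x
    fibers = (
        FiberFamily(c1=c11, c2=c21, eta=0.0),
        FiberFamily(c1=c12, c2=c22, eta=90.0),
        FiberFamily(c1=c1d, c2=c2d, eta=eta),
        FiberFamily(c1=c1d, c2=c2d, eta=-eta),
    )
    return LayerMaterial(mu=mu1), LayerMaterial(mu=mu2, fibers=fibers)


def _vector_from_params(params: VesselParameters):
    fams = params.outer.fibers
    return np.array([
        params.outer.mu, fams[0].c1, fams[0].c2, fams[1].c1, fams[1].c2,
        fams[2].c1, fams[2].c2, abs(fams[2].eta),
    ])


@lru_cache(maxsize=8)
def _gauss(nodes: int):
    return np.polynomial.legendre.leggauss(nodes)


def _forward_at_lumen(geometry, inner, outer, lz, a2, v=1.0, nodes=48):
    """Pressure (kPa) and axial force (mN) at given squared lumen radii.

    Vectorized over protocol points with per-point axial stretch.
    """
    A, B, C = geometry.A, geometry.B, geometry.C
    x, w = _gauss(nodes)
    b2 = a2 + v * (B**2 - A**2) / lz
    P = np.zeros(np.shape(lz))
    f = np.zeros(np.shape(lz))
    for (lo, hi), mat, jac, base2 in (
        ((A, B), inner, v, a2), ((B, C), outer, 1.0, b2)
    ):
        R = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)  # (nodes,)
        wR = 0.5 * (hi - lo) * w
        r2 = base2[:, None] + jac * (R**2 - lo**2) / lz[:, None]
        r = np.sqrt(r2)
        lt = r / R
        lrr = jac * R / (lz[:, None] * r)
        srr, stt, szz = passive_extra_stress(lrr, lt, lz[:, None], mat)
        srr, stt, szz = np.broadcast_arrays(srr, stt, szz)
        P += ((stt - srr) / r * lrr) @ wR
        f += ((2.0 * szz - stt - srr) * r * lrr) @ wR
    return P, f * np.pi * 1e-6


def predict_protocol(
    geometry: VesselGeometry,
    inner: LayerMaterial,
    outer: LayerMaterial,
    lambda_z,
    outer_diameter_um,
    v: float = 1.0,
    nodes: int = 48,
):
    """Pressure (mmHg) and axial force (mN) at measured configurations.

    Vectorized over protocol points: each point supplies its own axial
    stretch and measured outer diameter; the luminal radius follows from
    the deformation map and radial equilibrium gives the pressure.
    Points whose diameter implies a negative lumen return NaN.
    """
    lz = np.atleast_1d(np.asarray(lambda_z, dtype=float))
    c_out = 0.5 * np.atleast_1d(np.asarray(outer_diameter_um, dtype=float))
    A, B, C = geometry.A, geometry.B, geometry.C
    a2 = c_out**2 - (C**2 - B**2) / lz - v * (B**2 - A**2) / lz
    a2 = np.where(a2 > 0.0, a2, np.nan)
    P, f = _forward_at_lumen(geometry, inner, outer, lz, a2, v=v, nodes=nodes)
    return P / MMHG_TO_KPA, f


def solve_protocol(
    geometry: VesselGeometry,
    inner: LayerMaterial,
    outer: LayerMaterial,
    lambda_z,
    pressure_mmhg,
    v: float = 1.0,
    nodes: int = 48,
    a_init=None,
    return_lumen: bool = False,
):
    """Outer diameter (um) and axial force (mN) at controlled pressures.

    Inverse of :func:`predict_protocol`: for each (axial stretch, pressure)
    the lumen radius solves the monotone passive pressure-radius relation,
    by vectorized Newton iteration (warm-startable through ``a_init``) with
    a bisection fallback, then geometry and force follow.
    """
    lz = np.atleast_1d(np.asarray(lambda_z, dtype=float))
    Pt = np.atleast_1d(np.asarray(pressure_mmhg, dtype=float)) * MMHG_TO_KPA
    A = geometry.A
    a_lo, a_hi = 1e-3 * A, 3.0 * A

    def P_of(a):
        return _forward_at_lumen(geometry, inner, outer, lz, a**2, v=v,
                                 nodes=nodes)[0]

    def bisect(mask, iters=42):
        lo = np.full(lz.shape, a_lo)
        hi = np.full(lz.shape, a_hi)
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            low = P_of(mid) < Pt
            lo = np.where(low, mid, lo)
            hi = np.where(low, hi, mid)
        return 0.5 * (lo + hi)

    if a_init is None:
        a = bisect(None)
    else:
        a = np.clip(np.asarray(a_init, dtype=float), a_lo, a_hi)
        for _ in range(5):
            P1 = P_of(a)
            h = 1e-6 * np.maximum(a, 1.0)
            dP = (P_of(a + h) - P1) / h
            with np.errstate(divide="ignore", invalid="ignore"):
                step = (Pt - P1) / dP
            a = np.clip(a + np.where(np.isfinite(step), step, 0.0), a_lo, a_hi)
        bad = np.abs(P_of(a) - Pt) > 1e-9 + 1e-7 * np.abs(Pt)
        if np.any(bad):
            a = np.where(bad, bisect(bad), a)
    _, f = _forward_at_lumen(geometry, inner, outer, lz, a**2, v=v, nodes=nodes)
    B, C = geometry.B, geometry.C
    c2 = a**2 + v * (B**2 - A**2) / lz + (C**2 - B**2) / lz
    d = 2.0 * np.sqrt(c2)
    if return_lumen:
        return d, f, a
    return d, f


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------


@dataclass
class PassiveFitResults:
    """Estimates, uncertainties and diagnostics of a passive biaxial fit."""

    params: pd.Series
    bse: pd.Series
    objective: float
    residuals: np.ndarray
    fitted: pd.DataFrame
    n_obs: int
    n_starts: int
    start_objectives: np.ndarray
    bounds_hit: pd.Series
    converged: bool
    model: "PassiveBiaxialModel" = field(repr=False, default=None)

    @property
    def start_dispersion(self) -> float:
        """Spread of converged multi-start objectives relative to the best."""
        vals = self.start_objectives[np.isfinite(self.start_objectives)]
        if len(vals) < 2:
            return 0.0
        return float((np.max(vals) - np.min(vals)) / max(np.min(vals), 1e-12))

    def to_params(self) -> VesselParameters:
        """Best-fit parameters as a full vessel parameter set."""
        m = self.model
        inner, outer = _materials_from_vector(self.params.to_numpy(), m.mu1)
        return VesselParameters(geometry=m.data.geometry, inner=inner,
                                outer=outer, tone=m.tone)

    def summary(self) -> str:
        lines = ["Passive biaxial fit", "=" * 46]
        lines.append(f"observations: {self.n_obs}   objective: {self.objective:.6g}")
        lines.append(f"multi-starts: {self.n_starts}   converged: {self.converged}")
        lines.append("-" * 46)
        lines.append(f"{'parameter':<12}{'estimate':>12}{'std err':>12}{'at bound':>10}")
        for name in self.params.index:
            lines.append(
                f"{name:<12}{self.params[name]:>12.5g}{self.bse[name]:>12.3g}"
                f"{'yes' if self.bounds_hit[name] else '':>10}"
            )
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        payload = {
            "params": self.params.to_dict(),
            "bse": {k: (None if not np.isfinite(val) else val)
                    for k, val in self.bse.items()},
            "objective": self.objective,
            "n_obs": self.n_obs,
            "n_starts": self.n_starts,
            "start_objectives": [None if not np.isfinite(o) else o
                                 for o in self.start_objectives],
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class PassiveBiaxialModel:
    """Nonlinear regression of passive biaxial data on the bilayer model.

    Parameters
    ----------
    data : BiaxialProtocolData
        Protocol records with vessel geometry.
    mu1 : float
        Fixed inner-layer (GAG matrix) shear modulus, kPa.  Not
        identifiable from passive distension of the composite wall.
    v : float
        Inner-layer swelling ratio during passive testing (default 1).
    nodes : int
        Quadrature nodes per layer for the forward model.
    response : {"diameter", "pressure"}
        Regression direction.  "diameter" (default) treats pressure as the
        controlled variable and regresses the measured outer diameter and
        axial force on the model, matching how distension rigs operate and
        where the measurement noise lives.  "pressure" regresses pressure
        and force at the measured geometry (no root-finding, but stiff
        high-pressure points dominate under diameter noise).
    """

    def __init__(self, data: BiaxialProtocolData, mu1: float = 3.0,
                 v: float = 1.0, nodes: int = 32,
                 response: str = "diameter",
                 tone: ActiveTone | None = None):
        if response not in ("diameter", "pressure"):
            raise ValueError("response must be 'diameter' or 'pressure'")
        self.data = data
        self.mu1 = mu1
        self.v = v
        self.nodes = nodes
        self.response = response
        self.tone = tone if tone is not None else ActiveTone(T_act=0.0)
        df = data.records
        self._lz = df["lambda_z"].to_numpy(float)
        self._d = df["outer_diameter_um"].to_numpy(float)
        self._P_obs = df["pressure_mmHg"].to_numpy(float)
        self._f_obs = df["axial_force_mN"].to_numpy(float)

    # -- weights ------------------------------------------------------------

    def default_weights(self):
        """Per-protocol response scales (std of the regressed responses)."""
        df = self.data.records
        col = "outer_diameter_um" if self.response == "diameter" else "pressure_mmHg"
        y = self._d if self.response == "diameter" else self._P_obs
        s1 = df.groupby("protocol_id")[col].transform("std").to_numpy(float)
        sf = df.groupby("protocol_id")["axial_force_mN"].transform("std").to_numpy(float)
        s1 = np.maximum(s1, 1e-2 * max(np.abs(y).max(), 1.0))
        sf = np.maximum(sf, 1e-2 * max(np.abs(self._f_obs).max(), 1e-3))
        return s1, sf

    # -- forward ------------------------------------------------------------

    def predict(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Model responses at the observed protocol points.

        Returns (diameter um, force mN) for the "diameter" direction,
        (pressure mmHg, force mN) for the "pressure" direction.
        """
        inner, outer = _materials_from_vector(np.asarray(x, float), self.mu1)
        if self.response == "diameter":
            d, f, a = solve_protocol(
                self.data.geometry, inner, outer, self._lz, self._P_obs,
                v=self.v, nodes=self.nodes,
                a_init=getattr(self, "_a_warm", None), return_lumen=True,
            )
            self._a_warm = a
            return d, f
        return predict_protocol(
            self.data.geometry, inner, outer, self._lz, self._d,
            v=self.v, nodes=self.nodes,
        )

    def _residuals(self, x, s1, sf):
        y_mod, f_mod = self.predict(x)
        y_obs = self._d if self.response == "diameter" else self._P_obs
        r = np.concatenate([(y_mod - y_obs) / s1, (f_mod - self._f_obs) / sf])
        return np.where(np.isfinite(r), r, 1e3)

    # -- fitting ------------------------------------------------------------

    def fit(self, starts: int = 10, seed: int = 17, bounds: dict | None = None,
            weights: tuple | None = None, x0=None) -> PassiveFitResults:
        """Bounded weighted least squares with seeded multi-start.

        Positive parameters are optimized on a log10 scale.  Starts are
        log-uniform draws within bounds plus one neutral deterministic
        start; the best converged solution is returned together with the
        per-start objective log.
        """
        bset = dict(DEFAULT_BOUNDS)
        if bounds:
            bset.update(bounds)
        lo = np.array([bset[n][0] for n in PARAM_NAMES])
        hi = np.array([bset[n][1] for n in PARAM_NAMES])
        s1, sf = weights if weights is not None else self.default_weights()

        # internal transform: log10 for positive scale parameters, linear angle
        is_log = np.array([n != "eta_diag" for n in PARAM_NAMES])

        def to_internal(x):
            return np.where(is_log, np.log10(x), x)

        def to_external(z):
            return np.where(is_log, 10.0**z, z)

        def obj(z):
            return self._residuals(to_external(z), s1, sf)

        rng = np.random.default_rng(seed)
        neutral = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 45.0])
        start_points = [neutral]
        if x0 is not None:
            start_points.insert(0, np.asarray(x0, float))
        while len(start_points) < starts:
            u = rng.uniform(size=len(PARAM_NAMES))
            draw = to_external(to_internal(lo) + u * (to_internal(hi) - to_internal(lo)))
            start_points.append(draw)

        best = None
        objectives = np.full(len(start_points), np.nan)
        for i, sp in enumerate(start_points):
            try:
                res = least_squares(
                    obj, to_internal(np.clip(sp, lo, hi)),
                    bounds=(to_internal(lo), to_internal(hi)),
                    method="trf", x_scale="jac", xtol=1e-10, ftol=1e-10,
                    gtol=1e-10, max_nfev=250,
                )
            except Exception:
                continue
            objectives[i] = 2.0 * res.cost
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("all optimization starts failed")

        # polish the winner
        best = least_squares(
            obj, best.x, bounds=(to_internal(lo), to_internal(hi)),
            method="trf", x_scale="jac", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            max_nfev=400,
        )
        x_hat = to_external(best.x)
        # Gauss-Newton covariance in external coordinates via the chain rule
        J = best.jac * np.where(is_log, x_hat * np.log(10.0), 1.0)
        dof = max(len(best.fun) - len(x_hat), 1)
        s2 = 2.0 * best.cost / dof
        try:
            cov = s2 * np.linalg.pinv(J.T @ J)
            bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:  # pragma: no cover
            bse = np.full_like(x_hat, np.nan)

        y_mod, f_mod = self.predict(x_hat)
        fitted = self.data.records.copy()
        ycol = ("outer_diameter_um_fit" if self.response == "diameter"
                else "pressure_mmHg_fit")
        fitted[ycol] = y_mod
        fitted["axial_force_mN_fit"] = f_mod
        rel = 1e-6 * (hi - lo)
        hit = (x_hat - lo < rel) | (hi - x_hat < rel)
        return PassiveFitResults(
            params=pd.Series(x_hat, index=PARAM_NAMES),
            bse=pd.Series(bse, index=PARAM_NAMES),
            objective=float(2.0 * best.cost),
            residuals=best.fun.copy(),
            fitted=fitted,
            n_obs=2 * len(self._lz),
            n_starts=len(start_points),
            start_objectives=objectives,
            bounds_hit=pd.Series(hit, index=PARAM_NAMES),
            converged=bool(best.success),
            model=self,
        )


def fit_passive(data: BiaxialProtocolData, mu1: float = 3.0, **fit_kw) -> PassiveFitResults:
    """Functional wrapper around PassiveBiaxialModel(...).fit(...)."""
    return PassiveBiaxialModel(data, mu1=mu1).fit(**fit_kw)


# ---------------------------------------------------------------------------
# active tone calibration
# ---------------------------------------------------------------------------


def fit_active_tone(
    target_reduction_pct: float,
    params: VesselParameters,
    v_contracted: float = 1.0,
    pressure_mmhg: float = 25.0,
    search: tuple[float, float] = (0.0, 500.0),
    xtol: float = 0.1,
) -> ActiveTone:
    """Active stress magnitude reproducing an observed outer-diameter
    reduction at fixed pressure (e.g. KCl-stimulated contraction).

    The passive reference uses v = 1; the contracted state may use a
    reduced inner-layer volume to represent fluid exudation.  Raises if
    the reduction is unattainable within the search range.
    """
    if target_reduction_pct < 0.0 or target_reduction_pct >= 100.0:
        raise ValueError("target reduction must be in [0, 100)%")
    if target_reduction_pct == 0.0:
        return params.tone.with_magnitude(0.0)
    model = BilayerVesselModel(params)
    d0 = model.solve(pressure_mmhg, T_act=0.0, v=1.0).outer_diameter

    def gap(T):
        d = model.solve(pressure_mmhg, T_act=T, v=v_contracted).outer_diameter
        return 100.0 * (1.0 - d / d0) - target_reduction_pct

    glo, ghi = gap(search[0]), gap(search[1])
    if np.sign(glo) == np.sign(ghi):
        raise RuntimeError(
            f"target reduction {target_reduction_pct}% unattainable for "
            f"T_act in {search} kPa (gap {glo:.2f}..{ghi:.2f})"
        )
    T = brentq(gap, *search, xtol=xtol)
    return params.tone.with_magnitude(float(T))
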