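"""Constitutive description of the bilayered umbilical-artery wall.

The wall is modelled as two concentric layers of incompressible hyperelastic
material.  The inner layer (glycosaminoglycan-rich tunica media) is an
isotropic neo-Hookean ground matrix whose volume may differ from its
reference value by a prescribed swelling ratio ``v``.  The outer layer
(smooth-muscle-rich tunica media) combines a softer neo-Hookean matrix with
four exponentially stiffening fiber families (axial, circumferential and a
symmetric diagonal pair) and can generate an active circumferential stress
through a length--tension relationship of the smooth muscle.

Per layer the passive strain energy (per unit layer-reference volume) is

    W = mu/2 (lr^2 + lt^2 + lz^2 - 3)
        + sum_k c1k/(4 c2k) [exp(c2k (lk^2 - 1)^2) - 1]

where ``lk`` is the stretch of fiber family ``k`` lying in the
circumferential--axial plane at angle ``eta_k`` from the vessel axis.
Fibers only bear load in extension (``lk > 1``).  Principal "extra" Cauchy
stresses are ``sigma_i = l_i dW/dl_i``; the hydrostatic pressure enforcing
the volumetric constraint is handled by the equilibrium solver.

The active circumferential Cauchy stress follows a parabolic tone law

    t_act(lt) = T_act * lt * [1 - ((lm - lt)/(lm - l0))^2]_+

which vanishes at the minimum (``l0``) and far-overstretched contractile
lengths and peaks near ``lm``; the bracket is clamped at zero so the stress
is continuous in ``lt``.

Units: lengths in micrometres, stresses and moduli in kilopascals, angles
in degrees at the API surface (converted internally), stretches
dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VesselGeometry",
    "FiberFamily",
    "LayerMaterial",
    "ActiveTone",
    "SwellingSpec",
    "fiber_stretch",
    "strain_energy",
    "passive_extra_stress",
    "active_stress",
    "active_stress_derivative",
    "active_pseudo_energy",
    "wall_derivatives",
]

MMHG_TO_KPA = 0.133322


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VesselGeometry:
    """Unloaded bilayer geometry and the in vivo axial stretch.

    Attributes
    ----------
    A, B, C : float
        Unloaded inner, interface and outer radius (um), ``0 < A < B < C``.
    lambda_z : float
        Axial stretch imposed in the loaded configuration.
    """

    A: float
    B: float
    C: float
    lambda_z: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.A < self.B < self.C):
            raise ValueError(
                f"radii must satisfy 0 < A < B < C, got A={self.A}, B={self.B}, C={self.C}"
            )
        if self.lambda_z <= 0.0:
            raise ValueError("axial stretch must be positive")


@dataclass(frozen=True)
class FiberFamily:
    """One fiber family: stiffness c1 (kPa), exponent c2, angle eta (deg from axis)."""

    c1: float
    c2: float
    eta: float

    def __post_init__(self) -> None:
        if self.c1 < 0.0 or self.c2 < 0.0:
            raise ValueError("fiber parameters c1, c2 must be non-negative")
        if not (-90.0 < self.eta <= 90.0):
            raise ValueError("fiber angle must lie in (-90, 90] degrees")


@dataclass(frozen=True)
class LayerMaterial:
    """Passive material of one wall layer: neo-Hookean matrix plus fiber families."""

    mu: float
    fibers: tuple[FiberFamily, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mu <= 0.0:
            raise ValueError("shear modulus must be positive")
        object.__setattr__(self, "fibers", tuple(self.fibers))


@dataclass(frozen=True)
class ActiveTone:
    """Smooth-muscle tone: magnitude T_act (kPa) and contractile stretch window."""

    T_act: float
    lambda_m: float = 2.5
    lambda_0: float = 0.2

    def __post_init__(self) -> None:
        if self.T_act < 0.0:
            raise ValueError("active stress magnitude must be non-negative")
        if not (0.0 < self.lambda_0 < self.lambda_m):
            raise ValueError("contractile window requires 0 < lambda_0 < lambda_m")

    def with_magnitude(self, T_act: float) -> "ActiveTone":
        return replace(self, T_act=T_act)


@dataclass(frozen=True)
class SwellingSpec:
    """Normalized inner-layer volume v = current / reference inner-layer volume."""

    v: float = 1.0

    def __post_init__(self) -> None:
        if self.v <= 0.0:
            raise ValueError("swelling ratio v must be positive")


# ---------------------------------------------------------------------------
# kinematics and passive response
# ---------------------------------------------------------------------------


def fiber_stretch(lambda_theta, lambda_z, eta):
    """Stretch of a fiber family at angle ``eta`` (deg from the axial direction).

    ``lk = sqrt(lz^2 cos^2 eta + lt^2 sin^2 eta)``; eta = 0 is axial,
    eta = +/-90 deg circumferential.
    """
    lt = np.asarray(lambda_theta, dtype=float)
    lz = np.asarray(lambda_z, dtype=float)
    if np.any(lt <= 0.0) or np.any(lz <= 0.0):
        raise ValueError("stretches must be positive")
    e = np.deg2rad(eta)
    return np.sqrt(lz**2 * np.cos(e) ** 2 + lt**2 * np.sin(e) ** 2)


def _fiber_g(x, c1, c2):
    """Fiber energy as a function of x = lk^2, tension-only."""
    ext = np.maximum(x - 1.0, 0.0)
    if c2 == 0.0:
        return 0.25 * c1 * ext**2
    return c1 / (4.0 * c2) * np.expm1(c2 * ext**2)


def _fiber_gp(x, c1, c2):
    """dg/dx for x = lk^2 (zero in compression)."""
    ext = np.maximum(x - 1.0, 0.0)
    return 0.5 * c1 * ext * np.exp(c2 * ext**2)


def _fiber_gpp(x, c1, c2):
    """d2g/dx2 for x = lk^2 (zero in compression)."""
    ext = np.maximum(x - 1.0, 0.0)
    return 0.5 * c1 * np.exp(c2 * ext**2) * (1.0 + 2.0 * c2 * ext**2) * (ext > 0.0)


def strain_energy(lambda_r, lambda_theta, lambda_z, material: LayerMaterial):
    """Passive strain energy density W (kPa) at the given principal stretches."""
    lr = np.asarray(lambda_r, dtype=float)
    lt = np.asarray(lambda_theta, dtype=float)
    lz = np.asarray(lambda_z, dtype=float)
    W = 0.5 * material.mu * (lr**2 + lt**2 + lz**2 - 3.0)
    for fam in material.fibers:
        e = np.deg2rad(fam.eta)
        x = lz**2 * np.cos(e) ** 2 + lt**2 * np.sin(e) ** 2
        W = W + _fiber_g(x, fam.c1, fam.c2)
    return W


def passive_extra_stress(lambda_r, lambda_theta, lambda_z, material: LayerMaterial):
    """Principal extra Cauchy stresses ``sigma_i = l_i dW/dl_i`` (kPa).

    Returns ``(s_rr, s_tt, s_zz)``.  The Lagrange multiplier enforcing the
    per-layer volumetric constraint is *not* included; radial equilibrium
    determines it.
    """
    lr = np.asarray(lambda_r, dtype=float)
    lt = np.asarray(lambda_theta, dtype=float)
    lz = np.asarray(lambda_z, dtype=float)
    if np.any(lr <= 0.0) or np.any(lt <= 0.0) or np.any(lz <= 0.0):
        raise ValueError("stretches must be positive")
    srr = material.mu * lr**2
    stt = material.mu * lt**2
    szz = material.mu * lz**2
    for fam in material.fibers:
        e = np.deg2rad(fam.eta)
        s2, c2a = np.sin(e) ** 2, np.cos(e) ** 2
        x = lz**2 * c2a + lt**2 * s2
        # sigma_fib = c1 (lk^2-1) exp(c2 (lk^2-1)^2) * (stretch^2 * direction cosine^2)
        common = 2.0 * _fiber_gp(x, fam.c1, fam.c2)
        stt = stt + common * lt**2 * s2
        szz = szz + common * lz**2 * c2a
    return srr, stt, szz


# ---------------------------------------------------------------------------
# active smooth-muscle stress
# ---------------------------------------------------------------------------


def active_stress(lambda_theta, tone: ActiveTone):
    """Active circumferential Cauchy stress t_act(lt) (kPa), parabolic tone law.

    Zero wherever the parabolic bracket is negative, which keeps the law
    continuous across the contractile window.
    """
    lt = np.asarray(lambda_theta, dtype=float)
    if np.any(lt <= 0.0):
        raise ValueError("circumferential stretch must be positive")
    span = tone.lambda_m - tone.lambda_0
    bracket = 1.0 - ((tone.lambda_m - lt) / span) ** 2
    return tone.T_act * lt * np.maximum(bracket, 0.0)


def active_stress_derivative(lambda_theta, tone: ActiveTone):
    """d t_act / d lambda_theta, zero where the tone law is clamped."""
    lt = np.asarray(lambda_theta, dtype=float)
    span = tone.lambda_m - tone.lambda_0
    bracket = 1.0 - ((tone.lambda_m - lt) / span) ** 2
    active = bracket > 0.0
    return tone.T_act * (bracket + lt * 2.0 * (tone.lambda_m - lt) / span**2) * active


def active_pseudo_energy(lambda_theta, tone: ActiveTone):
    """Potential Wa(lt) with lt * dWa/dlt = t_act(lt), used by energy oracles.

    The tone law depends on lt only, so the active stress admits this
    one-dimensional potential even though active contraction is not
    hyperelastic in general.
    """
    lt = np.asarray(lambda_theta, dtype=float)
    lm, l0 = tone.lambda_m, tone.lambda_0
    span = lm - l0
    hi = 2.0 * lm - l0  # upper zero of the parabolic bracket
    s = np.clip(lt, l0, hi)
    # integral of [1 - ((lm - s)/span)^2] ds from l0 to s
    val = (s - l0) - (span**3 - (lm - s) ** 3) / (3.0 * span**2)
    return tone.T_act * val


# ---------------------------------------------------------------------------
# derivatives for incremental (small-on-large) analysis
# ---------------------------------------------------------------------------


def wall_derivatives(
    lambda_r,
    lambda_theta,
    lambda_z,
    material: LayerMaterial,
    tone: ActiveTone | None = None,
    active_stiffness: bool = True,
):
    """First and second partial derivatives of the layer energy in (lr, lt).

    Returns a dict with keys ``Wr, Wt, Wrr, Wtt, Wrt``.  When a tone is
    given, the active circumferential stress is folded in as an effective
    contribution ``Wt += t_act/lt`` so that ``lt*Wt`` is the total (passive
    + active) circumferential extra stress; its linearization enters ``Wtt``
    only if ``active_stiffness`` is true.
    """
    lr = np.asarray(lambda_r, dtype=float)
    lt = np.asarray(lambda_theta, dtype=float)
    lz = np.asarray(lambda_z, dtype=float)
    mu = material.mu
    Wr = mu * lr
    Wt = mu * lt
    Wrr = mu * np.ones_like(lr * lt)
    Wtt = mu * np.ones_like(lr * lt)
    Wrt = np.zeros_like(lr * lt)
    for fam in material.fibers:
        e = np.deg2rad(fam.eta)
        s2 = np.sin(e) ** 2
        x = lz**2 * np.cos(e) ** 2 + lt**2 * s2
        gp = _fiber_gp(x, fam.c1, fam.c2)
        gpp = _fiber_gpp(x, fam.c1, fam.c2)
        Wt = Wt + gp * 2.0 * lt * s2
        Wtt = Wtt + gpp * (2.0 * lt * s2) ** 2 + gp * 2.0 * s2
    if tone is not None and tone.T_act > 0.0:
        ta = active_stress(lt, tone)
        Wt = Wt + ta / lt
        if active_stiffness:
            tap = active_stress_derivative(lt, tone)
            Wtt = Wtt + tap / lt - ta / lt**2
    return {"Wr": Wr, "Wt": Wt, "Wrr": Wrr, "Wtt": Wtt, "Wrt": Wrt}
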