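"""Synthetic biaxial and contraction datasets for the murine umbilical vessels.

The generator stands in for ex vivo biaxial testing of late-gestation
(E18.5) mouse umbilical arteries and veins: cannulated vessels, cyclic
pressure-diameter protocols at a few fixed axial stretches up to ~25 mmHg,
axial force-length protocols at fixed pressures, and KCl-stimulated
contraction at fixed pressure.  Responses are forward-simulated from a
known ("truth") parameter set with the equilibrium model and perturbed by
multiplicative Gaussian measurement noise on the tracked responses (outer
diameter, axial force); geometry is treated as measured exactly.  Every
dataset embeds its seed and truth for recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibrium import BilayerVesselModel
from .fitting import BiaxialProtocolData, fit_active_tone
from .params import VesselParameters, baseline_parameters

__all__ = ["SyntheticSpec", "generate_biaxial", "generate_contraction"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Protocol grid, noise model and truth for one synthetic experiment.

    Defaults emulate the murine E18.5 study conditions: n = 4 vessels,
    pressure-diameter sweeps 0-25 mmHg at axial stretches 0.95/1.00/1.05
    of the in vivo value, force-length sweeps at 5/15/25 mmHg, 1 %
    multiplicative noise on diameter and 3 % on force.
    """

    params: VesselParameters = field(default_factory=baseline_parameters)
    n_vessels: int = 4
    pressures_mmhg: tuple = tuple(np.linspace(0.0, 25.0, 11))
    axial_factors: tuple = (0.95, 1.0, 1.05)
    fl_pressures_mmhg: tuple = (5.0, 15.0, 25.0)
    fl_axial_range: tuple = (0.92, 1.08)
    fl_points: int = 9
    noise_diameter: float = 0.01
    noise_force: float = 0.03
    v: float = 1.0
    seed: int = 17

    def __post_init__(self):
        if self.noise_diameter < 0 or self.noise_force < 0:
            raise ValueError("noise standard deviations must be non-negative")


def _forward_points(spec: SyntheticSpec):
    """Noise-free protocol responses from the truth parameters."""
    base = spec.params
    rows = []
    lz0 = base.geometry.lambda_z
    for fac in spec.axial_factors:
        lz = fac * lz0
        geom = replace(base.geometry, lambda_z=lz)
        model = BilayerVesselModel(replace(base, geometry=geom))
        pid = f"pd_lz{fac:.2f}"
        for P in spec.pressures_mmhg:
            st = model.solve(float(P), T_act=0.0, v=spec.v)
            rows.append((pid, "pd", lz, float(P), st.outer_diameter, st.f_axial,
                         st.occluded))
    lz_grid = np.linspace(spec.fl_axial_range[0] * lz0,
                          spec.fl_axial_range[1] * lz0, spec.fl_points)
    for P in spec.fl_pressures_mmhg:
        pid = f"fl_P{P:g}"
        for lz in lz_grid:
            geom = replace(base.geometry, lambda_z=float(lz))
            model = BilayerVesselModel(replace(base, geometry=geom))
            st = model.solve(float(P), T_act=0.0, v=spec.v)
            rows.append((pid, "fl", float(lz), float(P), st.outer_diameter,
                         st.f_axial, st.occluded))
    df = pd.DataFrame(rows, columns=["protocol_id", "protocol_type", "lambda_z",
                                     "pressure_mmHg", "outer_diameter_um",
                                     "axial_force_mN", "infeasible"])
    dropped = int(df["infeasible"].sum())
    return df[~df["infeasible"]].drop(columns="infeasible"), dropped


def generate_biaxial(spec: SyntheticSpec, seed: int | None = None):
    """Simulate a passive biaxial dataset.

    Returns ``(data, truth)``: the noisy `BiaxialProtocolData` across
    ``spec.n_vessels`` vessels and a truth/metadata dict (parameters,
    noise levels, seed, dropped-point count) for recovery scoring.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    clean, dropped = _forward_points(spec)
    frames = []
    for vid in range(1, spec.n_vessels + 1):
        df = clean.copy()
        df.insert(0, "vessel_id", vid)
        df["outer_diameter_um"] *= 1.0 + spec.noise_diameter * rng.standard_normal(len(df))
        df["axial_force_mN"] *= 1.0 + spec.noise_force * rng.standard_normal(len(df))
        frames.append(df)
    records = pd.concat(frames, ignore_index=True)
    truth = {
        "params": spec.params.to_dict(),
        "v": spec.v,
        "noise_diameter": spec.noise_diameter,
        "noise_force": spec.noise_force,
        "seed": seed,
        "n_vessels": spec.n_vessels,
        "dropped_points": dropped,
    }
    data = BiaxialProtocolData(
        records=records, geometry=spec.params.geometry, vessel_type="artery",
        meta={"seed": seed, "noise_diameter": spec.noise_diameter,
              "noise_force": spec.noise_force},
    )
    return data, truth


def generate_contraction(
    spec: SyntheticSpec,
    T_act: float | None = None,
    target_reduction_pct: float = 40.0,
    v_contracted: float = 0.5,
    pressure_mmhg: float = 25.0,
    seed: int | None = None,
):
    """Simulate KCl-type contraction: passive and contracted outer diameters
    at fixed pressure for each vessel.

    If no active stress magnitude is given it is calibrated so the
    noise-free reduction matches ``target_reduction_pct`` (artery-like
    default 40 %, inside the observed 30-50 % band; a vein-like dataset is
    obtained by passing a small target).  The contracted state uses a
    reduced inner-layer volume representing fluid exudation.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    params = spec.params
    if T_act is None:
        if target_reduction_pct == 0.0:
            T_act = 0.0
        else:
            T_act = fit_active_tone(
                target_reduction_pct, params, v_contracted=v_contracted,
                pressure_mmhg=pressure_mmhg,
            ).T_act
    model = BilayerVesselModel(params)
    d_pass = model.solve(pressure_mmhg, T_act=0.0, v=1.0).outer_diameter
    v_c = v_contracted if T_act > 0.0 else 1.0
    d_con = model.solve(pressure_mmhg, T_act=T_act, v=v_c).outer_diameter
    rows = []
    for vid in range(1, spec.n_vessels + 1):
        dp = d_pass * (1.0 + spec.noise_diameter * rng.standard_normal())
        dc = d_con * (1.0 + spec.noise_diameter * rng.standard_normal())
        rows.append({
            "vessel_id": vid,
            "pressure_mmHg": pressure_mmhg,
            "passive_outer_diameter_um": dp,
            "contracted_outer_diameter_um": dc,
            "reduction_pct": 100.0 * (1.0 - dc / dp),
        })
    df = pd.DataFrame(rows)
    meta = {
        "T_act_kPa": float(T_act),
        "v_contracted": v_c,
        "pressure_mmHg": pressure_mmhg,
        "seed": seed,
        "noise_diameter": spec.noise_diameter,
        "mean_reduction_pct": float(df["reduction_pct"].mean()),
    }
    return df, meta


def save_dataset(data: BiaxialProtocolData, truth: dict, stem: str | Path) -> None:
    """Write data CSV and truth JSON side by side (stem.csv / stem.json)."""
    stem = Path(stem)
    data.to_csv(stem.with_suffix(".csv"))
    stem.with_suffix(".json").write_text(json.dumps(truth, indent=2))
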