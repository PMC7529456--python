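"""Baseline model parameters and flat YAML parameter files.

The packaged file ``data/umbilical_artery.yaml`` holds the baseline
murine umbilical-artery parameter set used throughout: unloaded bilayer
geometry, layer shear moduli, four fiber families in the outer layer and
the smooth-muscle contractile stretch window.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .constitutive import ActiveTone, FiberFamily, LayerMaterial, VesselGeometry

__all__ = ["VesselParameters", "baseline_parameters", "load_parameters", "save_parameters"]


@dataclass(frozen=True)
class VesselParameters:
    """Complete parameter set for the bilayered vessel model."""

    geometry: VesselGeometry
    inner: LayerMaterial
    outer: LayerMaterial
    tone: ActiveTone

    def to_dict(self) -> dict:
        g = self.geometry
        d = {
            "A_um": g.A,
            "B_um": g.B,
            "C_um": g.C,
            "lambda_z": g.lambda_z,
            "mu1_kPa": self.inner.mu,
            "mu2_kPa": self.outer.mu,
            "lambda_m": self.tone.lambda_m,
            "lambda_0": self.tone.lambda_0,
            "T_act_kPa": self.tone.T_act,
        }
        for i, fam in enumerate(self.outer.fibers, start=1):
            d[f"c1_{i}_kPa"] = fam.c1
            d[f"c2_{i}"] = fam.c2
            d[f"eta_{i}_deg"] = fam.eta
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VesselParameters":
        geometry = VesselGeometry(
            A=float(d["A_um"]), B=float(d["B_um"]), C=float(d["C_um"]),
            lambda_z=float(d.get("lambda_z", 1.0)),
        )
        fibers = []
        i = 1
        while f"c1_{i}_kPa" in d:
            fibers.append(
                FiberFamily(
                    c1=float(d[f"c1_{i}_kPa"]),
                    c2=float(d[f"c2_{i}"]),
                    eta=float(d[f"eta_{i}_deg"]),
                )
            )
            i += 1
        inner = LayerMaterial(mu=float(d["mu1_kPa"]))
        outer = LayerMaterial(mu=float(d["mu2_kPa"]), fibers=tuple(fibers))
        tone = ActiveTone(
            T_act=float(d.get("T_act_kPa", 0.0)),
            lambda_m=float(d.get("lambda_m", 2.5)),
            lambda_0=float(d.get("lambda_0", 0.2)),
        )
        return cls(geometry=geometry, inner=inner, outer=outer, tone=tone)


def baseline_parameters() -> VesselParameters:
    """Baseline murine umbilical-artery parameter set (packaged YAML)."""
    with resources.files("cordclose.data").joinpath("umbilical_artery.yaml").open() as fh:
        return VesselParameters.from_dict(yaml.safe_load(fh))


def load_parameters(path: str | Path) -> VesselParameters:
    with open(path) as fh:
        return VesselParameters.from_dict(yaml.safe_load(fh))


def save_parameters(params: VesselParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
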