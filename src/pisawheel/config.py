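"""Pipeline configuration: every tunable constant in one declarative place.

Defaults reproduce the study conditions: the 57-residue syndecan-4
construct, TM torsions Φ = −69° / Ψ = −42°, ¹⁵N tensor (64, 77, 217) ppm,
bicelle order parameter S = 0.85 in the unflipped state, ν∥ = 10.52 kHz,
CSP weighting α = 0.14, and dimer tilts 6° / 16°.  Unknown keys in a
config file are rejected before any computation runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .construct import DEFAULT_FIRST_FULL_NUMBER, SYD4_ETC_SEQUENCE

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # construct
    sequence: str = SYD4_ETC_SEQUENCE
    first_full_number: int = DEFAULT_FIRST_FULL_NUMBER
    tm_span: tuple[int, int] = (5, 29)

    # helix geometry
    phi: float = -69.0
    psi: float = -42.0
    beta_deg: float = 17.0          # sigma33 / N-H angle in the peptide plane

    # 15N CSA tensor (ppm); sigma22 alternative 88.0 selectable
    sigma11: float = 64.0
    sigma22: float = 77.0
    sigma33: float = 217.0

    # bicelle
    order_parameter: float = 0.85
    flip: str = "unflipped"

    # dipolar scale (kHz)
    nu_parallel: float = 10.52

    # 1D CP topology classification
    classify_threshold: float = 120.0
    surface_below: bool = True

    # CSP
    alpha: float = 0.14
    csp_sqrt: bool = True
    flag_rule: str = "mean_plus_sd"
    flag_value: float = 3.0

    # tilt fitting grids (degrees)
    tau_min: float = 0.0
    tau_max: float = 30.0
    tau_step: float = 0.5
    rho_step: float = 5.0

    # dimer simulation truths
    tilt_a: float = 6.0
    tilt_b: float = 16.0
    rho_a: float = 40.0
    rho_b: float = 200.0

    # synthetic data
    seed: int = 0
    noise_h: float = 0.01
    noise_n: float = 0.05
    noise_shift: float = 0.5
    noise_coupling: float = 0.1
    perturbations: dict[int, tuple[float, float]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config file, rejecting unknown keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "perturbations" in raw and raw["perturbations"]:
            raw = dict(raw)
            raw["perturbations"] = {
                int(k): tuple(float(x) for x in v)
                for k, v in raw["perturbations"].items()
            }
        if "tm_span" in raw:
            raw = dict(raw)
            raw["tm_span"] = tuple(int(x) for x in raw["tm_span"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tm_span"] = list(self.tm_span)
        d["perturbations"] = {int(k): list(v) for k, v in self.perturbations.items()}
        return d
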