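"""Run configuration: one YAML/JSON document describing a study run.

All physical quantities in the document carry conventional clinical units
(mmHg, L/min, mm) and are converted to SI when the configuration is turned
into model objects.  The same document round-trips losslessly, and a hash
of its canonical form is recorded in every output for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .geometry import AgingSpec, GeometryConfig
from .inflow import InflowSpec
from .solver import SolverConfig
from .units import L_PER_MIN, MMHG


@dataclass
class RunConfig:
    """Study configuration (clinical units; see field comments)."""

    ages: tuple[int, ...] = (40, 60, 75)
    geometry_source: str = "synthetic"      # "synthetic" | path to a .vtk centerline
    mean_flow_l_min: float = 5.79
    heart_rate_bpm: float = 60.0
    systolic_fraction: float = 0.33
    peak_time_fraction: float = 0.30
    reverse_fraction: float = 0.05
    compliance_scale: float | None = None   # None -> package default
    dx_mm: float = 7.5
    cfl: float = 0.8
    min_cycles: int = 6
    max_cycles: int = 12
    periodicity_tol_mmhg: float = 0.375
    pwv_targets: dict[int, float] = field(
        default_factory=lambda: {40: 6.9, 60: 9.3, 75: 10.9})
    pwv_tol: float = 0.2
    dta_support_ratio: float = 0.5
    damping: dict[str, float] = field(
        default_factory=lambda: {"ATA": 200.0, "DTA": 200.0, "IAA": 200.0})
    height_reduction_per_decade: float = 0.01
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self):
        if self.geometry_source != "synthetic" and not str(self.geometry_source).endswith(".vtk"):
            raise ValueError(
                "geometry_source must be 'synthetic' or a .vtk path "
                f"(got {self.geometry_source!r})")
        for a in self.ages:
            if a not in (30, 40, 60, 75):
                raise ValueError(f"unsupported age {a}: table ages are 30/40/60/75")

    # -- object factories ---------------------------------------------------
    def inflow(self) -> InflowSpec:
        return InflowSpec(
            mean_flow=self.mean_flow_l_min * L_PER_MIN,
            heart_rate=self.heart_rate_bpm,
            systolic_fraction=self.systolic_fraction,
            peak_time_fraction=self.peak_time_fraction,
            reverse_fraction=self.reverse_fraction)

    def solver(self) -> SolverConfig:
        return SolverConfig(
            dx=self.dx_mm * 1e-3, cfl=self.cfl,
            min_cycles=self.min_cycles, max_cycles=self.max_cycles,
            periodicity_tol=self.periodicity_tol_mmhg * MMHG)

    def aging(self) -> AgingSpec:
        return AgingSpec(height_reduction_per_decade=self.height_reduction_per_decade)

    def geometry(self) -> GeometryConfig:
        cfg = GeometryConfig()
        if self.geometry_source != "synthetic":
            from .vtkio import read_centerline_vtk
            skel = read_centerline_vtk(self.geometry_source)
            trunk = skel.trunk
            cfg.trunk_length = trunk.arc_length / 1.27 \
                if trunk.arc_length > 0.8 * cfg.trunk_length * 1.27 else trunk.arc_length
            cfg.baseline_tortuosity = min(trunk.tortuosity, 1.5)
        return cfg

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["ages"] = list(self.ages)
        d["pwv_targets"] = {str(k): v for k, v in self.pwv_targets.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "ages" in d:
            d["ages"] = tuple(int(a) for a in d["ages"])
        if "pwv_targets" in d:
            d["pwv_targets"] = {int(k): float(v) for k, v in d["pwv_targets"].items()}
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
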