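"""Bundled regional wall-property and Windkessel outlet tables.

The package ships two small CSV tables: biaxial wall properties at three
aortic stations (ascending thoracic, proximal descending thoracic, and
infrarenal abdominal aorta — ATA/DTA/IAA) for ages 30/40/60/75, and
three-element Windkessel (RCR) parameters for the fifteen outlets of the
arterial tree.  Everything is converted to SI on load; accessors interpolate
station values linearly along the normalized aortic arc length ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .units import C_SCALE, MM, MMHG, MPA, R_SCALE

#: normalized arc-length coordinates where station properties are anchored
STATION_S = {"ATA": 0.12, "DTA": 0.40, "IAA": 0.88}

STIFFNESS_AGES = (40, 60, 75)

#: fifteen terminal outlets, in the order of the bundled Windkessel table
OUTLET_NAMES = (
    "right_subclavian", "left_subclavian", "right_carotid", "left_carotid",
    "right_renal", "left_renal", "celiac", "gastric", "splenic",
    "superior_mesenteric", "inferior_mesenteric",
    "right_ext_iliac", "right_int_iliac", "left_ext_iliac", "left_int_iliac",
)


def _read_bundled(name: str) -> pd.DataFrame:
    with resources.files("aortaflow.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


@dataclass(frozen=True)
class StationRow:
    """Wall properties at one (age, station), in SI units."""

    age: int
    station: str
    radius: float          # inner radius [m]
    thickness: float       # [m]
    map_pressure: float    # [Pa]
    ep: float              # external pressure [Pa]; nan for the 30 yo rows
    axial_stretch: float
    circ_stretch: float
    k_tt: float            # circumferential material stiffness [Pa]
    k_zz: float            # axial material stiffness [Pa]

    @property
    def tp(self) -> float:
        """Transmural pressure MAP - EP the stiffness was linearized at [Pa]."""
        return self.map_pressure - self.ep


class WallTable:
    """Station wall properties with linear interpolation along ``s``.

    Values are anchored at s = 0.12 (ATA), 0.4 (DTA) and 0.88 (IAA) and
    interpolated linearly in between; beyond the outer stations they are
    extrapolated constantly (to the aortic root proximally and through the
    iliac arteries distally).
    """

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            frame = _read_bundled("wall_properties.csv")
        self._rows: dict[tuple[int, str], StationRow] = {}
        for _, r in frame.iterrows():
            row = StationRow(
                age=int(r["age"]),
                station=str(r["station"]),
                radius=float(r["radius_mm"]) * MM,
                thickness=float(r["thickness_mm"]) * MM,
                map_pressure=float(r["map_mmhg"]) * MMHG,
                ep=float(r["ep_mmhg"]) * MMHG if pd.notna(r["ep_mmhg"]) else float("nan"),
                axial_stretch=float(r["axial_stretch"]) if pd.notna(r["axial_stretch"]) else float("nan"),
                circ_stretch=float(r["circ_stretch"]) if pd.notna(r["circ_stretch"]) else float("nan"),
                k_tt=float(r["k_tt_mpa"]) * MPA if pd.notna(r["k_tt_mpa"]) else float("nan"),
                k_zz=float(r["k_zz_mpa"]) * MPA if pd.notna(r["k_zz_mpa"]) else float("nan"),
            )
            self._rows[(row.age, row.station)] = row

    @property
    def ages(self) -> tuple[int, ...]:
        return tuple(sorted({a for a, _ in self._rows}))

    def row(self, age: int, station: str) -> StationRow:
        try:
            return self._rows[(age, station)]
        except KeyError:
            raise KeyError(
                f"no wall data for age {age} at {station}; available ages: {self.ages}"
            ) from None

    def _interp(self, age: int, s, attr: str) -> np.ndarray:
        xs = np.array([STATION_S[st] for st in ("ATA", "DTA", "IAA")])
        ys = np.array([getattr(self.row(age, st), attr) for st in ("ATA", "DTA", "IAA")])
        # np.interp clamps outside the station range = constant extrapolation
        return np.interp(np.asarray(s, dtype=float), xs, ys)

    def radius(self, age: int, s) -> np.ndarray:
        """Inner radius profile [m] at normalized arc length ``s``."""
        return self._interp(age, s, "radius")

    def thickness(self, age: int, s) -> np.ndarray:
        return self._interp(age, s, "thickness")

    def k_tt(self, age: int, s) -> np.ndarray:
        """Circumferential material stiffness [Pa] along the trunk."""
        return self._interp(age, s, "k_tt")

    def k_zz(self, age: int, s) -> np.ndarray:
        return self._interp(age, s, "k_zz")

    def map_pressure(self, age: int, s) -> np.ndarray:
        return self._interp(age, s, "map_pressure")

    def ep(self, age: int, s) -> np.ndarray:
        return self._interp(age, s, "ep")


@dataclass
class WindkesselRow:
    outlet: str
    r_prox: float      # [Pa s/m^3]
    r_dist: float      # [Pa s/m^3]
    compliance: float  # [m^3/Pa]


class WindkesselTable:
    """Per-outlet RCR values for one age, in SI units."""

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            frame = _read_bundled("windkessel.csv")
        self._frame = frame.set_index("outlet")

    def rows(self, age: int) -> dict[str, WindkesselRow]:
        if age not in STIFFNESS_AGES:
            raise KeyError(f"Windkessel table has ages {STIFFNESS_AGES}, not {age}")
        col = f"r_dist_{age}"
        out = {}
        for name, r in self._frame.iterrows():
            out[str(name)] = WindkesselRow(
                outlet=str(name),
                r_prox=float(r["r_prox"]) * R_SCALE,
                r_dist=float(r[col]) * R_SCALE,
                compliance=float(r["compliance"]) * C_SCALE,
            )
        return out

    def total_resistance(self, age: int) -> float:
        """Parallel combination of (R_prox + R_dist) over all outlets [Pa s/m^3]."""
        rows = self.rows(age)
        return 1.0 / sum(1.0 / (r.r_prox + r.r_dist) for r in rows.values())
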