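"""Arterial wall mechanics: four-fiber-family constitutive model,
small-on-large linearization, and the linearized pressure-area tube law.

The wall is a thin incompressible membrane.  Its strain energy combines a
neo-Hookean term for the elastin-dominated matrix with four exponential
(Fung-type) fiber families — axial, circumferential, and a symmetric
diagonal pair:

    W = c/2 (lt^2 + lz^2 + lr^2 - 3)
        + sum_k c1_k/(4 c2_k) [exp(c2_k (lk^2 - 1)^2) - 1],
    lk^2 = lz^2 cos^2(a_k) + lt^2 sin^2(a_k),   lr = 1/(lt lz).

Linearizing about the finitely deformed in vivo state (stretches at mean
transmural pressure) yields incremental biaxial plane-stress moduli
K_tt and K_zz; combined with thickness and radius these give the structural
stiffness that sets the local wave speed.  The default operating mode of
the pipeline takes K_tt/K_zz directly from the bundled station table (the
published linearized values); the constitutive path serves users who supply
their own fiber parameters.

The tube law closing the 1D solver is the membrane + external-support
incremental equilibrium:  dP = (K_tt h / R^2 + k_s) dr, hence

    dA/dP = 2 pi R / (K_tt h / R^2 + k_s),
    c = sqrt((K_tt h / R + k_s R) / (2 rho)),

the Moens-Korteweg speed generalized by perivascular support stiffness.
Axial stiffness K_zz is carried through the data model but does not enter
the radial-motion-only tube law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

BLOOD_DENSITY = 1060.0      # kg/m^3
BLOOD_VISCOSITY = 4.0e-3    # Pa s

_MAX_EXPONENT = 500.0


class FiberOverflowError(FloatingPointError):
    """Exponential fiber term overflow at extreme stretch."""


@dataclass(frozen=True)
class FourFiberParams:
    """Material parameters of the four-fiber-family strain energy."""

    c: float                          # neo-Hookean modulus [Pa]
    c1: tuple[float, float, float, float]   # fiber moduli [Pa]
    c2: tuple[float, float, float, float]   # fiber exponents [-]
    alpha: tuple[float, float, float, float] = (0.0, math.pi / 2, 0.7854, -0.7854)
    # fiber angles from the axial direction: axial, circumferential, +/- diagonal

    def __post_init__(self):
        if self.c < 0 or any(v < 0 for v in self.c1) or any(v < 0 for v in self.c2):
            raise ValueError("moduli and exponents must be >= 0")
        if not math.isclose(abs(self.alpha[2]), abs(self.alpha[3])):
            raise ValueError("diagonal fiber families must share angle magnitude")


@dataclass(frozen=True)
class InVivoState:
    """The finitely deformed in vivo configuration the wall is linearized about."""

    radius: float          # inner radius [m]
    thickness: float       # [m]
    axial_stretch: float
    circ_stretch: float
    tp: float              # transmural pressure MAP - EP [Pa]

    def __post_init__(self):
        if self.axial_stretch <= 0 or self.circ_stretch <= 0:
            raise ValueError("stretches must be > 0")
        if self.thickness >= self.radius:
            raise ValueError("thin-wall regime requires h < R")
        if self.tp <= 0:
            raise ValueError("transmural pressure must be > 0")


@dataclass
class LinearizedWall:
    """Biaxial incremental stiffness at one location."""

    k_tt: float            # circumferential material stiffness [Pa]
    k_zz: float            # axial material stiffness [Pa]
    thickness: float       # [m]
    radius: float          # in vivo inner radius [m]
    ep: float = 0.0        # external pressure the support carries at MAP [Pa]
    source: str = "table"  # {"table", "constitutive"}

    def __post_init__(self):
        if self.k_tt <= 0 or self.k_zz <= 0:
            raise ValueError("material stiffness must be > 0")

    @property
    def radial_stiffness(self) -> float:
        """Wall contribution to dP/dr [Pa/m]."""
        return self.k_tt * self.thickness / self.radius ** 2


@dataclass
class TubeLaw:
    """Linearized pressure-area relation including external support."""

    area_ref: float        # reference area at P_ref [m^2]
    p_ref: float           # reference (mean) pressure [Pa]
    dadp: float            # effective distensibility slope dA/dP [m^2/Pa]
    k_s: float = 0.0       # support stiffness [Pa/m]
    c_s: float = 0.0       # support damping [Pa s/m]
    rho: float = BLOOD_DENSITY

    def __post_init__(self):
        if self.dadp <= 0:
            raise ValueError("dA/dP must be > 0")

    @property
    def wave_speed(self) -> float:
        """Local pulse wave speed c = sqrt(A / (rho dA/dP)) [m/s]."""
        return math.sqrt(self.area_ref / (self.rho * self.dadp))

    def pressure(self, area):
        return self.p_ref + (np.asarray(area) - self.area_ref) / self.dadp

    def area(self, pressure):
        return self.area_ref + (np.asarray(pressure) - self.p_ref) * self.dadp


# --------------------------------------------------------------------------
# strain energy and stress


def _fiber_stretch_sq(lt, lz, alpha):
    return lz ** 2 * math.cos(alpha) ** 2 + lt ** 2 * math.sin(alpha) ** 2


def strain_energy(lt: float, lz: float, params: FourFiberParams) -> float:
    """Strain energy density W(lt, lz) [Pa] under incompressibility."""
    if lt <= 0 or lz <= 0:
        raise ValueError("stretches must be > 0")
    lr = 1.0 / (lt * lz)
    w = 0.5 * params.c * (lt ** 2 + lz ** 2 + lr ** 2 - 3.0)
    for k in range(4):
        lk2 = _fiber_stretch_sq(lt, lz, params.alpha[k])
        e = params.c2[k] * (lk2 - 1.0) ** 2
        if e > _MAX_EXPONENT:
            raise FiberOverflowError(
                f"fiber family {k} ({'axial circumferential diagonal diagonal'.split()[k]})"
                f" overflows at stretch^2 = {lk2:.3f}")
        if params.c2[k] > 0:
            w += params.c1[k] / (4.0 * params.c2[k]) * (math.exp(e) - 1.0)
        else:
            # c2 -> 0 limit: quadratic fiber energy c1/4 (lk^2-1)^2
            w += 0.25 * params.c1[k] * (lk2 - 1.0) ** 2
    return w


def _dW(lt: float, lz: float, params: FourFiberParams) -> tuple[float, float]:
    """Analytic (dW/dlt, dW/dlz)."""
    lr2 = 1.0 / (lt * lz) ** 2
    dwt = params.c * (lt - lr2 / lt)
    dwz = params.c * (lz - lr2 / lz)
    for k in range(4):
        a = params.alpha[k]
        lk2 = _fiber_stretch_sq(lt, lz, a)
        e = params.c2[k] * (lk2 - 1.0) ** 2
        if e > _MAX_EXPONENT:
            raise FiberOverflowError(f"fiber family {k} overflows")
        g = params.c1[k] * (lk2 - 1.0) * math.exp(e)
        dwt += g * lt * math.sin(a) ** 2
        dwz += g * lz * math.cos(a) ** 2
    return dwt, dwz


def biaxial_stress(lt: float, lz: float, params: FourFiberParams) -> tuple[float, float]:
    """Cauchy membrane stresses (sigma_tt, sigma_zz) [Pa].

    Incompressibility and zero mean radial stress give
    sigma_i = l_i dW/dl_i with W reduced to (lt, lz).
    """
    dwt, dwz = _dW(lt, lz, params)
    return lt * dwt, lz * dwz


def equilibrium_circ_stretch(params: FourFiberParams, lz: float,
                             tp: float, radius_over_thickness: float) -> float:
    """Circumferential stretch solving thin-wall equilibrium
    sigma_tt = TP * r/h at fixed axial stretch.

    ``radius_over_thickness`` is the deformed mid-wall ratio r/h; the Laplace
    stress TP*r/h is treated as the target mean wall stress.
    """
    target = tp * radius_over_thickness

    def f(lt):
        return biaxial_stress(lt, lz, params)[0] - target

    return brentq(f, 0.3, 3.0, xtol=1e-12)


def small_on_large(state: InVivoState, params: FourFiberParams,
                   check_equilibrium: bool = True) -> LinearizedWall:
    """Linearized incremental plane-stress moduli about the in vivo state.

    K_tt = lt d(sigma_tt)/dlt at fixed lz, and symmetrically for K_zz —
    the tangent stiffness of the membrane stress-stretch response at the
    operating point, computed from analytic second derivatives of W.
    """
    lt, lz = state.circ_stretch, state.axial_stretch
    if check_equilibrium:
        s_tt, _ = biaxial_stress(lt, lz, params)
        laplace = state.tp * state.radius / state.thickness
        if abs(s_tt - laplace) > 0.05 * max(abs(laplace), 1.0):
            raise ValueError(
                "in vivo state is not in membrane equilibrium "
                f"(sigma_tt = {s_tt:.0f} Pa vs TP*R/h = {laplace:.0f} Pa); "
                "solve equilibrium_circ_stretch first or pass "
                "check_equilibrium=False")

    # second derivatives of W
    lr2 = 1.0 / (lt * lz) ** 2
    d2wtt = params.c * (1.0 + 3.0 * lr2 / lt ** 2)
    d2wzz = params.c * (1.0 + 3.0 * lr2 / lz ** 2)
    for k in range(4):
        a = params.alpha[k]
        sa2, ca2 = math.sin(a) ** 2, math.cos(a) ** 2
        lk2 = _fiber_stretch_sq(lt, lz, a)
        x = lk2 - 1.0
        e = math.exp(params.c2[k] * x ** 2)
        # d/dlt [c1 x e lt sa2] = c1 sa2 (x e + lt * dx/dlt * e(1 + 2 c2 x^2))
        dxdt = 2.0 * lt * sa2
        dxdz = 2.0 * lz * ca2
        d2wtt += params.c1[k] * sa2 * (x * e + lt * dxdt * e * (1.0 + 2.0 * params.c2[k] * x ** 2))
        d2wzz += params.c1[k] * ca2 * (x * e + lz * dxdz * e * (1.0 + 2.0 * params.c2[k] * x ** 2))

    dwt, dwz = _dW(lt, lz, params)
    # K_i = l_i d(sigma_i)/dl_i = l_i (dW_i + l_i d2W_ii)
    k_tt = lt * (dwt + lt * d2wtt)
    k_zz = lz * (dwz + lz * d2wzz)
    return LinearizedWall(k_tt=k_tt, k_zz=k_zz, thickness=state.thickness,
                          radius=state.radius, source="constitutive")


# --------------------------------------------------------------------------
# tube law and property assignment


def tube_law(wall: LinearizedWall, k_s: float = 0.0, c_s: float = 0.0,
             rho: float = BLOOD_DENSITY, p_ref: float = 0.0) -> TubeLaw:
    """Linearized pressure-area law at the reference (MAP) configuration.

    dA/dP = 2 pi R / (K_tt h / R^2 + k_s); in the rigid-support limit
    (k_s -> inf) the slope vanishes and the wave speed diverges.
    """
    if wall.thickness <= 0 or wall.radius <= 0:
        raise ValueError("wall geometry must be positive")
    stiff = wall.radial_stiffness + k_s
    return TubeLaw(area_ref=math.pi * wall.radius ** 2, p_ref=p_ref,
                   dadp=2.0 * math.pi * wall.radius / stiff,
                   k_s=k_s, c_s=c_s, rho=rho)


#: branch wall rules: carotids/subclavians get isotropic, age-dependent
#: stiffness (sparse literature trend for the carotid elastic modulus,
#: approximate and configurable); muscular abdominal branches do not stiffen
#: with age and default to the 75 yo IAA stiffness.
CAROTID_STIFFNESS = {40: 0.55e6, 60: 0.75e6, 75: 0.95e6}   # [Pa]
CAROTID_H_OVER_R = 0.16
MUSCULAR_H_OVER_R = 0.214    # matches the 75 yo IAA thickness/radius ratio

UPPER_BRANCHES = frozenset({
    "right_subclavian", "left_subclavian", "right_carotid", "left_carotid"})


@dataclass
class BranchWallRules:
    carotid_stiffness: dict[int, float] = field(
        default_factory=lambda: dict(CAROTID_STIFFNESS))
    carotid_h_over_r: float = CAROTID_H_OVER_R
    muscular_h_over_r: float = MUSCULAR_H_OVER_R

    def muscular_stiffness(self, table) -> float:
        """Age-invariant stiffness of muscular branches = 75 yo IAA value."""
        return table.row(75, "IAA").k_tt


def assign_wall_properties(tree, age: int, table=None,
                           rules: BranchWallRules | None = None) -> dict[str, tuple[LinearizedWall, LinearizedWall]]:
    """Per-segment wall properties (proximal, distal ends) for one age.

    Trunk and iliac segments interpolate the station table linearly along
    ``s`` (constant extrapolation beyond the outer stations, through the
    iliacs).  Carotid and subclavian arteries get isotropic age-dependent
    stiffness; mesenteric, celiac, renal and the remaining muscular branches
    keep the 75 yo IAA stiffness at every age.
    """
    from .tables import STIFFNESS_AGES, WallTable

    if table is None:
        table = WallTable()
    if age not in STIFFNESS_AGES:
        raise KeyError(f"age {age} not in stiffness table ages {STIFFNESS_AGES}")
    rules = rules or BranchWallRules()

    out = {}
    for name, seg in tree.segments.items():
        if seg.is_aortic:
            walls = []
            for s_end, r_end in ((seg.s_range[0], seg.radius_prox),
                                 (seg.s_range[1], seg.radius_dist)):
                s_q = min(s_end, 1.0) if s_end > 1.0 else s_end
                walls.append(LinearizedWall(
                    k_tt=float(table.k_tt(age, s_q)),
                    k_zz=float(table.k_zz(age, s_q)),
                    thickness=float(table.thickness(age, s_q)),
                    radius=r_end,
                    ep=float(table.ep(age, s_q)),
                    source="table"))
            out[name] = (walls[0], walls[1])
        elif seg.region == "branch":
            if seg.name in UPPER_BRANCHES:
                k = rules.carotid_stiffness[age]
                h_over_r = rules.carotid_h_over_r
                k_zz = k   # isotropic
            else:
                k = rules.muscular_stiffness(table)
                h_over_r = rules.muscular_h_over_r
                k_zz = table.row(75, "IAA").k_zz
            walls = tuple(
                LinearizedWall(k_tt=k, k_zz=k_zz, thickness=h_over_r * r,
                               radius=r, ep=0.0, source="table")
                for r in (seg.radius_prox, seg.radius_dist))
            out[name] = walls
        else:   # pragma: no cover - regions are exhaustive
            raise KeyError(f"no wall rule for segment {name} ({seg.region})")
    return out
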