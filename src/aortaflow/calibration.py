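"""Calibration loops: Windkessel distal-resistance tuning and the iterative
external-tissue-support / external-pressure loop.

Two tuning problems close the model:

1. **Windkessel tuning** — the distal resistances of all outlets are scaled
   by one common factor so the steady 0D prediction of ascending-aortic
   mean pressure, Q_mean * R_total + P_out, matches the age-specific target
   MAP.  Scaling R_dist uniformly (R_prox and C untouched) preserves the
   outlet flow splits to first order; it mirrors the observation that
   distal resistance is the parameter that must rise with aging to
   reproduce the MAP increase.

2. **External-support tuning** — perivascular tethering stiffness k_s
   raises local wave speed (c^2 = (K_tt h/R + k_s R)/(2 rho)); the
   thoracic k_s is adjusted iteratively (bisection on log k_s, monotone
   response) until the computed foot-to-foot aorto-iliac PWV matches the
   age-specific population reference value.  The abdominal region is pinned
   to zero support (its computed external pressure is ~0 mmHg).  In the
   default table mode, the tabulated stiffness values (already linearized
   at the published transmural pressure) stay fixed and the support is
   anchored to carry the published external pressure at the reference
   radius; the loop then verifies self-consistency: the external pressure
   recovered from the converged mean displacement must match the anchor
   within tolerance.  In constitutive mode the wall is re-linearized at
   TP = MAP - EP each iteration.

The support damping c_s is set by a doubling search to the smallest value
whose converged waveforms carry less than 1% of their pulsatile energy
above 20 Hz (spurious node-scale oscillation), and is held fixed while
k_s is tuned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .solver import SupportMap, WindkesselBC
from .units import MMHG

log = logging.getLogger(__name__)

#: age-specific aorto-iliac PWV reference values used as calibration
#: targets (population data standardized on the intersecting-tangent
#: transit time and 0.8-corrected path length) [m/s]
REFERENCE_AORTOILIAC_PWV = {40: 6.9, 60: 9.3, 75: 10.9}


@dataclass
class CalibrationTargets:
    map_target: float                    # [Pa]
    pwv_target: float                    # aorto-iliac [m/s]
    pwv_tol: float = 0.2                 # [m/s]
    ep_tol: float = 0.5 * MMHG           # [Pa]
    map_tol: float = 1.0 * MMHG          # [Pa]
    flow_split_tol: float = 0.01
    max_iter: int = 20


@dataclass
class SupportState:
    """Converged external-support parameters and implied external pressures."""

    k_s: dict[str, float]
    c_s: dict[str, float]
    ep: dict[str, float]                 # anchored EP per region [Pa]
    ep_computed: dict[str, float] = field(default_factory=dict)
    pwv: float = float("nan")
    iterations: int = 0
    converged: bool = False
    history: list[dict] = field(default_factory=list)

    def as_support_map(self) -> SupportMap:
        return SupportMap(k_s=dict(self.k_s), c_s=dict(self.c_s), ep=dict(self.ep))


# --------------------------------------------------------------------------
# Windkessel tuning


def predicted_map(outlets: dict[str, WindkesselBC], mean_flow: float,
                  p_out: float = 0.0) -> float:
    """Steady 0D central mean pressure Q * R_total + P_out [Pa]."""
    g = sum(1.0 / (bc.r_prox + bc.r_dist) for bc in outlets.values())
    return p_out + mean_flow / g


def tune_windkessel(outlets: dict[str, WindkesselBC], target_map: float,
                    mean_flow: float, p_out: float = 0.0) -> tuple[dict[str, WindkesselBC], float]:
    """Scale every R_dist by a common factor so the steady 0D mean pressure
    matches ``target_map``; returns (adjusted outlets, scale factor)."""

    def resid(x):
        g = sum(1.0 / (bc.r_prox + x * bc.r_dist) for bc in outlets.values())
        return p_out + mean_flow / g - target_map

    if target_map <= p_out:
        raise ValueError("target MAP must exceed the distal reference pressure")
    lo, hi = 1e-3, 1e3
    if resid(lo) > 0:
        raise ValueError("target MAP unreachable: R_prox alone already exceeds it")
    x = brentq(resid, lo, hi, xtol=1e-10)
    if x <= 0:
        raise ValueError("non-physical (negative) distal resistance scaling")
    tuned = {
        name: WindkesselBC(r_prox=bc.r_prox, r_dist=x * bc.r_dist,
                           compliance=bc.compliance, p_out=bc.p_out)
        for name, bc in outlets.items()}
    return tuned, x


def flow_splits(outlets: dict[str, WindkesselBC]) -> dict[str, float]:
    """Steady-state fraction of total mean flow through each outlet."""
    g = {n: 1.0 / (bc.r_prox + bc.r_dist) for n, bc in outlets.items()}
    tot = sum(g.values())
    return {n: v / tot for n, v in g.items()}


# --------------------------------------------------------------------------
# external support tuning


def tune_external_support(evaluate, targets: CalibrationTargets,
                          k_seed: float = 1e5, k_cap: float = 1e9,
                          ep_anchor: dict[str, float] | None = None,
                          dta_ratio: float = 0.5,
                          c_s: dict[str, float] | None = None,
                          relinearize=None) -> SupportState:
    """Tune the thoracic support stiffness to the target aorto-iliac PWV.

    ``evaluate(support_map) -> (pwv, ep_computed)`` runs one converged
    simulation under the given support and measures the aorto-iliac PWV and
    the per-region external pressure recovered from the displacement field.
    The search variable is the ATA support stiffness ``k``; the DTA region
    follows at ``dta_ratio * k`` and the IAA region is pinned to zero
    support.  PWV(k) is monotone increasing, so a doubling bracket followed
    by log-space bisection converges.

    In constitutive mode, pass ``relinearize(ep_computed) -> ep_anchor'``:
    after each simulation the wall is re-linearized at the updated
    transmural pressure TP = MAP - EP and the support anchor follows; the
    loop then also drives |EP_assumed - EP_computed| below tolerance.
    """
    ep_anchor = dict(ep_anchor or {"ATA": 0.0, "DTA": 0.0, "IAA": 0.0})
    c_s = dict(c_s or {"ATA": 200.0, "DTA": 200.0, "IAA": 200.0})

    def make_map(k):
        ks = {"ATA": k, "DTA": dta_ratio * k, "IAA": 0.0}
        # the anchor scales out when k = 0 (no support, no carried EP)
        ep = {r: (ep_anchor.get(r, 0.0) if ks[r] > 0 else 0.0) for r in ks}
        return SupportMap(k_s=ks, c_s=dict(c_s), ep=ep)

    state = SupportState(k_s={}, c_s=dict(c_s), ep={})

    def f(k):
        pwv, ep_comp = evaluate(make_map(k))
        state.history.append({"k_ata": k, "pwv": pwv,
                              "ep": {r: v / MMHG for r, v in ep_comp.items()}})
        state.iterations += 1
        log.info("support iteration %d: k_ATA = %.3g Pa/m -> PWV %.2f m/s",
                 state.iterations, k, pwv)
        if relinearize is not None:
            updated = relinearize(ep_comp)
            if updated:
                ep_anchor.update(updated)
        return pwv, ep_comp

    pwv0, ep0 = f(0.0)
    if pwv0 >= targets.pwv_target - targets.pwv_tol:
        # already at (or above) target without support: converged fixed point
        state.k_s = {"ATA": 0.0, "DTA": 0.0, "IAA": 0.0}
        state.ep = {"ATA": 0.0, "DTA": 0.0, "IAA": 0.0}
        state.ep_computed = ep0
        state.pwv = pwv0
        state.converged = abs(pwv0 - targets.pwv_target) <= targets.pwv_tol
        if not state.converged:
            log.warning("unsupported PWV %.2f already exceeds target %.2f; "
                        "k_s cannot be negative", pwv0, targets.pwv_target)
        return state

    # doubling bracket
    k_lo, p_lo = 0.0, pwv0
    k = k_seed
    p_hi, ep_hi = f(k)
    while p_hi < targets.pwv_target and k < k_cap and state.iterations < targets.max_iter:
        k_lo, p_lo = k, p_hi
        k *= 2.0
        p_hi, ep_hi = f(k)
    k_hi = k
    if p_hi < targets.pwv_target:
        log.warning("support search cap reached (PWV %.2f < target %.2f)",
                    p_hi, targets.pwv_target)

    # log-space bisection (secant-accelerated on log k)
    best = (k_hi, p_hi, ep_hi)
    lo = max(k_lo, k_seed / 8.0)
    while state.iterations < targets.max_iter and \
            abs(best[1] - targets.pwv_target) > targets.pwv_tol:
        if p_lo is not None and p_hi > p_lo and k_lo > 0:
            # secant step in log k against PWV
            u = math.log(k_lo) + (targets.pwv_target - p_lo) * \
                (math.log(k_hi) - math.log(k_lo)) / (p_hi - p_lo)
            k_mid = math.exp(min(max(u, math.log(lo) if lo > 0 else u),
                                 math.log(k_hi)))
            if not (k_lo < k_mid < k_hi):
                k_mid = math.sqrt(max(k_lo, lo) * k_hi)
        else:
            k_mid = math.sqrt(max(k_lo, lo) * k_hi)
        p_mid, ep_mid = f(k_mid)
        if abs(p_mid - targets.pwv_target) < abs(best[1] - targets.pwv_target):
            best = (k_mid, p_mid, ep_mid)
        if p_mid < targets.pwv_target:
            k_lo, p_lo = k_mid, p_mid
        else:
            k_hi, p_hi = k_mid, p_mid

    k_fin, pwv_fin, ep_fin = best
    smap = make_map(k_fin)
    state.k_s = dict(smap.k_s)
    state.ep = dict(smap.ep)
    state.ep_computed = ep_fin
    state.pwv = pwv_fin
    state.converged = abs(pwv_fin - targets.pwv_target) <= targets.pwv_tol
    # self-consistency: EP recovered from displacement vs the anchor
    for region, anchor in state.ep.items():
        got = ep_fin.get(region)
        if got is not None and abs(got - anchor) > targets.ep_tol:
            log.warning("EP self-consistency residual at %s: %.2f vs %.2f mmHg",
                        region, got / MMHG, anchor / MMHG)
    if not state.converged:
        log.warning("support loop not converged: PWV %.2f vs target %.2f "
                    "after %d iterations", pwv_fin, targets.pwv_target,
                    state.iterations)
    return state


# --------------------------------------------------------------------------
# damping selection


def high_frequency_fraction(probe, f_cut: float = 20.0) -> float:
    """Fraction of pulsatile pressure energy above ``f_cut`` Hz."""
    from .metrics import _window

    w = _window(probe)
    p = probe.pressure[w]
    t = probe.time[w]
    p = p - p.mean()
    spec = np.abs(np.fft.rfft(p)) ** 2
    freq = np.fft.rfftfreq(len(p), d=float(t[1] - t[0]))
    total = spec[1:].sum()
    if total == 0:
        return 0.0
    return float(spec[freq > f_cut].sum() / total)


def choose_damping(evaluate_probe, seed: float = 25.0, cap: float = 6400.0,
                   threshold: float = 0.01, f_cut: float = 20.0) -> float:
    """Smallest support damping c_s whose waveforms keep less than
    ``threshold`` of their pulsatile energy above ``f_cut`` Hz.

    ``evaluate_probe(c_s) -> iterable of probes`` runs the model at the
    given damping.  Doubling search from ``seed``; returns ``cap`` with a
    warning if even the cap fails the criterion.
    """
    c = seed
    while c <= cap:
        frac = max(high_frequency_fraction(p, f_cut) for p in evaluate_probe(c))
        log.info("damping search: c_s = %g -> HF fraction %.4f", c, frac)
        if frac < threshold:
            return c
        c *= 2.0
    log.warning("damping search cap reached (c_s = %g)", cap)
    return cap
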