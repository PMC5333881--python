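"""Distributed 1D blood-flow solver over the arterial tree.

Reduced-order analogue of a 3D fluid-structure-interaction model: each
vessel is a 1D compliant tube governed by

    dA/dt + dQ/dx = 0
    dQ/dt + d(Q^2/A)/dx + (A/rho) dP/dx = -K_R Q/A,      K_R = 8 pi mu / rho

closed by the linearized tube law with external viscoelastic support,

    P = P_ref + (A - A_ref)/(dA/dP) + Gamma dA/dt,       Gamma = c_s/(2 pi R),

where dA/dP = 2 pi R / (K_tt h/R^2 + k_s).  The support damping c_s enters
as a Kelvin-Voigt wall term (a Q-diffusion in the momentum equation) that
suppresses node-scale oscillations without altering the propagation speed.

Discretization is a second-order Richtmyer (two-step Lax-Wendroff) scheme
with CFL-limited time step.  Boundaries are treated by linearized
characteristics: prescribed inflow at the root, static-pressure-continuity
junction coupling (mass conserved exactly by construction), and implicit
three-element Windkessel (RCR) models at the fifteen terminal outlets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import AortoTree
from .inflow import InflowSpec, inflow_value
from .units import MMHG
from .wall import BLOOD_DENSITY, BLOOD_VISCOSITY, LinearizedWall

log = logging.getLogger(__name__)


class AssemblyError(ValueError):
    pass


class CFLError(RuntimeError):
    pass


@dataclass
class WindkesselBC:
    """Three-element (R_prox, C, R_dist) Windkessel outlet."""

    r_prox: float          # [Pa s/m^3]
    r_dist: float          # [Pa s/m^3]
    compliance: float      # [m^3/Pa]
    p_out: float = 0.0     # distal (venous) reference pressure [Pa]
    p_c: float = 0.0       # capacitor pressure state [Pa]

    def __post_init__(self):
        if self.r_prox <= 0 or self.r_dist <= 0 or self.compliance <= 0:
            raise ValueError("Windkessel parameters must be > 0")


#: external-support region boundaries on the aortic axis
SUPPORT_BOUNDS = {"ATA": (0.0, 0.25), "DTA": (0.25, 0.66), "IAA": (0.66, float("inf"))}


@dataclass
class SupportMap:
    """Piecewise-constant external tissue support per aortic region.

    ``k_s`` [Pa/m] and ``c_s`` [Pa s/m] per region; ``ep`` is the external
    pressure the support is anchored to carry at the reference (MAP) state.
    Upper branches inherit the ATA values, lower branches (and iliacs) the
    IAA values.
    """

    k_s: dict[str, float] = field(default_factory=lambda: {"ATA": 0.0, "DTA": 0.0, "IAA": 0.0})
    c_s: dict[str, float] = field(default_factory=lambda: {"ATA": 0.0, "DTA": 0.0, "IAA": 0.0})
    ep: dict[str, float] = field(default_factory=lambda: {"ATA": 0.0, "DTA": 0.0, "IAA": 0.0})

    def region_of_s(self, s: float) -> str:
        for name, (a, b) in SUPPORT_BOUNDS.items():
            if a <= s < b or (name == "IAA" and s >= a):
                return name
        raise KeyError(f"no support region covers s = {s}")

    def region_of_segment(self, seg) -> str:
        if seg.is_aortic:
            return self.region_of_s(0.5 * (seg.s_range[0] + seg.s_range[1]))
        if seg.attach_s is None:
            raise KeyError(f"segment {seg.name} has no aortic anchor")
        return "ATA" if seg.attach_s < SUPPORT_BOUNDS["ATA"][1] else "IAA"

    def lookup(self, seg, s: float | None = None) -> tuple[float, float, float]:
        region = (self.region_of_s(s) if (s is not None and seg.is_aortic)
                  else self.region_of_segment(seg))
        return self.k_s[region], self.c_s[region], self.ep[region]


@dataclass
class SolverConfig:
    dx: float = 0.0075             # target node spacing [m]
    cfl: float = 0.8
    min_cycles: int = 6
    max_cycles: int = 12
    periodicity_tol: float = 50.0  # max cycle-to-cycle pressure change [Pa]
    samples_per_cycle: int = 1000
    advective_margin: float = 2.0  # added to c in the CFL bound [m/s]
    rho: float = BLOOD_DENSITY
    mu: float = BLOOD_VISCOSITY


@dataclass
class WaveformProbe:
    """Pressure/flow/area time series at one station over the final
    converged cycles (two periods are retained so that every station's
    systolic upstroke lies inside the window)."""

    label: str
    s: float | None
    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    area: np.ndarray
    period: float
    k_s: float = 0.0
    ep_anchor: float = 0.0
    r_ref: float = 0.0

    @property
    def n_periods(self) -> float:
        return (self.time[-1] - self.time[0]) / self.period

    def radius(self) -> np.ndarray:
        return np.sqrt(self.area / np.pi)


def external_pressure(probe: WaveformProbe, k_s: float | None = None) -> float:
    """External pressure carried by the perivascular support at a station [Pa].

    EP = EP_anchor + k_s * (time-averaged radius - reference radius): the
    support is anchored to carry ``ep_anchor`` at the reference (MAP) radius,
    so the time-averaged radial displacement measures the offset actually
    realized by the converged simulation.  With k_s = 0 the support carries
    nothing; in the rigid limit it carries the full local mean pressure.
    """
    ks = probe.k_s if k_s is None else k_s
    if ks == 0.0:
        return 0.0
    return probe.ep_anchor + ks * (float(np.mean(probe.radius())) - probe.r_ref)


@dataclass
class _MeshSegment:
    name: str
    i0: int
    n: int
    dx: float


class Model:
    """Assembled discrete model ready to time-step."""

    def __init__(self, tree: AortoTree, walls: dict[str, tuple[LinearizedWall, LinearizedWall]],
                 support: SupportMap, outlets: dict[str, WindkesselBC],
                 inflow: InflowSpec, config: SolverConfig | None = None,
                 p_ref: float | None = None):
        self.tree = tree
        self.support = support
        self.inflow = inflow
        self.config = config or SolverConfig()
        self._p_ref_override = p_ref
        self._assemble(walls, outlets)

    # ------------------------------------------------------------------
    def _assemble(self, walls, outlets):
        cfg = self.config
        tree = self.tree
        for t in tree.terminals:
            oid = tree.segments[t].outlet_id
            if oid is None:
                raise AssemblyError(f"terminal segment {t} has no outlet id")
            if oid not in outlets:
                raise AssemblyError(f"no Windkessel model for outlet {oid!r}")

        order = list(_dfs_order(tree))
        self.mesh: list[_MeshSegment] = []
        a_ref, dadp, p_ref, gamma, ks_node, ep_node = [], [], [], [], [], []
        i0 = 0
        self._seg_index: dict[str, _MeshSegment] = {}
        from .tables import WallTable
        table = WallTable()
        for name in order:
            seg = tree.segments[name]
            wp, wd = walls[name]
            n = max(3, int(round(seg.length / cfg.dx)) + 1)
            dx = seg.length / (n - 1)
            ms = _MeshSegment(name, i0, n, dx)
            self.mesh.append(ms)
            self._seg_index[name] = ms
            xi = np.linspace(0.0, 1.0, n)
            r = wp.radius + (wd.radius - wp.radius) * xi
            ktt = wp.k_tt + (wd.k_tt - wp.k_tt) * xi
            h = wp.thickness + (wd.thickness - wp.thickness) * xi
            if seg.is_aortic:
                s_nodes = seg.s_range[0] + (seg.s_range[1] - seg.s_range[0]) * xi
                if self._p_ref_override is not None:
                    pref = np.full(n, float(self._p_ref_override))
                else:
                    pref = table.map_pressure(tree.age, np.minimum(s_nodes, 1.0))
                kcs = np.array([self.support.lookup(seg, s) for s in s_nodes])
            else:
                if self._p_ref_override is not None:
                    pref = np.full(n, float(self._p_ref_override))
                else:
                    pref = np.full(n, float(table.map_pressure(tree.age, min(seg.attach_s, 1.0))))
                kcs = np.tile(np.array(self.support.lookup(seg)), (n, 1))
            ks, cs, ep = kcs[:, 0], kcs[:, 1], kcs[:, 2]
            stiff = ktt * h / r ** 2 + ks
            a_ref.append(np.pi * r ** 2)
            dadp.append(2.0 * np.pi * r / stiff)
            p_ref.append(pref)
            gamma.append(cs / (2.0 * np.pi * r))
            ks_node.append(ks)
            ep_node.append(ep)
            i0 += n

        self.n_nodes = i0
        self.a_ref = np.concatenate(a_ref)
        self.dadp = np.concatenate(dadp)
        self.inv_dadp = 1.0 / self.dadp
        self.p_ref = np.concatenate(p_ref)
        self.gamma = np.concatenate(gamma)
        self.ks_node = np.concatenate(ks_node)
        self.ep_node = np.concatenate(ep_node)
        self.r_ref = np.sqrt(self.a_ref / np.pi)
        self.c_ref = np.sqrt(self.a_ref / (cfg.rho * self.dadp))
        self.z_ref = cfg.rho * self.c_ref / self.a_ref
        self.k_fric = 8.0 * np.pi * cfg.mu / cfg.rho   # [m^2/s]

        # pair (half-node) index arrays within segments
        L, R, dxp = [], [], []
        int_idx, pairL, pairR, dx_int = [], [], [], []
        jpos = 0
        for ms in self.mesh:
            idx = np.arange(ms.i0, ms.i0 + ms.n)
            L.append(idx[:-1]); R.append(idx[1:])
            dxp.append(np.full(ms.n - 1, ms.dx))
            if ms.n > 2:
                ii = idx[1:-1]
                int_idx.append(ii)
                pairL.append(np.arange(jpos, jpos + ms.n - 2))
                pairR.append(np.arange(jpos + 1, jpos + ms.n - 1))
                dx_int.append(np.full(ms.n - 2, ms.dx))
            jpos += ms.n - 1
        self.L = np.concatenate(L); self.R = np.concatenate(R)
        self.dxp = np.concatenate(dxp)
        self.int_idx = np.concatenate(int_idx)
        self.pairL = np.concatenate(pairL); self.pairR = np.concatenate(pairR)
        self.dx_int = np.concatenate(dx_int)
        # half-node reference properties
        self.a_ref_h = 0.5 * (self.a_ref[self.L] + self.a_ref[self.R])
        self.inv_dadp_h = 0.5 * (self.inv_dadp[self.L] + self.inv_dadp[self.R])
        self.p_ref_h = 0.5 * (self.p_ref[self.L] + self.p_ref[self.R])
        self.gamma_h = 0.5 * (self.gamma[self.L] + self.gamma[self.R])

        # junctions: every non-terminal segment end
        self.junctions: list[tuple[int, list[int]]] = []
        for name in order:
            kids = tree.children.get(name, [])
            if not kids:
                continue
            p_end = self._seg_index[name].i0 + self._seg_index[name].n - 1
            c_starts = [self._seg_index[k].i0 for k in kids]
            self.junctions.append((p_end, c_starts))

        # outlets
        self.outlets: list[tuple[int, WindkesselBC, str]] = []
        for t in tree.terminals:
            ms = self._seg_index[t]
            oid = tree.segments[t].outlet_id
            self.outlets.append((ms.i0 + ms.n - 1, outlets[oid], oid))

        # time step
        cmax_bound = (self.c_ref + cfg.advective_margin)
        dt_wave = cfg.cfl * np.min(self.dxp / np.maximum(
            cmax_bound[self.L], cmax_bound[self.R]))
        visc = self.a_ref * self.gamma / cfg.rho
        dt_visc = np.inf
        if np.any(visc > 0):
            dmin = min(ms.dx for ms in self.mesh)
            dt_visc = 0.4 * dmin ** 2 / visc.max()
        dt = min(dt_wave, dt_visc)
        T = self.inflow.period
        self.n_steps = int(math.ceil(T / dt))
        self.dt = T / self.n_steps
        if self.dt > dt_wave:
            raise CFLError(f"dt {self.dt} exceeds CFL bound {dt_wave}")
        self.rec_stride = max(1, self.n_steps // cfg.samples_per_cycle)

        # local Courant numbers nu = c dt / dx at every boundary node: the
        # characteristic foot is interpolated a fraction nu into the cell,
        # so boundary coupling propagates information at the physical speed
        dx_of = {}
        for ms in self.mesh:
            for i in (ms.i0, ms.i0 + ms.n - 1):
                dx_of[i] = ms.dx
        self._nu = {i: float(self.c_ref[i]) * self.dt / dx for i, dx in dx_of.items()}
        self.reset()

    # ------------------------------------------------------------------
    def reset(self, p_init: float | None = None):
        """Initialize at a uniform (or MAP-profile) pressure, zero flow,
        Windkessel capacitors at their steady 0D estimate."""
        if p_init is None:
            self.P0 = self.p_ref.copy()
        else:
            self.P0 = np.full(self.n_nodes, float(p_init))
        self.A = self.a_ref + (self.P0 - self.p_ref) * self.dadp
        self.Q = np.zeros(self.n_nodes)
        self.t = 0.0
        for i, bc, _ in self.outlets:
            p_here = self.P0[i]
            q0 = (p_here - bc.p_out) / (bc.r_prox + bc.r_dist)
            bc.p_c = p_here - bc.r_prox * q0

    def pressure(self) -> np.ndarray:
        return self.p_ref + (self.A - self.a_ref) * self.inv_dadp

    def node_at_s(self, s: float) -> int:
        """Mesh node nearest to aortic coordinate s (canonical iliac side)."""
        path = self.tree.aortic_path
        s = min(max(s, 0.0), self.tree.s_max)
        for name in path:
            seg = self.tree.segments[name]
            s0, s1 = seg.s_range
            if s <= s1 + 1e-12:
                ms = self._seg_index[name]
                xi = (s - s0) / (s1 - s0)
                return ms.i0 + int(round(min(max(xi, 0.0), 1.0) * (ms.n - 1)))
        raise KeyError(f"s = {s} outside tree")

    def node_in_segment(self, name: str, frac: float = 0.5) -> int:
        ms = self._seg_index[name]
        return ms.i0 + int(round(min(max(frac, 0.0), 1.0) * (ms.n - 1)))

    # ------------------------------------------------------------------
    def _step(self, q_in_next: float):
        dt, rho = self.dt, self.config.rho
        A, Q = self.A, self.Q
        L, R = self.L, self.R
        P = self.p_ref + (A - self.a_ref) * self.inv_dadp

        # boundary characteristic invariants from the time-n state: the
        # outgoing invariant is sampled at the characteristic foot, a
        # fraction nu = c dt/dx inside the domain
        nu = self._nu
        Z = self.z_ref

        def w_out(i_b: int, i_in: int, sign: float) -> float:
            f = nu[i_b]
            p_f = (1.0 - f) * P[i_b] + f * P[i_in]
            q_f = (1.0 - f) * Q[i_b] + f * Q[i_in]
            return p_f + sign * Z[i_b] * q_f

        w_inlet = w_out(0, 1, -1.0)
        w_junc = []
        for p_end, c_starts in self.junctions:
            wp = w_out(p_end, p_end - 1, +1.0)
            wcs = [w_out(c, c + 1, -1.0) for c in c_starts]
            w_junc.append((wp, wcs))
        w_outlet = [w_out(e, e - 1, +1.0) for e, _, _ in self.outlets]

        AL, AR = A[L], A[R]
        QL, QR = Q[L], Q[R]
        F2L = QL * QL / AL
        F2R = QR * QR / AR
        Am = 0.5 * (AL + AR)
        Qm = 0.5 * (QL + QR)
        gradP = (P[R] - P[L]) / self.dxp
        hdt = 0.5 * dt
        Ah = Am - hdt * (QR - QL) / self.dxp
        Qh = (Qm - hdt * (F2R - F2L) / self.dxp
              - hdt * (Am / rho) * gradP
              - hdt * self.k_fric * Qm / Am)
        Ph = self.p_ref_h + (Ah - self.a_ref_h) * self.inv_dadp_h
        F2h = Qh * Qh / Ah

        i, l, r = self.int_idx, self.pairL, self.pairR
        Ai = A[i]
        Qi = Q[i]
        A[i] = Ai - dt * (Qh[r] - Qh[l]) / self.dx_int
        Q[i] = (Qi - dt * (F2h[r] - F2h[l]) / self.dx_int
                - dt * (Ai / rho) * (Ph[r] - Ph[l]) / self.dx_int
                - dt * self.k_fric * Qi / Ai)

        # Kelvin-Voigt wall viscosity: Q-diffusion
        if self.gamma.any():
            G = self.gamma_h * (Q[R] - Q[L]) / self.dxp
            Q[i] += dt * (A[i] / rho) * (G[r] - G[l]) / self.dx_int

        # --- boundaries (linearized characteristics) ---
        pref, aref, dadp = self.p_ref, self.a_ref, self.dadp

        # inlet: prescribed flow + backward invariant
        Q[0] = q_in_next
        p0 = w_inlet + Z[0] * q_in_next
        A[0] = aref[0] + (p0 - pref[0]) * dadp[0]

        # junctions: common static pressure, exact mass balance
        for (p_end, c_starts), (wp, wcs) in zip(self.junctions, w_junc):
            zp = Z[p_end]
            num = wp / zp
            den = 1.0 / zp
            for c, wc in zip(c_starts, wcs):
                num += wc / Z[c]
                den += 1.0 / Z[c]
            p_star = num / den
            Q[p_end] = (wp - p_star) / zp
            A[p_end] = aref[p_end] + (p_star - pref[p_end]) * dadp[p_end]
            for c, wc in zip(c_starts, wcs):
                Q[c] = (p_star - wc) / Z[c]
                A[c] = aref[c] + (p_star - pref[c]) * dadp[c]

        # outlets: Crank-Nicolson RCR capacitor update (second order)
        for (e, bc, _), w in zip(self.outlets, w_outlet):
            z = Z[e]
            zr = z + bc.r_prox
            h = 0.5 * dt / bc.compliance
            a_coef = 1.0 + h * (1.0 / zr + 1.0 / bc.r_dist)
            b_coef = bc.p_c + h * (Q[e] + w / zr
                                   + (2.0 * bc.p_out - bc.p_c) / bc.r_dist)
            bc.p_c = b_coef / a_coef
            q = (w - bc.p_c) / zr
            Q[e] = q
            p = w - z * q
            A[e] = aref[e] + (p - pref[e]) * dadp[e]

        self.t += dt

    # ------------------------------------------------------------------
    def run_until_periodic(self, stations: list[tuple[str, float | None, int]] | None = None,
                           ) -> dict[str, WaveformProbe]:
        """Run cardiac cycles until node pressures repeat cycle-to-cycle,
        then return probes covering the final two cycles.

        ``stations``: list of (label, s_or_None, node_index).  Defaults to
        the root node.
        """
        cfg = self.config
        T = self.inflow.period
        if stations is None:
            stations = [("root", 0.0, 0)]
        nodes = np.array([n for _, _, n in stations])

        q_in = inflow_value(self.inflow,
                            self.dt * np.arange(1, self.n_steps + 1))
        n_rec = self.n_steps // self.rec_stride
        prev_rec = None
        hist: list[dict[str, np.ndarray]] = []
        converged = False
        residual = np.inf
        for cycle in range(cfg.max_cycles):
            recP = np.empty((n_rec, len(nodes)))
            recQ = np.empty((n_rec, len(nodes)))
            recA = np.empty((n_rec, len(nodes)))
            rec_t = np.empty(n_rec)
            k = 0
            for step in range(self.n_steps):
                self._step(q_in[step])
                if (step + 1) % self.rec_stride == 0 and k < n_rec:
                    P = self.p_ref[nodes] + (self.A[nodes] - self.a_ref[nodes]) * self.inv_dadp[nodes]
                    recP[k] = P
                    recQ[k] = self.Q[nodes]
                    recA[k] = self.A[nodes]
                    rec_t[k] = self.t
                    k += 1
            hist.append({"P": recP, "Q": recQ, "A": recA, "t": rec_t})
            if len(hist) > 2:
                hist.pop(0)
            if prev_rec is not None:
                residual = float(np.max(np.abs(recP - prev_rec)))
                log.info("cycle %d: periodicity residual %.2f Pa (%.3f mmHg)",
                         cycle + 1, residual, residual / MMHG)
                if cycle + 1 >= cfg.min_cycles and residual < cfg.periodicity_tol:
                    converged = True
                    if len(hist) == 2:
                        break
            prev_rec = recP
        if not converged:
            log.warning("periodicity not reached in %d cycles (residual %.1f Pa)",
                        cfg.max_cycles, residual)
        self.last_residual = residual

        t = np.concatenate([h["t"] for h in hist])
        probes = {}
        for j, (label, s, n) in enumerate(stations):
            probes[label] = WaveformProbe(
                label=label, s=s,
                time=t,
                pressure=np.concatenate([h["P"][:, j] for h in hist]),
                flow=np.concatenate([h["Q"][:, j] for h in hist]),
                area=np.concatenate([h["A"][:, j] for h in hist]),
                period=T,
                k_s=float(self.ks_node[n]),
                ep_anchor=float(self.ep_node[n]),
                r_ref=float(self.r_ref[n]))
        return probes

    # ------------------------------------------------------------------
    def mean_flow_balance(self, probes_in: WaveformProbe | None = None) -> tuple[float, float]:
        """(mean inflow, sum of outlet mean flows) over the last run's final
        cycle, from the current state onward -- evaluated by one extra cycle
        of bookkeeping."""
        T = self.inflow.period
        q_in = inflow_value(self.inflow, self.dt * np.arange(1, self.n_steps + 1))
        out_idx = np.array([e for e, _, _ in self.outlets])
        acc_out = np.zeros(len(out_idx))
        acc_in = 0.0
        for step in range(self.n_steps):
            self._step(q_in[step])
            acc_in += q_in[step]
            acc_out += self.Q[out_idx]
        return acc_in / self.n_steps, float(acc_out.sum() / self.n_steps)


def _dfs_order(tree: AortoTree):
    stack = [tree.root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(tree.children.get(n, [])))


def assemble(tree: AortoTree, walls, support: SupportMap,
             outlets: dict[str, WindkesselBC], inflow: InflowSpec,
             config: SolverConfig | None = None) -> Model:
    """Build a ready-to-step discrete model (thin wrapper over Model)."""
    return Model(tree, walls, support, outlets, inflow, config)
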