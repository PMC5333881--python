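"""1D pulse-wave solver: equilibria, oracles, junctions, supports."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import aortaflow.metrics as mx
from aortaflow.geometry import AortoTree, VesselSegment
from aortaflow.inflow import InflowSpec
from aortaflow.solver import (AssemblyError, Model, SolverConfig, SupportMap,
                              WindkesselBC, external_pressure)
from aortaflow.units import L_PER_MIN, MMHG
from aortaflow.wall import BLOOD_DENSITY, BLOOD_VISCOSITY, LinearizedWall, tube_law

from conftest import (STD_WALL, make_bifurcation_tree, make_tube_tree,
                      matched_outlet, tube_model)


@pytest.fixture
def wall():
    return LinearizedWall(**STD_WALL)


def test_missing_outlet_raises_naming_terminal(wall):
    tree = make_tube_tree()
    with pytest.raises(AssemblyError, match="out"):
        Model(tree, {"t0": (wall, wall)}, SupportMap(), {},
              InflowSpec(), SolverConfig())


def test_zero_inflow_uniform_pressure_is_time_invariant(wall):
    m = tube_model(wall, inflow=InflowSpec(mean_flow=0.0), p_ref=9000.0)
    bc = m.outlets[0][1]
    # whole system in equilibrium at 9 kPa (distal reference included)
    bc.p_out = 9000.0
    bc.p_c = 9000.0
    m.reset(p_init=9000.0)
    a0 = m.A.copy()
    for _ in range(500):
        m._step(0.0)
    assert np.allclose(m.A, a0, rtol=1e-12)
    assert np.max(np.abs(m.Q)) < 1e-12


def test_constant_inflow_single_rcr_reaches_steady_zero_d_limit(wall):
    q0 = 4.0 * L_PER_MIN
    m = tube_model(wall, mean_flow=q0)
    rp, rd = m.outlets[0][1].r_prox, m.outlets[0][1].r_dist
    for _ in range(6 * m.n_steps):
        m._step(q0)
    p_in = m.pressure()[0]
    expect = (rp + rd) * q0
    # inlet pressure additionally carries the Poiseuille drop
    assert p_in == pytest.approx(expect, rel=0.02)
    assert m.Q[-1] == pytest.approx(q0, rel=1e-3)


def test_steady_pressure_gradient_matches_poiseuille(wall):
    q0 = 4.0 * L_PER_MIN
    m = tube_model(wall, mean_flow=q0)
    for _ in range(6 * m.n_steps):
        m._step(q0)
    p = m.pressure()
    ms = m.mesh[0]
    i, j = ms.n // 4, 3 * ms.n // 4
    grad = (p[j] - p[i]) / ((j - i) * ms.dx)
    expect = -8.0 * BLOOD_VISCOSITY * q0 / (np.pi * wall.radius ** 4)
    assert grad == pytest.approx(expect, rel=0.01)


def test_outlet_pressure_matches_rcr_ode_oracle(wall):
    """Single vessel + single RCR: outlet pressure must match the exact
    periodic 0D solution C dPc/dt = Q - Pc/Rd driven by the outlet flow."""
    m = tube_model(wall, config=SolverConfig(min_cycles=6, max_cycles=14))
    probes = m.run_until_periodic([("out", 1.0, m.n_nodes - 1)])
    p = probes["out"]
    bc = m.outlets[0][1]

    def rhs(tt, y):
        return (np.interp(tt, p.time, p.flow) - y[0] / bc.r_dist) / bc.compliance

    y0 = [float(p.pressure[0] - bc.r_prox * p.flow[0])]
    sol = solve_ivp(rhs, (p.time[0], p.time[-1]), y0, t_eval=p.time,
                    rtol=1e-9, atol=0.1)
    oracle = sol.y[0] + bc.r_prox * p.flow
    err = np.max(np.abs(oracle - p.pressure)) / (p.pressure.max() - p.pressure.min())
    assert err < 0.01


def test_pulse_travels_at_tube_law_wave_speed(wall):
    """Low-amplitude pulse on a uniform matched tube: foot-to-foot speed
    equals the closed-form tube-law speed within 2%."""
    c_th = tube_law(wall).wave_speed
    m = tube_model(wall, mean_flow=1.0 * L_PER_MIN, r_dist=6.0e8,
                   compliance=3e-9,
                   config=SolverConfig(min_cycles=5, max_cycles=12))
    probes = m.run_until_periodic([("a", 0.25, m.node_at_s(0.25)),
                                   ("b", 0.75, m.node_at_s(0.75))])
    v = mx.pwv(probes["a"], probes["b"], 0.5)
    assert v == pytest.approx(c_th, rel=0.02)


def _bifurcation_model(wall, r_child=None, **kw):
    tree = make_bifurcation_tree(r_child=r_child)
    child_wall = LinearizedWall(
        k_tt=wall.k_tt, k_zz=wall.k_zz,
        thickness=wall.thickness * tree.segments["c1"].radius_prox / wall.radius,
        radius=tree.segments["c1"].radius_prox)
    walls = {"p": (wall, wall), "c1": (child_wall, child_wall),
             "c2": (child_wall, child_wall)}
    bc1 = matched_outlet(child_wall)
    bc2 = matched_outlet(child_wall)
    inflow = InflowSpec(mean_flow=kw.pop("mean_flow", 4.0 * L_PER_MIN),
                        heart_rate=60, reverse_fraction=0.0)
    p_ref = (bc1.r_prox + bc1.r_dist) / 2.0 * inflow.mean_flow
    return Model(tree, walls, SupportMap(), {"o1": bc1, "o2": bc2}, inflow,
                 SolverConfig(min_cycles=4, max_cycles=10), p_ref=p_ref)


def test_symmetric_bifurcation_splits_flow_equally(wall):
    m = _bifurcation_model(wall)
    q_in = 4.0 * L_PER_MIN
    for _ in range(2 * m.n_steps):
        m._step(q_in)
    e1, e2 = m.outlets[0][0], m.outlets[1][0]
    assert m.Q[e1] == pytest.approx(m.Q[e2], rel=1e-10)


def test_junction_conserves_mass_to_machine_precision(wall):
    m = _bifurcation_model(wall)
    q_in = 4.0 * L_PER_MIN
    p_end, c_starts = m.junctions[0]
    for _ in range(200):
        m._step(q_in)
        q_p = m.Q[p_end]
        q_c = sum(m.Q[c] for c in c_starts)
        assert q_c == pytest.approx(q_p, rel=1e-12, abs=1e-18)


def test_area_matched_junction_is_nearly_reflectionless(wall):
    """Impedance-matched bifurcation: the reflected fraction of a narrow
    incident pulse stays below 2%."""
    # short pulse (80 ms) on a long parent so incident and reflected
    # pulses separate in time at the mid-parent probe
    tree = make_bifurcation_tree(parent_len=2.0, child_len=1.5)
    child_wall = LinearizedWall(
        k_tt=wall.k_tt, k_zz=wall.k_zz,
        thickness=wall.thickness * tree.segments["c1"].radius_prox / wall.radius,
        radius=tree.segments["c1"].radius_prox)
    walls = {"p": (wall, wall), "c1": (child_wall, child_wall),
             "c2": (child_wall, child_wall)}
    bcs = {"o1": matched_outlet(child_wall), "o2": matched_outlet(child_wall)}
    inflow = InflowSpec(mean_flow=0.3 * L_PER_MIN, heart_rate=20,
                        systolic_fraction=0.027, peak_time_fraction=0.5,
                        reverse_fraction=0.0)
    # start at the true steady operating point so the only transient in the
    # record is the pulse itself
    p_op = 0.5 * (bcs["o1"].r_prox + bcs["o1"].r_dist) * inflow.mean_flow
    m = Model(tree, walls, SupportMap(), bcs, inflow,
              SolverConfig(min_cycles=1, max_cycles=1), p_ref=p_op)
    probes = m.run_until_periodic([("mid", 0.5, m.node_at_s(0.5))])
    p = probes["mid"].pressure - p_op
    t = probes["mid"].time - probes["mid"].time[0]
    c = tube_law(wall).wave_speed
    t_pass = 1.0 / c          # incident pulse reaches mid-parent
    t_return = 3.0 / c        # junction echo back at mid-parent
    incident = np.abs(p[(t > t_pass - 0.15) & (t < t_pass + 0.2)]).max()
    echo_win = (t > t_return - 0.05) & (t < t_return + 0.3)
    echo = np.abs(p[echo_win]).max()
    assert echo / incident < 0.02


def test_mass_balance_over_converged_cycle(wall):
    m = _bifurcation_model(wall)
    m.run_until_periodic([("root", 0.0, 0)])
    q_in, q_out = m.mean_flow_balance()
    assert q_out == pytest.approx(q_in, rel=0.005)


def test_mesh_refinement_changes_pulse_pressure_below_one_percent(wall):
    pps = []
    for dx in (0.02, 0.01):
        m = tube_model(wall, config=SolverConfig(dx=dx, min_cycles=5, max_cycles=12))
        probes = m.run_until_periodic([("root", 0.0, 0)])
        pps.append(mx.pulse_pressure(probes["root"]))
    assert abs(pps[1] - pps[0]) / pps[1] < 0.01


def test_doubling_wall_stiffness_raises_measured_pwv(wall):
    speeds = []
    for factor in (1.0, 2.0):
        w = LinearizedWall(k_tt=factor * wall.k_tt, k_zz=wall.k_zz,
                           thickness=wall.thickness, radius=wall.radius)
        m = tube_model(w, config=SolverConfig(min_cycles=4, max_cycles=10))
        probes = m.run_until_periodic([("a", 0.25, m.node_at_s(0.25)),
                                       ("b", 0.75, m.node_at_s(0.75))])
        speeds.append(mx.pwv(probes["a"], probes["b"], 0.5))
    assert speeds[1] > speeds[0] * 1.2


# -- external support ------------------------------------------------------


def test_support_region_lookup_matches_boundaries():
    smap = SupportMap(k_s={"ATA": 1.0, "DTA": 2.0, "IAA": 3.0})
    assert smap.region_of_s(0.1) == "ATA"
    assert smap.region_of_s(0.3) == "DTA"
    assert smap.region_of_s(0.7) == "IAA"
    assert smap.region_of_s(1.2) == "IAA"


def test_branches_inherit_support_by_attachment():
    smap = SupportMap()
    upper = VesselSegment("x", "branch", 0.1, 1e-3, 1e-3, attach_s=0.19)
    lower = VesselSegment("y", "branch", 0.1, 1e-3, 1e-3, attach_s=0.70)
    assert smap.region_of_segment(upper) == "ATA"
    assert smap.region_of_segment(lower) == "IAA"


def test_zero_support_gives_zero_external_pressure(wall):
    m = tube_model(wall, config=SolverConfig(min_cycles=4, max_cycles=8))
    probes = m.run_until_periodic([("mid", 0.5, m.node_at_s(0.5))])
    assert external_pressure(probes["mid"]) == 0.0


def test_external_pressure_recovers_anchor_at_reference_state(wall):
    """With the support anchored to carry a given EP at the reference
    radius, a simulation whose mean pressure sits at the reference must
    recover that EP from the displacement field."""
    ep_anchor = 5.0 * MMHG
    smap = SupportMap(k_s={r: 2e6 for r in ("ATA", "DTA", "IAA")},
                      c_s={r: 100.0 for r in ("ATA", "DTA", "IAA")},
                      ep={r: ep_anchor for r in ("ATA", "DTA", "IAA")})
    m = tube_model(wall, support=smap,
                   config=SolverConfig(min_cycles=5, max_cycles=10))
    probes = m.run_until_periodic([("mid", 0.5, m.node_at_s(0.5))])
    ep = external_pressure(probes["mid"])
    assert ep == pytest.approx(ep_anchor, abs=0.5 * MMHG)


def test_support_raises_wave_speed_and_ep_tracks_mean_pressure_offset(wall):
    """Raising the operating pressure above the anchor raises the computed
    EP above the anchor (the support carries the extra load)."""
    smap = SupportMap(k_s={r: 2e6 for r in ("ATA", "DTA", "IAA")},
                      c_s={r: 100.0 for r in ("ATA", "DTA", "IAA")},
                      ep={r: 0.0 for r in ("ATA", "DTA", "IAA")})
    eps = []
    for rd in (1.0e8, 1.4e8):
        m = tube_model(wall, support=smap, r_dist=rd,
                       config=SolverConfig(min_cycles=5, max_cycles=10),
                       p_ref=9000.0)
        probes = m.run_until_periodic([("mid", 0.5, m.node_at_s(0.5))])
        eps.append(external_pressure(probes["mid"]))
    assert eps[1] > eps[0]


def test_periodicity_residual_below_tolerance(wall):
    cfg = SolverConfig(min_cycles=5, max_cycles=14, periodicity_tol=20.0)
    m = tube_model(wall, config=cfg)
    m.run_until_periodic([("root", 0.0, 0)])
    assert m.last_residual < cfg.periodicity_tol
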