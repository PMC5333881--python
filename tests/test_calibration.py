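"""Calibration loops: Windkessel scaling, support tuning, damping search."""

import numpy as np
import pytest

from aortaflow.calibration import (CalibrationTargets, choose_damping,
                                   flow_splits, high_frequency_fraction,
                                   predicted_map, tune_external_support,
                                   tune_windkessel)
from aortaflow.solver import WaveformProbe, WindkesselBC
from aortaflow.tables import WindkesselTable
from aortaflow.units import L_PER_MIN, MMHG


def outlets_40():
    from aortaflow.pipeline import make_outlets

    return make_outlets(40)


Q_MEAN = 5.79 * L_PER_MIN


def test_identity_when_target_equals_current_prediction():
    outl = outlets_40()
    current = predicted_map(outl, Q_MEAN)
    tuned, scale = tune_windkessel(outl, current, Q_MEAN)
    assert scale == pytest.approx(1.0, abs=1e-9)


def test_scaling_reproduces_target_map_by_zero_d_algebra():
    outl = outlets_40()
    target = 2.0 * predicted_map(outl, Q_MEAN)
    tuned, scale = tune_windkessel(outl, target, Q_MEAN)
    assert scale > 1.0
    assert predicted_map(tuned, Q_MEAN) == pytest.approx(target, abs=0.1 * MMHG)


def test_distal_resistance_rises_with_aging_map_targets():
    scales = {}
    for age, map_t in ((60, 95.0), (75, 102.0)):
        from aortaflow.pipeline import make_outlets

        _, s = tune_windkessel(make_outlets(age), map_t * MMHG, Q_MEAN)
        scales[age] = s
    outl60, _ = tune_windkessel(outlets_40(), 95 * MMHG, Q_MEAN)
    outl75, _ = tune_windkessel(outlets_40(), 102 * MMHG, Q_MEAN)
    r60 = 1.0 / sum(1.0 / (b.r_prox + b.r_dist) for b in outl60.values())
    r75 = 1.0 / sum(1.0 / (b.r_prox + b.r_dist) for b in outl75.values())
    assert r75 > r60


def test_uniform_scaling_preserves_flow_splits():
    outl = outlets_40()
    before = flow_splits(outl)
    tuned, _ = tune_windkessel(outl, 102 * MMHG, Q_MEAN)
    after = flow_splits(tuned)
    for name in before:
        assert after[name] == pytest.approx(before[name], rel=0.01)


def test_unreachable_target_raises():
    outl = outlets_40()
    with pytest.raises(ValueError):
        tune_windkessel(outl, 0.5 * MMHG, Q_MEAN)


def test_windkessel_table_iliac_rdist_age_invariant():
    wt = WindkesselTable()
    r40 = wt.rows(40)["right_ext_iliac"].r_dist
    r75 = wt.rows(75)["right_ext_iliac"].r_dist
    assert r40 == r75


# -- support loop (analytic monotone surrogate) ----------------------------


def analytic_evaluate(k_half=2e6, pwv0=6.5, pwv_max=14.0):
    """PWV(k) monotone saturating; EP proportional to k (surrogate)."""

    def evaluate(smap):
        k = smap.k_s["ATA"]
        v = pwv0 + (pwv_max - pwv0) * k / (k + k_half)
        ep = {r: smap.ep.get(r, 0.0) for r in ("ATA", "DTA", "IAA")}
        return v, ep

    return evaluate


def test_support_loop_converges_to_target_pwv():
    targets = CalibrationTargets(map_target=93 * MMHG, pwv_target=9.0)
    state = tune_external_support(analytic_evaluate(), targets)
    assert state.converged
    assert state.pwv == pytest.approx(9.0, abs=targets.pwv_tol)
    assert state.k_s["IAA"] == 0.0
    assert state.k_s["DTA"] == pytest.approx(0.5 * state.k_s["ATA"])
    assert state.iterations <= targets.max_iter


def test_support_loop_fixed_point_when_target_already_met():
    targets = CalibrationTargets(map_target=93 * MMHG, pwv_target=6.5)
    state = tune_external_support(analytic_evaluate(pwv0=6.5), targets)
    assert state.converged
    assert state.k_s["ATA"] == 0.0
    assert state.iterations <= 2


def test_support_loop_reports_unreachable_low_target():
    targets = CalibrationTargets(map_target=93 * MMHG, pwv_target=5.0)
    state = tune_external_support(analytic_evaluate(pwv0=6.5), targets)
    assert not state.converged
    assert state.k_s["ATA"] == 0.0


def test_constitutive_relinearization_hook_reaches_joint_fixed_point():
    """Re-linearizing the wall at the updated EP changes the PWV response;
    the loop still converges with the anchor following the computed EP."""
    wall_state = {"ep": 0.0}

    def evaluate(smap):
        k = smap.k_s["ATA"]
        # softer wall at higher EP (lower TP): PWV response shifts down
        soften = 1.0 - 0.2 * wall_state["ep"] / (10 * MMHG + wall_state["ep"])
        v = 6.5 * soften + 7.5 * k / (k + 2e6)
        ep = {"ATA": k / (k + 2e6) * 12 * MMHG, "DTA": 0.0, "IAA": 0.0}
        return v, ep

    def relinearize(ep_comp):
        wall_state["ep"] = ep_comp["ATA"]
        return {"ATA": ep_comp["ATA"]}

    targets = CalibrationTargets(map_target=93 * MMHG, pwv_target=9.0,
                                 max_iter=30)
    state = tune_external_support(evaluate, targets, relinearize=relinearize)
    assert state.converged
    # anchor followed the computed EP
    assert state.ep_computed["ATA"] > 0


# -- damping ---------------------------------------------------------------


def synthetic_probe(noise_amp):
    t = np.linspace(0, 2, 4000)
    p = 90 * MMHG + 20 * MMHG * np.sin(2 * np.pi * t) \
        + noise_amp * np.sin(2 * np.pi * 47.0 * t)
    return WaveformProbe(label="x", s=None, time=t, pressure=p,
                         flow=np.zeros_like(p), area=np.full_like(p, 3e-4),
                         period=1.0)


def test_high_frequency_fraction_separates_clean_from_noisy():
    clean = high_frequency_fraction(synthetic_probe(0.0))
    noisy = high_frequency_fraction(synthetic_probe(5 * MMHG))
    assert clean < 1e-6
    assert noisy > 0.01


def test_high_frequency_fraction_monotone_in_noise():
    fracs = [high_frequency_fraction(synthetic_probe(a * MMHG))
             for a in (0.5, 2.0, 8.0)]
    assert fracs[0] < fracs[1] < fracs[2]


def test_choose_damping_doubles_until_criterion_met():
    calls = []

    def evaluate_probe(c_s):
        calls.append(c_s)
        noise = 10 * MMHG * 100.0 / (100.0 + c_s)   # decays with damping
        return [synthetic_probe(noise)]

    c = choose_damping(evaluate_probe, seed=25.0, cap=102400.0)
    assert c == calls[-1]
    frac = high_frequency_fraction(evaluate_probe(c)[0])
    assert frac < 0.01
    # smallest passing value of the doubling ladder: half of it must fail
    if c > 25.0:
        assert high_frequency_fraction(evaluate_probe(c / 2)[0]) >= 0.01


def test_choose_damping_returns_cap_with_warning_when_unreachable(caplog):
    def evaluate_probe(c_s):
        return [synthetic_probe(20 * MMHG)]

    import logging

    with caplog.at_level(logging.WARNING, logger="aortaflow.calibration"):
        c = choose_damping(evaluate_probe, seed=25.0, cap=100.0)
    assert c == 100.0
    assert any("cap" in r.message for r in caplog.records)
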