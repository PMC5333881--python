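"""Aortic-root inflow waveform.

Only the waveform mean (5.79 L/min) and heart rate (60 bpm) of the measured
inflow are available, so the generator produces a standard physiologic
shape: a skewed systolic ejection lobe (quarter-sine rise to the peak at
~30% of ejection, quarter-cosine fall — aortic flow accelerates much faster
than it decelerates), a small end-systolic reverse-flow lobe (valve
closure), and zero diastolic flow.  The peak is fixed by the mean-flow
constraint and is independent of the skew.  The fast initial acceleration
matters for wave physics: it gives the pressure upstroke a well-defined
foot, so that foot-to-foot transit measures propagation rather than the
slow filling of the whole tree.  Cardiac output is held constant across
ages (resting cardiac output changes little with healthy aging), so the
same waveform drives every age group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import L_PER_MIN


@dataclass(frozen=True)
class InflowSpec:
    """Shape parameters of the aortic-root flow waveform."""

    mean_flow: float = 5.79 * L_PER_MIN   # [m^3/s]
    heart_rate: float = 60.0              # [bpm]
    systolic_fraction: float = 0.33       # ejection duration / period
    peak_time_fraction: float = 0.30      # time to peak / ejection duration
    reverse_fraction: float = 0.05        # reverse lobe volume / forward volume
    samples_per_cycle: int = 1000

    def __post_init__(self):
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be > 0")
        if not 0 < self.systolic_fraction < 1:
            raise ValueError("systolic_fraction must lie in (0, 1)")
        if not 0 < self.peak_time_fraction < 1:
            raise ValueError("peak_time_fraction must lie in (0, 1)")
        if not 0 <= self.reverse_fraction < 1:
            raise ValueError("reverse_fraction must lie in [0, 1)")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def stroke_volume(self) -> float:
        """Net ejected volume per beat [m^3]."""
        return self.mean_flow * self.period

    @property
    def peak_flow(self) -> float:
        """Systolic peak [m^3/s] implied by the mean-flow constraint."""
        t_sys = self.systolic_fraction * self.period
        peak = (np.pi * self.stroke_volume
                / (2.0 * t_sys * (1.0 - self.reverse_fraction)))
        if self.mean_flow > 0 and peak <= 0:
            raise ValueError("shape parameters produce a non-positive systolic peak")
        return peak


def inflow_value(spec: InflowSpec, t) -> np.ndarray:
    """Periodic flow rate Q(t) [m^3/s] at time(s) ``t`` [s]."""
    t = np.asarray(t, dtype=float)
    if spec.mean_flow == 0.0:
        return np.zeros_like(t)
    T = spec.period
    tau = np.mod(t, T)
    t_sys = spec.systolic_fraction * T
    t_rev = min(0.25 * t_sys, T - t_sys)
    t_pk = spec.peak_time_fraction * t_sys
    q = np.zeros_like(tau)
    # skewed lobe: quarter-sine rise over t_pk, quarter-cosine fall over the
    # rest; its integral, 2 Qp t_sys / pi, is independent of the skew
    rise = tau < t_pk
    fall = (tau >= t_pk) & (tau < t_sys)
    q[rise] = spec.peak_flow * np.sin(0.5 * np.pi * tau[rise] / t_pk)
    q[fall] = spec.peak_flow * np.cos(
        0.5 * np.pi * (tau[fall] - t_pk) / (t_sys - t_pk))
    if spec.reverse_fraction > 0 and t_rev > 0:
        v_rev = spec.reverse_fraction * spec.peak_flow * 2.0 * t_sys / np.pi
        q_rev = np.pi * v_rev / (2.0 * t_rev)
        rev = (tau >= t_sys) & (tau < t_sys + t_rev)
        q[rev] = -q_rev * np.sin(np.pi * (tau[rev] - t_sys) / t_rev)
    return q


def generate_inflow(spec: InflowSpec) -> tuple[np.ndarray, np.ndarray]:
    """One sampled period (t, Q) of the inflow waveform.

    The trapezoid integral of the returned samples matches
    ``mean_flow * period`` to within 0.1%.
    """
    t = np.linspace(0.0, spec.period, spec.samples_per_cycle + 1)
    return t, inflow_value(spec, t)
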