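"""Clinical metrics of arterial stiffening from converged waveform probes.

Four metrics are computed per aortic segment and age:

* pulse pressure  PP = P_sys - P_dia  (and MAP = P_dia + PP/3);
* distensibility  D = (d_sys^2 - d_dia^2) / (d_dia^2 * PP), with the
  equivalent circular diameter d = 2 sqrt(A/pi);
* foot-to-foot pulse wave velocity PWV = path / (t_foot_b - t_foot_a),
  where the foot of the pressure wave is located by the intersecting
  tangent algorithm (horizontal tangent at the diastolic minimum meets the
  tangent at the maximum systolic gradient), and the path is the actual
  centerline arc length (a direct-distance mode with the conventional 0.8
  correction factor is available);
* cyclic stored-energy change  dW = 0.5 (P_sys - P_dia)(A_sys - A_dia)/A_dia
  (an energy-per-volume proxy; in the ascending aorta it ignores cyclic
  axial lengthening and is reported with that caveat).

Spatial (across the six aortic segments, fixed age) and temporal (across
ages, fixed segment) Pearson correlations of each metric against the
prescribed circumferential material stiffness summarize how faithfully each
metric tracks the underlying wall stiffness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solver import WaveformProbe

#: six-segment spatial grid on the aortic axis: ascending aorta, arch,
#: descending thoracic, suprarenal abdominal, infrarenal abdominal, iliac
SEGMENT_GRID: tuple[tuple[float, float], ...] = (
    (0.0, 0.12), (0.12, 0.38), (0.38, 0.55),
    (0.55, 0.71), (0.71, 1.0), (1.0, 1.27),
)

SEGMENT_MIDPOINTS: tuple[float, ...] = tuple(
    0.5 * (a + b) for a, b in SEGMENT_GRID)


class FlatWaveformError(ValueError):
    """Waveform has no systolic upstroke to locate a foot on."""


def _window(probe: WaveformProbe) -> slice:
    """Analysis window: one full period centered in the recorded series, so
    that the systolic upstroke of every station lies strictly inside."""
    t = probe.time
    total = t[-1] - t[0]
    if total < probe.period * (1.0 - 1e-9):
        raise ValueError("probe does not cover a full period")
    if total <= probe.period * 1.05:
        return slice(0, len(t))
    t0 = t[0] + 0.5 * (total - probe.period)
    i0 = int(np.searchsorted(t, t0))
    i1 = int(np.searchsorted(t, t0 + probe.period))
    return slice(i0, min(i1 + 1, len(t)))


def pulse_pressure(probe: WaveformProbe) -> float:
    """Pulse pressure max(P) - min(P) over one cycle [Pa]."""
    w = _window(probe)
    p = probe.pressure[w]
    return float(p.max() - p.min())


def map_formula(p_sys: float, p_dia: float) -> float:
    """MAP = P_dia + (P_sys - P_dia)/3 (units follow the inputs)."""
    return p_dia + (p_sys - p_dia) / 3.0


def mean_pressure(probe: WaveformProbe) -> float:
    """Time-averaged pressure over one cycle [Pa]."""
    w = _window(probe)
    return float(np.trapezoid(probe.pressure[w], probe.time[w])
                 / (probe.time[w][-1] - probe.time[w][0]))


def systolic_diastolic(probe: WaveformProbe) -> tuple[float, float]:
    w = _window(probe)
    p = probe.pressure[w]
    return float(p.max()), float(p.min())


def distensibility(probe: WaveformProbe) -> float:
    """Cross-sectional distensibility (d_sys^2 - d_dia^2)/(d_dia^2 PP) [1/Pa]."""
    pp = pulse_pressure(probe)
    if pp <= 0:
        raise ZeroDivisionError("zero pulse pressure: distensibility undefined")
    w = _window(probe)
    a = probe.area[w]
    a_sys, a_dia = float(a.max()), float(a.min())
    # d^2 ratios equal area ratios for equivalent circular diameters
    return (a_sys - a_dia) / (a_dia * pp)


def delta_w(probe: WaveformProbe) -> float:
    """Cyclic change in stored strain energy per volume [Pa]:
    0.5 (P_sys - P_dia)(A_sys - A_dia)/A_dia."""
    w = _window(probe)
    p, a = probe.pressure[w], probe.area[w]
    return float(0.5 * (p.max() - p.min()) * (a.max() - a.min()) / a.min())


def foot_time(probe: WaveformProbe) -> float:
    """Foot of the pressure upstroke by the intersecting-tangent method [s].

    The foot is the intersection of the horizontal tangent through the
    diastolic minimum with the tangent at the point of maximum systolic
    gradient.  The gradient is evaluated on a 3-point smoothed derivative
    and the maximum located to sub-sample resolution by parabolic
    interpolation.
    """
    w = _window(probe)
    t, p = probe.time[w], probe.pressure[w]
    if p.max() - p.min() < 1e-9 * max(abs(p.max()), 1.0):
        raise FlatWaveformError("flat waveform: no upstroke")

    i_min = int(np.argmin(p))
    i_pk = i_min + int(np.argmax(p[i_min:]))
    if i_pk <= i_min + 1:
        # peak precedes the minimum in this window: wrap the search to the
        # upstroke after the global minimum
        raise FlatWaveformError("no upstroke after the diastolic minimum")

    dp = np.gradient(p, t)
    dp = np.convolve(dp, np.ones(3) / 3.0, mode="same")
    seg = slice(i_min, i_pk + 1)
    j = i_min + int(np.argmax(dp[seg]))
    # parabolic refinement of the max-gradient point
    if i_min < j < i_pk and 0 < j < len(t) - 1:
        y0, y1, y2 = dp[j - 1], dp[j], dp[j + 1]
        denom = y0 - 2.0 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = min(max(delta, -0.5), 0.5)
    else:
        delta = 0.0
    dt_s = t[1] - t[0]
    t_star = t[j] + delta * dt_s
    slope = float(np.interp(t_star, t, dp))
    p_star = float(np.interp(t_star, t, p))
    if slope <= 0:
        raise FlatWaveformError("non-positive maximum gradient")
    return t_star - (p_star - float(p.min())) / slope


def pwv(probe_a: WaveformProbe, probe_b: WaveformProbe, path: float,
        direct_distance: float | None = None) -> float:
    """Foot-to-foot pulse wave velocity between two stations [m/s].

    ``path`` is the centerline arc length between the stations.  If
    ``direct_distance`` is given, the straight-line estimate scaled by the
    conventional 0.8 factor is returned instead (the clinical
    direct-distance convention).
    """
    if path <= 0:
        raise ValueError("path must be > 0")
    dt_ff = foot_time(probe_b) - foot_time(probe_a)
    if dt_ff <= 0:
        raise ValueError(
            "non-positive transit time: probes reversed or path too short")
    if direct_distance is not None:
        return 0.8 * direct_distance / dt_ff
    return path / dt_ff


# --------------------------------------------------------------------------


@dataclass
class MetricsTable:
    """Per-(age, segment) stiffening metrics plus the prescribed
    circumferential stiffness at the segment evaluation station."""

    frame: pd.DataFrame   # columns: age, segment, k_tt, pp, map, dist, pwv, dw

    def for_age(self, age: int) -> pd.DataFrame:
        return self.frame[self.frame.age == age].sort_values("segment")

    def for_segment(self, segment: int) -> pd.DataFrame:
        return self.frame[self.frame.segment == segment].sort_values("age")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Population-normalized Pearson r (covariance over the product of
    standard deviations; identical under either n / n-1 convention)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def correlation_tables(table: MetricsTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spatial and temporal Pearson correlations of each metric vs K_tt.

    Returns (spatial, temporal): spatial has one column per age
    (correlating over the six segments), temporal one column per segment
    (correlating over the ages).  Zero-variance pairs yield NaN.
    """
    metrics = ["pp", "dist", "pwv", "dw"]
    ages = sorted(table.frame.age.unique())
    segments = sorted(table.frame.segment.unique())

    spatial = pd.DataFrame(index=metrics, columns=ages, dtype=float)
    for age in ages:
        sub = table.for_age(age)
        for m in metrics:
            spatial.loc[m, age] = _pearson(sub["k_tt"], sub[m])

    temporal = pd.DataFrame(index=metrics, columns=segments, dtype=float)
    for seg in segments:
        sub = table.for_segment(seg)
        for m in metrics:
            temporal.loc[m, seg] = _pearson(sub["k_tt"], sub[m])
    return spatial, temporal
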