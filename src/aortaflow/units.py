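"""Unit conversion constants (SI internally everywhere)."""

MMHG = 133.322          # Pa per mmHg
L_PER_MIN = 1.0 / 60000.0   # m^3/s per L/min
MM = 1e-3               # m per mm
MPA = 1e6               # Pa per MPa

# Windkessel table scales as printed: resistances in 1e9 kg/(m^4 s) = Pa s/m^3,
# compliances in 1e-9 m^4 s^2/kg = m^3/Pa.
R_SCALE = 1e9
C_SCALE = 1e-9


def mmhg(x: float) -> float:
    """Pa -> mmHg."""
    return x / MMHG


def pa(x: float) -> float:
    """mmHg -> Pa."""
    return x * MMHG
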