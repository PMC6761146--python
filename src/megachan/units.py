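"""Unit conventions used throughout the package.

Currents are picoamperes (pA), voltages millivolts (mV), conductances
picosiemens (pS), concentrations millimolar (mM), frequencies hertz (Hz)
and times seconds (s).  The pA/mV -> pS conversion factor lives here and
nowhere else.
"""

from __future__ import annotations

#: 1 pA / 1 mV = 1 nS = 1000 pS
PS_PER_PA_OVER_MV = 1000.0


def conductance_ps(current_pa: float, voltage_mv: float) -> float:
    """Ohmic chord conductance in pS from a current (pA) at a holding
    voltage (mV).  Magnitudes are used so recordings at negative holding
    potentials report positive conductances.
    """
    if voltage_mv == 0:
        raise ZeroDivisionError("conductance is undefined at 0 mV")
    return PS_PER_PA_OVER_MV * abs(current_pa) / abs(voltage_mv)
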