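"""Packaged simulator scenarios.

These are the study conditions the simulator ships with:

* ``fig3b_scenario`` — the multi-substate megachannel at -80 mV: closed
  (0 pS), the most frequent subconductance state (300 pS), a full-open
  state at the 1.3 nS maximal conductance, and a brief flicker state,
  under saturating Ca2+ with Bz-423 and PhAsO present.
* ``titration_template`` + ``TITRATION_CA_MM`` / ``TITRATION_REPLICATES``
  — a 23-recording Ca2+ titration (6 concentrations spanning 0.1-3 mM)
  of a 500 pS channel at -60 mV in the presence of 0.15 mM Bz-423.
* ``fixed_po_scenario`` — a minimal two-state channel pinned at a given
  stationary open probability, for conductance-recovery studies.
* ``iv_series`` — an exactly linear I-V table with a constant
  gradient-induced current shift added.

The Hill half-activation (0.6 mM) and asymptotic open probability (0.2
for the titration) are simulator assumptions — the experimental
dose-response literature reports the Hill coefficient but not these two
parameters — and are stated here in one place.
"""

from __future__ import annotations

import numpy as np

from .trace import ConditionLabel, CurrentTrace
from .sim import (
    CaActivation,
    GatingScheme,
    NoiseModel,
    SimScenario,
    two_state_scheme,
)

__all__ = [
    "multistate_scheme",
    "fig3b_scenario",
    "titration_template",
    "fixed_po_scenario",
    "iv_series",
    "TITRATION_CA_MM",
    "TITRATION_REPLICATES",
]

#: Ca2+ grid (mM) and per-concentration replicate counts of the packaged
#: titration design: 23 recordings over 6 concentrations spanning 0.1-3 mM.
TITRATION_CA_MM = (0.1, 0.25, 0.5, 1.0, 2.0, 3.0)
TITRATION_REPLICATES = (4, 4, 4, 4, 4, 3)


def multistate_scheme(
    g_sub_ps: float = 300.0,
    g_open_ps: float = 1300.0,
    k_close: float = 20.0,
    k_exchange: float = 5.0,
    k_flicker_exit: float = 500.0,
) -> GatingScheme:
    """Closed <-> substate <-> full-open scheme with a brief flicker state.

    The closed-row entries are relative opening weights (60% into the
    substate, 30% directly into the full-open state, 10% into the
    flicker); their absolute scale is set later by the Ca2+ modulation.
    Substate and full-open states close at ``k_close`` and exchange at
    ``k_exchange``; the flicker state exits at ``k_flicker_exit``
    (mean dwell 2 ms by default).
    """
    # states: closed, substate, full-open, flicker (full conductance, brief)
    q = np.array(
        [
            [0.0, 0.6, 0.3, 0.1],
            [k_close, 0.0, k_exchange, 0.0],
            [k_close, k_exchange, 0.0, 0.0],
            [k_flicker_exit, 0.0, 0.0, 0.0],
        ]
    )
    return GatingScheme(
        states=(
            ("closed", 0.0),
            ("substate", g_sub_ps),
            ("open", g_open_ps),
            ("flicker", g_open_ps),
        ),
        rate_matrix=q,
        flicker_states=("flicker",),
    )


def fig3b_scenario(
    duration: float = 60.0,
    sigma_white: float = 2.0,
    v_cis: float = -80.0,
) -> SimScenario:
    """Multi-substate activity at -80 mV under 3 mM Ca2+ + 0.1 mM Bz-423
    + 0.2 mM PhAsO, with the full-open state at 1300 pS (1.3 nS)."""
    return SimScenario(
        gating=multistate_scheme(),
        activation=CaActivation(n_hill=1.37, k_half=0.6, po_max=0.6, k_close=20.0),
        noise=NoiseModel(
            sigma_white=sigma_white, line_amp=0.5, drift_amp=1.0, drift_corner=0.5
        ),
        v_cis=v_cis,
        duration=duration,
        condition=ConditionLabel(ca_mm=3.0, bz423_mm=0.1, phaso_mm=0.2, source="direct"),
    )


def titration_template(
    n_hill: float,
    g_open_ps: float = 500.0,
    duration: float = 60.0,
    v_cis: float = -60.0,
) -> SimScenario:
    """Template scenario for the packaged 23-recording Ca2+ titration.

    The generating Hill coefficient is the caller's choice (the study
    statistic being titrated sets it); half-activation 0.6 mM, asymptotic
    open probability 0.2, closing rate 100 1/s (10 ms mean open dwell, so
    gating power sits well above the 2 Hz exclusion band), and 30%
    inter-experiment variability — the scatter typical of independent
    planar-bilayer insertions.
    """
    return SimScenario(
        gating=two_state_scheme(g_open_ps, k_close=100.0),
        activation=CaActivation(n_hill=n_hill, k_half=0.6, po_max=0.2, k_close=100.0),
        noise=NoiseModel(sigma_white=1.0, line_amp=0.5, drift_amp=0.5, drift_corner=0.5),
        v_cis=v_cis,
        duration=duration,
        condition=ConditionLabel(bz423_mm=0.15, source="direct"),
        experiment_cv=0.3,
    )


def fixed_po_scenario(
    g_open_ps: float,
    po: float,
    duration: float = 60.0,
    v_cis: float = -60.0,
    sigma_white: float = 1.5,
    line_amp: float = 1.0,
    drift_amp: float = 0.5,
    k_close: float = 20.0,
) -> SimScenario:
    """Two-state channel pinned at stationary open probability ``po``.

    Realized with a first-order activation (n = 1, k_half = 1 mM,
    po_max = 2*po) evaluated at 1 mM Ca2+, which places the stationary
    occupancy exactly at ``po``; po_max <= 1 restricts this construction
    to po <= 0.5.
    """
    if not 0 < po <= 0.5:
        raise ValueError("fixed_po_scenario supports 0 < po <= 0.5")
    return SimScenario(
        gating=two_state_scheme(g_open_ps, k_close=k_close),
        activation=CaActivation(n_hill=1.0, k_half=1.0, po_max=2 * po, k_close=k_close),
        noise=NoiseModel(
            sigma_white=sigma_white,
            line_amp=line_amp,
            drift_amp=drift_amp,
            drift_corner=0.5,
        ),
        v_cis=v_cis,
        duration=duration,
        condition=ConditionLabel(ca_mm=1.0, source="proteoliposome"),
    )


def dwell_rule_trace(
    v_cis: float = -60.0,
    stable_pa: float = -30.0,
    flicker_pa: float = -60.0,
    stable_ms: float = 50.0,
    flicker_ms: float = 2.0,
    gap_ms: float = 50.0,
    n_cycles: int = 8,
    sampling_rate: float = 10_000.0,
    filter_cutoff: float = 500.0,
) -> CurrentTrace:
    """Deterministic two-level test trace for the 10-ms stability rule.

    Stable openings (default -30 pA for 50 ms) interleaved with brief
    flicker excursions of twice the amplitude (-60 pA for 2 ms), separated
    by closed gaps, rendered noise-free through the causal 4-pole
    Butterworth low-pass of the acquisition chain.  The flickers are the
    larger current, but only the stable openings satisfy the >= 10 ms
    criterion, so the maximal stable conductance is |stable_pa/v_cis|.
    """
    from scipy import signal as _signal

    fs = sampling_rate

    def n(ms: float) -> int:
        return int(round(ms * 1e-3 * fs))

    cycle = np.concatenate(
        [
            np.zeros(n(gap_ms)),
            np.full(n(stable_ms), stable_pa),
            np.zeros(n(gap_ms)),
            np.full(n(flicker_ms), flicker_pa),
        ]
    )
    ideal = np.concatenate([np.tile(cycle, n_cycles), np.zeros(n(gap_ms))])
    b, a = _signal.butter(4, filter_cutoff / (fs / 2.0))
    filtered = _signal.lfilter(b, a, ideal)
    return CurrentTrace(
        samples=filtered,
        sampling_rate=fs,
        v_cis=v_cis,
        filter_cutoff=filter_cutoff,
    )


def iv_series(
    g_ps: float = 500.0,
    shift_pa: float = 13.0,
    voltages_mv: tuple[float, ...] = (-80.0, -60.0, -40.0, -20.0, 0.0, 20.0),
) -> list[tuple[float, float]]:
    """Exactly linear (V, I) points with a constant gradient-induced
    current shift added to every current: I = g*V/1000 + shift."""
    return [(v, g_ps * v / 1000.0 + shift_pa) for v in voltages_mv]
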