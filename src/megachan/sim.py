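"""Synthetic planar-bilayer recording simulator.

Ground truth is a continuous-time Markov chain (CTMC) over gating states,
each with an Ohmic conductance: one closed state (0 pS), optional
conductance substates, and a full-open state.  Ca2+ dependence enters
through a Hill dose-response for the stationary open probability, realized
as a Ca2+-dependent closed->open opening rate against a fixed closing rate.

A simulated trajectory is rendered through the standard acquisition chain:
Ohmic current per state (I[pA] = g[pS] * V[mV] / 1000, cis-side sign
convention), a constant instrumental offset, additive Gaussian noise,
50 Hz mains contamination, slow Ornstein-Uhlenbeck baseline drift, a
causal 4-pole Butterworth low-pass at the analog corner (500 Hz by
default), sampled at 10 kHz.  Everything is bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .trace import ConditionLabel, CurrentTrace

__all__ = [
    "GatingScheme",
    "CaActivation",
    "NoiseModel",
    "SimScenario",
    "two_state_scheme",
    "stationary_po",
    "ca_modulated_rates",
    "simulate_path",
    "render_trace",
    "simulate_scenario",
    "simulate_titration",
]


# ---------------------------------------------------------------------------
# ground-truth model types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GatingScheme:
    """A CTMC gating scheme.

    ``states`` is an ordered list of ``(label, conductance_pS)`` with
    exactly one 0 pS closed state.  ``rate_matrix`` holds transition rates
    in 1/s; the diagonal is the negative row sum (enforced on
    construction).  ``flicker_states`` optionally names states intended as
    brief-lived flickers (documentation + fixture bookkeeping; the
    dynamics come from the rates alone).
    """

    states: tuple[tuple[str, float], ...]
    rate_matrix: np.ndarray
    flicker_states: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        states = tuple((str(l), float(g)) for l, g in self.states)
        object.__setattr__(self, "states", states)
        q = np.array(self.rate_matrix, dtype=float)
        n = len(states)
        if q.shape != (n, n):
            raise ValueError(f"rate_matrix must be {n}x{n}, got {q.shape}")
        off = q[~np.eye(n, dtype=bool)]
        if np.any(off < 0) or not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal rates must be finite and >= 0")
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        q.setflags(write=False)
        object.__setattr__(self, "rate_matrix", q)
        g = np.array([c for _, c in states])
        if np.any(g < 0):
            raise ValueError("conductances must be >= 0")
        if int(np.sum(g == 0)) != 1:
            raise ValueError("scheme must have exactly one 0 pS closed state")
        for lbl in self.flicker_states:
            if lbl not in self.labels:
                raise ValueError(f"flicker state {lbl!r} not in scheme")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(l for l, _ in self.states)

    @property
    def conductances_ps(self) -> np.ndarray:
        return np.array([g for _, g in self.states])

    @property
    def closed_index(self) -> int:
        return int(np.flatnonzero(self.conductances_ps == 0)[0])

    @property
    def n_states(self) -> int:
        return len(self.states)


def two_state_scheme(
    g_open_ps: float, k_open: float = 0.0, k_close: float = 100.0
) -> GatingScheme:
    """Minimal closed <-> open scheme; the opening rate is typically
    rewritten later by :func:`ca_modulated_rates`."""
    q = np.array([[0.0, k_open], [k_close, 0.0]])
    return GatingScheme(states=(("closed", 0.0), ("open", g_open_ps)), rate_matrix=q)


@dataclass(frozen=True)
class CaActivation:
    """Hill-type Ca2+ activation: the stationary open probability is
    ``po_max * ca^n / (k_half^n + ca^n)``.

    ``k_close`` (1/s) is the conducting->closed rate against which the
    opening rate is balanced to realize that occupancy.
    """

    n_hill: float = 1.37
    k_half: float = 0.6  # mM
    po_max: float = 0.2
    k_close: float = 100.0  # 1/s

    def __post_init__(self) -> None:
        if not self.n_hill > 0:
            raise ValueError("n_hill must be > 0")
        if not self.k_half > 0:
            raise ValueError("k_half must be > 0")
        if not 0 < self.po_max <= 1:
            raise ValueError("po_max must be in (0, 1]")
        if not self.k_close > 0:
            raise ValueError("k_close must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Additive instrumentation noise.

    ``sigma_white`` is the Gaussian noise SD *after* the low-pass filter
    (the observable noise floor); the generator pre-scales accordingly.
    Drift is a first-order Gauss-Markov (Ornstein-Uhlenbeck) process with
    stationary SD ``drift_amp`` and corner ``drift_corner`` (< 2 Hz so its
    power sits inside the low-frequency exclusion band).  ``offset_pa``
    models a constant junction current, e.g. from an ionic gradient.
    """

    sigma_white: float = 1.0  # pA, post-filter
    line_amp: float = 0.0  # pA
    line_freq: float = 50.0  # Hz
    drift_amp: float = 0.0  # pA
    drift_corner: float = 0.5  # Hz
    offset_pa: float = 0.0  # pA
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_white", "line_amp", "drift_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.drift_corner < 2.0:
            raise ValueError("drift_corner must lie in (0, 2) Hz")


@dataclass(frozen=True)
class SimScenario:
    """Everything needed to synthesize one recording.

    ``experiment_cv`` models inter-experiment (membrane-to-membrane)
    variability: each simulated recording draws a lognormal factor with
    this coefficient of variation (mean 1) and applies it to the
    activation's asymptotic open probability, emulating the scatter
    between independent bilayer experiments.  0 disables it.
    """

    gating: GatingScheme
    activation: CaActivation
    noise: NoiseModel
    v_cis: float = -60.0  # mV
    duration: float = 60.0  # s
    sampling_rate: float = 10_000.0  # Hz
    filter_cutoff: float = 500.0  # Hz
    condition: ConditionLabel = field(default_factory=ConditionLabel)
    experiment_cv: float = 0.0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if self.experiment_cv < 0:
            raise ValueError("experiment_cv must be >= 0")
        if self.sampling_rate < 2 * self.filter_cutoff:
            raise ValueError(
                "sampling_rate must be at least twice filter_cutoff "
                f"({self.sampling_rate} < 2*{self.filter_cutoff}); aliasing"
            )


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def stationary_po(activation: CaActivation, ca_mm: float) -> float:
    """Ground-truth stationary open probability at a Ca2+ concentration."""
    if ca_mm < 0:
        raise ValueError("ca_mm must be >= 0")
    if ca_mm == 0:
        return 0.0
    x = (ca_mm / activation.k_half) ** activation.n_hill
    return activation.po_max * x / (1.0 + x)


def ca_modulated_rates(
    scheme: GatingScheme, activation: CaActivation, ca_mm: float
) -> GatingScheme:
    """Rescale the closed-state exit rates so the aggregate closed->open
    rate equals ``k_close * p / (1 - p)`` with ``p = stationary_po(...)``.

    For the two-state reduction this makes the CTMC's stationary open
    occupancy equal p exactly; relative weights among multiple opening
    targets are preserved (uniform over conducting states if the template
    closed row is all zero).  Other rows are untouched.
    """
    p = stationary_po(activation, ca_mm)
    if p >= 1.0:
        raise ValueError(
            "stationary open probability is 1; use po_max < 1 or finite ca_mm"
        )
    k_open = activation.k_close * p / (1.0 - p)
    q = np.array(scheme.rate_matrix, dtype=float)
    ci = scheme.closed_index
    row = q[ci].copy()
    row[ci] = 0.0
    total = row.sum()
    if total > 0:
        weights = row / total
    else:
        weights = np.zeros(scheme.n_states)
        conducting = np.flatnonzero(scheme.conductances_ps > 0)
        weights[conducting] = 1.0 / conducting.size
    q[ci] = k_open * weights
    return replace(scheme, rate_matrix=q)


def simulate_path(
    scheme: GatingScheme,
    duration: float,
    seed: int | np.random.Generator = 0,
    start_state: Optional[int] = None,
) -> list[tuple[int, float]]:
    """Gillespie trajectory: a list of ``(state_index, dwell_s)`` covering
    ``[0, duration]``.  Dwells are exponential with the state's exit rate;
    a state with zero exit rate absorbs.  Starts in the closed state
    unless ``start_state`` is given.  Reproducible for a fixed seed.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = scheme.rate_matrix
    state = scheme.closed_index if start_state is None else int(start_state)
    t = 0.0
    path: list[tuple[int, float]] = []
    while t < duration:
        exit_rate = -q[state, state]
        if exit_rate <= 0:
            path.append((state, duration - t))
            break
        dwell = rng.exponential(1.0 / exit_rate)
        if t + dwell >= duration:
            path.append((state, duration - t))
            break
        path.append((state, dwell))
        t += dwell
        probs = q[state].copy()
        probs[state] = 0.0
        state = int(rng.choice(scheme.n_states, p=probs / exit_rate))
    return path


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _butter_lowpass(cutoff: float, fs: float):
    return signal.butter(4, cutoff / (fs / 2.0))


def _filter_noise_gain(b: np.ndarray, a: np.ndarray, n: int = 4096) -> float:
    """sqrt(sum h^2) of the filter impulse response: the factor by which
    the filter attenuates the SD of white input noise."""
    impulse = np.zeros(n)
    impulse[0] = 1.0
    h = signal.lfilter(b, a, impulse)
    return float(np.sqrt(np.sum(h**2)))


def ideal_current(
    path: Sequence[tuple[int, float]], scenario: SimScenario
) -> np.ndarray:
    """Noise-free per-sample current (pA) implied by a trajectory."""
    fs = scenario.sampling_rate
    n = int(round(scenario.duration * fs))
    states = np.array([s for s, _ in path])
    dwells = np.array([d for _, d in path])
    ends = np.cumsum(dwells)
    if ends[-1] < scenario.duration - 0.5 / fs:
        raise ValueError("trajectory does not cover the scenario duration")
    t = np.arange(n) / fs
    seg = np.searchsorted(ends, t, side="right")
    seg = np.minimum(seg, len(states) - 1)
    g = scenario.gating.conductances_ps[states[seg]]
    return g * scenario.v_cis / 1000.0


def render_trace(
    path: Sequence[tuple[int, float]], scenario: SimScenario
) -> CurrentTrace:
    """Render a trajectory through the acquisition chain into a trace.

    Per-sample ideal current (g * V_cis / 1000) + constant offset + white
    noise + mains sinusoid + OU drift, then a causal 4-pole Butterworth
    low-pass at ``filter_cutoff``, sampled at ``sampling_rate``.
    """
    fs = scenario.sampling_rate
    if fs < 2 * scenario.filter_cutoff:
        raise ValueError("sampling_rate below 2*filter_cutoff: aliasing")
    x = ideal_current(path, scenario)
    n = x.size
    t = np.arange(n) / fs
    nm = scenario.noise
    rng = np.random.default_rng(nm.seed)
    b, a = _butter_lowpass(scenario.filter_cutoff, fs)

    total = x + nm.offset_pa
    if nm.sigma_white > 0:
        gain = _filter_noise_gain(b, a)
        total = total + rng.standard_normal(n) * (nm.sigma_white / gain)
    if nm.line_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        total = total + nm.line_amp * np.sin(2 * np.pi * nm.line_freq * t + phase)
    if nm.drift_amp > 0:
        # exact OU discretization: x[k] = a*x[k-1] + sqrt(1-a^2)*amp*N(0,1)
        ar = np.exp(-2 * np.pi * nm.drift_corner / fs)
        innov = rng.standard_normal(n) * (nm.drift_amp * np.sqrt(1 - ar**2))
        innov[0] = rng.standard_normal() * nm.drift_amp  # stationary start
        drift = signal.lfilter([1.0], [1.0, -ar], innov)
        total = total + drift
    filtered = signal.lfilter(b, a, total)
    return CurrentTrace(
        samples=filtered,
        sampling_rate=fs,
        v_cis=scenario.v_cis,
        condition=scenario.condition,
        filter_cutoff=scenario.filter_cutoff,
        offset_note=nm.offset_pa if nm.offset_pa != 0 else None,
    )


def simulate_scenario(scenario: SimScenario, seed: Optional[int] = None) -> CurrentTrace:
    """Modulate the scheme by the scenario's Ca2+, simulate a trajectory
    and render it.  ``seed`` (when given) reseeds both the trajectory and
    the noise deterministically."""
    if seed is not None:
        ss = np.random.SeedSequence(seed)
        path_seed, noise_seed, het_seed = (
            int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
        )
        scenario = replace(scenario, noise=replace(scenario.noise, seed=noise_seed))
    else:
        path_seed = scenario.noise.seed + 1
        het_seed = scenario.noise.seed + 2
    activation = scenario.activation
    if scenario.experiment_cv > 0:
        # lognormal with mean 1 and the requested CV
        s2 = math.log(1.0 + scenario.experiment_cv**2)
        factor = float(
            np.random.default_rng(het_seed).lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2))
        )
        po_eff = min(activation.po_max * factor, 0.95)
        activation = replace(activation, po_max=po_eff)
    scheme = ca_modulated_rates(scenario.gating, activation, scenario.condition.ca_mm)
    traj = simulate_path(scheme, scenario.duration, seed=path_seed)
    return render_trace(traj, replace(scenario, gating=scheme))


def simulate_titration(
    template: SimScenario,
    ca_list: Sequence[float],
    replicates: int | Sequence[int],
    seed: int = 0,
) -> list[CurrentTrace]:
    """Simulate replicate recordings at each Ca2+ concentration.

    ``replicates`` is either one count for every concentration or a
    per-concentration sequence (for unbalanced designs).  Per-trace seeds
    derive deterministically from ``(seed, ca_index, replicate_index)``,
    so the whole set is reproducible and every trace is distinct.
    """
    if len(ca_list) == 0:
        raise ValueError("ca_list must be non-empty")
    if list(ca_list) != sorted(ca_list):
        raise ValueError("ca_list must be ascending")
    if isinstance(replicates, int):
        reps = [replicates] * len(ca_list)
    else:
        reps = list(replicates)
        if len(reps) != len(ca_list):
            raise ValueError("per-concentration replicates must match ca_list length")
    if any(r < 1 for r in reps):
        raise ValueError("replicates must be >= 1")
    traces: list[CurrentTrace] = []
    for i, ca in enumerate(ca_list):
        cond = replace(template.condition, ca_mm=float(ca))
        for r in range(reps[i]):
            trace_seed = int(
                np.random.SeedSequence([seed, i, r]).generate_state(1)[0] % 2**31
            )
            scen = replace(template, condition=cond)
            traces.append(simulate_scenario(scen, seed=trace_seed))
    return traces
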