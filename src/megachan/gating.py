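"""Threshold idealization and per-trace channel metrics.

A trace is idealized by a noise band around the closed-state baseline:
a sample is *open* when its distance from the baseline exceeds
``k_sigma * noise_sigma``.  Maximal runs of open samples form events.
From the idealization the pipeline derives:

* **Po** — open probability: fraction of the record spent outside the
  noise band.
* **G_mean** — mean conductance: Ohm's-law conductance of the average
  current over *all* open samples.
* **G_max** — maximal stable conductance: the largest event level among
  events lasting at least ``min_dwell_ms`` (10 ms by default), so brief
  flicker excursions do not set the maximum.

Event levels are robust: the median of the event's samples after
trimming 1 ms at each edge, because the causal 500 Hz low-pass smears
transitions and drags threshold-defined event boundaries into the decay
tails; a trimmed median reads off the stable level itself.

Conductances are reported as magnitudes (|I|/|V|), so recordings at
negative holding potentials report positive pS.  Events whose polarity
opposes the holding potential are flagged as artifacts: they count for
Po and the event tally but are excluded from conductance estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.signal import find_peaks

from .config import RunConfig
from .spectra import BandExclusion, psa_of_trace
from .trace import ConditionLabel, CurrentTrace
from .units import conductance_ps

__all__ = [
    "BaselineNotFoundError",
    "Event",
    "IdealizedTrace",
    "ChannelMetrics",
    "AmplitudeHistogram",
    "estimate_baseline",
    "idealize",
    "compute_po",
    "compute_g_mean",
    "compute_g_max",
    "amplitude_histogram",
    "analyze_trace",
]

logger = logging.getLogger(__name__)


class BaselineNotFoundError(ValueError):
    """No amplitude-histogram peak near 0 pA: the record is never closed
    or carries an uncorrected offset."""


@dataclass(frozen=True)
class Event:
    """One maximal open run.

    ``local_baseline_pa`` is the median of nearby closed samples; event
    levels are referenced against it so slow baseline drift (which is
    effectively constant across one event but wanders between events)
    does not shift event amplitudes.
    """

    start_s: float
    end_s: float
    level_pa: float  # edge-trimmed median current
    mean_pa: float  # plain mean over all event samples
    n_samples: int
    local_baseline_pa: float = 0.0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def amplitude_pa(self) -> float:
        """Signed event amplitude relative to the local baseline."""
        return self.level_pa - self.local_baseline_pa


@dataclass
class IdealizedTrace:
    """Result of noise-band idealization; keeps a reference to the sample
    array so conductance estimators can revisit the raw currents."""

    open_flags: np.ndarray
    baseline: float
    noise_sigma: float
    noise_band_halfwidth: float
    events: tuple[Event, ...]
    samples: np.ndarray
    sampling_rate: float

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def n_open(self) -> int:
        return int(np.count_nonzero(self.open_flags))


@dataclass
class ChannelMetrics:
    """Per-recording result row.  Conductances are ``None`` (absent), not
    zero, when the trace shows no (qualifying) openings."""

    psa: float
    po: float
    g_mean: Optional[float]
    g_max: Optional[float]
    n_events: int
    condition: ConditionLabel
    v_cis: float
    baseline: float = 0.0
    noise_sigma: float = 0.0
    warnings: tuple[str, ...] = ()


@dataclass
class AmplitudeHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    peaks: tuple[tuple[float, float], ...]  # (level_pa, prominence), sorted by |level|

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _gaussian(x, a, mu, sig):
    return a * np.exp(-0.5 * ((x - mu) / sig) ** 2)


def estimate_baseline(
    trace: CurrentTrace, sigma_floor_pa: float = 0.02
) -> tuple[float, float]:
    """Locate the closed-state baseline and the noise SD around it.

    The baseline is the center of the dominant amplitude-histogram peak
    nearest the expected closed level (0 pA, or the trace's documented
    constant offset when present); the noise SD comes from a Gaussian
    fitted to that peak's core.  The SD is floored at ``sigma_floor_pa``
    so noiseless synthetic records still produce a usable
    (quantization-scale) noise band.

    Raises :class:`BaselineNotFoundError` when no significant peak lies
    within 5 robust SDs (at least 10 pA, the instrumental-offset scale)
    of the expected closed level — the signature of a never-closed or
    offset-corrupted record.
    """
    x = trace.samples
    if x.size < 1000:
        raise ValueError("baseline estimation requires at least 1000 samples")
    med = float(np.median(x))
    sigma0 = 1.4826 * float(np.median(np.abs(x - med)))
    sigma0 = max(sigma0, sigma_floor_pa)
    # bin width from the sample-to-sample noise scale (robust to the rare
    # gating transitions), not the global spread, so multimodal records
    # still resolve their peaks
    sigma_diff = 1.4826 * float(np.median(np.abs(np.diff(x))))
    bin_w = max(sigma_diff / 4.0, 0.01)
    lo, hi = float(np.min(x)), float(np.max(x))
    edges = np.arange(lo - bin_w, hi + 2 * bin_w, bin_w)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    padded = np.concatenate([[0], counts, [0]])
    pk, _ = find_peaks(padded, prominence=0.05 * counts.max())
    pk = pk - 1
    if pk.size == 0:
        pk = np.array([int(np.argmax(counts))])
    ref = trace.offset_note if trace.offset_note is not None else 0.0
    peak_levels = centers[pk]
    nearest = int(np.argmin(np.abs(peak_levels - ref)))
    c0 = float(peak_levels[nearest])
    allowance = max(5 * sigma0, 10.0)
    if abs(c0 - ref) > allowance:
        raise BaselineNotFoundError(
            f"nearest histogram peak is at {c0:.2f} pA, beyond {allowance:.2f} pA "
            f"of the expected closed level ({ref:.2f} pA)"
        )
    # initial peak width from the FWHM, capped at half the distance to the
    # nearest neighboring peak
    i0 = int(pk[nearest])
    half_count = counts[i0] / 2.0
    il = i0
    while il > 0 and counts[il - 1] > half_count:
        il -= 1
    ir = i0
    while ir < counts.size - 1 and counts[ir + 1] > half_count:
        ir += 1
    sigma = max((ir - il + 1) * bin_w / 2.355, bin_w / 2.355)
    cap = np.inf
    if peak_levels.size > 1:
        others = np.delete(peak_levels, nearest)
        cap = 0.5 * float(np.min(np.abs(others - c0)))
    baseline = c0
    core = x[np.abs(x - baseline) <= min(3 * sigma, cap)]
    if core.size:
        baseline = float(np.median(core))
    # refine by iterating a Gaussian fit to the histogram around the peak;
    # a plain truncated-sample SD would underestimate the width
    for _ in range(2):
        sel = np.abs(centers - baseline) <= min(3 * sigma, cap)
        if np.count_nonzero(sel) < 4:
            break
        try:
            popt, _ = optimize.curve_fit(
                _gaussian,
                centers[sel],
                counts[sel],
                p0=[counts[sel].max(), baseline, max(sigma, bin_w)],
                maxfev=5000,
            )
        except RuntimeError:
            break
        if not (np.isfinite(popt[1]) and np.isfinite(popt[2]) and abs(popt[2]) > 0):
            break
        baseline, sigma = float(popt[1]), float(abs(popt[2]))
    return baseline, max(sigma, sigma_floor_pa)


def _event_from_run(
    x: np.ndarray,
    flags: np.ndarray,
    start: int,
    stop: int,
    dt: float,
    edge_samples: int,
    global_baseline: float,
    window_samples: int,
) -> Event:
    seg = x[start:stop]
    if seg.size > 2 * edge_samples + 1:
        core = seg[edge_samples : seg.size - edge_samples]
    else:
        core = seg
    w0 = max(start - window_samples, 0)
    w1 = min(stop + window_samples, x.size)
    closed_near = x[w0:w1][~flags[w0:w1]]
    local = float(np.median(closed_near)) if closed_near.size >= 50 else global_baseline
    return Event(
        start_s=start * dt,
        end_s=stop * dt,
        level_pa=float(np.median(core)),
        mean_pa=float(np.mean(seg)),
        n_samples=int(seg.size),
        local_baseline_pa=local,
    )


def idealize(
    trace: CurrentTrace,
    k_sigma: float = 3.0,
    sigma_floor_pa: float = 0.02,
    edge_exclude_ms: float = 1.0,
) -> IdealizedTrace:
    """Noise-band idealization: open iff ``|I - baseline| > k_sigma*sigma``."""
    baseline, sigma = estimate_baseline(trace, sigma_floor_pa=sigma_floor_pa)
    half = k_sigma * sigma
    x = trace.samples
    flags = np.abs(x - baseline) > half
    edge_samples = int(round(edge_exclude_ms * 1e-3 * trace.sampling_rate))
    window_samples = int(round(0.5 * trace.sampling_rate))  # +/- 0.5 s
    events: list[Event] = []
    padded = np.concatenate([[False], flags, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    dt = trace.dt
    for s, e in zip(starts, stops):
        events.append(
            _event_from_run(
                x, flags, int(s), int(e), dt, edge_samples, baseline, window_samples
            )
        )
    return IdealizedTrace(
        open_flags=flags,
        baseline=baseline,
        noise_sigma=sigma,
        noise_band_halfwidth=half,
        events=tuple(events),
        samples=x,
        sampling_rate=trace.sampling_rate,
    )


def compute_po(ideal: IdealizedTrace, duration: float) -> float:
    """Open probability: (open samples * dt) / recording duration."""
    if not duration > 0:
        raise ValueError("duration must be > 0")
    po = ideal.n_open * ideal.dt / duration
    return float(min(max(po, 0.0), 1.0))


def _artifact(ideal: IdealizedTrace, event: Event, v_cis: float) -> bool:
    """True when the event's polarity opposes the holding potential."""
    return event.amplitude_pa * np.sign(v_cis) < 0


def compute_g_mean(ideal: IdealizedTrace, v_cis: float) -> Optional[float]:
    """Mean conductance (pS): Ohm's law on the average current over all
    open samples in correct-polarity events; ``None`` with no openings."""
    if v_cis == 0:
        raise ValueError("conductance is undefined at v_cis = 0 mV")
    keep = np.zeros_like(ideal.open_flags)
    dt = ideal.dt
    for ev in ideal.events:
        if not _artifact(ideal, ev, v_cis):
            i0 = int(round(ev.start_s / dt))
            i1 = int(round(ev.end_s / dt))
            keep[i0:i1] = True
    keep &= ideal.open_flags
    if not keep.any():
        return None
    mean_open = float(np.mean(ideal.samples[keep]))
    return conductance_ps(mean_open - ideal.baseline, v_cis)


def compute_g_max(
    ideal: IdealizedTrace, v_cis: float, min_dwell_ms: float = 10.0
) -> Optional[float]:
    """Maximal stable conductance (pS) among correct-polarity events
    lasting >= ``min_dwell_ms``.  The dwell rule is inclusive: an event of
    exactly the minimal duration qualifies.  ``None`` when no event
    qualifies.

    The maximal *level* is estimated as the mean amplitude of the top
    cluster of qualifying events (every event within 3 noise SDs of the
    largest), not the single largest event: a lone maximum over many
    noisy event amplitudes is biased upward, while the cluster mean reads
    off the stable level itself.  Levels separated by less than 3 noise
    SDs merge under this rule.
    """
    if v_cis == 0:
        raise ValueError("conductance is undefined at v_cis = 0 mV")
    min_dwell_s = min_dwell_ms * 1e-3
    amps = [
        abs(ev.amplitude_pa)
        for ev in ideal.events
        # durations are integer multiples of dt; tolerate float rounding
        if ev.duration_s >= min_dwell_s - 0.5 * ideal.dt
        and not _artifact(ideal, ev, v_cis)
    ]
    if not amps:
        return None
    amps_arr = np.asarray(amps)
    top = float(np.max(amps_arr))
    cluster = amps_arr[amps_arr >= top - 3 * ideal.noise_sigma]
    return conductance_ps(float(np.mean(cluster)), v_cis)


def amplitude_histogram(
    trace: CurrentTrace,
    bin_width_pa: float = 1.0,
    peak_prominence_frac: float = 0.05,
) -> AmplitudeHistogram:
    """All-sample current histogram with substate-peak detection.

    Peaks are local maxima of the counts whose prominence exceeds
    ``peak_prominence_frac`` of the modal count, reported as
    ``(level_pa, prominence)`` sorted by |level|.
    """
    if not bin_width_pa > 0:
        raise ValueError("bin_width_pa must be > 0")
    x = trace.samples
    lo = np.floor(np.min(x) / bin_width_pa) * bin_width_pa
    hi = np.ceil(np.max(x) / bin_width_pa) * bin_width_pa + bin_width_pa
    edges = np.arange(lo, hi + 0.5 * bin_width_pa, bin_width_pa)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width_pa])
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    padded = np.concatenate([[0], counts, [0]])
    pk, props = find_peaks(padded, prominence=peak_prominence_frac * counts.max())
    pk = pk - 1
    peaks = sorted(
        ((float(centers[i]), float(p)) for i, p in zip(pk, props["prominences"])),
        key=lambda lp: abs(lp[0]),
    )
    return AmplitudeHistogram(bin_edges=edges, counts=counts, peaks=tuple(peaks))


def analyze_trace(trace: CurrentTrace, config: Optional[RunConfig] = None) -> ChannelMetrics:
    """Full per-trace analysis: PSA, Po, G_mean, G_max and event count.

    A failing estimator (e.g. conductance at 0 mV, or no openings) leaves
    its field absent and records a warning; it never aborts the trace.
    """
    config = config if config is not None else RunConfig()
    warnings: list[str] = []
    psa = psa_of_trace(trace, BandExclusion.from_config(config)).psa
    ideal = idealize(
        trace,
        k_sigma=config.k_sigma,
        sigma_floor_pa=config.sigma_floor_pa,
        edge_exclude_ms=config.edge_exclude_ms,
    )
    po = compute_po(ideal, trace.duration)
    g_mean: Optional[float] = None
    g_max: Optional[float] = None
    if ideal.n_open == 0:
        warnings.append("no open samples: conductances absent")
    elif trace.v_cis == 0:
        warnings.append("v_cis = 0 mV: conductances undefined")
    else:
        g_mean = compute_g_mean(ideal, trace.v_cis)
        g_max = compute_g_max(ideal, trace.v_cis, min_dwell_ms=config.min_dwell_ms)
        if g_mean is None:
            warnings.append("all events are opposite-polarity artifacts")
        if g_max is None:
            warnings.append(
                f"no event lasted >= {config.min_dwell_ms} ms: g_max absent"
            )
    n_artifacts = sum(_artifact(ideal, ev, trace.v_cis) for ev in ideal.events) if trace.v_cis != 0 else 0
    if n_artifacts:
        warnings.append(f"{n_artifacts} opposite-polarity events excluded from conductances")
    for w in warnings:
        logger.warning("%s", w)
    return ChannelMetrics(
        psa=float(psa),
        po=float(po),
        g_mean=g_mean,
        g_max=g_max,
        n_events=len(ideal.events),
        condition=trace.condition,
        v_cis=trace.v_cis,
        baseline=ideal.baseline,
        noise_sigma=ideal.noise_sigma,
        warnings=tuple(warnings),
    )
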