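"""Power spectrum and the power-spectrum-area (PSA) activity statistic.

PSA is an integral statistic of channel activity: the one-sided power
spectral density of the mean-subtracted current is integrated over a
retained frequency band that excludes baseline drift (< 2 Hz), mains
contamination (near 50 Hz) and everything above the analog filter corner
(> 500 Hz).  Because gating fluctuations dominate the retained band, PSA
tracks total channel activity even when flickering and multiple
conductance levels defeat event-based analysis.

The default estimator is a full-record rectangular-window periodogram
(no Welch averaging): PSA is an integral whose expectation is
window-invariant, and a single long analysis window matches how the
statistic is used.  A Welch mode is available for smoother plots.

Normalization is Parseval-exact: the integral of the PSD over all
frequencies equals the sample variance of the mean-subtracted signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal as _signal

from .config import RunConfig
from .trace import CurrentTrace

__all__ = [
    "PowerSpectrum",
    "BandExclusion",
    "PsaResult",
    "periodogram",
    "apply_exclusions",
    "compute_psa",
    "psa_of_trace",
]


@dataclass
class PowerSpectrum:
    """One-sided PSD (pA^2/Hz) on an ascending frequency grid with a
    per-frequency retained mask."""

    freqs: np.ndarray
    psd: np.ndarray
    mask: np.ndarray
    record_duration: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.freqs.shape == self.psd.shape == self.mask.shape):
            raise ValueError("freqs, psd and mask must have identical shapes")
        if self.freqs[0] < 0 or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be ascending and non-negative")
        if np.any(self.psd < -0.0) and np.min(self.psd) < 0:
            raise ValueError("psd must be non-negative")

    def to_table(self) -> "np.ndarray":
        """(n, 3) array of (freq_hz, psd_pa2_per_hz, retained)."""
        return np.column_stack([self.freqs, self.psd, self.mask.astype(float)])


@dataclass(frozen=True)
class BandExclusion:
    """Frequency bands removed before integrating the spectrum.

    Retained support is ``[f_low, line_center - line_halfwidth) union
    (line_center + line_halfwidth, f_high]`` — the low bound and the line
    band are excluded inclusively, the ``f_high`` bin itself is retained
    (only frequencies strictly above it are dropped).  The DC bin is
    always excluded.
    """

    f_low: float = 2.0
    line_center: float = 50.0
    line_halfwidth: float = 1.0
    f_high: float = 500.0

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.line_center - self.line_halfwidth:
            raise ValueError("require 0 < f_low < line_center - line_halfwidth")
        if not self.line_center + self.line_halfwidth < self.f_high:
            raise ValueError("require line_center + line_halfwidth < f_high")

    @classmethod
    def from_config(cls, config: RunConfig) -> "BandExclusion":
        return cls(
            f_low=config.f_low,
            line_center=config.line_center,
            line_halfwidth=config.line_halfwidth,
            f_high=config.f_high,
        )


@dataclass
class PsaResult:
    """PSA (pA^2) with the spectrum it was integrated from."""

    psa: float
    retained_bandwidth: float
    spectrum: PowerSpectrum

    def __post_init__(self) -> None:
        if self.psa < 0:
            raise ValueError("psa must be >= 0")


def periodogram(
    trace: CurrentTrace,
    welch_nperseg: Optional[int] = None,
) -> PowerSpectrum:
    """One-sided periodogram of the mean-subtracted current.

    Rectangular window over the full record by default; pass
    ``welch_nperseg`` for a Welch (Hann, 50% overlap) estimate meant for
    plotting.  The discrete integral of the returned PSD over frequency
    recovers the sample variance (Parseval).
    """
    x = trace.samples
    if x.size < 2:
        raise ValueError("periodogram requires at least 2 samples")
    fs = trace.sampling_rate
    if welch_nperseg is None:
        freqs, psd = _signal.periodogram(
            x, fs=fs, window="boxcar", detrend="constant", scaling="density"
        )
    else:
        freqs, psd = _signal.welch(
            x, fs=fs, nperseg=welch_nperseg, detrend="constant", scaling="density"
        )
    mask = np.ones_like(freqs, dtype=bool)
    mask[0] = False  # DC carries no fluctuation information
    return PowerSpectrum(
        freqs=freqs, psd=psd, mask=mask, record_duration=trace.duration
    )


def apply_exclusions(spectrum: PowerSpectrum, bands: BandExclusion) -> PowerSpectrum:
    """Return a spectrum whose mask additionally excludes the drift, mains
    and above-corner bands; PSD values are untouched.  Idempotent."""
    f = spectrum.freqs
    keep = spectrum.mask.copy()
    keep &= f >= bands.f_low
    keep &= np.abs(f - bands.line_center) > bands.line_halfwidth
    keep &= f <= bands.f_high
    return replace(spectrum, mask=keep)


def _contiguous_runs(mask: np.ndarray) -> list[slice]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [slice(idx[s], idx[e] + 1) for s, e in zip(starts, ends)]


def compute_psa(spectrum: PowerSpectrum) -> PsaResult:
    """Trapezoidal integral of the PSD over the retained frequency set.

    Each contiguous retained run is integrated separately; the retained
    bandwidth is the summed frequency measure of the runs.
    """
    runs = _contiguous_runs(spectrum.mask)
    if not runs:
        raise ValueError("no retained frequency bins; cannot integrate")
    psa = 0.0
    bandwidth = 0.0
    for run in runs:
        f = spectrum.freqs[run]
        p = spectrum.psd[run]
        if f.size == 1:
            continue  # a single isolated bin has zero trapezoid measure
        psa += float(np.trapezoid(p, f))
        bandwidth += float(f[-1] - f[0])
    return PsaResult(psa=psa, retained_bandwidth=bandwidth, spectrum=spectrum)


def psa_of_trace(
    trace: CurrentTrace, bands: Optional[BandExclusion] = None
) -> PsaResult:
    """Periodogram -> band exclusion -> integration, in one call."""
    bands = bands if bands is not None else BandExclusion()
    return compute_psa(apply_exclusions(periodogram(trace), bands))
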