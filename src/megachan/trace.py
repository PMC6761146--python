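"""Core recording data model.

A :class:`CurrentTrace` is a uniformly sampled single-channel current
recording from a planar lipid bilayer (or any voltage-clamp setup that
reports current in pA), together with the acquisition metadata every
downstream stage needs: sampling rate, holding potential on the *cis*
side (*trans* grounded), the analog low-pass corner, and the pharmacological
condition the recording was made under.

Sign convention: current is positive when carried by cations flowing from
the *cis* to the *trans* compartment, so an open channel at a negative
holding potential produces a negative current deflection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

__all__ = ["ConditionLabel", "CurrentTrace", "validate_trace"]

#: recognized inhibitor tags
INHIBITORS = ("none", "Ba", "MgADP", "Gd", "EGTA", "BKA", "polyanion")

#: recognized protein-source tags
SOURCES = (
    "proteoliposome",
    "direct",
    "gel-eluted-monomer",
    "gel-eluted-dimer",
    "gel-eluted-oligomer",
)


@dataclass(frozen=True)
class ConditionLabel:
    """Pharmacological condition of a recording.

    Parameters
    ----------
    ca_mm :
        Total added Ca2+ (mM).
    bz423_mm :
        Bz-423 concentration (mM); a benzodiazepine agonist of the channel.
    phaso_mm :
        Phenylarsine oxide concentration (mM); a dithiol cross-linker agonist.
    inhibitor :
        Optional inhibitor tag (one of ``INHIBITORS``).
    source :
        Optional protein-source tag (one of ``SOURCES``).
    """

    ca_mm: float = 0.0
    bz423_mm: float = 0.0
    phaso_mm: float = 0.0
    inhibitor: str = "none"
    source: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("ca_mm", "bz423_mm", "phaso_mm"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.inhibitor not in INHIBITORS:
            raise ValueError(
                f"unknown inhibitor {self.inhibitor!r}; expected one of {INHIBITORS}"
            )
        if self.source is not None and self.source not in SOURCES:
            raise ValueError(
                f"unknown source {self.source!r}; expected one of {SOURCES}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CurrentTrace:
    """A uniformly sampled current recording.

    Attributes
    ----------
    samples :
        Current samples in pA.
    sampling_rate :
        Acquisition rate in Hz (10 kHz in the standard protocol).
    v_cis :
        Holding potential applied to the *cis* chamber in mV
        (*trans* grounded).
    condition :
        The pharmacological condition the trace was recorded under.
    filter_cutoff :
        Corner frequency of the analog low-pass filter in Hz (500 Hz in
        the standard protocol); must not exceed the Nyquist frequency.
    offset_note :
        A constant instrumental current offset (pA) known to be present,
        e.g. the junction current imposed by an ionic gradient.  ``None``
        means no offset is documented.
    """

    samples: np.ndarray
    sampling_rate: float
    v_cis: float = 0.0
    condition: ConditionLabel = field(default_factory=ConditionLabel)
    filter_cutoff: Optional[float] = None
    offset_note: Optional[float] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        problems = validate_trace(self)
        if problems:
            raise ValueError("invalid trace: " + "; ".join(problems))

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        """Record length in seconds (n_samples * dt)."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) * self.dt

    def with_samples(self, samples: np.ndarray) -> "CurrentTrace":
        """Copy of this trace with new samples, metadata unchanged."""
        return CurrentTrace(
            samples=np.asarray(samples, dtype=float),
            sampling_rate=self.sampling_rate,
            v_cis=self.v_cis,
            condition=self.condition,
            filter_cutoff=self.filter_cutoff,
            offset_note=self.offset_note,
        )


def validate_trace(trace: "CurrentTrace") -> list[str]:
    """Check every CurrentTrace invariant; return a list of violation
    descriptions (empty when the trace is valid).  Each message names the
    offending field and the rule it breaks.
    """
    problems: list[str] = []
    samples = np.asarray(trace.samples, dtype=float)
    if not (
        isinstance(trace.sampling_rate, (int, float))
        and math.isfinite(trace.sampling_rate)
        and trace.sampling_rate > 0
    ):
        problems.append(f"sampling_rate: must be finite and > 0, got {trace.sampling_rate}")
    if samples.ndim != 1:
        problems.append(f"samples: must be one-dimensional, got ndim={samples.ndim}")
    elif samples.size < 1:
        problems.append("samples: must contain at least 1 sample")
    else:
        bad = np.flatnonzero(~np.isfinite(samples))
        if bad.size:
            problems.append(
                f"samples: non-finite value at index {int(bad[0])}"
                f" ({bad.size} non-finite total)"
            )
    if not (isinstance(trace.v_cis, (int, float)) and math.isfinite(trace.v_cis)):
        problems.append(f"v_cis: must be finite, got {trace.v_cis}")
    if trace.filter_cutoff is not None:
        ok_rate = (
            isinstance(trace.sampling_rate, (int, float))
            and math.isfinite(trace.sampling_rate)
            and trace.sampling_rate > 0
        )
        if not (math.isfinite(trace.filter_cutoff) and trace.filter_cutoff > 0):
            problems.append(
                f"filter_cutoff: must be finite and > 0, got {trace.filter_cutoff}"
            )
        elif ok_rate and trace.filter_cutoff > trace.sampling_rate / 2:
            problems.append(
                "filter_cutoff: exceeds the Nyquist frequency "
                f"({trace.filter_cutoff} > {trace.sampling_rate / 2})"
            )
    if trace.offset_note is not None and not math.isfinite(trace.offset_note):
        problems.append(f"offset_note: must be finite, got {trace.offset_note}")
    return problems
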