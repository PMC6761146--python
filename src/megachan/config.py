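"""Run configuration.

A flat, YAML-serializable bag of every tunable the pipeline exposes:
spectral exclusion bands, idealization thresholds, histogram parameters,
the simulator scenario, the random seed and the output directory.
Defaults mirror the standard acquisition/analysis protocol (10 kHz
sampling, 500 Hz analog filter, 2/50/500 Hz exclusion bands, 10 ms
stability rule).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # spectral exclusion bands (Hz)
    f_low: float = 2.0
    line_center: float = 50.0
    line_halfwidth: float = 1.0
    f_high: float = 500.0
    # idealization
    k_sigma: float = 3.0
    min_dwell_ms: float = 10.0
    sigma_floor_pa: float = 0.02
    edge_exclude_ms: float = 1.0
    # amplitude histogram
    bin_width_pa: float = 1.0
    peak_prominence_frac: float = 0.05
    # simulator
    scenario: str = "fig3b"
    scenario_params: dict = field(default_factory=dict)
    # run plumbing
    seed: int = 0
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        for name in (
            "f_low",
            "line_halfwidth",
            "f_high",
            "k_sigma",
            "min_dwell_ms",
            "sigma_floor_pa",
            "edge_exclude_ms",
            "bin_width_pa",
            "peak_prominence_frac",
        ):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: Optional[str]) -> RunConfig:
    """Load a RunConfig from a YAML file; ``None`` gives the defaults."""
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str) -> str:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path
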