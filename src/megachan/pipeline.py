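"""Reproducible simulate -> analyze -> fit orchestration.

Each stage reads and writes plain-text artifacts (ATF/CSV traces, CSV
tables, JSON reports) plus a JSON run manifest that snapshots the
configuration, hashes every input and records per-stage timings, so a
run is fully reconstructable from its output directory.
"""

from __future__ import annotations

import dataclasses
import glob as _glob
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .fits import (
    TitrationTable,
    compare_conditions,
    hill_fit,
    iv_fit,
)
from .fixtures import (
    TITRATION_CA_MM,
    TITRATION_REPLICATES,
    fig3b_scenario,
    fixed_po_scenario,
    titration_template,
)
from .gating import ChannelMetrics, amplitude_histogram, analyze_trace
from .io import read_trace, write_trace
from .sim import simulate_scenario, simulate_titration
from .spectra import BandExclusion, apply_exclusions, periodogram
from .trace import ConditionLabel

__all__ = ["RunManifest", "cmd_simulate", "cmd_analyze", "cmd_fit", "run_all"]

logger = logging.getLogger(__name__)

METRICS_COLUMNS = [
    "file",
    "ca_mm",
    "bz423_mm",
    "phaso_mm",
    "inhibitor",
    "source",
    "v_cis",
    "psa_pa2",
    "po",
    "g_mean_ps",
    "g_max_ps",
    "n_events",
    "baseline_pa",
    "noise_sigma_pa",
    "warnings",
]


@dataclass
class RunManifest:
    stage: str
    config: dict
    seed: int
    version: str = __version__
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: list = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)

    def write(self, out_dir: str) -> str:
        path = os.path.join(out_dir, f"manifest_{self.stage}.json")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
        return path


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


#: scenario_params keys consumed by the simulate stage, not the scenario
_STAGE_KEYS = ("ca_mm", "replicates", "format")


def _scenario_from_config(config: RunConfig):
    params = {
        k: v for k, v in config.scenario_params.items() if k not in _STAGE_KEYS
    }
    name = config.scenario
    if name == "fig3b":
        return fig3b_scenario(**params)
    if name == "titration":
        n_hill = params.pop("n_hill", 1.37)
        return titration_template(n_hill, **params)
    if name == "two_state":
        g = params.pop("g_open_ps", 500.0)
        po = params.pop("po", 0.4)
        return fixed_po_scenario(g, po, **params)
    raise ValueError(f"unknown scenario {name!r}; expected fig3b/titration/two_state")


def cmd_simulate(config: RunConfig, out_dir: Optional[str] = None) -> list[str]:
    """Materialize the configured scenario as trace files; returns paths.

    ``fig3b`` and ``two_state`` emit a single recording; ``titration``
    emits the full 23-recording design (overridable via
    ``scenario_params: {ca_mm: [...], replicates: [...]}``).
    """
    out_dir = out_dir or config.out_dir
    t0 = time.perf_counter()
    scenario = _scenario_from_config(config)  # validate before writing anything
    os.makedirs(out_dir, exist_ok=True)
    fmt = str(config.scenario_params.get("format", "atf"))
    paths: list[str] = []
    if config.scenario == "titration":
        ca_list = list(config.scenario_params.get("ca_mm", TITRATION_CA_MM))
        reps = list(config.scenario_params.get("replicates", TITRATION_REPLICATES))
        traces = simulate_titration(scenario, ca_list, reps, seed=config.seed)
        k = 0
        for i, ca in enumerate(ca_list):
            for r in range(reps[i]):
                path = os.path.join(out_dir, f"titration_ca{ca:g}_r{r}.{fmt}")
                write_trace(traces[k], path, format=fmt)
                paths.append(path)
                k += 1
    else:
        trace = simulate_scenario(scenario, seed=config.seed)
        path = os.path.join(out_dir, f"{config.scenario}.{fmt}")
        write_trace(trace, path, format=fmt)
        paths.append(path)
    manifest = RunManifest(
        stage="simulate",
        config=config.to_dict(),
        seed=config.seed,
        outputs=paths,
        timings_s={"simulate": time.perf_counter() - t0},
    )
    manifest.write(out_dir)
    return paths


def _metrics_row(path: str, m: ChannelMetrics) -> dict:
    c = m.condition
    return {
        "file": os.path.basename(path),
        "ca_mm": c.ca_mm,
        "bz423_mm": c.bz423_mm,
        "phaso_mm": c.phaso_mm,
        "inhibitor": c.inhibitor,
        "source": c.source,
        "v_cis": m.v_cis,
        "psa_pa2": m.psa,
        "po": m.po,
        "g_mean_ps": m.g_mean,
        "g_max_ps": m.g_max,
        "n_events": m.n_events,
        "baseline_pa": m.baseline,
        "noise_sigma_pa": m.noise_sigma,
        "warnings": "; ".join(m.warnings),
    }


def cmd_analyze(
    inputs: Sequence[str] | str,
    config: Optional[RunConfig] = None,
    out_dir: Optional[str] = None,
    per_trace_outputs: bool = False,
) -> pd.DataFrame:
    """Analyze trace files into a metrics table (one row per readable
    trace).  Unreadable files are logged and flagged, not fatal; zero
    readable inputs is an error."""
    config = config if config is not None else RunConfig()
    if isinstance(inputs, str):
        paths = sorted(_glob.glob(inputs))
    else:
        paths = list(inputs)
    if not paths:
        raise ValueError("no input files matched")
    t0 = time.perf_counter()
    rows = []
    failures = []
    hashes = {}
    for path in paths:
        try:
            trace = read_trace(path)
            hashes[path] = _sha256(path)
            m = analyze_trace(trace, config)
        except Exception as exc:  # any per-file failure is recorded, not fatal
            logger.warning("failed to analyze %s: %s", path, exc)
            failures.append({"file": os.path.basename(path), "error": str(exc)})
            continue
        rows.append(_metrics_row(path, m))
        if per_trace_outputs and out_dir is not None:
            stem = os.path.splitext(os.path.basename(path))[0]
            spec = apply_exclusions(periodogram(trace), BandExclusion.from_config(config))
            pd.DataFrame(
                spec.to_table(), columns=["freq_hz", "psd_pa2_per_hz", "retained"]
            ).to_csv(os.path.join(out_dir, f"{stem}_spectrum.csv"), index=False)
            hist = amplitude_histogram(
                trace, config.bin_width_pa, config.peak_prominence_frac
            )
            pd.DataFrame(
                {"bin_center_pa": hist.bin_centers, "count": hist.counts}
            ).to_csv(os.path.join(out_dir, f"{stem}_histogram.csv"), index=False)
    if not rows:
        raise RuntimeError("no input file could be analyzed")
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        out_csv = os.path.join(out_dir, "metrics.csv")
        df.to_csv(out_csv, index=False)
        outputs = [out_csv]
        if failures:
            fail_csv = os.path.join(out_dir, "failures.csv")
            pd.DataFrame(failures).to_csv(fail_csv, index=False)
            outputs.append(fail_csv)
        RunManifest(
            stage="analyze",
            config=config.to_dict(),
            seed=config.seed,
            inputs=hashes,
            outputs=outputs,
            timings_s={"analyze": time.perf_counter() - t0},
        ).write(out_dir)
    return df


def _metrics_from_frame(df: pd.DataFrame) -> list[ChannelMetrics]:
    out = []
    for _, row in df.iterrows():
        cond = ConditionLabel(
            ca_mm=float(row.get("ca_mm", 0.0)),
            bz423_mm=float(row.get("bz423_mm", 0.0)),
            phaso_mm=float(row.get("phaso_mm", 0.0)),
            inhibitor=str(row.get("inhibitor", "none")),
            source=None if pd.isna(row.get("source")) else str(row.get("source")),
        )
        out.append(
            ChannelMetrics(
                psa=float(row["psa_pa2"]),
                po=float(row["po"]),
                g_mean=None if pd.isna(row.get("g_mean_ps")) else float(row["g_mean_ps"]),
                g_max=None if pd.isna(row.get("g_max_ps")) else float(row["g_max_ps"]),
                n_events=int(row.get("n_events", 0)),
                condition=cond,
                v_cis=float(row.get("v_cis", 0.0)),
            )
        )
    return out


def _titration_table(df: pd.DataFrame, statistic: str) -> TitrationTable:
    col = {"PSA": "psa_pa2", "Po": "po", "G_mean": "g_mean_ps", "G_max": "g_max_ps"}[
        statistic
    ]
    grouped = df.dropna(subset=[col]).groupby("ca_mm")[col]
    agg = grouped.agg(["mean", "sem", "count"]).reset_index()
    sem = agg["sem"].fillna(0.0).to_numpy()
    return TitrationTable(
        ca_mm=agg["ca_mm"].to_numpy(),
        value=agg["mean"].to_numpy(),
        sem=sem,
        n=agg["count"].to_numpy(),
        statistic=statistic,
    )


def cmd_fit(
    metrics: pd.DataFrame | str,
    config: Optional[RunConfig] = None,
    out_dir: Optional[str] = None,
) -> dict:
    """Fit stage: Hill dose-response for PSA and Po (when >= 4 positive
    Ca2+ concentrations are present), a linear I-V fit (when recordings
    span multiple voltages), and pairwise condition comparisons (when
    >= 2 groups are present).  Returns a dict of results; insufficient
    data for a given fit is skipped with a logged reason."""
    config = config if config is not None else RunConfig()
    t0 = time.perf_counter()
    df = pd.read_csv(metrics) if isinstance(metrics, str) else metrics
    results: dict = {}
    for statistic in ("PSA", "Po"):
        n_ca = df.loc[df["ca_mm"] > 0, "ca_mm"].nunique()
        if n_ca >= 4:
            table = _titration_table(df, statistic)
            results[f"hill_{statistic.lower()}"] = hill_fit(table)
        else:
            logger.info(
                "Hill fit for %s skipped: %d positive Ca2+ concentrations (< 4)",
                statistic,
                n_ca,
            )
    if df["v_cis"].nunique() >= 3:
        sub = df.dropna(subset=["g_mean_ps"])
        points = [
            (float(v), float(v * g / 1000.0))
            for v, g in zip(sub["v_cis"], sub["g_mean_ps"])
        ]
        if len(points) >= 3:
            results["iv"] = iv_fit(points, gradient_offset="auto")
    groups = df.groupby(["ca_mm", "bz423_mm", "phaso_mm", "inhibitor"]).ngroups
    if groups >= 2:
        results["comparisons"] = compare_conditions(_metrics_from_frame(df))
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        outputs = []
        report = {}
        for key in ("hill_psa", "hill_po"):
            if key in results:
                report[key] = results[key].to_dict()
        if "iv" in results:
            report["iv"] = results["iv"].to_dict()
            iv_csv = os.path.join(out_dir, "iv_points.csv")
            pd.DataFrame(
                {
                    "v_mv": results["iv"].v_mv,
                    "i_pa": results["iv"].i_pa,
                    "i_corrected_pa": results["iv"].i_corrected_pa,
                }
            ).to_csv(iv_csv, index=False)
            outputs.append(iv_csv)
        fit_json = os.path.join(out_dir, "fits.json")
        with open(fit_json, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        outputs.append(fit_json)
        if "comparisons" in results:
            comp_csv = os.path.join(out_dir, "comparisons.csv")
            results["comparisons"].to_csv(comp_csv, index=False)
            outputs.append(comp_csv)
        RunManifest(
            stage="fit",
            config=config.to_dict(),
            seed=config.seed,
            outputs=outputs,
            timings_s={"fit": time.perf_counter() - t0},
        ).write(out_dir)
    return results


def run_all(config: RunConfig, out_dir: Optional[str] = None) -> dict:
    """simulate -> analyze -> fit in one deterministic run."""
    out_dir = out_dir or config.out_dir
    paths = cmd_simulate(config, out_dir)
    df = cmd_analyze(paths, config, out_dir)
    return cmd_fit(df, config, out_dir)
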