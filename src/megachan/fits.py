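"""Dose-response, current-voltage and nonparametric group statistics.

* :func:`hill_fit` — weighted least-squares fit of the Hill equation
  ``y = y_max * ca^n / (k_half^n + ca^n)`` to an activity statistic
  (PSA, Po or a conductance) versus Ca2+ concentration.  ``k_half`` and
  ``n`` are optimized in log-space (positivity without constraints), with
  jittered restarts; the Hill coefficient is reported with its SE from
  the fit covariance.
* :func:`iv_fit` — ordinary least squares of current on voltage with
  constant-offset correction (either fitted as the intercept or supplied,
  e.g. the ~13 pA shift a salt gradient imposes).
* :func:`mann_whitney` — two-sided Mann-Whitney U with exact small-sample
  enumeration (n1+n2 <= 12, no ties) and a tie-corrected normal
  approximation otherwise.
* :func:`compare_conditions` — pairwise Mann-Whitney comparisons of PSA
  and Po between condition groups, unadjusted for multiplicity (flagged
  as such in the output).
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .gating import ChannelMetrics

__all__ = [
    "TitrationTable",
    "HillFit",
    "IVFit",
    "MWResult",
    "hill_equation",
    "hill_fit",
    "iv_fit",
    "mann_whitney",
    "compare_conditions",
    "titration_from_metrics",
]


# ---------------------------------------------------------------------------
# tables and results
# ---------------------------------------------------------------------------

STATISTIC_NAMES = ("PSA", "Po", "G_mean", "G_max")


@dataclass
class TitrationTable:
    """Aggregated dose-response data: one row per Ca2+ concentration."""

    ca_mm: np.ndarray
    value: np.ndarray
    sem: Optional[np.ndarray]
    n: np.ndarray
    statistic: str

    def __post_init__(self) -> None:
        self.ca_mm = np.asarray(self.ca_mm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if np.any(self.sem < 0):
                raise ValueError("SEM must be >= 0")
        if self.statistic not in STATISTIC_NAMES:
            raise ValueError(f"statistic must be one of {STATISTIC_NAMES}")
        if np.any(self.n < 1):
            raise ValueError("replicate counts must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        d = {"ca_mm": self.ca_mm, "value": self.value, "n": self.n}
        if self.sem is not None:
            d["sem"] = self.sem
        return pd.DataFrame(d)


@dataclass
class HillFit:
    y_max: float
    k_half: float
    n_hill: float
    se_n: float
    r2: float
    converged: bool
    n_points: int
    statistic: str = ""
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "y_max": self.y_max,
            "k_half_mm": self.k_half,
            "n_hill": self.n_hill,
            "se_n_hill": self.se_n,
            "r2": self.r2,
            "converged": self.converged,
            "n_points": self.n_points,
            "message": self.message,
        }


@dataclass
class IVFit:
    slope_conductance: float  # pS
    offset: float  # pA
    r2: float
    v_mv: np.ndarray
    i_pa: np.ndarray
    i_corrected_pa: np.ndarray
    offset_mode: str = "auto"

    def to_dict(self) -> dict:
        return {
            "slope_conductance_ps": self.slope_conductance,
            "offset_pa": self.offset,
            "r2": self.r2,
            "offset_mode": self.offset_mode,
        }


@dataclass
class MWResult:
    u_statistic: float
    p_two_sided: float
    n1: int
    n2: int
    method: str  # "exact" | "normal-approx"


# ---------------------------------------------------------------------------
# Hill fitting
# ---------------------------------------------------------------------------

def hill_equation(ca, y_max, k_half, n_hill):
    ca = np.asarray(ca, dtype=float)
    xn = (ca / k_half) ** n_hill
    return y_max * xn / (1.0 + xn)


def _hill_model_log(ca, y_max, log_k, log_n):
    return hill_equation(ca, y_max, np.exp(log_k), np.exp(log_n))


def hill_fit(
    table: TitrationTable,
    max_restarts: int = 20,
    fix_n: Optional[float] = None,
    weighting: str = "pooled",
) -> HillFit:
    """Fit the Hill equation to a titration table.

    Rows at ca = 0 are excluded (the model forces y = 0 there).

    ``weighting`` selects how per-concentration SEMs enter the fit:

    * ``"pooled"`` (default) — a common coefficient of variation is pooled
      across concentrations and each point is weighted by
      1/(CV*mean/sqrt(n))^2.  SEMs estimated from 3-4 replicates are too
      noisy to use raw, and channel-activity scatter between independent
      membranes is multiplicative, so a pooled relative-error model gives
      stable weights.
    * ``"sem"`` — raw 1/SEM^2 weights (zero SEMs floored to the smallest
      positive one).
    * ``"none"`` — unweighted.

    The covariance is scaled by the reduced chi-square, so the reported SE
    of the Hill coefficient reflects the actual residual scatter.
    ``fix_n`` pins the Hill coefficient (e.g. 1 for a rectangular
    hyperbola) and fits only ``y_max`` and ``k_half``.
    """
    if weighting not in ("pooled", "sem", "none"):
        raise ValueError("weighting must be 'pooled', 'sem' or 'none'")
    keep = (table.ca_mm > 0) & np.isfinite(table.value)
    ca = table.ca_mm[keep]
    y = table.value[keep]
    sem = table.sem[keep] if table.sem is not None else None
    nrep = table.n[keep]
    n_free = 2 if fix_n is not None else 3
    if np.unique(ca).size < max(4, n_free + 1):
        raise ValueError("hill_fit requires >= 4 distinct positive ca values")
    if sem is None or weighting == "none" or not np.any(sem > 0):
        sigma = None
    elif weighting == "sem":
        pos = sem[sem > 0]
        sigma = np.where(sem > 0, sem, pos.min())
    else:  # pooled
        with np.errstate(divide="ignore", invalid="ignore"):
            cvs = sem * np.sqrt(nrep) / np.abs(y)
        cvs = cvs[np.isfinite(cvs) & (cvs > 0)]
        cv = float(np.median(cvs)) if cvs.size else 0.0
        if cv > 0:
            sigma = cv * np.abs(y) / np.sqrt(nrep)
            pos = sigma[sigma > 0]
            sigma = np.where(sigma > 0, sigma, pos.min())  # guard y == 0 rows
        else:
            sigma = None

    if fix_n is not None:
        def model(ca_, y_max, log_k):
            return hill_equation(ca_, y_max, np.exp(log_k), fix_n)
    else:
        model = _hill_model_log

    # initialization: y_max from the plateau, k_half by interpolating the
    # half-maximal crossing, n = 1
    y_max0 = float(np.max(y))
    half = y_max0 / 2.0
    order = np.argsort(ca)
    k0 = float(np.interp(half, y[order], ca[order])) if np.any(y > half) else float(np.median(ca))
    k0 = min(max(k0, ca.min() / 10), ca.max() * 10)
    p0 = np.array([y_max0, np.log(k0), 0.0])[:n_free]
    jitter_scale = np.array([0.2 * abs(p0[0]) + 1e-12, 0.5, 0.5])[:n_free]

    rng = np.random.default_rng(12345)
    best = None
    message = ""
    for attempt in range(max_restarts + 1):
        start = p0 if attempt == 0 else p0 + rng.normal(0, jitter_scale)
        try:
            popt, pcov = optimize.curve_fit(
                model,
                ca,
                y,
                p0=start,
                sigma=sigma,
                absolute_sigma=False,
                maxfev=20000,
            )
        except RuntimeError as exc:
            message = str(exc)
            continue
        resid = (y - model(ca, *popt)) / (sigma if sigma is not None else 1.0)
        ssq = float(np.sum(resid**2))
        if best is None or ssq < best[2] - 1e-12:
            best = (popt, pcov, ssq)
    if best is None:
        return HillFit(
            y_max=math.nan,
            k_half=math.nan,
            n_hill=math.nan,
            se_n=math.nan,
            r2=math.nan,
            converged=False,
            n_points=int(ca.size),
            statistic=table.statistic,
            message=f"no restart converged: {message}",
        )
    popt, pcov, _ = best
    y_max, k_half = float(popt[0]), float(np.exp(popt[1]))
    if fix_n is not None:
        n_hill, se_n = float(fix_n), 0.0
    else:
        n_hill = float(np.exp(popt[2]))
        # delta method: se(n) = n * se(log n)
        se_log_n = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else math.nan
        se_n = n_hill * se_log_n
        if not math.isfinite(se_n) and best[2] <= 1e-16 * max(1.0, float(np.sum(y**2))):
            se_n = 0.0  # an exact interpolation has a singular covariance
    w = 1.0 / sigma**2 if sigma is not None else np.ones_like(y)
    yhat = model(ca, *popt)
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    return HillFit(
        y_max=y_max,
        k_half=k_half,
        n_hill=n_hill,
        se_n=se_n,
        r2=r2,
        converged=bool(np.isfinite(se_n) and np.isfinite(n_hill)),
        n_points=int(ca.size),
        statistic=table.statistic,
    )


# ---------------------------------------------------------------------------
# I-V fitting
# ---------------------------------------------------------------------------

def iv_fit(
    points: Sequence[tuple[float, float]],
    gradient_offset: float | str = "auto",
) -> IVFit:
    """Linear current-voltage fit with constant-offset correction.

    ``gradient_offset='auto'`` estimates the offset as the OLS intercept;
    a numeric value is subtracted from every current before a
    through-origin refit of the slope.  ``slope_conductance`` is
    1000 * slope (pA/mV -> pS).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("iv_fit requires >= 3 (v_mv, i_pa) points")
    v, i = pts[:, 0], pts[:, 1]
    if np.unique(v).size < 2:
        raise ValueError("all voltages identical: I-V slope is unidentifiable")
    if gradient_offset == "auto":
        slope, intercept = np.polyfit(v, i, 1)
        offset = float(intercept)
        mode = "auto"
    else:
        offset = float(gradient_offset)
        ic = i - offset
        slope = float(np.sum(v * ic) / np.sum(v * v))
        mode = "fixed"
    i_corr = i - offset
    yhat = slope * v + offset
    ss_res = float(np.sum((i - yhat) ** 2))
    ss_tot = float(np.sum((i - np.mean(i)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return IVFit(
        slope_conductance=float(1000.0 * slope),
        offset=offset,
        r2=float(min(max(r2, 0.0), 1.0)),
        v_mv=v,
        i_pa=i,
        i_corrected_pa=i_corr,
        offset_mode=mode,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 12


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a, by midrank summation."""
    n1, n2 = a.size, b.size
    ranks = stats.rankdata(np.concatenate([a, b]))
    r1 = float(np.sum(ranks[:n1]))
    return r1 - n1 * (n1 + 1) / 2.0


@functools.lru_cache(maxsize=64)
def _exact_null_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of U over all C(n1+n2, n1) group assignments of
    the ranks 1..n1+n2 (no ties): counts[u] = #assignments with U = u."""
    total = n1 + n2
    counts = np.zeros(n1 * n2 + 1, dtype=np.int64)
    base = n1 * (n1 + 1) // 2
    for combo in itertools.combinations(range(1, total + 1), n1):
        u = sum(combo) - base
        counts[u] += 1
    return counts


def mann_whitney(a: Iterable[float], b: Iterable[float]) -> MWResult:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of rank assignments when
    ``n1 + n2 <= 12`` and the pooled sample has no ties; otherwise a
    tie-corrected normal approximation.  The two-sided p is
    ``min(1, 2 * min(P(U <= u), P(U >= u)))`` under the exact null.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if n1 + n2 <= _EXACT_LIMIT and not has_ties:
        counts = _exact_null_counts(n1, n2)
        total = counts.sum()
        ui = int(round(u))
        p_le = counts[: ui + 1].sum() / total
        p_ge = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mu = n1 * n2 / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts)
        n = n1 + n2
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (u - mu) / math.sqrt(var)
            p = float(special.erfc(abs(z) / math.sqrt(2)))
        method = "normal-approx"
    return MWResult(
        u_statistic=float(u), p_two_sided=float(p), n1=int(n1), n2=int(n2), method=method
    )


def compare_conditions(
    metrics: Sequence[ChannelMetrics],
    grouping: str = "label",
    statistics: Sequence[str] = ("psa", "po"),
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of per-trace statistics between
    condition groups.

    ``grouping`` is a ConditionLabel field (``ca_mm``, ``bz423_mm``,
    ``phaso_mm``, ``inhibitor``, ``source``) or ``"label"`` for the full
    condition tuple.  P-values are unadjusted for multiplicity (as is
    conventional for these pairwise channel-activity comparisons); the
    output carries an explicit ``adjusted`` column set to False.
    """
    cond_fields = ("ca_mm", "bz423_mm", "phaso_mm", "inhibitor", "source")
    if grouping != "label" and grouping not in cond_fields:
        raise ValueError(f"unknown grouping field {grouping!r}")

    def key(m: ChannelMetrics):
        if grouping == "label":
            c = m.condition
            return (c.ca_mm, c.bz423_mm, c.phaso_mm, c.inhibitor, c.source)
        return getattr(m.condition, grouping)

    groups: dict = {}
    for m in metrics:
        groups.setdefault(key(m), []).append(m)
    if len(groups) < 2:
        raise ValueError("compare_conditions requires >= 2 groups")
    rows = []
    names = sorted(groups, key=str)
    for ga, gb in itertools.combinations(names, 2):
        for statistic in statistics:
            va = [getattr(m, statistic) for m in groups[ga] if getattr(m, statistic) is not None]
            vb = [getattr(m, statistic) for m in groups[gb] if getattr(m, statistic) is not None]
            if not va or not vb:
                continue
            res = mann_whitney(va, vb)
            rows.append(
                {
                    "group_a": str(ga),
                    "group_b": str(gb),
                    "statistic": statistic,
                    "u": res.u_statistic,
                    "p": res.p_two_sided,
                    "n1": res.n1,
                    "n2": res.n2,
                    "method": res.method,
                    "adjusted": False,
                }
            )
    return pd.DataFrame(rows)


def titration_from_metrics(
    metrics: Sequence[ChannelMetrics], statistic: str = "PSA"
) -> TitrationTable:
    """Aggregate per-trace metrics to mean +/- SEM per Ca2+ concentration."""
    attr = {"PSA": "psa", "Po": "po", "G_mean": "g_mean", "G_max": "g_max"}[statistic]
    by_ca: dict[float, list[float]] = {}
    for m in metrics:
        v = getattr(m, attr)
        if v is not None:
            by_ca.setdefault(m.condition.ca_mm, []).append(float(v))
    cas = sorted(by_ca)
    values = np.array([np.mean(by_ca[c]) for c in cas])
    ns = np.array([len(by_ca[c]) for c in cas])
    sems = np.array(
        [
            np.std(by_ca[c], ddof=1) / np.sqrt(len(by_ca[c])) if len(by_ca[c]) > 1 else 0.0
            for c in cas
        ]
    )
    return TitrationTable(
        ca_mm=np.array(cas), value=values, sem=sems, n=ns, statistic=statistic
    )
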