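"""Contraction and respirometry analysis of area and O2 time series.

Covers the behavioural side of the study: converting between percent air
saturation and µM dissolved O2, detecting contraction events as dips in the
normalized projected-area trace, comparing contraction rates across stable
O2 levels with a Poisson log-linear model (fixed per-individual intercepts,
log-exposure offset), and quantifying the extra O2 uptake during
contraction phases with a circular-shift permutation test.

A contraction event is a maximal interval in which the area, normalized by
a rolling upper-quantile baseline, stays below 1 − θ_sub; events whose
trough drops below 1 − θ_full are classed full-body, the rest
sub-contractions.  The default thresholds θ_full = 0.5 and θ_sub = 0.1 are
package conventions (the distinction between full-body and local
sub-contractions is qualitative in the source observations) and are
exposed in the config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from hypoxiscan.oxygen import (
    OxygenConditions,
    o2_saturation_uM,
    percent_as_to_uM,
    uM_to_percent_as,
)

__all__ = [
    "OxygenConditions",
    "o2_saturation_uM",
    "percent_as_to_uM",
    "uM_to_percent_as",
    "ContractionEvent",
    "DetectorConfig",
    "detect_contractions",
    "contraction_rate",
    "RateModelFit",
    "fit_rate_model",
    "respiration_rate",
    "phase_coupled_uptake",
    "read_trace_csv",
    "write_events_tsv",
]


# ---------------------------------------------------------------------------
# contraction detection


@dataclass(frozen=True)
class ContractionEvent:
    """One contraction: area dip below the rolling baseline."""

    start_s: float
    trough_s: float
    end_s: float
    amplitude: float  # 1 - min normalized area, in [0, 1]
    klass: str  # "full_body" | "sub"

    def __post_init__(self) -> None:
        if not (self.start_s <= self.trough_s <= self.end_s):
            raise ValueError("event must satisfy start <= trough <= end")


@dataclass(frozen=True)
class DetectorConfig:
    smooth_samples: int = 5
    baseline_window_s: float = 7200.0  # 2 h rolling baseline
    baseline_quantile: float = 0.90
    theta_full: float = 0.5
    theta_sub: float = 0.1
    merge_gap_s: float = 300.0  # events closer than 5 min are merged


def _as_trace(trace: pd.DataFrame, value_col: str = "value") -> tuple[np.ndarray, np.ndarray]:
    ts = np.asarray(trace["timestamp_s"], dtype=float)
    col = value_col if value_col in trace.columns else "area_px"
    values = np.asarray(trace[col], dtype=float)
    if len(ts) > 1 and not np.all(np.diff(ts) > 0):
        raise ValueError("timestamps must be strictly increasing")
    return ts, values


def detect_contractions(
    trace: pd.DataFrame, config: DetectorConfig = DetectorConfig()
) -> list[ContractionEvent]:
    """Detect contraction events in an area trace.

    ``trace`` has columns (timestamp_s, value) — or area_px — with NaN for
    missing frames.  The trace is median-smoothed, normalized by a rolling
    upper-quantile baseline, and thresholded; nearby sub-threshold runs are
    merged.  An all-missing trace yields an empty list.
    """
    ts, raw = _as_trace(trace)
    if np.all(~np.isfinite(raw)):
        return []
    n = len(ts)
    if n < 2:
        return []
    dt = float(np.median(np.diff(ts)))
    series = pd.Series(raw)
    smooth = series.rolling(
        config.smooth_samples, center=True, min_periods=1
    ).median()
    win = max(3, int(round(config.baseline_window_s / dt)))
    baseline = smooth.rolling(win, center=True, min_periods=1).quantile(
        config.baseline_quantile
    )
    norm = (smooth / baseline).to_numpy()

    below = np.isfinite(norm) & (norm < 1.0 - config.theta_sub)
    # maximal runs of below-threshold samples
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    # merge runs separated by less than merge_gap
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and ts[run[0]] - ts[merged[-1][1]] < config.merge_gap_s:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    events = []
    for i0, i1 in merged:
        seg = norm[i0 : i1 + 1]
        k = int(np.nanargmin(seg))
        amplitude = float(1.0 - seg[k])
        klass = "full_body" if seg[k] < 1.0 - config.theta_full else "sub"
        events.append(
            ContractionEvent(
                start_s=float(ts[i0]),
                trough_s=float(ts[i0 + k]),
                end_s=float(ts[i1]),
                amplitude=amplitude,
                klass=klass,
            )
        )
    return events


def contraction_rate(
    events: Iterable[ContractionEvent],
    interval_s: tuple[float, float],
    class_filter: Optional[str] = None,
) -> float:
    """Events per day within a time interval, optionally by class."""
    t0, t1 = interval_s
    if t1 <= t0:
        raise ValueError("interval must have positive length")
    count = sum(
        1
        for ev in events
        if t0 <= ev.trough_s < t1
        and (class_filter is None or ev.klass == class_filter)
    )
    return count / ((t1 - t0) / 86400.0)


# ---------------------------------------------------------------------------
# Poisson log-linear rate model


@dataclass
class RateModelFit:
    """Fixed-intercept Poisson log-linear model of contraction counts."""

    level_effects: dict[str, float]  # log-rate relative to reference level
    individual_intercepts: dict[str, float]
    reference_level: str
    loglik_fit: float
    loglik_null: float
    lrt_stat: float
    df: int
    p_value: float
    posthoc: pd.DataFrame = field(repr=False, default=None)

    @property
    def rate_ratio(self) -> dict[str, float]:
        return {k: math.exp(v) for k, v in self.level_effects.items()}


_ZERO_SENTINEL = float("-inf")


def fit_rate_model(
    counts: pd.DataFrame,
    alpha: float = 0.05,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> RateModelFit:
    """Compare contraction rates across O2-level groups.

    ``counts`` needs columns (individual, level, count, exposure_days), one
    row per individual × level.  The model is
    log E[count] = log(exposure) + α_individual + β_level, fitted by IRLS
    maximum likelihood; the likelihood-ratio test compares it against the
    null with all β_level equal, and the post-hoc table holds all pairwise
    level contrasts with Holm-adjusted Wald p-values.  A level whose counts
    are all zero sits on the boundary of the parameter space; its effect is
    reported as -inf.
    """
    required = {"individual", "level", "count", "exposure_days"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if (counts["exposure_days"] <= 0).any():
        raise ValueError("exposures must be > 0")
    levels = sorted(counts["level"].astype(str).unique())
    if len(levels) < 2:
        raise ValueError("need at least two O2-level groups")
    individuals = sorted(counts["individual"].astype(str).unique())

    y = counts["count"].to_numpy(dtype=float)
    exposure = counts["exposure_days"].to_numpy(dtype=float)
    ind = counts["individual"].astype(str).to_numpy()
    lvl = counts["level"].astype(str).to_numpy()

    X_ind = np.column_stack([(ind == i).astype(float) for i in individuals])
    # reference = level with the largest total count, so the baseline is
    # never an all-zero boundary group
    totals = counts.groupby(counts["level"].astype(str))["count"].sum()
    ref = str(totals.sort_values(ascending=False, kind="stable").index[0])
    non_ref = [l for l in levels if l != ref]
    X_lvl = np.column_stack([(lvl == l).astype(float) for l in non_ref])
    X_full = np.hstack([X_ind, X_lvl]) if len(levels) > 1 else X_ind

    zero_levels = {
        l for l in levels if counts.loc[counts["level"].astype(str) == l, "count"].sum() == 0
    }

    import warnings

    with warnings.catch_warnings():
        # boundary fits (all-zero groups, saturated designs) are legitimate
        # here; their effects are reported as -inf sentinels below
        warnings.simplefilter("ignore")
        fit = sm.GLM(
            y, X_full, family=sm.families.Poisson(), exposure=exposure
        ).fit(tol=tol, maxiter=maxiter)
        null = sm.GLM(
            y, X_ind, family=sm.families.Poisson(), exposure=exposure
        ).fit(tol=tol, maxiter=maxiter)
    if not fit.converged or not null.converged:
        if not zero_levels:  # boundary fits legitimately hit maxiter
            raise RuntimeError(
                f"IRLS did not converge (fit: {fit.converged}, "
                f"null: {null.converged}) after {maxiter} iterations"
            )

    loglik_fit = float(fit.llf)
    loglik_null = float(null.llf)
    lrt = max(0.0, 2.0 * (loglik_fit - loglik_null))
    df = len(levels) - 1
    p = float(scipy.stats.chi2.sf(lrt, df))

    k_ind = len(individuals)
    params = fit.params
    cov = np.asarray(fit.cov_params())
    beta = {ref: 0.0}
    beta_index: dict[str, int | None] = {ref: None}
    for i, l in enumerate(non_ref):
        beta[l] = float(params[k_ind + i])
        beta_index[l] = k_ind + i

    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            est = beta[a] - beta[b]
            contrast = np.zeros(X_full.shape[1])
            if beta_index[a] is not None:
                contrast[beta_index[a]] = 1.0
            if beta_index[b] is not None:
                contrast[beta_index[b]] -= 1.0
            se = float(np.sqrt(contrast @ cov @ contrast))
            if a in zero_levels or b in zero_levels:
                est = _ZERO_SENTINEL if a in zero_levels else -_ZERO_SENTINEL
                z = float("nan")
                p_raw = 1.0 if (a in zero_levels and b in zero_levels) else 0.0
            elif se == 0:
                z = float("nan")
                p_raw = 1.0
            else:
                z = est / se
                p_raw = float(2.0 * scipy.stats.norm.sf(abs(z)))
            rows.append(
                {"level_a": a, "level_b": b, "log_rate_ratio": est,
                 "se": se, "z": z, "p_raw": p_raw}
            )
    posthoc = pd.DataFrame(rows)
    if len(posthoc):
        posthoc["p_holm"] = multipletests(posthoc["p_raw"], method="holm")[1]
        posthoc["significant"] = posthoc["p_holm"] < alpha

    effects = {
        l: (_ZERO_SENTINEL if l in zero_levels else beta[l]) for l in levels
    }
    intercepts = {
        ind_name: float(params[i]) for i, ind_name in enumerate(individuals)
    }
    return RateModelFit(
        level_effects=effects,
        individual_intercepts=intercepts,
        reference_level=ref,
        loglik_fit=loglik_fit,
        loglik_null=loglik_null,
        lrt_stat=lrt,
        df=df,
        p_value=p,
        posthoc=posthoc,
    )


# ---------------------------------------------------------------------------
# respirometry


def respiration_rate(o2: pd.DataFrame, window: int) -> pd.DataFrame:
    """Rolling O2 uptake rate (µM/hr) from a dissolved-O2 trace.

    For each centred window of ``window`` samples the least-squares slope
    of O2 against time is computed; the sign convention is uptake > 0 when
    O2 declines.  Returns a DataFrame (timestamp_s, uptake_uM_per_hr) with
    NaN at the edges where the window does not fit.
    """
    if window < 3:
        raise ValueError("window must span at least 3 samples")
    ts, values = _as_trace(o2)
    n = len(ts)
    if window > n:
        raise ValueError(f"window ({window}) larger than trace ({n})")
    t_hr = ts / 3600.0
    half = window // 2
    rate = np.full(n, np.nan)
    for i in range(half, n - (window - 1 - half)):
        sl = slice(i - half, i - half + window)
        tt = t_hr[sl]
        yy = values[sl]
        tbar = tt.mean()
        denom = np.sum((tt - tbar) ** 2)
        slope = np.sum((tt - tbar) * (yy - yy.mean())) / denom
        rate[i] = -slope  # uptake positive when O2 declines
    return pd.DataFrame({"timestamp_s": ts, "uptake_uM_per_hr": rate})


def phase_coupled_uptake(
    rates: pd.DataFrame,
    events: Sequence[ContractionEvent],
    n_shifts: int = 999,
    seed: int = 0,
) -> dict:
    """Contrast mean O2 uptake during contraction vs expanded phases.

    Phase labels derive from the event intervals; the null distribution
    circularly shifts the label vector relative to the rate series, which
    preserves both the rate autocorrelation and the phase durations.
    p = (1 + #{|shifted diff| >= |observed|}) / (n_shifts + 1).
    """
    if not events:
        raise ValueError(
            "no contraction events: phase contrast is undefined"
        )
    ts = np.asarray(rates["timestamp_s"], dtype=float)
    rr = np.asarray(rates["uptake_uM_per_hr"], dtype=float)
    ok = np.isfinite(rr)
    in_phase = np.zeros(len(ts), dtype=bool)
    for ev in events:
        in_phase |= (ts >= ev.start_s) & (ts <= ev.end_s)

    def contrast(labels: np.ndarray) -> float:
        sel = ok & labels
        other = ok & ~labels
        if not sel.any() or not other.any():
            return float("nan")
        return float(rr[sel].mean() - rr[other].mean())

    observed = contrast(in_phase)
    rng = np.random.default_rng(seed)
    at_least = 0
    for _ in range(n_shifts):
        shift = int(rng.integers(1, len(ts)))
        if abs(contrast(np.roll(in_phase, shift))) >= abs(observed):
            at_least += 1
    return {
        "mean_uptake_contracted": float(rr[ok & in_phase].mean()),
        "mean_uptake_expanded": float(rr[ok & ~in_phase].mean()),
        "difference": observed,
        "p_value": (1 + at_least) / (n_shifts + 1),
        "n_shifts": n_shifts,
    }


# ---------------------------------------------------------------------------
# I/O helpers


def read_trace_csv(path) -> pd.DataFrame:
    """Read a trace CSV with columns (timestamp_s, value)."""
    df = pd.read_csv(path)
    if "timestamp_s" not in df.columns:
        raise ValueError(f"{path}: missing timestamp_s column")
    return df


def write_events_tsv(events: Iterable[ContractionEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("start_s\ttrough_s\tend_s\tamplitude\tclass\n")
        for ev in events:
            fh.write(
                f"{ev.start_s:.1f}\t{ev.trough_s:.1f}\t{ev.end_s:.1f}"
                f"\t{ev.amplitude:.4f}\t{ev.klass}\n"
            )
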