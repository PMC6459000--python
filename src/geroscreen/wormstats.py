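"""Organismal validation analytics: Kaplan-Meier survival, log-rank
comparisons, median-lifespan changes, and population activity curves
derived from worm-position correlations.

The activity procedure reconstructs, per plate and timepoint, a binary
occupancy grid of detected worm objects, computes the Pearson
correlation of every pair of adjacent timepoints (high correlation =
little movement), pools the correlations across plates, smooths them
with a GCV-tuned smoothing spline, and mirrors/normalizes the smoothed
curve so the most active timepoint maps to 1 and the least active to
0.  Values before the activity peak are clamped to 1 and values after
the end of movement to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.interpolate import make_smoothing_spline

log = logging.getLogger(__name__)

MIN_WORMS_PER_ARM = 50


def _arm_table(table: pd.DataFrame, arm: str, enforce_min_n: bool) -> pd.DataFrame:
    sub = table[table["arm"] == arm]
    if sub.empty:
        raise ValueError(f"arm {arm!r} has no worms")
    if (sub["day"] <= 0).any():
        raise ValueError(f"arm {arm!r} has nonpositive event times")
    if enforce_min_n and len(sub) < MIN_WORMS_PER_ARM:
        raise ValueError(
            f"arm {arm!r} has {len(sub)} worms; curves require at least "
            f"{MIN_WORMS_PER_ARM} tracked worms (pass enforce_min_n=False to waive)"
        )
    return sub


def km_estimate(
    table: pd.DataFrame, arm: str, enforce_min_n: bool = True
) -> tuple[pd.DataFrame, float | None]:
    """Product-limit survival curve and median lifespan for one arm.

    The median is the smallest time t with S(t) <= 0.5, absent (None)
    when the curve never reaches 0.5 (e.g. heavy censoring).
    Returns (curve DataFrame with columns time, survival; median).
    """
    sub = _arm_table(table, arm, enforce_min_n)
    kmf = KaplanMeierFitter()
    kmf.fit(sub["day"], event_observed=1 - sub["censored"].astype(int))
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    median = kmf.median_survival_time_
    if not np.isfinite(median):
        return curve, None
    return curve, float(median)


def logrank_test(
    table: pd.DataFrame, arm_a: str, arm_b: str, enforce_min_n: bool = True
) -> tuple[float, float]:
    """Unweighted two-group log-rank test; returns (chi-square
    statistic, p from chi2 with 1 df)."""
    a = _arm_table(table, arm_a, enforce_min_n)
    b = _arm_table(table, arm_b, enforce_min_n)
    events_a = 1 - a["censored"].astype(int)
    events_b = 1 - b["censored"].astype(int)
    if events_a.sum() + events_b.sum() == 0:
        raise ValueError("no observed events in either arm")
    res = _ll_logrank(a["day"], b["day"], event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def median_lifespan_change(treated_median: float | None, control_median: float | None) -> float:
    """Percent change of the treated median relative to control:
    100 * (treated - control) / control."""
    if treated_median is None or control_median is None:
        raise ValueError("median lifespan undefined for one of the arms")
    if control_median <= 0:
        raise ValueError("control median must be positive")
    return 100.0 * (treated_median - control_median) / control_median


@dataclass
class OccupancySeries:
    """Binary worm/non-worm occupancy grids for one plate, ordered by
    timepoint."""

    plate: str
    timepoints: np.ndarray
    grids: np.ndarray  # (n_timepoints, height, width) boolean


def occupancy_series(
    positions: pd.DataFrame, plate: str, grid_dims: tuple[int, int],
    timepoints=None,
) -> OccupancySeries:
    """Reconstruct the image space: one binary grid per timepoint with
    a 1 at every worm-object position (idempotent for coincident
    objects).  By default timepoints are those present in the log for
    the plate; an explicit ``timepoints`` sequence may include frames
    with no detected objects, which become all-zero grids."""
    w, h = grid_dims
    sub = positions[positions["plate"] == plate]
    if sub.empty and timepoints is None:
        raise ValueError(f"plate {plate!r} has no position records")
    bad = sub[(sub["x"] < 0) | (sub["x"] >= w) | (sub["y"] < 0) | (sub["y"] >= h)]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValueError(
            f"out-of-bounds coordinate ({r['x']}, {r['y']}) on plate {plate!r} "
            f"at timepoint {r['timepoint']}"
        )
    if timepoints is None:
        times = np.sort(sub["timepoint"].unique())
    else:
        times = np.sort(np.unique(np.asarray(timepoints, dtype=float)))
        sub = sub[sub["timepoint"].isin(times)]
    grids = np.zeros((len(times), h, w), dtype=bool)
    t_index = {t: i for i, t in enumerate(times)}
    ti = sub["timepoint"].map(t_index).to_numpy()
    if len(sub):
        grids[ti, sub["y"].to_numpy(dtype=int), sub["x"].to_numpy(dtype=int)] = True
    return OccupancySeries(plate=plate, timepoints=times, grids=grids)


def activity_correlations(
    series: OccupancySeries, death_time: float | None = None
) -> pd.DataFrame:
    """Pearson correlation of every adjacent timepoint pair's flattened
    grids.

    Timepoints beyond ``death_time`` (the death of the worm
    population) are omitted.  A pair involving a zero-variance
    (constant) frame yields a missing value.  Returns a DataFrame with
    columns time (the earlier timepoint of the pair) and r.
    """
    keep = (
        series.timepoints <= death_time
        if death_time is not None
        else np.ones(len(series.timepoints), dtype=bool)
    )
    times = series.timepoints[keep]
    flat = series.grids[keep].reshape(keep.sum(), -1).astype(float)
    if len(times) < 2:
        raise ValueError("need at least 2 usable timepoints for correlations")
    a, b = flat[:-1], flat[1:]
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a_c**2).sum(axis=1) * (b_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a_c * b_c).sum(axis=1) / denom, np.nan)
    return pd.DataFrame({"time": times[:-1], "r": r})


@dataclass
class ActivityCurve:
    """Normalized population-activity trajectory in [0, 1].

    ``peak_time`` is the time of maximal activity (everything before is
    clamped to 1); ``end_time`` is the end of movement (everything
    after is clamped to 0).
    """

    times: np.ndarray
    activity: np.ndarray
    peak_time: float
    end_time: float

    def first_crossing(self, level: float = 0.5) -> float | None:
        """First time the activity drops to or below ``level``."""
        below = self.activity <= level
        if not below.any():
            return None
        return float(self.times[int(np.argmax(below))])


def activity_curve(
    correlation_frames: list[pd.DataFrame],
    death_time: float | None = None,
    n_grid: int = 200,
    smooth: bool = True,
) -> ActivityCurve:
    """Pool adjacent-pair correlations from multiple plates into one
    normalized activity curve.

    The pooled (time, r) points (duplicate times averaged) are fitted
    with a GCV-tuned smoothing spline (``smooth=False`` skips the
    smoothing and interpolates the averaged raw correlations, for
    comparison).  The fitted curve is affinely mirrored so its minimum
    maps to activity 1 and its maximum to 0, then clamped: 1 before the
    activity peak, 0 after the end of movement.  A constant correlation
    sequence has no affine map; the curve degenerates to 1 up to
    ``death_time`` and 0 after, with a warning.
    """
    if not correlation_frames:
        raise ValueError("need at least one plate correlation sequence")
    pooled = pd.concat(correlation_frames, ignore_index=True).dropna(subset=["r"])
    if death_time is not None:
        pooled = pooled[pooled["time"] <= death_time]
    if len(pooled) < 2:
        raise ValueError("fewer than 2 usable correlation points")
    by_time = pooled.groupby("time")["r"].mean()
    t = by_time.index.to_numpy(dtype=float)
    r = by_time.to_numpy(dtype=float)

    grid = np.linspace(t.min(), t.max(), n_grid)
    if smooth and len(t) >= 5:
        spline = make_smoothing_spline(t, r)
        fitted = np.asarray(spline(grid))
    else:
        fitted = np.interp(grid, t, r)

    lo, hi = float(fitted.min()), float(fitted.max())
    if hi - lo <= 1e-12:
        log.warning("constant correlation sequence; returning degenerate activity curve")
        cut = death_time if death_time is not None else t.max()
        activity = np.where(grid <= cut, 1.0, 0.0)
        return ActivityCurve(times=grid, activity=activity, peak_time=grid[0], end_time=float(cut))

    activity = (hi - fitted) / (hi - lo)  # mirror: low correlation = most active
    peak_i = int(np.argmax(activity))
    end_i = int(np.argmin(activity[peak_i:])) + peak_i
    activity = activity.copy()
    activity[:peak_i] = 1.0
    activity[end_i + 1 :] = 0.0
    activity = np.clip(activity, 0.0, 1.0)
    return ActivityCurve(
        times=grid,
        activity=activity,
        peak_time=float(grid[peak_i]),
        end_time=float(grid[end_i]),
    )


def arm_activity_curve(
    positions: pd.DataFrame,
    survival: pd.DataFrame,
    arm: str,
    grid_dims: tuple[int, int],
    death_time: float | None = None,
    smooth: bool = True,
) -> ActivityCurve:
    """Convenience wrapper: occupancy -> correlations -> pooled curve
    for all plates of one arm.  ``death_time`` defaults to the arm's
    last observed (uncensored) event time."""
    sub = survival[survival["arm"] == arm]
    if death_time is None:
        events = sub[sub["censored"].astype(int) == 0]
        death_time = float(events["day"].max()) if len(events) else float(sub["day"].max())
    plates = sorted(sub["plate"].unique())
    frames = []
    for plate in plates:
        series = occupancy_series(positions, plate, grid_dims)
        frames.append(activity_correlations(series, death_time=death_time))
    return activity_curve(frames, death_time=death_time, smooth=smooth)
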