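"""Tonic/phasic decomposition of decoded concentration series.

Tonic levels are sliding-window means at a multi-minute timescale (default
4 min, non-overlapping). Phasic activity is summarized as stimulus-locked
epochs on a fixed grid relative to onset, baseline-corrected against the
pre-stimulus interval, and reduced to per-trial scalars by overlap-weighted
window means (the 625-670 ms cluster window does not align with the 100 ms
sampling grid, so samples are weighted by the fraction of their coverage
interval that falls inside the requested window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoder import ConcentrationSeries

__all__ = [
    "TonicSeries",
    "EpochSet",
    "WindowSummary",
    "compute_tonic",
    "extract_epochs",
    "window_mean",
]

CLUSTER_WINDOW = (0.625, 0.670)


@dataclass
class TonicSeries:
    """Multi-minute windowed mean concentrations."""

    window_centers: np.ndarray
    tonic_da: np.ndarray
    tonic_sert: np.ndarray
    window_length: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.window_centers) <= 0):
            raise ValueError("window centers must be strictly increasing")


@dataclass
class EpochSet:
    """Stimulus-locked epochs, one row per retained trial.

    ``epoch_times`` are seconds relative to stimulus onset and include 0;
    after baseline correction each trial's mean over the baseline window
    is zero (mode='baseline'); mode='zscore' z-scores each trial instead.
    """

    da: np.ndarray
    sert: np.ndarray
    epoch_times: np.ndarray
    baseline_window: tuple[float, float]
    trial_index: np.ndarray
    n_dropped: int
    mode: str = "baseline"

    @property
    def n_trials(self) -> int:
        return self.da.shape[0]

    @property
    def dt(self) -> float:
        return float(self.epoch_times[1] - self.epoch_times[0])


@dataclass
class WindowSummary:
    """Per-trial mean concentration over a post-onset window."""

    values: np.ndarray
    trial_index: np.ndarray
    window: tuple[float, float]
    analyte: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window summaries must be finite")


def compute_tonic(
    series: ConcentrationSeries,
    window_length: float = 240.0,
    step: float | None = None,
) -> TonicSeries:
    """Sliding-window arithmetic means; step defaults to the window length."""
    t = series.timestamps
    duration = t[-1] - t[0]
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if window_length > duration + 1e-9:
        raise ValueError("window_length exceeds the recording length")
    step = window_length if step is None else step
    if step <= 0:
        raise ValueError("step must be positive")
    starts = []
    s = t[0]
    while s + window_length <= t[-1] + 1e-9:
        starts.append(s)
        s += step
    centers, da, sert = [], [], []
    for s in starts:
        m = (t >= s - 1e-9) & (t < s + window_length - 1e-9)
        if not m.any():
            raise ValueError("empty tonic window")
        centers.append(s + window_length / 2.0)
        da.append(series.da[m].mean())
        sert.append(series.sert[m].mean())
    return TonicSeries(
        window_centers=np.asarray(centers),
        tonic_da=np.asarray(da),
        tonic_sert=np.asarray(sert),
        window_length=window_length,
    )


def extract_epochs(
    series: ConcentrationSeries,
    trials: pd.DataFrame,
    window: tuple[float, float] = (-0.5, 1.1),
    baseline: tuple[float, float] = (-0.5, 0.0),
    mode: str = "baseline",
) -> EpochSet:
    """Cut stimulus-locked epochs and baseline-correct them.

    Each trial's segment is linearly interpolated onto a fixed grid of
    relative times spanning ``window`` at the series' sampling period.
    Trials whose epoch extends past the recording are dropped with a
    warning. ``mode='baseline'`` subtracts the per-trial mean over
    ``baseline`` (default [-0.5, 0) s pre-stimulus); ``mode='zscore'``
    z-scores each trial's epoch.
    """
    if mode not in ("baseline", "zscore"):
        raise ValueError("mode must be 'baseline' or 'zscore'")
    t = series.timestamps
    dt = float(t[1] - t[0])
    k0 = int(np.round(window[0] / dt))
    k1 = int(np.round(window[1] / dt))
    epoch_times = np.arange(k0, k1 + 1) * dt

    onsets = trials["onset_s"].to_numpy(dtype=float)
    keep = (onsets + epoch_times[0] >= t[0] - 1e-9) & (onsets + epoch_times[-1] <= t[-1] + 1e-9)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} trial(s) with epochs outside the recording",
                      stacklevel=2)
    kept = np.flatnonzero(keep)
    sample_t = onsets[kept, None] + epoch_times[None, :]
    da = np.interp(sample_t, t, series.da)
    sert = np.interp(sample_t, t, series.sert)

    bmask = (epoch_times >= baseline[0] - 1e-9) & (epoch_times < baseline[1] - 1e-9)
    if mode == "baseline":
        if not bmask.any():
            raise ValueError("baseline window contains no samples")
        da = da - da[:, bmask].mean(axis=1, keepdims=True)
        sert = sert - sert[:, bmask].mean(axis=1, keepdims=True)
    else:
        da = (da - da.mean(axis=1, keepdims=True)) / da.std(axis=1, keepdims=True)
        sert = (sert - sert.mean(axis=1, keepdims=True)) / sert.std(axis=1, keepdims=True)
    return EpochSet(
        da=da,
        sert=sert,
        epoch_times=epoch_times,
        baseline_window=tuple(baseline),
        trial_index=kept,
        n_dropped=n_dropped,
        mode=mode,
    )


def window_mean(
    epochs: EpochSet,
    t0: float = CLUSTER_WINDOW[0],
    t1: float = CLUSTER_WINDOW[1],
    analyte: str = "da",
    mode: str = "overlap",
) -> WindowSummary:
    """Per-trial mean over [t0, t1] s post-onset.

    mode='overlap' (default): each sample at time t covers
    [t - dt/2, t + dt/2); samples are weighted by the fraction of the
    requested window their coverage interval overlaps. Reduces to exact
    sample means for grid-aligned windows. mode='nearest' uses the single
    sample nearest the window midpoint.
    """
    if t1 <= t0:
        raise ValueError("require t0 < t1")
    data = getattr(epochs, analyte)
    times = epochs.epoch_times
    dt = epochs.dt
    if t0 < times[0] - dt / 2 or t1 > times[-1] + dt / 2:
        raise ValueError("window exceeds the epoch span")
    if mode == "nearest":
        idx = int(np.argmin(np.abs(times - 0.5 * (t0 + t1))))
        vals = data[:, idx]
    elif mode == "overlap":
        lo = times - dt / 2.0
        hi = times + dt / 2.0
        w = np.clip(np.minimum(hi, t1) - np.maximum(lo, t0), 0.0, None)
        if w.sum() <= 0:
            raise ValueError("window overlaps no samples")
        w = w / w.sum()
        vals = data @ w
    else:
        raise ValueError("mode must be 'overlap' or 'nearest'")
    return WindowSummary(values=vals, trial_index=epochs.trial_index,
                         window=(t0, t1), analyte=analyte)
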