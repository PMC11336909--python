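"""Hemodynamic time-series analysis: relative changes, ROI statistics,
stimulation-paradigm summaries, and resting-state cross-correlation.

The same relative-change formula serves CBV, CBF and SO2 dynamics:

    r(t) = (x(t) - m) / m * 100 %,   m = mean of the first ``baseline_n`` frames

with ``baseline_n`` = 10 by default. Resting-state coupling between a
reference region (e.g. the cortex) and individual voxels or a second ROI
(e.g. a draining vein) is measured by the Pearson correlation at integer
frame lags over the truncated overlap window.

Map stacks are time-first: shape (n_frames, depth, lateral).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimeSeries",
    "RelativeSeries",
    "StimulusParadigm",
    "CrossCorrResult",
    "relative_change",
    "relative_change_stack",
    "roi_timecourse",
    "crosscorr_map",
    "roi_pair_crosscorr",
    "paradigm_summary",
]


@dataclass
class TimeSeries:
    """Frame-sampled scalar series with its frame period and baseline length."""

    values: np.ndarray
    frame_period_s: float = 3.3
    baseline_n: int = 10

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be 1-D")
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be > 0")


@dataclass
class RelativeSeries:
    """Percent change relative to the baseline-window mean."""

    percent: np.ndarray
    baseline_mean: float
    frame_period_s: float
    baseline_n: int


@dataclass(frozen=True)
class StimulusParadigm:
    """Baseline / stimulus / post-stimulus block durations in seconds
    (default: the 2 + 3 + 3 min hypercapnia paradigm)."""

    baseline_s: float = 120.0
    stimulus_s: float = 180.0
    post_s: float = 180.0
    label: str = "5% CO2"

    def __post_init__(self) -> None:
        if min(self.baseline_s, self.stimulus_s, self.post_s) <= 0:
            raise ValueError("paradigm durations must be > 0")

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.stimulus_s + self.post_s


@dataclass
class CrossCorrResult:
    """Pearson correlation against integer frame lags.

    ``r`` has the lag axis first: shape (n_lags,) for an ROI pair or
    (n_lags, depth, lateral) for a voxel map. Positive lag means the target
    series is delayed relative to the reference.
    """

    r: np.ndarray
    lags_frames: np.ndarray
    lags_s: np.ndarray

    @property
    def peak_lag_s(self) -> float:
        return float(self.lags_s[np.nanargmax(self.r)])

    @property
    def trough_lag_s(self) -> float:
        return float(self.lags_s[np.nanargmin(self.r)])


def relative_change(series: TimeSeries, baseline_floor: float = 1e-12) -> RelativeSeries:
    """Percent change of a series relative to its baseline-window mean.

    Raises if the series is shorter than the baseline window; a baseline mean
    at or below ``baseline_floor`` in magnitude marks the whole series
    undefined (NaN) rather than dividing by ~0.
    """
    n = len(series.values)
    if n < series.baseline_n:
        raise ValueError(
            f"series of length {n} shorter than baseline window {series.baseline_n}"
        )
    m = float(series.values[: series.baseline_n].mean())
    if abs(m) <= baseline_floor:
        percent = np.full(n, np.nan)
    else:
        percent = (series.values - m) / m * 100.0
    return RelativeSeries(
        percent=percent,
        baseline_mean=m,
        frame_period_s=series.frame_period_s,
        baseline_n=series.baseline_n,
    )


def relative_change_stack(stack: np.ndarray, baseline_n: int = 10,
                          baseline_floor: float = 1e-12) -> np.ndarray:
    """Per-pixel relative change of a (time, z, x) map stack, in percent.

    Pixels whose baseline mean is ~0 become NaN for all frames.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.shape[0] < baseline_n:
        raise ValueError("stack shorter than the baseline window")
    m = stack[:baseline_n].mean(axis=0)
    safe = np.abs(m) > baseline_floor
    out = np.full_like(stack, np.nan)
    out[:, safe] = (stack[:, safe] - m[safe]) / m[safe] * 100.0
    return out


def roi_timecourse(stack: np.ndarray, roi_mask: np.ndarray,
                   frame_period_s: float = 3.3, baseline_n: int = 10):
    """ROI mean and across-pixel std per frame of a (time, z, x) stack.

    The std is the population std over the ROI pixels at each frame (the
    shaded-band statistic for plots). NaN pixels (masked SO2 etc.) are
    ignored per frame. Returns (TimeSeries, std array).
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty")
    if mask.shape != stack.shape[1:]:
        raise ValueError("ROI mask shape must match the map shape")
    pix = stack[:, mask]
    mean = np.nanmean(pix, axis=1)
    std = np.nanstd(pix, axis=1)
    return TimeSeries(mean, frame_period_s=frame_period_s, baseline_n=baseline_n), std


def _pearson(a: np.ndarray, b: np.ndarray):
    """Pearson r between 1-D ``a`` and (possibly stacked) ``b`` along axis 0;
    (near-)zero-variance columns give NaN."""
    scale_b = np.sqrt((b.reshape(len(a), -1) ** 2).sum(axis=0))
    a = a - a.mean()
    b = b - b.mean(axis=0)
    bf = b.reshape(len(a), -1)
    num = (a[:, None] * bf).sum(axis=0)
    sb = np.sqrt((bf**2).sum(axis=0))
    den = np.sqrt((a**2).sum()) * sb
    r = np.full(num.shape, np.nan)
    # a column whose fluctuation is at rounding level of its magnitude is flat
    ok = (den > 0) & (sb > 1e-10 * scale_b)
    r[ok] = num[ok] / den[ok]
    return r.reshape(b.shape[1:]) if b.ndim > 1 else float(r[0])


def crosscorr_map(stack: np.ndarray, ref_mask: np.ndarray, max_lag: int,
                  frame_period_s: float = 0.71) -> CrossCorrResult:
    """Correlate every voxel against the ROI-mean reference at each lag.

    For lag ``l`` the voxel series is shifted by ``l`` frames (positive lag =
    voxel delayed) and the Pearson correlation is computed over the truncated
    overlap window, both series mean-removed over that window — no zero
    padding, so |r| does not decay artificially with lag.
    """
    stack = np.asarray(stack, dtype=float)
    nt = stack.shape[0]
    if nt <= 2 * max_lag:
        raise ValueError("stack length must exceed 2 * max_lag")
    ref, _ = roi_timecourse(stack, ref_mask, frame_period_s=frame_period_s)
    ref = ref.values
    lags = np.arange(-max_lag, max_lag + 1)
    maps = []
    for lag in lags:
        if lag >= 0:
            a = ref[: nt - lag]
            b = stack[lag:]
        else:
            a = ref[-lag:]
            b = stack[: nt + lag]
        maps.append(_pearson(a, b))
    return CrossCorrResult(
        r=np.stack(maps),
        lags_frames=lags,
        lags_s=lags * frame_period_s,
    )


def roi_pair_crosscorr(stack: np.ndarray, roi_a: np.ndarray, roi_b: np.ndarray,
                       max_lag: int, frame_period_s: float = 0.71) -> CrossCorrResult:
    """Lagged Pearson correlation between two ROI-mean series.

    Positive lag means ROI-b (e.g. the vein) is delayed relative to ROI-a
    (e.g. the cortex). Peak and trough lags are exposed on the result.
    """
    stack = np.asarray(stack, dtype=float)
    nt = stack.shape[0]
    if nt <= 2 * max_lag:
        raise ValueError("stack length must exceed 2 * max_lag")
    sa, _ = roi_timecourse(stack, roi_a, frame_period_s=frame_period_s)
    sb, _ = roi_timecourse(stack, roi_b, frame_period_s=frame_period_s)
    a_full, b_full = sa.values, sb.values
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if lag >= 0:
            a = a_full[: nt - lag]
            b = b_full[lag:]
        else:
            a = a_full[-lag:]
            b = b_full[: nt + lag]
        r[i] = _pearson(a, b)
    return CrossCorrResult(r=r, lags_frames=lags, lags_s=lags * frame_period_s)


def paradigm_summary(rel: RelativeSeries, paradigm: StimulusParadigm) -> dict:
    """Window means and peak timing of a relative-change series under a
    baseline / stimulus / post paradigm.

    Peak time is reported in seconds relative to stimulus onset (argmax over
    the stimulus + post windows).
    """
    dt = rel.frame_period_s
    n = len(rel.percent)
    n_base = int(round(paradigm.baseline_s / dt))
    n_stim = int(round(paradigm.stimulus_s / dt))
    n_post = int(round(paradigm.post_s / dt))
    if n < n_base + n_stim + n_post:
        raise ValueError(
            f"series of {n} frames does not cover the "
            f"{paradigm.total_s:.0f} s paradigm at {dt} s per frame"
        )
    base = rel.percent[:n_base]
    stim = rel.percent[n_base : n_base + n_stim]
    post = rel.percent[n_base + n_stim : n_base + n_stim + n_post]
    after_onset = rel.percent[n_base : n_base + n_stim + n_post]
    peak_idx = int(np.nanargmax(after_onset))
    return {
        "baseline_mean": float(np.nanmean(base)),
        "stimulus_mean": float(np.nanmean(stim)),
        "post_mean": float(np.nanmean(post)),
        "peak_value": float(after_onset[peak_idx]),
        "peak_time_s": peak_idx * dt,
        "label": paradigm.label,
    }
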