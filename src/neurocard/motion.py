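"""Dye-free motion analysis: frame cross-correlation and beat rates.

Contraction of a monolayer decorrelates each video frame from a reference
frame; the per-frame motion statistic is 1 − r_t, where r_t is the
Pearson correlation of frame t with the reference over all pixels.  The
statistic is invariant to affine intensity rescaling of the video, zero at
the reference frame and bounded by [0, 2].  Beats are local maxima of the
smoothed motion trace; rates over fixed windows (default 5 s) feed
pre/post intervention comparisons such as the beat-rate response to
nicotinic stimulation of co-cultured sympathetic neurons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import ttest_rel

from .trace import Trace
from .videostack import VideoStack

__all__ = ["BeatSeries", "RateChangeResult", "frame_crosscorrelation",
           "detect_beats", "rate_change"]


@dataclass
class BeatSeries:
    """Detected beat times (s) and per-window rates (beats/min)."""

    beat_times: np.ndarray
    rates_per_window: np.ndarray
    window_s: float

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=np.float64)
        if self.beat_times.size > 1 and np.any(np.diff(self.beat_times)
                                               <= 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    @property
    def mean_rate(self) -> float:
        """Mean rate in beats/min over the analyzed windows."""
        return float(np.mean(self.rates_per_window)) \
            if self.rates_per_window.size else 0.0

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame({"beat_time_s": self.beat_times}).to_csv(path,
                                                              index=False)
        return path


@dataclass
class RateChangeResult:
    pre_rate: float          # beats/min
    post_rate: float         # beats/min
    percent_change: float    # %
    se_percent_change: float # %
    p_value: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def frame_crosscorrelation(video: VideoStack,
                           reference_index: int = 0) -> Trace:
    """Motion trace 1 − Pearson r of every frame against a reference."""
    T = video.n_frames
    if not 0 <= reference_index < T:
        raise IndexError(f"reference_index {reference_index} outside video "
                         f"of {T} frames")
    x = video.frames.reshape(T, -1).astype(np.float64)
    ref = x[reference_index]
    ref_c = ref - ref.mean()
    ref_norm = np.linalg.norm(ref_c)
    if ref_norm == 0:
        raise ValueError("degenerate reference frame: zero pixel variance")
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    with np.errstate(invalid="ignore"):
        r = (xc @ ref_c) / (norms * ref_norm)
    r[norms == 0] = 0.0  # constant frame: define r = 0 (no correlation)
    return Trace(values=1.0 - r, sample_rate=video.sample_rate, t0=0.0)


def detect_beats(trace: Trace, smooth_window: float = 0.15,
                 min_interval: float = 0.25,
                 threshold_frac: float = 0.3,
                 rate_window: float = 5.0) -> BeatSeries:
    """Peak-picking beat detection on a (motion) trace.

    The trace is smoothed with a moving average of ``smooth_window``
    seconds; beats are local maxima above
    baseline + threshold_frac × (max − baseline), where the baseline is
    the smoothed trace's median, separated by at least ``min_interval``
    seconds.  A flat trace yields an empty series.  Rates are reported
    per consecutive ``rate_window``-second window in beats/min.
    """
    fs = trace.sample_rate
    if min_interval <= 1.0 / fs:
        raise ValueError("min_interval must exceed one sample interval")
    w = max(1, int(round(smooth_window * fs)))
    kernel = np.ones(w) / w
    smooth = np.convolve(trace.values, kernel, mode="same")
    baseline = np.median(smooth)
    amp = smooth.max() - baseline
    beat_times = np.empty(0)
    if amp > 0:
        height = baseline + threshold_frac * amp
        # strict threshold at the maximum keeps threshold_frac=1 empty
        if threshold_frac >= 1.0:
            peaks = np.empty(0, dtype=int)
        else:
            peaks, _ = find_peaks(smooth, height=height,
                                  distance=max(1, int(round(min_interval
                                                            * fs))))
        beat_times = trace.t0 + peaks / fs
    n_win = max(1, int(trace.duration // rate_window))
    rates = np.empty(n_win)
    for k in range(n_win):
        a = trace.t0 + k * rate_window
        b = a + rate_window
        rates[k] = np.sum((beat_times >= a) & (beat_times < b)) \
            * 60.0 / rate_window
    return BeatSeries(beat_times=beat_times, rates_per_window=rates,
                      window_s=rate_window)


def rate_change(pre: BeatSeries, post: BeatSeries) -> RateChangeResult:
    """Percent beat-rate change from pre- to post-intervention recordings.

    The change is computed between mean window rates; its standard error
    propagates the per-window SEs to first order, and the p-value is a
    two-tailed paired t-test across window pairs (windows are paired in
    order, truncated to the shorter recording).
    """
    if pre.n_beats == 0 or pre.mean_rate == 0:
        raise ValueError("pre-intervention rate is zero: percent change "
                         "undefined")
    pre_r, post_r = pre.mean_rate, post.mean_rate
    pct = 100.0 * (post_r - pre_r) / pre_r

    def sem(x):
        x = np.asarray(x, dtype=np.float64)
        return (x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0

    se_pre, se_post = sem(pre.rates_per_window), sem(post.rates_per_window)
    se_pct = 100.0 / pre_r * np.sqrt(
        se_post**2 + (post_r / pre_r) ** 2 * se_pre**2)

    n = min(pre.rates_per_window.size, post.rates_per_window.size)
    if n > 1:
        a = pre.rates_per_window[:n]
        b = post.rates_per_window[:n]
        if np.allclose(a, b):
            p = 1.0
        else:
            p = float(ttest_rel(b, a).pvalue)
    else:
        p = np.nan
    return RateChangeResult(pre_rate=pre_r, post_rate=post_r,
                            percent_change=pct, se_percent_change=se_pct,
                            p_value=p)
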