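"""Activation-time maps, isochrones, wave-speed statistics, classification.

The analysis chain mirrors standard optical mapping practice:

1. per-pixel traces are spatially binned and median-baseline-subtracted;
2. activation times are sub-frame, linearly interpolated upward crossings
   of a fraction (default 0.5) of each pixel's signal amplitude, one per
   detected cycle;
3. an isochronal map shows one cycle's activation times relative to its
   earliest point;
4. local wave speed is 1/‖∇T‖ on the Gaussian-smoothed activation-time
   surface, summarized as the 90th percentile over valid pixels × cycles
   (the conduction-velocity statistic used to compare monocultures with
   neuron co-cultures);
5. wave dynamics are classified from phase-singularity statistics as
   target / single_spiral / multi_spiral / wavelets, the first two being
   "simple", the latter two "complex".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d
from scipy.ndimage import binary_erosion, median_filter, uniform_filter
from skimage.measure import block_reduce, label

from .phase import PhaseField, phase_map
from .videostack import VideoStack

__all__ = [
    "FilteredTraces", "ActivationMap", "WaveSpeedField",
    "WaveClassification", "ClassifyThresholds", "extract_filtered_traces",
    "compute_activation_times", "isochronal_map", "wave_speed",
    "classify_dynamics",
]


@dataclass
class FilteredTraces:
    """Baseline-subtracted per-pixel traces (T, h, w) with calibration."""

    traces: np.ndarray
    frame_interval: float
    pixel_size: float  # μm per (binned) pixel

    @property
    def n_frames(self) -> int:
        return self.traces.shape[0]


@dataclass
class ActivationMap:
    """Upstroke times per pixel per cycle.

    ``times`` is (n_cycles, H, W) seconds, NaN-padded: times[k] holds each
    pixel's k-th detected upstroke, so the leading index is the cycle
    index.  Per-pixel times are strictly increasing along axis 0.
    """

    times: np.ndarray
    valid_mask: np.ndarray
    frame_interval: float
    pixel_size: float

    @property
    def n_cycles(self) -> int:
        return self.times.shape[0]

    def cycles_per_pixel(self) -> np.ndarray:
        return np.sum(np.isfinite(self.times), axis=0)


@dataclass
class WaveSpeedField:
    """Local wave speeds (mm/s) and their 90th-percentile summary."""

    local_speed: np.ndarray  # (n_cycles, H, W), NaN where invalid
    p90_speed: float
    pixel_size: float


@dataclass
class ClassifyThresholds:
    """Decision thresholds for the wave-dynamics classifier."""

    s_max: int = 3                 # multi_spiral vs wavelets boundary
    burst_margin: int = 2          # p90 count >= s_max+margin -> wavelets
    transient_frac: float = 0.2    # leading fraction of frames skipped
    min_duration_s: float = 10.0   # analyzable if duration >= this ...
    min_cycles: int = 10           # ... or this many cycles observed
    persistence: float = 0.8       # fraction of frames with >=1 rotor
    focus_dispersion_px: float = 15.0
    min_rotor_life: int = 3        # frames a track must persist to count


@dataclass
class WaveClassification:
    """Regime verdict for one recording."""

    regime: str | None             # target|single_spiral|multi_spiral|wavelets
    complexity: str | None         # simple|complex
    singularity_count_median: float
    wavefront_fragment_count_median: float
    status: str = "ok"             # ok | inconclusive
    detail: str = ""

    def __post_init__(self) -> None:
        if self.regime is not None:
            want = ("simple" if self.regime in ("target", "single_spiral")
                    else "complex")
            if self.complexity is None:
                self.complexity = want
            assert self.complexity == want


def extract_filtered_traces(video: VideoStack, spatial_bin: int = 1,
                            median_window: float = 2.0) -> FilteredTraces:
    """Bin pixels and subtract each trace's running-median baseline.

    The running median tracks slow drift but not fast transients, so a
    quiescent pixel comes out near zero while spikes keep their amplitude.
    The window should span a few beat periods (and at least ~5 transient
    durations); a window comparable to one period follows the beats
    themselves and distorts the waveform.
    """
    fs = video.sample_rate
    w = int(round(median_window * fs)) | 1
    if w < 3:
        raise ValueError("median_window must span at least 3 samples")
    if w > video.n_frames:
        raise ValueError("median_window longer than the recording")
    x = np.asarray(video.frames, dtype=np.float64)
    if spatial_bin > 1:
        x = block_reduce(x, (1, spatial_bin, spatial_bin), np.mean)
    # the baseline is slow by construction, so the running median is
    # computed on a temporally decimated copy and linearly interpolated
    stride = max(1, min(4, w // 8))
    if stride > 1:
        xs = x[::stride]
        ws = max(3, int(round(w / stride)) | 1)
        bs = median_filter(xs, size=(ws, 1, 1), mode="nearest")
        t_full = np.arange(x.shape[0])
        t_sub = t_full[::stride]
        baseline = interp1d(t_sub, bs, axis=0, kind="linear",
                            fill_value="extrapolate")(t_full)
    else:
        baseline = median_filter(x, size=(w, 1, 1), mode="nearest")
    return FilteredTraces(traces=x - baseline,
                          frame_interval=video.frame_interval,
                          pixel_size=video.pixel_size * spatial_bin)


def compute_activation_times(traces: FilteredTraces,
                             threshold_frac: float = 0.5,
                             min_snr: float = 4.0,
                             min_cycle_interval: float = 0.15
                             ) -> ActivationMap:
    """Sub-frame upstroke times per pixel per cycle.

    Per pixel, the trace is normalized to its 5–95 percentile range and
    upward crossings of ``threshold_frac`` are located with linear
    interpolation; a Schmitt trigger (release at threshold − 0.15) plus a
    ``min_cycle_interval`` dead time suppress noise double-counts.
    Pixels whose amplitude is below ``min_snr`` times their high-frequency
    noise are masked invalid.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must lie in (0, 1)")
    x = traces.traces
    T, H, W = x.shape
    P = H * W
    xf = x.reshape(T, P)
    dtf = traces.frame_interval

    # baseline from a robust low percentile; the top from the maximum, so
    # threshold_frac is a true fraction of the upstroke amplitude (a high
    # percentile would depend on the duty cycle and bias crossings early)
    lo = np.percentile(xf, 5, axis=0)
    hi = xf.max(axis=0)
    amp = hi - lo
    noise = 1.4826 * np.median(np.abs(np.diff(xf, axis=0)), axis=0) \
        / np.sqrt(2.0)
    valid = amp > np.maximum(min_snr * noise, 1e-12)

    norm = np.zeros_like(xf)
    nz = amp > 0
    norm[:, nz] = (xf[:, nz] - lo[nz]) / amp[nz]

    thr = threshold_frac
    release = thr - 0.15
    armed = np.ones(P, dtype=bool)
    last_t = np.full(P, -np.inf)
    times_per_px: list[list[float]] = [[] for _ in range(P)]
    for t in range(1, T):
        prev, cur = norm[t - 1], norm[t]
        cross = armed & (cur >= thr) & (prev < thr) & valid
        if np.any(cross):
            idx = np.nonzero(cross)[0]
            frac = (thr - prev[idx]) / (cur[idx] - prev[idx])
            tc = (t - 1 + frac) * dtf
            ok = tc - last_t[idx] >= min_cycle_interval
            for p, tci in zip(idx[ok], tc[ok]):
                times_per_px[p].append(float(tci))
            last_t[idx[ok]] = tc[ok]
            armed[idx] = False
        armed |= cur < release

    n_cycles = max((len(v) for v in times_per_px), default=0)
    times = np.full((n_cycles, P), np.nan)
    for p, v in enumerate(times_per_px):
        times[:len(v), p] = v
    return ActivationMap(times=times.reshape(n_cycles, H, W),
                         valid_mask=valid.reshape(H, W),
                         frame_interval=dtf, pixel_size=traces.pixel_size)


def isochronal_map(amap: ActivationMap, cycle: int) -> np.ndarray:
    """One cycle's activation times relative to its earliest activation.

    Returns an (H, W) float image in seconds with NaN at invalid pixels;
    the minimum over valid pixels is exactly 0.
    """
    if not 0 <= cycle < amap.n_cycles:
        raise IndexError(f"cycle {cycle} outside 0..{amap.n_cycles - 1}")
    iso = amap.times[cycle].copy()
    iso[~amap.valid_mask] = np.nan
    if np.all(np.isnan(iso)):
        return iso
    return iso - np.nanmin(iso)


def _plane_fit_gradient(tsurf: np.ndarray, pixel_size: float,
                        half_width: int) -> np.ndarray:
    """Gradient magnitude of T by local least-squares plane fits.

    Fitting T ≈ a + b·x + c·y over a (2h+1)² window averages out both
    noise and the frame-quantization staircase of activation times (the
    sub-frame crossing phase advances across the window), which a
    smoothing filter would instead spread into spurious flat patches.
    NaN pixels are excluded per window; windows with less than 60%
    support or a degenerate design are NaN.
    """
    m = np.isfinite(tsurf)
    t0 = np.where(m, tsurf, 0.0)
    H, W = tsurf.shape
    yy, xx = np.mgrid[:H, :W].astype(np.float64)
    k = 2 * half_width + 1

    def box(a):
        return uniform_filter(a, size=k, mode="constant")

    mf = m.astype(np.float64)
    n = box(mf)
    sx, sy, st = box(mf * xx), box(mf * yy), box(t0)
    sxx, syy, sxy = box(mf * xx * xx), box(mf * yy * yy), box(mf * xx * yy)
    sxt, syt = box(xx * t0), box(yy * t0)
    # normal equations for (b, c) after centering
    cxx = sxx - sx * sx / np.maximum(n, 1e-12)
    cyy = syy - sy * sy / np.maximum(n, 1e-12)
    cxy = sxy - sx * sy / np.maximum(n, 1e-12)
    cxt = sxt - sx * st / np.maximum(n, 1e-12)
    cyt = syt - sy * st / np.maximum(n, 1e-12)
    det = cxx * cyy - cxy * cxy
    with np.errstate(divide="ignore", invalid="ignore"):
        b = (cyy * cxt - cxy * cyt) / det
        c = (cxx * cyt - cxy * cxt) / det
    grad = np.hypot(b, c) / pixel_size  # s/μm
    grad[(n < 0.6) | (det <= 1e-12) | ~m] = np.nan
    return grad


def wave_speed(amap: ActivationMap, smoothing: float = 3.0,
               speed_cap_mm_s: float = 200.0,
               border_px: int | None = None,
               time_trim: tuple[float, float] = (0.1, 0.2),
               skip_first_cycle: bool = True) -> WaveSpeedField:
    """Local speed 1/‖∇T‖ per cycle and the pooled 90th percentile.

    Speeds above ``speed_cap_mm_s`` are masked as gradient-degenerate
    (activation-time gradients vanish on wave-collision lines), as is a
    border of width ~2 smoothing lengths where the smoothed gradient is
    biased.  Each cycle's earliest and latest activation quantiles
    (``time_trim``, leading/trailing fractions) are also excluded: fronts
    are born at the leading edge (stimulus sites, still accelerating) and
    die at the trailing edge (collisions and wall pile-ups, whose
    influence extends over the front's leading-tail length D/c), and
    neither transient reflects the bulk conduction speed.  When at least
    three cycles are present the first is skipped by default: the first
    beat propagates into fully rested tissue and is systematically
    faster than the paced steady state.  The percentile is the linearly
    interpolated (inclusive) percentile pooled over all valid pixels and
    cycles, in mm/s.
    """
    if amap.n_cycles == 0 or not np.any(amap.valid_mask):
        raise ValueError("no valid activation cycles: wave speed undefined")
    n, H, W = amap.times.shape
    speeds = np.full((n, H, W), np.nan)
    margin = border_px if border_px is not None \
        else int(np.ceil(2 * smoothing)) + 1
    n_valid = max(1, int(amap.valid_mask.sum()))
    first_cycle = 1 if (skip_first_cycle and n >= 3) else 0
    for k in range(first_cycle, n):
        tk = amap.times[k].copy()
        tk[~amap.valid_mask] = np.nan
        finite = np.isfinite(tk)
        # cycles only partially covered (recording edges, dying waves)
        # have biased smoothed gradients along their NaN frontier
        if finite.sum() < 0.5 * n_valid:
            continue
        # pass 1: flag gradient-degenerate zones (collision lines, wall
        # pile-ups, stimulus plateaus) at a fine scale, so the wide
        # plane-fit pass cannot bleed them into the bulk
        def speed_of(t_surf: np.ndarray, half_width: int) -> np.ndarray:
            grad = _plane_fit_gradient(t_surf, amap.pixel_size, half_width)
            with np.errstate(divide="ignore", invalid="ignore"):
                s = 1.0 / grad / 1000.0  # mm/s
            s[~np.isfinite(s)] = np.nan
            return s

        sp1 = speed_of(tk, 2)
        med = np.nanmedian(sp1)
        tk2 = tk.copy()
        if np.isfinite(med):
            tk2[(sp1 > 1.6 * med) | np.isnan(sp1)] = np.nan
        finite = np.isfinite(tk2)
        # window must span >= ~2 periods of the frame-quantization
        # staircase (front displacement per frame, in px)
        px_per_frame = 0.0
        if np.isfinite(med):
            px_per_frame = med * 1000.0 * amap.frame_interval \
                / amap.pixel_size
        half = int(min(10, max(np.ceil(smoothing) + 1,
                               np.ceil(px_per_frame))))
        sp = speed_of(tk2, half)
        sp[sp > speed_cap_mm_s] = np.nan
        r = int(np.ceil(smoothing))
        yy, xx = np.ogrid[-r:r + 1, -r:r + 1]
        sp[~binary_erosion(finite, yy**2 + xx**2 <= r**2)] = np.nan
        lead, trail = time_trim
        if lead > 0 or trail > 0:
            t_lo, t_hi = np.nanpercentile(tk, [100 * lead,
                                               100 * (1 - trail)])
            sp[(tk < t_lo) | (tk > t_hi) | ~finite] = np.nan
        if margin > 0:
            sp[:margin, :] = np.nan
            sp[-margin:, :] = np.nan
            sp[:, :margin] = np.nan
            sp[:, -margin:] = np.nan
        speeds[k] = sp
    flat = speeds[np.isfinite(speeds)]
    if flat.size == 0:
        raise ValueError("no valid local speeds (all masked)")
    p90 = float(np.percentile(flat, 90))
    return WaveSpeedField(local_speed=speeds, p90_speed=p90,
                          pixel_size=amap.pixel_size)


def _fragment_counts(amap: ActivationMap) -> np.ndarray:
    """Wavefront fragments per frame: connected components of the set of
    pixels whose upstroke falls in that frame."""
    n, H, W = amap.times.shape
    T = 0
    finite = amap.times[np.isfinite(amap.times)]
    if finite.size == 0:
        return np.zeros(0, dtype=np.int64)
    T = int(np.max(finite) / amap.frame_interval) + 1
    frame_of = np.full((n, H, W), -1, dtype=np.int64)
    ok = np.isfinite(amap.times)
    frame_of[ok] = (amap.times[ok] / amap.frame_interval).astype(np.int64)
    counts = np.zeros(T, dtype=np.int64)
    for t in range(T):
        front = np.any(frame_of == t, axis=0)
        if front.any():
            counts[t] = label(front, connectivity=2).max()
    return counts


def classify_dynamics(phase: PhaseField, amap: ActivationMap,
                      thresholds: ClassifyThresholds | None = None
                      ) -> WaveClassification:
    """Regime verdict from post-transient phase-singularity statistics.

    Decision rule (S = per-frame singularity count after the transient):
    sustained S median > s_max, or bursts of fragmented short-lived
    rotors (90th percentile ≥ s_max + burst_margin), mark wavelets;
    median ≥ 2 with a stable count marks multi_spiral; a single
    persistent rotor marks single_spiral; no rotors with a repeating
    focal origin marks target.  Too little activity or duration returns
    an inconclusive verdict rather than raising.
    """
    th = thresholds or ClassifyThresholds()
    T = phase.phase.shape[0]
    duration = T * phase.frame_interval
    cyc = amap.cycles_per_pixel()[amap.valid_mask]
    n_cycles = float(np.percentile(cyc, 75)) if cyc.size else 0.0

    frag = _fragment_counts(amap)
    frag_med = float(np.median(frag[frag > 0])) if np.any(frag > 0) else 0.0

    if n_cycles < 1 or not np.any(amap.valid_mask):
        return WaveClassification(None, None, 0.0, frag_med,
                                  status="inconclusive",
                                  detail="no activity detected")
    if duration < th.min_duration_s and n_cycles < th.min_cycles:
        return WaveClassification(
            None, None, 0.0, frag_med, status="inconclusive",
            detail=f"only {duration:.1f}s and {n_cycles:.0f} cycles "
                   f"(need {th.min_duration_s}s or {th.min_cycles} cycles)")

    skip = int(th.transient_frac * T)
    counts = phase.counts_per_frame(min_life=th.min_rotor_life)[skip:]
    s_med = float(np.median(counts))
    s_p90 = float(np.percentile(counts, 90))
    present = float(np.mean(counts >= 1))

    if s_med > th.s_max or s_p90 >= th.s_max + th.burst_margin:
        regime = "wavelets"
    elif s_med >= 2:
        regime = "multi_spiral"
    elif s_med >= 1 and present >= th.persistence:
        regime = "single_spiral"
    else:
        # no sustained rotor: look for a repeating focal origin
        origins = []
        for k in range(amap.n_cycles):
            tk = amap.times[k].copy()
            tk[~amap.valid_mask] = np.nan
            good = np.isfinite(tk)
            if good.sum() < 0.25 * amap.valid_mask.sum():
                continue
            cut = np.nanpercentile(tk, 5)
            rr, cc = np.nonzero(tk <= cut)
            origins.append((rr.mean(), cc.mean()))
        if len(origins) >= 2:
            o = np.asarray(origins)
            disp = float(np.hypot(*(o.std(axis=0))))
            if disp <= th.focus_dispersion_px:
                regime = "target"
            else:
                return WaveClassification(
                    None, None, s_med, frag_med, status="inconclusive",
                    detail=f"no rotors and wandering origin "
                           f"(dispersion {disp:.1f} px)")
        else:
            return WaveClassification(
                None, None, s_med, frag_med, status="inconclusive",
                detail="no rotors and too few full cycles to test focality")

    return WaveClassification(
        regime=regime, complexity=None,
        singularity_count_median=s_med,
        wavefront_fragment_count_median=frag_med)


def analyze_video(video: VideoStack, spatial_bin: int = 1,
                  median_window: float = 0.6,
                  threshold_frac: float = 0.5,
                  thresholds: ClassifyThresholds | None = None,
                  band_hz: tuple[float, float] = (0.5, 10.0)
                  ) -> tuple[ActivationMap, PhaseField, WaveClassification]:
    """Convenience chain: traces → activation map + phase → verdict."""
    ft = extract_filtered_traces(video, spatial_bin, median_window)
    amap = compute_activation_times(ft, threshold_frac)
    pf = phase_map(ft.traces, ft.frame_interval, band_hz)
    verdict = classify_dynamics(pf, amap, thresholds)
    return amap, pf, verdict
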