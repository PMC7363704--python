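"""Synthetic excitable-medium monolayer simulator.

A two-variable activator/inhibitor reaction-diffusion model (Barkley-type
kinetics with a cubic activator nullcline) stands in for the cardiomyocyte
monolayer:

    du/dt = D ∇²u + (1/ε) u (1 − u) (u − (v + b) / a)
    dv/dt = (u − v) / τ_v

u is the fast excitation variable (dimensionless, rest 0, excited ~1), v
the slow recovery variable.  ε sets the upstroke time scale (s), τ_v the
recovery time scale (s), a and b shape the excitation threshold
(v + b)/a, and D is the diffusion coefficient in μm²/s, which sets the
conduction speed c ∝ √(D/ε).  Boundaries are no-flux (dish edge).

Five stimulation/initial-condition regimes reproduce the wavefront
topologies seen in macroscopic monolayer recordings: paced plane waves,
focal target waves, a single re-entrant spiral, multiple interacting
spirals, and fibrillation-like wavelets sustained by strong frozen spatial
heterogeneity of excitability.  Every run returns the exact ground truth
(per-pixel upstroke times, per-frame phase-singularity counts, and for
plane waves the front speed measured on an independent 1D strip of the
same kinetics), so analyzers can be validated without any microscope data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
import hashlib
import json

import numpy as np
from scipy.ndimage import gaussian_filter

from ._kernels import advance
from ._rng import substream
from .phase import find_singularities
from .videostack import VideoStack

REGIMES = ("plane", "target", "single_spiral", "multi_spiral", "wavelets")

# state-space centre used for the ground-truth phase atan2(v - VC, u - UC);
# any point inside the (u, v) excitation loop works.
_UC, _VC = 0.5, 0.35

#: Per-regime kinetic and stimulation presets.  Diffusion values are chosen
#: so plane-front speeds land in the 25–40 mm/s band observed in confluent
#: neonatal-rat monolayers; see docs/methods.md for the calibration.
REGIME_PRESETS: dict[str, dict] = {
    "plane": dict(a=0.75, b=0.03, eps=0.006, tau_v=0.12,
                  diffusion=2.0e7, heterogeneity_amplitude=0.0,
                  pacing_period=0.7),
    "target": dict(a=0.75, b=0.03, eps=0.006, tau_v=0.12,
                   diffusion=2.0e7, heterogeneity_amplitude=0.0,
                   pacing_period=0.6),
    "single_spiral": dict(a=0.75, b=0.02, eps=0.004, tau_v=0.12,
                          diffusion=8.4e6, heterogeneity_amplitude=0.0,
                          pacing_period=None),
    "multi_spiral": dict(a=0.75, b=0.02, eps=0.004, tau_v=0.10,
                         diffusion=8.4e6, heterogeneity_amplitude=0.0,
                         pacing_period=None),
    "wavelets": dict(a=0.75, b=0.02, eps=0.004, tau_v=0.10,
                     diffusion=8.4e6, heterogeneity_amplitude=0.25,
                     pacing_period=None),
}


class SimulationInstabilityError(RuntimeError):
    """The field diverged: the (dt, diffusion, eps) combination is unstable."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic monolayer recording.

    Kinetic fields left as ``None`` take the per-regime preset from
    :data:`REGIME_PRESETS`.  Lengths are μm, times s, diffusion μm²/s.
    """

    grid_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 125.0
    frames: int = 300
    frame_interval: float = 0.02
    dt: float | None = None            # integration step; None = auto
    frame_stride: int | None = None    # steps per stored frame; None = auto
    regime: str = "plane"
    a: float | None = None
    b: float | None = None
    eps: float | None = None
    tau_v: float | None = None
    diffusion: float | None = None
    heterogeneity_amplitude: float | None = None
    heterogeneity_sigma: float = 5.0   # px, smoothing of the frozen field
    pacing_period: float | None = None
    apply_stimulus: bool = True        # False = quiescent medium
    noise_sd: float = 0.0              # forwarded to render_optical by CLI
    seed: int = 0

    def resolved(self) -> "SimulationConfig":
        """Fill None kinetic fields from the regime preset and validate."""
        if self.regime not in REGIMES:
            raise ValueError(
                f"unknown regime {self.regime!r}; choose from {REGIMES}")
        preset = REGIME_PRESETS[self.regime]
        out = replace(self)
        for name in ("a", "b", "eps", "tau_v", "diffusion",
                     "heterogeneity_amplitude"):
            if getattr(out, name) is None:
                setattr(out, name, preset[name])
        if out.pacing_period is None:
            out.pacing_period = preset["pacing_period"]
        H, W = out.grid_shape
        if H < 32 or W < 32:
            raise ValueError("grid_shape must be at least (32, 32)")
        if out.diffusion <= 0:
            raise ValueError("diffusion must be positive")
        if out.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        d_px = out.diffusion / out.pixel_size**2
        if out.dt is None:
            out.dt = min(0.18 / d_px, out.eps / 3.0)
        if out.dt <= 0:
            raise ValueError("dt must be positive")
        if out.frame_stride is None:
            # ceil keeps the realized dt at or below the stability bound
            out.frame_stride = max(1, int(np.ceil(out.frame_interval
                                                  / out.dt - 1e-9)))
        out.dt = out.frame_interval / out.frame_stride
        return out

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class GroundTruth:
    """Exact truth of a simulated recording.

    ``activation_times`` is (n_cycles, H, W) in seconds, NaN where a pixel
    saw fewer upstrokes; ``singularity_count`` is per stored frame, counted
    on the phase of the simulator's own state variables.
    """

    activation_times: np.ndarray
    true_plane_speed: float | None
    singularity_count: np.ndarray
    regime_label: str
    source_rc: tuple[int, int] | None = None
    pacing_period: float | None = None
    transient_s: float = 0.0


def _heterogeneity_fields(cfg: SimulationConfig, rng: np.random.Generator):
    """Frozen random fields modulating excitability and refractoriness.

    A smoothed unit-variance Gaussian field g scales both the threshold
    offset b (excitability) and the recovery time constant τ_v
    (refractoriness): patches of long refractoriness are what break
    incoming wavefronts in the wavelets regime.
    """
    b_field = np.full(cfg.grid_shape, cfg.b, dtype=np.float64)
    inv_tau = np.full(cfg.grid_shape, 1.0 / cfg.tau_v, dtype=np.float64)
    h = cfg.heterogeneity_amplitude
    if h > 0:
        g = rng.standard_normal(cfg.grid_shape)
        g = gaussian_filter(g, cfg.heterogeneity_sigma, mode="reflect")
        sd = g.std()
        if sd > 0:
            g /= sd
        # h is expressed on the threshold scale a: h ~ 0.02 perturbs wave
        # shape, h >~ 0.2 creates scattered conduction-block patches
        b_field = cfg.b + cfg.a * h * g
        np.clip(b_field, 0.005, 0.8 * cfg.a, out=b_field)
        tau_field = cfg.tau_v * (1.0 + 2.0 * h * np.abs(g))
        inv_tau = 1.0 / tau_field
    return b_field, inv_tau


def _state_phase(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.arctan2(v - _VC, u - _UC)


def _front_width_px(cfg: SimulationConfig) -> float:
    return float(np.sqrt(cfg.diffusion / cfg.pixel_size**2 * cfg.eps))


def _broken_bar(cfg: SimulationConfig, u: np.ndarray, v: np.ndarray,
                row: int, c0: int, c1: int, flip: bool = False) -> None:
    """Stamp a horizontal wave segment with a refractory tail.

    The bar propagates away from its tail; its free end(s) curl into
    spirals.  ``flip`` puts the tail on the other side so the bar runs the
    opposite direction.
    """
    H, W = u.shape
    tb = max(3, int(round(2.0 * _front_width_px(cfg))))
    tr = 4 * tb
    r0, r1 = max(row, 0), min(row + tb, H)
    u[r0:r1, c0:c1] = 1.0
    if flip:
        v[r1:min(r1 + tr, H), c0:c1] = 0.55 * cfg.a
    else:
        v[max(r0 - tr, 0):r0, c0:c1] = 0.55 * cfg.a


def _init_regime(cfg: SimulationConfig, rng: np.random.Generator):
    """Initial fields and the list of (frame_index, stim mask) events."""
    H, W = cfg.grid_shape
    u = np.zeros((H, W))
    v = np.zeros((H, W))
    events: list[tuple[int, np.ndarray]] = []
    source_rc = None
    duration = cfg.frames * cfg.frame_interval

    def pacing_frames(period):
        times = np.arange(0.0, duration, period)
        return sorted({int(round(t / cfg.frame_interval)) for t in times})

    # stimuli must exceed the critical nucleus, which scales with the
    # front width sqrt(D eps)
    stim_px = max(4, int(round(3.0 * _front_width_px(cfg))))
    if cfg.regime == "plane":
        mask = np.zeros((H, W), bool)
        mask[:, :stim_px] = True
        if cfg.apply_stimulus:
            for f in pacing_frames(cfg.pacing_period):
                events.append((f, mask))
    elif cfg.regime == "target":
        r0 = int(rng.integers(int(0.3 * H), int(0.7 * H)))
        c0 = int(rng.integers(int(0.3 * W), int(0.7 * W)))
        source_rc = (r0, c0)
        rr, cc = np.ogrid[:H, :W]
        # the 2D critical nucleus is curvature-limited: radius must beat
        # both the front width and the tip radius scale D/c
        radius = max(4.0, 2.0 * stim_px)
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
        if cfg.apply_stimulus:
            for f in pacing_frames(cfg.pacing_period):
                events.append((f, mask))
    elif cfg.regime == "single_spiral":
        if cfg.apply_stimulus:
            cr = int(rng.integers(int(0.40 * H), int(0.60 * H)))
            cc = int(rng.integers(int(0.45 * W), int(0.55 * W)))
            _broken_bar(cfg, u, v, cr, 0, cc)
            k = int(rng.integers(0, 4))
            u = np.ascontiguousarray(np.rot90(u, k))
            v = np.ascontiguousarray(np.rot90(v, k))
    elif cfg.regime == "multi_spiral":
        if cfg.apply_stimulus:
            # two counter-oriented broken bars -> a figure-of-two rotor pair
            cr = int(rng.integers(int(0.25 * H), int(0.40 * H)))
            cc = int(rng.integers(int(0.40 * W), int(0.60 * W)))
            _broken_bar(cfg, u, v, cr, 0, cc)
            cr2 = int(rng.integers(int(0.60 * H), int(0.75 * H)))
            cc2 = int(rng.integers(int(0.40 * W), int(0.60 * W)))
            _broken_bar(cfg, u, v, cr2, cc2, W, flip=True)
    elif cfg.regime == "wavelets":
        if cfg.apply_stimulus:
            for _ in range(6):
                r0 = int(rng.integers(int(0.1 * H), int(0.8 * H)))
                c0 = int(rng.integers(int(0.1 * W), int(0.6 * W)))
                ln = int(rng.integers(int(0.3 * W), int(0.6 * W)))
                _broken_bar(cfg, u, v, r0, c0, min(c0 + ln, W),
                            flip=bool(rng.random() < 0.5))
    return u, v, events, source_rc


def measure_plane_speed_1d(cfg: SimulationConfig, strip_px: int = 256,
                           paced: bool = True) -> float:
    """Front speed of the resolved kinetics on a quasi-1D strip, in mm/s.

    Pulses are launched down a (4, strip_px) strip with the same grid
    spacing and time step as the 2D run.  With ``paced`` (default) the
    strip is stimulated at the regime's pacing period and the third
    front is fitted, capturing the mild rate dependence of conduction;
    otherwise a single pulse into fully rested tissue is fitted.  Speed
    is the inverse slope of a linear fit of upstroke time vs distance
    over the strip interior.
    """
    cfg = cfg.resolved()
    H, W = 4, strip_px
    u = np.zeros((H, W))
    v = np.zeros((H, W))
    stim_px = max(4, int(round(3.0 * _front_width_px(cfg))))
    u[:, :stim_px] = 1.0
    b_field = np.full((H, W), cfg.b)
    inv_tau = np.full((H, W), 1.0 / cfg.tau_v)
    d_px = cfg.diffusion / cfg.pixel_size**2
    act_t = np.full((H * W, 6), np.nan)
    act_n = np.zeros(H * W, dtype=np.int32)
    prev = np.zeros(H * W, dtype=np.uint8)
    work = np.empty_like(u)

    period = cfg.pacing_period if (paced and cfg.pacing_period) else None
    ordinal = 2 if period is not None else 0
    # enough time for the fitted front to clear the strip
    cross_t = 2.0 * W * cfg.pixel_size / 10_000.0  # at >= 10 mm/s
    total = (ordinal * period if period else 0.0) + cross_t
    t = 0.0
    next_stamp = period if period is not None else np.inf
    while t < total:
        t_stop = min(total, next_stamp)
        nsteps = max(1, int(round((t_stop - t) / cfg.dt)))
        t = advance(u, v, b_field, cfg.a, cfg.eps, inv_tau, d_px, cfg.dt,
                    t, nsteps, act_t, act_n, prev, work)
        if t >= next_stamp - 0.5 * cfg.dt:
            u[:, :stim_px] = 1.0
            next_stamp += period

    times = act_t[:, ordinal].reshape(H, W)[1]
    j0 = max(int(0.15 * W), stim_px + int(3 * _front_width_px(cfg)))
    j1 = int(0.9 * W)
    cols = np.arange(j0, j1)
    tt = times[j0:j1]
    ok = np.isfinite(tt)
    if ok.sum() < 10:
        raise SimulationInstabilityError(
            "plane front did not traverse the calibration strip; "
            f"check diffusion={cfg.diffusion} and eps={cfg.eps}")
    slope = np.polyfit(cols[ok] * cfg.pixel_size, tt[ok], 1)[0]  # s/μm
    return 1.0 / slope / 1000.0


def diffusion_for_speed(target_mm_s: float,
                        cfg: SimulationConfig | None = None) -> float:
    """Diffusion coefficient (μm²/s) giving a plane-front speed target.

    Uses the √D scaling of front speed: one calibration run at the preset
    diffusion, then quadratic rescaling.
    """
    cfg = (cfg or SimulationConfig(regime="plane")).resolved()
    D = cfg.diffusion
    # two passes: the second corrects the small departure from pure
    # sqrt(D) scaling introduced by the finite-grid front width
    for _ in range(2):
        c = measure_plane_speed_1d(replace(cfg, diffusion=D, dt=None,
                                           frame_stride=None))
        D = D * (target_mm_s / c) ** 2
    return D


def simulate_monolayer(config: SimulationConfig) -> tuple[VideoStack,
                                                          GroundTruth]:
    """Run one synthetic recording; returns the state video and its truth.

    The returned video holds the raw excitation variable u in [0, ~1];
    pass it through :func:`render_optical` for voltage-dye-like or
    dye-free (motion-like) contrast.  Identical (config, seed) give
    bit-identical output.
    """
    cfg = config.resolved()
    rng = substream(cfg.seed, f"medium:{cfg.regime}")
    H, W = cfg.grid_shape
    b_field, inv_tau = _heterogeneity_fields(cfg, rng)
    u, v, events, source_rc = _init_regime(cfg, rng)
    events_by_frame: dict[int, list[np.ndarray]] = {}
    for f, mask in events:
        events_by_frame.setdefault(f, []).append(mask)

    d_px = cfg.diffusion / cfg.pixel_size**2
    max_cycles = max(8, int(cfg.frames * cfg.frame_interval / 0.1))
    act_t = np.full((H * W, max_cycles), np.nan)
    act_n = np.zeros(H * W, dtype=np.int32)
    prev = np.zeros(H * W, dtype=np.uint8)
    work = np.empty_like(u)

    frames_out = np.empty((cfg.frames, H, W), dtype=np.float32)
    sing_count = np.zeros(cfg.frames, dtype=np.int64)
    # wavelets only: if early extinction strikes, re-ignite with fresh
    # broken bars.  Conditional on the (deterministic) state, so live
    # wavelet activity is never reset by a shock.
    reignite = set()
    if cfg.regime == "wavelets" and cfg.apply_stimulus:
        step = max(1, int(round(0.2 / cfg.frame_interval)))
        reignite = set(range(step, cfg.frames, step))

    # frame f is the state at t = f * frame_interval: capture, then step
    t = 0.0
    for f in range(cfg.frames):
        for mask in events_by_frame.get(f, []):
            u[mask] = 1.0
        if f in reignite and (u > 0.5).mean() < 0.02:
            for _ in range(4):
                r0 = int(rng.integers(int(0.1 * H), int(0.8 * H)))
                c0 = int(rng.integers(int(0.1 * W), int(0.6 * W)))
                ln = int(rng.integers(int(0.3 * W), int(0.6 * W)))
                _broken_bar(cfg, u, v, r0, c0, min(c0 + ln, W),
                            flip=bool(rng.random() < 0.5))
        frames_out[f] = u
        sing_count[f] = find_singularities(_state_phase(u, v)).shape[0]
        if f == cfg.frames - 1:
            break
        t = advance(u, v, b_field, cfg.a, cfg.eps, inv_tau, d_px,
                    cfg.dt, t, cfg.frame_stride, act_t, act_n, prev, work)
        if not np.isfinite(u).all() or np.abs(u).max() > 10.0:
            raise SimulationInstabilityError(
                f"field diverged at t={t:.3f}s; reduce dt={cfg.dt:g} or "
                f"diffusion={cfg.diffusion:g}")

    n_cycles = int(act_n.max()) if act_n.max() > 0 else 0
    n_cycles = min(n_cycles, max_cycles)
    activation = act_t[:, :n_cycles].T.reshape(n_cycles, H, W).copy()

    plane_speed = None
    if cfg.regime == "plane" and cfg.apply_stimulus:
        plane_speed = measure_plane_speed_1d(cfg)

    video = VideoStack(frames=frames_out, pixel_size=cfg.pixel_size,
                       frame_interval=cfg.frame_interval,
                       provenance=cfg.config_hash())
    truth = GroundTruth(
        activation_times=activation,
        true_plane_speed=plane_speed,
        singularity_count=sing_count,
        regime_label=cfg.regime,
        source_rc=source_rc,
        pacing_period=cfg.pacing_period,
        transient_s=0.2 * cfg.frames * cfg.frame_interval,
    )
    return video, truth


def render_optical(state_video: VideoStack, noise_sd: float = 0.0,
                   blur_sigma: float = 0.0,
                   modality: str = "voltage_like",
                   seed: int = 0) -> VideoStack:
    """Turn a state video into an optical recording.

    ``voltage_like`` maps excitation monotonically to intensity (voltage
    dye); ``motion_like`` emits the absolute temporal derivative of the
    excitation variable, mimicking dye-free contrast with transients at
    both wavefront and waveback.  Gaussian blur then i.i.d. Gaussian noise
    are applied per frame.  Output shape equals input shape.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be non-negative")
    if modality not in ("voltage_like", "motion_like"):
        raise ValueError(f"unknown modality {modality!r}")
    frames = np.asarray(state_video.frames, dtype=np.float64)
    if modality == "voltage_like":
        out = frames.copy()
    else:
        out = np.zeros_like(frames)
        out[1:] = np.abs(np.diff(frames, axis=0)) / state_video.frame_interval
    if blur_sigma > 0:
        out = gaussian_filter(out, sigma=(0.0, blur_sigma, blur_sigma),
                              mode="reflect")
    if noise_sd > 0:
        rng = substream(seed, f"render:{modality}")
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return VideoStack(frames=out, pixel_size=state_video.pixel_size,
                      frame_interval=state_video.frame_interval,
                      provenance=state_video.provenance + f"+{modality}")
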