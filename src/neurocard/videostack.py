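"""Calibrated image time series and its on-disk representation.

A :class:`VideoStack` is the common currency between the simulator and every
analyzer: a (frames, H, W) array plus the two calibration numbers that turn
pixel and frame indices into micrometres and seconds.  On disk it is a
multi-page 16-bit TIFF with a JSON sidecar carrying the calibration, the
seed and a config hash, so every output directory is self-describing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

log = logging.getLogger(__name__)

SIDECAR_SUFFIX = ".json"


@dataclass
class VideoStack:
    """A calibrated grayscale video.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity values; float or integer.
    pixel_size : float
        Size of one pixel in μm.
    frame_interval : float
        Time between stored frames in s.
    provenance : str
        A config hash for simulated data, or ``"external"``.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    provenance: str = "external"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        if not (self.pixel_size > 0 and self.frame_interval > 0):
            raise ValueError("pixel_size and frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def sample_rate(self) -> float:
        """Frame rate in Hz."""
        return 1.0 / self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds from the first frame."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + SIDECAR_SUFFIX)


def write_video(video: VideoStack, path: str | Path, seed: int | None = None,
                extra: dict | None = None) -> Path:
    """Write a multi-page 16-bit TIFF plus a JSON sidecar.

    Intensities are scaled to the full uint16 range; the affine scale is
    recorded in the sidecar so :func:`read_video` can undo it.
    """
    path = Path(path)
    arr = np.asarray(video.frames, dtype=np.float64)
    lo = float(arr.min())
    hi = float(arr.max())
    span = hi - lo if hi > lo else 1.0
    scaled = np.round((arr - lo) / span * 65535.0).astype(np.uint16)
    tifffile.imwrite(path, scaled, photometric="minisblack")
    meta = {
        "pixel_size_um": video.pixel_size,
        "frame_interval_s": video.frame_interval,
        "provenance": video.provenance,
        "intensity_offset": lo,
        "intensity_scale": span / 65535.0,
    }
    if seed is not None:
        meta["seed"] = int(seed)
    if extra:
        meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_video(path: str | Path, pixel_size: float | None = None,
               frame_interval: float | None = None) -> VideoStack:
    """Load a TIFF (or .npy) video with calibration attached.

    Calibration comes from the JSON sidecar when present; a sidecar value
    overrides a conflicting argument with a logged warning.  If neither
    source provides calibration a ValueError is raised — it is never
    guessed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npy":
        frames = np.load(path)
    else:
        frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    frames = np.asarray(frames, dtype=np.float64)

    meta: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        if "intensity_scale" in meta:
            frames = frames * meta["intensity_scale"] + meta.get(
                "intensity_offset", 0.0)

    def pick(name: str, arg: float | None) -> float:
        val = meta.get(name)
        if val is not None:
            if arg is not None and not np.isclose(arg, val):
                log.warning("sidecar %s=%g overrides argument %g for %s",
                            name, val, arg, path)
            return float(val)
        if arg is not None:
            return float(arg)
        raise ValueError(
            f"no {name} for {path}: pass it explicitly or provide a sidecar")

    return VideoStack(
        frames=frames,
        pixel_size=pick("pixel_size_um", pixel_size),
        frame_interval=pick("frame_interval_s", frame_interval),
        provenance=str(meta.get("provenance", "external")),
    )
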