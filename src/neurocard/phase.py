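"""Phase mapping and phase-singularity detection.

A spiral wave (rotor) pivots around a phase singularity: a point where the
instantaneous phase is undefined and the winding number of the phase around
any small loop enclosing it is ±1.  Singularities are found on 2×2 pixel
plaquettes by summing the wrapped phase differences around the loop; a sum
of ±2π marks a singularity of that chirality.

Two phase constructions are used in this package: the simulator counts
singularities on the phase of its own state variables (ground truth), while
the analyzer builds phase from optical traces via the analytic signal
(:func:`phase_map`).  Both share the plaquette winding count below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import butter, hilbert, sosfiltfilt


def wrap_phase(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences to (−π, π]."""
    return np.pi - np.mod(np.pi - dphi, 2.0 * np.pi)


def find_singularities(phase: np.ndarray, valid: np.ndarray | None = None):
    """Locate phase singularities in one (H, W) phase frame.

    Returns an (n, 3) float array of rows (row, col, chirality) where
    (row, col) is the top-left corner of the 2×2 plaquette whose loop
    winding number is ±1.
    """
    p = phase
    # wrapped differences along the plaquette loop, counter-clockwise
    d1 = wrap_phase(p[1:, :-1] - p[:-1, :-1])   # down the left edge
    d2 = wrap_phase(p[1:, 1:] - p[1:, :-1])     # along the bottom
    d3 = wrap_phase(p[:-1, 1:] - p[1:, 1:])     # up the right edge
    d4 = wrap_phase(p[:-1, :-1] - p[:-1, 1:])   # along the top
    winding = (d1 + d2 + d3 + d4) / (2.0 * np.pi)
    hit = np.abs(np.abs(winding) - 1.0) < 0.01
    if valid is not None:
        ok = valid[:-1, :-1] & valid[1:, :-1] & valid[:-1, 1:] & valid[1:, 1:]
        hit &= ok
    rows, cols = np.nonzero(hit)
    chir = np.sign(winding[rows, cols])
    return np.column_stack([rows, cols, chir]).astype(np.float64)


def singularity_counts(phase_stack: np.ndarray,
                       valid: np.ndarray | None = None) -> np.ndarray:
    """Number of phase singularities in each frame of a (T, H, W) stack."""
    return np.array([find_singularities(f, valid).shape[0]
                     for f in phase_stack], dtype=np.int64)


def link_tracks(singularities: np.ndarray, radius: float = 6.0
                ) -> tuple[np.ndarray, np.ndarray]:
    """Greedy frame-to-frame linking of singularities into tracks.

    A singularity is linked to the nearest same-chirality singularity of
    the previous frame within ``radius`` pixels.  Returns (track_id per
    singularity, length in frames per track).  Real rotors persist for
    many frames; phase noise produces one-frame flickers.
    """
    n = singularities.shape[0]
    ids = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return ids, np.zeros(0, dtype=np.int64)
    frames = singularities[:, 0].astype(int)
    by_frame: dict[int, list[int]] = {}
    for i in range(n):
        by_frame.setdefault(frames[i], []).append(i)
    lengths: list[int] = []
    prev_frame = None
    prev_list: list[int] = []
    for f in sorted(by_frame):
        cand = prev_list if prev_frame == f - 1 else []
        used: set[int] = set()
        for i in by_frame[f]:
            r, c, ch = singularities[i, 1:4]
            best, best_d = -1, radius
            for j in cand:
                if singularities[j, 3] != ch or ids[j] in used:
                    continue
                d = np.hypot(singularities[j, 1] - r,
                             singularities[j, 2] - c)
                if d <= best_d:
                    best, best_d = j, d
            if best >= 0:
                ids[i] = ids[best]
                used.add(ids[i])
                lengths[ids[i]] += 1
            else:
                ids[i] = len(lengths)
                lengths.append(1)
        prev_frame, prev_list = f, by_frame[f]
    return ids, np.asarray(lengths, dtype=np.int64)


@dataclass
class PhaseField:
    """Instantaneous phase per pixel per frame, plus detected singularities.

    ``phase`` is (T, H, W) radians in (−π, π]; ``singularities`` is an
    (n, 4) array of rows (frame, row, col, chirality); ``valid`` marks
    pixels whose traces carried enough signal for a meaningful phase.
    ``track_ids``/``track_lengths`` link singularities into rotor tracks.
    """

    phase: np.ndarray
    singularities: np.ndarray
    valid: np.ndarray
    frame_interval: float
    track_ids: np.ndarray | None = None
    track_lengths: np.ndarray | None = None

    def counts_per_frame(self, min_life: int = 0) -> np.ndarray:
        """Singularities per frame, optionally only from tracks that
        persist at least ``min_life`` frames (suppresses phase noise)."""
        T = self.phase.shape[0]
        counts = np.zeros(T, dtype=np.int64)
        if not self.singularities.size:
            return counts
        sel = np.ones(self.singularities.shape[0], dtype=bool)
        if min_life > 0:
            if self.track_ids is None:
                ids, lens = link_tracks(self.singularities)
            else:
                ids, lens = self.track_ids, self.track_lengths
            sel = lens[ids] >= min_life
        idx, c = np.unique(self.singularities[sel, 0].astype(int),
                           return_counts=True)
        counts[idx] = c
        return counts


def phase_map(traces: np.ndarray, frame_interval: float,
              band_hz: tuple[float, float] = (0.5, 10.0),
              min_amplitude_frac: float = 0.1,
              spatial_sigma: float = 1.0) -> PhaseField:
    """Instantaneous phase of baseline-subtracted traces via analytic signal.

    Parameters
    ----------
    traces : ndarray, shape (T, H, W)
        Baseline-subtracted (zero-mean) optical traces.
    band_hz : (low, high)
        Band-pass applied before the Hilbert transform; the upper edge is
        clipped below the Nyquist frequency.
    min_amplitude_frac : float
        Pixels whose peak-to-peak range is below this fraction of the
        median pixel range are excluded (near-constant traces have no
        meaningful phase).
    spatial_sigma : float
        Gaussian smoothing (px) applied to the complex analytic signal
        per frame before the angle is taken.  During diastole the
        analytic signal sits near the origin and pixel noise would make
        the phase wander, littering the field with spurious plaquette
        windings; smoothing the complex signal (never the wrapped phase)
        removes these while preserving genuine rotor singularities.
    """
    T, H, W = traces.shape
    fs = 1.0 / frame_interval
    x = traces.reshape(T, H * W).astype(np.float64)

    ptp = x.max(axis=0) - x.min(axis=0)
    ref = np.median(ptp[ptp > 0]) if np.any(ptp > 0) else 0.0
    valid = ptp > min_amplitude_frac * ref if ref > 0 else np.zeros(H * W, bool)

    lo, hi = band_hz
    hi = min(hi, 0.45 * fs)
    if lo > 0 and hi > lo and T > 18:
        sos = butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
        x = sosfiltfilt(sos, x, axis=0)
    x = x - x.mean(axis=0)

    analytic = hilbert(x, axis=0).reshape(T, H, W)
    if spatial_sigma > 0:
        sig = (0.0, spatial_sigma, spatial_sigma)
        analytic = (gaussian_filter(analytic.real, sig, mode="nearest")
                    + 1j * gaussian_filter(analytic.imag, sig,
                                           mode="nearest"))
    phase = np.angle(analytic)
    valid2d = valid.reshape(H, W)

    sing = []
    for t in range(T):
        s = find_singularities(phase[t], valid2d)
        if s.shape[0]:
            sing.append(np.column_stack([np.full(s.shape[0], t), s]))
    singularities = (np.concatenate(sing, axis=0) if sing
                     else np.empty((0, 4)))
    ids, lens = link_tracks(singularities)
    return PhaseField(phase=phase, singularities=singularities,
                      valid=valid2d, frame_interval=frame_interval,
                      track_ids=ids, track_lengths=lens)
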