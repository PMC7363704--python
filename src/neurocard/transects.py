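"""Stereological transect analysis of cell-boundary masks.

Random line segments (transects) are cast across a segmented image of
cell boundaries; the number of boundary crossings N per transect of
length L estimates the mean spacing between cell boundaries as L/N̄
(mean intercept length).  Dividing a neuron's total dendritic process
length by that spacing estimates how many myocytes a single sympathetic
neuron can innervate in a 2D monolayer.

Conventions: transect start points are uniform over positions admitting
the whole segment inside the image (rejection sampling), angles uniform
in [0, π); the line is sampled at quarter-pixel steps and consecutive
boundary hits are merged into one crossing, so counts do not depend on
the drawn thickness of the boundary lines.  The spacing spread is
propagated to first order as sd(L/N) ≈ L·sd_N/mean_N² (per-transect
reciprocals are undefined whenever a transect crosses no boundary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .mosaic import BoundaryMask

_STEP_PX = 0.25  # sub-pixel sampling step along a transect


@dataclass
class TransectResult:
    """Crossing counts of n random transects and derived spacing."""

    transect_length: float        # μm
    counts: np.ndarray            # crossings per transect
    mean_N: float
    sd_N: float
    spacing_mean: float | None    # μm, L / mean_N
    spacing_sd: float | None      # μm, L sd_N / mean_N^2

    @property
    def n_transects(self) -> int:
        return int(self.counts.size)


@dataclass
class InnervationEstimate:
    """Myocytes innervated per neuron from process length and spacing."""

    process_length: float
    cells_min: int
    cells_max: int
    cells_mean: int
    raw_min: float
    raw_max: float
    raw_mean: float


@dataclass
class NeuriteLengthSummary:
    """Per-neuron total neurite lengths and weighted averages.

    Two weighting conventions are reported: ``by_neuron`` (each neuron's
    total counts once) and ``by_segment`` (neuron totals weighted by their
    segment counts).
    """

    per_neuron_totals: np.ndarray
    mean_by_neuron: float
    sd_by_neuron: float
    mean_by_segment: float
    sd_by_segment: float


def _count_crossings(mask: np.ndarray, r0: float, c0: float,
                     angle: float, length_px: float) -> int:
    n = int(length_px / _STEP_PX) + 1
    s = np.arange(n) * _STEP_PX
    rr = np.clip(np.round(r0 + s * np.sin(angle)).astype(int),
                 0, mask.shape[0] - 1)
    cc = np.clip(np.round(c0 + s * np.cos(angle)).astype(int),
                 0, mask.shape[1] - 1)
    hits = mask[rr, cc]
    # runs of consecutive boundary samples count once
    return int(np.sum(hits[1:] & ~hits[:-1]) + int(hits[0]))


def random_transects(mask: BoundaryMask, length_um: float = 50.0,
                     n_transects: int = 100, seed: int = 0
                     ) -> TransectResult:
    """Cast uniformly random transects and count boundary crossings."""
    m = mask.mask
    H, W = m.shape
    length_px = length_um / mask.pixel_size
    if length_px < 2:
        raise ValueError("transect must span at least 2 pixels")
    if length_px > np.hypot(H, W):
        raise ValueError(
            f"transect of {length_um} μm ({length_px:.0f} px) exceeds the "
            "image diagonal")
    rng = substream(seed, "transects")
    counts = np.empty(n_transects, dtype=np.int64)
    k = 0
    while k < n_transects:
        r0 = rng.uniform(0, H - 1)
        c0 = rng.uniform(0, W - 1)
        ang = rng.uniform(0.0, np.pi)
        r1 = r0 + length_px * np.sin(ang)
        c1 = c0 + length_px * np.cos(ang)
        if not (0 <= r1 <= H - 1 and 0 <= c1 <= W - 1):
            continue  # keep transects fully inside the image
        counts[k] = _count_crossings(m, r0, c0, ang, length_px)
        k += 1
    mean_n = float(counts.mean())
    sd_n = float(counts.std(ddof=1)) if n_transects > 1 else 0.0
    if mean_n > 0:
        spacing_mean = length_um / mean_n
        spacing_sd = length_um * sd_n / mean_n**2
    else:
        spacing_mean = spacing_sd = None
    return TransectResult(transect_length=length_um, counts=counts,
                          mean_N=mean_n, sd_N=sd_n,
                          spacing_mean=spacing_mean, spacing_sd=spacing_sd)


def spacing_from_counts(length_um: float, mean_N: float,
                        sd_N: float) -> tuple[float, float]:
    """Boundary spacing (mean, sd) from printed transect statistics."""
    if mean_N <= 0:
        raise ValueError("spacing undefined for mean_N = 0")
    return length_um / mean_N, length_um * sd_N / mean_N**2


def innervated_cell_range(process_length_um: float, spacing_mean: float,
                          spacing_sd: float,
                          rounding: str = "spacing_first"
                          ) -> InnervationEstimate:
    """Range of cell boundaries crossed by a neuron's processes.

    ``rounding="spacing_first"`` first rounds the spacing and its sd to
    integer μm (the worked-example convention: 11.9 ± 5.8 → 12 ± 6 μm);
    ``rounding="none"`` uses the spacing at full precision.  Cell counts
    are then rounded to the nearest integer, with the raw quotients also
    reported.
    """
    if spacing_sd < 0 or spacing_mean <= spacing_sd:
        raise ValueError(
            "spacing_mean must exceed spacing_sd >= 0 (otherwise the upper "
            "cell count is unbounded)")
    if rounding == "spacing_first":
        sm, ss = round(spacing_mean), round(spacing_sd)
        if sm <= ss:
            raise ValueError("rounded spacing interval includes zero")
    elif rounding == "none":
        sm, ss = spacing_mean, spacing_sd
    else:
        raise ValueError(f"unknown rounding convention {rounding!r}")
    raw_min = process_length_um / (sm + ss)
    raw_max = process_length_um / (sm - ss)
    raw_mean = process_length_um / sm
    return InnervationEstimate(
        process_length=process_length_um,
        cells_min=round(raw_min), cells_max=round(raw_max),
        cells_mean=round(raw_mean),
        raw_min=raw_min, raw_max=raw_max, raw_mean=raw_mean)


def weighted_neurite_length(per_neuron_segments: list[list[float]]
                            ) -> NeuriteLengthSummary:
    """Average total neurite length per neuron, both weighting conventions."""
    if not per_neuron_segments or any(len(s) == 0
                                      for s in per_neuron_segments):
        raise ValueError("need >= 1 neuron, each with >= 1 segment")
    totals = np.array([float(np.sum(s)) for s in per_neuron_segments])
    if np.any(np.concatenate([np.asarray(s) for s in per_neuron_segments])
              <= 0):
        raise ValueError("all segment lengths must be positive")
    weights = np.array([len(s) for s in per_neuron_segments], dtype=float)
    mean_bn = float(totals.mean())
    sd_bn = float(totals.std(ddof=1)) if totals.size > 1 else 0.0
    mean_bs = float(np.average(totals, weights=weights))
    var_bs = float(np.average((totals - mean_bs) ** 2, weights=weights))
    n = totals.size
    sd_bs = float(np.sqrt(var_bs * n / (n - 1))) if n > 1 else 0.0
    return NeuriteLengthSummary(
        per_neuron_totals=totals,
        mean_by_neuron=mean_bn, sd_by_neuron=sd_bn,
        mean_by_segment=mean_bs, sd_by_segment=sd_bs)
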