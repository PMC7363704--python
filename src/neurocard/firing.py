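"""Spike detection and the normalized firing score.

The normalized firing score quantifies how tightly detected spikes lock to
optical stimulation windows:

    score = (Ns/Ps − Nns/Pns) / (Ns/Ps + Nns/Pns)

where Ns and Nns are the numbers of detected spikes inside and outside the
stimulation windows and Ps, Pns the fractions of the recording that are
stimulated and not.  The score lies in [−1, 1]: +1 when every spike falls
in a stimulation window, −1 when none does, and its expectation is 0 for
firing that ignores the stimulus, because the counts are normalized to
rates before being compared.  (A reading of the formula with products
Ns·Ps instead of rates agrees at the ±1 endpoints but is biased away from
0 for stimulus-independent firing; it is available via ``convention=
"product"`` for comparison.)

Spikes are detected on median-baseline-subtracted traces with a threshold
of k times the MAD-estimated noise, aligned to local maxima, with an
enforced refractory gap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.stats import wilcoxon

from .trace import Trace

__all__ = [
    "Trace", "StimulationProtocol", "SpikeTrain", "FiringScoreResult",
    "DoseResponseTable", "detect_spikes", "normalized_firing_score",
    "dose_response",
]


@dataclass
class StimulationProtocol:
    """Stimulation windows within a recording span.

    Windows are closed-open intervals [start, end): a spike exactly on a
    window start counts as stimulated, one exactly on a window end does
    not.  Ps and Pns are the stimulated / unstimulated fractions of the
    span and always sum to 1.
    """

    windows: list[tuple[float, float]]
    span: tuple[float, float]

    def __post_init__(self) -> None:
        self.windows = sorted((float(a), float(b)) for a, b in self.windows)
        self.span = (float(self.span[0]), float(self.span[1]))
        self.validate()

    def validate(self) -> None:
        t0, t1 = self.span
        if not t1 > t0:
            raise ValueError("recording span must have positive length")
        prev_end = -np.inf
        for a, b in self.windows:
            if not b > a:
                raise ValueError(f"window ({a}, {b}) has non-positive length")
            if a < prev_end:
                raise ValueError("stimulation windows overlap")
            if a < t0 or b > t1:
                raise ValueError(f"window ({a}, {b}) outside span {self.span}")
            prev_end = b

    @property
    def stimulated_time(self) -> float:
        return sum(b - a for a, b in self.windows)

    @property
    def Ps(self) -> float:
        return self.stimulated_time / (self.span[1] - self.span[0])

    @property
    def Pns(self) -> float:
        return 1.0 - self.Ps

    def contains(self, t: float) -> bool:
        """True if t falls inside a stimulation window ([start, end))."""
        for a, b in self.windows:
            if a <= t < b:
                return True
        return False

    def contains_many(self, times: np.ndarray) -> np.ndarray:
        """Vectorized membership test for sorted or unsorted times."""
        if not self.windows:
            return np.zeros(np.asarray(times).shape, dtype=bool)
        edges = np.asarray(self.windows, dtype=np.float64).ravel()
        return np.searchsorted(edges, np.asarray(times),
                               side="right") % 2 == 1

    def complement(self) -> "StimulationProtocol":
        """Protocol with stimulated and unstimulated epochs swapped."""
        t0, t1 = self.span
        edges = [t0] + [e for w in self.windows for e in w] + [t1]
        comp = [(edges[i], edges[i + 1]) for i in range(0, len(edges), 2)
                if edges[i + 1] > edges[i]]
        return StimulationProtocol(windows=comp, span=self.span)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"windows": [list(w) for w in self.windows],
                              "span": list(self.span)}, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "StimulationProtocol":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(windows=[tuple(w) for w in d["windows"]],
                   span=tuple(d["span"]))


@dataclass
class SpikeTrain:
    """Sorted spike times plus their split against a protocol."""

    spike_times: np.ndarray
    Ns: int = 0
    Nns: int = 0

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike times must be sorted")

    @classmethod
    def from_times(cls, times: np.ndarray,
                   protocol: StimulationProtocol | None = None
                   ) -> "SpikeTrain":
        times = np.sort(np.asarray(times, dtype=np.float64))
        ns = nns = 0
        if protocol is not None:
            inside = protocol.contains_many(times)
            ns, nns = int(inside.sum()), int((~inside).sum())
        return cls(spike_times=times, Ns=ns, Nns=nns)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame({"beat_time_s": self.spike_times}).to_csv(path,
                                                               index=False)
        return path


@dataclass
class FiringScoreResult:
    score: float | None
    Ns: int
    Nns: int
    Ps: float
    Pns: float
    status: str  # "defined" | "undefined_no_spikes"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "score": self.score, "Ns": self.Ns, "Nns": self.Nns,
            "Ps": self.Ps, "Pns": self.Pns, "status": self.status}, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def detect_spikes(trace: Trace, median_window: float = 1.0,
                  threshold_k: float = 5.0, refractory: float = 0.2,
                  protocol: StimulationProtocol | None = None) -> SpikeTrain:
    """MAD-thresholded spike detection on a baseline-subtracted trace.

    The running median over ``median_window`` seconds is subtracted, noise
    is estimated as 1.4826×MAD of the residual, and upward crossings of
    ``threshold_k`` times that noise are aligned to the following local
    maximum.  Detections closer than ``refractory`` seconds to the
    previous one are discarded.
    """
    if not np.all(np.isfinite(trace.values)):
        raise ValueError("trace contains non-finite samples")
    fs = trace.sample_rate
    if refractory <= 1.0 / fs:
        raise ValueError("refractory must exceed one sample interval")
    w = max(3, int(round(median_window * fs)) | 1)
    x = trace.values - median_filter(trace.values, size=w, mode="nearest")
    sigma = 1.4826 * np.median(np.abs(x - np.median(x)))
    if sigma == 0:
        sigma = np.finfo(float).tiny
    thr = threshold_k * sigma

    above = x >= thr
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    times = []
    last = -np.inf
    half = max(1, int(round(0.5 * refractory * fs)))
    for i in crossings:
        # a crossing must be followed by a genuine local maximum, but the
        # reported time is the (sub-sample) upstroke crossing itself
        if np.max(x[i:i + half]) < thr:
            continue
        frac = (thr - x[i - 1]) / (x[i] - x[i - 1])
        t = trace.t0 + (i - 1 + frac) / fs
        if t - last >= refractory:
            times.append(t)
            last = t
    return SpikeTrain.from_times(np.asarray(times), protocol)


def normalized_firing_score(spikes: SpikeTrain,
                            protocol: StimulationProtocol,
                            convention: str = "rate") -> FiringScoreResult:
    """The stimulation-locking score in [−1, 1]; see the module docstring."""
    ps, pns = protocol.Ps, protocol.Pns
    if ps <= 0 or pns <= 0:
        raise ValueError(
            "degenerate protocol: both stimulated and unstimulated time "
            "must be positive")
    if spikes.Ns + spikes.Nns != spikes.n_spikes:
        spikes = SpikeTrain.from_times(spikes.spike_times, protocol)
    ns, nns = spikes.Ns, spikes.Nns
    if ns + nns == 0:
        return FiringScoreResult(score=None, Ns=0, Nns=0, Ps=ps, Pns=pns,
                                 status="undefined_no_spikes")
    if convention == "rate":
        num, den = ns / ps - nns / pns, ns / ps + nns / pns
    elif convention == "product":
        num, den = ns * ps - nns * pns, ns * ps + nns * pns
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return FiringScoreResult(score=num / den, Ns=ns, Nns=nns, Ps=ps,
                             Pns=pns, status="defined")


@dataclass
class DoseResponseTable:
    """Per-neuron-ratio firing-score summaries."""

    rows: pd.DataFrame  # ratio, n, median_score, p_value, flagged

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.rows.to_csv(path, index=False)
        return path


def dose_response(scores_by_ratio: dict[float, list[float | None]]
                  ) -> DoseResponseTable:
    """Group medians and signed-rank tests against zero effect.

    Each group holds per-well firing scores; None entries (undefined
    scores from spike-free wells) are dropped.  A group left with no
    defined scores is flagged and excluded from testing.  A group whose
    scores are all exactly zero gets p = 1 by convention (the signed-rank
    statistic is undefined with no nonzero differences).
    """
    rows = []
    for ratio in sorted(scores_by_ratio):
        vals = [s for s in scores_by_ratio[ratio] if s is not None]
        if len(scores_by_ratio[ratio]) == 0:
            raise ValueError(f"group {ratio} is empty")
        if not vals:
            rows.append(dict(ratio=ratio, n=0, median_score=np.nan,
                             p_value=np.nan, flagged=True))
            continue
        arr = np.asarray(vals, dtype=np.float64)
        if np.all(arr == 0):
            p = 1.0
        else:
            p = float(wilcoxon(arr, alternative="two-sided",
                               zero_method="wilcox").pvalue)
        rows.append(dict(ratio=ratio, n=len(vals),
                         median_score=float(np.median(arr)),
                         p_value=p, flagged=False))
    return DoseResponseTable(rows=pd.DataFrame(rows))
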