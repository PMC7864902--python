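"""Polysome-gradient trace segmentation and ribosomal area ratios.

An A254/A260 absorbance trace along a sucrose gradient resolves the small
(40S) and large (60S) ribosomal subunits, the 80S monosome, and a series
of polysome peaks. This module detects peaks, partitions the trace into
labelled regions bounded by the absorbance valleys between adjacent
peaks, subtracts a per-region linear baseline drawn between the trace
values at the region boundaries, and integrates the baseline-corrected
signal with the trapezoid rule (negative excursions clipped to zero).

Reported ratios:

* ``pm_ratio``   — polysome-to-monosome, sum of polysome areas / 80S area
  (the monosome is the 80S peak alone);
* ``ratio_60_80`` — free large subunit accumulation, 60S area / 80S area.

Elevated values of either indicate impaired translation elongation or
80S assembly. Cross-fraction western signal distributions (e.g. the
fraction of total eIF5A found in the 80S lane) are summarised with
:func:`fraction_in_lane`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

SUBUNIT_LABELS = ("40S", "60S", "80S")


@dataclass(frozen=True)
class Trace:
    """A sampled absorbance curve along the gradient."""

    positions: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        absb = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "absorbance", absb)
        if pos.shape != absb.shape or pos.ndim != 1:
            raise ValueError("positions and absorbance must be 1-D arrays of equal length")
        if pos.size < 50:
            raise ValueError(f"trace too short: {pos.size} samples (need >= 50)")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if not (np.isfinite(pos).all() and np.isfinite(absb).all()):
            raise ValueError("trace contains non-finite values")

    def __len__(self) -> int:
        return self.positions.size


@dataclass(frozen=True)
class Region:
    """A labelled slice of the trace with its baseline-corrected area."""

    label: str
    start_index: int  # inclusive
    end_index: int    # inclusive (regions share boundary samples)
    peak_index: int
    area: float


@dataclass(frozen=True)
class TraceSegmentation:
    """Labelled regions with areas and the derived ribosomal ratios."""

    regions: tuple[Region, ...]
    pm_ratio: float
    ratio_60_80: float

    def area(self, label: str) -> float:
        for r in self.regions:
            if r.label == label:
                return r.area
        raise KeyError(f"no region labelled {label!r}")

    @property
    def polysome_area(self) -> float:
        return sum(r.area for r in self.regions if r.label.startswith("polysome"))


@dataclass(frozen=True)
class FractionSignal:
    """Per-lane western signal of one antibody across gradient fractions."""

    lanes: tuple[str, ...]
    signal: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.lanes) != len(self.signal):
            raise ValueError("lanes and signal must have equal length")
        if any(v < 0 for v in self.signal):
            raise ValueError("signals must be non-negative")
        if not any(v > 0 for v in self.signal):
            raise ValueError("all-zero signal: fractions undefined")


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge-shrinking window."""
    if window <= 1:
        return y.astype(float)
    kernel = np.ones(window) / window
    padded = np.pad(y.astype(float), window // 2, mode="edge")
    out = np.convolve(padded, kernel, mode="same")
    half = window // 2
    return out[half:half + y.size]


def detect_peaks(
    trace: Trace,
    min_prominence: float = 0.05,
    smoothing_window: int = 9,
    min_width: int | None = None,
) -> np.ndarray:
    """Indices of local maxima of the smoothed trace, ordered by position.

    ``min_prominence`` is a fraction of the smoothed trace's amplitude
    (max minus min). ``min_width`` (samples, at half prominence) rejects
    narrow noise spikes; it defaults to twice ``smoothing_window``,
    because averaging over *w* samples leaves noise correlated on the
    scale *w* — a real peak must clearly outlast the smoothing scale.
    Raises if nothing passes the
    threshold, advising a lower one.
    """
    if not 0 < min_prominence < 1:
        raise ValueError("min_prominence must be a fraction in (0, 1)")
    if min_width is None:
        min_width = 2 * smoothing_window
    smoothed = _smooth(trace.absorbance, smoothing_window)
    amplitude = smoothed.max() - smoothed.min()
    if amplitude <= 0:
        raise ValueError("flat trace: no peaks detectable")
    peaks, _ = sps.find_peaks(
        smoothed, prominence=min_prominence * amplitude, width=min_width
    )
    if peaks.size == 0:
        raise ValueError(
            "no peaks found; lower min_prominence or check the trace"
        )
    return peaks


def default_labels(n_peaks: int) -> list[str]:
    """40S, 60S, 80S for the first three peaks; polysome_k for the rest."""
    labels = list(SUBUNIT_LABELS[:n_peaks])
    labels += [f"polysome_{k}" for k in range(1, n_peaks - len(labels) + 1)]
    return labels


def _region_area(
    positions: np.ndarray, values: np.ndarray, anchors: np.ndarray, lo: int, hi: int
) -> float:
    """Trapezoidal area above the chord baseline joining the endpoints.

    ``values`` is the smoothed signal: a centred moving average preserves
    area, and clipping the smoothed rather than raw signal at zero avoids
    rectifying noise into a systematic positive area bias. Baseline
    endpoint values come from ``anchors`` so a single noisy boundary
    sample cannot tilt the whole baseline.
    """
    x = positions[lo:hi + 1]
    y = values[lo:hi + 1]
    baseline = np.interp(x, [x[0], x[-1]], [anchors[lo], anchors[hi]])
    corrected = np.clip(y - baseline, 0.0, None)
    return float(np.trapezoid(corrected, x))


def segment_trace(
    trace: Trace,
    peaks: Sequence[int] | np.ndarray,
    labels: Sequence[str] | None = None,
    smoothing_window: int = 9,
) -> TraceSegmentation:
    """Partition the trace at inter-peak valleys and integrate each region.

    Parameters
    ----------
    trace
        The absorbance trace.
    peaks
        Sample indices of the peaks, strictly increasing (as returned by
        :func:`detect_peaks`).
    labels
        One label per peak, drawn from ``40S``/``60S``/``80S``/
        ``polysome_k``. Defaults to positional assignment: the first
        three peaks are 40S, 60S, 80S and every later peak a polysome.

    smoothing_window
        Moving-average window used to locate valleys and to read the
        baseline anchor values; integration always uses the raw trace.

    Region boundaries are the absorbance minima between adjacent peaks,
    plus the trace ends. Each region's baseline is the straight line
    joining the smoothed trace values at its boundaries; the area is the
    trapezoidal integral of the baseline-subtracted signal, clipped at
    zero. Ratios that need a missing label (no 80S, no polysomes, no 60S)
    are reported as ``nan``.
    """
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size < 2:
        raise ValueError(f"need at least 2 labelled peaks, got {peaks.size}")
    if not np.all(np.diff(peaks) > 0):
        raise ValueError("peak indices must be strictly increasing")
    if peaks[0] < 0 or peaks[-1] >= len(trace):
        raise ValueError("peak index out of trace bounds")
    if labels is None:
        labels = default_labels(peaks.size)
    if len(labels) != peaks.size:
        raise ValueError(f"{len(labels)} labels for {peaks.size} peaks")

    smoothed = _smooth(trace.absorbance, smoothing_window)
    # baseline anchors average over a wider window than peak smoothing:
    # valley floors are locally flat, so the extra averaging suppresses
    # noise without biasing the anchor up the peak flanks
    anchors = _smooth(trace.absorbance, 2 * smoothing_window + 1)

    # valleys between adjacent peaks located on the anchor-smoothed signal
    # (ties on a flat valley floor then resolve inside the plateau rather
    # than at a peak's base); boundary samples are shared
    boundaries = [0]
    for left, right in zip(peaks[:-1], peaks[1:]):
        valley = left + int(np.argmin(anchors[left:right + 1]))
        boundaries.append(valley)
    boundaries.append(len(trace) - 1)

    regions = tuple(
        Region(
            label=label,
            start_index=lo,
            end_index=hi,
            peak_index=int(pk),
            area=_region_area(trace.positions, smoothed, anchors, lo, hi),
        )
        for label, pk, lo, hi in zip(labels, peaks, boundaries[:-1], boundaries[1:])
    )

    areas = {r.label: r.area for r in regions}
    poly = sum(a for lbl, a in areas.items() if lbl.startswith("polysome"))
    a80 = areas.get("80S", np.nan)
    pm = poly / a80 if "80S" in areas and any(
        lbl.startswith("polysome") for lbl in areas
    ) else float("nan")
    r6080 = areas["60S"] / a80 if "60S" in areas and "80S" in areas else float("nan")
    return TraceSegmentation(regions=regions, pm_ratio=float(pm), ratio_60_80=float(r6080))


def analyze_trace(
    trace: Trace,
    min_prominence: float = 0.05,
    smoothing_window: int = 9,
    labels: Sequence[str] | None = None,
) -> TraceSegmentation:
    """Detect peaks and segment in one call."""
    peaks = detect_peaks(trace, min_prominence, smoothing_window)
    return segment_trace(trace, peaks, labels, smoothing_window)


def fraction_in_lane(signal: FractionSignal, lane: str) -> float:
    """Share of the antibody's total cross-gradient signal in one lane."""
    if lane not in signal.lanes:
        raise KeyError(f"lane {lane!r} not present (lanes: {signal.lanes})")
    total = sum(signal.signal)
    return signal.signal[signal.lanes.index(lane)] / total
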