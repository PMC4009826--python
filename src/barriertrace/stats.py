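"""Headline per-cell statistics and group comparisons.

Barrier Index (BI): during mother-side FLIP, the time of 50 % fluorescence
loss in the bud divided by that in the mother; BI ~ 1 means free exchange
across the bud neck, high BI a strong barrier.  Asymmetry index:
(Im - Ib)/(Im + Ib) of mean cortical-ER intensity in mother vs bud, 0 for
symmetric partitioning, 1 for full mother retention.  Exclusion class:
total/partial/none depletion of a marker at the bud neck, scored from the
neck-to-flank intensity ratio of a cortical transect.  Photoconversion:
red signal appearing in the bud after a mother-side green->red pulse,
normalized so the pre-conversion frame reads 10 and an equally normalized
unconverted control cell is subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simkit import NeckProfileSample, TraceBundle

__all__ = [
    "BarrierResult",
    "AsymmetryResult",
    "ExclusionSummary",
    "PhotoconversionResult",
    "barrier_index",
    "asymmetry_index",
    "classify_exclusion",
    "exclusion_summary",
    "photoconversion_bud_signal",
    "dot_count_histogram",
    "group_compare",
]


@dataclass
class BarrierResult:
    t50_mother: float
    t50_bud: float
    barrier_index: float
    flags: tuple[str, ...] = ()


@dataclass
class AsymmetryResult:
    Im: float
    Ib: float
    index: float


@dataclass
class ExclusionSummary:
    classes: list[str]
    fractions_pct: dict[str, float]
    n: int


@dataclass
class PhotoconversionResult:
    times: np.ndarray
    mean: np.ndarray  # control-subtracted normalized red-in-bud
    sem: np.ndarray
    n_cells: int
    per_cell: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))


def barrier_index(
    t50_bud: float, t50_mother: float, flags: Sequence[str] = ()
) -> BarrierResult:
    """BI = t50(bud) / t50(mother); both must be positive and defined."""
    if not (np.isfinite(t50_bud) and t50_bud > 0):
        raise ValueError(f"t50_bud must be finite and > 0, got {t50_bud!r}")
    if not (np.isfinite(t50_mother) and t50_mother > 0):
        raise ValueError(f"t50_mother must be finite and > 0, got {t50_mother!r}")
    return BarrierResult(
        t50_mother=t50_mother,
        t50_bud=t50_bud,
        barrier_index=t50_bud / t50_mother,
        flags=tuple(flags),
    )


def asymmetry_index(Im: float, Ib: float) -> AsymmetryResult:
    """(Im - Ib) / (Im + Ib): 0 symmetric, +1 fully mother-retained."""
    if Im < 0 or Ib < 0:
        raise ValueError("intensities must be >= 0")
    total = Im + Ib
    if total <= 0:
        raise ValueError("Im + Ib must be > 0")
    return AsymmetryResult(Im=Im, Ib=Ib, index=(Im - Ib) / total)


def _smooth(y: np.ndarray, window: int = 3) -> np.ndarray:
    # window 3: wide enough to damp single-sample noise minima, narrow
    # enough not to shallow a diffraction-scale dip
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    return np.convolve(padded, kernel, mode="valid")


def classify_exclusion(
    profile: NeckProfileSample,
    flank_window: float = 1.0,
    thresholds: tuple[float, float] = (0.3, 0.7),
) -> str:
    """Score bud-neck exclusion from a cortical transect.

    r = (minimum smoothed intensity in the central third) / (mean intensity
    over the two outer flank windows of width ``flank_window`` um).
    r <= 0.3 -> 'total', 0.3 < r <= 0.7 -> 'partial', r > 0.7 -> 'none'
    (thresholds configurable).
    """
    x, y = profile.positions, profile.intensities
    span = x[-1] - x[0]
    center = 0.5 * (x[0] + x[-1])
    if span / 2.0 - flank_window < (span / 6.0):
        raise ValueError("profile too short for the requested flank window")
    smoothed = _smooth(y)
    central = (x >= center - span / 6.0) & (x <= center + span / 6.0)
    flanks = (x <= x[0] + flank_window) | (x >= x[-1] - flank_window)
    flank_mean = float(smoothed[flanks].mean())
    if flank_mean <= 0:
        raise ValueError("flank mean must be > 0")
    r = float(smoothed[central].min()) / flank_mean
    lo, hi = thresholds
    if r <= lo:
        return "total"
    if r <= hi:
        return "partial"
    return "none"


def exclusion_summary(classes: Sequence[str]) -> ExclusionSummary:
    """Fraction of cells per exclusion class, in percent."""
    classes = list(classes)
    if not classes:
        raise ValueError("no cells classified")
    n = len(classes)
    fractions = {
        label: 100.0 * classes.count(label) / n for label in ("total", "partial", "none")
    }
    return ExclusionSummary(classes=classes, fractions_pct=fractions, n=n)


def photoconversion_bud_signal(
    red_bundles: TraceBundle | Sequence[TraceBundle],
    control_traces: Optional[Sequence[np.ndarray]] = None,
) -> PhotoconversionResult:
    """Aggregate normalized red-in-bud over a photoconversion chase.

    Per cell: subtract the background trace from the bud's red signal,
    rescale so the pre-conversion frame (frame 0) reads exactly 10, then
    subtract an equally normalized unconverted control (by default the
    cell's first neighbor-control trace).  Cells are averaged per time
    point with the SEM across cells.
    """
    if isinstance(red_bundles, TraceBundle):
        red_bundles = [red_bundles]
    if not red_bundles:
        raise ValueError("need at least one bundle")
    times = red_bundles[0].times
    per_cell = []
    for i, bundle in enumerate(red_bundles):
        if bundle.channel != "red":
            raise ValueError(f"bundle {bundle.cell_id} is not a red-channel bundle")
        if bundle.times.shape != times.shape or not np.allclose(bundle.times, times):
            raise ValueError("bundles must share a time axis")
        bud = bundle.bud - bundle.background
        control = (
            np.asarray(control_traces[i], dtype=float)
            if control_traces is not None
            else bundle.controls[0] - bundle.background
        )
        if bud[0] <= 0:
            raise ValueError(
                f"pre-conversion red signal <= 0 after background subtraction in {bundle.cell_id}"
            )
        if control[0] <= 0:
            raise ValueError(f"pre-conversion control signal <= 0 in {bundle.cell_id}")
        per_cell.append(10.0 * bud / bud[0] - 10.0 * control / control[0])
    arr = np.vstack(per_cell)
    n = arr.shape[0]
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(arr.shape[1])
    return PhotoconversionResult(
        times=times.copy(), mean=arr.mean(axis=0), sem=sem, n_cells=n, per_cell=arr
    )


def dot_count_histogram(counts: Sequence[int]) -> pd.DataFrame:
    """Frequency (percent of cells) of buds with 0, 1, 2, ... dots."""
    counts = np.asarray(list(counts), dtype=int)
    if counts.size == 0:
        raise ValueError("no counts supplied")
    if counts.min() < 0:
        raise ValueError("counts must be >= 0")
    bins = np.arange(counts.max() + 1)
    freq = np.array([(counts == b).sum() for b in bins])
    return pd.DataFrame(
        {"n_dots": bins, "n_cells": freq, "percent": 100.0 * freq / counts.size}
    )


def group_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t test between per-cell statistics (Welch by default)."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("zero variance in both groups")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
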