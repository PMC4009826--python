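"""Raw-trace and image quantification.

Turns raw arbitrary-unit traces into the percent units the kinetic fits
expect: per-frame background subtraction, then per-frame division by the
mean of five unbleached neighbor cells (which cancels acquisition
photobleaching frame-exactly), then rescaling so the first frame reads
exactly 100 %.  Also provides the ROI/image primitives the exclusion and
aggregate-counting analyses need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.feature import peak_local_max

from .simkit import NeckProfileSample, SpotImage, TraceBundle

__all__ = [
    "NormalizedBundle",
    "subtract_background",
    "normalize_to_controls",
    "roi_mean_intensity",
    "count_spots",
    "extract_neck_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class NormalizedBundle:
    """Background-corrected, neighbor-normalized percent traces.

    Both traces read exactly 100 at frame 0; values above 100 later on can
    only come from noise.  ``normalization_record`` keeps the background
    and per-frame control means that were divided out.
    """

    times: np.ndarray
    mother: np.ndarray
    bud: np.ndarray
    cell_id: str = "cell0"
    normalization_record: dict = field(default_factory=dict)

    def roi(self, name: str) -> np.ndarray:
        if name not in ("mother", "bud"):
            raise KeyError("roi must be 'mother' or 'bud'")
        return getattr(self, name)


def subtract_background(bundle: TraceBundle) -> TraceBundle:
    """Subtract the per-frame background trace from every ROI trace.

    Negative results are clamped to zero; the number of clamped samples is
    logged (noise can push dim pixels below the background estimate).
    """
    bg = bundle.background
    if bg.shape != bundle.times.shape:
        raise ValueError("background trace length does not match times")

    clamped = 0

    def _sub(trace: np.ndarray) -> np.ndarray:
        nonlocal clamped
        out = trace - bg
        neg = out < 0
        clamped += int(np.sum(neg))
        return np.where(neg, 0.0, out)

    result = TraceBundle(
        times=bundle.times.copy(),
        mother=_sub(bundle.mother),
        bud=_sub(bundle.bud),
        controls=np.vstack([_sub(c) for c in bundle.controls]),
        background=np.zeros_like(bg),
        channel=bundle.channel,
        cell_id=bundle.cell_id,
        ground_truth=bundle.ground_truth,
    )
    if clamped:
        logger.info("subtract_background: clamped %d negative samples in %s", clamped, bundle.cell_id)
    return result


def normalize_to_controls(bundle: TraceBundle) -> NormalizedBundle:
    """Divide mother/bud by the per-frame mean of the five controls, pin frame 0 to 100.

    Assumes the background has already been subtracted.  Raises if the
    control mean is not strictly positive at every frame.
    """
    ctrl_mean = bundle.controls.mean(axis=0)
    if np.any(ctrl_mean <= 0):
        raise ValueError("control mean must be > 0 at every frame")

    def _norm(trace: np.ndarray) -> np.ndarray:
        ratio = trace / ctrl_mean
        if ratio[0] <= 0:
            raise ValueError("first-frame intensity must be > 0 to set the 100 % reference")
        return 100.0 * ratio / ratio[0]

    return NormalizedBundle(
        times=bundle.times.copy(),
        mother=_norm(bundle.mother),
        bud=_norm(bundle.bud),
        cell_id=bundle.cell_id,
        normalization_record={
            "control_mean": ctrl_mean,
            "background": bundle.background.copy(),
        },
    )


def roi_mean_intensity(
    image: np.ndarray,
    mask: np.ndarray,
    background_mask: Optional[np.ndarray] = None,
) -> float:
    """Mean pixel intensity under ``mask``, optionally background-corrected.

    With ``background_mask`` given, the mean over that region is
    subtracted — the z-stack bud-neck intensity measurement.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask must match image shape")
    if not mask.any():
        raise ValueError("mask is empty")
    value = float(image[mask].mean())
    if background_mask is not None:
        background_mask = np.asarray(background_mask, dtype=bool)
        if not background_mask.any():
            raise ValueError("background mask is empty")
        value -= float(image[background_mask].mean())
    return value


def count_spots(
    image: SpotImage,
    threshold_sd: float = 6.0,
    min_separation: int = 3,
) -> tuple[int, int]:
    """Count fluorescent dots per compartment by thresholded local maxima.

    The detection threshold is the background median plus ``threshold_sd``
    robust standard deviations (1.4826 * MAD) estimated from pixels outside
    both masks; maxima closer than ``min_separation`` are suppressed and
    each surviving peak is assigned to the mask containing it.
    """
    px = image.pixels
    outside = ~(image.mother_mask | image.bud_mask)
    bg = px[outside]
    if bg.size == 0:
        raise ValueError("no background pixels outside the masks")
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med)))
    threshold = med + threshold_sd * 1.4826 * mad
    if not np.isfinite(threshold) or px.max() <= threshold:
        return (0, 0)
    peaks = peak_local_max(
        px, min_distance=int(min_separation), threshold_abs=threshold, exclude_border=False
    )
    n_mother = int(sum(image.mother_mask[y, x] for y, x in peaks))
    n_bud = int(sum(image.bud_mask[y, x] for y, x in peaks))
    return n_mother, n_bud


def extract_neck_profile(
    image: np.ndarray,
    transect: np.ndarray,
    pixel_size: float = 1.0,
) -> NeckProfileSample:
    """Sample intensities along an ordered (row, col) pixel path.

    Sub-pixel coordinates are linearly interpolated; positions are the
    cumulative arc length along the path times ``pixel_size`` (um/px).
    """
    image = np.asarray(image, dtype=float)
    transect = np.asarray(transect, dtype=float)
    if transect.ndim != 2 or transect.shape[1] != 2 or transect.shape[0] < 7:
        raise ValueError("transect must be an (n >= 7, 2) array of (row, col) points")
    h, w = image.shape
    if (
        transect[:, 0].min() < 0
        or transect[:, 0].max() > h - 1
        or transect[:, 1].min() < 0
        or transect[:, 1].max() > w - 1
    ):
        raise ValueError("transect exits image bounds")
    intensities = map_coordinates(image, transect.T, order=1, mode="nearest")
    steps = np.hypot(np.diff(transect[:, 0]), np.diff(transect[:, 1]))
    positions = np.concatenate([[0.0], np.cumsum(steps)]) * pixel_size
    return NeckProfileSample(positions=positions, intensities=intensities)
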