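"""Intensity quantification: integrated density, positive cutoffs, tyr/glu
ratios, focal-plane selection, network-area measurement and per-well
plate normalization.

The central quantity is the integrated density of a region of interest —
the sum of its pixel values, identically equal to positive area times mean
gray value.  A per-channel positive cutoff derived from the ROI intensity
histogram separates stained pixels from background; measurements whose
positive area falls below a configurable fraction of the ROI are flagged
below detection and refuse to enter ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk

from .errors import (
    DegenerateHistogramError,
    EmptyROIError,
    EmptyTableError,
    PairingError,
    ParameterError,
)
from .types import ImageStack, ROIMask

logger = logging.getLogger(__name__)

__all__ = [
    "AIDMeasurement",
    "RatioMeasurement",
    "NetworkAreaResult",
    "integrated_density",
    "positive_cutoff",
    "aid_measure",
    "tyr_glu_ratio",
    "select_focal_plane",
    "mt_network_area",
    "network_mask",
    "icw_normalize",
    "PLATE_COLUMNS",
]

#: Default fraction of the ROI that must be positive for a measurement to
#: count as detected (all-or-nothing behaviour for depolymerized networks
#: without discarding sparse real ones).
DEFAULT_MIN_POSITIVE_FRACTION = 0.005

PLATE_COLUMNS = ("well", "condition", "concentration_M", "signal_afu", "hoechst_afu")


@dataclass(frozen=True)
class AIDMeasurement:
    """Integrated density above the positive cutoff for one ROI/channel."""

    channel: str
    cutoff: float
    positive_area_px: int
    positive_area_um2: float
    aid: float
    mean_gray: float
    below_detection: bool
    roi_label: str = "roi"


@dataclass(frozen=True)
class RatioMeasurement:
    """tyr/glu integrated-density ratio; undefined when either channel is
    below detection or the denominator is zero."""

    tyr_aid: float
    glu_aid: float
    ratio: Optional[float]
    defined: bool


@dataclass(frozen=True)
class NetworkAreaResult:
    """Filled area of the largest connected filament network component."""

    plane_index: int
    area_px: int
    area_um2: float
    boundary_mask: ROIMask
    below_detection: bool = False


def _as_mask(roi: ROIMask | np.ndarray) -> np.ndarray:
    return roi.mask if isinstance(roi, ROIMask) else np.asarray(roi, dtype=bool)


def integrated_density(image: np.ndarray, roi: ROIMask | np.ndarray) -> float:
    """Sum of the pixel values of ``image`` inside ``roi``.

    Raises
    ------
    EmptyROIError
        If the mask has no pixels set.
    """
    image = np.asarray(image, dtype=float)
    mask = _as_mask(roi)
    if mask.shape != image.shape:
        raise ParameterError(f"ROI shape {mask.shape} != image shape {image.shape}")
    if not mask.any():
        raise EmptyROIError("integrated density of an empty ROI is undefined")
    return float(image[mask].sum())


def positive_cutoff(
    image: np.ndarray,
    roi: ROIMask | np.ndarray,
    method: str = "otsu",
    control_background: Optional[float] = None,
    k_mad: float = 3.0,
) -> float:
    """Positive cutoff intensity from the ROI's fluorescence histogram.

    ``method="otsu"`` maximizes between-class variance on the ROI
    histogram; ``method="background_k_mad"`` places the cutoff ``k_mad``
    robust standard deviations (1.4826 x MAD) above the histogram mode;
    ``method="half_max"`` takes the midpoint between the histogram median
    and its 99.9th percentile (unbiased for plateau-like stains whose
    edges are symmetric under blur).  When ``control_background`` is
    supplied (the autofluorescence measured from a secondary-only control)
    the returned cutoff is never below it.
    """
    image = np.asarray(image, dtype=float)
    mask = _as_mask(roi)
    if mask.shape != image.shape:
        raise ParameterError("ROI and image shapes differ")
    if not mask.any():
        raise EmptyROIError("cannot derive a cutoff from an empty ROI")
    if control_background is not None and control_background < 0:
        raise ParameterError("control_background must be non-negative")

    vals = image[mask]
    if np.ptp(vals) == 0:
        raise DegenerateHistogramError(float(vals[0]))

    if method == "otsu":
        cutoff = float(threshold_otsu(vals))
    elif method == "background_k_mad":
        counts, edges = np.histogram(vals, bins=256)
        mode = float((edges[:-1] + edges[1:])[np.argmax(counts)] / 2.0)
        med = np.median(vals)
        mad = 1.4826 * float(np.median(np.abs(vals - med)))
        cutoff = mode + k_mad * mad
    elif method == "half_max":
        low = float(np.median(vals))
        high = float(np.percentile(vals, 99.9))
        cutoff = 0.5 * (low + high)
    else:
        raise ParameterError(f"unknown cutoff method {method!r}")

    if control_background is not None:
        cutoff = max(cutoff, float(control_background))
    return cutoff


def aid_measure(
    image: np.ndarray,
    roi: ROIMask | np.ndarray,
    cutoff: float,
    min_positive_fraction: float = DEFAULT_MIN_POSITIVE_FRACTION,
    pixel_size: float = 1.0,
    channel: str = "",
) -> AIDMeasurement:
    """Integrated density of the ROI pixels strictly above ``cutoff``.

    The measurement is flagged ``below_detection`` when the positive area is
    less than ``min_positive_fraction`` of the ROI area.
    """
    image = np.asarray(image, dtype=float)
    mask = _as_mask(roi)
    if mask.shape != image.shape:
        raise ParameterError("ROI and image shapes differ")
    if not mask.any():
        raise EmptyROIError("AID of an empty ROI is undefined")
    if not np.isfinite(cutoff):
        raise ParameterError("cutoff must be finite")

    positive = mask & (image > cutoff)
    area = int(positive.sum())
    aid = float(image[positive].sum()) if area else 0.0
    mean_gray = aid / area if area else 0.0
    below = area / mask.sum() < min_positive_fraction
    return AIDMeasurement(
        channel=channel,
        cutoff=float(cutoff),
        positive_area_px=area,
        positive_area_um2=area * pixel_size**2,
        aid=aid,
        mean_gray=mean_gray,
        below_detection=below,
        roi_label=roi.label if isinstance(roi, ROIMask) else "roi",
    )


def tyr_glu_ratio(tyr: AIDMeasurement, glu: AIDMeasurement) -> RatioMeasurement:
    """Ratio of tyr to glu integrated density for one ROI.

    Undefined (``defined=False``, ``ratio=None``) when either channel is
    below detection or the glu density is zero — never zero or infinity.
    Both measurements must come from the same ROI.
    """
    if tyr.roi_label != glu.roi_label:
        raise PairingError(
            f"tyr ROI {tyr.roi_label!r} does not match glu ROI {glu.roi_label!r}"
        )
    defined = not (tyr.below_detection or glu.below_detection) and glu.aid > 0
    ratio = tyr.aid / glu.aid if defined else None
    return RatioMeasurement(tyr_aid=tyr.aid, glu_aid=glu.aid, ratio=ratio, defined=defined)


def select_focal_plane(
    stack: ImageStack, channel: str, cutoff_method: str = "otsu"
) -> int:
    """Index of the plane with the largest thresholded-positive area of
    ``channel``; ties break toward the lower index."""
    if len(stack) < 1:
        raise ParameterError("empty stack")
    areas = []
    for plane in stack:
        img = plane[channel]
        full = np.ones(img.shape, dtype=bool)
        try:
            cutoff = positive_cutoff(img, full, method=cutoff_method)
        except DegenerateHistogramError:
            areas.append(0)
            continue
        areas.append(int((img > cutoff).sum()))
    return int(np.argmax(areas))


def network_mask(binary: np.ndarray, closing_radius_px: int = 5) -> np.ndarray:
    """Closing + hole filling + largest connected component of a binary
    filament mask — the filled network as bounded by its outer boundary."""
    if closing_radius_px < 0:
        raise ParameterError("closing radius must be non-negative")
    mask = np.asarray(binary, dtype=bool)
    if not mask.any():
        return mask.copy()
    if closing_radius_px > 0:
        mask = closing(mask, disk(closing_radius_px))
    mask = binary_fill_holes(mask)
    labels = cc_label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def mt_network_area(
    image: np.ndarray,
    cutoff: float,
    closing_radius_px: int = 5,
    pixel_size: float = 1.0,
    plane_index: int = 0,
) -> NetworkAreaResult:
    """Area of the microtubule network as bounded by its outer boundary.

    Thresholds at ``cutoff``, closes with a disc of ``closing_radius_px``,
    fills holes and keeps the largest connected component.  When no pixel
    exceeds the cutoff the result has zero area and is flagged below
    detection.
    """
    image = np.asarray(image, dtype=float)
    raw = image > cutoff
    if not raw.any():
        empty = ROIMask(np.zeros(image.shape, dtype=bool), "network", "threshold")
        return NetworkAreaResult(plane_index, 0, 0.0, empty, below_detection=True)
    net = network_mask(raw, closing_radius_px)
    area_px = int(net.sum())
    return NetworkAreaResult(
        plane_index=plane_index,
        area_px=area_px,
        area_um2=area_px * pixel_size**2,
        boundary_mask=ROIMask(net, "network", "threshold"),
        below_detection=False,
    )


def icw_normalize(table):
    """Per-well normalized fluorescence: ``signal_afu / hoechst_afu``.

    ``table`` is a DataFrame with columns
    ``well, condition, concentration_M, signal_afu, hoechst_afu``.  Wells
    with non-positive nucleus-stain signal are excluded (and logged); if
    every well is excluded an :class:`EmptyTableError` is raised.  Returns
    a copy with a ``normalized_fau`` column.
    """
    import pandas as pd

    if not isinstance(table, pd.DataFrame):
        raise ParameterError("expected a pandas DataFrame plate table")
    missing = [c for c in PLATE_COLUMNS if c not in table.columns]
    if missing:
        raise ParameterError(f"plate table missing columns: {missing}")

    bad = table["hoechst_afu"] <= 0
    if bad.any():
        for well in table.loc[bad, "well"]:
            logger.warning("excluding well %s: non-positive Hoechst signal", well)
    kept = table.loc[~bad].copy()
    if kept.empty:
        raise EmptyTableError("all wells excluded (non-positive Hoechst signal)")
    kept["normalized_fau"] = kept["signal_afu"] / kept["hoechst_afu"]
    return kept
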