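"""Growth-cone domain segmentation and tyr-microtubule invasion scoring.

The cone is partitioned into the total area T (union of the actin and
membrane stains), the proximal glu-occupied area Pgc, and the peripheral
region of interest ROI = T \\ Pgc.  The invasion score is the percentage of
the ROI covered by tyr-positive pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.measure import label as cc_label
from skimage.morphology import closing, dilation, disk

from .errors import EmptyConeError, EmptyROIError, ParameterError
from .intensity import positive_cutoff
from .types import GrowthConeImage, ROIMask

__all__ = [
    "GrowthConeDomains",
    "InvasionResult",
    "growthcone_total_area",
    "proximal_area",
    "peripheral_roi",
    "invasion_percent",
    "analyze_growthcone",
]


@dataclass
class GrowthConeDomains:
    """The three growth-cone masks plus the tyr-positive invasion mask.

    Invariants (checked on construction): ``Pgc`` is contained in ``T``,
    ``ROI`` equals ``T`` minus ``Pgc`` pixelwise, and the invasion mask is
    contained in the ROI.
    """

    T: ROIMask
    Pgc: ROIMask
    ROI: ROIMask
    invasion_mask: ROIMask

    def __post_init__(self) -> None:
        t, p, r, inv = (m.mask for m in (self.T, self.Pgc, self.ROI, self.invasion_mask))
        if np.any(p & ~t):
            raise ParameterError("Pgc must be contained in T")
        if not np.array_equal(r, t & ~p):
            raise ParameterError("ROI must equal T \\ Pgc")
        if np.any(inv & ~r):
            raise ParameterError("invasion mask must be contained in the ROI")


@dataclass(frozen=True)
class InvasionResult:
    """Percent of the peripheral ROI covered by tyr-positive pixels."""

    percent_invaded: float
    area_T_um2: float
    area_Pgc_um2: float
    area_ROI_um2: float


def growthcone_total_area(
    actin: np.ndarray,
    membrane: np.ndarray,
    cutoffs: tuple[float, float],
    closing_radius_px: int = 3,
) -> ROIMask:
    """Total growth-cone mask T: union of the actin- and membrane-positive
    masks, closed, hole-filled, largest connected component retained."""
    actin = np.asarray(actin, dtype=float)
    membrane = np.asarray(membrane, dtype=float)
    if actin.shape != membrane.shape:
        raise ParameterError("actin and membrane channels must share a shape")
    c_actin, c_membrane = cutoffs
    union = (actin > c_actin) | (membrane > c_membrane)
    if not union.any():
        raise EmptyConeError("both structural channels are fully sub-threshold")
    if closing_radius_px > 0:
        union = closing(union, disk(closing_radius_px))
    union = binary_fill_holes(union)
    labels = cc_label(union, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    return ROIMask(mask, label="T", provenance="threshold")


def proximal_area(
    glu: np.ndarray, cutoff: float, dilation_px: int, T: ROIMask
) -> ROIMask:
    """Proximal glu-occupied mask Pgc: glu-positive pixels dilated by
    ``dilation_px`` (absorbing the transitional band), intersected with T
    and hole-filled.  An empty glu channel yields an empty Pgc."""
    if T.is_empty:
        raise EmptyROIError("total growth-cone mask is empty")
    if dilation_px < 0:
        raise ParameterError("dilation_px must be non-negative")
    glu_pos = np.asarray(glu, dtype=float) > cutoff
    if glu_pos.any() and dilation_px > 0:
        glu_pos = dilation(glu_pos, disk(dilation_px))
    mask = glu_pos & T.mask
    if mask.any():
        mask = binary_fill_holes(mask) & T.mask
    return ROIMask(mask, label="Pgc", provenance="threshold")


def peripheral_roi(T: ROIMask, Pgc: ROIMask) -> ROIMask:
    """Peripheral region of interest: pixelwise set difference T \\ Pgc."""
    pgc = Pgc.mask & T.mask  # enforce containment before subtracting
    roi = T.mask & ~pgc
    if not roi.any():
        raise EmptyROIError("peripheral ROI is empty; invasion is not computable")
    return ROIMask(roi, label="ROI", provenance="geometry")


def invasion_percent(
    tyr: np.ndarray,
    cutoff: float,
    roi: ROIMask,
    pixel_size: float = 1.0,
    T: ROIMask | None = None,
    Pgc: ROIMask | None = None,
) -> InvasionResult:
    """Percentage of the ROI area covered by tyr-positive pixels."""
    if roi.is_empty:
        raise EmptyROIError("cannot score invasion of an empty ROI")
    tyr = np.asarray(tyr, dtype=float)
    if tyr.shape != roi.mask.shape:
        raise ParameterError("tyr channel and ROI shapes differ")
    invaded = (tyr > cutoff) & roi.mask
    percent = 100.0 * invaded.sum() / roi.area_px
    px2 = pixel_size**2
    return InvasionResult(
        percent_invaded=float(percent),
        area_T_um2=(T.area_px * px2) if T is not None else float("nan"),
        area_Pgc_um2=(Pgc.area_px * px2) if Pgc is not None else float("nan"),
        area_ROI_um2=roi.area_px * px2,
    )


def analyze_growthcone(
    image: GrowthConeImage,
    cutoff_method: str = "otsu",
    dilation_px: int = 3,
    closing_radius_px: int = 3,
) -> tuple[GrowthConeDomains, InvasionResult]:
    """Full segmentation + invasion score for one growth-cone image.

    Per-channel cutoffs are derived with the same histogram method used by
    the intensity-quantification stage, over the full frame.
    """
    full = np.ones(image.shape, dtype=bool)
    cut = {
        name: positive_cutoff(chan, full, method=cutoff_method)
        for name, chan in image.channels.items()
    }
    T = growthcone_total_area(
        image.actin, image.membrane, (cut["actin"], cut["membrane"]), closing_radius_px
    )
    Pgc = proximal_area(image.glu, cut["glu"], dilation_px, T)
    roi = peripheral_roi(T, Pgc)
    invaded = ROIMask(
        (image.tyr > cut["tyr"]) & roi.mask, label="invasion", provenance="threshold"
    )
    domains = GrowthConeDomains(T=T, Pgc=Pgc, ROI=roi, invasion_mask=invaded)
    result = invasion_percent(
        image.tyr, cut["tyr"], roi, pixel_size=image.pixel_size, T=T, Pgc=Pgc
    )
    return domains, result
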