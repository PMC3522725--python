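"""Lane densitometry: band quantification, polymerized fractions and
loading-control normalization.

A lane is a 1D intensity profile with a declared band window (windows are
metadata from the generator or the user — auto-detection is deliberately
out of scope so quantification stays auditable).  The polymerized fraction
of an analyte is the background-subtracted P-band density divided by the
summed P + S densities of its paired lanes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import grey_opening

from .errors import PairingError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "LaneDensitometry",
    "FractionPair",
    "NormalizedBand",
    "band_density",
    "percent_polymerized",
    "analyte_fraction_table",
    "normalize_to_loading",
]

COMPARTMENTS = ("P", "S", "whole")

#: samples at each end of the band window used to anchor the linear baseline
_EDGE_SAMPLES = 3


@dataclass
class LaneDensitometry:
    """One gel lane: analyte, compartment (P / S / whole), intensity
    profile and the half-open band window ``[lo, hi)``."""

    analyte: str
    compartment: str
    profile: np.ndarray
    band_window: tuple[int, int]

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.ndim != 1:
            raise ParameterError("lane profile must be 1D")
        if np.any(self.profile < 0):
            raise ParameterError("lane intensities must be non-negative")
        if self.compartment not in COMPARTMENTS:
            raise ParameterError(f"unknown compartment {self.compartment!r}")
        lo, hi = self.band_window
        if not (0 <= lo < hi <= len(self.profile)):
            raise ParameterError(
                f"band window [{lo}, {hi}) outside profile support of length "
                f"{len(self.profile)}"
            )


@dataclass(frozen=True)
class FractionPair:
    """Paired P/S band densities and the derived percent polymerized."""

    analyte: str
    p_density: float
    s_density: float
    percent_polymerized: float


@dataclass(frozen=True)
class NormalizedBand:
    """A band density divided by its loading-control density."""

    analyte: str
    raw_density: float
    loading_density: float
    normalized: float


def _linear_baseline(profile: np.ndarray, lo: int, hi: int) -> np.ndarray:
    left = float(profile[lo : lo + _EDGE_SAMPLES].mean())
    right = float(profile[hi - _EDGE_SAMPLES : hi].mean())
    x_left = lo + (_EDGE_SAMPLES - 1) / 2.0
    x_right = hi - 1 - (_EDGE_SAMPLES - 1) / 2.0
    slope = (right - left) / (x_right - x_left)
    x = np.arange(lo, hi)
    return left + slope * (x - x_left)


def _rolling_min_baseline(profile: np.ndarray, lo: int, hi: int) -> np.ndarray:
    # a plain greyscale opening rides up the band shoulders on sloped
    # backgrounds, so detrend with the window-edge line first, open the
    # residual, and add the trend back
    left = float(profile[lo : lo + _EDGE_SAMPLES].mean())
    right = float(profile[hi - _EDGE_SAMPLES : hi].mean())
    x_left = lo + (_EDGE_SAMPLES - 1) / 2.0
    x_right = hi - 1 - (_EDGE_SAMPLES - 1) / 2.0
    slope = (right - left) / (x_right - x_left)
    x = np.arange(len(profile), dtype=float)
    trend = left + slope * (x - x_left)
    size = hi - lo if (hi - lo) % 2 else hi - lo + 1
    opened = grey_opening(profile - trend, size=size, mode="nearest")
    return (opened + trend)[lo:hi]


def band_density(lane: LaneDensitometry, background: str = "linear_baseline") -> float:
    """Background-subtracted integral of the profile over the band window.

    ``background`` is ``"linear_baseline"`` (line through the window-edge
    means) or ``"rolling_min"`` (greyscale opening wider than the band).
    Negative totals are clipped to zero with a warning.
    """
    lo, hi = lane.band_window
    if background == "linear_baseline":
        baseline = _linear_baseline(lane.profile, lo, hi)
    elif background == "rolling_min":
        baseline = _rolling_min_baseline(lane.profile, lo, hi)
    else:
        raise ParameterError(f"unknown background method {background!r}")
    total = float((lane.profile[lo:hi] - baseline).sum())
    if total < 0:
        logger.warning(
            "negative band density %.3g for %s/%s clipped to 0",
            total,
            lane.analyte,
            lane.compartment,
        )
        return 0.0
    return total


def percent_polymerized(p: float, s: float) -> float:
    """Percent of an analyte in the polymerized compartment: 100 p/(p+s)."""
    if p < 0 or s < 0:
        raise ParameterError("band densities must be non-negative")
    if p + s == 0:
        raise ParameterError("undefined fraction: p + s = 0")
    return 100.0 * p / (p + s)


def analyte_fraction_table(
    lanes: list[LaneDensitometry], background: str = "linear_baseline"
) -> list[FractionPair]:
    """One :class:`FractionPair` per analyte from its P and S lanes.

    Every analyte must contribute exactly one P and one S lane; missing or
    duplicated compartments raise a :class:`PairingError` naming the
    analyte rather than being silently dropped.  ``whole`` lanes are not
    part of P/S pairing and are rejected here.
    """
    by_analyte: dict[str, dict[str, LaneDensitometry]] = {}
    for lane in lanes:
        if lane.compartment not in ("P", "S"):
            raise PairingError(
                f"lane for {lane.analyte!r} has compartment {lane.compartment!r}; "
                "P/S pairing requires P and S lanes only"
            )
        slot = by_analyte.setdefault(lane.analyte, {})
        if lane.compartment in slot:
            raise PairingError(f"duplicate {lane.compartment} lane for {lane.analyte!r}")
        slot[lane.compartment] = lane

    pairs = []
    for analyte in sorted(by_analyte):
        slot = by_analyte[analyte]
        missing = [c for c in ("P", "S") if c not in slot]
        if missing:
            raise PairingError(f"analyte {analyte!r} missing {missing} lane(s)")
        p = band_density(slot["P"], background)
        s = band_density(slot["S"], background)
        pairs.append(
            FractionPair(
                analyte=analyte,
                p_density=p,
                s_density=s,
                percent_polymerized=percent_polymerized(p, s),
            )
        )
    return pairs


def normalize_to_loading(band: float, loading: float, analyte: str = "") -> NormalizedBand:
    """Band density divided by the loading-control density."""
    if loading <= 0:
        raise ParameterError("loading-control density must be positive")
    if band < 0:
        raise ParameterError("band density must be non-negative")
    return NormalizedBand(
        analyte=analyte,
        raw_density=float(band),
        loading_density=float(loading),
        normalized=float(band) / float(loading),
    )
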