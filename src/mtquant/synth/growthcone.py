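"""Synthetic fan-shaped growth-cone fixtures with a known invasion fraction.

The cone is a circular sector opening upward from an apex.  Structural
channels (actin, membrane) fill the whole fan plus thin filopodia beyond
its rim; glu filaments are radial spokes confined to the central disc; tyr
filaments extend from the central disc into the peripheral band until their
rendered coverage of the band reaches the requested invasion fraction
(tracked pixel by pixel, so the rendered fraction matches the request to
sub-percent precision).  Channels are binary masks softened by a small
Gaussian blur and scaled to ``channel_intensity``, which keeps half-maximum
thresholding unbiased at the mask boundaries.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from ..types import GroundTruth, GrowthConeImage
from .cells import apply_noise
from .params import GrowthConeParams

__all__ = ["make_growthcone_image"]

_GLU_RECESS = 4  # px the glu spokes stop short of the central radius
_TYR_START_RECESS = 5  # px inside the central radius where tyr filaments start
_FILAMENT_HALF_WIDTH = 1  # stamp half-width -> 3 px wide filaments


def _polar(shape: tuple[int, int], apex: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = apex[0] - rr  # positive pointing up from the apex
    dc = cc - apex[1]
    return np.hypot(dr, dc), np.arctan2(dc, dr)


def _stamp(mask: np.ndarray, r: float, c: float, half: int) -> None:
    r0, c0 = int(round(r)), int(round(c))
    lo_r = max(r0 - half, 0)
    hi_r = min(r0 + half + 1, mask.shape[0])
    lo_c = max(c0 - half, 0)
    hi_c = min(c0 + half + 1, mask.shape[1])
    mask[lo_r:hi_r, lo_c:hi_c] = True


def _radial_walk(
    rng: np.random.Generator,
    apex: tuple[float, float],
    angle: float,
    start_dist: float,
    max_dist: float,
    jitter: float = 0.06,
):
    """Yield (row, col) points walking outward from the apex with small
    angular jitter."""
    d = start_dist
    a = angle
    while d <= max_dist:
        yield apex[0] - d * np.cos(a), apex[1] + d * np.sin(a)
        a += rng.normal(0.0, jitter)
        d += 0.5


def _soft_channel(
    mask: np.ndarray,
    intensity: float,
    background: float,
    blur_sigma: float = 0.6,
) -> np.ndarray:
    return gaussian_filter(mask.astype(float), blur_sigma) * intensity + background


def make_growthcone_image(
    params: GrowthConeParams, seed: int, fixture_id: str = "cone"
) -> tuple[GrowthConeImage, GroundTruth]:
    """Render one four-channel growth cone with known ground truth.

    The returned image's ``meta`` carries the rendered binary masks
    (``T``, ``Pgc``, ``ROI``, ``tyr``) for use as test oracles; the
    :class:`GroundTruth` records the exact rendered invasion fraction and
    domain areas in pixels.
    """
    rng = np.random.default_rng(seed)
    h, w = params.image_size
    half_angle = np.deg2rad(params.fan_angle) / 2.0
    R = params.central_radius + params.peripheral_width
    apex = (0.88 * h, 0.5 * w)
    dist, ang = _polar((h, w), apex)

    sector = (dist <= R) & (np.abs(ang) <= half_angle)

    # filopodia: thin protrusions beyond the rim, part of the total area
    filopodia = np.zeros((h, w), dtype=bool)
    for _ in range(params.filopodia_count):
        a = rng.uniform(-half_angle * 0.95, half_angle * 0.95)
        length = rng.uniform(8.0, 14.0)
        for r, c in _radial_walk(rng, apex, a, R - 1.0, R + length, jitter=0.02):
            _stamp(filopodia, r, c, 0)
    t_true = sector | filopodia

    pgc_true = sector & (dist <= params.central_radius)
    roi_true = t_true & ~pgc_true
    roi_area = int(roi_true.sum())

    # glu: radial spokes confined to the central disc (3 px wide; started
    # away from the apex so overlap there does not skew the histogram top)
    glu_mask = np.zeros((h, w), dtype=bool)
    n_spokes = max(14, int(params.fan_angle / 5.0))
    spoke_angles = np.linspace(-half_angle * 0.96, half_angle * 0.96, n_spokes)
    for a in spoke_angles:
        for r, c in _radial_walk(
            rng, apex, a, 2.0, params.central_radius - _GLU_RECESS, jitter=0.015
        ):
            _stamp(glu_mask, r, c, 1)
    glu_mask &= dist <= params.central_radius  # geometric exclusivity

    # tyr: central filaments plus controlled invasion into the band
    tyr_mask = np.zeros((h, w), dtype=bool)
    for a in np.linspace(-half_angle * 0.9, half_angle * 0.9, 8):
        for r, c in _radial_walk(
            rng, apex, a, 6.0, params.central_radius - _TYR_START_RECESS, jitter=0.02
        ):
            _stamp(tyr_mask, r, c, _FILAMENT_HALF_WIDTH)
    tyr_mask &= dist <= params.central_radius - _TYR_START_RECESS - 2

    f = params.true_invasion_fraction
    if f >= 1.0:
        grown = gaussian_filter(t_true.astype(float), 1.0) > 1e-6  # ~2 px dilation
        band_mask = grown & (dist >= params.central_radius - _TYR_START_RECESS - 7)
        tyr_mask |= band_mask
        covered = roi_area
    elif f > 0.0:
        target = int(round(f * roi_area))
        covered_mask = np.zeros((h, w), dtype=bool)
        covered = 0
        start = params.central_radius - _TYR_START_RECESS
        for _ in range(800):
            if covered >= target:
                break
            a = rng.uniform(-half_angle * 0.97, half_angle * 0.97)
            max_d = start + rng.uniform(8.0, params.peripheral_width + 8.0)
            for r, c in _radial_walk(rng, apex, a, start, max_d, jitter=0.05):
                if not (0 <= r < h and 0 <= c < w) or not t_true[int(r), int(c)]:
                    break
                r0, c0 = int(round(r)), int(round(c))
                win = (
                    slice(max(r0 - 1, 0), min(r0 + 2, h)),
                    slice(max(c0 - 1, 0), min(c0 + 2, w)),
                )
                tyr_mask[win] |= t_true[win]
                new = roi_true[win] & ~covered_mask[win]
                covered += int(new.sum())
                covered_mask[win] |= roi_true[win]
                if covered >= target:
                    break
        # deficit fill for very high fractions the random walk cannot reach
        if covered < target:
            free = np.argwhere(roi_true & ~covered_mask)
            rng.shuffle(free)
            for r0, c0 in free:
                if covered >= target:
                    break
                if not covered_mask[r0, c0]:
                    covered_mask[r0, c0] = True
                    tyr_mask[r0, c0] = True
                    covered += 1
    else:
        covered = 0

    rendered_fraction = (
        float((tyr_mask & roi_true).sum()) / roi_area if roi_area else 0.0
    )

    intensity = params.channel_intensity
    bg = params.background_level
    clean = {
        "tyr": _soft_channel(tyr_mask, intensity, bg),
        "glu": _soft_channel(glu_mask, intensity, bg),
        "actin": _soft_channel(t_true, 0.9 * intensity, bg),
        "membrane": _soft_channel(t_true, intensity, bg),
    }
    noisy = {k: apply_noise(v, params.noise, rng) for k, v in clean.items()}

    image = GrowthConeImage(
        tyr=noisy["tyr"],
        glu=noisy["glu"],
        actin=noisy["actin"],
        membrane=noisy["membrane"],
        pixel_size=params.pixel_size,
        meta={
            "clean_channels": clean,
            "T": t_true,
            "Pgc": pgc_true,
            "ROI": roi_true,
            "tyr_mask": tyr_mask,
            "glu_mask": glu_mask,
        },
    )
    truth = GroundTruth(
        fixture_id=fixture_id,
        seed=seed,
        values={
            "true_invasion_fraction": float(f),
            "rendered_invasion_fraction": rendered_fraction,
            "area_T_px": float(t_true.sum()),
            "area_Pgc_px": float(pgc_true.sum()),
            "area_ROI_px": float(roi_area),
        },
    )
    return image, truth
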