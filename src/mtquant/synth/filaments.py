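"""Rasterization of smooth random-walk filament polylines.

Filaments are modelled as 2D polylines produced by a correlated random walk
(heading perturbed by Gaussian turns at each step), rasterized by depositing
unit mass at sub-pixel sample points and convolving with a Gaussian
line-spread function.  This is the simplest model that preserves the area
and integrated-intensity statistics the measurement stages operate on.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["random_walk_polyline", "deposit_polyline", "smooth_map", "footprint"]

_SAMPLE_SPACING = 0.5  # px between deposited mass points


def random_walk_polyline(
    rng: np.random.Generator,
    start: tuple[float, float],
    heading: float,
    length: float,
    turn_sigma: float = 0.18,
    inside=None,
) -> np.ndarray:
    """Sample points along a smooth random walk.

    Parameters
    ----------
    start : (row, col) starting point.
    heading : initial direction in radians.
    length : total arc length in pixels.
    turn_sigma : std-dev of the per-step heading perturbation (radians).
    inside : optional predicate ``inside(r, c) -> bool``; the walk stops
        when it would leave the region.

    Returns an ``(n, 2)`` array of (row, col) sample points spaced
    ``0.5`` px apart.
    """
    n = max(2, int(round(length / _SAMPLE_SPACING)))
    pts = np.empty((n, 2), dtype=float)
    r, c = start
    pts[0] = (r, c)
    theta = heading
    kept = 1
    for _ in range(1, n):
        theta += rng.normal(0.0, turn_sigma)
        r += _SAMPLE_SPACING * np.sin(theta)
        c += _SAMPLE_SPACING * np.cos(theta)
        if inside is not None and not inside(r, c):
            break
        pts[kept] = (r, c)
        kept += 1
    return pts[:kept]


def deposit_polyline(canvas: np.ndarray, points: np.ndarray) -> None:
    """Deposit unit mass per sample point onto ``canvas`` (in place)."""
    if len(points) == 0:
        return
    rr = np.clip(np.round(points[:, 0]).astype(int), 0, canvas.shape[0] - 1)
    cc = np.clip(np.round(points[:, 1]).astype(int), 0, canvas.shape[1] - 1)
    np.add.at(canvas, (rr, cc), 1.0)


def smooth_map(canvas: np.ndarray, line_sigma: float, peak_intensity: float) -> np.ndarray:
    """Convolve a mass canvas with the line-spread Gaussian and rescale so the
    brightest pixel equals ``peak_intensity``."""
    blurred = gaussian_filter(canvas, sigma=line_sigma)
    peak = blurred.max()
    if peak <= 0:
        return blurred
    return blurred * (peak_intensity / peak)


def footprint(signal_map: np.ndarray, rel_threshold: float = 0.05) -> np.ndarray:
    """Boolean footprint of a rendered signal map: pixels above
    ``rel_threshold`` of the map maximum."""
    peak = signal_map.max()
    if peak <= 0:
        return np.zeros(signal_map.shape, dtype=bool)
    return signal_map > rel_threshold * peak
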