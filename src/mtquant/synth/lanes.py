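"""Synthetic paired P/S lane densitometry profiles.

Each analyte yields two 1D profiles whose background-free band integrals
are ``total_amount * fraction`` (P) and ``total_amount * (1 - fraction)``
(S).  The band is a raised-cosine bump with compact support, so the whole
band lies strictly inside the declared window and noise-free recovery is
exact; a sloped linear background and Gaussian noise are added on top.
"""

from __future__ import annotations

import numpy as np

from ..fractionation import LaneDensitometry
from ..types import GroundTruth
from .params import LaneParams

__all__ = ["make_lane_profiles"]

_WINDOW_MARGIN = 4  # background-only samples on each side of the band support


def _band_shape(params: LaneParams) -> np.ndarray:
    """Unit-sum raised-cosine bump centred on ``band_center``."""
    x = np.arange(params.profile_length, dtype=float)
    u = (x - params.band_center) / params.band_width
    shape = np.where(np.abs(u) < 1.0, np.cos(np.pi * u / 2.0) ** 2, 0.0)
    return shape / shape.sum()


def make_lane_profiles(
    params: LaneParams, seed: int, fixture_id: str = "lanes"
) -> tuple[list[LaneDensitometry], GroundTruth]:
    """Paired P/S lane profiles for every analyte in ``params.fractions``."""
    rng = np.random.default_rng(seed)
    shape = _band_shape(params)
    x = np.arange(params.profile_length, dtype=float)
    background = params.background_offset + params.background_slope * x
    window = (
        params.band_center - params.band_width - _WINDOW_MARGIN,
        params.band_center + params.band_width + _WINDOW_MARGIN + 1,
    )

    lanes: list[LaneDensitometry] = []
    values: dict[str, float | str] = {"total_amount": params.total_amount}
    for analyte in sorted(params.fractions):
        fraction = params.fractions[analyte]
        for compartment, amount in (
            ("P", params.total_amount * fraction),
            ("S", params.total_amount * (1.0 - fraction)),
        ):
            profile = amount * shape + background
            if params.noise_sigma > 0:
                profile = profile + rng.normal(0.0, params.noise_sigma, profile.shape)
            lanes.append(
                LaneDensitometry(
                    analyte=analyte,
                    compartment=compartment,
                    profile=np.clip(profile, 0.0, None),
                    band_window=window,
                )
            )
            values[f"true_{compartment}_{analyte}"] = amount
        values[f"true_fraction_{analyte}"] = fraction

    truth = GroundTruth(fixture_id=fixture_id, seed=seed, values=values)
    return lanes, truth
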