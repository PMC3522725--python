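"""Shared data structures: images, stacks, masks and ground-truth records."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .errors import ParameterError

__all__ = [
    "MultiChannelImage",
    "ImageStack",
    "ROIMask",
    "GrowthConeImage",
    "GroundTruth",
]


@dataclass
class MultiChannelImage:
    """A set of registered single-channel 2D intensity images.

    Parameters
    ----------
    channels
        Mapping from channel label (e.g. ``"tyr"``, ``"glu"``, ``"nucleus"``)
        to a 2D float array of non-negative intensities in arbitrary
        fluorescence units.
    pixel_size
        Lateral pixel size in micrometres per pixel.
    bit_depth
        Nominal acquisition bit depth (used when writing integer TIFFs).
    meta
        Free-form metadata.  Generators stash their noise-free rendered
        channels here under ``"clean_channels"`` so tests can use them as
        oracles; ``meta`` is never serialized.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 1.0
    bit_depth: int = 16
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ParameterError("an image needs at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ParameterError(f"channel shapes differ: {shapes}")
        for label, arr in self.channels.items():
            if arr.ndim != 2:
                raise ParameterError(f"channel {label!r} is not 2D")
            if np.any(arr < 0):
                raise ParameterError(f"channel {label!r} has negative intensities")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, label: str) -> np.ndarray:
        return self.channels[label]


@dataclass
class ImageStack:
    """An ordered z-stack of registered multi-channel planes."""

    planes: list[MultiChannelImage]
    z_spacing: float = 1.0

    def __post_init__(self) -> None:
        if len(self.planes) < 1:
            raise ParameterError("a stack needs at least one plane")
        shapes = {p.shape for p in self.planes}
        if len(shapes) != 1:
            raise ParameterError("all planes must share a shape")

    def __len__(self) -> int:
        return len(self.planes)

    def __iter__(self) -> Iterator[MultiChannelImage]:
        return iter(self.planes)


@dataclass
class ROIMask:
    """A boolean region-of-interest mask with provenance.

    ``provenance`` records how the mask was produced: ``"manual"``,
    ``"threshold"`` or ``"geometry"``.
    """

    mask: np.ndarray
    label: str = "roi"
    provenance: str = "manual"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ParameterError("ROI mask must be 2D")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def area_um2(self, pixel_size: float) -> float:
        return self.area_px * pixel_size**2

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class GrowthConeImage:
    """Four-channel growth-cone image: tyr, glu, actin, membrane."""

    tyr: np.ndarray
    glu: np.ndarray
    actin: np.ndarray
    membrane: np.ndarray
    pixel_size: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {self.tyr.shape, self.glu.shape, self.actin.shape, self.membrane.shape}
        if len(shapes) != 1:
            raise ParameterError("growth-cone channels must share a shape")

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {
            "tyr": self.tyr,
            "glu": self.glu,
            "actin": self.actin,
            "membrane": self.membrane,
        }

    @property
    def shape(self) -> tuple[int, int]:
        return self.tyr.shape


@dataclass
class GroundTruth:
    """True generator parameters for one synthetic fixture.

    ``values`` maps parameter names to the exact values that were rendered
    (not merely requested), so estimators can be scored against them.  The
    record round-trips losslessly through a long-format CSV
    (``fixture_id, seed, key, value``).
    """

    fixture_id: str
    seed: int
    values: dict[str, float | str]

    def __getitem__(self, key: str) -> float | str:
        return self.values[key]

    def to_rows(self) -> list[tuple[str, str, str, str]]:
        rows = []
        for key in sorted(self.values):
            val = self.values[key]
            text = repr(float(val)) if isinstance(val, (int, float, np.floating)) else str(val)
            kind = "num" if isinstance(val, (int, float, np.floating)) else "str"
            rows.append((self.fixture_id, str(self.seed), key, f"{kind}:{text}"))
        return rows

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fixture_id", "seed", "key", "value"])
            writer.writerows(self.to_rows())

    @classmethod
    def from_rows(cls, rows: list[Mapping[str, str]]) -> "GroundTruth":
        if not rows:
            raise ParameterError("no rows for GroundTruth")
        fixture_id = rows[0]["fixture_id"]
        seed = int(rows[0]["seed"])
        values: dict[str, float | str] = {}
        for row in rows:
            kind, _, text = row["value"].partition(":")
            values[row["key"]] = float(text) if kind == "num" else text
        return cls(fixture_id=fixture_id, seed=seed, values=values)

    @classmethod
    def read_csv(cls, path: str | Path) -> list["GroundTruth"]:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        by_id: dict[str, list] = {}
        for row in rows:
            by_id.setdefault(row["fixture_id"], []).append(row)
        return [cls.from_rows(group) for group in by_id.values()]
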