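"""Standard-format I/O: 16-bit grayscale TIFF channels and CSV tables.

Images are written one file per channel as unsigned 16-bit grayscale TIFF
with the filename pattern ``<fixture>_<channel>.tif``.  Lane profiles and
plate tables are long-format CSV with a header row, UTF-8, "." decimal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ParameterError
from .fractionation import LaneDensitometry
from .types import GrowthConeImage, MultiChannelImage

__all__ = [
    "write_channel_tiffs",
    "read_channel_tiffs",
    "write_lanes_csv",
    "read_lanes_csv",
    "write_plate_csv",
    "read_plate_csv",
]


def write_channel_tiffs(
    image: MultiChannelImage | GrowthConeImage, out_dir: str | Path, fixture_id: str
) -> dict[str, Path]:
    """Write every channel as ``<fixture>_<channel>.tif`` (uint16)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in image.channels.items():
        data = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
        path = out_dir / f"{fixture_id}_{name}.tif"
        tifffile.imwrite(path, data, photometric="minisblack")
        paths[name] = path
    return paths


def read_channel_tiffs(
    paths: dict[str, str | Path], pixel_size: float = 1.0
) -> MultiChannelImage:
    """Read a channel-name -> file mapping into a registered image."""
    channels = {
        name: tifffile.imread(path).astype(float) for name, path in sorted(paths.items())
    }
    return MultiChannelImage(channels=channels, pixel_size=pixel_size, bit_depth=16)


def write_lanes_csv(lanes: list[LaneDensitometry], path: str | Path) -> None:
    """Long-format lane CSV: analyte, compartment, position, intensity,
    band_lo, band_hi."""
    rows = []
    for lane in lanes:
        lo, hi = lane.band_window
        for pos, val in enumerate(lane.profile):
            rows.append(
                {
                    "analyte": lane.analyte,
                    "compartment": lane.compartment,
                    "position": pos,
                    "intensity": val,
                    "band_lo": lo,
                    "band_hi": hi,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_lanes_csv(path: str | Path) -> list[LaneDensitometry]:
    df = pd.read_csv(path)
    lanes = []
    for (analyte, compartment), group in df.groupby(
        ["analyte", "compartment"], sort=True
    ):
        group = group.sort_values("position")
        if not (group["position"].to_numpy() == np.arange(len(group))).all():
            raise ParameterError(
                f"lane {analyte}/{compartment} has non-contiguous positions"
            )
        lanes.append(
            LaneDensitometry(
                analyte=str(analyte),
                compartment=str(compartment),
                profile=group["intensity"].to_numpy(),
                band_window=(int(group["band_lo"].iloc[0]), int(group["band_hi"].iloc[0])),
            )
        )
    return lanes


def write_plate_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
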