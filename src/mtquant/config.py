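"""Run configuration: a validated, hashable record driving simulate and
quantify runs.

Configs load from plain YAML; unknown keys are rejected so typos fail
loudly.  The SHA-256 of the canonical YAML dump is recorded in every run
report, making the provenance block sufficient to re-execute the run.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration for an end-to-end simulate/quantify run."""

    seed: int = 0
    out_dir: str = "runs/out"
    alpha: float = 0.05
    posthoc: str = "dunnett"
    cutoff_method: str = "otsu"
    min_positive_fraction: float = 0.005
    closing_radius_px: int = 5
    dilation_px: int = 3
    pixel_size: float = 0.2
    # fixture counts / parameters
    n_cells: int = 3
    cell_partition: float = 0.3
    n_colchicine: int = 1
    n_growthcones: int = 2
    invasion_fraction: float = 0.15
    lane_fractions: dict[str, float] = field(
        default_factory=lambda: {"tubulin": 0.5, "tau": 0.95, "actin": 0.5}
    )
    plate_shape: str = "bimodal"
    plate_effect: float = 1.5
    wells_per_condition: int = 9

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.closing_radius_px < 0 or self.dilation_px < 0:
            raise ParameterError("radii must be non-negative")
        if self.min_positive_fraction < 0:
            raise ParameterError("min_positive_fraction must be non-negative")
        if self.posthoc not in ("dunnett", "snk"):
            raise ParameterError(f"unknown posthoc method {self.posthoc!r}")
        if min(self.n_cells, self.n_colchicine, self.n_growthcones) < 0:
            raise ParameterError("fixture counts must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ParameterError("config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()
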