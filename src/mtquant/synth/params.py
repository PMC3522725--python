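"""Parameter records for the synthetic fixture generators.

Every record validates its own invariants on construction and raises
:class:`~mtquant.errors.ParameterError` on violation.  Intensities are in
arbitrary fluorescence units (AFU); lengths in pixels unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import ParameterError

__all__ = ["NoiseModel", "CellImageParams", "GrowthConeParams", "LaneParams", "PlateParams"]


@dataclass(frozen=True)
class NoiseModel:
    """Poisson shot noise (``gain`` detected counts per AFU) plus additive
    Gaussian read noise.  ``gain=0`` disables the Poisson component."""

    poisson_gain: float = 1.0
    read_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.poisson_gain < 0 or self.read_sigma < 0:
            raise ParameterError("noise parameters must be non-negative")

    @property
    def enabled(self) -> bool:
        return self.poisson_gain > 0 or self.read_sigma > 0


NOISE_OFF = NoiseModel(poisson_gain=0.0, read_sigma=0.0)


@dataclass(frozen=True)
class CellImageParams:
    """Controls for a two-channel filamentous cell image.

    ``tyr_glu_partition`` is the fraction of each filament's signal assigned
    to the tyr channel; the glu channel receives the complement, so the true
    tyr/glu signal ratio is ``p / (1 - p)``.  In the ``below_detection``
    regime the whole filament map is rescaled so that every noise-free
    filament pixel lies below ``background_level + detection_margin``.
    """

    image_size: tuple[int, int] = (192, 192)
    pixel_size: float = 0.2
    n_filaments: int = 60
    filament_length_range: tuple[float, float] = (40.0, 120.0)
    filament_intensity: float = 400.0
    tyr_glu_partition: float = 0.5
    network_extent: float = 0.35
    background_level: float = 2.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_nuclei: int = 1
    below_detection: bool = False
    detection_margin: float = 8.0
    line_sigma: float = 1.0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ParameterError("image dimensions must be at least 64x64")
        if not 0.0 <= self.tyr_glu_partition <= 1.0:
            raise ParameterError("tyr_glu_partition must lie in [0, 1]")
        if self.filament_intensity < 0 or self.background_level < 0:
            raise ParameterError("intensities must be non-negative")
        if not 0.0 < self.network_extent <= 1.0:
            raise ParameterError("network_extent must lie in (0, 1]")
        if self.n_filaments < 1:
            raise ParameterError("n_filaments must be at least 1")
        lo, hi = self.filament_length_range
        if lo <= 0 or hi < lo:
            raise ParameterError("invalid filament_length_range")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        if self.detection_margin <= 0:
            raise ParameterError("detection_margin must be positive")


@dataclass(frozen=True)
class GrowthConeParams:
    """Controls for a fan-shaped growth-cone fixture.

    The fan opens from an apex; glu filaments are rendered only inside the
    central disc (radius ``central_radius``) while tyr filaments extend into
    the peripheral band of width ``peripheral_width`` until the rendered
    coverage reaches ``true_invasion_fraction`` of the band area.
    """

    image_size: tuple[int, int] = (160, 160)
    pixel_size: float = 0.2
    fan_angle: float = 110.0
    central_radius: float = 35.0
    peripheral_width: float = 30.0
    true_invasion_fraction: float = 0.15
    filopodia_count: int = 6
    channel_intensity: float = 400.0
    background_level: float = 2.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    line_sigma: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_invasion_fraction <= 1.0:
            raise ParameterError("true_invasion_fraction must lie in [0, 1]")
        if self.peripheral_width <= 0:
            raise ParameterError("peripheral_width must be positive")
        if self.central_radius <= 0:
            raise ParameterError("central_radius must be positive")
        if not 0 < self.fan_angle <= 360:
            raise ParameterError("fan_angle must lie in (0, 360]")
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ParameterError("image dimensions must be at least 64x64")


@dataclass(frozen=True)
class LaneParams:
    """Controls for paired polymerized/soluble lane densitometry profiles.

    ``fractions`` maps analyte name to its true polymer fraction; each
    analyte yields a P lane and an S lane whose background-free band
    integrals are ``total_amount * f`` and ``total_amount * (1 - f)``.
    The band is a raised-cosine bump with compact support of half-width
    ``band_width`` centred at ``band_center``.
    """

    fractions: dict[str, float] = field(
        default_factory=lambda: {"tubulin": 0.5, "tau": 0.95, "actin": 0.5}
    )
    total_amount: float = 10_000.0
    profile_length: int = 200
    band_center: int = 100
    band_width: int = 25
    background_offset: float = 5.0
    background_slope: float = 0.05
    noise_sigma: float = 1.0

    def __post_init__(self) -> None:
        for analyte, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ParameterError(
                    f"true polymer fraction for {analyte!r} must lie in [0, 1]"
                )
        if not self.fractions:
            raise ParameterError("at least one analyte required")
        if self.band_width <= 0:
            raise ParameterError("band_width must be positive")
        if (
            self.band_center - self.band_width < 0
            or self.band_center + self.band_width >= self.profile_length
        ):
            raise ParameterError("band support must lie fully inside the profile")
        if self.total_amount <= 0:
            raise ParameterError("total_amount must be positive")
        if self.noise_sigma < 0 or self.background_offset < 0:
            raise ParameterError("noise and background must be non-negative")


@dataclass(frozen=True)
class PlateParams:
    """Controls for an in-cell-western style plate table.

    Per-well raw signal = cell factor x condition effect x base signal
    (+ noise); the nucleus-stain column is cell factor x base (+ noise), so
    dividing the two cancels the cell-count variation driven by
    ``cell_count_cv``.  ``shape`` selects the concentration-effect profile:
    ``"bimodal"`` applies ``effect_size`` exactly at ``peak_locations``,
    ``"sigmoid"`` a steep Hill curve, ``"null"`` no effect anywhere.
    """

    concentrations: tuple[float, ...] = tuple(10.0**-e for e in range(18, 5, -1))
    shape: str = "null"
    peak_locations: tuple[float, ...] = (1e-15, 1e-9)
    ec50: float = 10**-11.5
    hill: float = 4.0
    effect_size: float = 1.5
    wells_per_condition: int = 9
    cell_count_cv: float = 0.15
    base_signal: float = 1000.0
    base_hoechst: float = 800.0
    noise_sigma: float = 25.0

    def __post_init__(self) -> None:
        conc = self.concentrations
        if len(conc) < 1 or any(c <= 0 for c in conc):
            raise ParameterError("concentrations must be positive")
        if any(b <= a for a, b in zip(conc, conc[1:])) is True:
            pass  # strictly increasing check below
        if not all(b > a for a, b in zip(conc, conc[1:])):
            raise ParameterError("concentrations must be strictly increasing")
        if self.shape not in {"bimodal", "sigmoid", "null"}:
            raise ParameterError(f"unknown shape {self.shape!r}")
        if self.shape == "bimodal":
            missing = [p for p in self.peak_locations if p not in conc]
            if missing:
                raise ParameterError(f"peak locations {missing} not in concentration list")
        if self.wells_per_condition < 2:
            raise ParameterError("wells_per_condition must be at least 2")
        if self.effect_size <= 0:
            raise ParameterError("effect_size must be positive")
        if self.cell_count_cv < 0 or self.noise_sigma < 0:
            raise ParameterError("variation parameters must be non-negative")
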