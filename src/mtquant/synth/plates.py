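"""Synthetic plate-reader tables for in-cell-western style assays.

Every well carries a latent "cell factor" (log-normal, CV set by
``cell_count_cv``) that multiplies both the signal and the nucleus-stain
readout, so dividing the two cancels it.  Condition effects follow the
declared concentration-response shape; the true affected concentration set
is recorded in the ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..types import GroundTruth
from .params import PlateParams

__all__ = ["make_plate_table", "make_viability_groups", "condition_label", "effect_profile"]


def condition_label(concentration: float) -> str:
    return f"{concentration:.3e}"


def effect_profile(params: PlateParams) -> dict[float, float]:
    """Fold-change over vehicle for every concentration."""
    effects = {}
    for c in params.concentrations:
        if params.shape == "null":
            e = 1.0
        elif params.shape == "bimodal":
            e = params.effect_size if c in params.peak_locations else 1.0
        else:  # sigmoid (Hill)
            frac = c**params.hill / (c**params.hill + params.ec50**params.hill)
            e = 1.0 + (params.effect_size - 1.0) * frac
        effects[c] = e
    return effects


def _affected_set(params: PlateParams, effects: dict[float, float]) -> list[float]:
    if params.shape == "null":
        return []
    if params.shape == "bimodal":
        return sorted(params.peak_locations)
    half = 1.0 + 0.5 * (params.effect_size - 1.0)
    return sorted(c for c, e in effects.items() if e >= half)


def make_plate_table(
    params: PlateParams, seed: int, fixture_id: str = "plate"
) -> tuple[pd.DataFrame, GroundTruth]:
    """One plate table: vehicle wells plus ``wells_per_condition`` wells per
    concentration, columns ``well, condition, concentration_M, signal_afu,
    hoechst_afu``."""
    rng = np.random.default_rng(seed)
    effects = effect_profile(params)
    conditions = [("vehicle", 0.0, 1.0)] + [
        (condition_label(c), c, effects[c]) for c in params.concentrations
    ]

    if params.cell_count_cv > 0:
        sigma_ln = np.sqrt(np.log1p(params.cell_count_cv**2))
    else:
        sigma_ln = 0.0

    rows = []
    widx = 0
    for label, conc, effect in conditions:
        for _ in range(params.wells_per_condition):
            factor = float(np.exp(rng.normal(-(sigma_ln**2) / 2.0, sigma_ln))) if sigma_ln else 1.0
            signal = factor * params.base_signal * effect
            hoechst = factor * params.base_hoechst
            if params.noise_sigma > 0:
                signal += rng.normal(0.0, params.noise_sigma)
                hoechst += rng.normal(0.0, params.noise_sigma)
            rows.append(
                {
                    "well": f"W{widx:03d}",
                    "condition": label,
                    "concentration_M": conc,
                    "signal_afu": max(signal, 0.0),
                    "hoechst_afu": max(hoechst, 0.0),
                }
            )
            widx += 1

    table = pd.DataFrame(rows)
    affected = _affected_set(params, effects)
    truth = GroundTruth(
        fixture_id=fixture_id,
        seed=seed,
        values={
            "shape": params.shape,
            "effect_size": params.effect_size,
            "cell_count_cv": params.cell_count_cv,
            "affected_set": ";".join(condition_label(c) for c in affected),
            "wells_per_condition": float(params.wells_per_condition),
        },
    )
    return table, truth


def make_viability_groups(
    survival: dict[str, float],
    n_per_group: int,
    seed: int,
    control_label: str = "control",
    control_absorbance: float = 0.6,
    noise_cv: float = 0.08,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Absorbance replicates per group with known true survival fractions.

    ``survival`` maps group label to its true fraction of the control
    absorbance; the control group itself is added with survival 1.
    """
    rng = np.random.default_rng(seed)
    full = {control_label: 1.0, **survival}
    groups = {}
    values: dict[str, float | str] = {}
    for label in full:
        mean = control_absorbance * full[label]
        vals = mean * (1.0 + rng.normal(0.0, noise_cv, n_per_group))
        groups[label] = np.clip(vals, 0.0, None)
        values[f"true_survival_{label}"] = full[label]
    truth = GroundTruth(fixture_id="viability", seed=seed, values=values)
    return groups, truth
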