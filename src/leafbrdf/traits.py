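"""Leaf phenotypic traits: pigment contents, specific leaf weight, derived features.

Pigment contents come from spectrophotometer absorbances at 663, 645 and
470 nm via the classical chlorophyll/carotenoid equations:

    Chl.a = 12.72·A663 − 2.59·A645
    Chl.b = 22.88·A645 − 4.67·A663
    Car.  = (1000·A470 − 3.27·Chl.a − 104·Chl.b) / 229

These yield extract concentrations (µg·mL⁻¹); conversion to an areal content
(mg·dm⁻²) needs the extract volume and the disc area and is optional — the
downstream predictor z-scores its inputs, so the scale choice is immaterial
there.  Negative pigment values are flagged, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The nine predictor features used by the ensemble model, in canonical order.
TRAIT_FEATURES = (
    "thickness_mm",
    "slw_g_m2",
    "chl_a",
    "chl_b",
    "car",
    "chl_ab",
    "chl_ratio",
    "rho",
    "wavelength_nm",
)


@dataclass(frozen=True)
class AbsorbanceTriple:
    a663: float
    a645: float
    a470: float

    def __post_init__(self) -> None:
        if min(self.a663, self.a645, self.a470) < 0:
            raise ValueError("absorbances must be non-negative")


@dataclass(frozen=True)
class PigmentContents:
    chl_a: float
    chl_b: float
    car: float
    negative_flagged: bool = False


def pigment_contents(abs_triple: AbsorbanceTriple) -> PigmentContents:
    """Chlorophyll a/b and carotenoid concentrations from absorbances.

    Linear in the absorbances; negative outputs (possible for unusual
    absorbance ratios outside the equations' validity domain) are returned
    as-is with ``negative_flagged=True``.
    """
    chl_a = 12.72 * abs_triple.a663 - 2.59 * abs_triple.a645
    chl_b = 22.88 * abs_triple.a645 - 4.67 * abs_triple.a663
    car = (1000.0 * abs_triple.a470 - 3.27 * chl_a - 104.0 * chl_b) / 229.0
    return PigmentContents(chl_a, chl_b, car, negative_flagged=min(chl_a, chl_b, car) < 0)


def areal_content_mg_dm2(concentration_ug_ml: float, volume_ml: float, disc_area_cm2: float) -> float:
    """Convert an extract concentration to mg per dm² of leaf."""
    if volume_ml <= 0 or disc_area_cm2 <= 0:
        raise ValueError("extract volume and disc area must be positive")
    mg = concentration_ug_ml * volume_ml / 1000.0
    return mg / (disc_area_cm2 / 100.0)


def specific_leaf_weight(dry_weight_g: float, area_m2: float) -> float:
    """SLW = dry weight / area, g·m⁻²."""
    if area_m2 <= 0:
        raise ValueError("leaf area must be positive")
    if dry_weight_g < 0:
        raise ValueError("dry weight must be non-negative")
    return dry_weight_g / area_m2


def derive_features(record: dict) -> dict:
    """Fill the derived pigment features chl_ab and chl_ratio.

    Idempotent; a zero chl_b leaves the ratio missing (NaN) rather than
    raising, so batch tables keep flowing.
    """
    out = dict(record)
    chl_a, chl_b = out["chl_a"], out["chl_b"]
    out["chl_ab"] = chl_a + chl_b
    out["chl_ratio"] = chl_a / chl_b if chl_b != 0 else float("nan")
    return out


def process_trait_table(
    table: pd.DataFrame,
    volume_ml: float | None = None,
    disc_area_cm2: float | None = None,
) -> pd.DataFrame:
    """Compute pigments, SLW and derived features for a raw trait table.

    Expects columns ``a663, a645, a470`` and, for SLW, ``dry_weight_g`` and
    ``area_m2``.  Appends computed columns; raw columns are preserved.
    """
    out = table.copy()
    a663 = out["a663"].to_numpy(float)
    a645 = out["a645"].to_numpy(float)
    a470 = out["a470"].to_numpy(float)
    chl_a = 12.72 * a663 - 2.59 * a645
    chl_b = 22.88 * a645 - 4.67 * a663
    car = (1000.0 * a470 - 3.27 * chl_a - 104.0 * chl_b) / 229.0
    if volume_ml is not None and disc_area_cm2 is not None:
        factor = volume_ml / 1000.0 / (disc_area_cm2 / 100.0)
        chl_a, chl_b, car = chl_a * factor, chl_b * factor, car * factor
    out["chl_a"], out["chl_b"], out["car"] = chl_a, chl_b, car
    out["pigment_negative_flag"] = np.minimum(np.minimum(chl_a, chl_b), car) < 0
    out["chl_ab"] = chl_a + chl_b
    with np.errstate(divide="ignore", invalid="ignore"):
        out["chl_ratio"] = np.where(chl_b != 0, chl_a / chl_b, np.nan)
    if {"dry_weight_g", "area_m2"} <= set(out.columns):
        out["slw_g_m2"] = out["dry_weight_g"].to_numpy(float) / out["area_m2"].to_numpy(float)
    return out
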