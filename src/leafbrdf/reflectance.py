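"""Reduction of raw goniometer fluxes to calibrated bidirectional reflectance.

Calibration is purely ratio-based: the sample and the Lambertian reference
whiteboard are measured under identical geometry, so the incident flux and
the detector solid angle cancel and

    f_samp = Φ_sample / (π · Φ_reference)   [sr⁻¹]

with 1/π being the bidirectional reflectance of an ideal 100%-reflective
Lambertian surface.  The module also hosts the whiteboard cosine-law check
and the representative-wavelength selection used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import scan_frame_arrays

#: Representative wavelengths (nm): blue, green, red, and two NIR bands.
WAVELENGTHS_NM = (468.36, 556.26, 673.46, 819.88, 877.97)

#: Full scan range of the spectrometer, nm.
SCAN_RANGE_NM = (400.0, 992.0)


class CalibrationError(ValueError):
    """Raised when reference fluxes cannot calibrate a scan."""


class MissingWavelengthError(KeyError):
    """Raised when a requested wavelength has no sample within tolerance."""


def fsamp_from_fluxes(flux_sample, flux_reference):
    """Bidirectional reflectance (sr⁻¹) from sample/reference flux pairs.

    Linear in the sample flux and invariant to common rescaling of both
    fluxes.  Accepts scalars or arrays; any non-positive reference flux is a
    calibration error.
    """
    fs = np.asarray(flux_sample, dtype=float)
    fr = np.asarray(flux_reference, dtype=float)
    if np.any(fr <= 0.0):
        raise CalibrationError("reference flux must be positive everywhere")
    if np.any(fs < 0.0):
        raise CalibrationError("sample flux must be non-negative")
    out = fs / (np.pi * fr)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class LambertianFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def lambertian_check(intensities, view_zeniths_deg) -> LambertianFit:
    """OLS regression of reflected intensity on cos(θv).

    A Lambertian surface follows the cosine law, so the regression should be
    a tight line through the data (R² close to 1 on a well-aligned
    instrument).  Requires at least three distinct detection angles.
    """
    y = np.asarray(intensities, dtype=float)
    th = np.asarray(view_zeniths_deg, dtype=float)
    if y.shape != th.shape:
        raise ValueError("intensities and angles must have matching shapes")
    if np.unique(th).size < 3:
        raise ValueError("need at least 3 distinct detection angles")
    x = np.cos(np.radians(th))
    if np.ptp(x) < 1e-12:
        raise ValueError("cos(theta) is constant; regression is degenerate")
    res = stats.linregress(x, y)
    return LambertianFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(y.size),
    )


def select_wavelengths(
    spectrum: Mapping[float, float] | pd.Series,
    targets=WAVELENGTHS_NM,
    tolerance_nm: float = 1.0,
) -> dict[float, float]:
    """Pick the nearest sampled wavelength for each target, in target order.

    Returns ``{matched_sample_wavelength: value}``.  Targets with no sample
    within ``tolerance_nm`` raise :class:`MissingWavelengthError` naming all
    offenders.
    """
    if isinstance(spectrum, pd.Series):
        wl = spectrum.index.to_numpy(dtype=float)
        vals = spectrum.to_numpy(dtype=float)
    else:
        wl = np.array(sorted(spectrum.keys()), dtype=float)
        vals = np.array([spectrum[w] for w in wl], dtype=float)
    if wl.size == 0 and len(tuple(targets)) > 0:
        raise MissingWavelengthError(list(targets))
    out: dict[float, float] = {}
    missing: list[float] = []
    for t in targets:
        i = int(np.argmin(np.abs(wl - t)))
        if abs(wl[i] - t) > tolerance_nm:
            missing.append(t)
        else:
            out[float(wl[i])] = float(vals[i])
    if missing:
        raise MissingWavelengthError(missing)
    return out


@dataclass
class ReflectanceDataset:
    """Calibrated bidirectional reflectance over a geometry grid.

    ``table`` must carry the columns ``incident_zenith_deg``,
    ``view_zenith_deg``, ``view_azimuth_deg`` and ``f_samp_sr`` (plus
    anything else, e.g. ``wavelength_nm``).  Degenerate geometries (light or
    detector behind the leaf plane) are retained in the table but excluded
    from the arrays the fitters consume; ``n_dropped`` counts them.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    v_form: str = "corrected"

    _cache: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        required = {"incident_zenith_deg", "view_zenith_deg", "view_azimuth_deg", "f_samp_sr"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"dataset table missing columns: {sorted(missing)}")
        if np.any(self.table["f_samp_sr"].to_numpy() < 0):
            raise ValueError("bidirectional reflectance must be non-negative")

    def frame_arrays(self) -> dict[str, np.ndarray]:
        """Frame cosines and observed f for the usable (non-degenerate) rows."""
        if self._cache is None:
            t = self.table
            fr = scan_frame_arrays(
                t["incident_zenith_deg"].to_numpy(float),
                t["view_zenith_deg"].to_numpy(float),
                t["view_azimuth_deg"].to_numpy(float),
                v_form=self.v_form,
            )
            m = fr["usable"]
            cache = {key: np.asarray(val)[m] for key, val in fr.items() if key != "usable"}
            cache["f_samp"] = t["f_samp_sr"].to_numpy(float)[m]
            cache["n_dropped"] = int((~m).sum())
            self._cache = cache
        return self._cache

    @property
    def n_usable(self) -> int:
        return int(self.frame_arrays()["f_samp"].size)

    @property
    def n_dropped(self) -> int:
        return int(self.frame_arrays()["n_dropped"])

    def check_fit_eligible(self, min_view_angles: int = 6) -> None:
        """Require >= ``min_view_angles`` distinct view zeniths per incidence."""
        for inc, grp in self.table.groupby("incident_zenith_deg"):
            n = grp["view_zenith_deg"].nunique()
            if n < min_view_angles:
                raise ValueError(
                    f"incidence {inc} deg has only {n} distinct view angles "
                    f"(need >= {min_view_angles})"
                )


def calibrate_scan(scan: pd.DataFrame, reference: str = "per_row") -> pd.DataFrame:
    """Append a calibrated ``f_samp_sr`` column to a raw angular-scan table.

    ``reference="per_row"`` divides by the row's own whiteboard flux;
    ``reference="per_incidence"`` uses the mean whiteboard flux within each
    (wavelength, incidence) group, for instruments that log the reference
    only once per incidence setting.
    """
    out = scan.copy()
    if reference == "per_row":
        ref = out["flux_reference"].to_numpy(float)
    elif reference == "per_incidence":
        keys = [c for c in ("wavelength_nm", "incident_zenith_deg") if c in out.columns]
        ref = out.groupby(keys)["flux_reference"].transform("mean").to_numpy(float)
    else:
        raise ValueError(f"unknown reference mode {reference!r}")
    out["f_samp_sr"] = fsamp_from_fluxes(out["flux_sample"].to_numpy(float), ref)
    return out
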