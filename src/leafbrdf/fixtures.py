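"""Seeded synthetic-data generators emulating the measurement campaign.

No public dataset accompanies the instrument, so every downstream module is
exercised on forward-generated data with known ground truth:

* goniometer scans — the Cook-Torrance model evaluated on the instrument's
  standard geometry grid (incidences 0, π/6, π/4, 11π/36; detection ring
  every 5° over −5°..175°), converted back to flux pairs;
* whiteboard scans — cosine-law intensities with multiplicative noise;
* leaf cross-section images — a tissue band with a sinusoidal surface whose
  roughness is known analytically;
* trait tables — nine phenotypic features whose planted effects mirror the
  observed correlation structure (σ tracks surface roughness ρ; k rises
  with wavelength; n falls with thickness and specific leaf weight);
* layered canopies — randomly placed tilted triangular "leaves".

Every generator is a pure function of its arguments and seed.  Noise is
multiplicative Gaussian on the sample flux (spectrometer-like), never an
additive floor, so reflectances stay non-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .cooktorrance import BRDFParams, brdf_eval_arrays
from .geometry import HOLDER_PERPENDICULAR_DEG, RING_COVERAGE_DEG, scan_frame_arrays
from .raytracer import CanopyMesh
from .traits import TRAIT_FEATURES
from .reflectance import WAVELENGTHS_NM

#: Standard incidence angles of a scan, degrees (0, π/6, π/4, 11π/36).
DEFAULT_INCIDENCE_DEG = (0.0, 30.0, 45.0, 55.0)

#: Canopy-simulation parameter sets (σ, k, n).
CANOPY_PARAMETER_SETS = (
    (0.3, 0.01, 1.0),
    (0.3, 0.35, 1.0),
    (1.0, 0.01, 1.0),
    (0.3, 0.01, 2.2),
    (1.0, 0.35, 2.2),
    (0.3, 0.35, 2.2),
)


def ring_angles_deg(step: float = 5.0, coverage: tuple[float, float] = RING_COVERAGE_DEG) -> np.ndarray:
    return np.arange(coverage[0], coverage[1] + step / 2, step)


def synth_brdf_scan(
    params: BRDFParams,
    incidence_deg=DEFAULT_INCIDENCE_DEG,
    ring_step_deg: float = 5.0,
    wavelength_nm: float | None = None,
    noise_sd: float = 0.05,
    seed: int | None = None,
    convention: str = "as_printed",
) -> pd.DataFrame:
    """Forward-generate an angular-scan table for one parameter triple.

    Evaluates the BRDF on the full geometry grid, then inverts the
    calibration to flux pairs (reference flux 1, sample flux π·f) and
    applies multiplicative Gaussian noise to the sample flux.  Degenerate
    geometries are kept in the table; calibration-side filtering drops them.
    """
    rng = np.random.default_rng(seed)
    ring = ring_angles_deg(ring_step_deg)
    inc = np.asarray(incidence_deg, dtype=float)
    theta_i = np.repeat(inc, ring.size)
    theta_v = np.tile(ring, inc.size)
    phi_v = np.zeros_like(theta_v)

    fr = scan_frame_arrays(theta_i, theta_v, phi_v)
    f = brdf_eval_arrays(
        params.sigma, params.k, params.n,
        fr["cos_LN"], fr["cos_NV"], fr["cos_NH"],
        fr["cos_VH"], fr["cos_theta_h"], fr["alpha"],
        convention=convention,
    )
    f = np.where(fr["usable"], f, 0.0)
    flux_ref = np.ones_like(f)
    flux_samp = math.pi * f
    if noise_sd > 0:
        flux_samp = flux_samp * (1.0 + noise_sd * rng.standard_normal(flux_samp.shape))
        flux_samp = np.maximum(flux_samp, 0.0)
    wl = wavelength_nm if wavelength_nm is not None else (params.wavelength_nm or 556.26)
    return pd.DataFrame(
        {
            "wavelength_nm": wl,
            "holder_scale_deg": HOLDER_PERPENDICULAR_DEG - theta_i,
            "incident_zenith_deg": theta_i,
            "incident_azimuth_deg": 0.0,
            "view_zenith_deg": theta_v,
            "view_azimuth_deg": phi_v,
            "flux_sample": flux_samp,
            "flux_reference": flux_ref,
        }
    )


def synth_whiteboard_scan(
    noise_sd: float = 0.01,
    n_angles: int = 19,
    max_zenith_deg: float = 90.0,
    i0: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cosine-law whiteboard intensities at equally spaced detection zeniths.

    Angles span [0, max_zenith) so every cosine is positive; noise is
    multiplicative Gaussian.
    """
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, max_zenith_deg, n_angles, endpoint=False)
    intensity = i0 * np.cos(np.radians(theta))
    if noise_sd > 0:
        intensity = intensity * (1.0 + noise_sd * rng.standard_normal(theta.shape))
    return pd.DataFrame({"view_zenith_deg": theta, "intensity": intensity})


def sinusoid_arc_ratio(amplitude_px: float, period_px: float) -> float:
    """Arc length of y = A·sin(2πx/p) over one period, divided by the chord."""
    m = 2.0 * math.pi * amplitude_px / period_px

    def integrand(u):
        return math.sqrt(1.0 + (m * math.cos(u)) ** 2)

    val, _ = quad(integrand, 0.0, 2.0 * math.pi, limit=200)
    return val / (2.0 * math.pi)


def gaussian_sinusoid_gain(sigma_px: float, period_px: float) -> float:
    """Amplitude gain of a sinusoid of period p under 1-D Gaussian smoothing."""
    return math.exp(-2.0 * math.pi**2 * sigma_px**2 / period_px**2)


@dataclass(frozen=True)
class SectionFixture:
    image: np.ndarray
    boundary_rows: np.ndarray
    analytic_rho: float  # arc/chord ratio of the generating curve
    amplitude_px: float
    period_px: float


def synth_section_image(
    amplitude_px: float = 8.0,
    period_px: float = 40.0,
    width: int = 400,
    height: int = 200,
    noise_sd: float = 0.0,
    seed: int | None = None,
    tissue_level: float = 0.8,
    background_level: float = 0.1,
) -> SectionFixture:
    """Synthetic cross-section: a bright tissue band with a sinusoidal top edge.

    The returned ``analytic_rho`` is the smoothing-free arc/chord ratio of
    the generating sinusoid (quadrature of √(1+y′²)); pair it with
    :func:`gaussian_sinusoid_gain` to predict what the pixel pipeline should
    measure for a given smoothing bandwidth.
    """
    if period_px <= 4:
        raise ValueError("period must exceed 4 px")
    if amplitude_px >= height / 2:
        raise ValueError("amplitude must stay below half the image height")
    rng = np.random.default_rng(seed)
    x = np.arange(width)
    y0 = height * 0.35
    boundary = y0 + amplitude_px * np.sin(2.0 * math.pi * x / period_px)
    rows = np.arange(height)[:, None]
    img = np.where(rows >= np.round(boundary)[None, :], tissue_level, background_level)
    img = img.astype(float)
    if noise_sd > 0:
        img = img * (1.0 + noise_sd * rng.standard_normal(img.shape))
        img = np.clip(img, 0.0, 1.0)
    rho = sinusoid_arc_ratio(amplitude_px, period_px) if amplitude_px > 0 else 1.0
    return SectionFixture(
        image=img,
        boundary_rows=boundary,
        analytic_rho=rho,
        amplitude_px=amplitude_px,
        period_px=period_px,
    )


@dataclass(frozen=True)
class TraitEffectSpec:
    """Planted effects linking traits to BRDF parameters.

    σ = sigma0 + sigma_rho·(ρ − 1); k = k0 + k_wl·(λ − 400)/600;
    n = n0 − n_thickness·T − n_slw·SLW; each plus Gaussian noise with sd
    ``noise_sd`` × sd(signal), then clipped to the physical bounds.
    """

    sigma0: float = 0.05
    sigma_rho: float = 1.2
    k0: float = 0.05
    k_wl: float = 0.5
    n0: float = 3.5
    n_thickness: float = 2.0
    n_slw: float = 0.015


def synth_trait_dataset(
    n_samples: int = 270,
    effects: TraitEffectSpec | None = None,
    noise_sd: float = 0.15,
    seed: int | None = None,
) -> pd.DataFrame:
    """Trait table with planted trait→parameter effects.

    Leaves (one per 5 wavelengths, matching the measurement design) carry
    the anatomical traits; rows cross leaves with the representative
    wavelengths.  ``noise_sd`` is relative: each target's noise sd is that
    fraction of its signal's sd.
    """
    if n_samples < 50:
        raise ValueError("need at least 50 samples")
    eff = effects or TraitEffectSpec()
    rng = np.random.default_rng(seed)
    n_wl = len(WAVELENGTHS_NM)
    n_leaves = int(math.ceil(n_samples / n_wl))

    thickness = rng.uniform(0.10, 0.40, n_leaves)
    slw = rng.uniform(20.0, 80.0, n_leaves)
    chl_a = rng.uniform(2.0, 8.0, n_leaves)
    chl_b = rng.uniform(0.5, 3.0, n_leaves)
    car = rng.uniform(0.5, 2.5, n_leaves)
    rho = rng.uniform(1.0, 1.6, n_leaves)

    leaves = pd.DataFrame(
        {
            "leaf_id": np.arange(n_leaves),
            "thickness_mm": thickness,
            "slw_g_m2": slw,
            "chl_a": chl_a,
            "chl_b": chl_b,
            "car": car,
            "chl_ab": chl_a + chl_b,
            "chl_ratio": chl_a / chl_b,
            "rho": rho,
        }
    )
    df = leaves.loc[leaves.index.repeat(n_wl)].reset_index(drop=True)
    df["wavelength_nm"] = np.tile(np.array(WAVELENGTHS_NM), n_leaves)
    df = df.iloc[:n_samples].reset_index(drop=True)

    wl_scaled = (df["wavelength_nm"].to_numpy() - 400.0) / 600.0
    sig_sigma = eff.sigma0 + eff.sigma_rho * (df["rho"].to_numpy() - 1.0)
    sig_k = eff.k0 + eff.k_wl * wl_scaled
    sig_n = eff.n0 - eff.n_thickness * df["thickness_mm"].to_numpy() - eff.n_slw * df["slw_g_m2"].to_numpy()

    def add_noise(signal):
        sd = noise_sd * float(np.std(signal))
        return signal + sd * rng.standard_normal(signal.shape)

    df["sigma"] = np.clip(add_noise(sig_sigma), 0.01, 0.99)
    df["k"] = np.clip(add_noise(sig_k), 0.01, 0.99)
    df["n"] = np.clip(add_noise(sig_n), 1.1, 5.0)
    return df


def synth_canopy(
    n_layers: int = 5,
    facets_per_layer: int = 40,
    optics: tuple[float, float, float] = (0.3, 0.35, 1.0),
    tau: float = 0.05,
    box: tuple[float, float, float] = (1.0, 1.0, 1.0),
    leaf_size_m: float = 0.10,
    tilt_deg: float = 30.0,
    seed: int | None = None,
    convention: str = "as_printed",
) -> CanopyMesh:
    """Layered synthetic canopy of tilted triangular leaves.

    ``optics`` may be a single (σ, k, n) triple or a per-layer sequence of
    triples (layer 0 is the bottom layer).
    """
    if n_layers < 1 or facets_per_layer < 1:
        raise ValueError("layer and facet counts must be positive")
    rng = np.random.default_rng(seed)
    opt = np.asarray(optics, dtype=float)
    if opt.ndim == 1:
        opt = np.tile(opt, (n_layers, 1))
    if opt.shape != (n_layers, 3):
        raise ValueError("optics must be one triple or one per layer")

    tris, rows = [], []
    dz = box[2] / n_layers
    for layer in range(n_layers):
        z0 = layer * dz
        for _ in range(facets_per_layer):
            cx = rng.uniform(0.1 * box[0], 0.9 * box[0])
            cy = rng.uniform(0.1 * box[1], 0.9 * box[1])
            cz = z0 + rng.uniform(0.2, 0.8) * dz
            tilt = math.radians(rng.normal(tilt_deg, 5.0))
            az = rng.uniform(0.0, 2.0 * math.pi)
            normal = np.array(
                [math.sin(tilt) * math.cos(az), math.sin(tilt) * math.sin(az), math.cos(tilt)]
            )
            a = np.array([1.0, 0.0, 0.0])
            if abs(normal[0]) > 0.9:
                a = np.array([0.0, 1.0, 0.0])
            t1 = np.cross(normal, a)
            t1 /= np.linalg.norm(t1)
            t2 = np.cross(normal, t1)
            spin = rng.uniform(0.0, 2.0 * math.pi)
            center = np.array([cx, cy, cz])
            verts = [
                center
                + leaf_size_m
                * (math.cos(spin + j * 2.0 * math.pi / 3) * t1 + math.sin(spin + j * 2.0 * math.pi / 3) * t2)
                for j in range(3)
            ]
            tris.append(verts)
            rows.append([*opt[layer], tau])
    return CanopyMesh(
        triangles=np.array(tris), optics=np.array(rows), convention=convention
    )
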