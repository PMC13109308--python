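"""Cook-Torrance microfacet BRDF for leaf surfaces.

The reflectance of a leaf surface is modelled as the sum of a Lambertian
diffuse term ``k/π`` and a specular microfacet term

    f_spec = F(n, θh) · D(α, σ) · G(L, N, V, H) / (c · (L·N)(N·V))

where ``F`` is the exact unpolarized dielectric Fresnel factor, ``D`` the
Beckmann slope distribution (implemented exactly as the source formula, i.e.
without the 1/π of many rendering texts), ``G`` the Torrance-Sparrow
shadowing/masking term, and ``c`` a normalization constant.  The constant is
typeset ambiguously in the source literature ("2π2"), so it is exposed as a
``convention`` tag: ``as_printed`` (2π², default), ``pi``, or ``four`` (the
classical normalizations).  Fitted parameters are convention-dependent.

Cuticle absorption is neglected: the Fresnel term carries no absorption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import DegenerateGeometryError, GeometryFrame

#: Normalization constants for the specular denominator, by convention tag.
CONVENTIONS = {
    "as_printed": 2.0 * math.pi**2,
    "pi": math.pi,
    "four": 4.0,
}

SIGMA_BOUNDS = (0.0, 1.0)
K_BOUNDS = (0.0, 1.0)
N_BOUNDS = (1.0, 5.0)


@dataclass(frozen=True)
class BRDFParams:
    """Per-wavelength surface parameters (σ roughness, k diffuse weight, n index).

    σ is the RMS microfacet slope in [0, 1]; k weights the Lambertian term in
    [0, 1]; n is the effective refractive index, ranging 1–5 for leaves.
    """

    sigma: float
    k: float
    n: float
    wavelength_nm: float | None = None

    def __post_init__(self) -> None:
        if not SIGMA_BOUNDS[0] <= self.sigma <= SIGMA_BOUNDS[1]:
            raise ValueError(f"sigma {self.sigma} outside {SIGMA_BOUNDS}")
        if not K_BOUNDS[0] <= self.k <= K_BOUNDS[1]:
            raise ValueError(f"k {self.k} outside {K_BOUNDS}")
        if not N_BOUNDS[0] <= self.n <= N_BOUNDS[1]:
            raise ValueError(f"n {self.n} outside {N_BOUNDS}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sigma, self.k, self.n)


def normalization_constant(convention: str) -> float:
    try:
        return CONVENTIONS[convention]
    except KeyError:
        raise ValueError(
            f"unknown convention {convention!r}; expected one of {sorted(CONVENTIONS)}"
        ) from None


def fresnel(n, cos_theta_h):
    """Unpolarized dielectric Fresnel factor F(n, θh).

    Exact form with ``g = sqrt(n² + cos²θh − 1)``.  Index-matched media
    (n = 1) reflect nothing; the grazing limit (cosθh → 0) reflects
    everything.  Accepts scalars or arrays.
    """
    n = np.asarray(n, dtype=float)
    c = np.asarray(cos_theta_h, dtype=float)
    if np.any(n < 1.0):
        raise ValueError("refractive index must be >= 1")
    if np.any(c < 0.0) or np.any(c > 1.0):
        raise ValueError("cos_theta_h must lie in [0, 1]")
    g = np.sqrt(np.maximum(n**2 + c**2 - 1.0, 0.0))
    # grazing limit: F -> 1 as c -> 0
    denom1 = g + c
    first = np.where(denom1 > 0.0, ((g - c) / np.where(denom1 > 0.0, denom1, 1.0)) ** 2, 1.0)
    num2 = c * (g + c) - 1.0
    den2 = c * (g - c) + 1.0
    second = 1.0 + np.where(np.abs(den2) > 1e-300, (num2 / np.where(np.abs(den2) > 1e-300, den2, 1.0)) ** 2, 1.0)
    F = 0.5 * first * second
    F = np.clip(F, 0.0, 1.0)
    if F.ndim == 0:
        return float(F)
    return F


def beckmann(alpha, sigma):
    """Beckmann microfacet distribution D(α, σ) = exp(−(tanα/σ)²)/(σ² cos⁴α).

    Implemented exactly as stated (no 1/π prefactor).  α must lie in
    [0, π/2); σ must be positive (σ = 0 is a point mass).
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(sigma <= 0.0):
        raise ValueError("sigma must be positive (sigma = 0 is a specular point mass)")
    if np.any(alpha < 0.0) or np.any(alpha >= math.pi / 2):
        raise ValueError("alpha must lie in [0, pi/2)")
    t = np.tan(alpha)
    D = np.exp(-((t / sigma) ** 2)) / (sigma**2 * np.cos(alpha) ** 4)
    if D.ndim == 0 and np.ndim(sigma) == 0:
        return float(D)
    return D


def geometric_attenuation(frame: GeometryFrame) -> float:
    """Torrance-Sparrow shadowing/masking factor G ∈ (0, 1]."""
    if frame.degenerate:
        raise DegenerateGeometryError("frame has light or detector behind the surface")
    if frame.cos_VH <= 0.0:
        raise DegenerateGeometryError("V·H <= 0; geometric attenuation undefined")
    return float(
        min(
            1.0,
            2.0 * frame.cos_NV * frame.cos_NH / frame.cos_VH,
            2.0 * frame.cos_LN * frame.cos_NH / frame.cos_VH,
        )
    )


def brdf_value(params: BRDFParams, frame: GeometryFrame, convention: str = "as_printed") -> float:
    """Cook-Torrance BRDF value (sr⁻¹) for one geometry frame.

    With n = 1 the Fresnel factor vanishes and the value reduces to the
    Lambertian k/π at every frame.
    """
    c = normalization_constant(convention)
    if frame.degenerate:
        raise DegenerateGeometryError("cannot evaluate BRDF on a degenerate frame")
    diffuse = params.k / math.pi
    if params.n <= 1.0:
        return diffuse
    F = fresnel(params.n, max(frame.cos_theta_h, 0.0))
    # behind-the-lobe half vectors carry no specular energy
    if frame.cos_NH <= 0.0 or frame.alpha >= math.pi / 2:
        return diffuse
    D = beckmann(frame.alpha, max(params.sigma, 1e-12))
    G = geometric_attenuation(frame)
    spec = F * D * G / (c * frame.cos_LN * frame.cos_NV)
    return float(spec + diffuse)


def brdf_eval_arrays(
    sigma,
    k,
    n,
    cos_LN,
    cos_NV,
    cos_NH,
    cos_VH,
    cos_theta_h,
    alpha,
    convention: str = "as_printed",
):
    """Vectorized BRDF evaluation on precomputed frame arrays.

    Parameters and frame arrays broadcast against each other, which lets the
    fitters evaluate hundreds of candidate parameter triples against a whole
    scan in one call.  Frames must already be non-degenerate (use the
    ``usable`` mask from :func:`leafbrdf.geometry.scan_frame_arrays`).
    """
    c = normalization_constant(convention)
    sigma = np.asarray(sigma, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    cth = np.clip(np.asarray(cos_theta_h, dtype=float), 0.0, 1.0)
    alpha = np.asarray(alpha, dtype=float)

    g = np.sqrt(np.maximum(n**2 + cth**2 - 1.0, 0.0))
    gp = g + cth
    F = np.where(
        gp > 0.0,
        0.5
        * ((g - cth) / np.where(gp > 0.0, gp, 1.0)) ** 2
        * (1.0 + ((cth * gp - 1.0) / (cth * (g - cth) + 1.0)) ** 2),
        1.0,
    )
    F = np.clip(F, 0.0, 1.0)

    safe_alpha = np.clip(alpha, 0.0, math.pi / 2 - 1e-9)
    t = np.tan(safe_alpha)
    D = np.exp(-((t / sigma) ** 2)) / (sigma**2 * np.cos(safe_alpha) ** 4)

    cvh = np.where(np.abs(cos_VH) < 1e-300, 1e-300, cos_VH)
    G = np.minimum(
        1.0, np.minimum(2.0 * cos_NV * cos_NH / cvh, 2.0 * cos_LN * cos_NH / cvh)
    )
    G = np.maximum(G, 0.0)

    denom = c * cos_LN * cos_NV
    ok = (cos_NH > 0.0) & (alpha < math.pi / 2) & (cos_VH > 0.0) & (denom > 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        spec = np.where(ok, F * D * G / np.where(ok, denom, 1.0), 0.0)
    return spec + k / math.pi
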