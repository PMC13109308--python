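"""Minimal Monte-Carlo photon tracer for BRDF-governed canopy scattering.

A canopy is a bag of triangular leaf facets, each carrying surface
parameters (σ, k, n), a Lambertian transmittance τ, and an implied
directional-hemispherical reflectance R(θi) obtained by integrating the
Cook-Torrance BRDF (cosine-weighted) over the exit hemisphere.  Photons are
emitted from the top of the domain along the source direction and traced by
nearest-triangle intersection; at each hit the photon reflects with
probability R(θi), transmits with probability τ (cosine-weighted into the
far hemisphere), or is absorbed with the remainder.  Reflected directions
are drawn from the exact BRDF lobe: a cosine-weighted draw for the diffuse
component and Beckmann-about-mirror sampling with rejection for the
specular component.

A facet's *scattered* PPFD counts only photons that interacted with at
least one surface before arriving; direct-beam interception is tallied
separately.  The photon ledger (absorbed + exited + terminated-at-max-
bounces = emitted) holds exactly on every run.

Units: one photon carries source_ppfd × domain_area / n_photons of flux
(µmol·s⁻¹ worth of photons); facet PPFD is accumulated flux divided by
facet area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cooktorrance import BRDFParams, brdf_eval_arrays, normalization_constant


class MeshConfigurationError(ValueError):
    pass


@dataclass
class CanopyMesh:
    """Triangle facets (meters, Z vertical) with per-facet optics (σ, k, n, τ)."""

    triangles: np.ndarray  # (T, 3, 3)
    optics: np.ndarray  # (T, 4): sigma, k, n, tau
    convention: str = "as_printed"

    normals: np.ndarray = field(init=False)
    areas: np.ndarray = field(init=False)
    centroids: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        tri = np.asarray(self.triangles, dtype=float)
        if tri.size == 0:
            tri = tri.reshape(0, 3, 3)
        if tri.ndim != 3 or tri.shape[1:] != (3, 3):
            raise ValueError("triangles must have shape (T, 3, 3)")
        opt = np.asarray(self.optics, dtype=float).reshape(-1, 4) if np.asarray(self.optics).size else np.zeros((0, 4))
        if opt.shape != (tri.shape[0], 4):
            raise ValueError("optics must have shape (T, 4): sigma, k, n, tau")
        e1 = tri[:, 1] - tri[:, 0]
        e2 = tri[:, 2] - tri[:, 0]
        cross = np.cross(e1, e2)
        norms = np.linalg.norm(cross, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("mesh contains degenerate triangles")
        if np.any((opt[:, 3] < 0) | (opt[:, 3] > 1)):
            raise MeshConfigurationError("transmittance tau must lie in [0, 1]")
        for j, (lo, hi), name in ((0, (0.0, 1.0), "sigma"), (1, (0.0, 1.0), "k"), (2, (1.0, 5.0), "n")):
            if np.any((opt[:, j] < lo) | (opt[:, j] > hi)):
                raise MeshConfigurationError(f"facet {name} outside [{lo}, {hi}]")
        self.triangles = tri
        self.optics = opt
        self.normals = cross / norms[:, None]
        self.areas = 0.5 * norms
        self.centroids = tri.mean(axis=1)

    @property
    def n_facets(self) -> int:
        return int(self.triangles.shape[0])

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if self.n_facets == 0:
            return np.zeros(3), np.ones(3)
        pts = self.triangles.reshape(-1, 3)
        return pts.min(axis=0), pts.max(axis=0)


@dataclass(frozen=True)
class PhotonSource:
    """Collimated downward source at the canopy top."""

    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    ppfd: float = 1500.0
    n_photons: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction[2] >= 0:
            raise ValueError("source direction must point downward (z < 0)")
        if self.n_photons < 1:
            raise ValueError("need at least one photon")


@dataclass
class EnergyLedger:
    emitted: int = 0
    absorbed: int = 0
    exited: int = 0
    terminated: int = 0

    def check(self) -> None:
        assert self.absorbed + self.exited + self.terminated == self.emitted


@dataclass
class LayerProfile:
    n_layers: int
    layer_bounds: np.ndarray  # (n_layers+1,) z edges, ascending
    mean_scattered_ppfd: np.ndarray  # (n_layers,), area-weighted
    facet_ppfd: np.ndarray
    facet_layer: np.ndarray
    histogram: np.ndarray
    histogram_bins: tuple[float, ...]


def directional_hemispherical_reflectance(
    params: BRDFParams,
    incident_zenith_rad: float,
    n_quad: int = 64,
    convention: str = "as_printed",
    clip: bool = True,
) -> float:
    """R(θi) = ∮ f(ωi, ωo) cosθo dωo over the exit hemisphere.

    Product quadrature: Gauss-Legendre in µ = cosθo, midpoint in azimuth.
    A pure-diffuse surface (n = 1) integrates exactly to k.  The raw
    integral can exceed 1 for extreme parameter/convention combinations; it
    is clipped to [0, 1] with a warning.
    """
    if n_quad < 8:
        raise ValueError("n_quad must be at least 8")
    ti = float(incident_zenith_rad)
    if not 0.0 <= ti < math.pi / 2:
        raise ValueError("incident zenith must lie in [0, pi/2)")
    L = np.array([math.sin(ti), 0.0, math.cos(ti)])
    N = np.array([0.0, 0.0, 1.0])

    mu, wmu = np.polynomial.legendre.leggauss(n_quad)
    mu = 0.5 * (mu + 1.0)  # map to (0, 1)
    wmu = 0.5 * wmu
    phi = (np.arange(n_quad) + 0.5) * (2.0 * math.pi / n_quad)
    wphi = 2.0 * math.pi / n_quad

    MU, PHI = np.meshgrid(mu, phi, indexing="ij")
    st = np.sqrt(1.0 - MU**2)
    V = np.stack([st * np.cos(PHI), st * np.sin(PHI), MU], axis=-1)

    S = V + L
    ns = np.linalg.norm(S, axis=-1, keepdims=True)
    H = S / np.where(ns < 1e-12, 1.0, ns)
    cos_LN = float(L @ N)
    cos_NV = MU
    cos_NH = H[..., 2]
    cos_VH = np.einsum("...i,...i->...", V, H)
    cos_th = np.clip(np.einsum("...i,i->...", H, L), -1.0, 1.0)
    alpha = np.arccos(np.clip(cos_NH, -1.0, 1.0))

    f = brdf_eval_arrays(
        max(params.sigma, 1e-12), params.k, params.n,
        cos_LN, cos_NV, cos_NH, cos_VH, cos_th, alpha,
        convention=convention,
    )
    R = float(np.sum(f * MU * wmu[:, None] * wphi))
    if clip and R > 1.0:
        warnings.warn(f"raw hemispherical reflectance {R:.3f} > 1; clipping", stacklevel=2)
        R = 1.0
    return max(R, 0.0)


def reflectance_table(
    params: BRDFParams,
    n_angles: int = 19,
    n_quad: int = 64,
    convention: str = "as_printed",
) -> tuple[np.ndarray, np.ndarray]:
    """R(θi) sampled on a zenith grid, for interpolation during tracing."""
    thetas = np.linspace(0.0, math.pi / 2 * 0.995, n_angles)
    R = np.array(
        [
            directional_hemispherical_reflectance(params, t, n_quad=n_quad, convention=convention)
            for t in thetas
        ]
    )
    return thetas, R


def _orthonormal_basis(n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(n, a)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(n, t1)


def _cosine_sample(n: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    t1, t2 = _orthonormal_basis(n)
    u1, u2 = rng.random(), rng.random()
    r = math.sqrt(u1)
    phi = 2.0 * math.pi * u2
    z = math.sqrt(max(0.0, 1.0 - u1))
    return r * math.cos(phi) * t1 + r * math.sin(phi) * t2 + z * n


def _sample_specular(
    sigma: float,
    k: float,
    n_idx: float,
    L: np.ndarray,
    normal: np.ndarray,
    rng: np.random.Generator,
    convention: str,
    max_tries: int = 1000,
) -> np.ndarray | None:
    """Draw an exit direction from the specular lobe, ∝ f_spec·cosθo.

    Proposal: Beckmann-distributed half-vectors about the normal, mapped to
    exit directions by mirror reflection; acceptance uses the exact ratio
    f_spec·cosθo / (M·q), whose analytic bound is M = 8π·F/c ≤ 8π/c (the
    bisector identity makes L·H = V·H).  Returns None if no sample is
    accepted within ``max_tries`` (vanishing lobes).
    """
    c = normalization_constant(convention)
    t1, t2 = _orthonormal_basis(normal)
    cos_LN = float(L @ normal)
    for _ in range(max_tries):
        u1 = rng.random()
        u1 = min(u1, 1.0 - 1e-12)
        tan_a = sigma * math.sqrt(-math.log(1.0 - u1))
        a = math.atan(tan_a)
        phi = 2.0 * math.pi * rng.random()
        sa = math.sin(a)
        H = sa * math.cos(phi) * t1 + sa * math.sin(phi) * t2 + math.cos(a) * normal
        LH = float(L @ H)
        if LH <= 0.0:
            continue
        V = 2.0 * LH * H - L
        cos_NV = float(V @ normal)
        if cos_NV <= 0.0:
            continue
        # accept with ratio/M = [4π F G (L·H)] / [c cos_LN cosα] / (8π/c)
        cos_th = max(min(LH, 1.0), 0.0)
        g = math.sqrt(max(n_idx**2 + cos_th**2 - 1.0, 0.0))
        if g + cos_th <= 0:
            F = 1.0
        else:
            F = 0.5 * ((g - cos_th) / (g + cos_th)) ** 2 * (
                1.0 + ((cos_th * (g + cos_th) - 1.0) / (cos_th * (g - cos_th) + 1.0)) ** 2
            )
        cos_NH = float(H @ normal)
        cos_VH = float(V @ H)
        if cos_VH <= 0.0 or cos_NH <= 0.0:
            continue
        G = min(1.0, 2.0 * cos_NV * cos_NH / cos_VH, 2.0 * cos_LN * cos_NH / cos_VH)
        ratio = 4.0 * math.pi * F * G * LH / (c * cos_LN * math.cos(a))
        M = 8.0 * math.pi / c
        if rng.random() < ratio / M:
            return V
    return None


def sample_scatter_direction(
    params: BRDFParams,
    tau: float,
    incident: np.ndarray,
    normal: np.ndarray,
    rng: np.random.Generator,
    reflectance: float | None = None,
    convention: str = "as_printed",
) -> tuple[str, np.ndarray | None]:
    """Sample the fate of a photon hitting a facet: (event, new direction).

    ``incident`` is the photon's direction of travel; ``normal`` the facet
    normal.  Events are 'reflect', 'transmit' or 'absorb' with probabilities
    {R(θi), τ, 1−R−τ}.  Reflection mixes a cosine-weighted diffuse draw
    (weight k/R) with exact specular-lobe sampling.
    """
    d = np.asarray(incident, dtype=float)
    n = np.asarray(normal, dtype=float)
    n_eff = n if float(d @ n) < 0 else -n  # face the incoming photon
    L = -d  # surface-to-source
    cos_i = float(L @ n_eff)
    if cos_i <= 0:
        return "absorb", None
    if reflectance is None:
        reflectance = directional_hemispherical_reflectance(
            params, math.acos(min(cos_i, 1.0)), convention=convention
        )
    R = min(reflectance, 1.0)
    if R + tau > 1.0 + 1e-9:
        raise MeshConfigurationError(f"R + tau = {R + tau:.3f} > 1")
    u = rng.random()
    if u < R:
        w_diff = 1.0 if R <= 0 else min(1.0, params.k / R)
        if params.n <= 1.0 or rng.random() < w_diff:
            return "reflect", _cosine_sample(n_eff, rng)
        V = _sample_specular(
            max(params.sigma, 1e-12), params.k, params.n, L, n_eff, rng, convention
        )
        if V is None:  # vanishing specular lobe: fall back to diffuse
            V = _cosine_sample(n_eff, rng)
        return "reflect", V
    if u < R + tau:
        return "transmit", _cosine_sample(-n_eff, rng)
    return "absorb", None


def _intersect(
    origin: np.ndarray, direction: np.ndarray, mesh: CanopyMesh, eps: float = 1e-9
) -> tuple[int, float]:
    """Nearest-triangle intersection (vectorized Moller-Trumbore)."""
    if mesh.n_facets == 0:
        return -1, math.inf
    v0 = mesh.triangles[:, 0]
    e1 = mesh.triangles[:, 1] - v0
    e2 = mesh.triangles[:, 2] - v0
    h = np.cross(direction, e2)
    a = np.einsum("ij,ij->i", e1, h)
    mask = np.abs(a) > 1e-12
    f = np.where(mask, 1.0 / np.where(mask, a, 1.0), 0.0)
    s = origin - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * (q @ direction)
    t = f * np.einsum("ij,ij->i", q, e2)
    hit = mask & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1.0 + 1e-12) & (t > eps)
    if not hit.any():
        return -1, math.inf
    idx = np.flatnonzero(hit)
    best = idx[np.argmin(t[idx])]
    return int(best), float(t[best])


@dataclass
class TraceResult:
    facet_scattered_ppfd: np.ndarray
    facet_direct_ppfd: np.ndarray
    ledger: EnergyLedger
    mesh: CanopyMesh


def simulate(
    mesh: CanopyMesh, source: PhotonSource, max_bounces: int = 20
) -> TraceResult:
    """Trace all photons through the canopy and accumulate per-facet PPFD."""
    lo, hi = mesh.bounds()
    extent = hi - lo
    if not np.all(np.isfinite(extent)):
        raise ValueError("mesh domain must be bounded")
    domain_area = float(extent[0] * extent[1])
    if domain_area <= 0:
        domain_area = float(max(mesh.areas.sum(), 1.0))
    w = source.ppfd * domain_area / source.n_photons  # flux per photon

    # cache R(theta_i) tables per unique optics row
    uniq, inverse = np.unique(mesh.optics, axis=0, return_inverse=True)
    tables = []
    for row in uniq:
        p = BRDFParams(*row[:3])
        th, R = reflectance_table(p, convention=mesh.convention)
        if R.max() + row[3] > 1.0 + 1e-9:
            raise MeshConfigurationError(
                f"optics {tuple(row)} give R + tau = {R.max() + row[3]:.3f} > 1"
            )
        tables.append((th, R))

    facet_params = [BRDFParams(*row[:3]) for row in mesh.optics]
    rng = np.random.default_rng(source.seed)
    d0 = np.asarray(source.direction, dtype=float)
    d0 = d0 / np.linalg.norm(d0)
    z_top = hi[2] + 1e-3

    scattered = np.zeros(mesh.n_facets)
    direct = np.zeros(mesh.n_facets)
    ledger = EnergyLedger(emitted=source.n_photons)

    for _ in range(source.n_photons):
        x = lo[0] + rng.random() * extent[0]
        y = lo[1] + rng.random() * extent[1]
        pos = np.array([x, y, z_top])
        dirn = d0.copy()
        bounces = 0
        while True:
            fi, t = _intersect(pos, dirn, mesh)
            if fi < 0:
                ledger.exited += 1
                break
            if bounces == 0:
                direct[fi] += w
            else:
                scattered[fi] += w
            pos = pos + t * dirn
            row = mesh.optics[fi]
            normal = mesh.normals[fi]
            n_eff = normal if float(dirn @ normal) < 0 else -normal
            cos_i = float(-dirn @ n_eff)
            th_grid, R_grid = tables[inverse[fi]]
            R = float(np.interp(math.acos(min(max(cos_i, 0.0), 1.0)), th_grid, R_grid))
            event, new_dir = sample_scatter_direction(
                facet_params[fi], row[3], dirn, normal, rng,
                reflectance=R, convention=mesh.convention,
            )
            if event == "absorb":
                ledger.absorbed += 1
                break
            dirn = new_dir
            bounces += 1
            if bounces >= max_bounces:
                ledger.terminated += 1
                break
    ledger.check()
    return TraceResult(
        facet_scattered_ppfd=scattered / mesh.areas,
        facet_direct_ppfd=direct / mesh.areas,
        ledger=ledger,
        mesh=mesh,
    )


DEFAULT_BINS = (0.0, 40.0, 80.0, 150.0, math.inf)


def layer_summary(
    mesh: CanopyMesh,
    facet_ppfd: np.ndarray,
    n_layers: int,
    bins: tuple[float, ...] = DEFAULT_BINS,
) -> LayerProfile:
    """Equal-thickness horizontal layers with area-weighted mean PPFD.

    Facets are assigned to layers by centroid height; the histogram counts
    facets per intensity bin across the whole canopy.
    """
    if n_layers < 1:
        raise ValueError("need at least one layer")
    ppfd = np.asarray(facet_ppfd, dtype=float)
    lo, hi = mesh.bounds()
    edges = np.linspace(lo[2], hi[2], n_layers + 1)
    z = mesh.centroids[:, 2]
    idx = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, n_layers - 1)
    means = np.zeros(n_layers)
    for layer in range(n_layers):
        m = idx == layer
        if m.any():
            means[layer] = float(np.average(ppfd[m], weights=mesh.areas[m]))
    hist, _ = np.histogram(ppfd, bins=np.array(bins))
    return LayerProfile(
        n_layers=n_layers,
        layer_bounds=edges,
        mean_scattered_ppfd=means,
        facet_ppfd=ppfd,
        facet_layer=idx,
        histogram=hist,
        histogram_bins=tuple(bins),
    )
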