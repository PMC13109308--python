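"""Leaf-surface roughness from cross-section micrographs.

The roughness metric is the ratio ρ = l_inner / l_outer, where l_inner is
the pixel-path length of the extracted surface edge and l_outer the length
of the same profile after 1-D Gaussian smoothing.  A flat surface gives
ρ = 1; finer or taller surface corrugation gives larger ρ.

Edge extraction is deliberately simple and reproducible: Otsu threshold on
the region of interest, keep the largest connected tissue component, take
the per-column extremal pixel (topmost for the adaxial surface, bottommost
for the abaxial).  Path lengths use the 8-connected (octile) metric: a step
of (dx, dy) contributes max(|dx|,|dy|) + (√2−1)·min(|dx|,|dy|), so an axial
step counts 1 and a diagonal step counts √2.  ROI size and position are
randomized over replicates to reduce operator bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.filters import threshold_otsu
from skimage.measure import label

MIN_ROI_WIDTH = 20

#: Default 1-D Gaussian sd for the outer edge, as a fraction of ROI width.
DEFAULT_SIGMA_FRAC = 0.02


class SegmentationError(ValueError):
    """Raised when no usable tissue edge can be extracted from an ROI."""


@dataclass(frozen=True)
class EdgeCurve:
    """An x-monotone pixel path along one leaf surface."""

    columns: np.ndarray
    rows: np.ndarray
    side: str

    def __post_init__(self) -> None:
        if self.columns.size < 2:
            raise ValueError("edge curve needs at least 2 points")
        if np.any(np.diff(self.columns) <= 0):
            raise ValueError("edge curve must be strictly x-monotone")


@dataclass(frozen=True)
class RoughnessResult:
    rho: float
    l_inner: float
    l_outer: float
    replicates: tuple[float, ...] = ()
    mean: float | None = None
    se: float | None = None
    rois: tuple[tuple[int, int, int, int], ...] = ()


def as_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) image to a single float channel."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D (or RGB) image")
    return img


def extract_surface_edge(
    image: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    side: str = "adaxial",
    foreground: str = "bright",
) -> EdgeCurve:
    """Extract the per-column surface edge of the largest tissue component.

    ``roi`` is (x0, y0, x1, y1) in pixel coordinates, exclusive upper bounds;
    ``side`` selects the topmost (adaxial) or bottommost (abaxial) foreground
    pixel per column.  Columns where the component is absent are skipped; if
    more than 5% are missing the segmentation is considered failed.
    """
    if side not in ("adaxial", "abaxial"):
        raise ValueError("side must be 'adaxial' or 'abaxial'")
    img = as_grayscale(image)
    h, w = img.shape
    if roi is None:
        roi = (0, 0, w, h)
    x0, y0, x1, y1 = (int(v) for v in roi)
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"ROI {roi} outside image bounds {(w, h)}")
    if x1 - x0 < MIN_ROI_WIDTH:
        raise ValueError(f"ROI narrower than {MIN_ROI_WIDTH} px")
    patch = img[y0:y1, x0:x1]
    if np.ptp(patch) < 1e-12:
        raise SegmentationError("ROI has no tissue/background contrast")
    thr = threshold_otsu(patch)
    mask = patch > thr if foreground == "bright" else patch < thr
    if not mask.any():
        raise SegmentationError("no foreground pixels in ROI")
    lab = label(mask, connectivity=2)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    comp = lab == largest

    cols, rows = [], []
    for c in range(comp.shape[1]):
        idx = np.flatnonzero(comp[:, c])
        if idx.size == 0:
            continue
        r = idx[0] if side == "adaxial" else idx[-1]
        cols.append(c + x0)
        rows.append(int(r) + y0)
    if len(cols) < 2:
        raise SegmentationError("tissue component too small to trace an edge")
    if len(cols) < 0.95 * comp.shape[1]:
        raise SegmentationError(
            f"edge present in only {len(cols)}/{comp.shape[1]} columns"
        )
    return EdgeCurve(np.array(cols), np.array(rows, dtype=float), side)


def path_length(columns: np.ndarray, rows: np.ndarray) -> float:
    """Octile path length of an x-monotone pixel path."""
    dx = np.abs(np.diff(np.asarray(columns, dtype=float)))
    dy = np.abs(np.diff(np.asarray(rows, dtype=float)))
    big = np.maximum(dx, dy)
    small = np.minimum(dx, dy)
    return float(np.sum(big + (math.sqrt(2.0) - 1.0) * small))


def inner_length(curve: EdgeCurve) -> float:
    """Exact pixel-path length of the raw edge."""
    return path_length(curve.columns, curve.rows)


def outer_length(curve: EdgeCurve, gaussian_sigma: float) -> float:
    """Path length of the edge after 1-D Gaussian smoothing (reflect padding)."""
    if gaussian_sigma <= 0:
        raise ValueError("gaussian_sigma must be positive")
    if curve.rows.size < 2:
        raise ValueError("profile collapsed below 2 points")
    smoothed = gaussian_filter1d(curve.rows.astype(float), gaussian_sigma, mode="reflect")
    return path_length(curve.columns, smoothed)


def roughness_ratio(l_inner: float, l_outer: float) -> float:
    """ρ = l_inner / l_outer."""
    if l_outer <= 0:
        raise ValueError("outer length must be positive")
    return float(l_inner) / float(l_outer)


def measure_roughness(
    image: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    side: str = "adaxial",
    gaussian_sigma: float | None = None,
    foreground: str = "bright",
) -> RoughnessResult:
    """Single-ROI roughness: extract the edge, smooth, and take the ratio."""
    curve = extract_surface_edge(image, roi=roi, side=side, foreground=foreground)
    width = int(curve.columns[-1] - curve.columns[0] + 1)
    sigma = gaussian_sigma if gaussian_sigma is not None else DEFAULT_SIGMA_FRAC * width
    li = inner_length(curve)
    lo = outer_length(curve, sigma)
    return RoughnessResult(rho=roughness_ratio(li, lo), l_inner=li, l_outer=lo)


def replicate_roughness(
    image: np.ndarray,
    side: str = "adaxial",
    n_replicates: int = 5,
    seed: int | None = None,
    width_frac: tuple[float, float] = (0.3, 0.8),
    gaussian_sigma: float | None = None,
    foreground: str = "bright",
) -> RoughnessResult:
    """Roughness over ``n_replicates`` randomized ROIs (width 30–80% of the image).

    Reproducible for a fixed seed.  If fewer than ``n_replicates`` ROIs
    segment successfully the call fails, listing the per-ROI errors.
    """
    img = as_grayscale(image)
    h, w = img.shape
    rng = np.random.default_rng(seed)
    rhos: list[float] = []
    rois: list[tuple[int, int, int, int]] = []
    failures: list[str] = []
    attempts = 0
    while len(rhos) < n_replicates and attempts < 20 * n_replicates:
        attempts += 1
        width = max(MIN_ROI_WIDTH, int(rng.uniform(*width_frac) * w))
        x0 = int(rng.integers(0, max(1, w - width + 1)))
        roi = (x0, 0, min(w, x0 + width), h)
        try:
            res = measure_roughness(
                img, roi=roi, side=side, gaussian_sigma=gaussian_sigma, foreground=foreground
            )
        except (SegmentationError, ValueError) as exc:
            failures.append(f"roi {roi}: {exc}")
            continue
        rhos.append(res.rho)
        rois.append(roi)
    if len(rhos) < n_replicates:
        raise SegmentationError(
            f"only {len(rhos)}/{n_replicates} ROIs segmented; failures: {failures[:5]}"
        )
    arr = np.array(rhos)
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return RoughnessResult(
        rho=float(arr.mean()),
        l_inner=float("nan"),
        l_outer=float("nan"),
        replicates=tuple(rhos),
        mean=float(arr.mean()),
        se=se,
        rois=tuple(rois),
    )
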