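"""Estimation of (σ, k, n) from calibrated bidirectional reflectance.

Two fitters are provided, both minimizing the unweighted sum of squared
residuals over all non-degenerate geometries pooled across the scan's
incidence angles:

* :func:`fit_least_squares` — bounded trust-region nonlinear least squares
  (scipy) from the standard initial point (0.5, 0.5, 3).
* :func:`fit_adaptive_grid` — a two-layer adaptive grid search: cyclic
  coordinate descent over a coarse 1e-2 grid inside the bounds until the SSE
  stops improving, then repeated per-parameter sweeps of a fine 1e-4 grid
  spanning one coarse step around the incumbent.  Ties break toward the
  smaller parameter value, so the result is deterministic.

Fits are independent per wavelength, surface, and canopy layer; no
information is shared across wavelengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares as _scipy_least_squares

from .cooktorrance import BRDFParams, brdf_eval_arrays, normalization_constant
from .reflectance import ReflectanceDataset

DEFAULT_INITIAL = (0.5, 0.5, 3.0)
DEFAULT_LOWER = (0.01, 0.01, 1.1)
DEFAULT_UPPER = (0.99, 0.99, 5.0)


@dataclass(frozen=True)
class FitConfig:
    method: str = "least_squares"
    initial: tuple[float, float, float] = DEFAULT_INITIAL
    lower_bounds: tuple[float, float, float] = DEFAULT_LOWER
    upper_bounds: tuple[float, float, float] = DEFAULT_UPPER
    coarse_step: float = 1e-2
    fine_step: float = 1e-4
    max_sweeps: int = 50
    sse_rel_tol: float = 1e-12
    convention: str = "as_printed"

    def __post_init__(self) -> None:
        normalization_constant(self.convention)
        physical_lo, physical_hi = (0.0, 0.0, 1.0), (1.0, 1.0, 5.0)
        names = ("sigma", "k", "n")
        for name, plo, lo, x0, hi, phi in zip(
            names, physical_lo, self.lower_bounds, self.initial, self.upper_bounds, physical_hi
        ):
            if not plo <= lo <= hi <= phi:
                raise ValueError(
                    f"{name} bounds [{lo}, {hi}] must lie inside the physical box [{plo}, {phi}]"
                )
            if not lo <= x0 <= hi:
                raise ValueError("initial point must lie within the bounds")


@dataclass
class FitResult:
    params: BRDFParams
    r_squared: float | None
    rmse: float
    residuals: np.ndarray
    n_points: int
    method: str
    convention: str
    converged: bool = True
    message: str = ""
    sse_trace: list[float] = field(default_factory=list)

    @property
    def sse(self) -> float:
        return float(np.sum(self.residuals**2))


def goodness_of_fit(predicted, observed) -> tuple[float | None, float]:
    """(R², RMSE) of predictions against observations.

    R² is 1 − SSE/SStot about the observed mean; it is undefined (returned
    as None) when the observations are constant, in which case RMSE is still
    meaningful.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have matching shapes")
    if p.size < 2:
        raise ValueError("need at least 2 points")
    sse = float(np.sum((o - p) ** 2))
    rmse = math.sqrt(sse / o.size)
    sstot = float(np.sum((o - o.mean()) ** 2))
    if sstot <= 0.0:
        return None, rmse
    return 1.0 - sse / sstot, rmse


def _model(x: np.ndarray, arrays: dict, convention: str) -> np.ndarray:
    return brdf_eval_arrays(
        x[..., 0:1] if np.ndim(x) > 1 else x[0],
        x[..., 1:2] if np.ndim(x) > 1 else x[1],
        x[..., 2:3] if np.ndim(x) > 1 else x[2],
        arrays["cos_LN"],
        arrays["cos_NV"],
        arrays["cos_NH"],
        arrays["cos_VH"],
        arrays["cos_theta_h"],
        arrays["alpha"],
        convention=convention,
    )


def residuals(
    params: BRDFParams, dataset: ReflectanceDataset, convention: str = "as_printed"
) -> np.ndarray:
    """Model-minus-observed residual vector over the usable geometries."""
    arrays = dataset.frame_arrays()
    if arrays["f_samp"].size == 0:
        raise ValueError("dataset has no usable (non-degenerate) records")
    pred = _model(np.array(params.as_tuple()), arrays, convention)
    return pred - arrays["f_samp"]


def _require_points(dataset: ReflectanceDataset, minimum: int = 4) -> dict:
    arrays = dataset.frame_arrays()
    if arrays["f_samp"].size < minimum:
        raise ValueError(
            f"need at least {minimum} usable records, have {arrays['f_samp'].size}"
        )
    return arrays


def _finalize(
    x: np.ndarray,
    dataset: ReflectanceDataset,
    config: FitConfig,
    method: str,
    converged: bool,
    message: str,
    sse_trace: list[float] | None = None,
) -> FitResult:
    arrays = dataset.frame_arrays()
    x = np.clip(np.asarray(x, dtype=float), config.lower_bounds, config.upper_bounds)
    wl = None
    if "wavelength_nm" in dataset.table.columns:
        uniq = dataset.table["wavelength_nm"].unique()
        if uniq.size == 1:
            wl = float(uniq[0])
    params = BRDFParams(float(x[0]), float(x[1]), float(x[2]), wavelength_nm=wl)
    pred = _model(np.asarray(x, dtype=float), arrays, config.convention)
    res = pred - arrays["f_samp"]
    r2, rmse = goodness_of_fit(pred, arrays["f_samp"])
    return FitResult(
        params=params,
        r_squared=r2,
        rmse=rmse,
        residuals=res,
        n_points=int(res.size),
        method=method,
        convention=config.convention,
        converged=converged,
        message=message,
        sse_trace=list(sse_trace or []),
    )


def fit_least_squares(dataset: ReflectanceDataset, config: FitConfig | None = None) -> FitResult:
    """Bounded nonlinear least squares from the configured initial point.

    Deterministic for a fixed dataset; non-convergence is flagged on the
    result (``converged=False`` with the solver message) rather than raised.
    """
    config = config or FitConfig(method="least_squares")
    arrays = _require_points(dataset)

    def fun(x):
        return _model(x, arrays, config.convention) - arrays["f_samp"]

    sol = _scipy_least_squares(
        fun,
        x0=np.array(config.initial, dtype=float),
        bounds=(np.array(config.lower_bounds), np.array(config.upper_bounds)),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=2000,
    )
    return _finalize(
        sol.x, dataset, config, "least_squares",
        converged=bool(sol.success), message=str(sol.message),
    )


def _sweep_sse(
    x: np.ndarray, j: int, candidates: np.ndarray, arrays: dict, convention: str
) -> tuple[float, float]:
    """Best (value, SSE) for parameter j over a candidate grid, others fixed."""
    cols = []
    for i in range(3):
        if i == j:
            cols.append(candidates[:, None])
        else:
            cols.append(np.full((candidates.size, 1), x[i]))
    pred = brdf_eval_arrays(
        cols[0], cols[1], cols[2],
        arrays["cos_LN"], arrays["cos_NV"], arrays["cos_NH"],
        arrays["cos_VH"], arrays["cos_theta_h"], arrays["alpha"],
        convention=convention,
    )
    sse = np.sum((pred - arrays["f_samp"]) ** 2, axis=1)
    best = int(np.argmin(sse))  # argmin takes the first (smallest value) on ties
    return float(candidates[best]), float(sse[best])


def fit_adaptive_grid(dataset: ReflectanceDataset, config: FitConfig | None = None) -> FitResult:
    """Two-layer adaptive grid search (coarse 1e-2, then fine 1e-4).

    Coordinate-wise descent: each sweep optimizes σ, k, n in turn over a
    regular grid, repeating until the relative SSE improvement drops below
    tolerance or ``max_sweeps`` is hit; the fine stage re-sweeps each
    parameter on a 1e-4 grid spanning one coarse step around the incumbent.
    The SSE trace is non-increasing by construction.
    """
    config = config or FitConfig(method="adaptive_grid")
    arrays = _require_points(dataset)
    lo = np.array(config.lower_bounds, dtype=float)
    hi = np.array(config.upper_bounds, dtype=float)
    x = np.array(config.initial, dtype=float)

    def exact_k(xv: np.ndarray) -> float:
        # the model is linear in k: profile it out exactly, then clip to bounds
        pred0 = _model(np.array([xv[0], 0.0, xv[2]]), arrays, config.convention)
        k_star = math.pi * float(np.mean(arrays["f_samp"] - pred0))
        return float(np.clip(k_star, lo[1], hi[1]))

    def run_phase(step: float, window: float | None, trace: list[float], sse: float) -> float:
        for _ in range(config.max_sweeps):
            prev = sse
            for j in range(3):
                if window is None:
                    cand = np.arange(lo[j], hi[j] + step / 2, step)
                else:
                    cand = np.arange(
                        max(lo[j], x[j] - window), min(hi[j], x[j] + window) + step / 2, step
                    )
                cand = np.clip(cand, lo[j], hi[j])
                if j == 1:
                    # k is the linear coordinate; add its exact conditional
                    # optimum to the grid so the sweep can land on it
                    cand = np.sort(np.append(cand, exact_k(x)))
                val, best = _sweep_sse(x, j, cand, arrays, config.convention)
                if best < sse:
                    x[j] = val
                    sse = best
            trace.append(sse)
            if prev - sse <= config.sse_rel_tol * max(prev, 1e-300):
                break
        return sse

    def joint_sigma_n_sweep(sigma_step: float, sigma_window: float | None, n_step: float, sse: float) -> float:
        # escape hatch for coordinate-blocked points: sigma and n jointly set
        # the specular amplitude, so single-axis sweeps can stall on their
        # ridge; sweep the (sigma, n) plane with k profiled out exactly.
        # n always spans its full bounds (the ridge is long in n).
        if sigma_window is None:
            sig = np.arange(lo[0], hi[0] + sigma_step / 2, sigma_step)
        else:
            sig = np.arange(
                max(lo[0], x[0] - sigma_window),
                min(hi[0], x[0] + sigma_window) + sigma_step / 2,
                sigma_step,
            )
        nn = np.clip(np.arange(lo[2], hi[2] + n_step / 2, n_step), lo[2], hi[2])
        sig = np.clip(sig, lo[0], hi[0])
        S, NN = np.meshgrid(sig, nn, indexing="ij")
        S = S.ravel()[:, None]
        NN = NN.ravel()[:, None]
        pred0 = brdf_eval_arrays(
            S, 0.0, NN,
            arrays["cos_LN"], arrays["cos_NV"], arrays["cos_NH"],
            arrays["cos_VH"], arrays["cos_theta_h"], arrays["alpha"],
            convention=config.convention,
        )
        y = arrays["f_samp"]
        k_star = np.clip(math.pi * np.mean(y - pred0, axis=1), lo[1], hi[1])
        sse_all = np.sum((pred0 + k_star[:, None] / math.pi - y) ** 2, axis=1)
        best = int(np.argmin(sse_all))
        if sse_all[best] < sse:
            x[0], x[1], x[2] = float(S[best, 0]), float(k_star[best]), float(NN[best, 0])
            sse = float(sse_all[best])
        return sse

    pred0 = _model(x, arrays, config.convention)
    sse = float(np.sum((pred0 - arrays["f_samp"]) ** 2))
    trace: list[float] = [sse]
    # below this the fit already matches the data to numerical precision and
    # the escape sweeps cannot matter
    sse_floor = 1e-20 * float(np.sum(arrays["f_samp"] ** 2))
    escape_sigma_step = config.fine_step
    for _cycle in range(3):
        sse = run_phase(config.coarse_step, None, trace, sse)
        if sse <= sse_floor:
            break
        before = sse
        sse = joint_sigma_n_sweep(config.coarse_step, None, config.coarse_step, sse)
        trace.append(sse)
        if before - sse <= config.sse_rel_tol * max(before, 1e-300):
            break
    if sse > sse_floor:
        # sigma at fine resolution around the incumbent, n over its full
        # range: the true basin may only be representable once sigma leaves
        # the coarse grid
        sse = joint_sigma_n_sweep(escape_sigma_step, config.coarse_step, config.coarse_step, sse)
        trace.append(sse)
    for _cycle in range(3):
        sse = run_phase(config.fine_step, config.coarse_step, trace, sse)
        if sse <= sse_floor:
            break
        before = sse
        sse = joint_sigma_n_sweep(escape_sigma_step, config.coarse_step, config.coarse_step, sse)
        trace.append(sse)
        if before - sse <= config.sse_rel_tol * max(before, 1e-300):
            break
    sse = run_phase(config.fine_step, config.coarse_step, trace, sse)
    return _finalize(
        x, dataset, config, "adaptive_grid",
        converged=True, message="coordinate descent converged", sse_trace=trace,
    )
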