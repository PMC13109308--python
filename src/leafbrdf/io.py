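"""Readers/writers for the package's tabular formats plus run provenance.

All structured outputs are JSON; tabular data are plain CSV with headers.
Angular-scan CSVs carry one row per (wavelength, geometry) with raw sample
and whiteboard fluxes; mesh CSVs carry one triangle per row (9 vertex
coordinates plus σ, k, n, τ).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .raytracer import CanopyMesh
from .reflectance import ReflectanceDataset, calibrate_scan

SCAN_COLUMNS = (
    "wavelength_nm",
    "holder_scale_deg",
    "incident_zenith_deg",
    "incident_azimuth_deg",
    "view_zenith_deg",
    "view_azimuth_deg",
    "flux_sample",
    "flux_reference",
)

MESH_COLUMNS = (
    "x0", "y0", "z0", "x1", "y1", "z1", "x2", "y2", "z2",
    "sigma", "k", "n", "tau",
)


class SchemaError(ValueError):
    pass


def read_scan_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate an angular-scan CSV (header required, '.' decimal)."""
    df = pd.read_csv(path)
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"scan file {path} is missing columns: {missing}")
    for c in SCAN_COLUMNS:
        if not np.issubdtype(df[c].dtype, np.number):
            raise SchemaError(f"column {c!r} is not numeric")
    return df


def write_scan_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def dataset_from_scan(
    scan: pd.DataFrame,
    wavelength_nm: float | None = None,
    reference: str = "per_row",
    metadata: dict | None = None,
) -> ReflectanceDataset:
    """Calibrate a raw scan and wrap it as a fit-ready dataset."""
    df = scan
    if wavelength_nm is not None:
        df = df[np.isclose(df["wavelength_nm"], wavelength_nm)]
        if df.empty:
            raise ValueError(f"no rows at wavelength {wavelength_nm} nm")
    calibrated = calibrate_scan(df, reference=reference)
    return ReflectanceDataset(table=calibrated, metadata=dict(metadata or {}))


def read_mesh_csv(path: str | Path, convention: str = "as_printed") -> CanopyMesh:
    df = pd.read_csv(path)
    missing = [c for c in MESH_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"mesh file {path} is missing columns: {missing}")
    tri = df[list(MESH_COLUMNS[:9])].to_numpy(float).reshape(-1, 3, 3)
    optics = df[list(MESH_COLUMNS[9:])].to_numpy(float)
    return CanopyMesh(triangles=tri, optics=optics, convention=convention)


def write_mesh_csv(mesh: CanopyMesh, path: str | Path) -> None:
    data = np.hstack([mesh.triangles.reshape(-1, 9), mesh.optics])
    pd.DataFrame(data, columns=list(MESH_COLUMNS)).to_csv(path, index=False)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def provenance(seed: int | None = None, inputs: dict | None = None, **params) -> dict:
    """A reproducibility block embedded in every structured output."""
    return {
        "package": "leafbrdf",
        "version": __version__,
        "seed": seed,
        "inputs": {k: file_sha256(v) for k, v in (inputs or {}).items()},
        "parameters": params,
    }


def save_json(obj: dict, path: str | Path) -> None:
    class _Encoder(json.JSONEncoder):
        def default(self, o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return super().default(o)

    Path(path).write_text(json.dumps(obj, indent=2, cls=_Encoder) + "\n")
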