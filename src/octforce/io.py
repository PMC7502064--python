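"""Readers and writers: HDF5 calibration containers, CSV traces, reports.

HDF5 layout (schema v1), one container per needle dataset:

    /raw        float32, (1024, N_t)   raw spectral M-scan
    /force      float32, (N_t,)        axial force trace in newtons
    /timestamps float64, (N_t,)        acquisition times in seconds
    /chirp      float64, (1024,)       pixel -> wavenumber map (1/mm)
    /recon      float32, (512, N_t)    optional reconstructed A-scans

    attrs: needle_id, provenance (JSON string), schema_version,
           chirp_is_uniform
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .experiment import EvalReport
from .signal_model import (
    CalibrationDataset,
    ChirpMap,
    ForceTrace,
    RawMScan,
)

SCHEMA_VERSION = 1

__all__ = [
    "SCHEMA_VERSION",
    "DatasetFormatError",
    "write_dataset",
    "read_dataset",
    "write_force_csv",
    "read_force_csv",
    "render_report",
]


class DatasetFormatError(ValueError):
    """Raised for missing datasets, shape mismatches or unknown schemas."""

    def __init__(self, code: str, message: str) -> None:
        super().__init__(f"[{code}] {message}")
        self.code = code


def write_dataset(
    dataset: CalibrationDataset, path: str | Path, *, overwrite: bool = False
) -> None:
    """Write a calibration dataset to its HDF5 container.

    Refuses to clobber an existing file unless ``overwrite`` is set.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True (CLI: --force)")
    with h5py.File(path, "w") as f:
        f.create_dataset("raw", data=dataset.mscan.spectra.astype(np.float32))
        f.create_dataset("force", data=dataset.force_trace.forces.astype(np.float32))
        f.create_dataset("timestamps", data=dataset.mscan.timestamps.astype(np.float64))
        f.create_dataset("chirp", data=dataset.mscan.chirp.wavenumbers.astype(np.float64))
        if dataset.recon is not None:
            f.create_dataset("recon", data=np.asarray(dataset.recon, dtype=np.float32))
        f.attrs["needle_id"] = dataset.needle_id
        f.attrs["provenance"] = json.dumps(dataset.provenance)
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["chirp_is_uniform"] = bool(dataset.mscan.chirp.is_uniform)


def read_dataset(path: str | Path) -> CalibrationDataset:
    """Read and validate a calibration dataset from HDF5."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise DatasetFormatError(
                "schema", f"unsupported schema_version {version} in {path}"
            )
        for name in ("raw", "force", "timestamps", "chirp"):
            if name not in f:
                raise DatasetFormatError("missing", f"dataset /{name} absent from {path}")
        raw = np.asarray(f["raw"], dtype=np.float64)
        force = np.asarray(f["force"], dtype=np.float64)
        timestamps = np.asarray(f["timestamps"], dtype=np.float64)
        chirp_k = np.asarray(f["chirp"], dtype=np.float64)
        recon = np.asarray(f["recon"], dtype=np.float64) if "recon" in f else None
        needle_id = str(f.attrs.get("needle_id", "unknown"))
        provenance = json.loads(f.attrs.get("provenance", "{}"))
        is_uniform = bool(f.attrs.get("chirp_is_uniform", False))

    if raw.ndim != 2 or raw.shape[1] != force.size or force.size != timestamps.size:
        raise DatasetFormatError(
            "alignment",
            f"/raw {raw.shape}, /force {force.shape} and /timestamps "
            f"{timestamps.shape} are not aligned in {path}",
        )
    if recon is not None and recon.shape[1] != raw.shape[1]:
        raise DatasetFormatError("alignment", f"/recon misaligned with /raw in {path}")
    try:
        chirp = ChirpMap(wavenumbers=chirp_k, is_uniform=is_uniform)
        mscan = RawMScan(spectra=raw, timestamps=timestamps, chirp=chirp)
        trace = ForceTrace(forces=force, timestamps=timestamps)
        return CalibrationDataset(
            mscan=mscan,
            force_trace=trace,
            needle_id=needle_id,
            provenance=provenance,
            recon=recon,
        )
    except ValueError as exc:
        raise DatasetFormatError("shape", str(exc)) from exc


def write_force_csv(trace: ForceTrace, path: str | Path) -> None:
    """Export a force trace as CSV with columns timestamp,force_N."""
    pd.DataFrame({"timestamp": trace.timestamps, "force_N": trace.forces}).to_csv(
        path, index=False
    )


def read_force_csv(path: str | Path) -> ForceTrace:
    df = pd.read_csv(path)
    return ForceTrace(
        forces=df["force_N"].to_numpy(float), timestamps=df["timestamp"].to_numpy(float)
    )


def render_report(report: EvalReport, path: str | Path) -> None:
    """Emit an evaluation report as CSV (runs + aggregate) and JSON.

    ``<path>.csv`` holds the per-run rows, ``<path>_aggregate.csv`` the
    mean +/- std cells (two decimals, the conventional table style) and
    ``<path>.json`` the full machine-readable report.
    """
    path = Path(path)
    base = path.with_suffix("") if path.suffix else path
    report.runs.to_csv(base.with_suffix(".csv"), index=False)
    agg = report.aggregate.copy()
    agg["mae_mean_pm_std"] = [
        f"{m:.2f} ± {s:.2f}" for m, s in zip(agg["mean_mae_mN"], agg["std_mae_mN"])
    ]
    agg.to_csv(base.parent / (base.name + "_aggregate.csv"), index=False)
    with open(base.with_suffix(".json"), "w") as f:
        json.dump(report.to_dict(), f, indent=2, default=float)
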