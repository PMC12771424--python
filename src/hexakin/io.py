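"""Delimited-text I/O for spectra, traces, calibrations and manifests.

Spectrum files: CSV with header ``wavelength_nm,absorbance``.
Trace files: CSV with header ``time_<unit>,signal`` plus a JSON metadata
sidecar (``<stem>.meta.json``) carrying monitor wavelength, ligand
concentrations and replicate id.
Calibration files: CSV with header ``ratio,f_h``.
Autoxidation series: a JSON manifest listing ``{"time_h": ..., "file": ...}``
entries with paths relative to the manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coordination import CalibrationTable, Spectrum
from .kinetics import KineticTrace

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_trace",
    "write_trace",
    "read_calibration",
    "write_calibration",
    "read_autoox_series",
    "write_autoox_series",
]

_FLOAT_FMT = "%.12g"


def write_spectrum(path, spectrum: Spectrum) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "absorbance": spectrum.absorbances}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_spectrum(path, state: str = "ferrous-deoxy", sample_id: str | None = None) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns or "absorbance" not in df.columns:
        raise ValueError(f"{path}: expected columns wavelength_nm,absorbance")
    return Spectrum(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        absorbances=df["absorbance"].to_numpy(float),
        state=state,
        sample_id=path.stem if sample_id is None else sample_id,
    )


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_trace(path, trace: KineticTrace) -> Path:
    path = Path(path)
    pd.DataFrame({f"time_{trace.time_unit}": trace.times, "signal": trace.signal}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    meta = {
        "monitor_wavelength_nm": trace.monitor_wavelength_nm,
        "o2_uM": trace.o2_uM,
        "co_uM": trace.co_uM,
        "replicate_id": trace.replicate_id,
        "time_unit": trace.time_unit,
    }
    _meta_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_trace(path) -> KineticTrace:
    path = Path(path)
    df = pd.read_csv(path)
    time_cols = [c for c in df.columns if c.startswith("time_")]
    if len(time_cols) != 1 or "signal" not in df.columns:
        raise ValueError(f"{path}: expected columns time_<unit>,signal")
    unit = time_cols[0].split("_", 1)[1]
    meta = {}
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
        meta.pop("time_unit", None)
    return KineticTrace(
        times=df[time_cols[0]].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        time_unit=unit,
        monitor_wavelength_nm=meta.get("monitor_wavelength_nm"),
        o2_uM=meta.get("o2_uM", 0.0),
        co_uM=meta.get("co_uM", 0.0),
        replicate_id=meta.get("replicate_id", ""),
    )


def write_calibration(path, calibration: CalibrationTable) -> Path:
    path = Path(path)
    pd.DataFrame({"ratio": calibration.ratios, "f_h": calibration.fractions}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    return path


def read_calibration(path) -> CalibrationTable:
    df = pd.read_csv(path)
    if "ratio" not in df.columns or "f_h" not in df.columns:
        raise ValueError(f"{path}: expected columns ratio,f_h")
    return CalibrationTable(ratios=df["ratio"].to_numpy(float), fractions=df["f_h"].to_numpy(float))


def write_autoox_series(manifest_path, series, file_prefix: str = "autoox") -> Path:
    """Write a timestamped spectral series plus its JSON manifest."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    entries = []
    for i, (t_h, spec) in enumerate(series):
        fname = f"{file_prefix}_{i:03d}.csv"
        write_spectrum(directory / fname, spec)
        entries.append({"time_h": float(t_h), "file": fname})
    manifest_path.write_text(json.dumps({"series": entries}, indent=2) + "\n")
    return manifest_path


def read_autoox_series(manifest_path) -> list[tuple[float, Spectrum]]:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    series = []
    for entry in manifest["series"]:
        spec = read_spectrum(manifest_path.parent / entry["file"], state="oxy")
        series.append((float(entry["time_h"]), spec))
    return series
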