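"""Plain-text readers and writers for recordings, covariates and results.

Native recording format: a tab-separated values file holding the time base,
one intensity column per channel and the three accelerometer axes, plus a
JSON sidecar (same path with ``.json`` appended) holding sampling rate,
montage, annotations and participant metadata.  The format is deliberately
human-diffable; a read-only SNIRF (HDF5) loader is provided as a convenience
for data exported from standard acquisition software.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

from .types import (
    Annotation,
    DataError,
    FormatError,
    Montage,
    RawNIRSRecording,
    SchemaError,
)

__all__ = [
    "read_recording",
    "write_recording",
    "read_snirf",
    "read_covariates",
    "write_covariates",
    "write_table",
    "STROOP_CONDITIONS",
]

STROOP_CONDITIONS = ("naming", "reading", "inhibition", "switching")

ACCEL_COLUMNS = ("accel_x", "accel_y", "accel_z")

COVARIATE_REQUIRED = ["participant_id", "timepoint", "pase", "framingham", "sbp", "dbp"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(rec: RawNIRSRecording, path: str | Path) -> Path:
    """Write a recording as TSV + JSON sidecar. Lossless round-trip."""
    path = Path(path)
    cols = {"time_s": rec.time_s}
    for i, cid in enumerate(rec.montage.channel_ids):
        cols[cid] = rec.intensity[i]
    for j, name in enumerate(ACCEL_COLUMNS):
        cols[name] = rec.accel[j]
    df = pd.DataFrame(cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    sidecar = {
        "sampling_rate": rec.sampling_rate,
        "participant_id": rec.participant_id,
        "timepoint": rec.timepoint,
        "block": rec.block,
        "montage": rec.montage.table.to_dict(orient="records"),
        "annotations": [[a.label, a.start_s, a.end_s] for a in rec.annotations],
        "meta": {k: v for k, v in rec.meta.items() if _json_safe(v)},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_recording(path: str | Path) -> RawNIRSRecording:
    """Read a TSV + sidecar recording (or a ``.snirf``/HDF5 container)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"recording file not found: {path}")
    if path.suffix.lower() in (".snirf", ".h5", ".hdf5"):
        return read_snirf(path)

    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    try:
        side = json.loads(sidecar.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"unreadable sidecar {sidecar}: {e}") from e

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "time_s" not in df.columns:
        raise SchemaError("intensity file lacks a time_s column")
    montage = Montage(pd.DataFrame(side["montage"]))
    missing = [c for c in montage.channel_ids if c not in df.columns]
    if missing:
        raise SchemaError(f"montage channels absent from data columns: {missing}")
    for name in ACCEL_COLUMNS:
        if name not in df.columns:
            raise SchemaError(f"missing accelerometer column {name}")

    t = df["time_s"].to_numpy()
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise DataError("time column is not strictly increasing")

    intensity = np.vstack([df[c].to_numpy() for c in montage.channel_ids])
    accel = np.vstack([df[c].to_numpy() for c in ACCEL_COLUMNS])
    annotations = [Annotation(l, float(s), float(e)) for l, s, e in side["annotations"]]
    return RawNIRSRecording(
        sampling_rate=float(side["sampling_rate"]),
        intensity=intensity,
        montage=montage,
        accel=accel,
        annotations=annotations,
        participant_id=str(side.get("participant_id", "P00")),
        timepoint=str(side.get("timepoint", "T0")),
        block=int(side.get("block", 1)),
        meta=dict(side.get("meta", {})),
    )


def read_snirf(path: str | Path) -> RawNIRSRecording:
    """Read an HDF5 container laid out like a SNIRF file (read-only support).

    Expects ``/nirs/data1`` with ``dataTimeSeries`` (samples x channels),
    ``time``, and per-channel ``measurementList<k>`` groups naming source,
    detector and wavelength index into ``/nirs/probe/wavelengths``.
    Accelerometer channels may be stored under ``/nirs/aux1..3``; absent aux
    data yields a zero accelerometer trace.  Annotations come from
    ``/nirs/stim<k>`` groups named BW/WALK/AW.
    """
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise FormatError(f"cannot open HDF5 file {path}: {e}") from e
    with f:
        try:
            nirs = f["nirs"] if "nirs" in f else f["/nirs1"]
            data = nirs["data1"]
            ts = np.asarray(data["dataTimeSeries"], dtype=float)
            time = np.asarray(data["time"], dtype=float).ravel()
            wavelengths = np.asarray(nirs["probe"]["wavelengths"], dtype=float).ravel()
            src_pos = np.asarray(nirs["probe"]["sourcePos3D"], dtype=float)
            det_pos = np.asarray(nirs["probe"]["detectorPos3D"], dtype=float)
        except KeyError as e:
            raise SchemaError(f"not a SNIRF-layout file ({e})") from e

        if len(time) > 1 and not np.all(np.diff(time) > 0):
            raise DataError("SNIRF time vector not strictly increasing")
        fs = 1.0 / float(np.median(np.diff(time)))

        rows = []
        order = []
        for name in sorted(k for k in data.keys() if k.startswith("measurementList")):
            ml = data[name]
            k = int(name[len("measurementList"):])
            si = int(np.asarray(ml["sourceIndex"]).item())
            di = int(np.asarray(ml["detectorIndex"]).item())
            wi = int(np.asarray(ml["wavelengthIndex"]).item())
            wl = int(round(wavelengths[wi - 1]))
            sxyz, dxyz = src_pos[si - 1], det_pos[di - 1]
            mid = (sxyz + dxyz) / 2.0
            rows.append(
                dict(
                    channel_id=f"S{si}D{di}_{wl}",
                    source_id=f"S{si}",
                    detector_id=f"D{di}",
                    wavelength=wl,
                    separation=float(np.linalg.norm(sxyz - dxyz)),
                    label=f"S{si}D{di}",
                    x=float(mid[0]),
                    y=float(mid[1]),
                    z=float(mid[2]),
                )
            )
            order.append(k - 1)
        montage = Montage(pd.DataFrame(rows))
        intensity = ts[:, order].T

        accel = np.zeros((3, intensity.shape[1]))
        for j in range(3):
            aux = f"aux{j + 1}"
            if aux in nirs:
                a = np.asarray(nirs[aux]["dataTimeSeries"], dtype=float).ravel()
                accel[j, : len(a)] = a[: intensity.shape[1]]

        annotations = []
        for name in sorted(k for k in nirs.keys() if k.startswith("stim")):
            g = nirs[name]
            label = g.attrs.get("name", None)
            if isinstance(label, bytes):
                label = label.decode()
            if label is None and "name" in g:
                raw = np.asarray(g["name"])
                label = raw.item().decode() if raw.dtype.kind == "S" else str(raw.item())
            sd = np.atleast_2d(np.asarray(g["data"], dtype=float))
            for row in sd:
                annotations.append(Annotation(str(label), row[0], row[0] + row[1]))
        annotations.sort(key=lambda a: a.start_s)

    return RawNIRSRecording(
        sampling_rate=fs,
        intensity=intensity,
        montage=montage,
        accel=accel,
        annotations=annotations,
    )


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the participant covariate table (CSV).

    One row per (participant, timepoint) with PASE, Framingham, blood
    pressure and Stroop response times/error counts for the four conditions.
    ``pulse_pressure`` is computed as sbp - dbp when absent and validated
    against it when present.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"covariate file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in COVARIATE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"covariate table missing columns: {missing}")
    if df.duplicated(subset=["participant_id", "timepoint"]).any():
        raise DataError("duplicate (participant, timepoint) rows in covariates")
    if "pulse_pressure" in df.columns:
        expect = df["sbp"] - df["dbp"]
        if not np.allclose(df["pulse_pressure"], expect, atol=1e-6):
            raise DataError("pulse_pressure inconsistent with sbp - dbp")
    else:
        df["pulse_pressure"] = df["sbp"] - df["dbp"]
    for cond in STROOP_CONDITIONS:
        col = f"stroop_rt_{cond}"
        if col in df.columns and (df[col] <= 0).any():
            raise DataError(f"non-positive response time in {col}")
    return df


def write_covariates(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_table(rows: pd.DataFrame | Iterable[dict], path: str | Path) -> Path:
    """Write a result table as UTF-8 CSV with a header row and dot decimals."""
    path = Path(path)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False, encoding="utf-8")
    return path
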