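"""Serialization and standard-format import/export.

Models round-trip through an ``.npz`` container (JSON header + binary
arrays).  Simulated sessions export to SNIRF (fNIRS; written directly as the
HDF5 schema), EDF (EEG; 16-bit, 1-second records) and a JSON ground-truth
manifest; a single internal HDF5 container keeps both modalities plus the
ground truth for lossless round-trips.  Run configuration is TOML with
strict schema validation (unknown keys are rejected before any compute).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path

import h5py
import numpy as np

from .core import ChannelTimeSeries, DecompositionModel, FilterSet, PatternSet
from .simulate import SimulatedSession

SCHEMA_VERSION = 1


# ---------------------------------------------------------------- models

def _jsonable(value):
    if isinstance(value, (bool, int, float, str)) or value is None:
        return value
    if isinstance(value, (np.integer, np.floating)):
        return value.item()
    if isinstance(value, (list, tuple)) and all(
        isinstance(v, (bool, int, float, str)) for v in value
    ):
        return list(value)
    if isinstance(value, dict):
        out = {k: _jsonable(v) for k, v in value.items()}
        if all(v is not None for v in out.values()):
            return out
        return None
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        try:
            return {"__dataclass__": type(value).__name__,
                    **{k: _jsonable(v) for k, v in dataclasses.asdict(value).items()}}
        except Exception:
            return None
    return None


def save_model(model: DecompositionModel, path: str | Path) -> None:
    """Serialize a fitted model to ``.npz`` (JSON header + arrays)."""
    arrays = {
        "wx": model.wx,
        "wy": model.wy,
        "correlations": model.correlations,
        "objective_history": model.objective_history,
    }
    if model.patterns is not None:
        arrays["ax"] = model.patterns.ax
        arrays["ay"] = model.patterns.ay
    extras_meta = {}
    for key, value in model.extras.items():
        if isinstance(value, np.ndarray):
            arrays[f"extra__{key}"] = value
        else:
            j = _jsonable(value)
            if j is not None:
                extras_meta[key] = j
    header = {
        "schema_version": SCHEMA_VERSION,
        "method": model.method,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "constraint_mode": model.constraint_mode,
        "train_tag": model.train_tag,
        "extras": extras_meta,
    }
    arrays["__header__"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path: str | Path) -> DecompositionModel:
    with np.load(path, allow_pickle=False) as npz:
        header = json.loads(bytes(npz["__header__"].tobytes()).decode())
        if header.get("schema_version") != SCHEMA_VERSION:
            raise ValueError("unsupported model schema version")
        patterns = None
        if "ax" in npz:
            patterns = PatternSet(ax=npz["ax"], ay=npz["ay"])
        extras = dict(header["extras"])
        for key in npz.files:
            if key.startswith("extra__"):
                extras[key[len("extra__"):]] = npz[key]
        return DecompositionModel(
            method=header["method"],
            filters=FilterSet(
                wx=npz["wx"], wy=npz["wy"],
                constraint_mode=header["constraint_mode"],
            ),
            patterns=patterns,
            correlations=npz["correlations"],
            converged=header["converged"],
            n_iter=header["n_iter"],
            objective_history=npz["objective_history"],
            constraint_mode=header["constraint_mode"],
            train_tag=header["train_tag"],
            extras=extras,
        )


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------- SNIRF

def write_snirf(session: SimulatedSession, path: str | Path) -> None:
    """Write the fNIRS side as a SNIRF (HDF5) file.

    One data block of HbO concentration time courses with the probe's
    source/detector geometry and the per-channel measurement list.
    """
    y = session.y
    geom = session.geometry
    str_dt = h5py.string_dtype("utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0", dtype=str_dt)
        nirs = f.create_group("/nirs")
        meta = nirs.create_group("metaDataTags")
        for key, value in {
            "SubjectID": "synthetic-01",
            "MeasurementDate": "2000-01-01",
            "MeasurementTime": "00:00:00",
            "LengthUnit": "mm",
            "TimeUnit": "s",
            "FrequencyUnit": "Hz",
        }.items():
            meta.create_dataset(key, data=value, dtype=str_dt)
        data1 = nirs.create_group("data1")
        data1.create_dataset("dataTimeSeries", data=y.data.T)
        data1.create_dataset("time", data=y.times())
        for i, (s, d, _) in enumerate(geom.channel_pairs, start=1):
            ml = data1.create_group(f"measurementList{i}")
            ml.create_dataset("sourceIndex", data=np.int32(s + 1))
            ml.create_dataset("detectorIndex", data=np.int32(d + 1))
            ml.create_dataset("wavelengthIndex", data=np.int32(1))
            ml.create_dataset("dataType", data=np.int32(99999))
            ml.create_dataset("dataTypeLabel", data="HbO", dtype=str_dt)
            ml.create_dataset("dataTypeIndex", data=np.int32(1))
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array([760.0, 850.0]))
        probe.create_dataset("sourcePos3D", data=geom.fnirs_sources)
        probe.create_dataset("detectorPos3D", data=geom.fnirs_detectors)


def read_snirf(path: str | Path) -> ChannelTimeSeries:
    """Minimal SNIRF ingestion: first data block as a ChannelTimeSeries."""
    with h5py.File(path, "r") as f:
        data = np.asarray(f["/nirs/data1/dataTimeSeries"]).T
        t = np.asarray(f["/nirs/data1/time"])
        if t.size > 1:
            rate = 1.0 / float(np.median(np.diff(t)))
        else:
            rate = 1.0
        n_chan = data.shape[0]
        labels = []
        for i in range(1, n_chan + 1):
            ml = f[f"/nirs/data1/measurementList{i}"]
            labels.append(
                f"S{int(ml['sourceIndex'][()])}-D{int(ml['detectorIndex'][()])}"
            )
    return ChannelTimeSeries(data, rate, labels, "fnirs-hbo", float(t[0]))


# ---------------------------------------------------------------- EDF

def write_edf(x: ChannelTimeSeries, path: str | Path) -> None:
    """Write a multichannel series as EDF (16-bit, 1-second data records).

    Requires an integer sampling rate; the trailing partial second is
    dropped (EDF stores fixed-duration records).
    """
    rate = x.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError(f"EDF export requires an integer rate, got {rate}")
    spr = int(round(rate))
    n_rec = x.n_samples // spr
    if n_rec < 1:
        raise ValueError("series shorter than one EDF record (1 s)")
    ns = x.n_channels
    data = x.data[:, : n_rec * spr]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    span = pmax - pmin
    pmin = np.where(span == 0, pmin - 1.0, pmin)
    pmax = np.where(span == 0, pmax + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.round((data - pmin[:, None]) * scale[:, None] + dmin), dmin, dmax
    ).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii", "replace")[:n]
        return b + b" " * (n - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2000 X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + ns)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )
    fields = [
        ("label", 16, [str(c) for c in x.channel_ids]),
        ("transducer", 80, [""] * ns),
        ("dim", 8, ["uV"] * ns),
        ("pmin", 8, [f"{v:.6g}"[:8] for v in pmin]),
        ("pmax", 8, [f"{v:.6g}"[:8] for v in pmax]),
        ("dmin", 8, [str(dmin)] * ns),
        ("dmax", 8, [str(dmax)] * ns),
        ("prefilter", 80, [""] * ns),
        ("spr", 8, [str(spr)] * ns),
        ("reserved", 32, [""] * ns),
    ]
    sig_header = b"".join(
        b"".join(pad(v, width) for v in values) for _, width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        records = digital.reshape(ns, n_rec, spr).transpose(1, 0, 2)
        fh.write(records.tobytes())


# ---------------------------------------------------------------- session container

def write_session_h5(session: SimulatedSession, path: str | Path) -> None:
    """Lossless internal HDF5 container: both modalities plus ground truth."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["manifest"] = json.dumps(session.manifest)
        for name, cts in (("x", session.x), ("y", session.y)):
            g = f.create_group(name)
            g.create_dataset("data", data=cts.data)
            g.attrs["rate"] = cts.rate
            g.attrs["modality"] = cts.modality
            g.attrs["t0"] = cts.t0
            g.create_dataset(
                "channel_ids",
                data=np.array(cts.channel_ids, dtype=h5py.string_dtype("utf-8")),
            )
        gt = f.create_group("truth")
        gt.create_dataset("sx", data=session.truth.sx.data)
        gt.create_dataset("sy", data=session.truth.sy.data)
        gt.attrs["sx_rate"] = session.truth.sx.rate
        gt.attrs["sy_rate"] = session.truth.sy.rate
        gt.attrs["lead_in_s"] = session.truth.lead_in_s
        gt.create_dataset("onsets", data=session.truth.schedule.onsets)
        gt.attrs["stim_s"] = session.truth.schedule.stim_s
        gt.create_dataset("erd_depths", data=session.truth.erd_depths)
        gt.create_dataset("hrf_amplitudes", data=session.truth.hrf_amplitudes)
        if session.patterns is not None:
            f.create_dataset("patterns/ax", data=session.patterns.ax)
            f.create_dataset("patterns/ay", data=session.patterns.ay)


def read_session_h5(path: str | Path) -> SimulatedSession:
    """Rebuild a session from the internal container via its manifest."""
    from .simulate import session_from_manifest

    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
    return session_from_manifest(manifest)


# ---------------------------------------------------------------- config

_SIMULATE_KEYS = {
    "seed", "snr_db", "n_trials", "stim_s", "eeg_rate", "fnirs_rate",
    "lead_in_s", "tail_s",
}
_BENCHMARK_KEYS = {
    "methods", "snr_grid_db", "n_simulations", "seed", "n_trials",
    "train_fraction", "lags_s",
}
_FIT_KEYS = {"method", "seed", "lags_s"}

_SCHEMAS = {
    "simulate": _SIMULATE_KEYS,
    "benchmark": _BENCHMARK_KEYS,
    "fit": _FIT_KEYS,
}


def load_config(path: str | Path, command: str) -> dict:
    """Load and validate a TOML run configuration for one CLI command.

    The file may hold a top-level table per command; unknown keys are
    rejected with the failing key path.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    section = raw.get(command, raw)
    allowed = _SCHEMAS[command]
    for key in section:
        if key in _SCHEMAS and key != command:
            continue  # sibling command tables are fine
        if key not in allowed:
            raise ValueError(f"unknown configuration key: {command}.{key}")
    return {k: v for k, v in section.items() if k in allowed}
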