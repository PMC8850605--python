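"""File formats: recordings (HDF5 / CSV), events (JSON Lines), tables.

The recording container is an HDF5 file with one dataset per channel named
``Q{1-4}_{808|980}`` and root attributes ``sample_rate``, ``start_time``
(ISO-8601) and ``device_id``; small fixtures may use a plain 9-column CSV
(time plus the 8 channels) instead.  Round-trips are lossless for HDF5 and
float-tolerant for CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .errors import RecordingFormatError
from .extract import BaselineModel, InsectEvent
from .recording import CHANNELS, RawRecording

SCHEMA_VERSION = 1

__all__ = [
    "read_recording",
    "write_recording",
    "write_events",
    "read_events",
    "write_extraction_metadata",
    "config_hash",
    "output_stamp",
]


def config_hash(config_dict: dict) -> str:
    """Short stable hash of a configuration mapping."""
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def output_stamp(config_dict: dict | None = None) -> dict:
    """Provenance block attached to every JSON output."""
    stamp = {"package": "entosense", "version": __version__}
    if config_dict is not None:
        stamp["config_hash"] = config_hash(config_dict)
    return stamp


# --------------------------------------------------------------------------
# recordings
# --------------------------------------------------------------------------

def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording to HDF5 (``.h5``/``.hdf5``) or CSV (``.csv``)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_recording_csv(rec, path)
        return
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["sample_rate"] = rec.sample_rate
        fh.attrs["start_time"] = rec.start_time
        fh.attrs["device_id"] = rec.device_id
        for i, name in enumerate(CHANNELS):
            fh.create_dataset(name, data=rec.data[i])


def read_recording(path: str | Path) -> RawRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise RecordingFormatError(f"no such recording file: {path}")
    if path.suffix.lower() == ".csv":
        return _read_recording_csv(path)
    try:
        handle = h5py.File(path, "r")
    except OSError as exc:
        raise RecordingFormatError(f"not a readable HDF5 file: {path}") from exc
    with handle as fh:
        version = int(fh.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise RecordingFormatError(
                f"unknown recording schema version {version}"
            )
        missing = [c for c in CHANNELS if c not in fh]
        if missing:
            raise RecordingFormatError(
                f"recording lacks channel(s): {', '.join(missing)}"
            )
        arrays = [np.asarray(fh[c]) for c in CHANNELS]
        lengths = {a.shape for a in arrays}
        if len(lengths) != 1:
            raise RecordingFormatError("channel lengths differ")
        return RawRecording(
            data=np.stack(arrays),
            sample_rate=float(fh.attrs["sample_rate"]),
            start_time=str(fh.attrs["start_time"]),
            device_id=str(fh.attrs["device_id"]),
        )


def _write_recording_csv(rec: RawRecording, path: Path) -> None:
    df = pd.DataFrame({"time_s": rec.times()})
    for i, name in enumerate(CHANNELS):
        df[name] = rec.data[i]
    with open(path, "w") as fh:
        fh.write(f"# sample_rate={rec.sample_rate} start_time={rec.start_time}"
                 f" device_id={rec.device_id} schema_version={SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def _read_recording_csv(path: Path) -> RawRecording:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise RecordingFormatError("CSV recording lacks metadata header")
        meta = dict(item.split("=", 1) for item in header[1:].split())
        df = pd.read_csv(fh)
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise RecordingFormatError(
            f"recording lacks channel(s): {', '.join(missing)}"
        )
    return RawRecording(
        data=df[list(CHANNELS)].to_numpy().T,
        sample_rate=float(meta.get("sample_rate", 20000.0)),
        start_time=meta.get("start_time", "1970-01-01T00:00:00"),
        device_id=meta.get("device_id", "unknown"),
    )


# --------------------------------------------------------------------------
# events
# --------------------------------------------------------------------------

def write_events(
    events: list[InsectEvent],
    path: str | Path,
    config_dict: dict | None = None,
) -> None:
    """Write events as JSON Lines; first line is a provenance header,
    then one record per event with the snippet inline."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"header": output_stamp(config_dict)},
                            sort_keys=True) + "\n")
        for ev in events:
            rec = {
                "start": ev.start,
                "end": ev.end,
                "start_time_s": ev.start_time_s,
                "end_time_s": ev.end_time_s,
                "sample_rate": ev.sample_rate,
                "device_id": ev.device_id,
                "peak_snr": ev.peak_snr,
                "snippet": [np.round(row, 9).tolist() for row in ev.snippet],
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_events(path: str | Path) -> list[InsectEvent]:
    events = []
    with open(path) as fh:
        first = fh.readline()
        if first and "header" not in first:
            fh.seek(0)
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            events.append(InsectEvent(
                start=rec["start"], end=rec["end"],
                snippet=np.asarray(rec["snippet"], dtype=float),
                peak_snr=rec["peak_snr"],
                sample_rate=rec["sample_rate"],
                device_id=rec.get("device_id", ""),
                start_time_s=rec.get("start_time_s", 0.0),
                end_time_s=rec.get("end_time_s", 0.0),
            ))
    return events


def write_extraction_metadata(
    model: BaselineModel,
    path: str | Path,
    config_dict: dict | None = None,
) -> None:
    """Per-channel baseline and noise tracks as JSON."""
    payload = {
        "header": output_stamp(config_dict),
        "noise_level": model.noise_level(),
        "tracks": {
            name: {
                "centers_s": tr.centers_s.tolist(),
                "median": tr.median.tolist(),
                "sd": tr.sd.tolist(),
                "window_s": tr.window_s,
                "overlap": tr.overlap,
                "rate": tr.rate,
            }
            for name, tr in model.tracks.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)
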