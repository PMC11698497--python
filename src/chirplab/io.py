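"""Recording, event-table and protocol I/O.

Waveforms travel as float32 multichannel WAV (the format the study's
raw voltage data are distributed in) or as raw float32 binary with a
JSON sidecar carrying the sampling rate and channel map. Event tables
are CSV with unit-suffixed column names ('.' decimal, comma separator,
UTF-8) and '#'-prefixed provenance header lines (version, seed,
parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from . import __version__

EVENT_COLUMNS = ["t_s", "fm_hz", "duration_ms", "type", "sender", "receiver",
                 "df_hz", "confidence", "flags"]


class SchemaError(ValueError):
    """Malformed metadata, table, or channel layout."""


@dataclass
class RecordingBundle:
    """A multichannel voltage recording plus the metadata detection needs."""

    waveform: np.ndarray          # (n_channels, n_samples) float32
    fs: float
    channel_map: dict             # channel index -> compartment/fish id
    temperature_c: float | None = None
    conductivity_us_cm: float | None = None
    fish: dict = field(default_factory=dict)   # fish id -> metadata
    path: str | None = None

    def __post_init__(self):
        self.waveform = np.atleast_2d(np.asarray(self.waveform))
        if len(self.channel_map) != self.waveform.shape[0]:
            raise SchemaError(
                f"channel map has {len(self.channel_map)} entries for "
                f"{self.waveform.shape[0]} channels")

    @property
    def duration_s(self) -> float:
        return self.waveform.shape[1] / self.fs


def write_wav(path, waveform: np.ndarray, fs: float) -> None:
    """Float32 (multi)channel WAV; channels become WAV columns."""
    w = np.atleast_2d(np.asarray(waveform, dtype=np.float32))
    wavfile.write(path, int(fs), w.T.copy())


def read_wav(path):
    fs, data = wavfile.read(path)
    if data.ndim == 1:
        data = data[:, None]
    return data.T.astype(np.float32), float(fs)


def write_raw(path, waveform: np.ndarray, fs: float, channel_map: dict,
              **metadata) -> None:
    """Raw float32 binary (channel-interleaved) with a JSON sidecar."""
    w = np.atleast_2d(np.asarray(waveform, dtype=np.float32))
    w.T.tofile(path)
    side = {"fs": fs, "n_channels": w.shape[0], "dtype": "float32",
            "channel_map": {str(k): v for k, v in channel_map.items()},
            "version": __version__, **metadata}
    Path(str(path) + ".json").write_text(json.dumps(side, indent=1))


def read_recording(path, metadata: dict | None = None) -> RecordingBundle:
    """Load a WAV or raw-binary recording into a RecordingBundle.

    For WAV, ``metadata`` must supply at least fs-consistent
    ``channel_map``; raw binaries read their JSON sidecar.
    """
    path = Path(path)
    if path.suffix.lower() == ".wav":
        wave, fs = read_wav(path)
        meta = dict(metadata or {})
        cmap = meta.pop("channel_map", {i: str(i) for i in range(wave.shape[0])})
        if "fs" in meta and float(meta["fs"]) != fs:
            raise SchemaError(f"metadata fs {meta['fs']} != file fs {fs}")
        meta.pop("fs", None)
        return RecordingBundle(wave, fs, cmap, path=str(path), **meta)
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise SchemaError(f"raw recording {path} has no JSON sidecar")
    side = json.loads(sidecar.read_text())
    n_ch = int(side["n_channels"])
    data = np.fromfile(path, dtype=np.float32)
    if len(data) % n_ch:
        raise SchemaError("raw file length is not a multiple of n_channels")
    wave = data.reshape(-1, n_ch).T
    cmap = {int(k): v for k, v in side["channel_map"].items()}
    return RecordingBundle(
        wave, float(side["fs"]), cmap,
        temperature_c=side.get("temperature_c"),
        conductivity_us_cm=side.get("conductivity_us_cm"),
        fish=side.get("fish", {}), path=str(path))


def _provenance_header(seed=None, **params) -> str:
    items = {"version": __version__}
    if seed is not None:
        items["seed"] = seed
    items.update(params)
    return "".join(f"# {k} = {v}\n" for k, v in items.items())


def write_events(events, path, seed=None, **params) -> None:
    """Chirp-event table to CSV with a provenance header.

    ``events`` is a DataFrame or a list of detect.ChirpEvent.
    """
    if not isinstance(events, pd.DataFrame):
        rows = [{
            "t_s": e.t, "fm_hz": e.fm, "duration_ms": e.duration_ms,
            "type": e.type_label, "sender": e.sender, "receiver": e.receiver,
            "df_hz": e.df, "confidence": 1.0,
            "flags": ";".join(e.flags),
        } for e in events]
        events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed=seed, **params))
        events.to_csv(fh, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("t_s",) if c not in df.columns]
    if missing:
        raise SchemaError(f"event table {path} lacks columns {missing}")
    return df


def write_protocol(protocol, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed=protocol.seed,
                                    fish_eodf=protocol.fish_eodf))
        protocol.to_frame().to_csv(fh, index=False)


def read_annotations(path) -> pd.DataFrame:
    """Behavior annotations: CSV with start_s, end_s, label columns."""
    df = pd.read_csv(path, comment="#")
    need = {"start_s", "end_s", "label"}
    if not need <= set(df.columns):
        raise SchemaError(f"annotation table {path} needs columns {need}")
    return df
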