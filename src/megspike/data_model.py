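"""Core domain types and file I/O.

The pipeline operates on four kinds of objects:

* :class:`SensorRecording` -- a multichannel MEG time series with per-channel
  sensor-type labels (gradiometer / magnetometer / other).
* :class:`ForwardModel` -- a leadfield matrix mapping cortical sources to
  sensors, together with source-space vertex coordinates in millimetres.
* :class:`EventTable` -- timestamps of detected (or visually marked) spikes.
* :class:`CorticalMap` -- a per-vertex scalar or binary map on the source
  space; the irritative zone and the resection mask are binary maps.

Recordings are read either from FIF files (via MNE-Python) or from plain
matrix files with a JSON channel manifest.  Event tables round-trip through
TSV, cortical maps and forward models through NPZ.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SENSOR_TYPES = ("gradiometer", "magnetometer", "other")

#: target sampling rate of the pipeline, Hz
PIPELINE_SFREQ = 200.0


@dataclass
class SensorRecording:
    """Multichannel sensor time series.

    data is [n_channels x n_samples] in sensor units; timestamps are seconds
    from recording start and sample indices are 0-based.
    """

    data: np.ndarray
    sfreq: float
    channel_names: list[str]
    sensor_types: list[str]
    bads: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D [n_channels x n_samples]")
        n = self.data.shape[0]
        if len(self.channel_names) != n or len(self.sensor_types) != n:
            raise ValueError("channel metadata length mismatch")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        bad = set(self.sensor_types) - set(SENSOR_TYPES)
        if bad:
            raise ValueError(f"unknown sensor types: {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def drop_bads(self) -> "SensorRecording":
        keep = [i for i, c in enumerate(self.channel_names) if c not in self.bads]
        return SensorRecording(
            self.data[keep],
            self.sfreq,
            [self.channel_names[i] for i in keep],
            [self.sensor_types[i] for i in keep],
            [],
        )

    def pick_type(self, sensor_type: str) -> "SensorRecording":
        """Restrict to one sensor type (the pipeline never mixes types)."""
        if sensor_type not in SENSOR_TYPES:
            raise ValueError(f"unknown sensor type {sensor_type!r}")
        keep = [i for i, t in enumerate(self.sensor_types) if t == sensor_type]
        if not keep:
            raise ValueError(f"no channels of type {sensor_type!r}")
        return SensorRecording(
            self.data[keep],
            self.sfreq,
            [self.channel_names[i] for i in keep],
            [self.sensor_types[i] for i in keep],
            [b for b in self.bads if b in {self.channel_names[i] for i in keep}],
        )

    def pick_channels(self, names: list[str]) -> "SensorRecording":
        index = {c: i for i, c in enumerate(self.channel_names)}
        keep = [index[c] for c in names]
        return SensorRecording(
            self.data[keep], self.sfreq, list(names),
            [self.sensor_types[i] for i in keep],
            [b for b in self.bads if b in names],
        )


@dataclass
class ForwardModel:
    """Leadfield matrix plus source-space geometry.

    leadfield is [n_channels x (n_vertices * n_orientations)]; vertex
    coordinates are millimetres in head coordinates.  With free orientations
    (n_orientations == 3) the columns of one vertex are contiguous.
    """

    leadfield: np.ndarray
    vertex_coords: np.ndarray
    channel_names: list[str]
    n_orientations: int = 1

    def __post_init__(self) -> None:
        self.leadfield = np.asarray(self.leadfield, dtype=float)
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        if self.n_orientations not in (1, 3):
            raise ValueError("n_orientations must be 1 or 3")
        if self.leadfield.shape[1] != self.n_vertices * self.n_orientations:
            raise ValueError("leadfield column count != n_vertices * n_orientations")
        if self.leadfield.shape[0] != len(self.channel_names):
            raise ValueError("leadfield row count != n_channels")
        if not np.all(np.isfinite(self.vertex_coords)):
            raise ValueError("vertex coordinates must be finite")

    @property
    def n_channels(self) -> int:
        return self.leadfield.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    def vertex_columns(self, j: int) -> np.ndarray:
        """Leadfield block of vertex j: [n_channels x n_orientations]."""
        k = self.n_orientations
        return self.leadfield[:, j * k:(j + 1) * k]

    def pick_channels(self, names: list[str]) -> "ForwardModel":
        index = {c: i for i, c in enumerate(self.channel_names)}
        keep = [index[c] for c in names]
        return ForwardModel(self.leadfield[keep], self.vertex_coords,
                            list(names), self.n_orientations)

    def save(self, path: str | Path) -> None:
        np.savez(path, leadfield=self.leadfield, vertex_coords=self.vertex_coords,
                 channel_names=np.array(self.channel_names),
                 n_orientations=self.n_orientations)

    @classmethod
    def load(cls, path: str | Path) -> "ForwardModel":
        with np.load(path, allow_pickle=False) as f:
            return cls(f["leadfield"], f["vertex_coords"],
                       [str(c) for c in f["channel_names"]],
                       int(f["n_orientations"]))


EVENT_COLUMNS = ("time_s", "sample", "stage", "gof", "sensor_type")


class EventTable:
    """Table of spike timestamps.

    Rows carry (time_s, sample, stage, gof, sensor_type) where ``stage`` is
    ``stage1``, ``cluster:<k>`` or ``visual``.  Sample indices satisfy
    ``sample == round(time_s * sfreq)`` for the sampling rate given at
    construction, and timestamps are strictly increasing within one stage.
    """

    def __init__(self, df: pd.DataFrame, sfreq: float = PIPELINE_SFREQ):
        missing = set(EVENT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing event columns: {sorted(missing)}")
        df = df.loc[:, list(EVENT_COLUMNS)].reset_index(drop=True)
        df["sample"] = df["sample"].astype(int)
        expected = np.round(df["time_s"].to_numpy() * sfreq).astype(int)
        if not np.array_equal(expected, df["sample"].to_numpy()):
            raise ValueError("sample indices inconsistent with timestamps")
        for stage, grp in df.groupby("stage"):
            t = grp["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"timestamps not strictly increasing in {stage!r}")
        self.df = df
        self.sfreq = float(sfreq)

    @classmethod
    def from_times(cls, times_s: np.ndarray, sfreq: float, stage: str,
                   gof: np.ndarray | float = np.nan,
                   sensor_type: str = "other") -> "EventTable":
        times_s = np.asarray(times_s, dtype=float)
        order = np.argsort(times_s, kind="stable")
        times_s = times_s[order]
        gof = np.broadcast_to(np.asarray(gof, dtype=float), times_s.shape)[order]
        df = pd.DataFrame({
            "time_s": times_s,
            "sample": np.round(times_s * sfreq).astype(int),
            "stage": stage,
            "gof": gof,
            "sensor_type": sensor_type,
        })
        return cls(df, sfreq)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["time_s"].to_numpy()

    @property
    def samples(self) -> np.ndarray:
        return self.df["sample"].to_numpy()

    def select_stage(self, stage: str) -> "EventTable":
        return EventTable(self.df[self.df["stage"] == stage], self.sfreq)

    def save(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path, sfreq: float = PIPELINE_SFREQ) -> "EventTable":
        return cls(pd.read_csv(path, sep="\t"), sfreq)


@dataclass
class CorticalMap:
    """Per-vertex scalar or binary map on the source space."""

    values: np.ndarray
    vertex_coords: np.ndarray
    kind: str = "activation"  # "activation" | "binary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=float)
        if self.values.shape[0] != self.vertex_coords.shape[0]:
            raise ValueError("values length != number of vertices")
        if self.kind == "binary":
            if not np.all(np.isin(self.values, (0.0, 1.0))):
                raise ValueError("binary map must contain only 0/1")
        elif self.kind == "activation":
            if np.any(self.values < 0):
                raise ValueError("activation map must be non-negative")
        else:
            raise ValueError(f"unknown map kind {self.kind!r}")

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.values))

    def active_coords(self) -> np.ndarray:
        return self.vertex_coords[self.values > 0]

    def save(self, path: str | Path) -> None:
        np.savez(path, values=self.values, vertex_coords=self.vertex_coords,
                 kind=self.kind)

    @classmethod
    def load(cls, path: str | Path) -> "CorticalMap":
        with np.load(path, allow_pickle=False) as f:
            return cls(f["values"], f["vertex_coords"], str(f["kind"]))


# ---------------------------------------------------------------------------
# Recording I/O and standard preprocessing
# ---------------------------------------------------------------------------

def _sensor_type_from_mne(ch_type: str) -> str:
    if ch_type == "grad":
        return "gradiometer"
    if ch_type == "mag":
        return "magnetometer"
    return "other"


def load_recording(path: str | Path, sensor_type_filter: str | None = None,
                   manifest: str | Path | None = None) -> SensorRecording:
    """Read a recording from FIF or from a matrix file with a channel manifest.

    FIF files are read with MNE-Python and restricted to MEG channels.  A
    ``.npz`` file may embed its own metadata (keys ``data``, ``sfreq``,
    ``channel_names``, ``sensor_types``, optionally ``bads``); a bare ``.npy``
    matrix requires a JSON ``manifest`` with the same fields.  Bad channels
    are dropped, then the requested sensor type is selected.
    """
    path = Path(path)
    if path.suffix == ".fif":
        import mne
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
        raw.pick("meg", verbose="error")
        types = [_sensor_type_from_mne(t) for t in raw.get_channel_types()]
        rec = SensorRecording(raw.get_data(), raw.info["sfreq"],
                              list(raw.ch_names), types, list(raw.info["bads"]))
    elif path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            bads = [str(b) for b in f["bads"]] if "bads" in f else []
            rec = SensorRecording(f["data"], float(f["sfreq"]),
                                  [str(c) for c in f["channel_names"]],
                                  [str(t) for t in f["sensor_types"]], bads)
    elif path.suffix == ".npy":
        if manifest is None:
            raise ValueError("matrix input requires a JSON channel manifest")
        meta = json.loads(Path(manifest).read_text())
        rec = SensorRecording(np.load(path), float(meta["sfreq"]),
                              list(meta["channel_names"]),
                              list(meta["sensor_types"]),
                              list(meta.get("bads", [])))
    else:
        raise ValueError(f"unknown recording format {path.suffix!r}")
    rec = rec.drop_bads()
    if sensor_type_filter is not None:
        rec = rec.pick_type(sensor_type_filter)
    if rec.n_channels == 0:
        raise ValueError("zero channels after filtering")
    return rec


def save_recording(rec: SensorRecording, path: str | Path) -> None:
    np.savez(path, data=rec.data, sfreq=rec.sfreq,
             channel_names=np.array(rec.channel_names),
             sensor_types=np.array(rec.sensor_types),
             bads=np.array(rec.bads, dtype=str))


def bandpass(rec: SensorRecording, lo_hz: float, hi_hz: float) -> SensorRecording:
    """Zero-phase FIR band-pass (Hamming window) preserving shape."""
    nyq = rec.sfreq / 2.0
    if not (0 < lo_hz < hi_hz < nyq):
        raise ValueError(f"band [{lo_hz}, {hi_hz}] Hz outside (0, {nyq}) Hz")
    filtered = bandpass_array(rec.data, rec.sfreq, lo_hz, hi_hz)
    return replace(rec, data=filtered)


def bandpass_array(data: np.ndarray, sfreq: float, lo_hz: float,
                   hi_hz: float) -> np.ndarray:
    """Band-pass rows of ``data`` with MNE's zero-phase windowed FIR design."""
    from mne.filter import filter_data
    return filter_data(np.atleast_2d(np.asarray(data, dtype=float)), sfreq,
                       lo_hz, hi_hz, fir_design="firwin", phase="zero",
                       fir_window="hamming", verbose="error")


def resample(rec: SensorRecording, new_sfreq: float) -> SensorRecording:
    """Downsample (polyphase, anti-aliased); duration kept within one sample."""
    if new_sfreq > rec.sfreq:
        raise ValueError("upsampling not supported")
    if new_sfreq == rec.sfreq:
        return rec
    from mne.filter import resample as mne_resample
    data = mne_resample(rec.data, down=rec.sfreq / new_sfreq, npad="auto",
                        verbose="error")
    return replace(rec, data=data, sfreq=float(new_sfreq))


def preprocess(rec: SensorRecording, lo_hz: float = 2.0, hi_hz: float = 90.0,
               sfreq: float = PIPELINE_SFREQ) -> SensorRecording:
    """Standard front end: resample to 200 Hz, band-pass 2-90 Hz."""
    if rec.sfreq > sfreq:
        rec = resample(rec, sfreq)
    return bandpass(rec, lo_hz, hi_hz)
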