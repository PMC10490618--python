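"""Reading, aligning and labelling raw multi-sensor recordings.

A recording bundles tri-axial accelerometer, gyroscope and magnetometer
streams (required by the activity bank) plus optional mono audio and GPS
(used by the localization bank).  Channels arrive as timestamped CSV, one
file per channel; :func:`align_and_resample` puts all inertial channels on
one uniform grid so the windowing stage can treat them as a matrix.

Conventions
-----------
* timestamps are seconds from recording start, strictly increasing;
* device frame is x-right, y-forward, z-up, right-handed;
* intervals are half-open ``[t0, t1)``; indexing is 0-based;
* audio may keep its own (higher) rate but must cover the same time span.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RawChannel",
    "MultiSensorRecording",
    "SchemaError",
    "FormatError",
    "AlignmentError",
    "read_generic_csv",
    "write_generic_csv",
    "read_recording_dir",
    "write_recording_dir",
    "align_and_resample",
    "read_extrasensory",
    "read_shl",
    "DEFAULT_SHL_LABEL_MAP",
]

logger = logging.getLogger(__name__)

IMU_CHANNELS = ("acc", "gyr", "mag")


class SchemaError(ValueError):
    """A column mapping refers to a column the CSV does not have."""


class FormatError(ValueError):
    """The file violates a structural invariant (e.g. non-monotone time)."""


class AlignmentError(ValueError):
    """Channels share no overlapping time span."""


@dataclass
class RawChannel:
    """One sensor stream: ``axes`` is (n_axes, n_samples) in native units."""

    name: str
    axes: np.ndarray
    timestamps: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.axes = np.atleast_2d(np.asarray(self.axes, dtype=float))
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.axes.shape[1] != self.timestamps.shape[0]:
            raise FormatError(
                f"channel {self.name!r}: {self.axes.shape[1]} samples but "
                f"{self.timestamps.shape[0]} timestamps"
            )
        dt = np.diff(self.timestamps)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            # bad[0] indexes the diff; the offending sample is the next row
            # (1-based over the data rows)
            raise FormatError(
                f"channel {self.name!r}: timestamps not strictly increasing "
                f"at row {int(bad[0]) + 2}"
            )

    @property
    def n_samples(self) -> int:
        return self.axes.shape[1]

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class MultiSensorRecording:
    """Aligned channel bundle with optional activity/location labels."""

    channels: dict[str, RawChannel]
    fs: float | None = None
    activity_label: str | None = None
    location_label: str | None = None
    subject_id: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return max(c.duration_s for c in self.channels.values())

    def has(self, *names: str) -> bool:
        return all(n in self.channels for n in names)

    def imu_matrix(self) -> np.ndarray:
        """Stacked (9, n) array of acc/gyr/mag axes; requires alignment."""
        return np.vstack([self.channels[c].axes for c in IMU_CHANNELS])


# ---------------------------------------------------------------------------
# generic CSV
# ---------------------------------------------------------------------------

def read_generic_csv(path, schema: dict) -> MultiSensorRecording:
    """Read one CSV holding a timestamp column plus mapped sensor columns.

    ``schema`` maps channel names to their value columns, e.g.::

        {"timestamp": "t", "channels": {"acc": ["ax", "ay", "az"]}}

    Timestamps are shifted to seconds relative to the recording start.
    """
    df = pd.read_csv(path)
    tcol = schema.get("timestamp", "t")
    missing = [c for c in [tcol] + [c for cols in schema["channels"].values() for c in cols]
               if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mapped column(s) {missing}")
    t = df[tcol].to_numpy(dtype=float)
    t = t - t[0]
    channels = {}
    for name, cols in schema["channels"].items():
        axes = df[cols].to_numpy(dtype=float).T
        rate = (len(t) - 1) / (t[-1] - t[0]) if len(t) > 1 else 0.0
        channels[name] = RawChannel(name, axes, t.copy(), rate)
    return MultiSensorRecording(channels=channels)


def write_generic_csv(rec: MultiSensorRecording, path, schema: dict) -> None:
    """Inverse of :func:`read_generic_csv` for channels sharing one grid."""
    tcol = schema.get("timestamp", "t")
    names = list(schema["channels"])
    t = rec.channels[names[0]].timestamps
    data = {tcol: t}
    for name in names:
        ch = rec.channels[name]
        if not np.array_equal(ch.timestamps, t):
            raise FormatError("write_generic_csv requires channels on one grid")
        for col, ax in zip(schema["channels"][name], ch.axes):
            data[col] = ax
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# recording directories (the layout the synthetic generator writes)
# ---------------------------------------------------------------------------

_AXIS_COLS = {"acc": ["x", "y", "z"], "gyr": ["x", "y", "z"], "mag": ["x", "y", "z"],
              "audio": ["amplitude"], "gps": ["lat", "lon"]}


def write_recording_dir(rec: MultiSensorRecording, path) -> None:
    """Write one directory per recording: ``<ch>.csv`` files + labels.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, ch in rec.channels.items():
        cols = _AXIS_COLS.get(name, [f"a{i}" for i in range(ch.axes.shape[0])])
        df = pd.DataFrame({"t": ch.timestamps})
        for col, ax in zip(cols, ch.axes):
            df[col] = ax
        df.to_csv(path / f"{name}.csv", index=False, float_format="%.10g")
    meta = {"activity": rec.activity_label, "location": rec.location_label,
            "subject_id": rec.subject_id, "fs": rec.fs}
    (path / "labels.json").write_text(json.dumps(meta, indent=1))


def read_recording_dir(path) -> MultiSensorRecording:
    path = Path(path)
    channels = {}
    for f in sorted(path.glob("*.csv")):
        name = f.stem
        df = pd.read_csv(f)
        t = df["t"].to_numpy(dtype=float)
        axes = df.drop(columns=["t"]).to_numpy(dtype=float).T
        rate = (len(t) - 1) / (t[-1] - t[0]) if len(t) > 1 else 0.0
        channels[name] = RawChannel(name, axes, t, rate)
    meta = {}
    meta_path = path / "labels.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    return MultiSensorRecording(
        channels=channels,
        fs=meta.get("fs"),
        activity_label=meta.get("activity"),
        location_label=meta.get("location"),
        subject_id=meta.get("subject_id") or "",
    )


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_and_resample(rec: MultiSensorRecording, fs: float = 40.0) -> MultiSensorRecording:
    """Linearly interpolate all IMU channels onto one uniform grid at ``fs``.

    The grid covers the intersection of the channels' time spans.  Audio and
    GPS keep their native rates (they are consumed by stages that do their
    own framing).  Applying the operation twice equals applying it once.
    """
    imu = [n for n in IMU_CHANNELS if n in rec.channels]
    if not imu:
        return replace(rec, fs=fs)
    t0 = max(rec.channels[n].timestamps[0] for n in imu)
    t1 = min(rec.channels[n].timestamps[-1] for n in imu)
    if t1 - t0 < 1.0 / fs:
        raise AlignmentError(
            f"channels overlap for only {t1 - t0:.4f}s (< one sample at {fs} Hz)"
        )
    n = int(np.floor((t1 - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs
    channels = dict(rec.channels)
    for name in imu:
        ch = rec.channels[name]
        axes = np.vstack([np.interp(grid, ch.timestamps, ax) for ax in ch.axes])
        channels[name] = RawChannel(name, axes, grid - t0, fs)
    for name in set(channels) - set(imu):
        ch = channels[name]
        keep = (ch.timestamps >= t0) & (ch.timestamps <= t1)
        channels[name] = RawChannel(name, ch.axes[:, keep], ch.timestamps[keep] - t0,
                                    ch.rate_hz)
    return replace(rec, channels=channels, fs=fs)


# ---------------------------------------------------------------------------
# dataset-style adapters
# ---------------------------------------------------------------------------

DEFAULT_SHL_LABEL_MAP = {
    "Still": "standing",
    "Walk": "walking",
    "Walking": "walking",
    "Run": "running",
    "Running": "running",
    "Sit": "sitting",
    "Sitting": "sitting",
}


def read_extrasensory(directory, schema: dict | None = None) -> list[MultiSensorRecording]:
    """Read an ExtraSensory-style tree: ``<dir>/<uuid>/<interval>/``.

    Each interval directory holds per-channel CSVs (``acc.csv`` etc., columns
    ``t,x,y,z``) and a ``labels.json`` with ``activity``/``location`` strings.
    Intervals missing a required IMU channel are flagged rather than dropped,
    so downstream feature stages can raise their own precondition errors.
    """
    directory = Path(directory)
    out: list[MultiSensorRecording] = []
    for uuid_dir in sorted(p for p in directory.iterdir() if p.is_dir()):
        for interval in sorted(p for p in uuid_dir.iterdir() if p.is_dir()):
            rec = read_recording_dir(interval)
            rec.subject_id = uuid_dir.name
            missing = [c for c in IMU_CHANNELS if c not in rec.channels]
            if missing:
                rec.flags.append(f"missing:{','.join(missing)}")
                logger.warning("interval %s lacks channel(s) %s", interval, missing)
            out.append(rec)
    return out


def read_shl(directory, fs_hint: float = 100.0,
             label_map: dict[str, str] | None = None) -> list[MultiSensorRecording]:
    """Read an SHL-style tree: ``<dir>/<day>/Motion.txt`` + ``Label.txt``.

    ``Motion.txt`` is whitespace-separated ``time_ms acc_xyz gyr_xyz mag_xyz``;
    ``Label.txt`` pairs ``time_ms label``.  One recording is emitted per
    contiguous run of a single label; labels are translated through
    ``label_map`` (default :data:`DEFAULT_SHL_LABEL_MAP`); unknown labels are
    skipped with a logged warning.
    """
    label_map = DEFAULT_SHL_LABEL_MAP if label_map is None else label_map
    directory = Path(directory)
    out: list[MultiSensorRecording] = []
    for day in sorted(p for p in directory.iterdir() if p.is_dir()):
        motion = np.loadtxt(day / "Motion.txt", ndmin=2)
        labels = pd.read_csv(day / "Label.txt", sep=r"\s+", header=None,
                             names=["time_ms", "label"])
        t = motion[:, 0] / 1000.0
        runs = _label_runs(labels)
        for raw_label, t_start, t_end in runs:
            if raw_label not in label_map:
                logger.warning("unknown SHL label %r in %s: skipped", raw_label, day)
                continue
            sel = (t >= t_start) & (t < t_end)
            if sel.sum() < 2:
                continue
            ts = t[sel] - t[sel][0]
            channels = {
                "acc": RawChannel("acc", motion[sel, 1:4].T, ts, fs_hint),
                "gyr": RawChannel("gyr", motion[sel, 4:7].T, ts, fs_hint),
                "mag": RawChannel("mag", motion[sel, 7:10].T, ts, fs_hint),
            }
            out.append(MultiSensorRecording(
                channels=channels, activity_label=label_map[raw_label],
                subject_id=day.name))
    return out


def _label_runs(labels: pd.DataFrame) -> list[tuple[str, float, float]]:
    """Collapse a per-timestamp label track into (label, t0, t1) runs."""
    runs = []
    cur = None
    t0 = None
    times = labels["time_ms"].to_numpy(dtype=float) / 1000.0
    labs = labels["label"].astype(str).to_numpy()
    for ts, lab in zip(times, labs):
        if lab != cur:
            if cur is not None:
                runs.append((cur, t0, ts))
            cur, t0 = lab, ts
    if cur is not None:
        runs.append((cur, t0, np.inf))
    return runs
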