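"""CSV signal dialect and run-level containers.

A collection run is stored as one directory of per-sensor CSV files, each with
a two-column header ``elapsed_time_s,value`` (dot decimal separator, seconds
with microsecond precision), mimicking acquisition-software exports.  Eight
sensors carry EMG (2 kHz) from the forearm/biceps muscles; two hand-mounted
sensors carry 3-axis accelerometer data (148.1 Hz) used only for labelling.
An optional ``truth.csv`` holds the ground-truth activity track written by the
simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .protocol import CLASS_CODES, CLASS_INDEX

__all__ = [
    "EMG_SENSORS",
    "ACC_SENSORS",
    "ACC_AXES",
    "ChannelSeries",
    "RunBundle",
    "read_run",
    "write_run",
    "write_labeled_instances",
    "read_labeled_instances",
]

EMG_RATE = 2000.0
ACC_RATE = 148.1

#: (sensor number, muscle/site, short code) for the eight EMG channels
EMG_SENSORS: list[tuple[int, str, str]] = [
    (1, "extensor digitorum", "ED"),
    (2, "extensor indicis", "EI"),
    (3, "flexor carpi radialis", "FCR"),
    (4, "flexor digitorum superficialis", "FDS"),
    (5, "flexor carpi ulnaris", "FCU"),
    (6, "pronator quadratus", "PQ"),
    (7, "brachioradialis", "Bra"),
    (8, "biceps brachii", "Bic"),
]

#: hand-mounted accelerometer sensors (labelling aid, not features)
ACC_SENSORS: list[tuple[int, str, str]] = [
    (9, "base of the thumb (posterior)", "Thumb"),
    (10, "base of little finger (posterior)", "Pinky"),
]

ACC_AXES = ("x", "y", "z")


def emg_filename(num: int, code: str) -> str:
    return f"sensor{num:02d}_{code}_EMG.csv"


def acc_filename(num: int, code: str, axis: str) -> str:
    return f"sensor{num:02d}_{code}_ACC_{axis}.csv"


@dataclass
class ChannelSeries:
    """One sensor channel: uniformly sampled values with a start time."""

    sensor_id: str
    kind: str  # "EMG" | "ACC"
    rate: float
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("EMG", "ACC"):
            raise ValueError(f"kind must be EMG or ACC, got {self.kind!r}")
        if not self.rate > 0:
            raise ValueError("sample rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite samples in channel {self.sensor_id}")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return self.values.size / self.rate


@dataclass
class RunBundle:
    """All channels of one collection run, plus optional ground truth."""

    emg: list[ChannelSeries]
    acc: list[ChannelSeries]
    group_id: Optional[str] = None
    truth: Optional[list[tuple[str, float, float]]] = None

    def __post_init__(self) -> None:
        if len(self.emg) != 8:
            raise ValueError(f"expected 8 EMG channels, got {len(self.emg)}")
        rates = {c.rate for c in self.emg}
        lens = {c.values.size for c in self.emg}
        if len(rates) > 1 or len(lens) > 1:
            raise ValueError("EMG channels must share sample rate and length")
        if self.acc:
            if len({c.rate for c in self.acc}) > 1 or len({c.values.size for c in self.acc}) > 1:
                raise ValueError("ACC channels must share sample rate and length")

    @property
    def emg_rate(self) -> float:
        return self.emg[0].rate

    @property
    def emg_matrix(self) -> np.ndarray:
        """(8, n) array of EMG samples."""
        return np.stack([c.values for c in self.emg])

    @property
    def acc_matrix(self) -> np.ndarray:
        return np.stack([c.values for c in self.acc])


def _read_channel_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError(f"empty signal file: {path.name}")
    if list(df.columns[:2]) != ["elapsed_time_s", "value"]:
        raise ValueError(f"{path.name}: expected columns (elapsed_time_s, value)")
    t = df["elapsed_time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path.name}: timestamps are not strictly increasing")
    return t, df["value"].to_numpy(dtype=float)


def _infer_rate(t: np.ndarray) -> float:
    if t.size < 2:
        raise ValueError("cannot infer sample rate from fewer than 2 samples")
    return (t.size - 1) / (t[-1] - t[0])


def read_run(directory) -> RunBundle:
    """Load a run directory of per-sensor CSVs into a :class:`RunBundle`."""
    directory = Path(directory)
    missing = []
    for num, muscle, code in EMG_SENSORS:
        if not (directory / emg_filename(num, code)).exists():
            missing.append(f"sensor {num} ({muscle}, {code}) EMG")
    for num, site, code in ACC_SENSORS:
        for axis in ACC_AXES:
            if not (directory / acc_filename(num, code, axis)).exists():
                missing.append(f"sensor {num} ({site}) ACC {axis}")
    if missing:
        raise FileNotFoundError(
            f"run directory {directory} is missing channels: " + "; ".join(missing)
        )

    emg = []
    for num, muscle, code in EMG_SENSORS:
        t, v = _read_channel_csv(directory / emg_filename(num, code))
        emg.append(ChannelSeries(f"{num}:{code}", "EMG", _infer_rate(t), v, t[0]))
    acc = []
    for num, site, code in ACC_SENSORS:
        for axis in ACC_AXES:
            t, v = _read_channel_csv(directory / acc_filename(num, code, axis))
            acc.append(ChannelSeries(f"{num}:{code}:{axis}", "ACC", _infer_rate(t), v, t[0]))

    meta_path = directory / "run.json"
    group_id = None
    if meta_path.exists():
        group_id = json.loads(meta_path.read_text()).get("group_id")
    truth = None
    truth_path = directory / "truth.csv"
    if truth_path.exists():
        tdf = pd.read_csv(truth_path)
        truth = [
            (str(r.code), float(r.onset_s), float(r.offset_s)) for r in tdf.itertuples()
        ]
    return RunBundle(emg=emg, acc=acc, group_id=group_id, truth=truth)


def _write_channel_csv(path: Path, times: np.ndarray, values: np.ndarray) -> None:
    df = pd.DataFrame({"elapsed_time_s": times, "value": values})
    df.to_csv(path, index=False, float_format="%.6f")


def write_run(bundle: RunBundle, directory) -> Path:
    """Write a run to per-sensor CSVs (the dialect ``read_run`` accepts)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for series, (num, _, code) in zip(bundle.emg, EMG_SENSORS):
        _write_channel_csv(directory / emg_filename(num, code), series.times, series.values)
    acc_iter = iter(bundle.acc)
    for num, _, code in ACC_SENSORS:
        for axis in ACC_AXES:
            series = next(acc_iter)
            _write_channel_csv(directory / acc_filename(num, code, axis), series.times, series.values)
    if bundle.group_id is not None:
        (directory / "run.json").write_text(json.dumps({"group_id": bundle.group_id}))
    if bundle.truth is not None:
        pd.DataFrame(bundle.truth, columns=["code", "onset_s", "offset_s"]).to_csv(
            directory / "truth.csv", index=False, float_format="%.6f"
        )
    return directory


def write_labeled_instances(stream, path) -> Path:
    """Write a labelled MAV stream as CSV (timestamp, 8 channels, label)."""
    labels = np.asarray(stream.labels)
    bad = sorted(set(labels) - set(CLASS_CODES))
    if bad:
        raise ValueError(f"unknown label code(s): {', '.join(map(str, bad))}")
    df = pd.DataFrame(stream.values, columns=[f"ch{j + 1}" for j in range(8)])
    # timestamps at microsecond precision; MAV values at full precision so the
    # write/read round trip is lossless
    df.insert(0, "elapsed_time_s", [f"{t:.6f}" for t in stream.times])
    df["label"] = labels
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_labeled_instances(path):
    """Read a labelled MAV stream written by :func:`write_labeled_instances`."""
    from .labeling import LabeledStream

    df = pd.read_csv(path)
    labels = df["label"].astype(str).to_numpy()
    bad = sorted(set(labels) - set(CLASS_CODES))
    if bad:
        raise ValueError(f"unknown label code(s): {', '.join(map(str, bad))}")
    values = df[[f"ch{j + 1}" for j in range(8)]].to_numpy(dtype=float)
    times = df["elapsed_time_s"].to_numpy(dtype=float)
    return LabeledStream(times=times, values=values, labels=labels)
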