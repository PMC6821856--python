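"""Reading and writing of recordings, annotations, feature tables and checkpoints.

Recordings travel as :class:`SignalRecord` (channels x samples, row-major).
On disk they are EDF (one file per subject, 16-bit) or a flat CSV alternative;
seizure annotations live in a sidecar CSV with columns ``subject_id,
onset_seconds``. Extracted bispectral features are persisted long-format (one
row per channel-window) so the file layout is independent of channel count.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io as _io
import json

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_COLUMNS = [
    "subject_id",
    "hour_id",
    "class_label",
    "seizure_index",
    "window_index",
    "channel_label",
    "e1",
    "e2",
]

CLASS_LABELS = ("interictal", "preictal")


@dataclass
class SignalRecord:
    """A multichannel recording with its seizure annotations.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Amplitudes in arbitrary units (standardization downstream removes scale).
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
    start_time : float
        Offset of the first sample in seconds.
    seizure_onsets : ndarray
        Onset times in seconds, strictly increasing, within the record.
    subject_id : str
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    start_time: float = 0.0
    seizure_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples))
        self.seizure_onsets = np.asarray(self.seizure_onsets, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        if self.seizure_onsets.size:
            if np.any(np.diff(self.seizure_onsets) <= 0):
                raise ValueError("seizure onsets must be strictly increasing")
            dur = self.duration_s
            if self.seizure_onsets[0] < self.start_time or self.seizure_onsets[-1] > (
                self.start_time + dur
            ):
                raise ValueError("seizure onsets fall outside the record")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class AnnotationTable:
    """Seizure onset annotations for one subject."""

    subject_id: str
    onset_seconds: np.ndarray

    def __post_init__(self) -> None:
        self.onset_seconds = np.asarray(self.onset_seconds, dtype=float)
        if self.onset_seconds.size and np.any(np.diff(self.onset_seconds) <= 0):
            raise ValueError("onsets must be unique and increasing")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_RECORD_SECONDS = 1


def write_edf(rec: SignalRecord, path) -> None:
    """Write a record as EDF (16-bit, one data record per second).

    The sampling rate must be a positive integer and the record an integer
    number of seconds long; both hold for simulated subjects. Each channel is
    scaled to its own physical range so quantization error is at most
    ``max|x| / 32767`` per channel.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9 or fs <= 0:
        raise ValueError(f"EDF export requires an integer sampling rate, got {rec.fs}")
    if rec.n_samples % fs != 0:
        raise ValueError("EDF export requires an integer number of seconds")
    n_records = rec.n_samples // fs
    ns = rec.n_channels

    phys_max = np.maximum(np.abs(rec.samples).max(axis=1), 1e-12)
    dig_max = 32767

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            b = b[:width]
        return b.ljust(width)

    now = _dt.datetime(2000, 1, 1)
    header = _io.BytesIO()
    header.write(pad("0", 8))
    header.write(pad(rec.subject_id, 80))
    header.write(pad("Startdate 01-JAN-2000", 80))
    header.write(pad(now.strftime("%d.%m.%y"), 8))
    header.write(pad(now.strftime("%H.%M.%S"), 8))
    header.write(pad(str(256 * (ns + 1)), 8))
    header.write(pad("", 44))
    header.write(pad(str(n_records), 8))
    header.write(pad(str(_EDF_RECORD_SECONDS), 8))
    header.write(pad(str(ns), 4))
    for lab in rec.channel_labels:
        header.write(pad(lab, 16))
    for _ in range(ns):
        header.write(pad("", 80))  # transducer
    for _ in range(ns):
        header.write(pad("uV", 8))
    for pm in phys_max:
        header.write(pad(f"{-pm:.6g}"[:8], 8))
    for pm in phys_max:
        header.write(pad(f"{pm:.6g}"[:8], 8))
    for _ in range(ns):
        header.write(pad(str(-dig_max), 8))
    for _ in range(ns):
        header.write(pad(str(dig_max), 8))
    for _ in range(ns):
        header.write(pad("", 80))  # prefiltering
    for _ in range(ns):
        header.write(pad(str(fs), 8))
    for _ in range(ns):
        header.write(pad("", 32))

    # re-read the printed physical extrema so quantization matches the header
    pm_printed = np.array([float(f"{pm:.6g}"[:8]) for pm in phys_max])
    scale = (dig_max / pm_printed)[:, None]

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        chunk = max(1, 2**22 // (ns * fs))  # quantize a few seconds at a time
        for r0 in range(0, n_records, chunk):
            r1 = min(r0 + chunk, n_records)
            block = np.round(rec.samples[:, r0 * fs : r1 * fs] * scale).astype("<i2")
            for r in range(r1 - r0):
                fh.write(block[:, r * fs : (r + 1) * fs].tobytes())


def _read_edf(path) -> tuple[np.ndarray, float, list[str], str]:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne rescales microvolt channels to volts
    labels = list(raw.ch_names)
    with open(path, "rb") as fh:
        subject = fh.read(256)[8:88].decode("ascii").strip()
    return data, float(raw.info["sfreq"]), labels, subject


# ---------------------------------------------------------------------------
# CSV signal format
# ---------------------------------------------------------------------------


def write_signal_csv(rec: SignalRecord, path) -> None:
    """Flat CSV alternative to EDF: a metadata comment line, a header of
    channel labels, then one row per sample."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={rec.fs} subject_id={rec.subject_id} start_time={rec.start_time}\n")
        writer = csv.writer(fh)
        writer.writerow(rec.channel_labels)
        for row in rec.samples.T:
            writer.writerow([f"{v:.9g}" for v in row])


def _read_signal_csv(path) -> tuple[np.ndarray, float, list[str], str, float]:
    with open(path, newline="") as fh:
        meta_line = fh.readline()
        if not meta_line.startswith("#"):
            raise ValueError(f"{path}: missing '# fs=...' metadata line")
        meta = dict(tok.split("=", 1) for tok in meta_line[1:].split())
        fs = float(meta["fs"])
        if fs <= 0:
            raise ValueError(f"{path}: fs must be positive, got {fs}")
        reader = csv.reader(fh)
        labels = next(reader)
        rows = []
        for i, row in enumerate(reader):
            if len(row) != len(labels):
                raise ValueError(
                    f"{path}: row {i + 3} has {len(row)} fields, expected {len(labels)}"
                )
            rows.append([float(v) for v in row])
    samples = np.asarray(rows).T if rows else np.empty((len(labels), 0))
    return samples, fs, labels, meta.get("subject_id", "subject"), float(
        meta.get("start_time", 0.0)
    )


def read_recording(path, format: str | None = None, annotations=None) -> SignalRecord:
    """Read a recording from EDF or the CSV alternative.

    Parameters
    ----------
    path : path-like
    format : {"edf", "csv"}, optional
        Inferred from the extension when omitted.
    annotations : path-like or AnnotationTable, optional
        Sidecar annotation CSV; onsets are attached to the returned record.
    """
    path = str(path)
    if format is None:
        format = "edf" if path.lower().endswith(".edf") else "csv"
    if format == "edf":
        samples, fs, labels, subject = _read_edf(path)
        start_time = 0.0
    elif format == "csv":
        samples, fs, labels, subject, start_time = _read_signal_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    onsets = np.empty(0)
    if annotations is not None:
        tab = (
            annotations
            if isinstance(annotations, AnnotationTable)
            else read_annotations(annotations)
        )
        onsets = tab.onset_seconds
        subject = tab.subject_id
    return SignalRecord(
        samples=samples,
        fs=fs,
        channel_labels=labels,
        start_time=start_time,
        seizure_onsets=onsets,
        subject_id=subject,
    )


def write_annotations(tab: AnnotationTable, path) -> None:
    pd.DataFrame(
        {"subject_id": tab.subject_id, "onset_seconds": tab.onset_seconds}
    ).to_csv(path, index=False)


def read_annotations(path) -> AnnotationTable:
    df = pd.read_csv(path)
    subject = str(df["subject_id"].iloc[0]) if len(df) else "subject"
    return AnnotationTable(subject_id=subject, onset_seconds=df["onset_seconds"].to_numpy())


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def validate_features(table: pd.DataFrame) -> None:
    """Check the long-format feature-table invariants."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    if len(table) == 0:
        return
    keys = table[["hour_id", "window_index", "channel_label"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0]
        raise ValueError(
            "duplicate feature key "
            f"(hour={dup['hour_id']}, window={dup['window_index']}, "
            f"channel={dup['channel_label']})"
        )
    bad = table[~table["class_label"].isin(CLASS_LABELS)]
    if len(bad):
        raise ValueError(f"unknown class label {bad['class_label'].iloc[0]!r}")
    vals = table[["e1", "e2"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals < 0):
        raise ValueError("E1/E2 must be finite and non-negative")


def write_features(table: pd.DataFrame, path) -> None:
    validate_features(table)
    table.to_csv(path, index=False, float_format="%.12g")


def read_features(path) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        dtype={
            "subject_id": str,
            "hour_id": str,
            "class_label": str,
            "channel_label": str,
        },
    )
    if len(table) == 0:
        table = pd.DataFrame(columns=FEATURE_COLUMNS)
    validate_features(table)
    return table


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(weights: dict[str, np.ndarray], config: dict, path) -> None:
    """Persist named weight tensors plus the training config in one archive."""
    arrays = dict(weights)
    arrays["__config_json__"] = np.frombuffer(
        json.dumps(config, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files if k != "__config_json__"}
        config = json.loads(bytes(npz["__config_json__"].tobytes()).decode())
    return arrays, config
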