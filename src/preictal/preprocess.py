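"""Filtering, standardization and segmentation into labeled 30-s windows.

The labeling scheme: for each seizure with 65 minutes of clean history, the
preictal hour is ``[onset - 65 min, onset - 5 min]`` (the trailing 5 minutes
are intervention time and never labeled); interictal hours are sampled at
least ``interictal_gap_h`` hours from every onset, one per preictal hour so
the classes stay balanced. Hours are cut into 120 contiguous non-overlapping
30-second windows per channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .io import SignalRecord

WINDOW_SECONDS = 30.0
WINDOWS_PER_HOUR = 120


@dataclass
class PreprocessConfig:
    band_low: float = 0.5
    band_high: float = 180.0
    notch: float = 60.0
    notch_q: float = 30.0
    butter_order: int = 4
    preictal_len_min: float = 60.0
    horizon_min: float = 5.0
    interictal_gap_h: float = 4.0
    standardize_scope: str = "window"  # "window" | "hour"
    seed: int = 0


@dataclass
class EpochWindow:
    """One standardized 30-s single-channel window with its provenance."""

    samples: np.ndarray
    fs: float
    channel_label: str
    hour_id: str
    window_index: int
    class_label: str  # "preictal" | "interictal"
    seizure_index: int
    subject_id: str


@dataclass
class LabeledHour:
    """A 60-minute multichannel segment with one class label."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_labels: list[str]
    class_label: str
    seizure_index: int
    hour_id: str
    subject_id: str
    start_time: float


def bandpass_notch(
    rec: SignalRecord,
    low: float = 0.5,
    high: float = 180.0,
    notch: float = 60.0,
    notch_q: float = 30.0,
    order: int = 4,
) -> SignalRecord:
    """Zero-phase band-pass plus power-line notch filtering, per channel.

    Forward-backward (zero-phase) filtering is used throughout so the filters
    cannot introduce spurious phase relations between frequency components —
    essential upstream of a phase-coupling detector. Butterworth band-pass of
    the given order; IIR notch of quality factor ``notch_q``.
    """
    if high >= rec.fs / 2:
        raise ValueError(f"band edge {high} Hz >= Nyquist {rec.fs / 2} Hz")
    if low >= high:
        raise ValueError("low cut must be below high cut")
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    b_n, a_n = scipy.signal.iirnotch(notch, notch_q, fs=rec.fs)
    out = np.empty_like(rec.samples, dtype=rec.samples.dtype)
    for ch in range(rec.n_channels):
        x = scipy.signal.sosfiltfilt(sos, rec.samples[ch].astype(np.float64))
        x = scipy.signal.filtfilt(b_n, a_n, x)
        out[ch] = x
    return SignalRecord(
        samples=out,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        start_time=rec.start_time,
        seizure_onsets=rec.seizure_onsets.copy(),
        subject_id=rec.subject_id,
    )


def standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Rescale to zero mean and unit population standard deviation.

    Raises on (near-)constant input, where the rescaling is undefined.
    """
    x = np.asarray(x, dtype=np.float64)
    mean = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)  # population convention (ddof=0)
    if np.any(sd <= 1e-300) or not np.all(np.isfinite(sd)):
        raise ValueError("cannot standardize zero-variance input")
    return (x - mean) / sd


def extract_labeled_hours(
    rec: SignalRecord, cfg: PreprocessConfig | None = None
) -> list[LabeledHour]:
    """Cut a recording into balanced preictal / interictal hours.

    A seizure qualifies only if the full ``preictal_len_min + horizon_min``
    history lies inside the record and contains no other onset. For each
    qualifying seizure one interictal hour is sampled (seeded) from the
    regions at least ``interictal_gap_h`` hours from every onset.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    if rec.seizure_onsets.size == 0:
        raise ValueError("recording has no seizure annotations")
    fs = rec.fs
    pre_len = cfg.preictal_len_min * 60.0
    horizon = cfg.horizon_min * 60.0
    gap = cfg.interictal_gap_h * 3600.0
    t0 = rec.start_time
    dur = rec.duration_s
    hours: list[LabeledHour] = []

    def cut(start_s: float) -> np.ndarray:
        i0 = int(round((start_s - t0) * fs))
        return rec.samples[:, i0 : i0 + int(round(3600.0 * fs))]

    qualifying: list[tuple[int, float]] = []
    for k, onset in enumerate(rec.seizure_onsets):
        hist_start = onset - pre_len - horizon
        if hist_start < t0:
            continue  # not enough clean history
        others = np.delete(rec.seizure_onsets, k)
        if np.any((others >= hist_start) & (others < onset)):
            continue  # history interrupted by another seizure
        qualifying.append((k, onset))

    for k, onset in qualifying:
        start = onset - pre_len - horizon
        hours.append(
            LabeledHour(
                samples=cut(start),
                fs=fs,
                channel_labels=list(rec.channel_labels),
                class_label="preictal",
                seizure_index=k,
                hour_id=f"{rec.subject_id}_sz{k:02d}_pre",
                subject_id=rec.subject_id,
                start_time=start,
            )
        )

    # candidate interictal hour starts on an hour grid, >= gap from every onset
    n_needed = len(qualifying)
    candidates = []
    start = t0
    while start + 3600.0 <= t0 + dur + 1e-9:
        if all(
            o <= start - gap or o >= start + 3600.0 + gap for o in rec.seizure_onsets
        ):
            candidates.append(start)
        start += 3600.0
    if len(candidates) < n_needed:
        raise ValueError(
            f"only {len(candidates)} interictal hours available at "
            f">= {cfg.interictal_gap_h} h from every onset; need {n_needed} "
            "to balance the preictal class"
        )
    rng = np.random.default_rng(cfg.seed)
    chosen = sorted(rng.choice(len(candidates), size=n_needed, replace=False))
    for (k, _), ci in zip(qualifying, chosen):
        start = candidates[ci]
        hours.append(
            LabeledHour(
                samples=cut(start),
                fs=fs,
                channel_labels=list(rec.channel_labels),
                class_label="interictal",
                seizure_index=k,
                hour_id=f"{rec.subject_id}_sz{k:02d}_int",
                subject_id=rec.subject_id,
                start_time=start,
            )
        )
    return hours


def window_hour(hour: LabeledHour, standardize_scope: str = "window") -> list[EpochWindow]:
    """Cut one labeled hour into 120 standardized 30-s windows per channel."""
    n_per_window = int(round(WINDOW_SECONDS * hour.fs))
    expected = n_per_window * WINDOWS_PER_HOUR
    if hour.samples.shape[1] != expected:
        raise ValueError(
            f"hour {hour.hour_id!r} has {hour.samples.shape[1]} samples; "
            f"expected exactly {expected} (60 min at {hour.fs} Hz)"
        )
    if standardize_scope not in ("window", "hour"):
        raise ValueError(f"unknown standardize scope {standardize_scope!r}")
    windows = []
    data = hour.samples
    if standardize_scope == "hour":
        data = standardize(data, axis=1)
    for w in range(WINDOWS_PER_HOUR):
        sl = slice(w * n_per_window, (w + 1) * n_per_window)
        for ch, label in enumerate(hour.channel_labels):
            x = data[ch, sl]
            if standardize_scope == "window":
                x = standardize(x)
            windows.append(
                EpochWindow(
                    samples=np.asarray(x, dtype=np.float64),
                    fs=hour.fs,
                    channel_label=label,
                    hour_id=hour.hour_id,
                    window_index=w,
                    class_label=hour.class_label,
                    seizure_index=hour.seizure_index,
                    subject_id=hour.subject_id,
                )
            )
    return windows
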