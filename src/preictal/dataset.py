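"""Sequence assembly and leak-free temporal splitting.

Each labeled hour (120 windows) tiles into 12 non-overlapping sequences of
10 consecutive 30-s windows (5 minutes each); every sequence carries the 32
feature columns in fixed channel-major order (ch1 E1, ch1 E2, ..., chN E1,
chN E2). Splitting is temporal and seizure-per-seizure: the first 40% of a
subject's seizures (by onset order) train, the next 30% validate, the last
30% test, and every sequence of a seizure's preictal hour and its paired
interictal hour inherits that assignment — no hour ever feeds two splits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import validate_features

SEQ_LEN = 10
LABEL_OF_CLASS = {"interictal": 0, "preictal": 1}


@dataclass
class SequenceSample:
    matrix: np.ndarray  # (SEQ_LEN, 2 * n_channels)
    label: int  # 0 interictal, 1 preictal
    subject_id: str
    hour_id: str
    seizure_index: int
    start_window_index: int


@dataclass
class SplitPlan:
    """Seizure -> split assignment for each subject, in temporal order."""

    assignment: dict[tuple[str, int], str]  # (subject_id, seizure_index) -> split
    fractions: tuple[float, float, float]

    def split_of(self, sample: SequenceSample) -> str:
        return self.assignment[(sample.subject_id, sample.seizure_index)]

    def apply(self, samples: list[SequenceSample]) -> dict[str, list[SequenceSample]]:
        out: dict[str, list[SequenceSample]] = {"train": [], "val": [], "test": []}
        for s in samples:
            out[self.split_of(s)].append(s)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject_id": sub, "seizure_index": k, "split": split}
            for (sub, k), split in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows, columns=["subject_id", "seizure_index", "split"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fractions=(0.4, 0.3, 0.3)) -> "SplitPlan":
        assignment = {
            (str(r.subject_id), int(r.seizure_index)): str(r.split)
            for r in df.itertuples()
        }
        return cls(assignment=assignment, fractions=tuple(fractions))


def feature_matrix_columns(channel_labels: list[str]) -> list[tuple[str, str]]:
    """Fixed feature order: (channel, e1), (channel, e2) per channel in turn."""
    return [(ch, feat) for ch in channel_labels for feat in ("e1", "e2")]


def assemble_sequences(features: pd.DataFrame) -> list[SequenceSample]:
    """Build 10-step sequence samples from the long-format feature table.

    Every hour must be complete (120 windows x all channels); incomplete
    hours are an error, named, rather than silently truncated.
    """
    validate_features(features)
    if len(features) == 0:
        return []
    channels = sorted(features["channel_label"].unique())
    cols = feature_matrix_columns(channels)
    samples: list[SequenceSample] = []
    for hour_id, grp in features.groupby("hour_id", sort=True):
        n_windows = grp["window_index"].nunique()
        if n_windows != 120 or len(grp) != 120 * len(channels):
            raise ValueError(
                f"hour {hour_id!r} incomplete: {n_windows} window indices, "
                f"{len(grp)} rows (expected 120 x {len(channels)})"
            )
        wide = grp.pivot(index="window_index", columns="channel_label", values=["e1", "e2"])
        wide = wide.sort_index()
        mat = np.column_stack([wide[(feat, ch)].to_numpy() for ch, feat in cols])
        label = LABEL_OF_CLASS[grp["class_label"].iloc[0]]
        subject = grp["subject_id"].iloc[0]
        seizure = int(grp["seizure_index"].iloc[0])
        for s0 in range(0, 120, SEQ_LEN):
            samples.append(
                SequenceSample(
                    matrix=mat[s0 : s0 + SEQ_LEN].astype(np.float64),
                    label=label,
                    subject_id=subject,
                    hour_id=hour_id,
                    seizure_index=seizure,
                    start_window_index=s0,
                )
            )
    return samples


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_by_seizure(
    samples: list[SequenceSample], fractions: tuple[float, float, float] = (0.4, 0.3, 0.3)
) -> SplitPlan:
    """Assign each subject's seizures, in temporal order, to train/val/test.

    Counts are round-half-up of fraction x S for train and val; the
    remainder tests. Requires at least 3 seizures per subject so every split
    is populated.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    assignment: dict[tuple[str, int], str] = {}
    subjects = sorted({s.subject_id for s in samples})
    for sub in subjects:
        seizures = sorted({s.seizure_index for s in samples if s.subject_id == sub})
        S = len(seizures)
        if S < 3:
            raise ValueError(
                f"subject {sub!r} has {S} seizures; need >= 3 to populate "
                "train, validation and test"
            )
        n_train = _round_half_up(fractions[0] * S)
        n_val = _round_half_up(fractions[1] * S)
        n_test = S - n_train - n_val
        if n_test < 1 or n_train < 1 or n_val < 1:
            raise ValueError(
                f"subject {sub!r}: split {n_train}/{n_val}/{n_test} leaves an empty split"
            )
        for i, k in enumerate(seizures):
            if i < n_train:
                split = "train"
            elif i < n_train + n_val:
                split = "val"
            else:
                split = "test"
            assignment[(sub, k)] = split
    return SplitPlan(assignment=assignment, fractions=tuple(fractions))


def sequence_arrays(samples: list[SequenceSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (n, 10, n_features) inputs and (n,) labels."""
    X = np.stack([s.matrix for s in samples])
    y = np.array([s.label for s in samples], dtype=np.int64)
    return X, y
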