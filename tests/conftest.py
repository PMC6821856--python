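import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from preictal.dataset import SequenceSample
from preictal.hos import EstimatorConfig
from preictal.io import FEATURE_COLUMNS

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reduced_est() -> EstimatorConfig:
    return EstimatorConfig(nfft=256, record_len=256)


def make_feature_table(
    n_hours_per_class: int = 1,
    n_channels: int = 16,
    subject_id: str = "sub01",
    seed: int = 0,
    class_shift: float = 0.0,
) -> pd.DataFrame:
    """Synthetic long-format feature table satisfying all invariants.

    ``class_shift`` lowers preictal E1/E2 by that amount, mimicking
    concentrated bispectral mass before seizures.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_hours_per_class):
        for cls, tag in (("preictal", "pre"), ("interictal", "int")):
            hour_id = f"{subject_id}_sz{k:02d}_{tag}"
            for w in range(120):
                for ch in range(n_channels):
                    base = 4.0 + 0.1 * rng.standard_normal(2)
                    if cls == "preictal":
                        base -= class_shift
                    rows.append(
                        (
                            subject_id,
                            hour_id,
                            cls,
                            k,
                            w,
                            f"ch{ch + 1:02d}",
                            abs(base[0]),
                            abs(base[1] - 0.5),
                        )
                    )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def make_sequences(
    n_per_class: int = 36,
    n_seizures: int = 3,
    separation: float = 0.0,
    n_features: int = 32,
    seed: int = 0,
    subject_id: str = "sub01",
) -> list[SequenceSample]:
    """Gaussian-cluster sequence samples; preictal means shifted by ``separation``."""
    rng = np.random.default_rng(seed)
    samples = []
    per_seizure = n_per_class // n_seizures
    for k in range(n_seizures):
        for label, tag in ((1, "pre"), (0, "int")):
            for j in range(per_seizure):
                mat = rng.standard_normal((10, n_features))
                if label == 1:
                    mat -= separation
                samples.append(
                    SequenceSample(
                        matrix=mat,
                        label=label,
                        subject_id=subject_id,
                        hour_id=f"{subject_id}_sz{k:02d}_{tag}",
                        seizure_index=k,
                        start_window_index=10 * j,
                    )
                )
    return samples
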