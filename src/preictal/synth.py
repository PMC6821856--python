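"""Synthetic multichannel iEEG with controllable quadratic phase coupling.

The generator emulates the statistical structure the bispectral pipeline
assumes: preictal stretches contain three oscillatory components at
``f1``, ``f2`` and ``f1 + f2`` whose phases satisfy ``phi3 = phi1 + phi2``
(quadratic phase coupling, QPC) riding on Gaussian ``1/f^beta`` background;
interictal stretches have the identical spectral content but an independent
phase for the harmonic. The two classes are therefore indistinguishable to
second-order statistics (power spectra match) and separable only through the
bispectrum — which is exactly the property the feature extractor must detect.

Phases are re-drawn for every sub-epoch (default 4096 samples, the
estimator's record length) so the record averaging in the bispectrum
estimator sees independent phase realizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SignalRecord

HORIZON_MINUTES = 5.0  # intervention time: coupling (and labels) stop 5 min before onset


@dataclass
class SimConfig:
    """Study conditions for one simulated subject.

    Defaults mirror the canine recording layout the pipeline targets:
    16 bilateral channels at 400 Hz, 65 minutes of clean preictal history per
    usable seizure (the last 5 of which are intervention time), interictal
    data at least 4 hours from any onset.
    """

    n_channels: int = 16
    fs: float = 400.0
    n_seizures: int = 3
    preictal_minutes: float = 65.0
    interictal_gap_hours: float = 4.0
    f1: float = 25.0
    f2: float = 50.0
    coupling_strength: float = 1.5  # lambda: amplitude of the phase-locked harmonic
    snr_db: float = 10.0  # oscillation power over background power; inf = no background
    background_exponent: float = 1.0  # 1/f^beta slope of the background
    subepoch_len: int = 4096  # samples per independent phase realization
    duration_hours: float | None = None  # None: auto-sized minimal feasible timeline
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f1 <= 0 or self.f2 <= 0:
            raise ValueError("f1 and f2 must be positive")
        if self.f1 + self.f2 >= self.fs / 2:
            raise ValueError(
                f"f1 + f2 = {self.f1 + self.f2} Hz aliases: must be < fs/2 = {self.fs / 2}"
            )
        if self.coupling_strength < 0:
            raise ValueError("coupling strength must be >= 0")
        if self.n_seizures < 1:
            raise ValueError("need at least one seizure")


def _background(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian 1/f^beta noise of length n (spectral shaping)."""
    w = rng.standard_normal(n)
    if beta == 0:
        return w
    spec = np.fft.rfft(w)
    freq = np.fft.rfftfreq(n)
    spec[1:] *= freq[1:] ** (-beta / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _oscillation(
    n: int, cfg: SimConfig, coupled: bool, rng: np.random.Generator
) -> np.ndarray:
    t = np.arange(n) / cfg.fs
    phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
    phi3 = (phi1 + phi2) if coupled else rng.uniform(0, 2 * np.pi)
    lam = cfg.coupling_strength
    return (
        np.cos(2 * np.pi * cfg.f1 * t + phi1)
        + np.cos(2 * np.pi * cfg.f2 * t + phi2)
        + lam * np.cos(2 * np.pi * (cfg.f1 + cfg.f2) * t + phi3)
    )


def _background_scale(cfg: SimConfig) -> float:
    if np.isinf(cfg.snr_db):
        return 0.0
    osc_power = 0.5 + 0.5 + 0.5 * cfg.coupling_strength**2
    return float(np.sqrt(osc_power / 10 ** (cfg.snr_db / 10.0)))


def _channel_samples(
    n: int, cfg: SimConfig, coupled_mask, rng: np.random.Generator
) -> np.ndarray:
    """One channel, built sub-epoch by sub-epoch.

    coupled_mask : callable mapping sub-epoch start sample -> bool
    """
    out = np.empty(n, dtype=np.float32)
    bg_scale = _background_scale(cfg)
    step = cfg.subepoch_len
    for s0 in range(0, n, step):
        m = min(step, n - s0)
        seg = _oscillation(m, cfg, coupled_mask(s0), rng)
        if bg_scale > 0:
            seg = seg + bg_scale * _background(m, cfg.background_exponent, rng)
        out[s0 : s0 + m] = seg
    return out


def simulate_qpc_segment(
    duration_s: float,
    cfg: SimConfig,
    coupled: bool,
    rng: np.random.Generator | None = None,
) -> SignalRecord:
    """Generate a single-channel segment, uniformly coupled or uncoupled."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(duration_s * cfg.fs))
    samples = _channel_samples(n, cfg, lambda s0: coupled, rng)
    return SignalRecord(
        samples=samples[None, :],
        fs=cfg.fs,
        channel_labels=["ch01"],
        subject_id="segment",
    )


def _timeline(cfg: SimConfig) -> tuple[np.ndarray, float]:
    """Onset times and total duration for a feasible subject layout.

    Consecutive onsets are spaced so that between any two there is room for
    the full clean preictal history of the later one plus at least one
    interictal hour at ``interictal_gap_hours`` from both.
    """
    gap = cfg.interictal_gap_hours * 3600.0
    pre = cfg.preictal_minutes * 60.0
    spacing = 2 * gap + 3600.0 + pre + 600.0
    first = gap + 3600.0 + pre + 300.0
    onsets = first + spacing * np.arange(cfg.n_seizures)
    duration = onsets[-1] + 600.0
    if cfg.duration_hours is not None:
        requested = cfg.duration_hours * 3600.0
        if requested < duration:
            raise ValueError(
                f"duration {cfg.duration_hours} h cannot accommodate "
                f"{cfg.n_seizures} seizures with gap {cfg.interictal_gap_hours} h "
                f"(needs >= {duration / 3600.0:.2f} h)"
            )
        duration = requested
    return onsets, duration


def simulate_subject(cfg: SimConfig, subject_id: str = "sim01") -> SignalRecord:
    """Simulate a full multichannel subject with ground-truth annotations.

    For every onset the interval ``[onset - preictal_minutes, onset - 5 min]``
    is generated with quadratic phase coupling on all channels; everywhere
    else the harmonic's phase is independent. Channels share the
    coupled/uncoupled state but have independent noise and phases.
    Deterministic for a given config (including its seed).
    """
    onsets, duration = _timeline(cfg)
    n = int(round(duration * cfg.fs))
    pre = cfg.preictal_minutes * 60.0
    horizon = HORIZON_MINUTES * 60.0
    spans = [(o - pre, o - horizon) for o in onsets]

    def coupled_mask(s0: int) -> bool:
        t0 = s0 / cfg.fs
        t1 = (s0 + cfg.subepoch_len) / cfg.fs
        return any(t1 > a and t0 < b for a, b in spans)

    child_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_channels)
    samples = np.empty((cfg.n_channels, n), dtype=np.float32)
    for ch, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        samples[ch] = _channel_samples(n, cfg, coupled_mask, rng)
    labels = [f"ch{ch + 1:02d}" for ch in range(cfg.n_channels)]
    return SignalRecord(
        samples=samples,
        fs=cfg.fs,
        channel_labels=labels,
        seizure_onsets=onsets,
        subject_id=subject_id,
    )


def reduced_sim_config(seed: int = 0, n_seizures: int = 3, **overrides) -> SimConfig:
    """Scaled-down study conditions used by the worked examples and tests.

    Keeps the structural conditions (16 channels, 400 Hz, 65-minute preictal
    history with 5-minute intervention time) but shrinks the interictal gap so
    a subject fits in memory at desk scale.
    """
    # the gap must stay longer than the 65-min coupled preictal span, or
    # sampled interictal hours could overlap a later seizure's coupling
    kw = dict(
        n_seizures=n_seizures,
        interictal_gap_hours=1.25,
        coupling_strength=1.5,
        snr_db=10.0,
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)
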