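"""Bispectrum estimator and entropy features against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from preictal.hos import (
    EstimatorConfig,
    entropy_e1,
    entropy_e2,
    estimate_bispectrum,
    principal_domain,
    principal_domain_direct,
    PrincipalDomain,
)
from preictal.preprocess import EpochWindow
from preictal.synth import SimConfig, simulate_qpc_segment


def brute_force_bispectrum(x: np.ndarray, nfft: int) -> np.ndarray:
    """Naive triple-loop evaluation of the average triple product (1 record,
    mean detrend, no taper), the independent oracle for the estimator."""
    xd = x - x.mean()
    n = np.arange(len(xd))
    X = np.array([np.sum(xd * np.exp(-2j * np.pi * k * n / nfft)) for k in range(nfft)])
    B = np.empty((nfft, nfft), dtype=complex)
    for i in range(nfft):
        for j in range(nfft):
            B[i, j] = X[(i + j) % nfft] * np.conj(X[i]) * np.conj(X[j])
    return B / nfft


@pytest.mark.parametrize("nfft", [8, 16, 32, 64])
def test_estimator_matches_triple_loop_oracle(nfft):
    rng = np.random.default_rng(42)
    x = rng.standard_normal(nfft)
    cfg = EstimatorConfig(nfft=nfft, record_len=nfft, overlap_fraction=0.0,
                          taper="rect", detrend="mean")
    grid = estimate_bispectrum(x, cfg, fs=400.0)
    ref = brute_force_bispectrum(x, nfft)
    rel = np.max(np.abs(grid.values - ref)) / np.max(np.abs(ref))
    assert rel < 1e-10


def test_grid_shape_and_symmetry(reduced_est):
    rng = np.random.default_rng(0)
    grid = estimate_bispectrum(rng.standard_normal(1024), reduced_est, fs=400.0)
    assert grid.values.shape == (256, 256)
    assert np.array_equal(grid.values, grid.values.T)  # exact f1 <-> f2 symmetry


def test_zero_input_gives_zero_grid(reduced_est):
    grid = estimate_bispectrum(np.zeros(1024), reduced_est, fs=400.0)
    assert np.all(grid.values == 0)


def test_qpc_peak_at_coupling_bins(reduced_est):
    # f1 = 25 Hz (bin 16), f2 = 50 Hz (bin 32) at 400 Hz / nfft 256
    cfg = SimConfig(f1=25.0, f2=50.0, coupling_strength=1.0, snr_db=np.inf,
                    subepoch_len=256, seed=9)
    rec = simulate_qpc_segment(8 * 256 / 400.0, cfg, coupled=True)
    est = EstimatorConfig(nfft=256, record_len=256, overlap_fraction=0.0)
    dom = principal_domain(estimate_bispectrum(rec.samples[0], est, fs=400.0))
    m, n = dom.index_pairs[dom.magnitudes.argmax()]
    assert dom.freq_axis[m] == 50.0 and dom.freq_axis[n] == 25.0


def test_fast_omega_path_equals_full_grid(reduced_est):
    rng = np.random.default_rng(3)
    w = EpochWindow(rng.standard_normal(12000), 400.0, "ch01", "h0", 0,
                    "preictal", 0, "s")
    fast = principal_domain_direct(w, reduced_est)
    full = principal_domain(estimate_bispectrum(w, reduced_est))
    np.testing.assert_allclose(fast.magnitudes, full.magnitudes, rtol=0, atol=1e-12)
    assert np.array_equal(fast.index_pairs, full.index_pairs)


def test_principal_domain_enumeration_nfft8():
    grid = estimate_bispectrum(np.arange(8.0), EstimatorConfig(nfft=8, record_len=8),
                               fs=8.0)
    dom = principal_domain(grid)
    expected = {(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2), (3, 0), (3, 1), (4, 0)}
    assert set(map(tuple, dom.index_pairs)) == expected
    assert dom.L == 9


@pytest.mark.parametrize("nfft", [8, 16, 32, 64])
def test_principal_domain_size_bound(nfft):
    # enumeration oracle vs the triangle bound (nfft/4 + 1)^2
    count = sum(
        1
        for m in range(nfft // 2 + 1)
        for n in range(m + 1)
        if m + n <= nfft // 2
    )
    grid = estimate_bispectrum(np.ones(nfft) + np.arange(nfft) % 3,
                               EstimatorConfig(nfft=nfft, record_len=nfft), fs=1.0)
    dom = principal_domain(grid)
    assert dom.L == count
    assert dom.L <= (nfft // 4 + 1) ** 2


def _dom(mags):
    mags = np.asarray(mags, dtype=float)
    pairs = np.zeros((len(mags), 2), dtype=np.int64)
    return PrincipalDomain(magnitudes=mags, index_pairs=pairs, freq_axis=np.zeros(1))


def test_entropy_hand_values():
    # p = [.25, .25, .5] and q = [1/6, 1/6, 2/3], evaluated by hand
    dom = _dom([1.0, 1.0, 2.0])
    assert entropy_e1(dom) == pytest.approx(1.03972, abs=1e-5)
    assert entropy_e2(dom) == pytest.approx(0.86756, abs=1e-5)


def test_entropy_uniform_and_degenerate():
    uniform = _dom(np.full(100, 3.7))
    assert entropy_e1(uniform) == pytest.approx(np.log(100), rel=1e-12)
    assert entropy_e2(uniform) == pytest.approx(np.log(100), rel=1e-12)
    degenerate = _dom([0.0, 0.0, 5.0, 0.0])
    assert entropy_e1(degenerate) == 0.0
    assert entropy_e2(degenerate) == 0.0


def test_entropy_all_zero_is_error():
    with pytest.raises(ValueError, match="all-zero"):
        entropy_e1(_dom([0.0, 0.0]))


@given(st.lists(st.floats(min_value=0.0, max_value=1e6), min_size=1, max_size=200)
       .filter(lambda v: max(v) > 1e-3))
def test_entropy_bounds_property(mags):
    dom = _dom(mags)
    for ent in (entropy_e1(dom), entropy_e2(dom)):
        assert -1e-12 <= ent <= np.log(dom.L) + 1e-9


def test_coupled_windows_have_lower_entropy():
    """Coupling concentrates bispectral mass, so E1/E2 drop versus the
    phase-randomized control with the identical power spectrum."""
    est = EstimatorConfig(nfft=256, record_len=256)
    vals = {}
    for coupled in (True, False):
        e1s, e2s = [], []
        for seed in range(50):
            cfg = SimConfig(f1=25.0, f2=50.0, coupling_strength=1.5, snr_db=10.0,
                            subepoch_len=256, seed=seed)
            rec = simulate_qpc_segment(8 * 256 / 400.0, cfg, coupled)
            dom = principal_domain_direct(rec.samples[0], est, fs=400.0)
            e1s.append(entropy_e1(dom))
            e2s.append(entropy_e2(dom))
        vals[coupled] = (np.mean(e1s), np.mean(e2s))
    assert vals[True][0] < vals[False][0]
    assert vals[True][1] < vals[False][1]


def test_white_noise_peak_shrinks_with_averaging():
    """For Gaussian noise the bispectrum is zero in expectation; more record
    averaging must shrink the largest |B| over Omega (median over trials)."""
    est = {K: EstimatorConfig(nfft=64, record_len=64, overlap_fraction=0.0)
           for K in (4, 64)}
    medians = {}
    for K in (4, 64):
        peaks = []
        for trial in range(20):
            rng = np.random.default_rng(1000 + trial)
            x = rng.standard_normal(64 * K)
            dom = principal_domain_direct(x, est[K], fs=400.0)
            peaks.append(dom.magnitudes.max())
        medians[K] = np.median(peaks)
    assert medians[64] < medians[4]


def test_estimator_config_validation():
    with pytest.raises(ValueError, match="power of two"):
        EstimatorConfig(nfft=100, record_len=100)
    with pytest.raises(ValueError, match="record_len"):
        EstimatorConfig(nfft=64, record_len=128)
    with pytest.raises(ValueError, match="exceeds window length"):
        estimate_bispectrum(np.ones(32), EstimatorConfig(nfft=64, record_len=64), fs=1.0)
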