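"""LSTM forward/backward against independent oracles; training behavior."""

import math

import numpy as np
import pytest

from preictal.classifier import (
    LstmModel,
    TrainConfig,
    _backward,
    _cross_entropy,
    _forward_full,
    init_lstm,
    learning_rate,
    lstm_accuracy,
    lstm_forward,
    mlp_baseline_train_eval,
    train_lstm,
)
from preictal.dataset import split_by_seizure
from tests.conftest import make_feature_table, make_sequences


def reference_lstm_recursion(x_seq, model):
    """Gate-by-gate scalar recursion, written independently of the
    vectorized implementation, as the forward-pass oracle."""

    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))

    h = model.hidden_size
    hs = [0.0] * h
    cs = [0.0] * h
    for x in x_seq:
        new_h, new_c = [], []
        for j in range(h):
            zi = model.b[j] + sum(model.W[j, a] * x[a] for a in range(len(x)))
            zi += sum(model.U[j, a] * hs[a] for a in range(h))
            zf = model.b[h + j] + sum(model.W[h + j, a] * x[a] for a in range(len(x)))
            zf += sum(model.U[h + j, a] * hs[a] for a in range(h))
            zg = model.b[2 * h + j] + sum(model.W[2 * h + j, a] * x[a] for a in range(len(x)))
            zg += sum(model.U[2 * h + j, a] * hs[a] for a in range(h))
            zo = model.b[3 * h + j] + sum(model.W[3 * h + j, a] * x[a] for a in range(len(x)))
            zo += sum(model.U[3 * h + j, a] * hs[a] for a in range(h))
            c = sig(zf) * cs[j] + sig(zi) * math.tanh(zg)
            new_c.append(c)
            new_h.append(sig(zo) * math.tanh(c))
        hs, cs = new_h, new_c
    logits = [
        model.b_fc[k] + sum(model.w_fc[k, a] * hs[a] for a in range(h)) for k in range(2)
    ]
    mx = max(logits)
    ex = [math.exp(v - mx) for v in logits]
    return np.array([v / sum(ex) for v in ex])


def test_forward_matches_scalar_recursion_oracle():
    model = init_lstm(input_size=4, hidden_size=2, seed=12)
    rng = np.random.default_rng(0)
    x = rng.standard_normal((3, 4))
    np.testing.assert_allclose(
        lstm_forward(x, model), reference_lstm_recursion(x, model), atol=1e-12
    )


def test_forward_probabilities_normalized():
    model = init_lstm(input_size=32, hidden_size=100, seed=0)
    x = np.random.default_rng(1).standard_normal((10, 32))
    p = lstm_forward(x, model)
    assert np.all(p >= 0)
    assert p.sum() == pytest.approx(1.0, abs=1e-9)


def test_zero_weights_give_even_odds():
    h = 5
    model = LstmModel(
        W=np.zeros((4 * h, 3)), U=np.zeros((4 * h, h)), b=np.zeros(4 * h),
        w_fc=np.zeros((2, h)), b_fc=np.zeros(2),
    )
    p = lstm_forward(np.ones((10, 3)), model)
    np.testing.assert_allclose(p, [0.5, 0.5], atol=1e-15)


def test_forward_rejects_bad_input():
    model = init_lstm(input_size=4, hidden_size=2)
    with pytest.raises(ValueError, match="expected"):
        lstm_forward(np.ones((3, 5)), model)
    bad = np.ones((3, 4))
    bad[1, 1] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        lstm_forward(bad, model)


def test_bptt_gradients_match_numerical():
    """Central-difference gradient of the cross-entropy loss as the oracle
    for the handwritten backpropagation-through-time."""
    model = init_lstm(input_size=3, hidden_size=4, seed=7)
    rng = np.random.default_rng(2)
    X = rng.standard_normal((5, 4, 3))
    y = np.array([0, 1, 1, 0, 1])
    probs, state = _forward_full(X, model)
    grads = _backward(X, y, model, probs, state)
    eps = 1e-6
    for name, arr in model.weights().items():
        flat = arr.ravel()
        for idx in rng.choice(flat.size, size=min(6, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = _cross_entropy(_forward_full(X, model)[0], y)
            flat[idx] = orig - eps
            lm = _cross_entropy(_forward_full(X, model)[0], y)
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[name].ravel()[idx] == pytest.approx(num, rel=1e-4, abs=1e-8), name


def test_learning_rate_schedule_exact():
    cfg = TrainConfig()
    for epoch, expected in [(0, 1e-3), (49, 1e-3), (50, 1e-4), (99, 1e-4),
                            (100, 1e-5), (250, 1e-8)]:
        assert learning_rate(cfg, epoch) == pytest.approx(expected, rel=1e-12)


def test_training_is_seed_deterministic():
    train = make_sequences(n_per_class=12, n_seizures=3, separation=1.0, seed=1)
    val = make_sequences(n_per_class=6, n_seizures=3, separation=1.0, seed=2)
    cfg = TrainConfig(hidden_size=8, max_iterations=20, seed=11)
    m1, log1 = train_lstm(train, val, cfg)
    m2, log2 = train_lstm(train, val, cfg)
    for k in m1.weights():
        assert np.array_equal(m1.weights()[k], m2.weights()[k])
    assert log1["train_loss"].tolist() == log2["train_loss"].tolist()


def test_lstm_learns_separable_clusters():
    train = make_sequences(n_per_class=24, n_seizures=3, separation=1.5, seed=1)
    val = make_sequences(n_per_class=12, n_seizures=3, separation=1.5, seed=2)
    cfg = TrainConfig(hidden_size=20, max_iterations=300, seed=0)
    model, log = train_lstm(train, val, cfg)
    assert lstm_accuracy(model, val) >= 0.9
    assert log["iteration"].iloc[-1] == 300


def test_chance_level_on_permuted_labels():
    """Permutation control: shuffling labels across the whole dataset breaks
    the feature-label association, so held-out accuracy sits at chance."""
    rng = np.random.default_rng(0)
    accs = []
    for seed in range(3):
        allsamp = make_sequences(n_per_class=48, n_seizures=3, separation=1.5, seed=3)
        labels = np.array([s.label for s in allsamp])
        for s, lab in zip(allsamp, rng.permutation(labels)):
            s.label = int(lab)
        train, heldout = allsamp[:48], allsamp[48:]
        cfg = TrainConfig(hidden_size=10, max_iterations=200, seed=seed)
        model, _ = train_lstm(train, train, cfg)
        accs.append(lstm_accuracy(model, heldout))
    assert abs(np.mean(accs) - 0.5) <= 0.10


def test_mlp_baseline_learns_and_has_16_inputs():
    from preictal.dataset import assemble_sequences

    table = make_feature_table(n_hours_per_class=5, n_channels=16, seed=3,
                               class_shift=0.5)
    samples_plan = split_by_seizure(assemble_sequences(table))
    rep = mlp_baseline_train_eval(table, samples_plan, feature_choice="e1", seed=0)
    assert rep.p + rep.n == 2 * 120  # one test seizure-pair, per-window scoring
    assert rep.accuracy >= 80.0
    with pytest.raises(ValueError, match="feature_choice"):
        mlp_baseline_train_eval(table, samples_plan, feature_choice="power")
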