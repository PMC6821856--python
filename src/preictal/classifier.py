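"""Sequence classifiers: a single-layer LSTM and an MLP per-window baseline.

The LSTM takes 10 sequential 32-feature vectors (5 minutes of bispectral
entropies), runs them through one unidirectional layer of 100 hidden units,
and classifies from the 10th step's hidden state through a fully connected
layer and softmax. Training minimizes cross-entropy on minibatches of 24
sequences with Adam at an initial learning rate of 1e-3 dropped by a factor
of 0.1 every 50 epochs, for a capped number of minibatch iterations and no
early stopping. The network and backpropagation-through-time are implemented
directly in numpy; the forward pass is validated in the test suite against
an independently coded gate-by-gate recursion and a numerical gradient.

The MLP baseline classifies a single 30-s window from one feature per
channel (a 16-vector) through hidden layers of 30, 60 and 30 ReLU units;
it trains with SGD and early-stops on the validation slice.

Gate layout: the stacked weight matrices hold the input (i), forget (f),
candidate (g) and output (o) blocks in that order, each of ``hidden`` rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SequenceSample, sequence_arrays
from .evaluate import MetricsReport, score


@dataclass
class TrainConfig:
    initial_lr: float = 1e-3
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 50  # epochs (full passes)
    batch_size: int = 24
    max_iterations: int = 4800  # minibatch updates
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    hidden_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.initial_lr, self.batch_size, self.max_iterations, self.hidden_size) <= 0:
            raise ValueError("training hyperparameters must be positive")


def learning_rate(cfg: TrainConfig, epoch: int) -> float:
    """Step schedule: initial_lr * decay^floor(epoch / decay_every)."""
    return cfg.initial_lr * cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)


@dataclass
class LstmModel:
    """Weights of the single-layer LSTM classifier.

    W: (4h, input) input kernels; U: (4h, h) recurrent kernels; b: (4h,)
    biases; w_fc/b_fc: the hidden -> 2 classification head.
    """

    W: np.ndarray
    U: np.ndarray
    b: np.ndarray
    w_fc: np.ndarray
    b_fc: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.U.shape[1]

    @property
    def input_size(self) -> int:
        return self.W.shape[1]

    def weights(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "U": self.U, "b": self.b, "w_fc": self.w_fc, "b_fc": self.b_fc}


def init_lstm(input_size: int = 32, hidden_size: int = 100, seed: int = 0) -> LstmModel:
    """Glorot-uniform kernels, zero biases with the forget-gate bias at 1."""
    rng = np.random.default_rng(seed)

    def glorot(shape, fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    h = hidden_size
    W = glorot((4 * h, input_size), input_size, h)
    U = glorot((4 * h, h), h, h)
    b = np.zeros(4 * h)
    b[h : 2 * h] = 1.0  # forget gate open at init
    w_fc = glorot((2, h), h, 2)
    b_fc = np.zeros(2)
    return LstmModel(W=W, U=U, b=b, w_fc=w_fc, b_fc=b_fc)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _forward_full(X: np.ndarray, model: LstmModel):
    """Batched forward pass keeping per-step activations for BPTT.

    X: (batch, T, input). Returns (probs, cache).
    """
    B, T, _ = X.shape
    h = model.hidden_size
    hs = np.zeros((B, h))
    cs = np.zeros((B, h))
    cache = []
    for t in range(T):
        z = X[:, t] @ model.W.T + hs @ model.U.T + model.b
        i = _sigmoid(z[:, :h])
        f = _sigmoid(z[:, h : 2 * h])
        g = np.tanh(z[:, 2 * h : 3 * h])
        o = _sigmoid(z[:, 3 * h :])
        c_new = f * cs + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache.append((X[:, t], hs, cs, i, f, g, o, c_new, tc))
        hs, cs = h_new, c_new
    logits = hs @ model.w_fc.T + model.b_fc
    probs = _softmax(logits)
    return probs, (cache, hs)


def lstm_forward(seq: np.ndarray | SequenceSample, model: LstmModel) -> np.ndarray:
    """Class probabilities (interictal, preictal) for one 10 x 32 sequence."""
    X = seq.matrix if isinstance(seq, SequenceSample) else np.asarray(seq, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.input_size:
        raise ValueError(f"expected (T, {model.input_size}) input, got {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input sequence")
    probs, _ = _forward_full(X[None], model)
    return probs[0]


def _backward(X, y, model: LstmModel, probs, cache_state):
    """Cross-entropy gradients via backpropagation through time."""
    cache, h_last = cache_state
    B = X.shape[0]
    h = model.hidden_size
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads = {
        "w_fc": dlogits.T @ h_last,
        "b_fc": dlogits.sum(axis=0),
        "W": np.zeros_like(model.W),
        "U": np.zeros_like(model.U),
        "b": np.zeros_like(model.b),
    }
    dh = dlogits @ model.w_fc
    dc = np.zeros((B, h))
    for t in range(len(cache) - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, c_new, tc = cache[t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc**2)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        grads["W"] += dz.T @ x_t
        grads["U"] += dz.T @ h_prev
        grads["b"] += dz.sum(axis=0)
        dh = dz @ model.U
        dc = dc * f
    return grads


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-300, None)
    return float(-np.log(p).mean())


def lstm_predict(model: LstmModel, samples: list[SequenceSample]) -> np.ndarray:
    X, _ = sequence_arrays(samples)
    probs, _ = _forward_full(X, model)
    return probs.argmax(axis=1)


def lstm_accuracy(model: LstmModel, samples: list[SequenceSample]) -> float:
    X, y = sequence_arrays(samples)
    probs, _ = _forward_full(X, model)
    return float((probs.argmax(axis=1) == y).mean())


def train_lstm(
    train: list[SequenceSample],
    val: list[SequenceSample],
    cfg: TrainConfig | None = None,
) -> tuple[LstmModel, pd.DataFrame]:
    """Train the LSTM; returns the model and a per-iteration training log.

    Minibatches are reshuffled each epoch (seeded); the iteration counter is
    the number of minibatch updates and training stops at
    ``cfg.max_iterations`` — no early stopping. The log has one row per
    iteration (epoch, lr, train loss) with validation accuracy filled in on
    the last iteration of each epoch.
    """
    if cfg is None:
        cfg = TrainConfig()
    if not train or not val:
        raise ValueError("train and validation sets must be nonempty")
    X_tr, y_tr = sequence_arrays(train)
    model = init_lstm(input_size=X_tr.shape[2], hidden_size=cfg.hidden_size, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    m = {k: np.zeros_like(v) for k, v in model.weights().items()}
    v = {k: np.zeros_like(val_) for k, val_ in model.weights().items()}
    log_rows = []
    iteration = 0
    epoch = 0
    while iteration < cfg.max_iterations:
        order = rng.permutation(len(X_tr))
        lr = learning_rate(cfg, epoch)
        for b0 in range(0, len(order), cfg.batch_size):
            if iteration >= cfg.max_iterations:
                break
            idx = order[b0 : b0 + cfg.batch_size]
            Xb, yb = X_tr[idx], y_tr[idx]
            probs, state = _forward_full(Xb, model)
            loss = _cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at iteration {iteration} (non-finite loss); "
                    f"log has {len(log_rows)} entries"
                )
            grads = _backward(Xb, yb, model, probs, state)
            iteration += 1
            weights = model.weights()
            for k, g in grads.items():
                m[k] = cfg.adam_beta1 * m[k] + (1 - cfg.adam_beta1) * g
                v[k] = cfg.adam_beta2 * v[k] + (1 - cfg.adam_beta2) * g**2
                mhat = m[k] / (1 - cfg.adam_beta1**iteration)
                vhat = v[k] / (1 - cfg.adam_beta2**iteration)
                weights[k] -= lr * mhat / (np.sqrt(vhat) + cfg.adam_eps)
            log_rows.append(
                {"iteration": iteration, "epoch": epoch, "lr": lr,
                 "train_loss": loss, "val_accuracy": np.nan}
            )
        if log_rows:
            log_rows[-1]["val_accuracy"] = lstm_accuracy(model, val)
        epoch += 1
    return model, pd.DataFrame(log_rows)


def evaluate_lstm(
    model: LstmModel, samples: list[SequenceSample], split_name: str = "test"
) -> MetricsReport:
    X, y = sequence_arrays(samples)
    probs, _ = _forward_full(X, model)
    subjects = sorted({s.subject_id for s in samples})
    return score(
        probs.argmax(axis=1), y, split_name=split_name,
        subject_id=subjects[0] if len(subjects) == 1 else "+".join(subjects),
    )


# ---------------------------------------------------------------------------
# MLP per-window baseline
# ---------------------------------------------------------------------------


def mlp_baseline_train_eval(
    features: pd.DataFrame,
    split_plan,
    feature_choice: str = "e1",
    seed: int = 0,
    max_epochs: int = 200,
    patience: int = 10,
) -> MetricsReport:
    """Train the per-window MLP on one bispectral feature and score the test split.

    Input per window is the 16-vector of the chosen feature (one per
    channel); windows inherit their hour's seizure split assignment. Early
    stopping monitors validation accuracy with the given patience.
    """
    from sklearn.neural_network import MLPClassifier

    if feature_choice not in ("e1", "e2"):
        raise ValueError(f"feature_choice must be 'e1' or 'e2', got {feature_choice!r}")
    channels = sorted(features["channel_label"].unique())
    wide = features.pivot_table(
        index=["subject_id", "seizure_index", "hour_id", "class_label", "window_index"],
        columns="channel_label",
        values=feature_choice,
    )[channels].reset_index()
    X = wide[channels].to_numpy(dtype=np.float64)
    y = (wide["class_label"] == "preictal").to_numpy(dtype=np.int64)
    split_of = np.array(
        [
            split_plan.assignment[(str(sub), int(k))]
            for sub, k in zip(wide["subject_id"], wide["seizure_index"])
        ]
    )
    masks = {name: split_of == name for name in ("train", "val", "test")}
    if not all(m.any() for m in masks.values()):
        raise ValueError("every split must contain windows")
    mu, sd = X[masks["train"]].mean(axis=0), X[masks["train"]].std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd  # feature scaling fit on the training slice only
    clf = MLPClassifier(
        hidden_layer_sizes=(30, 60, 30),
        activation="relu",
        solver="sgd",
        learning_rate_init=1e-3,
        random_state=seed,
        max_iter=1,
        warm_start=False,
    )
    best_val, best_coefs, since_best = -np.inf, None, 0
    rng = np.random.default_rng(seed)
    tr_idx = np.flatnonzero(masks["train"])
    batch = 24
    for _epoch in range(max_epochs):
        order = rng.permutation(tr_idx)
        for b0 in range(0, len(order), batch):
            idx = order[b0 : b0 + batch]
            clf.partial_fit(Xs[idx], y[idx], classes=[0, 1])
        val_acc = float((clf.predict(Xs[masks["val"]]) == y[masks["val"]]).mean())
        if val_acc > best_val + 1e-12:
            best_val, since_best = val_acc, 0
            best_coefs = ([c.copy() for c in clf.coefs_], [b.copy() for b in clf.intercepts_])
        else:
            since_best += 1
            if since_best >= patience:
                break
    if best_coefs is not None:
        clf.coefs_, clf.intercepts_ = best_coefs
    preds = clf.predict(Xs[masks["test"]])
    subjects = sorted(set(wide["subject_id"]))
    return score(
        preds, y[masks["test"]], split_name="test",
        subject_id=subjects[0] if len(subjects) == 1 else "+".join(subjects),
    )
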