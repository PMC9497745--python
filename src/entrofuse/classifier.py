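"""Sequence-to-sequence LSTM / BiLSTM emotion classifiers in NumPy.

One training sequence is a subject's full window sequence (per-window
entropy features in, per-window emotion label out), so the recurrence can
carry emotional context across clips.  The cell is the standard LSTM:
sigmoid input/forget/output gates, tanh candidate, element-wise cell-state
update; the bidirectional variant runs a second cell over the reversed
sequence and concatenates the two hidden states before the dense softmax
output layer.  Training is mini-batch Adam over subject sequences with
gradient clipping, optional input dropout, and optional early stopping on
one held-out training subject (monitored by validation accuracy).

Everything is plain NumPy, so training is bit-reproducible for a fixed
seed on a single thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .entropy import FeatureMatrix
from .errors import ConfigurationError, EmptyInputError, ShapeError
from .fusion import LabeledSequence, fuse, normalize, split_subjects

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "train",
    "predict",
    "predict_proba",
    "evaluate",
    "run_benchmark",
    "n_parameters",
]

#: Fixed class order: index 0 -> negative, 1 -> neutral, 2 -> positive.
CLASS_CODES = np.array([-1, 0, 1])


@dataclass(frozen=True)
class ModelConfig:
    architecture: str = "bilstm"
    hidden_units: int = 64  # per direction
    input_dim: int | None = None  # inferred from data when None
    n_classes: int = 3
    learning_rate: float = 1e-3
    max_epochs: int = 100
    batch_size: int | None = None  # None: all sequences in one batch
    seed: int = 0
    patience: int = 10
    clip_norm: float = 5.0
    weight_decay: float = 0.0  # decoupled L2 (AdamW-style)
    input_dropout: float = 0.0  # per-element input dropout during training
    early_stopping: bool = True  # hold out one training subject and
    # restore the parameters with the best validation accuracy; when off,
    # train on all subjects for the full epoch budget

    def __post_init__(self):
        if self.architecture not in ("lstm", "bilstm"):
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if self.hidden_units < 1:
            raise ConfigurationError("hidden_units must be >= 1")
        if self.n_classes != 3:
            raise ConfigurationError("classifier is fixed to 3 emotion classes")


@dataclass
class TrainedModel:
    architecture: str
    params: dict
    config: ModelConfig
    loss_log: list = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.params["Wx_f"].shape[0]

    @property
    def hidden_units(self) -> int:
        return self.params["Wh_f"].shape[0]


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _init_params(rng: np.random.Generator, d: int, h: int, n_classes: int,
                 bidirectional: bool) -> dict:
    def glorot(fan_in, fan_out):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, (fan_in, fan_out))

    def cell():
        wx = glorot(d, 4 * h)
        wh = glorot(h, 4 * h)
        b = np.zeros(4 * h)
        b[h:2 * h] = 1.0  # forget-gate bias: remember by default
        return wx, wh, b

    params = {}
    params["Wx_f"], params["Wh_f"], params["b_f"] = cell()
    dirs = 1
    if bidirectional:
        params["Wx_b"], params["Wh_b"], params["b_b"] = cell()
        dirs = 2
    params["Wout"] = glorot(dirs * h, n_classes)
    params["bout"] = np.zeros(n_classes)
    return params


def _lstm_forward(x, mask, wx, wh, b):
    """Run one direction over x (T, B, D); mask (T, B) freezes padded steps.

    Returns the hidden sequence (T, B, H) and the cache needed for BPTT.
    """
    t_len, b_sz, _ = x.shape
    h_dim = wh.shape[0]
    xp = x @ wx + b  # (T, B, 4H): one large matmul instead of T small ones
    hs = np.zeros((t_len, b_sz, h_dim))
    cache = {k: np.zeros((t_len, b_sz, h_dim)) for k in
             ("i", "f", "g", "o", "tanh_c", "c_prev", "h_prev")}
    h = np.zeros((b_sz, h_dim))
    c = np.zeros((b_sz, h_dim))
    for t in range(t_len):
        m = mask[t][:, None]
        z = xp[t] + h @ wh
        i = _sigmoid(z[:, :h_dim])
        f = _sigmoid(z[:, h_dim:2 * h_dim])
        g = np.tanh(z[:, 2 * h_dim:3 * h_dim])
        o = _sigmoid(z[:, 3 * h_dim:])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t] = i, f, g, o
        cache["tanh_c"][t] = tanh_c
        cache["c_prev"][t] = c
        cache["h_prev"][t] = h
        c = m * c_new + (1.0 - m) * c
        h = m * h_new + (1.0 - m) * h
        hs[t] = h
    return hs, cache


def _lstm_backward(dhs, x, mask, wx, wh, cache):
    """BPTT through one direction; returns gradients and dX."""
    t_len, b_sz, _ = x.shape
    h_dim = wh.shape[0]
    d_wx = np.zeros_like(wx)
    d_wh = np.zeros_like(wh)
    d_b = np.zeros(4 * h_dim)
    dx = np.zeros_like(x)
    dh_next = np.zeros((b_sz, h_dim))
    dc_next = np.zeros((b_sz, h_dim))
    for t in range(t_len - 1, -1, -1):
        m = mask[t][:, None]
        i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
        tanh_c = cache["tanh_c"][t]
        c_prev = cache["c_prev"][t]
        h_prev = cache["h_prev"][t]
        dh = dhs[t] + dh_next
        dh_new = dh * m
        dh_prev = dh * (1.0 - m)
        dc_new = dc_next * m
        dc_prev = dc_next * (1.0 - m)
        do = dh_new * tanh_c
        dc_new = dc_new + dh_new * o * (1.0 - tanh_c ** 2)
        df = dc_new * c_prev
        di = dc_new * g
        dg = dc_new * i
        dc_prev = dc_prev + dc_new * f
        dz = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g ** 2),
            do * o * (1.0 - o),
        ], axis=1)
        d_wx += x[t].T @ dz
        d_wh += h_prev.T @ dz
        d_b += dz.sum(axis=0)
        dx[t] = dz @ wx.T
        dh_next = dh_prev + dz @ wh.T
        dc_next = dc_prev
    return d_wx, d_wh, d_b, dx


def _forward(params, x, mask, bidirectional):
    hs_f, cache_f = _lstm_forward(x, mask, params["Wx_f"], params["Wh_f"],
                                  params["b_f"])
    if bidirectional:
        hs_b_rev, cache_b = _lstm_forward(x[::-1], mask[::-1], params["Wx_b"],
                                          params["Wh_b"], params["b_b"])
        hs = np.concatenate([hs_f, hs_b_rev[::-1]], axis=2)
    else:
        cache_b = None
        hs = hs_f
    logits = hs @ params["Wout"] + params["bout"]
    z = logits - logits.max(axis=2, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=2, keepdims=True)
    return probs, hs, cache_f, cache_b


def _loss_and_grads(params, x, mask, y_onehot, bidirectional):
    probs, hs, cache_f, cache_b = _forward(params, x, mask, bidirectional)
    n_valid = mask.sum()
    eps = 1e-12
    loss = -np.sum(mask[..., None] * y_onehot * np.log(probs + eps)) / n_valid
    dlogits = (probs - y_onehot) * mask[..., None] / n_valid
    grads = {}
    t_len, b_sz, _ = x.shape
    h2 = hs.shape[2]
    grads["Wout"] = hs.reshape(-1, h2).T @ dlogits.reshape(-1, probs.shape[2])
    grads["bout"] = dlogits.sum(axis=(0, 1))
    dhs = dlogits @ params["Wout"].T
    h_dim = params["Wh_f"].shape[0]
    d_wx, d_wh, d_b, _ = _lstm_backward(dhs[:, :, :h_dim], x, mask,
                                        params["Wx_f"], params["Wh_f"], cache_f)
    grads["Wx_f"], grads["Wh_f"], grads["b_f"] = d_wx, d_wh, d_b
    if bidirectional:
        dhs_b = dhs[:, :, h_dim:][::-1]
        d_wx, d_wh, d_b, _ = _lstm_backward(dhs_b, x[::-1], mask[::-1],
                                            params["Wx_b"], params["Wh_b"],
                                            cache_b)
        grads["Wx_b"], grads["Wh_b"], grads["b_b"] = d_wx, d_wh, d_b
    return loss, grads


def _stack_sequences(data):
    """Pad sequences to a common length -> x (T, B, D), mask, y (T, B)."""
    dims = {fm.n_rows for fm, _ in data}
    if len(dims) != 1:
        raise ShapeError(f"inconsistent feature dimensions: {sorted(dims)}")
    for fm, seq in data:
        if len(seq) != fm.n_windows:
            raise ShapeError(
                f"{len(seq)} labels for {fm.n_windows} windows "
                f"(subject {fm.subject_id})")
    d = dims.pop()
    t_max = max(fm.n_windows for fm, _ in data)
    b = len(data)
    x = np.zeros((t_max, b, d))
    mask = np.zeros((t_max, b))
    y = np.zeros((t_max, b), dtype=int)
    for k, (fm, seq) in enumerate(data):
        t = fm.n_windows
        x[:t, k, :] = fm.values.T
        mask[:t, k] = 1.0
        y[:t, k] = np.searchsorted(CLASS_CODES, seq.labels)
    return x, mask, y


def _onehot(y, n_classes):
    out = np.zeros(y.shape + (n_classes,))
    np.put_along_axis(out, y[..., None], 1.0, axis=-1)
    return out


class _Adam:
    def __init__(self, params, lr, weight_decay=0.0):
        self.lr = lr
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads, clip_norm):
        gnorm = np.sqrt(sum(float(np.sum(g ** 2)) for g in grads.values()))
        scale = min(1.0, clip_norm / (gnorm + 1e-12))
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k in params:
            g = grads[k] * scale
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * (mhat / (np.sqrt(vhat) + eps)
                                    + self.weight_decay * params[k])


def train(train_data, config: ModelConfig = ModelConfig()) -> TrainedModel:
    """Fit an LSTM/BiLSTM on full-subject window sequences.

    With early stopping enabled and four or more training sequences, one
    sequence (seeded choice) is held out and training stops once its
    accuracy has not improved for ``patience`` epochs, restoring the
    best-validation parameters; with fewer sequences the training loss is
    monitored instead.  With ``early_stopping=False`` all sequences are
    used and the final parameters after ``max_epochs`` are kept.
    """
    train_data = list(train_data)
    if not train_data:
        raise EmptyInputError("no training sequences")
    dims = {fm.n_rows for fm, _ in train_data}
    if len(dims) != 1:
        raise ShapeError(f"inconsistent feature dimensions: {sorted(dims)}")
    rng = np.random.default_rng(config.seed)
    bidirectional = config.architecture == "bilstm"

    if config.early_stopping and len(train_data) >= 4:
        val_idx = int(rng.integers(len(train_data)))
        val_data = [train_data[val_idx]]
        fit_data = [s for k, s in enumerate(train_data) if k != val_idx]
    else:
        val_data = None
        fit_data = train_data

    x, mask, y = _stack_sequences(fit_data)
    d = x.shape[2]
    if config.input_dim is not None and config.input_dim != d:
        raise ShapeError(f"config.input_dim={config.input_dim} but data has {d}")
    y1h = _onehot(y, config.n_classes)
    if val_data is not None:
        xv, maskv, yv = _stack_sequences(val_data)
        yv1h = _onehot(yv, config.n_classes)

    params = _init_params(rng, d, config.hidden_units, config.n_classes,
                          bidirectional)
    opt = _Adam(params, config.learning_rate, config.weight_decay)
    loss_log = []
    best = {k: v.copy() for k, v in params.items()}
    best_monitor = np.inf
    stale = 0
    n_seq = x.shape[1]
    bs = config.batch_size or n_seq
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n_seq)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n_seq, bs):
            sel = order[start:start + bs]
            xb = x[:, sel]
            if config.input_dropout > 0.0:
                # feature bagging: random input deletion forces the model to
                # spread weight across redundant feature rows, which is what
                # lets a fused feature set beat its best member
                keep = 1.0 - config.input_dropout
                xb = xb * (rng.random(xb.shape) < keep) / keep
            loss, grads = _loss_and_grads(params, xb, mask[:, sel],
                                          y1h[:, sel], bidirectional)
            opt.step(params, grads, config.clip_norm)
            epoch_loss += loss
            n_batches += 1
        epoch_loss /= n_batches
        if val_data is not None:
            # monitor validation *error*: accuracy tracks the deployment
            # metric, unlike the loss, which rises with overconfidence
            # long before accuracy degrades
            probs, _, _, _ = _forward(params, xv, maskv, bidirectional)
            hits = (np.argmax(probs, axis=2) == yv) * maskv
            monitor = 1.0 - float(hits.sum() / maskv.sum())
        else:
            monitor = epoch_loss
        loss_log.append({"train_loss": float(epoch_loss),
                         "monitor": float(monitor)})
        if not config.early_stopping:
            continue
        if monitor < best_monitor - 1e-6:
            best_monitor = monitor
            best = {k: v.copy() for k, v in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    final = params if not config.early_stopping else best
    return TrainedModel(architecture=config.architecture, params=final,
                        config=config, loss_log=loss_log)


def predict_proba(model: TrainedModel, fm: FeatureMatrix) -> np.ndarray:
    """Per-window class posteriors, shape (n_windows, 3)."""
    if fm.n_rows != model.input_dim:
        raise ShapeError(
            f"feature dim {fm.n_rows} != model input dim {model.input_dim}")
    x = fm.values.T[:, None, :]
    mask = np.ones((fm.n_windows, 1))
    probs, _, _, _ = _forward(model.params, x, mask,
                              model.architecture == "bilstm")
    return probs[:, 0, :]


def predict(model: TrainedModel, fm: FeatureMatrix) -> LabeledSequence:
    """Argmax labels in {-1, 0, 1}; ties resolve to the lowest class code."""
    probs = predict_proba(model, fm)
    labels = CLASS_CODES[np.argmax(probs, axis=1)]
    clip_index = fm.clip_index if fm.clip_index is not None \
        else np.zeros(fm.n_windows, dtype=int)
    return LabeledSequence(labels=labels, window_times=fm.window_times,
                           clip_index=clip_index)


def evaluate(model: TrainedModel, test_data) -> dict:
    """Per-subject window accuracy, their unweighted mean, and a 3x3
    confusion matrix (rows: true -1/0/1, columns: predicted)."""
    per_subject = {}
    confusion = np.zeros((3, 3), dtype=int)
    for fm, seq in test_data:
        pred = predict(model, fm)
        acc = float(np.mean(pred.labels == seq.labels))
        per_subject[fm.subject_id or f"seq{len(per_subject)}"] = acc
        for true_lab, pred_lab in zip(seq.labels, pred.labels):
            confusion[true_lab + 1, pred_lab + 1] += 1
    return {
        "per_subject": per_subject,
        "mean_accuracy": float(np.mean(list(per_subject.values()))),
        "confusion": confusion,
    }


def n_parameters(model: TrainedModel) -> int:
    return int(sum(v.size for v in model.params.values()))


BENCHMARK_FEATURE_SETS = ("ae", "fe", "re", "de", "mse", "all")


def run_benchmark(cohort, feature_sets=BENCHMARK_FEATURE_SETS,
                  architectures=("lstm", "bilstm"),
                  config: ModelConfig = ModelConfig(), n_test: int = 5,
                  seed: int = 0) -> pd.DataFrame:
    """Train/evaluate every (architecture, feature set) cell on one cohort.

    ``cohort`` is a list of dicts with keys ``subject_id``, ``features``
    (mapping feature name -> FeatureMatrix) and ``labels``.  Each subject's
    matrices are min-max normalised subject-wise; "all" fuses the five
    entropy features (540 rows for 12 channels).  Subjects are split
    ``len - n_test`` train / ``n_test`` test under ``seed``; the same split
    is used for every cell so the comparison is paired.
    """
    cohort = list(cohort)
    if not cohort:
        raise EmptyInputError("empty cohort")
    available = set(cohort[0]["features"])
    for fs in feature_sets:
        needed = available if fs == "all" else {fs}
        missing = needed - available
        if missing:
            raise ConfigurationError(f"feature set {fs!r} missing {missing}")

    ids = [s["subject_id"] for s in cohort]
    split = split_subjects(ids, n_test=n_test, seed=seed)
    by_id = {s["subject_id"]: s for s in cohort}

    def matrix_for(subj, fs):
        if fs == "all":
            fused = fuse([subj["features"][f] for f in
                          ("mse", "ae", "fe", "re", "de")
                          if f in subj["features"]])
            return normalize(fused)
        return normalize(subj["features"][fs])

    results = pd.DataFrame(index=list(architectures),
                           columns=list(feature_sets), dtype=float)
    for fs in feature_sets:
        train_set = [(matrix_for(by_id[i], fs), by_id[i]["labels"])
                     for i in split.train_ids]
        test_set = [(matrix_for(by_id[i], fs), by_id[i]["labels"])
                    for i in split.test_ids]
        for arch in architectures:
            cfg = replace(config, architecture=arch, seed=seed)
            model = train(train_set, cfg)
            report = evaluate(model, test_set)
            results.loc[arch, fs] = report["mean_accuracy"]
    return results
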