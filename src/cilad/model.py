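"""The two-pathway CILAD-Net classifier: build, train, predict, split, CV.

Pathway 1 stacks conv(32) -> maxpool -> dropout -> conv(64) -> maxpool -> a
1-D inception block -> LSTM(64) (final hidden state).  Pathway 2 ("angle"
branch) is conv(128) -> ReLU -> maxpool -> batchnorm, flattened.  Both are
concatenated into fully connected layers with dropout and a softmax output.
Inputs are 1-D rows: raw ECG beats or selected feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .datatypes import BeatTable, FeatureTable
from .metrics import ClassificationReport, classification_report
from .nn import (Adam, BatchNorm1D, Conv1D, Dense, Dropout, Inception1D, LSTM,
                 MaxPool1D, Tensor, concat, no_grad)


@dataclass
class CiladConfig:
    """Architecture and training hyperparameters (all config-exposed)."""

    input_len: int
    n_classes: int
    filters1: int = 32
    filters2: int = 64
    kernel: int = 3
    pool: int = 2
    dropout: float = 0.5
    inception_branch: int = 16
    lstm_units: int = 64
    path2_filters: int = 128
    fc: tuple[int, ...] = (128, 64)
    head_dropout: float = 0.5
    optimizer: str = "adam"
    lr: float = 1e-3
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1 and 0 <= self.head_dropout < 1):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


def _path1_out_len(L: int, k: int, p: int) -> int:
    L = L - k + 1          # conv 1
    if L < 1:
        return 0
    L = L // p             # pool 1
    if L < 1:
        return 0
    L = L - k + 1          # conv 2
    if L < 1:
        return 0
    L = L // p             # pool 2
    return L               # inception preserves length


def _min_input_len(k: int, p: int) -> int:
    for L in range(1, 1024):
        if _path1_out_len(L, k, p) >= 1 and (L - k + 1) // p >= 1:
            return L
    raise ValueError("no admissible input length below 1024")


class CiladNet:
    """Built network plus (optional) input-standardization statistics."""

    def __init__(self, config: CiladConfig):
        c = config
        L1 = _path1_out_len(c.input_len, c.kernel, c.pool)
        L2 = (c.input_len - c.kernel + 1) // c.pool
        if L1 < 1 or L2 < 1:
            raise ValueError(
                f"input_len={c.input_len} too short for the pooling chain; "
                f"minimal admissible length is {_min_input_len(c.kernel, c.pool)}")
        rng = np.random.default_rng(c.seed)
        self.config = c
        # pathway 1
        self.conv1 = Conv1D(1, c.filters1, c.kernel, rng)
        self.pool1 = MaxPool1D(c.pool)
        self.drop1 = Dropout(c.dropout)
        self.conv2 = Conv1D(c.filters1, c.filters2, c.kernel, rng)
        self.pool2 = MaxPool1D(c.pool)
        self.inception = Inception1D(c.filters2, c.inception_branch, rng)
        self.lstm = LSTM(4 * c.inception_branch, c.lstm_units, rng)
        # pathway 2 (angle branch)
        self.conv3 = Conv1D(1, c.path2_filters, c.kernel, rng)
        self.pool3 = MaxPool1D(c.pool)
        self.bn = BatchNorm1D(c.path2_filters)
        # head
        width = c.lstm_units + c.path2_filters * L2
        self.head: list = []
        for size in c.fc:
            self.head.append(Dense(width, size, rng))
            width = size
        self.head_drop = Dropout(c.head_dropout)
        self.out = Dense(width, c.n_classes, rng)
        self.input_mean: np.ndarray | None = None
        self.input_sd: np.ndarray | None = None

    # ------------------------------------------------------------------
    def params(self) -> list[Tensor]:
        ps = (self.conv1.params() + self.conv2.params() + self.inception.params()
              + self.lstm.params() + self.conv3.params() + self.bn.params())
        for layer in self.head:
            ps += layer.params()
        return ps + self.out.params()

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.input_mean is not None:
            X = (X - self.input_mean) / self.input_sd
        return X

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Logits for a batch of 1-D rows."""
        rng = rng or np.random.default_rng(0)
        x = Tensor(self._prepare(X).reshape(len(X), 1, -1))
        # pathway 1
        h = self.conv1(x).relu()
        h = self.pool1(h)
        h = self.drop1(h, train, rng)
        h = self.conv2(h).relu()
        h = self.pool2(h)
        h = self.inception(h)
        h = h.transpose(0, 2, 1)  # (B, T, C): channel sequence as time steps
        h = self.lstm(h)
        # pathway 2
        a = self.conv3(x).relu()
        a = self.pool3(a)
        a = self.bn(a, train)
        a = a.reshape(len(X), -1)
        z = concat([h, a], axis=1)
        for layer in self.head:
            z = layer(z).relu()
            z = self.head_drop(z, train, rng)
        return self.out(z)


def build_cilad(config: CiladConfig) -> CiladNet:
    """Instantiate CILAD-Net, validating the pooling-chain shape arithmetic."""
    return CiladNet(config)


def train_model(model: CiladNet, X, y, val: tuple | None = None,
                config: CiladConfig | None = None) -> pd.DataFrame:
    """Train by minimizing cross-entropy with Adam; returns per-epoch history
    (train/val loss and accuracy).  Zero epochs leaves the model unchanged."""
    c = config or model.config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    present = np.unique(y)
    if set(range(c.n_classes)) - set(present.tolist()):
        raise ValueError("every class in [0, n_classes) must appear in training labels")
    if c.standardize and model.input_mean is None:
        model.input_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        model.input_sd = sd
    rows = []
    if c.epochs == 0:
        return pd.DataFrame(rows, columns=["epoch", "train_loss", "train_acc",
                                           "val_loss", "val_acc"])
    rng = np.random.default_rng(c.seed + 1)
    opt = Adam(model.params(), lr=c.lr)
    onehot = np.eye(c.n_classes)
    for epoch in range(c.epochs):
        order = rng.permutation(len(X))
        losses, correct = [], 0
        for start in range(0, len(X), c.batch_size):
            idx = order[start:start + c.batch_size]
            logits = model.forward(X[idx], train=True, rng=rng)
            logp = logits.log_softmax(axis=1)
            loss = -(logp * Tensor(onehot[y[idx]])).sum() * (1.0 / len(idx))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "train_acc": correct / len(X), "val_loss": np.nan, "val_acc": np.nan}
        if val is not None:
            vl, va = evaluate_loss(model, val[0], val[1], c.n_classes)
            row["val_loss"], row["val_acc"] = vl, va
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_loss(model: CiladNet, X, y, n_classes: int) -> tuple[float, float]:
    proba, labels = predict(model, X)
    y = np.asarray(y, dtype=int)
    eps = 1e-12
    loss = float(-np.mean(np.log(proba[np.arange(len(y)), y] + eps)))
    acc = float(np.mean(labels == y))
    return loss, acc


def predict(model: CiladNet, X, batch_size: int = 256):
    """Per-class probabilities (rows sum to 1) and argmax labels."""
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        return (np.zeros((0, model.config.n_classes)), np.zeros(0, dtype=int))
    probs = []
    with no_grad():
        for start in range(0, len(X), batch_size):
            logits = model.forward(X[start:start + batch_size], train=False)
            lp = logits.log_softmax(axis=1).data
            probs.append(np.exp(lp))
    proba = np.vstack(probs)
    return proba, proba.argmax(axis=1)


# --------------------------------------------------------------------------
# Splitting and cross-validation
# --------------------------------------------------------------------------

@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_data(table, spec: SplitSpec):
    """Deterministic train/test split of a BeatTable or FeatureTable."""
    labels = table.labels
    idx = np.arange(len(labels))
    train_idx, test_idx = train_test_split(
        idx, train_size=spec.train_fraction, random_state=spec.seed,
        shuffle=True, stratify=labels if spec.stratified else None)
    return table.subset(np.sort(train_idx)), table.subset(np.sort(test_idx))


@dataclass
class CVResult:
    fold_reports: list[ClassificationReport]
    fold_test_indices: list[np.ndarray]
    predictions: np.ndarray          # out-of-fold prediction for every sample
    summary: pd.DataFrame            # metric -> mean, sd

    @property
    def pooled_accuracy(self) -> float:
        return float(self._pooled_acc)

    _pooled_acc: float = 0.0


def crossvalidate(table, k: int, config: CiladConfig,
                  averaging: str = "macro") -> CVResult:
    """Stratified k-fold CV: each sample is tested exactly once; the summary
    aggregates all nine metrics as mean +/- sd over folds."""
    X = table.signals if isinstance(table, BeatTable) else table.values
    y = np.asarray(table.labels, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    reports, fold_idx = [], []
    preds = np.full(len(y), -1, dtype=int)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        cfg = CiladConfig(**{**config.__dict__, "seed": config.seed + fold})
        net = build_cilad(cfg)
        train_model(net, X[tr], y[tr], config=cfg)
        _, labels = predict(net, X[te])
        preds[te] = labels
        reports.append(classification_report(y[te], labels, averaging=averaging))
        fold_idx.append(te)
    frame = pd.DataFrame([r.to_dict() for r in reports])
    metric_cols = [c for c in frame.columns if frame[c].dtype.kind == "f"]
    summary = pd.DataFrame({"mean": frame[metric_cols].mean(),
                            "sd": frame[metric_cols].std(ddof=0)})
    result = CVResult(reports, fold_idx, preds, summary)
    result._pooled_acc = float(np.mean(preds == y))
    return result
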