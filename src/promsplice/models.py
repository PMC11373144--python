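"""The four splicing-change classifiers and their shared plumbing.

All models consume delta events in one of two feature signatures: ``flat``
(a binary per-TF occupancy-change vector) or ``positional`` (the 2500 x n_TF
binary change matrix; TFs are channels along the promoter axis).  Logistic
regression and the gradient-boosted trees take flat vectors; the DNN takes
either (positional input is flattened); the CNN takes positional matrices
through a 1-D convolution, ReLU, max-pool(10, 10), dropout, and two
128-unit dense/ReLU/dropout blocks before the sigmoid output.  Class
imbalance is handled by resampling the training indices so both classes have
equal expected frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

from ._nn import Adam, Conv1D, Dense, Dropout, Flatten, MaxPool1D, Network, ReLU

FLAT, POSITIONAL = "flat", "positional"
MODEL_KINDS = ("logreg", "gbtree", "dnn", "cnn")


@dataclass(frozen=True)
class TrainConfig:
    model_kind: str = "gbtree"
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    dropout_rate: float = 0.25
    conv_filters: int = 64
    kernel_size: int = 20
    pool_window: int = 10
    pool_stride: int = 10
    n_rounds: int = 200          # boosting rounds
    early_stop_patience: int = 5
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.pool_window <= 0 or self.pool_stride <= 0:
            raise ValueError("pool parameters must be positive")
        if self.pool_window != self.pool_stride:
            raise ValueError("pooling is non-overlapping: window must equal stride")


class Features:
    """Feature access with lazy densification for positional input.

    ``data`` is a 2-D array (flat), a 3-D array (positional, dense), or a
    sequence of sparse (length x n_TF) matrices (positional, lazy).
    """

    def __init__(self, data, kind: str | None = None):
        if isinstance(data, Features):
            self.data, self.kind = data.data, data.kind
            return
        if isinstance(data, np.ndarray) and data.ndim == 2:
            self.kind = kind or FLAT
            self.data = np.asarray(data, dtype=np.float32)
        elif isinstance(data, np.ndarray) and data.ndim == 3:
            self.kind = POSITIONAL
            self.data = np.asarray(data, dtype=np.float32)
        elif isinstance(data, (list, tuple)) and len(data) and sparse.issparse(data[0]):
            self.kind = POSITIONAL
            self.data = list(data)
        else:
            raise ValueError("unsupported feature container")

    def __len__(self):
        return len(self.data)

    @property
    def signature(self) -> tuple:
        if self.kind == FLAT:
            return (FLAT, self.data.shape[1])
        shape = self.data[0].shape if isinstance(self.data, list) else self.data.shape[1:]
        return (POSITIONAL, tuple(shape))

    def batch(self, idx: np.ndarray) -> np.ndarray:
        if isinstance(self.data, np.ndarray):
            return self.data[idx]
        return np.stack(
            [np.asarray(self.data[i].todense(), dtype=np.float32) for i in idx]
        )

    def flat_view(self) -> "Features":
        """Positional features flattened to one vector per event."""
        if self.kind == FLAT:
            return self
        if isinstance(self.data, np.ndarray):
            return Features(self.data.reshape(len(self.data), -1))
        n = self.data[0].shape[0] * self.data[0].shape[1]
        out = np.empty((len(self.data), n), dtype=np.float32)
        for i, m in enumerate(self.data):
            out[i] = np.asarray(m.todense(), dtype=np.float32).ravel()
        return Features(out)

    def subset(self, idx) -> "Features":
        idx = np.asarray(idx)
        if isinstance(self.data, np.ndarray):
            return Features(self.data[idx], kind=self.kind)
        return Features([self.data[i] for i in idx])


@dataclass
class Classifier:
    kind: str
    signature: tuple
    config: TrainConfig
    _impl: object = field(repr=False, default=None)

    def predict_proba(self, features) -> np.ndarray:
        """P(discordance) per event; inference is deterministic (no dropout)."""
        feats = Features(features)
        if feats.signature != self.signature:
            raise ValueError(
                f"feature signature {feats.signature} does not match the "
                f"model's {self.signature}"
            )
        if self.kind == "logreg":
            return self._impl.predict_proba(feats.flat_view().data)[:, 1]
        if self.kind == "gbtree":
            return self._impl.predict_proba(feats.flat_view().data)[:, 1]
        if self.kind == "dnn":
            return _batched_proba(self._impl, feats.flat_view(), flat=True)
        return _batched_proba(self._impl, feats, flat=False)

    def predict(self, features) -> np.ndarray:
        return (self.predict_proba(features) >= 0.5).astype(int)


def _batched_proba(net: Network, feats: Features, flat: bool, batch=256) -> np.ndarray:
    out = np.empty(len(feats))
    for lo in range(0, len(feats), batch):
        idx = np.arange(lo, min(lo + batch, len(feats)))
        x = feats.batch(idx)
        if flat and x.ndim > 2:
            x = x.reshape(len(idx), -1)
        out[idx] = net.predict_proba(x)
    return out


def balanced_sample(labels: Sequence[int], seed: int) -> np.ndarray:
    """Resample indices (with replacement, same total size) so both classes
    have equal expected frequency; deterministic per seed."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balanced sampling needs both classes present")
    weights = np.empty(len(y))
    for cls, cnt in zip(classes, counts):
        weights[y == cls] = 1.0 / (len(classes) * cnt)
    rng = np.random.default_rng(seed)
    return rng.choice(len(y), size=len(y), replace=True, p=weights)


def _build_dnn(n_in: int, cfg: TrainConfig, rng) -> Network:
    layers = []
    widths = [512, 256, 128]
    prev = n_in
    for w in widths:
        layers += [Dense(prev, w, rng), ReLU(), Dropout(cfg.dropout_rate, rng)]
        prev = w
    layers.append(Dense(prev, 1, rng))
    return Network(layers)


def _build_cnn(shape: tuple[int, int], cfg: TrainConfig, rng) -> Network:
    length, channels = shape
    conv = Conv1D(channels, cfg.conv_filters, cfg.kernel_size, rng)
    out_len = (length - cfg.kernel_size + 1) // cfg.pool_window
    layers = [
        conv,
        ReLU(),
        MaxPool1D(cfg.pool_window),
        Dropout(cfg.dropout_rate, rng),
        Flatten(),
        Dense(out_len * cfg.conv_filters, 128, rng),
        ReLU(),
        Dropout(cfg.dropout_rate, rng),
        Dense(128, 128, rng),
        ReLU(),
        Dropout(cfg.dropout_rate, rng),
        Dense(128, 1, rng),
    ]
    return Network(layers)


def train(features, labels: Sequence[int], config: TrainConfig) -> Classifier:
    """Fit one classifier of ``config.model_kind`` on labelled delta events.

    Labels are binary (1 = discordance).  Training indices are re-balanced by
    :func:`balanced_sample`; neural nets use binary cross-entropy, Adam, and
    early stopping on the AUROC of an internal validation split.
    """
    feats = Features(features)
    y = np.asarray(labels, dtype=np.float32)
    if len(feats) != len(y):
        raise ValueError("features and labels disagree in length")
    if np.unique(y).size < 2:
        raise ValueError("training needs both classes")
    kind = config.model_kind
    if kind in ("logreg", "gbtree"):
        X = feats.flat_view().data
        if not np.isfinite(X).all():
            raise ValueError("features contain non-finite values")
        idx = balanced_sample(y, config.seed)
        if kind == "logreg":
            from sklearn.exceptions import ConvergenceWarning
            from sklearn.linear_model import LogisticRegression

            model = LogisticRegression()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(X[idx], y[idx])
        else:
            from xgboost import XGBClassifier

            model = XGBClassifier(
                max_depth=6,
                learning_rate=1.0,
                booster="gbtree",
                n_estimators=config.n_rounds,
                objective="binary:logistic",
                random_state=config.seed,
                n_jobs=1,
                verbosity=0,
            )
            model.fit(X[idx], y[idx])
        return Classifier(kind=kind, signature=feats.signature, config=config, _impl=model)

    return _train_net(feats, y, config)


def _train_net(feats: Features, y: np.ndarray, config: TrainConfig) -> Classifier:
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(config.seed)
    kind = config.model_kind
    flat = kind == "dnn"
    sig = feats.signature
    if flat:
        n_in = sig[1] if sig[0] == FLAT else int(np.prod(sig[1]))
        net = _build_dnn(n_in, config, rng)
    else:
        if sig[0] != POSITIONAL:
            raise ValueError("cnn requires positional features")
        net = _build_cnn(sig[1], config, rng)

    n = len(feats)
    perm = rng.permutation(n)
    n_val = max(int(round(config.validation_fraction * n)), 1)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if np.unique(y[tr_idx]).size < 2:
        tr_idx = perm  # degenerate tiny input: train on everything
        val_idx = perm
    opt = Adam(net.params, lr=config.learning_rate)
    y_val = y[val_idx]
    use_auc = np.unique(y_val).size == 2

    def val_score():
        p = _batched_proba(net, feats.subset(val_idx), flat=flat)
        if use_auc:
            return roc_auc_score(y_val, p)
        eps = 1e-7
        p = np.clip(p, eps, 1 - eps)
        return float(np.mean(y_val * np.log(p) + (1 - y_val) * np.log(1 - p)))

    best, best_params, patience = -np.inf, None, 0
    for _ in range(config.epochs):
        order = tr_idx[balanced_sample(y[tr_idx], int(rng.integers(2**31)))]
        for lo in range(0, len(order), config.batch_size):
            bidx = order[lo : lo + config.batch_size]
            x = feats.batch(bidx)
            if flat and x.ndim > 2:
                x = x.reshape(len(bidx), -1)
            if not np.isfinite(x).all():
                raise ValueError("features contain non-finite values")
            net.train_step(x, y[bidx], opt)
        score = val_score()
        if score > best + 1e-9:
            best, patience = score, 0
            best_params = [p.copy() for p in net.params]
        else:
            patience += 1
            if patience >= config.early_stop_patience:
                break
    if best_params is not None:
        for p, bp in zip(net.params, best_params):
            p[...] = bp
    return Classifier(kind=kind, signature=sig, config=config, _impl=net)


def predict_proba(model: Classifier, features) -> np.ndarray:
    return model.predict_proba(features)
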