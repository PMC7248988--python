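"""Convolutional fatigue classifier and its cross-validated training protocol.

Architecture: five (temporal convolution -> ReLU -> average pool k=2) blocks
with filter counts [256, 128, 64, 32, 32] and kernel sizes [3, 5, 7, 9, 9],
then a fully connected layer and softmax over the two boundary fatigue
classes.  On a 6-channel, 768-sample input the temporal extents evolve
768 -> 766 -> 383 -> 379 -> 189 -> 183 -> 91 -> 83 -> 41 -> 33 -> 16.

Training follows a Monte-Carlo reading of nested 20-fold cross validation:
each fold draws a seeded, label-stratified 60/20/20 train/validation/test
split; training runs at least 15 epochs; every 5 consecutive epochs without
validation-accuracy improvement the learning rate is cut by 20%; after 15
stale epochs training terminates; the best-validation weights are restored
before the test accuracy is recorded.  The report aggregates fold test
accuracies as mean +/- std.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fusion import FusedSegment
from .labeling import LABEL_HIGH, LABEL_LOW
from .nn import (
    Adam,
    avg_pool,
    avg_pool_backward,
    conv1d_backward,
    conv1d_forward,
    cross_entropy,
    relu,
    softmax,
)

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "FatigueCNN",
    "FoldResult",
    "CVReport",
    "train_cv",
    "train_final",
    "CLASS_NAMES",
]

CLASS_NAMES = (LABEL_LOW, LABEL_HIGH)  # class 0 = low fatigue, class 1 = high


@dataclass(frozen=True)
class ModelSpec:
    """Shape of the convolutional classifier."""

    n_channels: int
    conv_filters: Tuple[int, ...] = (256, 128, 64, 32, 32)
    conv_kernels: Tuple[int, ...] = (3, 5, 7, 9, 9)
    n_classes: int = 2
    input_length: int = 768
    pool_kernel: int = 2

    def __post_init__(self) -> None:
        if len(self.conv_filters) != len(self.conv_kernels):
            raise ValueError("conv_filters and conv_kernels must have equal length")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")

    @property
    def n_layers(self) -> int:
        return len(self.conv_filters)

    @property
    def input_shape(self) -> Tuple[int, int]:
        return (self.n_channels, self.input_length)

    def temporal_extents(self) -> List[Tuple[int, int]]:
        """(post-conv, post-pool) lengths per block; raises if a kernel no longer fits."""
        L = self.input_length
        out = []
        for k in self.conv_kernels:
            if k > L:
                raise ValueError(f"kernel {k} does not fit temporal extent {L}")
            Lc = L - k + 1
            Lp = Lc // self.pool_kernel
            out.append((Lc, Lp))
            L = Lp
        return out

    @property
    def n_features(self) -> int:
        return self.conv_filters[-1] * self.temporal_extents()[-1][1]

    @staticmethod
    def demo(n_channels: int) -> "ModelSpec":
        """Reduced filter bank for desk-scale CPU training; same depth/kernels."""
        return ModelSpec(n_channels=n_channels, conv_filters=(16, 16, 8, 8, 8))

    def to_dict(self) -> Dict[str, object]:
        return {
            "n_channels": self.n_channels,
            "conv_filters": list(self.conv_filters),
            "conv_kernels": list(self.conv_kernels),
            "n_classes": self.n_classes,
            "input_length": self.input_length,
            "pool_kernel": self.pool_kernel,
        }

    @staticmethod
    def from_dict(d: Dict[str, object]) -> "ModelSpec":
        d = dict(d)
        d["conv_filters"] = tuple(d["conv_filters"])  # type: ignore[arg-type]
        d["conv_kernels"] = tuple(d["conv_kernels"])  # type: ignore[arg-type]
        return ModelSpec(**d)  # type: ignore[arg-type]


@dataclass
class TrainConfig:
    """Hyper-parameters of the cross-validated training protocol."""

    folds: int = 20
    split: Tuple[float, float, float] = (0.6, 0.2, 0.2)
    min_epochs: int = 15
    max_epochs: int = 200
    lr_init: float = 3e-3
    lr_decay: float = 0.2  # each decay event multiplies the rate by (1 - lr_decay)
    lr_patience: int = 5
    stop_patience: int = 15
    batch_size: int = 32
    seed: int = 0
    split_mode: str = "random"  # "random" (segment-level) or "block" (contiguous)

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.lr_patience <= 0 or self.stop_patience <= 0:
            raise ValueError("patience values must be positive")
        if self.split_mode not in ("random", "block"):
            raise ValueError("split_mode must be 'random' or 'block'")


class FatigueCNN:
    """The five-block temporal CNN with a dense softmax head."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        self.params: Dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        c_in = spec.n_channels
        for i, (f, k) in enumerate(zip(spec.conv_filters, spec.conv_kernels)):
            fan_in = c_in * k
            self.params[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (f, c_in, k))
            self.params[f"b{i}"] = np.zeros(f)
            c_in = f
        nf = spec.n_features
        self.params["Wd"] = rng.normal(0.0, np.sqrt(2.0 / nf), (nf, spec.n_classes))
        self.params["bd"] = np.zeros(spec.n_classes)
        self.init_seed = seed

    # ---- forward ----

    def forward_cached(self, x: np.ndarray) -> Dict[str, object]:
        """Full forward pass keeping per-block intermediates.

        x: (N, C, L).  Cache holds, per block: pre-activation conv output,
        post-ReLU map and post-pool map.  Returns logits and probabilities.
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"input shape mismatch: expected {self.spec.input_shape}, "
                f"got {x.shape[1:]}"
            )
        cache: Dict[str, object] = {"x": x, "conv": [], "relu": [], "pool": []}
        h = x
        for i in range(self.spec.n_layers):
            z = conv1d_forward(h, self.params[f"W{i}"], self.params[f"b{i}"])
            a = relu(z)
            p = avg_pool(a, self.spec.pool_kernel)
            cache["conv"].append(z)
            cache["relu"].append(a)
            cache["pool"].append(p)
            h = p
        flat = h.reshape(h.shape[0], -1)
        logits = flat @ self.params["Wd"] + self.params["bd"]
        cache["flat"] = flat
        cache["logits"] = logits
        cache["probs"] = softmax(logits, axis=1)
        return cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward_cached(x)["probs"]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class indices; ties resolve to the lower index (np.argmax)."""
        return np.argmax(self.predict_proba(x), axis=1)

    # ---- backward ----

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> Tuple[float, Dict[str, np.ndarray]]:
        cache = self.forward_cached(x)
        probs = cache["probs"]
        n = probs.shape[0]
        loss = cross_entropy(probs, y)
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads: Dict[str, np.ndarray] = {}
        flat = cache["flat"]
        grads["Wd"] = flat.T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dflat = dlogits @ self.params["Wd"].T
        h = cache["pool"][-1]
        dh = dflat.reshape(h.shape)
        for i in reversed(range(self.spec.n_layers)):
            a = cache["relu"][i]
            z = cache["conv"][i]
            da = avg_pool_backward(dh, a.shape[-1], self.spec.pool_kernel)
            dz = da * (z > 0)
            x_in = cache["x"] if i == 0 else cache["pool"][i - 1]
            dx, dw, db = conv1d_backward(x_in, self.params[f"W{i}"], dz)
            grads[f"W{i}"] = dw
            grads[f"b{i}"] = db
            dh = dx
        return loss, grads

    def copy_params(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: Dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


@dataclass
class FoldResult:
    fold: int
    val_history: List[float]
    best_epoch: int
    test_accuracy: float
    n_lr_decays: int
    final_lr: float


@dataclass
class CVReport:
    """Cross-validation summary in the "avg +/- std" reporting convention."""

    folds: List[FoldResult]
    mean_test_accuracy: float
    std_test_accuracy: float
    model_spec: ModelSpec
    train_config: TrainConfig
    null_run: bool = False

    def summary(self) -> str:
        s = f"{self.mean_test_accuracy:.2f} ± {self.std_test_accuracy:.2f}"
        return s + (" [NULL RUN: permuted labels]" if self.null_run else "")

    def to_table(self) -> str:
        lines = ["fold\tbest_epoch\ttest_acc"]
        for fr in self.folds:
            lines.append(f"{fr.fold}\t{fr.best_epoch}\t{fr.test_accuracy:.4f}")
        lines.append(f"Test acc (avg ± std)\t\t{self.summary()}")
        return "\n".join(lines)


def _segments_to_arrays(segments: Sequence[FusedSegment]) -> Tuple[np.ndarray, np.ndarray]:
    label_map = {LABEL_LOW: 0, LABEL_HIGH: 1}
    xs, ys = [], []
    for s in segments:
        if s.label not in label_map:
            raise ValueError(
                f"segment at t={s.start_time} has no boundary label; "
                "filter with labeling.labeled_subset first"
            )
        xs.append(s.matrix)
        ys.append(label_map[s.label])
    return np.stack(xs), np.asarray(ys, dtype=np.int64)


def _stratified_split(
    y: np.ndarray, split: Tuple[float, float, float], rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label-stratified random index split; remainders go to the training set."""
    tr, va, te = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = idx.size
        n_va = int(np.floor(split[1] * n))
        n_te = int(np.floor(split[2] * n))
        te.append(idx[:n_te])
        va.append(idx[n_te:n_te + n_va])
        tr.append(idx[n_te + n_va:])
    out = tuple(np.sort(np.concatenate(p)) for p in (tr, va, te))
    if any(p.size == 0 for p in out):
        raise ValueError("split too small: a partition would be empty")
    return out  # type: ignore[return-value]


def _block_split(
    n: int, split: Tuple[float, float, float], fold: int, folds: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contiguous (circular) blocks in time order, rotated per fold.

    Controls the train/test correlation induced by the 2 s window overlap.
    """
    n_te = max(1, int(np.floor(split[2] * n)))
    n_va = max(1, int(np.floor(split[1] * n)))
    offset = (fold * n) // max(folds, 1)
    order = np.arange(n)
    rolled = np.roll(order, -offset)
    te = rolled[:n_te]
    va = rolled[n_te:n_te + n_va]
    tr = rolled[n_te + n_va:]
    if tr.size == 0:
        raise ValueError("split too small: a partition would be empty")
    return np.sort(tr), np.sort(va), np.sort(te)


def _accuracy(model: FatigueCNN, x: np.ndarray, y: np.ndarray, batch: int = 256) -> float:
    preds = np.concatenate(
        [model.predict(x[i:i + batch]) for i in range(0, x.shape[0], batch)]
    )
    return float(np.mean(preds == y))


def _train_one_fold(
    x: np.ndarray,
    y: np.ndarray,
    model_spec: ModelSpec,
    cfg: TrainConfig,
    fold: int,
    split_ss: np.random.SeedSequence,
    init_ss: np.random.SeedSequence,
) -> FoldResult:
    split_rng = np.random.default_rng(split_ss)
    if cfg.split_mode == "random":
        tr, va, te = _stratified_split(y, cfg.split, split_rng)
    else:
        tr, va, te = _block_split(len(y), cfg.split, fold, cfg.folds)
    if np.unique(y[tr]).size < 2:
        raise ValueError("training partition lost a class; need more segments")

    init_seed = int(init_ss.generate_state(1)[0] % (2**31))
    model = FatigueCNN(model_spec, seed=init_seed)
    opt = Adam(model.params, lr=cfg.lr_init)
    epoch_rng = np.random.default_rng(split_ss.spawn(1)[0])

    best_acc = -1.0
    best_epoch = -1
    best_params = model.copy_params()
    stale = 0
    n_decays = 0
    val_history: List[float] = []

    for epoch in range(cfg.max_epochs):
        order = epoch_rng.permutation(tr)
        for i in range(0, order.size, cfg.batch_size):
            bi = order[i:i + cfg.batch_size]
            _, grads = model.loss_and_grads(x[bi], y[bi])
            opt.step(model.params, grads)
        val_acc = _accuracy(model, x[va], y[va])
        val_history.append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_epoch = epoch
            best_params = model.copy_params()
            stale = 0
        else:
            stale += 1
            if stale % cfg.lr_patience == 0:
                opt.lr *= 1.0 - cfg.lr_decay
                n_decays += 1
        if epoch + 1 >= cfg.min_epochs and stale >= cfg.stop_patience:
            break

    model.set_params(best_params)
    test_acc = _accuracy(model, x[te], y[te])
    return FoldResult(
        fold=fold,
        val_history=val_history,
        best_epoch=best_epoch,
        test_accuracy=test_acc,
        n_lr_decays=n_decays,
        final_lr=opt.lr,
    )


def train_cv(
    segments: Sequence[FusedSegment],
    model_spec: ModelSpec,
    train_config: TrainConfig | None = None,
    permute_labels: bool = False,
) -> CVReport:
    """Monte-Carlo cross-validated training on labeled fused segments.

    Each fold draws a fresh seeded stratified 60/20/20 split, trains with
    dynamic learning rate and early stopping, restores the best-validation
    checkpoint and records test accuracy.  ``permute_labels`` shuffles labels
    once (seeded) before splitting — the permutation-null control.
    """
    cfg = train_config or TrainConfig()
    x, y = _segments_to_arrays(segments)
    if np.unique(y).size < 2:
        raise ValueError("need segments from both boundary classes to train")
    if permute_labels:
        null_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(999,)))
        y = null_rng.permutation(y)

    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.folds * 2)
    folds: List[FoldResult] = []
    for fold in range(cfg.folds):
        fr = _train_one_fold(
            x, y, model_spec, cfg, fold,
            split_ss=children[2 * fold], init_ss=children[2 * fold + 1],
        )
        folds.append(fr)
    accs = np.array([f.test_accuracy for f in folds])
    return CVReport(
        folds=folds,
        mean_test_accuracy=float(accs.mean()),
        std_test_accuracy=float(accs.std()),
        model_spec=model_spec,
        train_config=cfg,
        null_run=permute_labels,
    )


def train_final(
    segments: Sequence[FusedSegment],
    model_spec: ModelSpec,
    train_config: TrainConfig | None = None,
) -> Tuple[FatigueCNN, FoldResult]:
    """Train a single deployable model (one seeded split, same protocol)."""
    cfg = train_config or TrainConfig()
    x, y = _segments_to_arrays(segments)
    if np.unique(y).size < 2:
        raise ValueError("need segments from both boundary classes to train")
    root = np.random.SeedSequence(cfg.seed)
    split_ss, init_ss = root.spawn(2)
    split_rng = np.random.default_rng(split_ss)
    tr, va, _te = _stratified_split(y, cfg.split, split_rng)

    init_seed = int(init_ss.generate_state(1)[0] % (2**31))
    model = FatigueCNN(model_spec, seed=init_seed)
    opt = Adam(model.params, lr=cfg.lr_init)
    epoch_rng = np.random.default_rng(split_ss.spawn(1)[0])

    best_acc, best_epoch, stale, n_decays = -1.0, -1, 0, 0
    best_params = model.copy_params()
    val_history: List[float] = []
    for epoch in range(cfg.max_epochs):
        order = epoch_rng.permutation(tr)
        for i in range(0, order.size, cfg.batch_size):
            bi = order[i:i + cfg.batch_size]
            _, grads = model.loss_and_grads(x[bi], y[bi])
            opt.step(model.params, grads)
        val_acc = _accuracy(model, x[va], y[va])
        val_history.append(val_acc)
        if val_acc > best_acc:
            best_acc, best_epoch, stale = val_acc, epoch, 0
            best_params = model.copy_params()
        else:
            stale += 1
            if stale % cfg.lr_patience == 0:
                opt.lr *= 1.0 - cfg.lr_decay
                n_decays += 1
        if epoch + 1 >= cfg.min_epochs and stale >= cfg.stop_patience:
            break
    model.set_params(best_params)
    fr = FoldResult(fold=0, val_history=val_history, best_epoch=best_epoch,
                    test_accuracy=best_acc, n_lr_decays=n_decays, final_lr=opt.lr)
    return model, fr
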