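"""The window classifier: per-frame convolutional encoder, GRU, dense head.

Each frame of a (T, H, W) window goes through four blocks of
[3×3 same convolution → batch normalisation → ReLU → 2×2 max pool]; with the
default 45-px window the spatial side shrinks 45 → 22 → 11 → 5 while the
filter count grows 8 → 16 → 32 → 64.  A final global max pool encodes each
frame as a 64-vector; the resulting T×64 sequence feeds a GRU whose last
state passes through dropout and dense layers to an n-class softmax, so the
output is a probability vector over (none, extrusion, sop, division)
truncated to ``n_classes``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ..errors import FormatError, InvalidInputError, SpecError
from ..scaling import CLASS_ORDER, EventClass
from ..windows import TrainingSet, WindowSequence, augment_window
from .layers import (
    Adam,
    BatchNorm,
    Conv2DSame,
    Dense,
    Dropout,
    GRU,
    GlobalMaxPool,
    MaxPool2x2,
    ReLU,
    softmax,
    softmax_cross_entropy,
)

__all__ = [
    "NetworkSpec",
    "WindowClassifier",
    "build_network",
    "predict_window",
    "train_network",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters of the window classifier."""

    n_conv_blocks: int = 4
    base_filters: int = 8
    filter_growth: int = 2
    recurrent_units: Optional[int] = 64
    dense_sizes: tuple = (32,)
    dropout_rate: float = 0.5
    n_classes: int = 2
    window_shape: tuple = (10, 45, 45)

    @property
    def feature_dim(self) -> int:
        return self.base_filters * self.filter_growth ** (self.n_conv_blocks - 1)

    @property
    def filters(self) -> tuple:
        return tuple(
            self.base_filters * self.filter_growth ** i
            for i in range(self.n_conv_blocks)
        )

    def spatial_sides(self) -> tuple:
        """Spatial side seen by each conv block (45 → 22 → 11 → 5).

        Blocks 1..n−1 end in a 2×2 max pool (floor division of the side);
        the last block's pooling step is the final global max pool that
        collapses the remaining grid into one feature vector per frame.
        """
        sides = [self.window_shape[1]]
        for _ in range(self.n_conv_blocks - 1):
            sides.append(sides[-1] // 2)
        return tuple(sides)

    def validate(self) -> None:
        if self.n_classes not in (2, 3, 4):
            raise SpecError("n_classes must be 2, 3 or 4")
        if self.window_shape[1] != self.window_shape[2]:
            raise SpecError("window must be spatially square")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise SpecError("dropout_rate must be in [0, 1)")
        if any(s < 1 for s in self.spatial_sides()):
            raise SpecError(
                f"window side {self.window_shape[1]} collapses to zero before "
                f"block {self.n_conv_blocks} (sides {self.spatial_sides()})"
            )

    @property
    def class_order(self) -> tuple:
        return CLASS_ORDER[: self.n_classes]


class WindowClassifier:
    """A (possibly trained) window classifier with its weights and spec."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        spec.validate()
        self.spec = spec
        self.history: dict = {}
        self.train_config_text: str = ""
        self.blocks = []
        c_in = 1
        for i, c_out in enumerate(spec.filters):
            # the last block's pooling step is the final global max pool
            pool = MaxPool2x2() if i < spec.n_conv_blocks - 1 else None
            self.blocks.append(
                (
                    Conv2DSame(c_in, c_out, rng, name=f"conv{i}"),
                    BatchNorm(c_out, name=f"bn{i}"),
                    ReLU(),
                    pool,
                )
            )
            c_in = c_out
        self.global_pool = GlobalMaxPool()
        units = spec.recurrent_units or spec.feature_dim
        self.gru = GRU(spec.feature_dim, units, rng)
        self.dropout = Dropout(spec.dropout_rate)
        self.head = []
        d_in = units
        for j, d_out in enumerate(spec.dense_sizes):
            self.head.append((Dense(d_in, d_out, rng, name=f"dense{j}"), ReLU()))
            d_in = d_out
        self.out = Dense(d_in, spec.n_classes, rng, name="out")

    # -- parameter bookkeeping ---------------------------------------------
    @property
    def params(self) -> list:
        ps = []
        for conv, bn, _, _ in self.blocks:
            ps += conv.params + bn.params
        ps += self.gru.params
        for dense, _ in self.head:
            ps += dense.params
        ps += self.out.params
        return ps

    def state_dict(self) -> dict:
        state = {p.name: p.value for p in self.params}
        for _, bn, _, _ in self.blocks:
            state[bn.gamma.name.replace("gamma", "rmean")] = bn.running_mean
            state[bn.gamma.name.replace("gamma", "rvar")] = bn.running_var
        return state

    def load_state_dict(self, state: dict) -> None:
        for p in self.params:
            if p.name not in state:
                raise FormatError(f"missing weight {p.name}")
            if state[p.name].shape != p.value.shape:
                raise FormatError(
                    f"weight {p.name}: shape {state[p.name].shape} does not "
                    f"match spec {p.value.shape}"
                )
            p.value = state[p.name].astype(np.float32)
        for _, bn, _, _ in self.blocks:
            bn.running_mean = state[bn.gamma.name.replace("gamma", "rmean")].astype(
                np.float32
            )
            bn.running_var = state[bn.gamma.name.replace("gamma", "rvar")].astype(
                np.float32
            )

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Logits for a normalised batch ``(B, T, H, W)``."""
        b, t, h, w = x.shape
        T, H, W = self.spec.window_shape
        if (t, h, w) != (T, H, W):
            raise InvalidInputError(
                f"window shape {(t, h, w)} does not match spec {(T, H, W)}"
            )
        z = x.reshape(b * t, h, w, 1).astype(np.float32)
        for conv, bn, relu, pool in self.blocks:
            z = relu.forward(bn.forward(conv.forward(z, train), train), train)
            if pool is not None:
                z = pool.forward(z, train)
        feat = self.global_pool.forward(z, train)  # (B*T, F)
        seq = feat.reshape(b, t, -1)
        hlast = self.gru.forward(seq, train)
        hlast = self.dropout.forward(hlast, train, rng)
        for dense, relu in self.head:
            hlast = relu.forward(dense.forward(hlast, train), train)
        return self.out.forward(hlast, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.out.backward(dlogits)
        for dense, relu in reversed(self.head):
            d = dense.backward(relu.backward(d))
        d = self.dropout.backward(d)
        d = self.gru.backward(d)
        b, t, f = d.shape
        d = self.global_pool.backward(d.reshape(b * t, f))
        for conv, bn, relu, pool in reversed(self.blocks):
            if pool is not None:
                d = pool.backward(d)
            d = conv.backward(bn.backward(relu.backward(d)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (rows sum to 1) for a normalised batch."""
        return softmax(self.forward(x, train=False))


def build_network(spec: NetworkSpec = NetworkSpec(),
                  seed: int = 0) -> WindowClassifier:
    """Build an untrained classifier with seeded weight initialisation."""
    return WindowClassifier(spec, np.random.default_rng(seed))


def normalize_windows(x: np.ndarray) -> np.ndarray:
    """Min-max normalise each window to [0, 1] (flat windows map to 0)."""
    x = np.asarray(x, dtype=np.float32)
    flat = x.reshape(x.shape[0], -1)
    lo = flat.min(axis=1)[:, None, None, None]
    hi = flat.max(axis=1)[:, None, None, None]
    span = np.where(hi > lo, hi - lo, 1.0)
    return (x - lo) / span


def predict_window(net: WindowClassifier, window) -> np.ndarray:
    """Probability vector (length ``n_classes``, sums to 1) for one window."""
    vox = window.voxels if isinstance(window, WindowSequence) else np.asarray(window)
    if tuple(vox.shape) != tuple(net.spec.window_shape):
        raise InvalidInputError(
            f"window shape {vox.shape} does not match spec "
            f"{net.spec.window_shape}"
        )
    x = normalize_windows(vox[None])
    return net.predict_proba(x)[0]


def _labels_to_indices(windows: Sequence[WindowSequence], spec: NetworkSpec):
    order = {c: i for i, c in enumerate(spec.class_order)}
    labels = []
    for w in windows:
        if w.label not in order:
            raise InvalidInputError(
                f"label {w.label} not in the {spec.n_classes}-class ordering "
                f"{[c.value for c in spec.class_order]}"
            )
        labels.append(order[w.label])
    return np.asarray(labels, dtype=np.int64)


def train_network(
    net: WindowClassifier,
    training_set: TrainingSet,
    config,
    rng_seed: int = 0,
) -> tuple:
    """Train in place with Adam on categorical cross-entropy.

    With ``config.balance`` set, every epoch trains on a *fresh* balanced
    subsample of the training split (each class downsampled to the minimum
    class count): each epoch is class-balanced, yet over the epochs the
    network sees the whole pool of the over-represented class rather than
    one frozen subset.  Augmented copies
    (``config.augmentation_factor − 1`` per window, redrawn every epoch)
    are appended on the fly.  Returns ``(net, history)`` with per-epoch
    train/validation loss and accuracy (correct / all predictions).
    """
    from ..windows import balance_classes

    rng = np.random.default_rng(rng_seed)
    train_windows = training_set.subset("train")
    val_windows = training_set.subset("validation")
    if not train_windows:
        raise InvalidInputError("empty training split")
    if len({w.label for w in train_windows}) < 2:
        raise InvalidInputError("training set must contain >= 2 classes")

    balance = bool(getattr(config, "balance", False))
    if val_windows:
        if balance:
            val_windows = balance_classes(val_windows,
                                          np.random.default_rng(rng_seed))
        x_val = normalize_windows(np.stack([w.voxels for w in val_windows]))
        y_val = _labels_to_indices(val_windows, net.spec)
    else:
        x_val = y_val = None

    opt = Adam(net.params, lr=config.learning_rate)
    history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    n_aug = max(0, int(config.augmentation_factor) - 1)
    decay_epoch = max(1, int(0.7 * int(config.epochs)))
    best_val = np.inf
    best_state = None
    for epoch in range(int(config.epochs)):
        if epoch == decay_epoch:
            opt.lr *= 0.5  # step decay stabilises the last epochs
        epoch_windows = (
            balance_classes(train_windows, rng) if balance else train_windows
        )
        x_base = normalize_windows(
            np.stack([w.voxels for w in epoch_windows]))
        y_base = _labels_to_indices(epoch_windows, net.spec)
        xs, ys = [x_base], [y_base]
        for _ in range(n_aug):
            aug = [augment_window(w, rng) for w in epoch_windows]
            xs.append(normalize_windows(np.stack([a.voxels for a in aug])))
            ys.append(y_base)
        x_ep = np.concatenate(xs)
        y_ep = np.concatenate(ys)
        order = rng.permutation(len(x_ep))
        x_ep, y_ep = x_ep[order], y_ep[order]

        losses, correct, seen = [], 0, 0
        for i in range(0, len(x_ep), config.batch_size):
            xb = x_ep[i : i + config.batch_size]
            yb = y_ep[i : i + config.batch_size]
            logits = net.forward(xb, train=True, rng=rng)
            loss, dlogits, probs = softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss * len(xb))
            correct += int((probs.argmax(axis=1) == yb).sum())
            seen += len(xb)
        history["loss"].append(sum(losses) / seen)
        history["accuracy"].append(correct / seen)
        if x_val is not None:
            vl, va = evaluate_batch(net, x_val, y_val,
                                    batch_size=config.batch_size)
            history["val_loss"].append(vl)
            history["val_accuracy"].append(va)
            if vl < best_val:
                best_val = vl
                best_state = {k: v.copy() for k, v in net.state_dict().items()}
    if best_state is not None:
        # keep the best-validation checkpoint, not the last epoch's weights
        net.load_state_dict(best_state)
    net.history = history
    net.train_config_text = config.to_text() if hasattr(config, "to_text") else ""
    return net, history


def evaluate_batch(net: WindowClassifier, x: np.ndarray, y: np.ndarray,
                   batch_size: int = 64) -> tuple:
    """(mean loss, accuracy) on a normalised batch, in inference mode."""
    losses, correct = 0.0, 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = net.forward(xb, train=False)
        loss, _, probs = softmax_cross_entropy(logits, yb)
        losses += loss * len(xb)
        correct += int((probs.argmax(axis=1) == yb).sum())
    return losses / len(x), correct / len(x)


def save_network(net: WindowClassifier, path) -> None:
    """Persist weights (npz) plus a key=value spec/config sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **net.state_dict())
    lines = []
    for f in dataclasses.fields(net.spec):
        v = getattr(net.spec, f.name)
        if isinstance(v, tuple):
            v = ",".join(str(t) for t in v)
        lines.append(f"{f.name}={v}")
    lines.append(
        "classes=" + ",".join(c.value for c in net.spec.class_order)
    )
    (path / "network.cfg").write_text("\n".join(lines) + "\n")
    if net.train_config_text:
        (path / "train_config.cfg").write_text(net.train_config_text)


def load_network(path) -> WindowClassifier:
    """Load a model directory written by :func:`save_network`."""
    path = Path(path)
    cfg_file = path / "network.cfg"
    weights_file = path / "weights.npz"
    if not cfg_file.exists() or not weights_file.exists():
        raise FormatError(f"{path}: not a model directory")
    raw = {}
    for line in cfg_file.read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            raw[k.strip()] = v.strip()
    expected = [c.value for c in CLASS_ORDER[: int(raw["n_classes"])]]
    stored = raw.get("classes", ",".join(expected)).split(",")
    if stored != expected:
        raise FormatError(f"{path}: class ordering {stored} not canonical")
    spec = NetworkSpec(
        n_conv_blocks=int(raw["n_conv_blocks"]),
        base_filters=int(raw["base_filters"]),
        filter_growth=int(raw["filter_growth"]),
        recurrent_units=(
            None if raw["recurrent_units"] == "None"
            else int(raw["recurrent_units"])
        ),
        dense_sizes=tuple(int(s) for s in raw["dense_sizes"].split(",")),
        dropout_rate=float(raw["dropout_rate"]),
        n_classes=int(raw["n_classes"]),
        window_shape=tuple(int(s) for s in raw["window_shape"].split(",")),
    )
    net = WindowClassifier(spec, np.random.default_rng(0))
    with np.load(weights_file) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    train_cfg = path / "train_config.cfg"
    if train_cfg.exists():
        net.train_config_text = train_cfg.read_text()
    return net
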