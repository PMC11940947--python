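"""Two-pathway (bifocal) convolutional patch classifier.

One convolutional pathway sees the 32x32 cell-level crop, the other the
64x64 context crop.  Each pathway ends in global average pooling; the two
GAP feature vectors are concatenated and fed to a small fully connected head
producing 2 logits (negative, positive).  Training minimizes 2-class
cross-entropy between the predicted class probabilities and the dot labels.
The positive-class probability y is thresholded by T (default 0.5,
``y >= T`` is positive) to yield the final call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .patches import BifocalPatch

CLASS_ORDER = ("negative", "positive")


class TrainingError(RuntimeError):
    pass


@dataclass
class ClassifierConfig:
    """Architecture and optimization settings.

    ``inner_blocks``/``outer_blocks`` are tuples of (channels, kernel,
    stride); each block is conv + ReLU and downsamples by its stride.  Both
    pathways end in GAP, and the head input size is the sum of the two final
    channel counts (concatenation).
    """

    inner_blocks: tuple = ((16, 3, 1), (32, 3, 2), (64, 3, 2))
    outer_blocks: tuple = ((16, 3, 2), (32, 3, 2), (64, 3, 2))
    head_hidden: tuple = (32,)
    learning_rate: float = 2e-3
    epochs: int = 25
    batch_size: int = 32
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _pathway(blocks, in_ch: int, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    c = in_ch
    for channels, kernel, stride in blocks:
        layers.append(nn.Conv2D(c, channels, kernel, stride, kernel // 2, rng))
        layers.append(nn.ReLU())
        c = channels
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(layers)


class BifocalNet:
    """The two pathways plus the concatenation head."""

    def __init__(self, config: ClassifierConfig):
        rng = np.random.default_rng(config.seed)
        self.inner_path = _pathway(config.inner_blocks, 3, rng)
        self.outer_path = _pathway(config.outer_blocks, 3, rng)
        gap_dim = config.inner_blocks[-1][0] + config.outer_blocks[-1][0]
        head: list[nn.Layer] = []
        d = gap_dim
        for hidden in config.head_hidden:
            head.append(nn.Dense(d, hidden, rng))
            head.append(nn.ReLU())
            d = hidden
        head.append(nn.Dense(d, 2, rng))
        self.head = nn.Sequential(head)
        self._split = config.inner_blocks[-1][0]

    def forward(self, inner: np.ndarray, outer: np.ndarray,
                train: bool = False) -> np.ndarray:
        fi = self.inner_path.forward(inner, train)
        fo = self.outer_path.forward(outer, train)
        return self.head.forward(np.concatenate([fi, fo], axis=1), train)

    def backward(self, dlogits: np.ndarray) -> None:
        dconcat = self.head.backward(dlogits)
        self.inner_path.backward(dconcat[:, :self._split])
        self.outer_path.backward(dconcat[:, self._split:])

    @property
    def parameters(self):
        return (self.inner_path.parameters + self.outer_path.parameters
                + self.head.parameters)

    def state(self) -> list[np.ndarray]:
        return [p for p, _ in self.parameters]

    def load_state(self, arrays: Sequence[np.ndarray]) -> None:
        for (p, _), a in zip(self.parameters, arrays):
            p[...] = a


def to_arrays(patches: Sequence[BifocalPatch]) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Stack patches into (inner, outer) NCHW float32 in [-0.5, 0.5] plus an
    integer label vector (None if any patch is unlabeled)."""
    inner = np.stack([p.inner for p in patches]).astype(np.float32)
    outer = np.stack([p.outer for p in patches]).astype(np.float32)
    inner = inner.transpose(0, 3, 1, 2) / 255.0 - 0.5
    outer = outer.transpose(0, 3, 1, 2) / 255.0 - 0.5
    if any(p.label is None for p in patches):
        return inner, outer, None
    labels = np.array([CLASS_ORDER.index(p.label) for p in patches])
    return inner, outer, labels


@dataclass
class TrainedModel:
    net: BifocalNet
    config: ClassifierConfig
    training_log: list[dict] = field(default_factory=list)
    class_order: tuple[str, str] = CLASS_ORDER

    def predict_proba_arrays(self, inner: np.ndarray, outer: np.ndarray,
                             batch_size: int = 256) -> np.ndarray:
        """Positive-class probability for stacked NCHW inputs."""
        out = np.empty(inner.shape[0], dtype=np.float64)
        for start in range(0, inner.shape[0], batch_size):
            sl = slice(start, start + batch_size)
            logits = self.net.forward(inner[sl], outer[sl], train=False)
            out[sl] = nn.softmax(logits)[:, 1]
        return out

    def predict_proba(self, patches: BifocalPatch | Sequence[BifocalPatch]) -> float | np.ndarray:
        single = isinstance(patches, BifocalPatch)
        batch = [patches] if single else list(patches)
        for p in batch:
            if p.inner.shape != (32, 32, 3) or p.outer.shape != (64, 64, 3):
                raise ValueError(
                    f"patch shape mismatch: inner {p.inner.shape}, "
                    f"outer {p.outer.shape}")
        inner, outer, _ = to_arrays(batch)
        proba = self.predict_proba_arrays(inner, outer)
        return float(proba[0]) if single else proba

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": a for i, a in enumerate(self.net.state())}
        meta = json.dumps({
            "config": asdict(self.config),
            "class_order": list(self.class_order),
            "training_log": self.training_log,
        })
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        data = np.load(path if str(path).endswith(".npz") else f"{path}.npz")
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = meta["config"]
        for key in ("inner_blocks", "outer_blocks", "head_hidden"):
            cfg[key] = tuple(tuple(b) if isinstance(b, list) else b
                             for b in cfg[key])
        config = ClassifierConfig(**cfg)
        net = BifocalNet(config)
        net.load_state([data[f"p{i}"] for i in range(len(net.parameters))])
        return cls(net=net, config=config,
                   training_log=meta["training_log"],
                   class_order=tuple(meta["class_order"]))


def classify(proba: float, threshold: float) -> str:
    """Threshold function T: positive iff y >= T."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly in (0, 1)")
    return "positive" if proba >= threshold else "negative"


def train(
    train_patches: Sequence[BifocalPatch],
    val_patches: Sequence[BifocalPatch],
    config: ClassifierConfig,
) -> TrainedModel:
    """Train the bifocal network with Adam on cross-entropy.

    Fully seeded: weight initialization and per-epoch shuffling derive from
    ``config.seed``, so identical data and config reproduce the model
    exactly.  Raises if the training set does not contain both classes or if
    the loss becomes non-finite.
    """
    labels_present = {p.label for p in train_patches}
    if labels_present != set(CLASS_ORDER):
        raise ValueError(
            f"training set must contain both classes, got {sorted(labels_present - {None})}")
    inner, outer, labels = to_arrays(train_patches)
    vi, vo, vl = (to_arrays(val_patches) if val_patches else (None, None, None))

    net = BifocalNet(config)
    opt = nn.Adam(net.parameters, lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    n = inner.shape[0]
    log: list[dict] = []
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = net.forward(inner[idx], outer[idx], train=True)
            loss, dlogits = nn.cross_entropy(logits, labels[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if vi is not None:
            model = TrainedModel(net=net, config=config)
            proba = model.predict_proba_arrays(vi, vo)
            pred = (proba >= config.threshold).astype(int)
            entry["val_accuracy"] = float((pred == vl).mean())
        log.append(entry)
    return TrainedModel(net=net, config=config, training_log=log)


def write_training_log(model: TrainedModel, path: str | Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "train_loss", "val_accuracy"])
        for row in model.training_log:
            writer.writerow([row["epoch"], f"{row['train_loss']:.6f}",
                             f"{row.get('val_accuracy', '')}"])
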