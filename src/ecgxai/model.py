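"""Residual 1D convolutional classifier for two-class rhythm detection.

The network is the standard residual design for rhythm classification:
a strided stem (conv–BN–ReLU–maxpool), a stack of residual blocks
(conv–BN–ReLU–conv–BN with shortcut, 16 by default) that downsample and
widen every few blocks, global average pooling so any input length is
accepted, and a linear two-class head.  Class index 0 is sinus rhythm,
index 1 atrial fibrillation.

The desk profile (``base_channels=16``) trains on a few hundred synthetic
records in minutes on one CPU; ``paper_scale_config`` returns a much wider
preset for real-corpus work.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .nn import (
    Adam,
    BatchNorm1d,
    Conv1d,
    GlobalAvgPool,
    Linear,
    MaxPool1d,
    ReLU,
    ResidualBlock,
    cross_entropy_grad,
    softmax,
)
from .records import EcgRecord, Rhythm

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "ResNet1D",
    "build_model",
    "paper_scale_config",
    "train",
    "predict_proba",
    "save_model",
    "load_model",
    "CLASS_ORDER",
]

CLASS_ORDER: Tuple[Rhythm, Rhythm] = (Rhythm.NORMAL, Rhythm.AFIB)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``downsample_every`` blocks, the feature length halves and channel count
    doubles (capped at ``max_channels``).  ``input_length`` is advisory:
    global pooling makes the network length-agnostic above ``kernel_size``.
    """

    n_blocks: int = 16
    base_channels: int = 16
    kernel_size: int = 15
    downsample_every: int = 4
    dropout: float = 0.0
    n_classes: int = 2
    input_length: Optional[int] = None
    max_channels: int = 32
    stem_stride: int = 2
    stem_pool: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("need at least one residual block")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.n_classes != 2:
            raise ValueError("this classifier is strictly two-class")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


def paper_scale_config() -> ModelConfig:
    """Wide preset for full-corpus training (not exercised by the tests)."""
    return ModelConfig(base_channels=64, max_channels=512)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 16
    lr: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must lie in [0, 1)")


class ResNet1D:
    """The network itself; see module docstring for the layout."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.base_channels
        self.stem_conv = Conv1d(1, ch, config.kernel_size, stride=config.stem_stride, rng=rng)
        self.stem_bn = BatchNorm1d(ch)
        self.stem_relu = ReLU()
        self.stem_pool = MaxPool1d(config.stem_pool) if config.stem_pool > 1 else None
        self.blocks: List[ResidualBlock] = []
        c_in = ch
        for i in range(config.n_blocks):
            downsample = i > 0 and i % config.downsample_every == 0
            c_out = min(c_in * 2, config.max_channels) if downsample else c_in
            stride = 2 if downsample else 1
            self.blocks.append(ResidualBlock(c_in, c_out, config.kernel_size, stride, rng))
            c_in = c_out
        self.gap = GlobalAvgPool()
        self.head = Linear(c_in, config.n_classes, rng=rng)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        # filled by forward(..., capture=...) / backward(...)
        self.captured_activations: Dict[int, np.ndarray] = {}
        self.captured_gradients: Dict[int, np.ndarray] = {}

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        capture: Sequence[int] = (),
    ) -> np.ndarray:
        """Batch ``(N, L)`` or ``(N, 1, L)`` to logits ``(N, n_classes)``.

        ``capture`` lists 0-based block indices whose output feature maps
        (and, after :meth:`backward`, gradients) are stored for Grad-CAM.
        """
        if x.ndim == 2:
            x = x[:, None, :]
        if x.shape[2] < self.config.kernel_size:
            raise ValueError("input shorter than one convolution kernel")
        self.captured_activations = {}
        self.captured_gradients = {}
        self._capture = set(capture)
        out = self.stem_conv.forward(x, training)
        out = self.stem_bn.forward(out, training)
        out = self.stem_relu.forward(out, training)
        if self.stem_pool is not None:
            out = self.stem_pool.forward(out, training)
        for i, block in enumerate(self.blocks):
            out = block.forward(out, training)
            if i in self._capture:
                self.captured_activations[i] = out
        feats = self.gap.forward(out, training)
        if training and self.config.dropout > 0:
            mask = self._dropout_rng.random(feats.shape) >= self.config.dropout
            self._dropout_mask = mask / (1.0 - self.config.dropout)
            feats = feats * self._dropout_mask
        else:
            self._dropout_mask = None
        return self.head.forward(feats, training)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate; returns the gradient w.r.t. the input batch."""
        grad = self.head.backward(dlogits)
        if self._dropout_mask is not None:
            grad = grad * self._dropout_mask
        grad = self.gap.backward(grad)
        for i in range(len(self.blocks) - 1, -1, -1):
            if i in self._capture:
                self.captured_gradients[i] = grad
            grad = self.blocks[i].backward(grad)
        if self.stem_pool is not None:
            grad = self.stem_pool.backward(grad)
        grad = self.stem_relu.backward(grad)
        grad = self.stem_bn.backward(grad)
        return self.stem_conv.backward(grad)

    # -- bookkeeping --------------------------------------------------------

    def _layers(self) -> List:
        layers = [self.stem_conv, self.stem_bn] + list(self.blocks) + [self.head]
        return layers

    def parameters(self) -> List[Dict]:
        params: List[Dict] = []
        for layer in self._layers():
            params.extend(layer.parameters())
        return params

    def n_parameters(self) -> int:
        return int(sum(p["value"].size for p in self.parameters()))

    def state_arrays(self) -> List[np.ndarray]:
        """All learned state in fixed traversal order (incl. BN statistics)."""
        arrays: List[np.ndarray] = []

        def visit(layer) -> None:
            if isinstance(layer, Conv1d):
                arrays.extend([layer.w, layer.b])
            elif isinstance(layer, BatchNorm1d):
                arrays.extend([layer.gamma, layer.beta, layer.running_mean, layer.running_var])
            elif isinstance(layer, Linear):
                arrays.extend([layer.w, layer.b])
            elif isinstance(layer, ResidualBlock):
                visit(layer.conv1); visit(layer.bn1); visit(layer.conv2); visit(layer.bn2)
                if layer.projection is not None:
                    visit(layer.projection); visit(layer.proj_bn)

        for layer in self._layers():
            visit(layer)
        return arrays


def build_model(config: ModelConfig = ModelConfig()) -> ResNet1D:
    """Construct the network with seeded He initialization."""
    return ResNet1D(config)


def _standardize(samples: np.ndarray) -> np.ndarray:
    sd = samples.std()
    out = (samples - samples.mean()) / (sd if sd > 0 else 1.0)
    return out.astype(np.float32)


def _labels(records: Sequence[EcgRecord]) -> np.ndarray:
    y = []
    for r in records:
        if r.label is None:
            raise ValueError(f"record {r.record_id!r} has no label")
        y.append(CLASS_ORDER.index(r.label))
    return np.asarray(y, dtype=np.int64)


def _batches(
    records: Sequence[EcgRecord], order: np.ndarray, batch_size: int
) -> List[np.ndarray]:
    """Index batches grouping records of equal length (batching needs it)."""
    by_len: Dict[int, List[int]] = {}
    for i in order:
        by_len.setdefault(records[i].n_samples, []).append(int(i))
    batches = []
    for idxs in by_len.values():
        for j in range(0, len(idxs), batch_size):
            batches.append(np.asarray(idxs[j : j + batch_size]))
    return batches


def train(
    model: ResNet1D,
    records: Sequence[EcgRecord],
    tcfg: TrainConfig = TrainConfig(),
) -> List[Dict[str, float]]:
    """Train in place; returns per-epoch history.

    Records are standardized per record (zero mean, unit variance) before
    entering the network.  The shuffle order is drawn once from the seed and
    reused every epoch, so a zero learning rate provably freezes the loss.
    A held-out fraction, if requested, is scored in eval mode each epoch.
    """
    y_all = _labels(records)
    if len(np.unique(y_all)) < 2:
        raise ValueError("training requires both rhythm classes")
    if tcfg.optimizer.lower() != "adam":
        raise ValueError(f"unknown optimizer {tcfg.optimizer!r}")

    rng = np.random.default_rng(tcfg.seed)
    order = rng.permutation(len(records))
    n_val = int(round(tcfg.val_fraction * len(records)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(np.unique(y_all[train_idx])) < 2:
        raise ValueError("training split lost a class; lower val_fraction")

    batches = _batches(records, train_idx, tcfg.batch_size)
    inputs = {i: _standardize(records[i].samples) for i in order}
    optimizer = Adam(model.parameters(), lr=tcfg.lr)

    history: List[Dict[str, float]] = []
    for epoch in range(tcfg.epochs):
        losses, hits, seen = [], 0, 0
        for batch in batches:
            x = np.stack([inputs[i] for i in batch])
            y = y_all[batch]
            logits = model.forward(x, training=True)
            loss, dlogits = cross_entropy_grad(logits, y)
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss * len(batch))
            hits += int((logits.argmax(axis=1) == y).sum())
            seen += len(batch)
        entry = {
            "epoch": float(epoch),
            "train_loss": float(np.sum(losses) / seen),
            "train_acc": hits / seen,
        }
        if n_val:
            val_hits = 0
            for i in val_idx:
                logits = model.forward(inputs[i][None, :], training=False)
                val_hits += int(logits.argmax(axis=1)[0] == y_all[i])
            entry["val_acc"] = val_hits / n_val
        history.append(entry)
    return history


def predict_proba(model: ResNet1D, record: EcgRecord) -> Tuple[float, float]:
    """Class probabilities ``(p_normal, p_afib)`` for one record."""
    x = _standardize(record.samples)[None, :]
    logits = model.forward(x, training=False)
    p = softmax(logits)[0]
    return float(p[0]), float(p[1])


def save_model(model: ResNet1D, path: str) -> None:
    """Single-file checkpoint: config as JSON plus all state arrays."""
    state = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, config=json.dumps(asdict(model.config)), **state)


def load_model(path: str) -> ResNet1D:
    data = np.load(path, allow_pickle=False)
    config = ModelConfig(**json.loads(str(data["config"])))
    model = ResNet1D(config)
    for i, target in enumerate(model.state_arrays()):
        source = data[f"arr_{i}"]
        if source.shape != target.shape:
            raise ValueError("checkpoint does not match the model architecture")
        target[...] = source
    return model
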