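"""SE-ResNet-18 binary classifier for log-mel spectrograms.

An 18-weighted-layer residual network with squeeze-and-excitation channel
attention in every residual block: a 3x3 stem convolution with 2x2 max
pooling, four stages of two residual blocks (each conv-BN-ReLU, conv-BN, SE,
shortcut add, ReLU; stride-2 projection shortcuts at stage transitions),
global average pooling, and a single-logit head.  Every convolution uses 3x3
filters; the SE reduction ratio is r=8 throughout.  Training uses Adam with
binary cross-entropy; "loose" is the positive class.

The published configuration (stage widths 64-512, lr 1e-5, 10 epochs) is the
default.  A narrower desk-scale configuration is provided for CPU-budget
experiments on synthetic data; see :func:`desk_scale_config`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import nn
from .excitation import ConfigurationError
from .features import Spectrogram

__all__ = [
    "ModelConfig",
    "SEResNet",
    "TrainedModel",
    "build_model",
    "desk_scale_config",
    "se_block",
    "train",
    "predict",
    "predict_batch",
    "classify",
    "save_model",
    "load_model",
]

LOOSE, FIXED = "loose", "fixed"


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults are the published training recipe; ``use_se=False`` yields the
    plain 18-layer residual baseline used in the ablation.
    """

    stage_filter_counts: tuple[int, int, int, int] = (64, 128, 256, 512)
    blocks_per_stage: int = 2
    kernel_size: int = 3
    se_reduction: int = 8
    learning_rate: float = 1e-5
    epochs: int = 10
    batch_size: int = 16
    use_se: bool = True
    input_shape: tuple[int, int] = (256, 218)
    threshold: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.use_se:
            bad = [c for c in self.stage_filter_counts if c % self.se_reduction]
            if bad:
                raise ConfigurationError(
                    f"SE reduction {self.se_reduction} must divide every stage "
                    f"filter count; offending counts: {bad}"
                )


def desk_scale_config(**overrides) -> ModelConfig:
    """A narrow, fast-converging configuration for CPU experiments.

    Same 18-layer topology, stage widths divided by 8 and a larger step size
    so that a few epochs on a small synthetic dataset suffice.
    """
    base = dict(
        stage_filter_counts=(8, 16, 32, 64),
        learning_rate=1e-3,
        epochs=3,
    )
    base.update(overrides)
    return ModelConfig(**base)


def se_block(feature_map: np.ndarray, r: int,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply a freshly initialized squeeze-and-excitation block.

    Functional wrapper used for inspection and testing; inside the network SE
    blocks are stateful layers with trained weights.
    """
    x = np.asarray(feature_map, dtype=np.float32)
    if x.ndim != 4:
        raise ValueError(f"feature map must be (N, H, W, C), got {x.shape}")
    c = x.shape[-1]
    if c % r != 0:
        raise ConfigurationError(f"channel count {c} not divisible by r={r}")
    block = nn.SEBlock(c, r, rng=rng or np.random.default_rng(0))
    return block.forward(x, train=False)


class _ResidualBlock:
    def __init__(self, c_in: int, c_out: int, stride: int, r: int,
                 use_se: bool, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(c_in, c_out, k=3, stride=stride, rng=rng)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(c_out, c_out, k=3, stride=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(c_out)
        self.se = nn.SEBlock(c_out, r, rng=rng) if use_se else None
        self.relu_out = nn.ReLU()
        if stride != 1 or c_in != c_out:
            self.proj = nn.Conv2d(c_in, c_out, k=1, stride=stride, rng=rng)
            self.proj_bn = nn.BatchNorm2d(c_out)
        else:
            self.proj = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        if self.se is not None:
            y = self.se.forward(y, train)
        if self.proj is not None:
            sc = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            sc = x
        return self.relu_out.forward(y + sc, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu_out.backward(dy)
        d_main, d_sc = dy, dy
        if self.se is not None:
            d_main = self.se.backward(d_main)
        d_main = self.conv1.backward(
            self.relu1.backward(self.bn1.backward(
                self.conv2.backward(self.bn2.backward(d_main))
            ))
        )
        if self.proj is not None:
            d_sc = self.proj.backward(self.proj_bn.backward(d_sc))
        return d_main + d_sc

    def parameters(self) -> list[nn.Param]:
        ps = (self.conv1.parameters() + self.bn1.parameters()
              + self.conv2.parameters() + self.bn2.parameters())
        if self.se is not None:
            ps += self.se.parameters()
        if self.proj is not None:
            ps += self.proj.parameters() + self.proj_bn.parameters()
        return ps


class SEResNet:
    """The 18-layer SE residual network (stem + 16 block convs + head)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 77]))
        w = config.stage_filter_counts
        self.stem = nn.Conv2d(1, w[0], k=3, stride=1, rng=rng)
        self.stem_bn = nn.BatchNorm2d(w[0])
        self.stem_relu = nn.ReLU()
        self.pool = nn.MaxPool2x2()
        self.blocks: list[_ResidualBlock] = []
        c_in = w[0]
        for stage, c_out in enumerate(w):
            for b in range(config.blocks_per_stage):
                stride = 2 if (stage > 0 and b == 0) else 1
                self.blocks.append(
                    _ResidualBlock(c_in, c_out, stride, config.se_reduction,
                                   config.use_se, rng)
                )
                c_in = c_out
        self.gap = nn.GlobalAvgPool()
        self.head = nn.Dense(c_in, 1, rng=rng)

    @property
    def weighted_layer_count(self) -> int:
        """Stem + block convolutions + classification head (projection
        shortcuts, SE bottlenecks and norms excluded, as in the usual
        residual-network layer count)."""
        return 1 + sum(2 for _ in self.blocks) + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch shaped (N, H, W) or (N, H, W, 1)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        h, w = self.config.input_shape
        if x.shape[1:3] != (h, w):
            raise ValueError(
                f"input spatial shape {x.shape[1:3]} does not match model "
                f"input {self.config.input_shape}"
            )
        y = self.pool.forward(
            self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(x, train), train), train),
            train,
        )
        for blk in self.blocks:
            y = blk.forward(y, train)
        return self.head.forward(self.gap.forward(y, train), train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.gap.backward(self.head.backward(dlogits[:, None].astype(np.float32)))
        for blk in reversed(self.blocks):
            dy = blk.backward(dy)
        self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(self.pool.backward(dy))))

    def parameters(self) -> list[nn.Param]:
        ps = self.stem.parameters() + self.stem_bn.parameters()
        for blk in self.blocks:
            ps += blk.parameters()
        return ps + self.head.parameters()


def build_model(config: ModelConfig | None = None) -> SEResNet:
    return SEResNet(config or ModelConfig())


@dataclass
class TrainedModel:
    """A trained network with its configuration and provenance."""

    network: SEResNet
    config: ModelConfig
    loss_history: list[float] = field(default_factory=list)
    train_digest: str = ""


def _as_array(spec) -> np.ndarray:
    if isinstance(spec, Spectrogram):
        return spec.values
    return np.asarray(spec)


def train(
    model: SEResNet,
    train_set: Sequence[tuple[object, int]],
    config: ModelConfig | None = None,
    log: list[str] | None = None,
) -> TrainedModel:
    """Train with Adam and binary cross-entropy for exactly ``epochs`` passes.

    ``train_set`` is a sequence of (spectrogram, label) pairs with label 1 for
    loose and 0 for fixed; both classes must be present.  Shuffling and
    optimization are driven by ``config.rng_seed`` only, so runs are exactly
    reproducible.
    """
    config = config or model.config
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    y = np.array([int(lbl) for _, lbl in train_set])
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes (fixed and loose)")
    X = np.stack([_as_array(s) for s, _ in train_set]).astype(np.float32)
    params = model.parameters()
    opt = nn.Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 88]))
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            logits = model.forward(X[idx], train=True)
            loss, dlogits = nn.bce_with_logits(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        if log is not None:
            log.append(f"epoch {epoch + 1}/{config.epochs}: bce={epoch_loss:.4f}")
    return TrainedModel(network=model, config=config, loss_history=history)


def predict(model: SEResNet | TrainedModel, spec) -> float:
    """Probability that a spectrogram comes from a loose screw."""
    net = model.network if isinstance(model, TrainedModel) else model
    arr = _as_array(spec)
    if arr.ndim != 2:
        raise ValueError(f"expected a single 2-D spectrogram, got shape {arr.shape}")
    logit = net.forward(arr[None], train=False)[0]
    return float(nn.sigmoid(np.array([logit]))[0])


def predict_batch(model: SEResNet | TrainedModel, specs: Iterable,
                  batch_size: int = 16) -> np.ndarray:
    net = model.network if isinstance(model, TrainedModel) else model
    arrs = [_as_array(s) for s in specs]
    out = []
    for start in range(0, len(arrs), batch_size):
        batch = np.stack(arrs[start : start + batch_size])
        out.append(nn.sigmoid(net.forward(batch, train=False)))
    return np.concatenate(out) if out else np.array([])


def classify(p: float, threshold: float = 0.5) -> str:
    """Map a loose-probability to a label; the boundary p == threshold is
    classified fixed (the decision requires strictly exceeding it)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    return LOOSE if p > threshold else FIXED


def save_model(model: TrainedModel, path: str | Path) -> Path:
    path = Path(path)
    params = model.network.parameters()
    arrays = {f"p{i}": p.data for i, p in enumerate(params)}
    bns = [l for l in _all_bn(model.network)]
    for i, bn in enumerate(bns):
        arrays[f"rm{i}"] = bn.running_mean
        arrays[f"rv{i}"] = bn.running_var
    cfg = asdict(model.config)
    np.savez(path, __config__=json.dumps(cfg), __losses__=np.array(model.loss_history), **arrays)
    return path


def load_model(path: str | Path) -> TrainedModel:
    with np.load(Path(path), allow_pickle=False) as data:
        cfg = json.loads(str(data["__config__"]))
        cfg["stage_filter_counts"] = tuple(cfg["stage_filter_counts"])
        cfg["input_shape"] = tuple(cfg["input_shape"])
        config = ModelConfig(**cfg)
        net = SEResNet(config)
        for i, p in enumerate(net.parameters()):
            p.data = data[f"p{i}"].astype(np.float32)
        for i, bn in enumerate(_all_bn(net)):
            bn.running_mean = data[f"rm{i}"].astype(np.float32)
            bn.running_var = data[f"rv{i}"].astype(np.float32)
            bn._initialized = True
        losses = [float(v) for v in data["__losses__"]]
    return TrainedModel(network=net, config=config, loss_history=losses)


def _all_bn(net: SEResNet):
    yield net.stem_bn
    for blk in net.blocks:
        yield blk.bn1
        yield blk.bn2
        if blk.proj is not None:
            yield blk.proj_bn
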