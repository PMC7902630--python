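"""The three 2D encoder-decoder segmentation architectures.

All share one U-shaped skeleton: ``depth`` contracting steps of
[block, 2×2 max-pool] with filters doubling per level, a bottleneck block
with dropout, and a mirrored expanding path of [stride-2 transposed conv,
skip concatenation, block], closed by a 1×1 convolution with sigmoid.  The
variants differ only in the block:

* ``unet``     — two conv3×3-BN-ReLU units;
* ``resunet``  — the same 3×3 path summed with a parallel 1×1 projection,
  then ReLU;
* ``seunet``   — the plain block followed by a squeeze-and-excitation
  channel recalibration with one constant reduction ratio at every level.

The input channel count X ∈ {1,2,3} carries the auto-context: stage s of the
cascade consumes the raw slice plus the s−1 predecessor masks.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from ..errors import ConfigurationError, ContractError
from ..volume_io import SliceStack
from .layers import (
    BatchNorm2D,
    Conv2D,
    Dropout,
    Layer,
    MaxPool2,
    Param,
    ReLU,
    Sequential,
    SqueezeExcite,
    UpConv2,
)

ARCHITECTURES = ("unet", "resunet", "seunet")


@dataclass
class SegModelConfig:
    arch: str = "unet"
    in_channels: int = 1
    depth: int = 4
    base_filters: int = 16
    dropout_rate: float = 0.2
    se_ratio: int = 8
    input_size: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if self.arch not in ARCHITECTURES:
            raise ConfigurationError(f"arch must be one of {ARCHITECTURES}, got {self.arch!r}")
        if self.in_channels not in (1, 2, 3):
            raise ConfigurationError(f"in_channels must be 1, 2 or 3, got {self.in_channels}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError(f"dropout_rate must be in [0,1), got {self.dropout_rate}")
        if self.depth < 1 or self.base_filters < 1 or self.se_ratio < 1:
            raise ConfigurationError("depth, base_filters and se_ratio must be >= 1")
        self.input_size = tuple(int(s) for s in self.input_size)  # type: ignore[assignment]
        h, w = self.input_size
        f = 2**self.depth
        if h % f or w % f:
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by 2^depth = {f}"
            )


class _ResBlock(Layer):
    """3×3 conv-BN-ReLU ×2 summed with a 1×1 projection, then ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.main = Sequential(
            Conv2D(cin, cout, 3, rng), BatchNorm2D(cout), ReLU(),
            Conv2D(cout, cout, 3, rng), BatchNorm2D(cout), ReLU(),
        )
        self.proj = Conv2D(cin, cout, 1, rng)
        self._mask = None

    def params(self) -> list[Param]:
        return self.main.params() + self.proj.params()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        s = self.main.forward(x, training) + self.proj.forward(x, training)
        if training:
            self._mask = s > 0
        return np.maximum(s, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        ds = dout * self._mask
        self._mask = None
        return self.main.backward(ds) + self.proj.backward(ds)


def _make_block(arch: str, cin: int, cout: int, se_ratio: int,
                rng: np.random.Generator) -> Layer:
    if arch == "resunet":
        return _ResBlock(cin, cout, rng)
    layers: list[Layer] = [
        Conv2D(cin, cout, 3, rng), BatchNorm2D(cout), ReLU(),
        Conv2D(cout, cout, 3, rng), BatchNorm2D(cout), ReLU(),
    ]
    if arch == "seunet":
        layers.append(SqueezeExcite(cout, se_ratio, rng))
    return Sequential(*layers)


class _UNet(Layer):
    def __init__(self, cfg: SegModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        d, base = cfg.depth, cfg.base_filters
        filters = [base * 2**i for i in range(d + 1)]
        self.enc = []
        cin = cfg.in_channels
        for i in range(d):
            self.enc.append(_make_block(cfg.arch, cin, filters[i], cfg.se_ratio, rng))
            cin = filters[i]
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = _make_block(cfg.arch, filters[d - 1], filters[d], cfg.se_ratio, rng)
        self.dropout = Dropout(cfg.dropout_rate, rng)
        self.ups, self.dec = [], []
        cur = filters[d]
        for i in reversed(range(d)):
            self.ups.append(UpConv2(cur, filters[i], rng))
            self.dec.append(_make_block(cfg.arch, 2 * filters[i], filters[i], cfg.se_ratio, rng))
            cur = filters[i]
        self.head = Conv2D(base, 1, 1, rng)
        self._split: list[int] = []

    def _modules(self) -> list[Layer]:
        return [*self.enc, *self.pools, self.bottleneck, self.dropout,
                *self.ups, *self.dec, self.head]

    def params(self) -> list[Param]:
        return [p for m in self._modules() for p in m.params()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        skips = []
        h = x
        for block, pool in zip(self.enc, self.pools):
            h = block.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        h = self.bottleneck.forward(h, training)
        h = self.dropout.forward(h, training)
        self._split = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, training)
            self._split.append(h.shape[1])
            h = np.concatenate([h, skip], axis=1)
            h = dec.forward(h, training)
        return self.head.forward(h, training)  # logits

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.head.backward(dlogits)
        dskips = []
        for up, dec, c_up in zip(reversed(self.ups), reversed(self.dec),
                                 reversed(self._split)):
            d = dec.backward(d)
            d_up, d_skip = d[:, :c_up], d[:, c_up:]
            dskips.append(d_skip)
            d = up.backward(np.ascontiguousarray(d_up))
        d = self.dropout.backward(d)
        d = self.bottleneck.backward(d)
        # backward visited decoder stages shallowest-first, so dskips is
        # ordered [level 0, level 1, ...]; the encoder unwinds deepest-first
        for block, pool, d_skip in zip(reversed(self.enc), reversed(self.pools),
                                       reversed(dskips)):
            d = pool.backward(d)
            d = block.backward(d + d_skip)
        return d


class SegModel:
    """Trainable per-slice segmentation function: (N,H,W,X) -> (N,H,W) ∈ [0,1]."""

    def __init__(self, config: SegModelConfig, seed: int):
        self.config = config
        self.seed = seed
        self.net = _UNet(config, np.random.default_rng(seed))

    # -- core passes --------------------------------------------------------
    def forward_logits(self, x_nchw: np.ndarray, training: bool) -> np.ndarray:
        return self.net.forward(x_nchw.astype(np.float32, copy=False), training)

    def backward(self, dlogits: np.ndarray) -> None:
        self.net.backward(dlogits.astype(np.float32, copy=False))

    def params(self) -> list[Param]:
        return self.net.params()

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def num_params(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- inference ----------------------------------------------------------
    def predict_probs(self, x_nhwc: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """(N,H,W,C) -> (N,H,W) probabilities; dropout off, BN running stats."""
        x = np.ascontiguousarray(np.moveaxis(x_nhwc, 3, 1), dtype=np.float32)
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward_logits(x[i:i + batch_size], training=False)
            out.append(1.0 / (1.0 + np.exp(-logits[:, 0])))
        return np.concatenate(out, axis=0)

    # -- serialization ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.value for i, p in enumerate(self.params())}
        bn = [m for m in _walk_layers(self.net) if isinstance(m, BatchNorm2D)]
        for i, layer in enumerate(bn):
            state[f"bn{i}_mean"] = layer.running_mean
            state[f"bn{i}_var"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = state[f"p{i}"].astype(np.float32).copy()
            p.grad = np.zeros_like(p.value)
        bn = [m for m in _walk_layers(self.net) if isinstance(m, BatchNorm2D)]
        for i, layer in enumerate(bn):
            layer.running_mean = state[f"bn{i}_mean"].astype(np.float32).copy()
            layer.running_var = state[f"bn{i}_var"].astype(np.float32).copy()

    def save(self, path: str | Path) -> None:
        """npz weight checkpoint with the config alongside as YAML."""
        path = Path(path)
        np.savez(path, **self.state_arrays())
        cfg = asdict(self.config) | {"seed": self.seed}
        path.with_suffix(".yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        path = Path(path)
        cfg = yaml.safe_load(path.with_suffix(".yaml").read_text())
        seed = cfg.pop("seed")
        cfg["input_size"] = tuple(cfg["input_size"])
        model = cls(SegModelConfig(**cfg), seed)
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as st:
            model.load_state_arrays(dict(st))
        return model


def _walk_layers(layer: Layer):
    yield layer
    children: list[Layer] = []
    if isinstance(layer, Sequential):
        children = layer.layers
    elif isinstance(layer, _ResBlock):
        children = [layer.main, layer.proj]
    elif isinstance(layer, _UNet):
        children = layer._modules()
    for c in children:
        yield from _walk_layers(c)


def build_model(cfg: SegModelConfig, seed: int) -> SegModel:
    """Instantiate one of the three architectures with seeded deterministic init."""
    return SegModel(cfg, seed)


def predict_stack(m: SegModel, s: SliceStack) -> SliceStack:
    """Per-slice inference over an ordered stack; returns probabilities (C=1)."""
    if s.channels != m.config.in_channels:
        raise ContractError(
            f"stack has {s.channels} channels but model expects "
            f"{m.config.in_channels} (auto-context stage mismatch)"
        )
    if s.slices.shape[1:3] != m.config.input_size:
        raise ContractError(
            f"slice shape {s.slices.shape[1:3]} does not match model input "
            f"{m.config.input_size}"
        )
    probs = m.predict_probs(s.slices)
    return SliceStack(slices=probs[..., np.newaxis].astype(np.float64), axis=s.axis)
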