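"""U-Net and U-Net++ slice segmenters.

Both networks map a single-channel (h, w) intensity image to a same-size
probability map. The U-Net is the classic contracting/expanding encoder–
decoder with skip connections; the U-Net++ variant uses a ResNet-18-style
residual encoder and the nested dense skip pathways that define the
architecture, with deep supervision off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import BatchNorm2d, Conv2d, ConvBlock, Module, ResidualBlock

__all__ = ["ModelConfig", "UNet", "UNetPlusPlus", "build_model"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of a slice segmenter.

    ``depth`` counts resolution levels (so depth 2 pools once); input
    dimensions must be divisible by ``2**(depth - 1)``.
    """

    architecture: str = "unet"  # "unet" | "unetpp"
    encoder: str = "plain"  # "resnet18" forced for unetpp
    depth: int = 4
    base_filters: int = 32
    input_size: tuple[int, int] = (64, 64)
    use_batchnorm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("unet", "unetpp"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        div = 2 ** (self.depth - 1)
        h, w = self.input_size
        if h % div or w % div:
            raise ValueError(
                f"input size {self.input_size} must be divisible by {div} "
                f"(depth {self.depth})"
            )


class _Segmenter(Module):
    """Shared plumbing: logits forward, probability forward, summary."""

    config: ModelConfig

    def forward(self, x: Tensor) -> Tensor:  # logits
        raise NotImplementedError

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Probability map for one (h, w) image, in eval mode."""
        was_training = self.training
        self.set_training(False)
        try:
            x = Tensor(np.asarray(image, dtype=np.float64)[None, None])
            p = ad.sigmoid(self.forward(x)).data[0, 0]
        finally:
            self.set_training(was_training)
        return p

    def summary(self) -> str:
        cfg = self.config
        return (
            f"{cfg.architecture} (encoder={cfg.encoder}, depth={cfg.depth}, "
            f"base_filters={cfg.base_filters}, input={cfg.input_size[0]}x"
            f"{cfg.input_size[1]}): {self.n_parameters():,} parameters"
        )


class UNet(_Segmenter):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = [cfg.base_filters * 2**i for i in range(cfg.depth)]
        self.encoders = _ModuleList(
            self, "enc",
            [ConvBlock(1 if i == 0 else ch[i - 1], ch[i], cfg.use_batchnorm, rng)
             for i in range(cfg.depth)],
        )
        self.decoders = _ModuleList(
            self, "dec",
            [ConvBlock(ch[i] + ch[i + 1], ch[i], cfg.use_batchnorm, rng)
             for i in reversed(range(cfg.depth - 1))],
        )
        self.head = Conv2d(ch[0], 1, k=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        for i, enc in enumerate(self.encoders):
            if i > 0:
                x = ad.maxpool2x2(x)
            x = enc(x)
            skips.append(x)
        for j, dec in enumerate(self.decoders):
            skip = skips[self.config.depth - 2 - j]
            x = dec(ad.concat_channels([skip, ad.upsample2x(x)]))
        return self.head(x)


class UNetPlusPlus(_Segmenter):
    """Nested U-Net with a residual (ResNet-18 basic-block) encoder.

    Decoder node X[i][j] fuses all same-level predecessors X[i][0..j-1]
    with the upsampled deeper node X[i+1][j-1]; the output head reads
    X[0][depth-1]. Deep supervision is off by default: auxiliary heads on
    X[0][1..depth-2] are built only when requested.
    """

    def __init__(self, cfg: ModelConfig, deep_supervision: bool = False):
        super().__init__()
        if cfg.encoder not in ("resnet18", "plain"):
            raise ValueError(f"unknown encoder {cfg.encoder!r}")
        self.config = cfg
        self.deep_supervision = deep_supervision
        rng = np.random.default_rng(cfg.seed)
        d = cfg.depth
        ch = [cfg.base_filters * 2**i for i in range(d)]

        if cfg.encoder == "resnet18":
            encs = [
                _Pair(ResidualBlock(1 if i == 0 else ch[i - 1], ch[i], rng),
                      ResidualBlock(ch[i], ch[i], rng))
                for i in range(d)
            ]
        else:
            encs = [
                ConvBlock(1 if i == 0 else ch[i - 1], ch[i], cfg.use_batchnorm, rng)
                for i in range(d)
            ]
        self.encoders = _ModuleList(self, "enc", encs)

        # nested nodes X[i][j], j >= 1: input channels j*ch[i] + ch[i+1]
        nodes = {}
        for j in range(1, d):
            for i in range(d - j):
                nodes[(i, j)] = ConvBlock(
                    j * ch[i] + ch[i + 1], ch[i], cfg.use_batchnorm, rng
                )
        self._node_keys = sorted(nodes)
        self.nodes = _ModuleList(self, "node", [nodes[k] for k in self._node_keys])
        self.head = Conv2d(ch[0], 1, k=1, rng=rng)
        if deep_supervision:
            self.aux_heads = _ModuleList(
                self, "aux", [Conv2d(ch[0], 1, k=1, rng=rng) for _ in range(d - 2)]
            )

    def _node(self, i: int, j: int):
        return self.nodes[self._node_keys.index((i, j))]

    def forward(self, x: Tensor) -> Tensor:
        d = self.config.depth
        grid: dict[tuple[int, int], Tensor] = {}
        for i, enc in enumerate(self.encoders):
            if i > 0:
                x = ad.maxpool2x2(x)
            x = enc(x)
            grid[(i, 0)] = x
        for j in range(1, d):
            for i in range(d - j - 1, -1, -1):
                parts = [grid[(i, k)] for k in range(j)]
                parts.append(ad.upsample2x(grid[(i + 1, j - 1)]))
                grid[(i, j)] = self._node(i, j)(ad.concat_channels(parts))
        return self.head(grid[(0, d - 1)])


class _Pair(Module):
    """Two blocks applied in sequence (a ResNet stage)."""

    def __init__(self, first: Module, second: Module):
        super().__init__()
        self.first = first
        self.second = second

    def __call__(self, x: Tensor) -> Tensor:
        return self.second(self.first(x))


class _ModuleList(Module):
    """Indexed container that registers its items as child modules."""

    def __init__(self, parent: Module, name: str, modules: list[Module]):
        super().__init__()
        self._items = list(modules)
        for k, m in enumerate(self._items):
            setattr(self, f"{name}{k}", m)

    def __iter__(self):
        return iter(self._items)

    def __getitem__(self, k):
        return self._items[k]

    def __len__(self):
        return len(self._items)


def build_model(cfg: ModelConfig) -> _Segmenter:
    """Construct the configured segmenter; see :class:`ModelConfig`."""
    if cfg.architecture == "unet":
        return UNet(cfg)
    if cfg.encoder == "plain":
        cfg = replace(cfg, encoder="resnet18")
    return UNetPlusPlus(cfg)
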