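"""The triple-attention encoder-decoder network and its ablation variants.

The architecture is a U-shaped encoder-decoder.  The encoder is a stack of
double (3x3 conv - BN - ReLU) blocks separated by 2x2 max pooling, doubling
the channel count at every level; a bottleneck block sits at the bottom.  Each
decoder stage is a *triple-attention decoder block*:

  (a) 2x2 stride-2 transpose convolution up-samples the deeper features and
      halves their channels;
  (b) the skip features are rescaled by an attention gate driven by the
      up-sampled tensor (if enabled);
  (c) gated skip and up-sampled tensor are concatenated;
  (d) a 3x3 conv - BN - ReLU reduces the concatenation to the stage width;
  (e) a channel-attention (SE) path and a spatial-attention path run in
      parallel on that tensor (disabled channel path = identity, disabled
      spatial path = zero mask);
  (f) the two paths are fused as Fc * (Fs + 1).

With all three attention flags off the stage reduces exactly to a plain
U-Net decoder stage.  The head is a 1x1 convolution to one channel followed
by a sigmoid, so the forward maps (B, 3, H, W) -> (B, 1, H, W) probabilities.

The eight on/off combinations of {attention gate, spatial, channel} form the
ablation matrix; :func:`ablation_suite` instantiates all eight under one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .attention import AttentionGate, ChannelAttention, SpatialAttention, fuse_dual_attention
from .autodiff import Module, ModuleList, Tensor


@dataclass(frozen=True)
class AttentionConfig:
    """Which of the three attention mechanisms a network variant enables."""

    ag: bool = True
    spatial: bool = True
    channel: bool = True

    def name(self) -> str:
        for name, cfg in VARIANTS.items():
            if cfg == self:
                return name
        raise AssertionError("unreachable: all 8 combinations are named")


#: The eight ablation variants, keyed by their canonical names.
VARIANTS: dict[str, AttentionConfig] = {
    "No-attention": AttentionConfig(False, False, False),
    "single-AG": AttentionConfig(True, False, False),
    "single-spatial": AttentionConfig(False, True, False),
    "single-channel": AttentionConfig(False, False, True),
    "AG+channel": AttentionConfig(True, False, True),
    "AG+spatial": AttentionConfig(True, True, False),
    "Spatial+channel": AttentionConfig(False, True, True),
    "Ours": AttentionConfig(True, True, True),
}


def variant_config(name: str) -> AttentionConfig:
    """Look up an :class:`AttentionConfig` by variant name (case-insensitive)."""
    for key, cfg in VARIANTS.items():
        if key.lower() == name.lower():
            return cfg
    raise KeyError(f"unknown variant {name!r}; choose from {list(VARIANTS)}")


@dataclass
class NetworkConfig:
    """Hyper-parameters defining one network instance.

    ``base_channels`` is the width of the first encoder level; widths double
    at each of the ``depth`` down-samplings, so the bottleneck is
    ``base_channels * 2**depth`` wide.  ``f_int_ratio`` divides the skip width
    to give the attention gate's intermediate width, and ``r`` is the SE
    reduction ratio.
    """

    in_channels: int = 3
    base_channels: int = 64
    depth: int = 4
    attention: AttentionConfig = field(default_factory=AttentionConfig)
    f_int_ratio: int = 2
    r: int = 16
    double_decoder_conv: bool = False

    def __post_init__(self):
        if isinstance(self.attention, (list, tuple)):
            self.attention = AttentionConfig(*self.attention)
        elif isinstance(self.attention, dict):
            self.attention = AttentionConfig(**self.attention)
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 2 or self.base_channels % 2:
            raise ValueError("base_channels must be even and >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


class ConvBlock(Module):
    """Two successive (3x3 conv -> batch norm -> ReLU) stages."""

    def __init__(self, in_channels: int, width: int, rng: np.random.Generator, dtype=None):
        super().__init__()
        self.conv1 = ad.Conv2d(in_channels, width, 3, rng, dtype=dtype)
        self.bn1 = ad.BatchNorm2d(width, dtype=dtype)
        self.conv2 = ad.Conv2d(width, width, 3, rng, dtype=dtype)
        self.bn2 = ad.BatchNorm2d(width, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        x = ad.relu(self.bn1(self.conv1(x)))
        return ad.relu(self.bn2(self.conv2(x)))


class TripleAttentionDecoderBlock(Module):
    """One decoder stage: up-sample, gate, concatenate, convolve, dual-attend.

    ``channels`` is the stage width C; the tensor from the level below must
    have 2C channels and half the spatial extent of the skip tensor.
    """

    def __init__(self, channels: int, attention: AttentionConfig, rng: np.random.Generator,
                 f_int_ratio: int = 2, r: int = 16, double_conv: bool = False, dtype=None):
        super().__init__()
        self.channels = channels
        self.attention = attention
        self.up = ad.ConvTranspose2d(2 * channels, channels, rng, dtype=dtype)
        if attention.ag:
            self.gate = AttentionGate(channels, channels, rng,
                                      f_int=max(1, channels // f_int_ratio), dtype=dtype)
        self.conv1 = ad.Conv2d(2 * channels, channels, 3, rng, dtype=dtype)
        self.bn1 = ad.BatchNorm2d(channels, dtype=dtype)
        if double_conv:
            self.conv2 = ad.Conv2d(channels, channels, 3, rng, dtype=dtype)
            self.bn2 = ad.BatchNorm2d(channels, dtype=dtype)
        self.double_conv = double_conv
        if attention.channel:
            self.cam = ChannelAttention(channels, rng, r=r, dtype=dtype)
        if attention.spatial:
            self.sam = SpatialAttention(channels, rng, dtype=dtype)

    def forward(self, skip: Tensor, below: Tensor) -> Tensor:
        if below.shape[1] != 2 * self.channels or skip.shape[1] != self.channels:
            raise ValueError(f"decoder stage of width {self.channels} got skip "
                             f"{skip.shape} and below {below.shape}")
        up = self.up(below)                                     # (a)
        if up.shape != skip.shape:
            raise ValueError(f"up-sampled shape {up.shape} does not match skip {skip.shape}")
        gated = self.gate(skip, up)[0] if self.attention.ag else skip   # (b)
        x = ad.concat([gated, up], axis=1)                      # (c)
        x = ad.relu(self.bn1(self.conv1(x)))                    # (d)
        if self.double_conv:
            x = ad.relu(self.bn2(self.conv2(x)))
        fc = self.cam(x) if self.attention.channel else x       # (e)
        if self.attention.spatial:
            fs = self.sam(x)
            return fuse_dual_attention(fc, fs)                  # (f)
        return fc  # Fs = 0: Fc * (0 + 1) = Fc


class ASCUNet(Module):
    """Encoder-decoder segmentation network with triple-attention decoding."""

    def __init__(self, config: NetworkConfig, seed: int = 0, dtype=None):
        super().__init__()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        widths = [config.base_channels * 2 ** k for k in range(config.depth + 1)]
        self.encoders = ModuleList()
        cin = config.in_channels
        for w in widths[:-1]:
            self.encoders.append(ConvBlock(cin, w, rng, dtype=dtype))
            cin = w
        self.bottleneck = ConvBlock(widths[-2], widths[-1], rng, dtype=dtype)
        self.decoders = ModuleList()
        for w in reversed(widths[:-1]):
            self.decoders.append(TripleAttentionDecoderBlock(
                w, config.attention, rng, f_int_ratio=config.f_int_ratio,
                r=config.r, double_conv=config.double_decoder_conv, dtype=dtype))
        self.head = ad.Conv2d(config.base_channels, 1, 1, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        n, c, h, w = x.shape
        div = 2 ** self.config.depth
        if h % div or w % div:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by 2**depth = {div}")
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = ad.maxpool2x2(x)
        x = self.bottleneck(x)
        for dec, skip in zip(self.decoders, reversed(skips)):
            x = dec(skip, x)
        return ad.sigmoid(self.head(x))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Probability maps (B, 1, H, W) for a batch, in eval mode, no grad."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(Tensor(images)).data
        finally:
            self.train(was_training)
        return out

    def predict_mask(self, images: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Binary masks (B, H, W); probabilities >= threshold are foreground."""
        return (self.predict_proba(images)[:, 0] >= threshold).astype(np.uint8)


def build_ascunet(config: NetworkConfig, seed: int = 0, dtype=None) -> ASCUNet:
    """Construct a network from a config with deterministic initialization."""
    return ASCUNet(config, seed=seed, dtype=dtype)


def ablation_suite(base_config: NetworkConfig, seed: int = 0, dtype=None
                   ) -> list[tuple[str, ASCUNet]]:
    """All eight attention variants of ``base_config``, in canonical order.

    Every variant is built from the same seed, so shared sub-modules that are
    constructed in the same order receive identical initial weights.
    """
    suite = []
    for name, att in VARIANTS.items():
        cfg = NetworkConfig(**{**base_config.to_dict(), "attention": att})
        suite.append((name, build_ascunet(cfg, seed=seed, dtype=dtype)))
    return suite
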