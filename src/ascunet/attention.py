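"""The three attention mechanisms of the triple-attention decoder.

* :class:`AttentionGate` — additive attention on the skip connection: a coarse
  gating signal and the skip features are projected to a shared intermediate
  width by 1x1 convolutions, summed, passed through ReLU and a 1x1 projection
  to a single channel, and squashed by a sigmoid into one scalar attention
  coefficient per pixel,

      alpha = sigmoid( psi^T relu(Wx^T x + Wg^T g + b_g) + b_psi ),

  which then rescales every channel of the skip features.
* :class:`SpatialAttention` — a position-wise mask: 1x1 conv to C/2 channels,
  batch norm, ReLU, 1x1 conv to a single channel, sigmoid; the single-channel
  map is replicated across all C channels.
* :class:`ChannelAttention` — a squeeze-and-excitation block: global average
  pooling per channel, a two-layer bottleneck MLP (reduction ratio ``r``) and
  a sigmoid, yielding one scaling factor in [0, 1] per channel.
* :func:`fuse_dual_attention` — combines the parallel channel and spatial
  paths as ``Fc * (Fs + 1)``; the +1 means the spatial mask can only amplify
  features, never zero them out.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Tensor


def _validate_finite(t: Tensor, name: str) -> None:
    if not np.all(np.isfinite(t.data)):
        raise ValueError(f"{name} contains non-finite values")


class AttentionGate(Module):
    """Additive attention gate producing one scalar coefficient per pixel.

    Parameters
    ----------
    f_l : channels of the skip features ``x``.
    f_g : channels of the gating signal ``g``.
    f_int : intermediate width; defaults to ``max(1, f_l // 2)``.

    ``Wx`` is bias-free; the gate path carries the bias ``b_g`` and the final
    1x1 projection ``psi`` carries the scalar bias ``b_psi``.  If ``g`` lives
    on a coarser grid than ``x`` it is resampled to ``x``'s grid by bilinear
    interpolation before the additive step.
    """

    def __init__(self, f_l: int, f_g: int, rng: np.random.Generator,
                 f_int: int | None = None, dtype=None):
        super().__init__()
        if f_int is None:
            f_int = max(1, f_l // 2)
        if f_int < 1:
            raise ValueError("f_int must be >= 1")
        self.f_l, self.f_g, self.f_int = f_l, f_g, f_int
        self.Wx = ad.Conv2d(f_l, f_int, 1, rng, bias=False, dtype=dtype)
        self.Wg = ad.Conv2d(f_g, f_int, 1, rng, bias=True, dtype=dtype)
        self.psi = ad.Conv2d(f_int, 1, 1, rng, bias=True, dtype=dtype)

    def forward(self, x: Tensor, g: Tensor) -> tuple[Tensor, Tensor]:
        """Return ``(gated, alpha)``: rescaled skip features and the map."""
        if x.shape[0] != g.shape[0]:
            raise ValueError(f"batch mismatch: x has {x.shape[0]}, g has {g.shape[0]}")
        _validate_finite(x, "attention gate input x")
        _validate_finite(g, "attention gate gating signal g")
        if g.shape[2:] != x.shape[2:]:
            g = ad.resize_bilinear(g, x.shape[2:])
        q = ad.relu(self.Wx(x) + self.Wg(g))
        alpha = ad.sigmoid(self.psi(q))          # (N, 1, H, W)
        return x * alpha, alpha


class SpatialAttention(Module):
    """Two 1x1 convolutions collapsing channels to a sigmoid position mask.

    The first convolution halves the channel count (C must be even) and is
    followed by batch normalization and ReLU; the second reduces to a single
    channel which the sigmoid maps into [0, 1].  The mask is then stacked
    channel-wise C times so its shape matches the input.
    """

    def __init__(self, channels: int, rng: np.random.Generator, dtype=None):
        super().__init__()
        if channels < 2 or channels % 2:
            raise ValueError(f"SpatialAttention requires an even channel count >= 2, got {channels}")
        self.channels = channels
        self.conv1 = ad.Conv2d(channels, channels // 2, 1, rng, dtype=dtype)
        self.bn = ad.BatchNorm2d(channels // 2, dtype=dtype)
        self.conv2 = ad.Conv2d(channels // 2, 1, 1, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        mask = ad.sigmoid(self.conv2(ad.relu(self.bn(self.conv1(x)))))  # (N,1,H,W)
        n, _, h, w = mask.shape
        return ad.broadcast_to(mask, (n, self.channels, h, w))


class ChannelAttention(Module):
    """Squeeze-and-excitation: per-channel scaling factors in [0, 1].

    ``r`` is the bottleneck reduction ratio (SENet convention, default 16),
    clamped to the channel count so narrow test networks still construct;
    after clamping the channel count must be divisible by ``r``.
    """

    def __init__(self, channels: int, rng: np.random.Generator, r: int = 16, dtype=None):
        super().__init__()
        r = min(r, channels)
        if channels % r:
            raise ValueError(f"channels ({channels}) must be divisible by reduction ratio ({r})")
        self.channels, self.r = channels, r
        self.fc1 = ad.Linear(channels, channels // r, rng, dtype=dtype)
        self.fc2 = ad.Linear(channels // r, channels, rng, dtype=dtype)

    def excite(self, z: Tensor) -> Tensor:
        """Map squeezed descriptors (N, C) to scaling factors (N, C)."""
        return ad.sigmoid(self.fc2(ad.relu(self.fc1(z))))

    def forward(self, x: Tensor) -> Tensor:
        z = channel_squeeze(x)
        cs = self.excite(z)
        n, c = cs.shape
        return x * ad.reshape(cs, (n, c, 1, 1))


def channel_squeeze(x: Tensor) -> Tensor:
    """Global average pooling: (N, C, H, W) -> (N, C) per-channel means."""
    return ad.global_avg_pool(x)


def fuse_dual_attention(fc: Tensor, fs: Tensor) -> Tensor:
    """Fuse the channel path ``Fc`` and spatial mask ``Fs`` as ``Fc * (Fs + 1)``.

    Because ``Fs`` lies in [0, 1], the fused output never attenuates:
    ``|out| >= |Fc|`` element-wise.
    """
    if fc.shape != fs.shape:
        raise ValueError(f"shape mismatch: Fc {fc.shape} vs Fs {fs.shape}")
    return fc * (fs + 1.0)
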