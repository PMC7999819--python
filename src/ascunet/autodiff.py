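"""Minimal reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operator set the segmentation network needs: broadcasted
arithmetic, matmul, sigmoid/ReLU/log/clip, reductions, channel concatenation,
2-D convolution (stride 1, "same" padding for odd kernels), 2x2/stride-2
transpose convolution, 2x2 max pooling, bilinear resizing, and batch
normalization, plus layer classes (`Conv2d`, `ConvTranspose2d`, `BatchNorm2d`,
`Linear`), a `Module` container protocol and an `AdamW` optimizer.

Gradients flow through a dynamically built tape: every op records its parents
and a closure that scatters the output gradient back to them; `Tensor.backward`
walks the tape in reverse topological order.  All computation is plain numpy,
so results are deterministic for a fixed seed on a fixed BLAS.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator

import numpy as np

# Default parameter/compute dtype.  float32 keeps training fast on one core;
# every op preserves the dtype of its inputs, so float64 flows through
# unchanged when callers need tighter numerics.
DTYPE = np.float32


def _as_array(x, dtype=None) -> np.ndarray:
    a = np.asarray(x)
    if dtype is not None:
        a = a.astype(dtype, copy=False)
    elif not np.issubdtype(a.dtype, np.floating):
        a = a.astype(DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverses numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # reverse topological order over the tape
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = _accumulate(self.grad, _as_array(grad, self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _add_grad(self, g: np.ndarray) -> None:
        self.grad = _accumulate(self.grad, g)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_ensure_tensor(other))

    def __rsub__(self, other):
        return add(_ensure_tensor(other), -self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, pow_(other, -1.0))

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- conveniences --------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def _accumulate(current: np.ndarray | None, update: np.ndarray) -> np.ndarray:
    if current is None:
        # always copy: the incoming array may be shared with a sibling's grad
        return np.array(update)
    current += update
    return current


def _ensure_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _ensure_tensor(a), _ensure_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._add_grad(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._add_grad(_unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b) -> Tensor:
    a, b = _ensure_tensor(a), _ensure_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._add_grad(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._add_grad(_unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def pow_(a, p: float) -> Tensor:
    a = _ensure_tensor(a)
    out_data = a.data ** p

    def backward(g):
        a._add_grad(g * p * a.data ** (p - 1.0))

    return Tensor(out_data, parents=(a,), backward=backward)


def matmul(a, b) -> Tensor:
    a, b = _ensure_tensor(a), _ensure_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._add_grad(g @ b.data.swapaxes(-1, -2))
        if b.requires_grad:
            b._add_grad(a.data.swapaxes(-1, -2) @ g)

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(a) -> Tensor:
    a = _ensure_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0)

    def backward(g):
        a._add_grad(g * mask)

    return Tensor(out_data, parents=(a,), backward=backward)


def sigmoid(a) -> Tensor:
    a = _ensure_tensor(a)
    # numerically stable two-sided form
    out_data = np.empty_like(a.data)
    pos = a.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    e = np.exp(a.data[~pos])
    out_data[~pos] = e / (1.0 + e)

    def backward(g):
        a._add_grad(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(a,), backward=backward)


def log(a) -> Tensor:
    a = _ensure_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        a._add_grad(g / a.data)

    return Tensor(out_data, parents=(a,), backward=backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient is passed only through unclamped entries."""
    a = _ensure_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._add_grad(g * mask)

    return Tensor(out_data, parents=(a,), backward=backward)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._add_grad(np.broadcast_to(g, a.shape).astype(a.dtype, copy=False))
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            a._add_grad(np.broadcast_to(g, a.shape).astype(a.dtype, copy=False))

    return Tensor(out_data, parents=(a,), backward=backward)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = _ensure_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[i] for i in ax]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = _ensure_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a._add_grad(g.reshape(a.shape))

    return Tensor(out_data, parents=(a,), backward=backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [_ensure_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._add_grad(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def broadcast_to(a, shape) -> Tensor:
    a = _ensure_tensor(a)
    out_data = np.broadcast_to(a.data, shape).copy()

    def backward(g):
        a._add_grad(_unbroadcast(g, a.shape))

    return Tensor(out_data, parents=(a,), backward=backward)


# ---------------------------------------------------------------------------
# spatial ops (NCHW layout)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*kh*kw) patch matrix, stride 1."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    n, c, ho, wo, _, _ = win.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return cols, (n, ho, wo)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, pad: int) -> Tensor:
    """2-D cross-correlation, stride 1. weight: (Cout, Cin, kh, kw)."""
    cout, cin, kh, kw = weight.shape
    n, c, h, w = x.shape
    if c != cin:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {cin}")
    cols, (n_, ho, wo) = _im2col(x.data, kh, kw, pad)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out = cols @ wmat.T
    if bias is not None:
        out += bias.data
    out_data = out.reshape(n_, ho, wo, cout).transpose(0, 3, 1, 2)

    def backward(g):
        gcols = g.transpose(0, 2, 3, 1).reshape(-1, cout)  # (N*Ho*Wo, Cout)
        if weight.requires_grad:
            gw = gcols.T @ cols
            weight._add_grad(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._add_grad(gcols.sum(axis=0))
        if x.requires_grad:
            dcols = (gcols @ wmat).reshape(n_, ho, wo, cin, kh, kw)
            hp, wp = h + 2 * pad, w + 2 * pad
            dxp = np.zeros((n, cin, hp, wp), dtype=x.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + ho, j:j + wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            x._add_grad(dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out_data, parents=parents, backward=backward)


def conv_transpose2d_2x2(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """2x2, stride-2 transpose convolution: doubles H and W.

    weight: (Cin, Cout, 2, 2).  Non-overlapping windows, so each output pixel
    receives exactly one contribution.
    """
    n, cin, h, w = x.shape
    cin_w, cout = weight.shape[0], weight.shape[1]
    if cin != cin_w:
        raise ValueError(f"conv_transpose2d: input has {cin} channels, weight expects {cin_w}")
    # (N,H,W,Cout,2,2)
    t = np.tensordot(x.data, weight.data, axes=([1], [0]))
    out_data = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, cout, 2 * h, 2 * w)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None, None]

    def backward(g):
        gb = g.reshape(n, cout, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)  # (N,H,W,Cout,2,2)
        if x.requires_grad:
            gx = np.tensordot(gb, weight.data, axes=([3, 4, 5], [1, 2, 3]))
            x._add_grad(gx.transpose(0, 3, 1, 2))
        if weight.requires_grad:
            gw = np.tensordot(x.data, gb, axes=([0, 2, 3], [0, 1, 2]))
            weight._add_grad(gw)
        if bias is not None and bias.requires_grad:
            bias._add_grad(g.sum(axis=(0, 2, 3)))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out_data, parents=parents, backward=backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 requires even spatial dims, got {h}x{w}")
    h2, w2 = h // 2, w // 2
    v = x.data.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    idx = v.argmax(axis=-1)  # first max wins ties: deterministic
    out_data = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gv = np.zeros_like(v)
        np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
        gx = gv.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._add_grad(gx)

    return Tensor(out_data, parents=(x,), backward=backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C): per-channel spatial mean (SE-style squeeze)."""
    if x.ndim != 4 or x.shape[2] < 1 or x.shape[3] < 1:
        raise ValueError("global_avg_pool expects a non-empty NCHW tensor")
    return mean(x, axis=(2, 3))


def _bilinear_weights(out_size: int, in_size: int):
    """Half-pixel-center (align_corners=False) source indices and weights."""
    if in_size == 1:
        lo = np.zeros(out_size, dtype=np.intp)
        return lo, lo, np.ones(out_size)
    scale = in_size / out_size
    src = (np.arange(out_size) + 0.5) * scale - 0.5
    src = np.clip(src, 0, in_size - 1)
    lo = np.floor(src).astype(np.intp)
    hi = np.minimum(lo + 1, in_size - 1)
    w_hi = src - lo
    return lo, hi, 1.0 - w_hi


def resize_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Differentiable bilinear resize of an NCHW tensor."""
    n, c, h, w = x.shape
    oh, ow = out_hw
    if (oh, ow) == (h, w):
        return x
    rlo, rhi, rwl = _bilinear_weights(oh, h)
    clo, chi, cwl = _bilinear_weights(ow, w)
    rwl_ = rwl[:, None]
    cwl_ = cwl[None, :]

    d = x.data
    top = d[:, :, rlo][:, :, :, clo] * cwl_ + d[:, :, rlo][:, :, :, chi] * (1 - cwl_)
    bot = d[:, :, rhi][:, :, :, clo] * cwl_ + d[:, :, rhi][:, :, :, chi] * (1 - cwl_)
    out_data = top * rwl_ + bot * (1 - rwl_)

    def backward(g):
        gx = np.zeros_like(x.data)
        for rw_sel, ridx in ((rwl_, rlo), (1 - rwl_, rhi)):
            for cw_sel, cidx in ((cwl_, clo), (1 - cwl_, chi)):
                contrib = g * rw_sel * cw_sel
                np.add.at(gx, (slice(None), slice(None), ridx[:, None], cidx[None, :]), contrib)
        x._add_grad(gx)

    return Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Container with parameter discovery, train/eval mode, and state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffers", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")
        for name, p in own.items():
            p.data = _as_array(state[name], p.data.dtype).reshape(p.shape)
        # buffers are plain arrays on the module; assign through the owner
        for name in bufs:
            owner, attr = self._resolve(name)
            setattr(owner, attr, np.asarray(state[name], dtype=bufs[name].dtype).copy())

    def _resolve(self, dotted: str) -> tuple["Module", str]:
        obj: Module | ModuleList = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if isinstance(obj, ModuleList) else getattr(obj, part)
        return obj, parts[-1]


class ModuleList(list):
    """A list whose Module items are visible to parameter discovery."""


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


def kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int, dtype=None) -> np.ndarray:
    """He/Kaiming uniform init for ReLU networks: U(-sqrt(6/fan_in), +)."""
    bound = float(np.sqrt(6.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape).astype(dtype or DTYPE)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True, dtype=None):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("Conv2d supports odd kernel sizes (stride 1, same padding)")
        self.in_channels, self.out_channels, self.kernel_size = in_channels, out_channels, kernel_size
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(kaiming_uniform(rng, (out_channels, in_channels, kernel_size, kernel_size),
                                             fan_in, dtype), requires_grad=True)
        if bias:
            bound = 1.0 / np.sqrt(fan_in)
            self.bias = Tensor(rng.uniform(-bound, bound, out_channels).astype(dtype or DTYPE),
                               requires_grad=True)
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.pad)


class ConvTranspose2d(Module):
    """Fixed 2x2 kernel, stride 2: the U-Net up-sampling operator."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 bias: bool = True, dtype=None):
        super().__init__()
        self.in_channels, self.out_channels = in_channels, out_channels
        fan_in = in_channels  # each output pixel sees one input pixel per in-channel
        self.weight = Tensor(kaiming_uniform(rng, (in_channels, out_channels, 2, 2),
                                             fan_in, dtype), requires_grad=True)
        if bias:
            bound = 1.0 / np.sqrt(fan_in)
            self.bias = Tensor(rng.uniform(-bound, bound, out_channels).astype(dtype or DTYPE),
                               requires_grad=True)
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d_2x2(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, dtype=None):
        super().__init__()
        self.weight = Tensor(kaiming_uniform(rng, (in_features, out_features), in_features, dtype),
                             requires_grad=True)
        if bias:
            bound = 1.0 / np.sqrt(in_features)
            self.bias = Tensor(rng.uniform(-bound, bound, out_features).astype(dtype or DTYPE),
                               requires_grad=True)
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight)
        return add(out, self.bias) if self.bias is not None else out


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics.

    In training mode the batch statistics over (N, H, W) normalize the
    activations and update the running estimates; in eval mode the running
    estimates are used, so a freshly initialized layer in eval mode applies
    unit scale and zero shift.
    """

    _buffers = ("running_mean", "running_var")

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1, dtype=None):
        super().__init__()
        dt = dtype or DTYPE
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features, dtype=dt), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=dt), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != self.num_features:
            raise ValueError(f"BatchNorm2d({self.num_features}) got shape {x.shape}")
        if self.training:
            mu = mean(x, axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = mean(centered * centered, axis=(0, 2, 3), keepdims=True)
            n = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            inv_std = pow_(var + self.eps, -0.5)
            xhat = centered * inv_std
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1).astype(x.dtype)
            inv = (1.0 / np.sqrt(self.running_var + self.eps)).reshape(1, -1, 1, 1).astype(x.dtype)
            xhat = (x - Tensor(mu)) * Tensor(inv)
        g = reshape(self.gamma, (1, -1, 1, 1))
        b = reshape(self.beta, (1, -1, 1, 1))
        return xhat * g + b


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: Iterable[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
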