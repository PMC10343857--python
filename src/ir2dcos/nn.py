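"""A compact NumPy neural-network engine for small residual CNNs.

Implements exactly the pieces the image classifier needs: 2-D
convolution (im2col + GEMM), batch normalization, ReLU, global average
pooling, a fully connected layer, identity / convolution residual
blocks, softmax cross-entropy and SGD with momentum and weight decay.
Forward and backward passes are plain float32 array code; everything is
deterministic for a fixed seed on one machine.

Convolution spatial arithmetic follows

    n_out = floor((n_in + 2p - f) / s) + 1

with ``p`` padding, ``f`` filter side, ``s`` stride; every layer's
realized output size is checked against this formula by
:func:`shape_audit`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConvSpec", "conv_output_size", "Parameter",
    "Conv2d", "BatchNorm2d", "ReLU", "GlobalAvgPool", "Linear", "Sequential",
    "IdentityBlock", "ConvBlock", "ResNet",
    "softmax", "cross_entropy", "SGD", "shape_audit",
]


@dataclass(frozen=True)
class ConvSpec:
    """Spatial parameters of one convolution: input side, padding, filter, stride."""

    n_in: int
    p: int
    f: int
    s: int
    channels_out: int = 1

    def __post_init__(self) -> None:
        if min(self.n_in, self.f, self.s, self.channels_out) <= 0 or self.p < 0:
            raise ValueError(f"invalid ConvSpec {self}")
        if self.f > self.n_in + 2 * self.p:
            raise ValueError(f"filter {self.f} exceeds padded input {self.n_in + 2 * self.p}")


def conv_output_size(spec: ConvSpec) -> int:
    """Output side length: floor((n_in + 2p - f)/s) + 1."""
    n_out = (spec.n_in + 2 * spec.p - spec.f) // spec.s + 1
    if n_out <= 0:
        raise ValueError(f"non-positive output size for {spec}")
    return int(n_out)


class Parameter:
    """A trainable array with its gradient buffer."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Layer:
    """Base layer: forward caches whatever backward needs."""

    training = True

    def forward(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []

    def set_training(self, flag: bool) -> None:
        self.training = flag


class Conv2d(Layer):
    """2-D convolution via im2col; NCHW layout, square filters, no bias.

    Bias is omitted because every convolution here is followed by batch
    normalization, whose shift absorbs it.
    """

    def __init__(self, in_ch: int, out_ch: int, f: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.f, self.stride, self.padding = f, stride, padding
        fan_in = in_ch * f * f
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, f, f))
        self.weight = Parameter(w, "conv_w")
        self._cache: tuple | None = None
        self.last_in_size: int | None = None
        self.last_out_size: int | None = None

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, int, int]:
        n, c, h, w = x.shape
        f, s, p = self.f, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        hp, wp = x.shape[2], x.shape[3]
        ho = (hp - f) // s + 1
        wo = (wp - f) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (f, f), axis=(2, 3))
        win = win[:, :, ::s, ::s]                       # n, c, ho, wo, f, f
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
        return cols.reshape(n * ho * wo, c * f * f), ho, wo

    def forward(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        self.last_in_size = int(x.shape[2])
        cols, ho, wo = self._im2col(x)
        self.last_out_size = ho
        wmat = self.weight.data.reshape(self.out_ch, -1)
        out = cols @ wmat.T                             # (n*ho*wo, out_ch)
        self._cache = (cols, x.shape, ho, wo)
        return np.ascontiguousarray(
            out.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)
        )

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        f, s, p = self.f, self.stride, self.padding
        g = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        self.weight.grad += (g.T @ cols).reshape(self.weight.data.shape)
        dcols = g @ self.weight.data.reshape(self.out_ch, -1)
        dcols = dcols.reshape(n, ho, wo, c, f, f)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for fi in range(f):
            for fj in range(f):
                dxp[:, :, fi:fi + s * ho:s, fj:fj + s * wo:s] += (
                    dcols[:, :, :, :, fi, fj].transpose(0, 3, 1, 2)
                )
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp

    def parameters(self) -> list[Parameter]:
        return [self.weight]

    def spec(self) -> ConvSpec:
        if self.last_in_size is None:
            raise RuntimeError("layer has not seen input yet")
        return ConvSpec(self.last_in_size, self.padding, self.f, self.stride,
                        self.out_ch)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W).

    ``momentum`` is the fraction of the batch statistic blended into the
    running estimate each step; evaluation mode uses the running stats.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels), "bn_gamma")
        self.beta = Parameter(np.zeros(channels), "bn_beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return self.gamma.data[None, :, None, None] * xhat + \
            self.beta.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        if not self.training:
            return g * inv[None, :, None, None]
        # dx = inv/m * (m*g - sum(g) - xhat*sum(g*xhat))
        sum_g = g.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_gx = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv[None, :, None, None] / m) * (m * g - sum_g - xhat * sum_gx)

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class GlobalAvgPool(Layer):
    """Collapse each feature map to its spatial mean: (N,C,H,W) -> (N,C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.weight = Parameter(w, "fc_w")
        self.bias = Parameter(np.zeros(n_out), "fc_b")

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for layer in self.layers:
            layer.set_training(flag)


class IdentityBlock(Layer):
    """Residual block with an identity shortcut: out = ReLU(x + F(x)).

    F is conv3x3 - BN - ReLU - conv3x3 - BN; input and output shapes are
    equal by construction, so the shortcut is the raw input.
    """

    kind = "identity"

    def __init__(self, channels: int, rng: np.random.Generator):
        self.f = Sequential(
            Conv2d(channels, channels, 3, 1, 1, rng), BatchNorm2d(channels),
            ReLU(),
            Conv2d(channels, channels, 3, 1, 1, rng), BatchNorm2d(channels),
        )
        self.out_relu = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.out_relu.forward(x + self.f.forward(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.out_relu.backward(grad)
        return g + self.f.backward(g)

    def parameters(self) -> list[Parameter]:
        return self.f.parameters()

    def set_training(self, flag: bool) -> None:
        self.training = flag
        self.f.set_training(flag)
        self.out_relu.set_training(flag)


class ConvBlock(Layer):
    """Residual block with a projection shortcut (dimensions change).

    Main path conv3x3(stride) - BN - ReLU - conv3x3 - BN; shortcut
    conv1x1(stride) - BN; out = ReLU(main + shortcut).
    """

    kind = "convolution"

    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator):
        self.f = Sequential(
            Conv2d(in_ch, out_ch, 3, stride, 1, rng), BatchNorm2d(out_ch),
            ReLU(),
            Conv2d(out_ch, out_ch, 3, 1, 1, rng), BatchNorm2d(out_ch),
        )
        self.shortcut = Sequential(
            Conv2d(in_ch, out_ch, 1, stride, 0, rng), BatchNorm2d(out_ch),
        )
        self.out_relu = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.out_relu.forward(self.f.forward(x) + self.shortcut.forward(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.out_relu.backward(grad)
        return self.f.backward(g) + self.shortcut.backward(g)

    def parameters(self) -> list[Parameter]:
        return self.f.parameters() + self.shortcut.parameters()

    def set_training(self, flag: bool) -> None:
        self.training = flag
        self.f.set_training(flag)
        self.shortcut.set_training(flag)
        self.out_relu.set_training(flag)


class ResNet(Layer):
    """Stem conv-BN-ReLU, four residual stages, GAP, fully connected head.

    Each stage opens with one convolution (projection) block followed by
    a configurable number of identity blocks; the default plan
    (1, 2, 2, 1) realizes 4 convolution + 6 identity blocks.
    """

    def __init__(
        self,
        n_classes: int,
        in_ch: int = 3,
        channels: tuple[int, ...] = (16, 32, 64, 128),
        identity_plan: tuple[int, ...] = (1, 2, 2, 1),
        stem_filter: int = 7,
        stem_stride: int = 2,
        bn_momentum: float = 0.1,
        seed: int = 0,
    ):
        if len(channels) != len(identity_plan):
            raise ValueError("channels and identity_plan lengths differ")
        rng = np.random.default_rng(seed)
        self.stem = Sequential(
            Conv2d(in_ch, channels[0], stem_filter, stem_stride,
                   stem_filter // 2, rng),
            BatchNorm2d(channels[0], bn_momentum), ReLU(),
        )
        self.blocks: list[Layer] = []
        prev = channels[0]
        for i, (ch, n_id) in enumerate(zip(channels, identity_plan)):
            stride = 1 if i == 0 else 2
            self.blocks.append(ConvBlock(prev, ch, stride, rng))
            for _ in range(n_id):
                self.blocks.append(IdentityBlock(ch, rng))
            prev = ch
        for b in self.blocks:
            for seq in (getattr(b, "f", None), getattr(b, "shortcut", None)):
                if seq is not None:
                    for layer in seq.layers:
                        if isinstance(layer, BatchNorm2d):
                            layer.momentum = bn_momentum
        self.pool = GlobalAvgPool()
        self.head = Linear(prev, n_classes, rng)
        self.n_classes = n_classes

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self.stem.forward(x)
        for b in self.blocks:
            x = b.forward(x)
        return self.head.forward(self.pool.forward(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.pool.backward(self.head.backward(grad))
        for b in reversed(self.blocks):
            grad = b.backward(grad)
        return self.stem.backward(grad)

    def parameters(self) -> list[Parameter]:
        ps = self.stem.parameters()
        for b in self.blocks:
            ps += b.parameters()
        return ps + self.pool.parameters() + self.head.parameters()

    def set_training(self, flag: bool) -> None:
        self.training = flag
        self.stem.set_training(flag)
        for b in self.blocks:
            b.set_training(flag)

    def bn_layers(self) -> list[BatchNorm2d]:
        bns = [l for l in self.stem.layers if isinstance(l, BatchNorm2d)]
        for b in self.blocks:
            for seq in (b.f, getattr(b, "shortcut", None)):
                if seq is not None:
                    bns += [l for l in seq.layers if isinstance(l, BatchNorm2d)]
        return bns

    def recalibrate_bn(self, X: np.ndarray, batch_size: int = 64) -> None:
        """Replace BN running statistics with statistics of ``X``.

        Small-batch training leaves running estimates lagging the batch
        statistics actually used during optimization, which distorts
        evaluation-mode outputs; a cumulative-average pass over the
        training images (as in stochastic weight averaging's BN update)
        re-anchors them.
        """
        bns = self.bn_layers()
        saved = [bn.momentum for bn in bns]
        self.set_training(True)
        n_batches = 0
        for i in range(0, X.shape[0], batch_size):
            for bn in bns:
                bn.momentum = 1.0 / (n_batches + 1)   # cumulative average
            self.forward(X[i:i + batch_size])
            n_batches += 1
        for bn, m in zip(bns, saved):
            bn.momentum = m
        self.set_training(False)

    def block_counts(self) -> dict[str, int]:
        counts = {"identity": 0, "convolution": 0}
        for b in self.blocks:
            counts[b.kind] += 1
        return counts

    def conv_layers(self) -> list[Conv2d]:
        """Every Conv2d in the network, in forward order."""
        convs = [l for l in self.stem.layers if isinstance(l, Conv2d)]
        for b in self.blocks:
            for seq in (b.f, getattr(b, "shortcut", None)):
                if seq is not None:
                    convs += [l for l in seq.layers if isinstance(l, Conv2d)]
        return convs


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), y] + eps).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(logits.dtype)


class SGD:
    """Stochastic gradient descent with momentum and decoupled-style L2 decay.

    Update: v <- mu*v - lr*(grad + wd*param); param <- param + v.
    """

    def __init__(self, params: list[Parameter], lr: float = 0.01,
                 momentum: float = 0.9, weight_decay: float = 1e-4):
        if lr < 0 or weight_decay < 0 or not 0 <= momentum < 1:
            raise ValueError("invalid optimizer hyperparameters")
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * (p.grad + self.weight_decay * p.data)
            p.data += v


def shape_audit(model: ResNet, input_size: int, in_ch: int = 3) -> list[dict]:
    """Run a dummy forward pass and verify every conv layer's spatial size.

    Returns one record per convolution with the realized and predicted
    output sizes; raises if any layer disagrees with the closed-form
    ``conv_output_size``.
    """
    model.set_training(False)
    x = np.zeros((1, in_ch, input_size, input_size), dtype=np.float32)
    model.forward(x)
    report = []
    for conv in model.conv_layers():
        spec = conv.spec()
        predicted = conv_output_size(spec)
        record = {
            "n_in": spec.n_in, "p": spec.p, "f": spec.f, "s": spec.s,
            "channels_out": spec.channels_out,
            "n_out_realized": conv.last_out_size,
            "n_out_predicted": predicted,
        }
        report.append(record)
        if predicted != conv.last_out_size:
            raise AssertionError(f"shape mismatch: {record}")
    return report
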