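"""Layer and module abstractions over the autodiff core.

Mirrors the familiar deep-learning Module pattern: parameters are
discovered by attribute traversal, `train()`/`eval()` toggle behaviour of
regularisers and batch norm, and `state_dict()` round-trips both
parameters and running statistics.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    """A learnable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self._training = True

    # -- traversal -----------------------------------------------------------
    def _named_children(self):
        """Yield (name, Parameter | Module), recursing through nested
        lists/tuples so e.g. a list of lists of layers is discovered."""

        def walk(name, value):
            if isinstance(value, (Parameter, Module)):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    yield from walk(f"{name}.{i}", item)

        for name, value in vars(self).items():
            if not name.startswith("_"):
                yield from walk(name, value)

    def named_parameters(self, prefix=""):
        for name, value in self._named_children():
            if isinstance(value, Parameter):
                yield prefix + name, value
            else:
                yield from value.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for _, value in self._named_children():
            if isinstance(value, Module):
                yield from value.modules()

    def named_buffers(self, prefix=""):
        for name, value in self._named_children():
            if isinstance(value, Module):
                yield from value.named_buffers(prefix=f"{prefix}{name}.")
        for name, value in getattr(self, "_buffers", {}).items():
            yield f"{prefix}{name}", value

    # -- mode ----------------------------------------------------------------
    @property
    def training(self):
        return self._training

    def train(self, mode: bool = True):
        for m in self.modules():
            m._training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- serialisation -------------------------------------------------------
    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state["buffer:" + name] = np.array(buf, copy=True)
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = bufs[key[len("buffer:"):]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.data = np.asarray(value, dtype=np.float64).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """3x3/7x7/1x1-style convolution layer with optional dilation.

    ``padding="same"`` preserves spatial extents (odd kernels only).
    """

    def __init__(self, in_channels, out_channels, kernel_size, *,
                 dilation=1, padding="same", bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        k = int(kernel_size)
        if padding == "same":
            if k % 2 == 0:
                raise ValueError(
                    "size-preserving padding requires an odd kernel length")
            padding = dilation * (k - 1) // 2
        self._padding = padding
        self._dilation = dilation
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * k * k
        self.weight = Parameter(_he_init(rng, (out_channels, in_channels, k, k),
                                         fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, padding=self._padding,
                        dilation=self._dilation)


class ConvTranspose2x2(Module):
    """2x2 stride-2 transposed convolution (exact spatial doubling)."""

    def __init__(self, in_channels, out_channels, *, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_init(rng, (in_channels, out_channels, 2, 2),
                                         in_channels * 4))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return T.conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels, *, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self._momentum = momentum
        self._eps = eps
        self._running = {"mean": np.zeros(channels), "var": np.ones(channels)}
        self._buffers = {"running_mean": self._running["mean"],
                         "running_var": self._running["var"]}

    def forward(self, x):
        return T.batch_norm2d(x, self.gamma, self.beta, self._running,
                              training=self._training, momentum=self._momentum,
                              eps=self._eps)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)
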