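"""Layer containers built on the autograd tensor.

Parameter discovery walks instance attributes recursively (lists and dicts of
modules included), so composite blocks need no registration boilerplate.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, no_grad


class Parameter(Tensor):
    def __init__(self, data, dtype=None):
        super().__init__(data, requires_grad=True, dtype=dtype)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ------------------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v
            elif isinstance(val, dict):
                for k, v in val.items():
                    if isinstance(v, Module):
                        yield f"{name}.{k}", v

    def modules(self):
        yield "", self
        for name, child in self._children():
            for sub, m in child.modules():
                yield (f"{name}.{sub}" if sub else name), m

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield (f"{prefix}{name}", val)
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def train(self, mode: bool = True):
        for _, m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization --------------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self.modules():
            if isinstance(m, BatchNorm2d):
                pre = f"{name}." if name else ""
                state[f"{pre}running_mean"] = m.running_mean.copy()
                state[f"{pre}running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict):
        """Load parameters; shapes may differ from the freshly built module
        (channel-pruned checkpoints), so layer bookkeeping follows the loaded
        tensors."""
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.array(state[name], dtype=p.data.dtype)
        for name, m in self.modules():
            if isinstance(m, BatchNorm2d):
                pre = f"{name}." if name else ""
                m.running_mean = np.array(state[f"{pre}running_mean"])
                m.running_var = np.array(state[f"{pre}running_var"])
                m.channels = m.weight.data.shape[0]
            elif isinstance(m, Conv2d):
                w = m.weight.data
                m.cout = w.shape[0]
                if m.groups > 1:
                    m.groups = w.shape[0]
                    m.cin = w.shape[0]
                else:
                    m.cin = w.shape[1] * m.groups
        return self

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng, shape, fan_in):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, kernel=1, stride=1, padding=None, groups=1,
                 bias=False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if padding is None:
            padding = kernel // 2
        self.cin, self.cout = cin, cout
        self.kernel, self.stride, self.padding, self.groups = kernel, stride, padding, groups
        fan_in = (cin // groups) * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (cout, cin // groups, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    """Per-channel normalize-then-affine: z=(x-mu)/sqrt(var+eps); out = gamma*z + beta."""

    def __init__(self, channels, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels, dtype=np.float32))   # gamma
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))    # beta
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xn = (x - mu) / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xn = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.weight.reshape(1, self.channels, 1, 1)
        b = self.bias.reshape(1, self.channels, 1, 1)
        return xn * g + b


class Linear(Module):
    def __init__(self, cin, cout, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (cin, cout), cin))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Seeded per instance."""

    def __init__(self, p: float = 0.5, seed: int = 0):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(seed)

    def reseed(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def forward(self, x):
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(x.data.dtype))


class Adam:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


__all__ = ["Parameter", "Module", "Sequential", "Conv2d", "BatchNorm2d",
           "Linear", "Dropout", "Adam", "no_grad"]
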