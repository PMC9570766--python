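"""Module system and standard layers built on the autograd core."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, batch_norm, conv2d

__all__ = ["Parameter", "Module", "ModuleList", "Conv2d", "BatchNorm2d", "Linear",
           "Identity", "ReLU", "Sigmoid"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Container tracking parameters, buffers and submodules by attribute."""

    def __init__(self):
        self.training = True

    # -- discovery ---------------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = ""):
        out = {}
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                out[prefix + name] = val
        for name, child in self._children():
            out.update(child.named_parameters(prefix + name + "."))
        return out

    def parameters(self):
        return list(self.named_parameters().values())

    def named_buffers(self, prefix: str = ""):
        out = {}
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                out[prefix + name] = val
        for name, child in self._children():
            out.update(child.named_buffers(prefix + name + "."))
        return out

    # -- state -------------------------------------------------------------
    def state_dict(self):
        state = {k: v.data.copy() for k, v in self.named_parameters().items()}
        state.update({k: v.copy() for k, v in self.named_buffers().items()})
        return state

    def load_state_dict(self, state, strict: bool = True):
        params = self.named_parameters()
        buffers = self.named_buffers()
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: "
                        f"{params[key].data.shape} vs {value.shape}"
                    )
                params[key].data = np.asarray(value, dtype=params[key].data.dtype)
            elif key in buffers:
                buffers[key][...] = value
            elif strict:
                raise KeyError(f"unexpected state entry {key!r}")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    pass


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0,
                 groups=1, bias=True, rng=None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        rng = rng or np.random.default_rng()
        fan_in = in_channels // groups * kernel_size * kernel_size
        # He initialisation, appropriate for ReLU networks
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std,
                       (out_channels, in_channels // groups,
                        kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x):
        return batch_norm(x, self.weight, self.bias, self.running_mean,
                          self.running_var, self.training, self.momentum, self.eps)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = math.sqrt(1.0 / in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()
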