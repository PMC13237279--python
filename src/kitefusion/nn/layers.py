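"""Layer/module abstractions on top of the autodiff tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, batch_norm, concat

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ConvBNReLU",
    "InvertedResidual",
    "Linear",
]


class Module:
    """Container with recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        """Flat name -> array mapping of parameters and batch-norm statistics."""
        out = {}

        def visit(mod, prefix):
            for k, v in mod.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    out[f"{prefix}{k}"] = v.data
                elif isinstance(v, np.ndarray):
                    out[f"{prefix}{k}"] = v
                elif isinstance(v, Module):
                    visit(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{prefix}{k}.{i}.")

        visit(self, "")
        return out

    def load_state_dict(self, state: dict):
        def visit(mod, prefix):
            for k, v in mod.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    v.data = np.array(state[f"{prefix}{k}"], dtype=v.data.dtype)
                elif isinstance(v, np.ndarray):
                    mod.__dict__[k] = np.array(state[f"{prefix}{k}"], dtype=v.dtype)
                elif isinstance(v, Module):
                    visit(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{prefix}{k}.{i}.")

        visit(self, "")
        return self


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel=3, stride=1, pad=None, rng=None, bias=True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)).astype(
                np.float32
            ),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
            if bias
            else None
        )

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            out, mu, var = batch_norm(x, self.gamma, self.beta, eps=self.eps)
            self.running_mean = (
                1 - self.momentum
            ) * self.running_mean + self.momentum * mu.astype(np.float32)
            self.running_var = (
                1 - self.momentum
            ) * self.running_var + self.momentum * var.astype(np.float32)
            return out
        mean = self.running_mean.reshape(1, c, 1, 1)
        std = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
        xhat = (x - Tensor(mean)) * Tensor(1.0 / std)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ConvBNReLU(Module):
    def __init__(self, c_in, c_out, kernel=3, stride=1, rng=None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, kernel=kernel, stride=stride, rng=rng)
        self.bn = BatchNorm2d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class InvertedResidual(Module):
    """MobileNet-style block: 1x1 expand -> 3x3 (optionally strided) -> 1x1 project.

    A residual shortcut is used when stride is 1 and channel counts match.
    """

    def __init__(self, c_in, c_out, stride=1, expand=2, rng=None):
        super().__init__()
        c_mid = max(c_in * expand, c_out)
        self.expand = ConvBNReLU(c_in, c_mid, kernel=1, rng=rng)
        self.depth = ConvBNReLU(c_mid, c_mid, kernel=3, stride=stride, rng=rng)
        self.project = Conv2d(c_mid, c_out, kernel=1, rng=rng)
        self.project_bn = BatchNorm2d(c_out)
        self.use_residual = stride == 1 and c_in == c_out

    def __call__(self, x: Tensor) -> Tensor:
        y = self.project_bn(self.project(self.depth(self.expand(x))))
        if self.use_residual:
            y = y + x
        return y


class Linear(Module):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias
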