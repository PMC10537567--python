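"""Layer modules over the autodiff ops: parameters, init, train/eval state."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class; concrete modules populate ``_params`` and ``_modules``."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def parameters(self):
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix=""):
        for k, v in self._params.items():
            yield f"{prefix}{k}", v
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def named_buffers(self, prefix=""):
        for k in getattr(self, "_buffers", ()):
            yield f"{prefix}{k}", getattr(self, k)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix=f"{prefix}{name}.")

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self):
        d = {k: np.array(v.data) for k, v in self.named_parameters()}
        d.update({k: np.array(v) for k, v in self.named_buffers()})
        return d

    def load_state_dict(self, d):
        for k, v in self.named_parameters():
            v.data = np.array(d[k])
        for k, _ in self.named_buffers():
            parts = k.split(".")
            obj = self
            for p in parts[:-1]:
                obj = obj._modules[p]
            setattr(obj, parts[-1], np.array(d[k]))


class Conv2d(Module):
    """Grouped 2-D convolution with Kaiming-uniform weight init."""

    def __init__(self, cin, cout, k, stride=1, padding=0, groups=1,
                 bias=False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (cin // groups) * k * k
        bound = np.sqrt(6.0 / fan_in)
        w = rng.uniform(-bound, bound, size=(cout, cin // groups, k, k))
        self._params["weight"] = Tensor(w.astype(np.float32), requires_grad=True)
        if bias:
            self._params["bias"] = Tensor(
                np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self._params["weight"], self._params.get("bias"),
                         stride=self.stride, padding=self.padding,
                         groups=self.groups)


class BatchNorm2d(Module):
    """Batch normalization with running statistics (momentum update)."""

    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self._params["gamma"] = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self._params["beta"] = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._buffers = ("running_mean", "running_var")

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        g, b = self._params["gamma"], self._params["beta"]
        if training:
            out, mean, var = ag.batch_norm_train(x, g, b, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
            return out
        return ag.batch_norm(x, g, b, self.running_mean, self.running_var, self.eps)


class ConvBNAct(Module):
    """Conv → BatchNorm → ReLU6, the basic unit of every encoder/decoder layer."""

    def __init__(self, cin, cout, k, stride=1, padding=0, groups=1,
                 act=True, rng=None):
        super().__init__()
        self.act = act
        self._modules["conv"] = Conv2d(cin, cout, k, stride, padding, groups, rng=rng)
        self._modules["bn"] = BatchNorm2d(cout)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        y = self._modules["conv"](x)
        y = self._modules["bn"](y, training)
        return ag.relu6(y) if self.act else y
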