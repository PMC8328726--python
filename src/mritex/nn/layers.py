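"""Layer and optimizer primitives built on the autodiff tensors."""

from __future__ import annotations

from typing import Dict, Iterable, List

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "Adam"]


class Module:
    """Minimal parameter container; subclasses assign Conv2d/Module attrs."""

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        seen = set()

        def collect(obj) -> None:
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        collect(self)
        return params

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict size mismatch")
        for i, p in enumerate(params):
            p.data = np.asarray(state[str(i)], dtype=np.float64).reshape(p.data.shape)


class Conv2d(Module):
    """Stride-1 'same' convolution with He-normal initialisation."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        dilation: int = 1,
    ):
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.standard_normal((out_channels, in_channels, kernel_size, kernel_size)) * std,
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, dilation=self.dilation)


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
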