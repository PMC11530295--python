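"""Parameter containers, basic layers, and the Adam optimizer.

A `Module` is a plain object whose attributes may be `Tensor` parameters or
other Modules; `parameters()` walks that tree.  Initialization is explicit
and seeded everywhere — the package guarantees bit-reproducible training
given a seed, so no layer ever draws from global RNG state.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Module:
    """Base class: parameter discovery plus train/eval mode switching."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for sub, p in val.parameters().items():
                    out[f"{name}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = p
        return out

    def set_training(self, flag: bool):
        for val in vars(self).values():
            if isinstance(val, Module):
                val.set_training(flag)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item.set_training(flag)
        if hasattr(self, "training"):
            self.training = flag

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    """Affine map  x @ W.T + b  with Glorot-uniform init; bias optional.

    Vector-channel linears in the geometric layers must use ``bias=False``:
    a bias on a 3-vector channel would break rotation equivariance.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_out, n_in)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim > 2:
            # flatten to one big GEMM instead of a batched loop of small ones
            lead = x.shape[:-1]
            y = x.reshape(int(np.prod(lead)), x.shape[-1]) @ self.W.transpose()
            y = y.reshape(*lead, self.W.shape[0])
        else:
            y = x @ self.W.transpose()
        if self.b is not None:
            y = y + self.b
        return y


class VectorLinear(Module):
    """Channel-mixing linear map on stacks of 3-vectors, no bias.

    Input (..., n_in, 3) -> output (..., n_out, 3).  Acting only on the
    channel axis commutes with any rotation applied to the spatial axis.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_out, n_in)), requires_grad=True)

    def __call__(self, v: Tensor) -> Tensor:
        # (L, n_in, 3) -> (L*3, n_in) @ W.T as a single GEMM -> (L, n_out, 3)
        L, n_in = v.shape[0], v.shape[1]
        flat = v.transpose(0, 2, 1).reshape(L * 3, n_in)
        out = flat @ self.W.transpose()
        return out.reshape(L, 3, self.W.shape[0]).transpose(0, 2, 1)


class Dropout(Module):
    """Inverted dropout; active only in training mode, mask drawn from `rng`."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1): {rate}")
        self.rate = rate
        self.training = False

    def __call__(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class MLP(Module):
    """One-hidden-layer perceptron with ReLU, the default readout block."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, rng: np.random.Generator):
        self.fc1 = Linear(n_in, n_hidden, rng)
        self.fc2 = Linear(n_hidden, n_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class Adam:
    """Standard Adam with bias correction; operates on a parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_grad_norm(params: dict[str, Tensor], max_norm: float) -> float:
    """Global-norm gradient clipping; returns the pre-clip norm."""
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float((p.grad**2).sum())
    total = np.sqrt(total)
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params.values():
            if p.grad is not None:
                p.grad = p.grad * scale   # no in-place: grad buffers may be shared
    return float(total)
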