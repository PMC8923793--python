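"""Neural layers used by the extraction models: embeddings, linear maps,
(bi)LSTM and (bi)GRU encoders, dropout bookkeeping, and the Adam optimizer.

All layers are batch-first: sequence inputs have shape ``(B, T, d)`` with an
accompanying ``(B, T)`` 0/1 mask for right-padding.  Hidden states are carried
unchanged through masked steps, so padded positions never influence real ones.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, concat, embedding, stack


def glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class with parameter registration and train/eval mode."""

    def __init__(self) -> None:
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out = {prefix + n: p for n, p in self._params.items()}
        for mn, m in self._modules.items():
            out.update(m.named_parameters(prefix + mn + "."))
        return out

    def train(self) -> None:
        self.training = True
        for m in self._modules.values():
            m.train()

    def eval(self) -> None:
        self.training = False
        for m in self._modules.values():
            m.eval()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # parameter (de)serialization -- arrays only, keyed by dotted names
    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch for parameters: {sorted(missing)}")
        for n, p in params.items():
            arr = np.asarray(state[n], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {n}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Embedding(Module):
    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.n_rows, self.dim = n_rows, dim
        self.weight = Parameter(rng.normal(0.0, 0.1, size=(n_rows, dim)))

    def __call__(self, indices: np.ndarray) -> Tensor:
        return embedding(self.weight, indices)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(glorot(rng, (d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class _RecurrentBase(Module):
    """Shared gate-matrix plumbing for LSTM/GRU cells."""

    def __init__(self, d_in: int, d_h: int, n_gates: int,
                 rng: np.random.Generator):
        super().__init__()
        self.d_in, self.d_h = d_in, d_h
        self.w_x = Parameter(glorot(rng, (d_in, n_gates * d_h)))
        self.w_h = Parameter(glorot(rng, (d_h, n_gates * d_h)))
        self.b = Parameter(np.zeros(n_gates * d_h))


class LSTM(_RecurrentBase):
    """Unidirectional LSTM over a padded batch."""

    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator):
        super().__init__(d_in, d_h, 4, rng)
        # forget-gate bias at 1: standard initialization for gradient flow
        self.b.data[d_h:2 * d_h] = 1.0

    def step(self, x_t: Tensor, h: Tensor, c: Tensor,
             m_t: np.ndarray) -> tuple[Tensor, Tensor]:
        d = self.d_h
        gates = x_t @ self.w_x + h @ self.w_h + self.b
        i = gates[:, 0 * d:1 * d].sigmoid()
        f = gates[:, 1 * d:2 * d].sigmoid()
        g = gates[:, 2 * d:3 * d].tanh()
        o = gates[:, 3 * d:4 * d].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        m = Tensor(m_t[:, None])
        keep = Tensor(1.0 - m_t[:, None])
        return m * h_new + keep * h, m * c_new + keep * c

    def __call__(self, x: Tensor, mask: np.ndarray,
                 reverse: bool = False) -> Tensor:
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.d_h)))
        c = Tensor(np.zeros((B, self.d_h)))
        order = range(T - 1, -1, -1) if reverse else range(T)
        outs: list[Tensor | None] = [None] * T
        for t in order:
            h, c = self.step(x[:, t, :], h, c, mask[:, t])
            outs[t] = h
        return stack(outs, axis=1)  # type: ignore[arg-type]


class GRU(_RecurrentBase):
    """Unidirectional GRU over a padded batch."""

    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator):
        super().__init__(d_in, d_h, 3, rng)

    def step(self, x_t: Tensor, h: Tensor, m_t: np.ndarray) -> Tensor:
        d = self.d_h
        gx = x_t @ self.w_x + self.b
        gh = h @ self.w_h
        r = (gx[:, 0 * d:1 * d] + gh[:, 0 * d:1 * d]).sigmoid()
        z = (gx[:, 1 * d:2 * d] + gh[:, 1 * d:2 * d]).sigmoid()
        n = (gx[:, 2 * d:3 * d] + r * gh[:, 2 * d:3 * d]).tanh()
        h_new = (Tensor(np.ones(1)) - z) * n + z * h
        m = Tensor(m_t[:, None])
        keep = Tensor(1.0 - m_t[:, None])
        return m * h_new + keep * h

    def __call__(self, x: Tensor, mask: np.ndarray,
                 reverse: bool = False) -> Tensor:
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.d_h)))
        order = range(T - 1, -1, -1) if reverse else range(T)
        outs: list[Tensor | None] = [None] * T
        for t in order:
            h = self.step(x[:, t, :], h, mask[:, t])
            outs[t] = h
        return stack(outs, axis=1)  # type: ignore[arg-type]


class BiLSTM(Module):
    """Bidirectional LSTM; output dim is ``2 * d_h``."""

    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTM(d_in, d_h, rng)
        self.bwd = LSTM(d_in, d_h, rng)
        self.d_out = 2 * d_h

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        return concat([self.fwd(x, mask), self.bwd(x, mask, reverse=True)],
                      axis=-1)


class BiGRU(Module):
    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = GRU(d_in, d_h, rng)
        self.bwd = GRU(d_in, d_h, rng)
        self.d_out = 2 * d_h

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        return concat([self.fwd(x, mask), self.bwd(x, mask, reverse=True)],
                      axis=-1)


class Adam:
    """Adam optimizer (Kingma & Ba) over a fixed parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm
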