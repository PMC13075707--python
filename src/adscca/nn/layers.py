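"""Neural building blocks: linear layers, batch normalization, dropout,
multilayer perceptrons and a bidirectional LSTM, all on the Tensor engine."""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .tensor import Tensor, concat, stack


class Module:
    """Base class tracking parameters and train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> List[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> List[tuple[str, Tensor]]:
        out = [(prefix + k, v) for k, v in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
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
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: v.data.copy() for k, v in self.named_parameters()}
        for name, m in self._modules.items():
            for k, v in getattr(m, "_buffers", {}).items():
                d[f"{name}.{k}"] = v.copy()
        for k, v in getattr(self, "_buffers", {}).items():
            d[k] = v.copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for k, v in d.items():
            if k in params:
                params[k].data = np.array(v, dtype=np.float64)
            else:  # buffer on a (possibly nested) module
                obj: Module = self
                parts = k.split(".")
                for part in parts[:-1]:
                    obj = obj._modules[part]
                obj._buffers[parts[-1]] = np.array(v, dtype=np.float64)


class Linear(Module):
    """Affine map with fan-in scaled Gaussian initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "fanin"):
        super().__init__()
        if init == "identity":
            if n_in != n_out:
                raise ValueError("identity init requires square layer")
            w = np.eye(n_in) + rng.normal(0.0, 1e-3, size=(n_in, n_out))
        else:
            w = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out))
        self.W = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class BatchNorm1d(Module):
    """Batch normalization over the sample axis with running statistics."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self._buffers = {
            "running_mean": np.zeros(n_features),
            "running_var": np.ones(n_features),
        }

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.ravel()
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.ravel()
            xhat = centered / (var + self.eps) ** 0.5
        else:
            mu = self._buffers["running_mean"]
            var = self._buffers["running_var"]
            xhat = (x - mu) / np.sqrt(var + self.eps)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.binomial(1, keep, size=x.shape) / keep
        return x * mask


class MLP(Module):
    """Feed-forward network with optional batch norm and ReLU between layers.

    `widths` gives [n_in, hidden..., n_out]; the final layer is linear.
    """

    def __init__(self, widths: Sequence[int], rng: np.random.Generator,
                 batchnorm: bool = True, activation: str = "relu",
                 init: str = "fanin"):
        super().__init__()
        self.n_layers = len(widths) - 1
        self.activation = activation
        self.use_bn = batchnorm
        for i in range(self.n_layers):
            setattr(self, f"lin{i}", Linear(widths[i], widths[i + 1], rng, init=init))
            if batchnorm and i < self.n_layers - 1:
                setattr(self, f"bn{i}", BatchNorm1d(widths[i + 1]))

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for i in range(self.n_layers):
            h = getattr(self, f"lin{i}")(h)
            if i < self.n_layers - 1:
                if self.use_bn:
                    h = getattr(self, f"bn{i}")(h)
                if self.activation == "relu":
                    h = h.relu()
                elif self.activation == "tanh":
                    h = h.tanh()
                elif self.activation != "none":
                    raise ValueError(f"unknown activation {self.activation!r}")
        return h


class GeneLocalMLP(Module):
    """Shared scalar MLP applied independently to every matrix entry.

    Used as a residual branch h = x + φ(x) where φ: ℝ→ℝ is a small
    1→width→1 network shared across genes within a modality. It can
    learn a per-modality nonlinear rescaling (e.g. undo a logistic
    squash) but cannot mix genes, so a sparse gate applied to h keeps
    its gene-level meaning.
    """

    def __init__(self, width: int, rng: np.random.Generator,
                 activation: str = "tanh"):
        super().__init__()
        self.inner = Linear(1, width, rng)
        self.outer = Linear(width, 1, rng)
        self.outer.W.data[:] = 0.0  # branch starts at zero → identity map
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        n, p = x.shape
        flat = x.reshape(n * p, 1)
        h = self.inner(flat)
        h = h.tanh() if self.activation == "tanh" else h.relu()
        return self.outer(h).reshape(n, p)


class LSTMCell(Module):
    """Standard LSTM cell (input/forget/cell/output gates)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        scale_x = 1.0 / np.sqrt(n_in)
        scale_h = 1.0 / np.sqrt(n_hidden)
        self.Wx = Tensor(rng.normal(0, scale_x, size=(n_in, 4 * n_hidden)),
                         requires_grad=True)
        self.Wh = Tensor(rng.normal(0, scale_h, size=(n_hidden, 4 * n_hidden)),
                         requires_grad=True)
        b = np.zeros(4 * n_hidden)
        b[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias, standard trick
        self.b = Tensor(b, requires_grad=True)
        self.n_hidden = n_hidden

    def __call__(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = x @ self.Wx + h @ self.Wh + self.b
        H = self.n_hidden
        i = z[:, 0:H].sigmoid()
        f = z[:, H:2 * H].sigmoid()
        g = z[:, 2 * H:3 * H].tanh()
        o = z[:, 3 * H:4 * H].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


class BiLSTM(Module):
    """Single bidirectional LSTM layer over a (n, L, d) token array.

    Returns the (n, L, 2*hidden) sequence of hidden states (forward and
    backward directions concatenated per position).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTMCell(n_in, n_hidden, rng)
        self.bwd = LSTMCell(n_in, n_hidden, rng)
        self.n_hidden = n_hidden

    def __call__(self, tokens: np.ndarray) -> Tensor:
        n, L, _ = tokens.shape
        h0 = Tensor(np.zeros((n, self.n_hidden)))
        c0 = Tensor(np.zeros((n, self.n_hidden)))
        hs_f: list[Tensor] = []
        h, c = h0, c0
        for l in range(L):
            h, c = self.fwd(Tensor(tokens[:, l, :]), h, c)
            hs_f.append(h)
        hs_b: list[Optional[Tensor]] = [None] * L
        h, c = h0, c0
        for l in reversed(range(L)):
            h, c = self.bwd(Tensor(tokens[:, l, :]), h, c)
            hs_b[l] = h
        per_pos = [concat([hf, hb], axis=1) for hf, hb in zip(hs_f, hs_b)]
        return stack(per_pos, axis=1)


class Adam:
    """Adam optimizer with optional classic L2 regularization and step-decay
    learning-rate schedule; gradient clipping by global norm."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, clip_norm: Optional[float] = None,
                 lr_decay: float = 0.5, lr_decay_every: int = 100,
                 decay_exclude: Sequence[Tensor] = ()):
        self.params = list(params)
        self.lr0 = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.lr_decay = lr_decay
        self.lr_decay_every = lr_decay_every
        self._no_decay = {id(p) for p in decay_exclude}
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def lr_at_epoch(self, epoch: int) -> float:
        return self.lr0 * self.lr_decay ** (epoch // self.lr_decay_every)

    def step(self, epoch: int = 0) -> None:
        grads = [np.zeros_like(p.data) if p.grad is None else p.grad
                 for p in self.params]
        if self.weight_decay > 0:
            grads = [g + self.weight_decay * p.data
                     if id(p) not in self._no_decay else g
                     for g, p in zip(grads, self.params)]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        lr = self.lr_at_epoch(epoch)
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
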