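"""Neural-network building blocks on top of :mod:`cardiofm.autograd`.

Modules follow the familiar container pattern: parameters are discovered by
attribute walking, `state_dict` / `load_state_dict` move weights in and out as
plain numpy arrays, and AdamW supports per-group learning-rate scales (used by
layer-wise learning-rate decay during fine-tuning).
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                params.append(p)
        return params

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data = state[name].astype(p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _init_linear(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    # Xavier-uniform
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.weight = Parameter(_init_linear(rng, in_features, out_features))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x.linear(self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.eps) * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Full (bidirectional) self-attention with optional additive bias mask.

    `attn_bias` has shape (B, 1, 1, L) or (B, 1, L, L); padded key positions
    carry a large negative value so they receive zero attention weight.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor, attn_bias: np.ndarray | None = None) -> Tensor:
        B, L, D = x.shape
        H, hd = self.n_heads, self.head_dim
        qkv = self.qkv(x)  # (B, L, 3D)
        qkv = qkv.reshape(B, L, 3, H, hd).transpose(2, 0, 3, 1, 4)  # (3, B, H, L, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))  # (B,H,L,L)
        if attn_bias is not None:
            scores = scores + Tensor(attn_bias)
        attn = scores.softmax(axis=-1)
        out = attn @ v  # (B, H, L, hd)
        out = out.transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.proj(out)


class MLP(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class TransformerBlock(Module):
    """Pre-norm transformer block (attention + MLP, residual connections)."""

    def __init__(self, dim: int, n_heads: int, mlp_ratio: float, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = MLP(dim, int(dim * mlp_ratio), rng)

    def forward(self, x: Tensor, attn_bias: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.norm1(x), attn_bias)
        x = x + self.mlp(self.norm2(x))
        return x


class Conv1d(Module):
    """Stride-1, 'same'-padded 1-D convolution over (B, C_in, L) inputs."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for 'same' padding")
        fan_in = in_channels * kernel_size
        bound = math.sqrt(6.0 / (fan_in + out_channels * kernel_size))
        self.weight = Parameter(rng.uniform(-bound, bound,
                                            size=(out_channels, in_channels, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels))
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        B, C, L = x.shape
        k = self.kernel_size
        pad = k // 2
        xp = x.pad_last(pad, pad)                       # (B, C, L+2p)
        cols = xp.unfold_last(k, 1)                     # (B, C, L, k)
        cols = cols.transpose(0, 2, 1, 3).reshape(B, L, C * k)
        w = self.weight.reshape(self.weight.shape[0], C * k).transpose(1, 0)
        out = cols @ w + self.bias                      # (B, L, C_out)
        return out.transpose(0, 2, 1)


class ResidualConvUnit(Module):
    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator):
        self.conv1 = Conv1d(channels, channels, kernel_size, rng)
        self.conv2 = Conv1d(channels, channels, kernel_size, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(x.relu())
        h = self.conv2(h.relu())
        return x + h


class AdamW:
    """AdamW with decoupled weight decay and per-group LR scales."""

    def __init__(self, param_groups, lr: float = 1e-3, betas=(0.9, 0.95),
                 weight_decay: float = 5e-2, eps: float = 1e-8):
        # param_groups: list of dicts {"params": [...], "lr_scale": float}
        if param_groups and isinstance(param_groups[0], Parameter):
            param_groups = [{"params": list(param_groups), "lr_scale": 1.0}]
        self.groups = param_groups
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for group in self.groups:
            glr = lr * group.get("lr_scale", 1.0)
            wd = group.get("weight_decay", self.weight_decay)
            for p in group["params"]:
                if p.grad is None:
                    continue
                key = id(p)
                if key not in self._m:
                    self._m[key] = np.zeros_like(p.data)
                    self._v[key] = np.zeros_like(p.data)
                m = self._m[key]
                v = self._v[key]
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                g2 = p.grad * p.grad
                g2 *= (1 - b2)
                v += g2
                denom = np.sqrt(v, out=g2)         # reuse buffer
                denom *= 1.0 / np.sqrt(bc2)
                denom += self.eps
                update = np.divide(m, denom, out=denom)
                update *= glr / bc1
                if wd:
                    p.data *= 1.0 - glr * wd
                p.data -= update

    def zero_grad(self):
        for group in self.groups:
            for p in group["params"]:
                p.zero_grad()


def warmup_cosine_lr(step: int, max_steps: int, base_lr: float,
                     warmup_frac: float = 0.05) -> float:
    """Linear warmup over the initial `warmup_frac` of training, then cosine
    decay to zero at `max_steps`."""
    warmup_steps = max(1, int(round(warmup_frac * max_steps)))
    if step < warmup_steps:
        return base_lr * (step + 1) / warmup_steps
    progress = (step - warmup_steps) / max(1, max_steps - warmup_steps)
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * min(progress, 1.0)))


__all__ = [
    "Parameter", "Module", "Linear", "LayerNorm", "MultiHeadAttention", "MLP",
    "TransformerBlock", "Conv1d", "ResidualConvUnit", "AdamW",
    "warmup_cosine_lr", "concat",
]
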