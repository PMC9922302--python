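"""Neural-network building blocks on top of the autodiff engine.

Contains exactly what the generator/discriminator/selector architectures
require: linear layers (optionally with spectral normalization), layer norm,
multi-head self-attention, transformer blocks, and a padded 2D convolution.
Parameters are ``Tensor`` objects with ``requires_grad=True``; modules expose
them through ``parameters()`` for the optimizer and through ``state_dict`` /
``load_state_dict`` for checkpointing.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
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

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def _named(self, prefix: str = "") -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                out[key] = v.data
            elif isinstance(v, Module):
                out.update(v._named(key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item._named(f"{key}.{i}."))
        return out

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._named().items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        named = self._named()
        missing = set(named) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor):
                v.data = np.array(state[name], dtype=np.float64)
            elif isinstance(v, Module):
                v.load_state_dict({k[len(name) + 1:]: s for k, s in state.items()
                                   if k.startswith(name + ".")})
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        pre = f"{name}.{i}."
                        item.load_state_dict({k[len(pre):]: s for k, s in state.items()
                                              if k.startswith(pre)})


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 gain: float = 1.0):
        scale = gain * math.sqrt(2.0 / (n_in + n_out))
        self.weight = Tensor(rng.normal(scale=scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.affine(x, self.weight, self.bias)


class SpectralLinear(Module):
    """Linear layer whose weight is divided by its largest singular value.

    The singular value is tracked by one power iteration per forward pass
    (training mode); the iteration vectors are buffers, not parameters, and
    the normalizing sigma enters the graph as a differentiable function of
    the raw weight with the vectors held fixed.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (n_in + n_out))
        self.weight = Tensor(rng.normal(scale=scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)
        self._u = rng.normal(size=n_out)
        self._u /= np.linalg.norm(self._u)
        self._v = self.weight.data @ self._u
        self._v /= np.linalg.norm(self._v) + 1e-12

    def __call__(self, x: Tensor, update_power_iter: bool = True) -> Tensor:
        W = self.weight
        if update_power_iter:
            v = W.data @ self._u
            v /= np.linalg.norm(v) + 1e-12
            u = W.data.T @ v
            u /= np.linalg.norm(u) + 1e-12
            self._u = u
            self._v = v
        v, u = self._v, self._u
        sigma = (Tensor(v[None, :]) @ W @ Tensor(u[:, None])).reshape(1)
        return x @ (W / sigma) + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gain, self.bias)


class MultiheadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.qkv = Linear(d_model, 3 * d_model, rng)
        self.proj = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, D = x.shape
        H, dh = self.n_heads, self.d_head
        qkv = self.qkv(x).reshape(B, L, 3, H, dh).transpose(2, 0, 3, 1, 4)  # (3,B,H,L,dh)
        out = ad.scaled_dot_attention(qkv[0], qkv[1], qkv[2], 1.0 / math.sqrt(dh))
        return self.proj(out.transpose(0, 2, 1, 3).reshape(B, L, D))


class FeedForward(Module):
    def __init__(self, d_model: int, d_hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(d_model, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(ad.relu(self.fc1(x)))


class TransformerBlock(Module):
    """Self-attention + position-wise feed-forward with residual connections.

    ``layernorm_mode`` selects the classic post-norm arrangement or the
    pre-norm variant.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 d_ff: Optional[int] = None, layernorm_mode: str = "post"):
        if layernorm_mode not in ("post", "pre"):
            raise ValueError("layernorm_mode must be 'post' or 'pre'")
        self.mode = layernorm_mode
        self.attn = MultiheadSelfAttention(d_model, n_heads, rng)
        self.ffn = FeedForward(d_model, d_ff or 2 * d_model, rng)
        self.ln1 = LayerNorm(d_model)
        self.ln2 = LayerNorm(d_model)

    def __call__(self, x: Tensor) -> Tensor:
        if self.mode == "post":
            x = self.ln1(x + self.attn(x))
            x = self.ln2(x + self.ffn(x))
        else:
            x = x + self.attn(self.ln1(x))
            x = x + self.ffn(self.ln2(x))
        return x


class Conv2d(Module):
    """Stride-1 2D convolution with symmetric zero padding.

    Implemented as a sum of shifted slice-matmuls, which keeps the whole
    operation inside the autodiff primitives.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.kernel = kernel
        scale = math.sqrt(2.0 / (c_in * kernel * kernel + c_out))
        self.weight = Tensor(rng.normal(scale=scale, size=(kernel, kernel, c_in, c_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, H, W, C_in) -> (B, H, W, C_out)
        B, H, W, C = x.shape
        k, p = self.kernel, self.kernel // 2
        pad = np.zeros((B, H + 2 * p, W + 2 * p, C))
        xp = Tensor(pad, x.requires_grad, (x,))
        def bw(g):
            if x.requires_grad:
                x._accum(g[:, p:p + H, p:p + W, :])
        xp._backward = bw
        xp.data[:, p:p + H, p:p + W, :] = x.data
        out = None
        for di in range(k):
            for dj in range(k):
                piece = xp[:, di:di + H, dj:dj + W, :] @ self.weight[di, dj]
                out = piece if out is None else out + piece
        return out + self.bias


def sinusoidal_positions(L: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal residue-index encodings, shape (L, dim)."""
    pos = np.arange(L)[:, None]
    i = np.arange(dim // 2)[None, :]
    freq = np.exp(-math.log(10000.0) * 2 * i / dim)
    enc = np.zeros((L, dim))
    enc[:, 0::2] = np.sin(pos * freq)
    enc[:, 1::2] = np.cos(pos * freq)
    return enc
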