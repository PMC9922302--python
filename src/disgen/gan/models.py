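"""Conditional generator and discriminator architectures.

The generator is a transformer: per-residue latent noise concatenated with
the one-hot sequence is embedded, fixed sinusoidal residue-index encodings
are added, the embedding passes through self-attention blocks and a
position-wise head maps it to 3D C-alpha coordinates (nm).  It accepts any
chain length with unchanged weights.

Discriminators score (distance features, sequence) pairs.  The MLP variant
takes a fixed length; the 2D convolutional variant zero-pads distance
matrices to a maximum length and is length-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from ..ensembles_io import Conformation, ResidueSequence
from ..nn import autodiff as ad
from ..nn import (
    Conv2d,
    LayerNorm,
    Linear,
    Module,
    SpectralLinear,
    TransformerBlock,
    sinusoidal_positions,
)
from ..nn.autodiff import Tensor
from .features import FeatureStandardizer, pair_indices


@dataclass(frozen=True)
class GeneratorArchitecture:
    n_z: int = 16
    n_blocks: int = 4
    d_model: int = 128
    n_heads: int = 8
    layernorm_mode: str = "post"

    @classmethod
    def tiny(cls) -> "GeneratorArchitecture":
        # pre-norm keeps amplitude modes in the residual stream, which the
        # small width needs to express the large long-range distance variance
        return cls(n_z=8, n_blocks=2, d_model=32, n_heads=4, layernorm_mode="pre")


@dataclass(frozen=True)
class DiscriminatorArchitecture:
    mode: str = "mlp_per_length"          # or "conv2d_padded"
    hidden: Tuple[int, ...] = (256, 256)
    output: str = "probability"           # or "score" (hinge / Wasserstein)
    use_torsions: bool = False
    leaky_slope: float = 0.2
    conv_channels: int = 16
    conv_max_length: int = 110

    @classmethod
    def tiny(cls, **kw) -> "DiscriminatorArchitecture":
        return cls(hidden=(64, 64), conv_channels=8, **kw)


class ConformationGenerator(Module):
    """Transformer mapping (z, a) -> C-alpha coordinates."""

    def __init__(self, arch: GeneratorArchitecture, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.arch = arch
        d = arch.d_model
        self.embed = Linear(arch.n_z + 20, d, rng)
        self.blocks = [
            TransformerBlock(d, arch.n_heads, rng, layernorm_mode=arch.layernorm_mode)
            for _ in range(arch.n_blocks)
        ]
        # latent/sequence re-injection before every block keeps the noise
        # path alive through the normalization layers
        self.injectors = [Linear(arch.n_z + 20, d, rng) for _ in range(arch.n_blocks)]
        self.head_hidden = Linear(d, d, rng)
        self.head_out = Linear(d, 3, rng)

    def __call__(self, z: Tensor, onehot: np.ndarray) -> Tensor:
        """z: (B, L, n_z); onehot: (L, 20) or (B, L, 20).  Returns (B, L, 3) nm."""
        if z.shape[-1] != self.arch.n_z:
            raise ValueError(f"latent width {z.shape[-1]} != n_z {self.arch.n_z}")
        B, L, _ = z.shape
        oh = np.broadcast_to(onehot, (B, L, 20)) if onehot.ndim == 2 else onehot
        if oh.shape[:2] != (B, L):
            raise ValueError("one-hot shape does not match latent sequence")
        za = ad.concat([z, Tensor(oh)], axis=-1)
        x = self.embed(za) + Tensor(sinusoidal_positions(L, self.arch.d_model))
        for blk, inj in zip(self.blocks, self.injectors):
            x = blk(x + inj(za))
        h = ad.leaky_relu(self.head_hidden(x), 0.2)
        return self.head_out(h)

    def sample(self, seq: ResidueSequence, n: int, rng: np.random.Generator,
               batch_cap: int = 512) -> np.ndarray:
        """Generate n conformations (numpy, no gradients), shape (n, L, 3)."""
        L = len(seq)
        oh = seq.onehot
        out = []
        for start in range(0, n, batch_cap):
            b = min(batch_cap, n - start)
            z = Tensor(rng.standard_normal((b, L, self.arch.n_z)))
            out.append(self(z, oh).data)
        return np.concatenate(out)


class DistanceDiscriminator(Module):
    """Fixed-length MLP discriminator on standardized distance features.

    Input: standardized upper-triangle distances (P = L(L-1)/2) concatenated
    with the flattened one-hot sequence (20L), optionally with L-3
    pseudo-torsions (radians / pi).  Three spectral-normalized linear layers,
    two leaky rectifier nonlinearities, sigmoid or linear output.
    """

    def __init__(self, L: int, std: FeatureStandardizer,
                 arch: DiscriminatorArchitecture, seed: int = 0):
        if arch.mode != "mlp_per_length":
            raise ValueError("DistanceDiscriminator implements the mlp_per_length mode")
        rng = np.random.default_rng(seed)
        self.L = L
        self.arch = arch
        m, s = std.vectors_for_length(L)
        self._m, self._s = m, s
        n_in = L * (L - 1) // 2 + 20 * L + (L - 3 if arch.use_torsions else 0)
        h1, h2 = arch.hidden
        self.fc1 = SpectralLinear(n_in, h1, rng)
        self.fc2 = SpectralLinear(h1, h2, rng)
        self.fc3 = SpectralLinear(h2, 1, rng)

    def _score(self, x_std: Tensor, onehot_flat: np.ndarray,
               torsions: Optional[Tensor], update_power_iter: bool) -> Tensor:
        parts = [x_std, Tensor(onehot_flat)]
        if self.arch.use_torsions:
            if torsions is None:
                raise ValueError("architecture expects torsion features")
            parts.append(torsions * (1.0 / np.pi))
        h = ad.concat(parts, axis=-1)
        slope = self.arch.leaky_slope
        h = ad.leaky_relu(self.fc1(h, update_power_iter), slope)
        h = ad.leaky_relu(self.fc2(h, update_power_iter), slope)
        return self.fc3(h, update_power_iter)

    def __call__(self, distances: Tensor, onehot: np.ndarray,
                 torsions: Optional[Tensor] = None,
                 update_power_iter: bool = True) -> Tensor:
        """distances: raw (B, P) distance features in nm; onehot: (B, L, 20) or (L, 20)."""
        B = distances.shape[0]
        if distances.shape[-1] != self.L * (self.L - 1) // 2:
            raise ValueError(
                f"discriminator built for L={self.L}; got feature width {distances.shape[-1]}"
            )
        x_std = (distances - Tensor(self._m)) * Tensor(1.0 / self._s)
        oh = np.broadcast_to(onehot, (B, self.L, 20)) if onehot.ndim == 2 else onehot
        score = self._score(x_std, oh.reshape(B, 20 * self.L), torsions, update_power_iter)
        if self.arch.output == "probability":
            return ad.sigmoid(score)
        return score

    def gradient_norm_expression(self, distances: Tensor, onehot: np.ndarray,
                                 torsions: Optional[Tensor] = None) -> Tensor:
        """||d score / d features|| as a differentiable expression in the weights.

        Uses the piecewise-linear structure of the leaky-rectifier MLP: the
        activation slopes at the evaluation point are held fixed (they are
        locally constant), so the input-gradient is a product of effective
        weight matrices and can be penalized without second-order autodiff.
        """
        B = distances.shape[0]
        x_std = (distances - Tensor(self._m)) * Tensor(1.0 / self._s)
        oh = np.broadcast_to(onehot, (B, self.L, 20)).reshape(B, 20 * self.L)
        parts = [x_std, Tensor(oh)]
        if self.arch.use_torsions:
            parts.append(torsions * (1.0 / np.pi))
        h0 = ad.concat(parts, axis=-1)
        slope = self.arch.leaky_slope
        z1 = self.fc1(h0, update_power_iter=False)
        a1 = ad.leaky_relu(z1, slope)
        z2 = self.fc2(a1, update_power_iter=False)
        d1 = np.where(z1.data > 0, 1.0, slope)           # (B, h1), detached masks
        d2 = np.where(z2.data > 0, 1.0, slope)           # (B, h2)

        def eff(layer: SpectralLinear) -> Tensor:
            W = layer.weight
            v, u = layer._v, layer._u
            sigma = (Tensor(v[None, :]) @ W @ Tensor(u[:, None])).reshape(1)
            return W / sigma

        W1, W2, W3 = eff(self.fc1), eff(self.fc2), eff(self.fc3)
        # grad_x score = W1 (d1 * (W2 (d2 * w3)))
        g2 = (W3.reshape(1, -1) * Tensor(d2)) @ W2.transpose(1, 0)   # (B, h1)
        g1 = (g2 * Tensor(d1)) @ W1.transpose(1, 0)                  # (B, n_in)
        return ad.sqrt((g1 * g1).sum(axis=-1) + 1e-12)


class ConvDiscriminator(Module):
    """Length-agnostic 2D convolutional discriminator on padded distance matrices.

    The standardized distance matrix is zero-padded to ``conv_max_length``;
    a validity mask and broadcast one-hot row/column channels carry the
    sequence conditioning.  Global average pooling over valid cells feeds a
    linear output head.
    """

    def __init__(self, std: FeatureStandardizer, arch: DiscriminatorArchitecture,
                 seed: int = 0):
        if arch.mode != "conv2d_padded":
            raise ValueError("ConvDiscriminator implements the conv2d_padded mode")
        rng = np.random.default_rng(seed)
        self.arch = arch
        self.std = std
        c = arch.conv_channels
        self.conv1 = Conv2d(2 + 40, c, 3, rng)
        self.conv2 = Conv2d(c, c, 3, rng)
        self.conv3 = Conv2d(c, c, 3, rng)
        self.head = Linear(c, 1, rng)

    def __call__(self, distances: Tensor, onehot: np.ndarray,
                 update_power_iter: bool = True) -> Tensor:
        B, P = distances.shape
        L = int((1 + np.sqrt(1 + 8 * P)) / 2)
        Lmax = self.arch.conv_max_length
        if L > Lmax:
            raise ValueError(f"length {L} exceeds conv_max_length {Lmax}")
        m, s = self.std.vectors_for_length(L)
        x_std = (distances - Tensor(m)) * Tensor(1.0 / s)
        i, j = pair_indices(L)
        # scatter features into a symmetric (B, Lmax, Lmax) map
        mat = Tensor(np.zeros((B, Lmax, Lmax)), x_std.requires_grad, (x_std,))
        flat_u = np.ravel_multi_index((i, j), (Lmax, Lmax))
        flat_l = np.ravel_multi_index((j, i), (Lmax, Lmax))
        mat.data.reshape(B, -1)[:, flat_u] = x_std.data
        mat.data.reshape(B, -1)[:, flat_l] = x_std.data
        def bw(g):
            if x_std.requires_grad:
                gf = g.reshape(B, -1)
                x_std._accum(gf[:, flat_u] + gf[:, flat_l])
        mat._backward = bw
        mask = np.zeros((Lmax, Lmax))
        mask[:L, :L] = 1.0
        oh = np.broadcast_to(onehot, (B, L, 20))
        row = np.zeros((B, Lmax, Lmax, 20))
        col = np.zeros((B, Lmax, Lmax, 20))
        row[:, :L, :L, :] = oh[:, :, None, :]
        col[:, :L, :L, :] = oh[:, None, :, :]
        chans = ad.concat([
            mat.reshape(B, Lmax, Lmax, 1),
            Tensor(np.broadcast_to(mask[None, :, :, None], (B, Lmax, Lmax, 1)).copy()),
            Tensor(row), Tensor(col),
        ], axis=-1)
        h = ad.leaky_relu(self.conv1(chans), self.arch.leaky_slope)
        h = ad.leaky_relu(self.conv2(h), self.arch.leaky_slope)
        h = ad.leaky_relu(self.conv3(h), self.arch.leaky_slope)
        # average over the valid L x L block only
        w = mask / mask.sum()
        pooled = (h * Tensor(w[None, :, :, None])).sum(axis=(1, 2))
        score = self.head(pooled)
        if self.arch.output == "probability":
            return ad.sigmoid(score)
        return score


def generator_forward(z: np.ndarray, seq: ResidueSequence,
                      model: ConformationGenerator) -> Conformation:
    """Single-conformation convenience wrapper around the generator."""
    if z.shape != (len(seq), model.arch.n_z):
        raise ValueError(f"latent shape {z.shape} does not match (L={len(seq)}, n_z)")
    coords = model(Tensor(z[None]), seq.onehot).data[0]
    return Conformation(coords, sequence_ref=seq.id)


def discriminator_forward(conf: Conformation, seq: ResidueSequence,
                          disc: Module,
                          torsions: Optional[np.ndarray] = None) -> float:
    """Score one (conformation, sequence) pair with a discriminator network."""
    from .features import distance_features
    x = Tensor(distance_features(conf)[None])
    t = Tensor(torsions[None]) if torsions is not None else None
    if isinstance(disc, DistanceDiscriminator):
        out = disc(x, seq.onehot, torsions=t, update_power_iter=False)
    else:
        out = disc(x, seq.onehot, update_power_iter=False)
    return float(out.data.ravel()[0])
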