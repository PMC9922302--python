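"""Adversarial training objectives.

Three interchangeable modes: the non-saturated GAN loss (probability
outputs), the hinge loss with optional top-k sample selection, and the
Wasserstein critic loss with gradient penalty.  The generator objective
additionally carries the stereochemical clash term w_C * E_C computed on raw
(unstandardized) distances.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from ..nn import autodiff as ad
from ..nn.autodiff import Tensor
from .features import nonbonded_feature_mask

MODES = ("nonsaturated", "hinge_topk", "wasserstein_gp")


def _check_probability(d: Tensor) -> None:
    if np.any(d.data <= 0.0) or np.any(d.data >= 1.0):
        raise ValueError("non-saturated loss requires discriminator outputs in (0, 1)")


def loss_discriminator(d_real: Tensor, d_fake: Tensor, mode: str = "nonsaturated",
                       gradient_penalty: Optional[Tensor] = None,
                       gp_lambda: float = 10.0) -> Tensor:
    """Discriminator/critic loss for a batch of real and generated scores."""
    if mode == "nonsaturated":
        _check_probability(d_real)
        _check_probability(d_fake)
        return -(ad.log(d_real).mean() + ad.log(1.0 - d_fake).mean())
    if mode == "hinge_topk":
        return ad.relu(1.0 - d_real).mean() + ad.relu(1.0 + d_fake).mean()
    if mode == "wasserstein_gp":
        loss = d_fake.mean() - d_real.mean()
        if gradient_penalty is not None:
            loss = loss + gp_lambda * gradient_penalty
        return loss
    raise ValueError(f"unknown objective mode {mode!r}")


def wgan_gradient_penalty(grad_norms: Tensor) -> Tensor:
    """Mean squared deviation of interpolate gradient norms from 1."""
    return ((grad_norms - 1.0) ** 2.0).mean()


def topk_count(batch: int, nu: float, gamma: float, epoch: int) -> int:
    """Number of fake samples the generator keeps: ceil(nu * gamma^epoch * batch), >= 1."""
    nu_eff = nu * gamma**epoch
    return max(1, min(batch, math.ceil(nu_eff * batch)))


def clash_term(distances: Tensor, L: int, x_t: float) -> Tensor:
    """Differentiable E_C per sample: sum over |i-j| >= 3 of max(x_t - d, 0).

    ``distances``: (B, P) raw distance features in nm.  Returns a (B,) tensor.
    """
    mask = nonbonded_feature_mask(L)
    return ad.relu(x_t - distances[:, mask]).sum(axis=-1)


def loss_generator(d_fake: Tensor, distances: Tensor, L: int,
                   mode: str = "nonsaturated", w_C: float = 0.3, x_t: float = 0.59,
                   topk: Optional[int] = None) -> Tensor:
    """Generator loss: adversarial term plus the batch-mean clash term.

    In ``hinge_topk`` mode only the ``topk`` highest-scoring generated
    samples contribute to the adversarial term (the clash term always
    averages over the full batch).
    """
    if w_C < 0:
        raise ValueError("w_C must be non-negative")
    if mode == "nonsaturated":
        _check_probability(d_fake)
        adv = -ad.log(d_fake).mean()
    elif mode == "hinge_topk":
        scores = d_fake.reshape(-1)
        if topk is not None and topk < scores.shape[0]:
            keep = np.argsort(scores.data)[::-1][:topk].copy()
            scores = scores[keep]
        adv = -scores.mean()
    elif mode == "wasserstein_gp":
        adv = -d_fake.mean()
    else:
        raise ValueError(f"unknown objective mode {mode!r}")
    if w_C == 0.0:
        return adv
    return adv + w_C * clash_term(distances, L, x_t).mean()
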