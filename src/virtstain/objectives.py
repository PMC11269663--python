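"""Loss functions of the dual contrastive translation objective.

The contrastive term treats each sampled location of a translated image as
a query that must pick out the same location of the source image (the
positive) against the source's other sampled locations (negatives) — an
(N+1)-way classification on cosine similarities scaled by a temperature.
Together with the two adversarial terms and an L1 identity term it forms
the collective objective

    L = lambda_GAN * (L_GAN1 + L_GAN2)
      + lambda_NCE * (L_PatchNCE_A + L_PatchNCE_B)
      + lambda_idt * L_identity

with default weights lambda_GAN = 1, lambda_NCE = 2, lambda_idt = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigurationError, InputError, NumericError
from .networks import EmbeddingStack

DEFAULT_TEMPERATURE = 0.07


@dataclass
class NCEBatch:
    """One query vector, its positive, and N negatives (rows)."""

    query: np.ndarray | Tensor
    positive: np.ndarray | Tensor
    negatives: np.ndarray | Tensor  # (N, K); N may be 0
    temperature: float = DEFAULT_TEMPERATURE


@dataclass(frozen=True)
class LossWeights:
    lambda_gan: float = 1.0
    lambda_nce: float = 2.0
    lambda_idt: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if min(self.lambda_gan, self.lambda_nce, self.lambda_idt) < 0:
            raise ConfigurationError("loss weights must be non-negative")
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be positive")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|), in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise InputError("cosine similarity is undefined for zero vectors")
    return float(np.dot(u, v) / (nu * nv))


def _normalize_rows(x: Tensor) -> Tensor:
    norm = ad.sqrt(ad.add(ad.sum_(ad.mul(x, x), axis=-1, keepdims=True), 1e-12))
    return ad.div(x, norm)


def nce_cross_entropy(batch: NCEBatch) -> Tensor:
    """-log[ exp(sim(v,v+)/tau) / (exp(sim(v,v+)/tau) + sum_n exp(sim(v,vn-)/tau)) ].

    Computed as logsumexp(logits) - logits[positive] for numerical
    stability; inputs need not be pre-normalized.
    """
    if batch.temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    q = _normalize_rows(ad.reshape(ad.as_tensor(batch.query), (1, -1)))
    pos = _normalize_rows(ad.reshape(ad.as_tensor(batch.positive), (1, -1)))
    neg = ad.as_tensor(batch.negatives)
    sims = [ad.sum_(ad.mul(q, pos))]
    if neg.data.size:
        negs = _normalize_rows(ad.reshape(neg, (neg.data.shape[0], -1)))
        sims.append(ad.reshape(ad.matmul(negs, ad.transpose(ad.reshape(q, (1, -1)), (1, 0))), (-1,)))
    logits = ad.div(ad.concat([ad.reshape(s, (-1,)) for s in sims], axis=0), batch.temperature)
    return ad.sub(ad.logsumexp(logits, axis=0), logits[np.intp(0)])


def patchnce_loss(input_stack: EmbeddingStack, output_stack: EmbeddingStack,
                  temperature: float = DEFAULT_TEMPERATURE) -> Tensor:
    """Multilayer patchwise NCE between a source stack and its translation.

    For the A-to-B direction the input stack comes from H_A(G1enc(a)) and
    the output stack from H_B(G2enc(G1(a))); the query is the translated
    location embedding, the positive the same location in the source, and
    the negatives all other sampled source locations in that layer.
    Returns the mean over layers and locations.
    """
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    if input_stack.layer_ids != output_stack.layer_ids:
        raise InputError("stacks were sampled from different layer sets")
    per_layer = []
    for li in range(input_stack.n_layers):
        if not np.array_equal(input_stack.locations[li], output_stack.locations[li]):
            raise InputError(f"stacks disagree on sampled locations in layer index {li}")
        z = input_stack.vectors[li]      # (S, K) positives/negatives
        zhat = output_stack.vectors[li]  # (S, K) queries
        s = z.data.shape[0]
        logits = ad.div(ad.matmul(zhat, ad.transpose(z, (1, 0))), temperature)  # (S, S)
        diag_idx = (np.arange(s), np.arange(s))
        per_loc = ad.sub(ad.logsumexp(logits, axis=1), ad.take(logits, diag_idx))
        per_layer.append(ad.mean(per_loc))
    total = per_layer[0]
    for t in per_layer[1:]:
        total = ad.add(total, t)
    return ad.div(total, float(len(per_layer)))


def adversarial_losses(d_real, d_fake, form: str = "log") -> tuple[Tensor, Tensor]:
    """Discriminator and (non-saturating) generator losses on realness maps.

    ``log`` form expects maps squashed into (0, 1):
        d_loss = -1/2 E[log D(real)] - 1/2 E[log(1 - D(fake))]
        g_loss = -E[log D(fake)]
    ``lsgan`` form expects unbounded maps:
        d_loss = 1/2 E[(D(real) - 1)^2] + 1/2 E[D(fake)^2]
        g_loss = E[(D(fake) - 1)^2]
    """
    d_real = ad.as_tensor(d_real)
    d_fake = ad.as_tensor(d_fake)
    if form == "log":
        eps = 1e-8
        d_loss = ad.add(
            ad.mul(ad.mean(ad.log(d_real, eps=eps)), -0.5),
            ad.mul(ad.mean(ad.log(ad.sub(1.0, d_fake), eps=eps)), -0.5),
        )
        g_loss = ad.mul(ad.mean(ad.log(d_fake, eps=eps)), -1.0)
    elif form == "lsgan":
        rm1 = ad.sub(d_real, 1.0)
        fm1 = ad.sub(d_fake, 1.0)
        d_loss = ad.add(ad.mul(ad.mean(ad.mul(rm1, rm1)), 0.5),
                        ad.mul(ad.mean(ad.mul(d_fake, d_fake)), 0.5))
        g_loss = ad.mean(ad.mul(fm1, fm1))
    else:
        raise ConfigurationError(f"unknown adversarial form {form!r}; use 'log' or 'lsgan'")
    return d_loss, g_loss


def identity_loss(g1, g2, a, b) -> Tensor:
    """E||G2(a) - a||_1 + E||G1(b) - b||_1 for generators near the identity.

    ``g1``/``g2`` are callables mapping images to images; ``a`` and ``b``
    are [-1, 1] images already in each generator's output domain.
    """
    a = ad.as_tensor(a)
    b = ad.as_tensor(b)
    ga = ad.as_tensor(g2(a))
    gb = ad.as_tensor(g1(b))
    if ga.data.shape != a.data.shape or gb.data.shape != b.data.shape:
        raise InputError("generator output shape does not match its input")
    return ad.add(ad.mean(ad.abs_(ad.sub(ga, a))), ad.mean(ad.abs_(ad.sub(gb, b))))


@dataclass
class LossComponents:
    """Scalar pieces entering the collective objective."""

    gan_1: Tensor | float
    gan_2: Tensor | float
    nce_a: Tensor | float
    nce_b: Tensor | float
    identity: Tensor | float


def total_objective(components: LossComponents, weights: LossWeights = LossWeights()) -> Tensor:
    """Weighted sum of the five loss pieces (see module docstring)."""
    terms = {
        "gan_1": components.gan_1,
        "gan_2": components.gan_2,
        "nce_a": components.nce_a,
        "nce_b": components.nce_b,
        "identity": components.identity,
    }
    for name, t in terms.items():
        val = t.data if isinstance(t, Tensor) else t
        if not np.all(np.isfinite(val)):
            raise NumericError(f"loss component {name!r} is not finite")
    gan = ad.add(ad.as_tensor(components.gan_1), ad.as_tensor(components.gan_2))
    nce = ad.add(ad.as_tensor(components.nce_a), ad.as_tensor(components.nce_b))
    return ad.add(
        ad.add(ad.mul(gan, weights.lambda_gan), ad.mul(nce, weights.lambda_nce)),
        ad.mul(ad.as_tensor(components.identity), weights.lambda_idt),
    )
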