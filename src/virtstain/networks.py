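"""Dual-GAN components: generators, patch discriminators, projection heads.

The translation model keeps two directions alive at once: G1 maps unstained
(domain A) to stained (domain B) and G2 maps back.  Each direction has its
own patch-level discriminator (D_A judges domain-A realness, D_B domain-B)
and its own two-layer projection head (H_A, H_B) that embeds selected
encoder feature maps into unit-norm K-vectors for the contrastive loss.
A-side features always pass through H_A and B-side features through H_B;
the per-domain heads are what let the model learn domain-specific
embeddings.

Images are float tensors in [-1, 1], NHWC.  Architectures follow the
residual encoder-decoder / 70x70 patch-discriminator lineage standard for
unpaired translation, scaled down by the ``tiny`` preset for CPU work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .errors import ConfigurationError, InputError


@dataclass(frozen=True)
class GeneratorConfig:
    base_channels: int = 64
    n_downsamples: int = 2
    n_resnet_blocks: int = 9
    norm_kind: str = "instance"
    pad_mode: str = "reflect"
    stem_kernel: int = 7  # kernel of the full-resolution stem and output convs

    def __post_init__(self):
        if self.n_resnet_blocks < 1:
            raise ConfigurationError("n_resnet_blocks must be >= 1")
        if self.norm_kind not in ("instance",):
            raise ConfigurationError(f"unsupported norm_kind {self.norm_kind!r}")
        if self.stem_kernel % 2 == 0:
            raise ConfigurationError("stem_kernel must be odd")


@dataclass(frozen=True)
class DiscriminatorConfig:
    base_channels: int = 64
    n_layers: int = 3


#: CPU-scale preset used by the test suite and the desk-scale pipeline
TINY_GENERATOR = GeneratorConfig(base_channels=8, n_downsamples=1, n_resnet_blocks=2,
                                 stem_kernel=3)
TINY_DISCRIMINATOR = DiscriminatorConfig(base_channels=8, n_layers=2)
TINY_EMBED_DIM = 32
TINY_N_LOCATIONS = 64


class ResnetBlock(nn.Module):
    def __init__(self, ch: int, pad_mode: str, rng):
        self.conv1 = nn.Conv2d(ch, ch, 3, padding=1, pad_mode=pad_mode, rng=rng)
        self.norm1 = nn.InstanceNorm2d(ch)
        self.conv2 = nn.Conv2d(ch, ch, 3, padding=1, pad_mode=pad_mode, rng=rng)
        self.norm2 = nn.InstanceNorm2d(ch)

    def forward(self, x):
        h = ad.relu(self.norm1(self.conv1(x)))
        h = self.norm2(self.conv2(h))
        return ad.add(x, h)


class ResnetGenerator(nn.Module):
    """Residual encoder-decoder generator with tappable encoder layers.

    Encoder tap ids: 0 is the input image itself; 1 the stem conv; then one
    per downsampling conv; then one per residual block.  The default tap
    set for the contrastive loss is the input, the stem, every downsample
    and the middle residual block.
    """

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.config = config
        c = config.base_channels
        pm = config.pad_mode
        sk = config.stem_kernel
        self.stem = nn.Conv2d(3, c, sk, padding=sk // 2, pad_mode=pm, rng=rng)
        self.stem_norm = nn.InstanceNorm2d(c)
        self.downs = []
        self.down_norms = []
        for _ in range(config.n_downsamples):
            self.downs.append(nn.Conv2d(c, c * 2, 3, stride=2, padding=1, pad_mode="zeros", rng=rng))
            self.down_norms.append(nn.InstanceNorm2d(c * 2))
            c *= 2
        self.blocks = [ResnetBlock(c, pm, rng) for _ in range(config.n_resnet_blocks)]
        self.ups = []
        self.up_norms = []
        for _ in range(config.n_downsamples):
            self.ups.append(nn.Conv2d(c, c // 2, 3, padding=1, pad_mode=pm, rng=rng))
            self.up_norms.append(nn.InstanceNorm2d(c // 2))
            c //= 2
        self.head = nn.Conv2d(c, 3, sk, padding=sk // 2, pad_mode=pm, rng=rng)

    # -- taps ---------------------------------------------------------------
    @property
    def n_encoder_layers(self) -> int:
        return 2 + self.config.n_downsamples + self.config.n_resnet_blocks

    def default_tap_layers(self) -> tuple[int, ...]:
        mid_block = 2 + self.config.n_downsamples + (self.config.n_resnet_blocks - 1) // 2
        return tuple([0, 1] + [2 + i for i in range(self.config.n_downsamples)] + [mid_block])

    def encode(self, x, layer_ids: tuple[int, ...] | None = None):
        """Run the encoder half, returning requested feature maps and the code."""
        x = ad.as_tensor(x)
        self._check_size(x)
        wanted = set(layer_ids) if layer_ids is not None else set()
        if layer_ids is not None:
            bad = [l for l in layer_ids if not 0 <= l < self.n_encoder_layers]
            if bad:
                raise ConfigurationError(
                    f"unknown encoder layer ids {bad}; valid range is 0..{self.n_encoder_layers - 1}"
                )
        taps: dict[int, Tensor] = {}
        idx = 0
        if idx in wanted:
            taps[idx] = x
        h = ad.relu(self.stem_norm(self.stem(x)))
        idx += 1
        if idx in wanted:
            taps[idx] = h
        for conv, norm in zip(self.downs, self.down_norms):
            h = ad.relu(norm(conv(h)))
            idx += 1
            if idx in wanted:
                taps[idx] = h
        for block in self.blocks:
            h = block(h)
            idx += 1
            if idx in wanted:
                taps[idx] = h
        if layer_ids is None:
            return [], h
        return [taps[l] for l in layer_ids], h

    def decode(self, code):
        h = code
        for conv, norm in zip(self.ups, self.up_norms):
            h = ad.relu(norm(conv(ad.upsample_nearest(h, 2))))
        return ad.tanh(self.head(h))

    def forward(self, x):
        _, code = self.encode(x)
        return self.decode(code)

    def _check_size(self, x) -> None:
        h, w = x.data.shape[1], x.data.shape[2]
        div = 2**self.config.n_downsamples
        if h % div or w % div:
            raise InputError(
                f"spatial size {h}x{w} must be divisible by 2^{self.config.n_downsamples}"
            )

    def layer_channels(self, layer_ids: tuple[int, ...]) -> list[int]:
        """Channel count C_l for each tap id."""
        chans = [3, self.config.base_channels]
        c = self.config.base_channels
        for _ in range(self.config.n_downsamples):
            c *= 2
            chans.append(c)
        chans.extend([c] * self.config.n_resnet_blocks)
        return [chans[l] for l in layer_ids]


class PatchDiscriminator(nn.Module):
    """Convolutional classifier emitting a spatial realness map (logits)."""

    def __init__(self, config: DiscriminatorConfig, rng: np.random.Generator):
        self.config = config
        c = config.base_channels
        self.convs = [nn.Conv2d(3, c, 4, stride=2, padding=1, pad_mode="zeros", rng=rng)]
        self.norms: list[nn.InstanceNorm2d | None] = [None]
        for _ in range(config.n_layers - 1):
            self.convs.append(nn.Conv2d(c, c * 2, 4, stride=2, padding=1, pad_mode="zeros", rng=rng))
            self.norms.append(nn.InstanceNorm2d(c * 2))
            c *= 2
        self.convs.append(nn.Conv2d(c, c, 4, stride=1, padding=1, pad_mode="zeros", rng=rng))
        self.norms.append(nn.InstanceNorm2d(c))
        self.out = nn.Conv2d(c, 1, 4, stride=1, padding=1, pad_mode="zeros", rng=rng)

    def forward(self, x):
        h = ad.as_tensor(x)
        for conv, norm in zip(self.convs, self.norms):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = ad.leaky_relu(h, 0.2)
        return self.out(h)


class ProjectionHead(nn.Module):
    """Per-tap-layer two-layer MLPs projecting features to unit K-vectors."""

    def __init__(self, channel_dims: list[int], output_dim: int, rng: np.random.Generator,
                 hidden_dim: int | None = None):
        self.output_dim = output_dim
        hidden = hidden_dim or output_dim
        self.fc1 = [nn.Linear(c, hidden, rng=rng) for c in channel_dims]
        self.fc2 = [nn.Linear(hidden, output_dim, rng=rng) for _ in channel_dims]

    def project(self, layer_index: int, vectors):
        """Map (S, C_l) feature vectors to L2-normalized (S, K) embeddings."""
        h = ad.relu(self.fc1[layer_index](vectors))
        z = self.fc2[layer_index](h)
        norm = ad.sqrt(ad.add(ad.sum_(ad.mul(z, z), axis=1, keepdims=True), 1e-10))
        return ad.div(z, norm)


@dataclass
class EmbeddingStack:
    """Per-layer sampled, projected, unit-norm feature vectors.

    ``locations[l]`` are flat spatial indices into layer l's (H_l * W_l)
    grid; a paired stack built for the translated image must reuse them so
    that positives correspond spatially.
    """

    layer_ids: tuple[int, ...]
    locations: list[np.ndarray]
    vectors: list[Tensor]
    channel_dims: list[int]

    @property
    def n_layers(self) -> int:
        return len(self.layer_ids)


def generator_forward(generator: ResnetGenerator, image) -> Tensor:
    """Translate a [-1, 1] NHWC image; output is the same size, in [-1, 1]."""
    return generator(image)


def encoder_features(generator: ResnetGenerator, image, layer_ids: tuple[int, ...]):
    """Raw (un-projected) feature maps of the selected encoder layers."""
    feats, _ = generator.encode(image, layer_ids)
    return feats


def sample_and_project(features, layer_ids: tuple[int, ...], head: ProjectionHead,
                       n_locations: int, rng: np.random.Generator | None = None,
                       locations: list[np.ndarray] | None = None) -> EmbeddingStack:
    """Sample spatial locations per layer and project them through ``head``.

    When ``locations`` is given (the paired-image path) the same index sets
    are reused; otherwise ``n_locations`` positions are drawn uniformly
    without replacement with ``rng``.
    """
    chosen: list[np.ndarray] = []
    vectors: list[Tensor] = []
    channel_dims: list[int] = []
    for li, fmap in enumerate(features):
        n, h, w, c = fmap.data.shape
        if n != 1:
            raise InputError("sample_and_project expects singleton batches")
        total = h * w
        if locations is not None:
            ids = np.asarray(locations[li], dtype=np.int64)
        else:
            if n_locations > total:
                raise ConfigurationError(
                    f"n_locations {n_locations} exceeds {total} positions in layer {layer_ids[li]}"
                )
            if rng is None:
                raise ConfigurationError("rng required when locations are not given")
            ids = np.sort(rng.choice(total, size=n_locations, replace=False))
        flat = ad.reshape(fmap, (total, c))
        sampled = ad.gather_rows(flat, ids)  # ids are drawn without replacement
        vectors.append(head.project(li, sampled))
        chosen.append(ids)
        channel_dims.append(c)
    return EmbeddingStack(layer_ids=tuple(layer_ids), locations=chosen,
                          vectors=vectors, channel_dims=channel_dims)
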