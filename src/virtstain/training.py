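"""Stage 2: the dual-mapping optimization loop over patch sets.

Although the synthetic fixtures are pixel-aligned pairs, training is
deliberately unpaired: batches from the unstained and stained patch pools
are drawn by independent shuffles, so the model never sees pixel
correspondences — matching the unsupervised setting of dual contrastive
translation.  Each step first updates both discriminators on detached
translations, then jointly updates both generators and projection heads
against the collective objective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .errors import InputError, NumericError
from .networks import (
    DiscriminatorConfig,
    GeneratorConfig,
    PatchDiscriminator,
    ProjectionHead,
    ResnetGenerator,
    TINY_DISCRIMINATOR,
    TINY_EMBED_DIM,
    TINY_GENERATOR,
    TINY_N_LOCATIONS,
    sample_and_project,
)
from .nn import Adam
from .objectives import (
    LossComponents,
    LossWeights,
    adversarial_losses,
    identity_loss,
    patchnce_loss,
    total_objective,
)
from .utils import load_image, to_model

LOSS_COLUMNS = ["iter", "d_A", "d_B", "g_adv_1", "g_adv_2", "nce_A", "nce_B", "idt", "total"]


@dataclass(frozen=True)
class TrainConfig:
    iterations: int = 1000
    batch_size: int = 1
    learning_rate: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    seed: int = 0
    checkpoint_every: int = 500
    image_size: int = 64
    weights: LossWeights = field(default_factory=LossWeights)
    adversarial_form: str = "log"
    n_locations: int = TINY_N_LOCATIONS
    embed_dim: int = TINY_EMBED_DIM
    generator: GeneratorConfig = TINY_GENERATOR
    discriminator: DiscriminatorConfig = TINY_DISCRIMINATOR

    def __post_init__(self):
        if self.iterations < 1:
            raise InputError("iterations must be >= 1")


class ModelState:
    """All six trainable components plus optimizers and the step RNG."""

    def __init__(self, config: TrainConfig):
        self.config = config
        init_rng = np.random.default_rng(config.seed)
        self.g1 = ResnetGenerator(config.generator, init_rng)
        self.g2 = ResnetGenerator(config.generator, init_rng)
        self.d_a = PatchDiscriminator(config.discriminator, init_rng)
        self.d_b = PatchDiscriminator(config.discriminator, init_rng)
        self.tap_layers = self.g1.default_tap_layers()
        chans = self.g1.layer_channels(self.tap_layers)
        self.h_a = ProjectionHead(chans, config.embed_dim, init_rng)
        self.h_b = ProjectionHead(chans, config.embed_dim, init_rng)
        g_params = (self.g1.parameters() + self.g2.parameters()
                    + self.h_a.parameters() + self.h_b.parameters())
        d_params = self.d_a.parameters() + self.d_b.parameters()
        self.opt_g = Adam(g_params, lr=config.learning_rate, betas=config.betas)
        self.opt_d = Adam(d_params, lr=config.learning_rate, betas=config.betas)
        self.rng = np.random.default_rng(init_rng.integers(2**31))
        self.iteration = 0

    # -- checkpointing ------------------------------------------------------
    _modules = ("g1", "g2", "d_a", "d_b", "h_a", "h_b")

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {}
        for name in self._modules:
            for k, v in getattr(self, name).state_dict().items():
                arrays[f"{name}/{k}"] = v
        for opt_name in ("opt_g", "opt_d"):
            for k, v in getattr(self, opt_name).state_dict().items():
                arrays[f"{opt_name}/{k}"] = v
        meta = {
            "iteration": self.iteration,
            "rng_state": self.rng.bit_generator.state,
            "config": _config_to_dict(self.config),
            "tap_layers": list(self.tap_layers),
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            state = cls(_config_from_dict(meta["config"]))
            for name in cls._modules:
                prefix = f"{name}/"
                sub = {k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)}
                getattr(state, name).load_state_dict(sub)
            for opt_name in ("opt_g", "opt_d"):
                prefix = f"{opt_name}/"
                sub = {k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)}
                getattr(state, opt_name).load_state_dict(sub)
            state.iteration = int(meta["iteration"])
            state.rng.bit_generator.state = meta["rng_state"]
        return state


def _config_to_dict(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    d["weights"] = asdict(cfg.weights)
    d["generator"] = asdict(cfg.generator)
    d["discriminator"] = asdict(cfg.discriminator)
    return d


def _config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    d["weights"] = LossWeights(**d["weights"])
    d["generator"] = GeneratorConfig(**d["generator"])
    d["discriminator"] = DiscriminatorConfig(**d["discriminator"])
    d["betas"] = tuple(d["betas"])
    return TrainConfig(**d)


def _squash(logits: Tensor, form: str) -> Tensor:
    return ad.sigmoid(logits) if form == "log" else logits


def _generator_adversarial(d_fake: Tensor, form: str) -> Tensor:
    return adversarial_losses(d_fake, d_fake, form)[1]


def train_step(state: ModelState, a_batch: np.ndarray, b_batch: np.ndarray) -> dict[str, float]:
    """One discriminator update then one joint generator/head update.

    ``a_batch`` and ``b_batch`` are (B, H, W, 3) arrays in [-1, 1] with
    equal batch sizes (the contrastive term is evaluated per sample).
    Returns the component losses of this step.
    """
    if a_batch.shape != b_batch.shape:
        raise InputError(f"batch shapes differ: {a_batch.shape} vs {b_batch.shape}")
    cfg = state.config
    form = cfg.adversarial_form
    tau = cfg.weights.temperature
    a = Tensor(a_batch)
    b = Tensor(b_batch)

    # translation graphs are built once; the discriminator update sees the
    # detached values, the generator update reuses the graph
    taps = state.tap_layers
    per_sample_nce_a, per_sample_nce_b = [], []
    fake_b_parts, fake_a_parts = [], []
    for i in range(a_batch.shape[0]):
        ai = Tensor(a_batch[i : i + 1])
        bi = Tensor(b_batch[i : i + 1])
        feats_a, code_a = state.g1.encode(ai, taps)
        fb = state.g1.decode(code_a)
        fake_b_parts.append(fb)
        stack_a = sample_and_project(feats_a, taps, state.h_a, cfg.n_locations, rng=state.rng)
        feats_fb, _ = state.g2.encode(fb, taps)
        stack_fb = sample_and_project(feats_fb, taps, state.h_b, cfg.n_locations,
                                      locations=stack_a.locations)
        per_sample_nce_a.append(patchnce_loss(stack_a, stack_fb, tau))

        feats_b, code_b = state.g2.encode(bi, taps)
        fa = state.g2.decode(code_b)
        fake_a_parts.append(fa)
        stack_b = sample_and_project(feats_b, taps, state.h_b, cfg.n_locations, rng=state.rng)
        feats_fa, _ = state.g1.encode(fa, taps)
        stack_fa = sample_and_project(feats_fa, taps, state.h_a, cfg.n_locations,
                                      locations=stack_b.locations)
        per_sample_nce_b.append(patchnce_loss(stack_b, stack_fa, tau))
    fake_b_full = ad.concat(fake_b_parts, axis=0)
    fake_a_full = ad.concat(fake_a_parts, axis=0)

    # -- discriminators on detached translations ---------------------------
    d_loss_b, _ = adversarial_losses(_squash(state.d_b(b), form),
                                     _squash(state.d_b(fake_b_full.detach()), form), form)
    d_loss_a, _ = adversarial_losses(_squash(state.d_a(a), form),
                                     _squash(state.d_a(fake_a_full.detach()), form), form)
    state.opt_d.zero_grad()
    d_total = ad.add(d_loss_a, d_loss_b)
    d_total.backward()
    state.opt_d.step()

    # -- generators + heads against the freshly updated discriminators -----
    state.opt_g.zero_grad()
    nce_a = _mean_scalars(per_sample_nce_a)
    nce_b = _mean_scalars(per_sample_nce_b)
    g_adv_1 = _generator_adversarial(_squash(state.d_b(fake_b_full), form), form)
    g_adv_2 = _generator_adversarial(_squash(state.d_a(fake_a_full), form), form)
    idt = identity_loss(state.g1, state.g2, a, b)
    total = total_objective(
        LossComponents(gan_1=g_adv_1, gan_2=g_adv_2, nce_a=nce_a, nce_b=nce_b, identity=idt),
        cfg.weights,
    )
    total.backward()
    state.opt_g.step()
    state.iteration += 1

    record = {
        "iter": state.iteration,
        "d_A": float(d_loss_a),
        "d_B": float(d_loss_b),
        "g_adv_1": float(g_adv_1),
        "g_adv_2": float(g_adv_2),
        "nce_A": float(nce_a),
        "nce_B": float(nce_b),
        "idt": float(idt),
        "total": float(total),
    }
    bad = [k for k, v in record.items() if not np.isfinite(v)]
    if bad:
        raise NumericError(f"non-finite loss components at iteration {state.iteration}: {bad}")
    return record


def _mean_scalars(parts):
    total = parts[0]
    for p in parts[1:]:
        total = ad.add(total, p)
    return ad.div(total, float(len(parts)))


class PatchPool:
    """Sorted PNG files of one domain, served as shuffled [-1, 1] batches."""

    def __init__(self, directory: str | Path):
        self.paths = sorted(Path(directory).glob("*.png"))
        if not self.paths:
            raise InputError(f"no PNG patches found in {directory}")
        self._cache: dict[Path, np.ndarray] = {}

    def __len__(self):
        return len(self.paths)

    def load(self, idx: int) -> np.ndarray:
        p = self.paths[idx]
        if p not in self._cache:
            self._cache[p] = to_model(load_image(p))[0]
        return self._cache[p]


def batch_indices(n: int, batch_size: int, iterations: int, rng: np.random.Generator):
    """Independent per-epoch shuffles, yielding ``iterations`` index batches."""
    order: list[int] = []
    while len(order) < iterations * batch_size:
        order.extend(rng.permutation(n).tolist())
    for it in range(iterations):
        yield order[it * batch_size : (it + 1) * batch_size]


def fit(config: TrainConfig, unstained_dir: str | Path, stained_dir: str | Path,
        out_dir: str | Path) -> tuple[ModelState, pd.DataFrame]:
    """Train on two patch directories; write checkpoints and a loss history.

    Checkpoints land in ``out_dir`` at the configured cadence plus a final
    ``checkpoint_final.npz``; the per-iteration loss table is written to
    ``out_dir/loss_history.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pool_a = PatchPool(unstained_dir)
    pool_b = PatchPool(stained_dir)
    state = ModelState(config)
    seq_a, seq_b = np.random.SeedSequence(config.seed).spawn(2)
    idx_a = list(batch_indices(len(pool_a), config.batch_size, config.iterations,
                               np.random.default_rng(seq_a)))
    idx_b = list(batch_indices(len(pool_b), config.batch_size, config.iterations,
                               np.random.default_rng(seq_b)))

    rows = []
    for ia, ib in zip(idx_a, idx_b):
        a = np.stack([pool_a.load(i) for i in ia])
        b = np.stack([pool_b.load(i) for i in ib])
        rows.append(train_step(state, a, b))
        if config.checkpoint_every and state.iteration % config.checkpoint_every == 0:
            state.save(out_dir / f"checkpoint_{state.iteration:06d}.npz")
    state.save(out_dir / "checkpoint_final.npz")
    history = pd.DataFrame(rows, columns=LOSS_COLUMNS)
    history.to_csv(out_dir / "loss_history.csv", index=False)
    return state, history
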