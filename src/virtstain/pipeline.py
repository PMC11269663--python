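"""End-to-end orchestration of the three pipeline stages on disk.

Each stage reads its inputs from the previous stage's output directory and
is individually re-runnable; ``run_all`` chains them on fixture data:
fixtures -> preprocess (register + patch + filter) -> train -> infer ->
evaluate, leaving fixtures/, patches/, checkpoints/, stained/ and
report.json under the configured output root.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as pp
from .config import PipelineConfig, echo_config
from .errors import InputError
from .fixtures import StainOracle, SyntheticTissueSpec, build_paired_dataset
from .geometry import HomographyTransform
from .metrics import ToyFeatureExtractor, evaluate_sets
from .networks import (
    TINY_DISCRIMINATOR,
    TINY_EMBED_DIM,
    TINY_GENERATOR,
    TINY_N_LOCATIONS,
    DiscriminatorConfig,
    GeneratorConfig,
)
from .objectives import LossWeights
from .stitching import translate_whole_slide
from .training import ModelState, TrainConfig, fit
from .utils import load_image, save_image

log = logging.getLogger(__name__)


def _require(path: Path, stage: str, hint: str) -> Path:
    if not path.exists():
        raise InputError(f"{stage}: missing input {path}; run the '{hint}' stage first")
    return path


def model_configs(config: PipelineConfig):
    if config.model.preset == "tiny":
        gen, disc = TINY_GENERATOR, TINY_DISCRIMINATOR
        embed = config.model.embed_dim or TINY_EMBED_DIM
        locs = config.model.n_locations or TINY_N_LOCATIONS
    elif config.model.preset == "full":
        gen, disc = GeneratorConfig(), DiscriminatorConfig()
        embed = config.model.embed_dim or 256
        locs = config.model.n_locations or 256
    else:
        raise InputError(f"unknown model preset {config.model.preset!r}")
    return gen, disc, embed, locs


def run_fixtures(config: PipelineConfig) -> Path:
    out = Path(config.out_root) / "fixtures"
    fx = config.fixtures
    spec = SyntheticTissueSpec(
        height=fx.height, width=fx.width, nucleus_density=fx.nucleus_density,
        nucleus_radius_range=tuple(fx.nucleus_radius_range),
        cytoplasm_fraction=fx.cytoplasm_fraction, noise_sd=fx.noise_sd, seed=config.seed,
    )
    build_paired_dataset(spec, StainOracle(), fx.n_pairs, fx.misalign, out)
    echo_config(config, out)
    log.info("fixtures: wrote %d pairs to %s", fx.n_pairs, out)
    return out


def run_preprocess(config: PipelineConfig) -> Path:
    fixtures_dir = _require(Path(config.out_root) / "fixtures" / "manifest.csv",
                            "preprocess", "fixtures").parent
    out = Path(config.out_root) / "patches"
    cfg = config.preprocess
    manifest = pd.read_csv(fixtures_dir / "manifest.csv")
    kept: list[pp.PatchRecord] = []
    for _, row in manifest.iterrows():
        pair_id = f"pair{int(row.pair_id):03d}"
        unstained = load_image(fixtures_dir / row.unstained_path)
        stained = load_image(fixtures_dir / row.stained_path)
        true_h = HomographyTransform(np.array(
            [[row.h11, row.h12, row.h13], [row.h21, row.h22, row.h23],
             [row.h31, row.h32, row.h33]]))
        if not true_h.is_identity(tol=1e-9):
            _, unstained = pp.register_pair(
                unstained, stained, ratio_threshold=cfg.ratio_threshold,
                ransac_tol_px=cfg.ransac_tol_px, pair_id=pair_id, seed=config.seed)
        mask = pp.segment_foreground(stained, block_size=cfg.block_size, offset=cfg.offset)
        records = pp.extract_patches(unstained, stained, pair_id, out,
                                     patch_size=cfg.patch_size, stride=cfg.stride)
        kept.extend(pp.filter_background_patches(records, mask,
                                                 min_fraction=cfg.min_foreground,
                                                 patch_size=cfg.patch_size))
    # drop the tiles filtering rejected
    keep_names = {Path(r.unstained_patch_path).name for r in kept}
    for sub in ("unstained", "stained"):
        for f in (out / sub).glob("*.png"):
            if f.name not in keep_names:
                f.unlink()
    pp.records_to_manifest(kept, out / "patches.csv")
    echo_config(config, out)
    log.info("preprocess: kept %d patches", len(kept))
    return out


def train_config_from(config: PipelineConfig) -> TrainConfig:
    gen, disc, embed, locs = model_configs(config)
    tr = config.train
    return TrainConfig(
        iterations=tr.iterations, batch_size=tr.batch_size, learning_rate=tr.learning_rate,
        seed=config.seed, checkpoint_every=tr.checkpoint_every,
        image_size=config.preprocess.patch_size,
        weights=LossWeights(lambda_gan=tr.lambda_gan, lambda_nce=tr.lambda_nce,
                            lambda_idt=tr.lambda_idt, temperature=tr.temperature),
        adversarial_form=tr.adversarial_form, n_locations=locs, embed_dim=embed,
        generator=gen, discriminator=disc,
    )


def run_train(config: PipelineConfig) -> Path:
    patches = Path(config.out_root) / "patches"
    _require(patches / "unstained", "train", "preprocess")
    out = Path(config.out_root) / "checkpoints"
    fit(train_config_from(config), patches / "unstained", patches / "stained", out)
    echo_config(config, out)
    return out


def run_infer(config: PipelineConfig) -> Path:
    ckpt = (Path(config.infer.checkpoint) if config.infer.checkpoint
            else Path(config.out_root) / "checkpoints" / "checkpoint_final.npz")
    _require(ckpt, "infer", "train")
    fixtures_dir = _require(Path(config.out_root) / "fixtures" / "manifest.csv",
                            "infer", "fixtures").parent
    out = Path(config.out_root) / "stained"
    out.mkdir(parents=True, exist_ok=True)
    state = ModelState.load(ckpt)
    manifest = pd.read_csv(fixtures_dir / "manifest.csv")
    for _, row in manifest.iterrows():
        slide = load_image(fixtures_dir / row.unstained_path)
        virtual = translate_whole_slide(state.g1, slide, patch_size=config.infer.patch_size)
        save_image(virtual, out / f"pair{int(row.pair_id):03d}_virtual.png")
    # patch-level translations of the kept training patches, for evaluation
    patches = Path(config.out_root) / "patches" / "unstained"
    if patches.exists():
        patch_out = out / "patches"
        patch_out.mkdir(exist_ok=True)
        from .utils import from_model, to_model

        for p in sorted(patches.glob("*.png")):
            virtual = from_model(state.g1(to_model(load_image(p))).data)
            save_image(virtual, patch_out / p.name)
    echo_config(config, out)
    log.info("infer: stained %d slides", len(manifest))
    return out


def run_evaluate(config: PipelineConfig) -> Path:
    patches = Path(config.out_root) / "patches"
    stained_dir = _require(patches / "stained", "evaluate", "preprocess")
    virtual_dir = _require(Path(config.out_root) / "stained" / "patches", "evaluate", "infer")
    out = Path(config.out_root) / "report.json"
    if config.evaluate.extractor == "toy":
        extractor = ToyFeatureExtractor()
    else:
        from .metrics import get_extractor

        extractor = get_extractor(config.evaluate.extractor)
    evaluate_sets(stained_dir, virtual_dir, extractor=extractor,
                  subset_size=config.evaluate.subset_size,
                  n_subsets=config.evaluate.n_subsets, seed=config.seed,
                  report_path=out)
    log.info("evaluate: wrote %s", out)
    return out


def run_all(config: PipelineConfig) -> Path:
    run_fixtures(config)
    run_preprocess(config)
    run_train(config)
    run_infer(config)
    return run_evaluate(config)
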