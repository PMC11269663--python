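"""Shared fixtures: synthetic tissue pairs, patch pools, a briefly trained model."""

from __future__ import annotations

import numpy as np
import pytest

from virtstain.fixtures import (
    StainOracle,
    SyntheticTissueSpec,
    apply_stain_oracle,
    generate_unstained_image,
)
from virtstain.training import ModelState, TrainConfig, fit
from virtstain.utils import save_image


@pytest.fixture(scope="session")
def oracle():
    return StainOracle()


@pytest.fixture(scope="session")
def tissue_pair(oracle):
    """One aligned 192x192 unstained/stained pair with its label map."""
    spec = SyntheticTissueSpec(height=192, width=192, cytoplasm_fraction=0.40, seed=11)
    unstained, labels = generate_unstained_image(spec)
    stained = apply_stain_oracle(unstained, labels, oracle)
    return unstained, stained, labels


def make_patch_pools(out_dir, oracle, n_canvases=4, canvas=192, patch=64, seed0=1000,
                     cytoplasm_fraction=0.45):
    """Cut aligned 64x64 patch pairs from a few fixture canvases onto disk."""
    dir_a = out_dir / "unstained"
    dir_b = out_dir / "stained"
    dir_a.mkdir(parents=True, exist_ok=True)
    dir_b.mkdir(parents=True, exist_ok=True)
    n = 0
    for s in range(n_canvases):
        spec = SyntheticTissueSpec(height=canvas, width=canvas, seed=seed0 + s,
                                   cytoplasm_fraction=cytoplasm_fraction)
        u, lab = generate_unstained_image(spec)
        st = apply_stain_oracle(u, lab, oracle)
        for r in range(0, canvas, patch):
            for c in range(0, canvas, patch):
                save_image(u[r : r + patch, c : c + patch], dir_a / f"p{n:04d}.png")
                save_image(st[r : r + patch, c : c + patch], dir_b / f"p{n:04d}.png")
                n += 1
    return dir_a, dir_b


@pytest.fixture(scope="session")
def patch_pools(tmp_path_factory, oracle):
    out = tmp_path_factory.mktemp("pools")
    return make_patch_pools(out, oracle)


@pytest.fixture(scope="session")
def trained_session_model(tmp_path_factory, patch_pools):
    """A tiny model trained briefly (300 iterations) plus its loss history."""
    dir_a, dir_b = patch_pools
    out = tmp_path_factory.mktemp("train300")
    cfg = TrainConfig(iterations=300, seed=3, checkpoint_every=150)
    state, history = fit(cfg, dir_a, dir_b, out)
    return state, history, out
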