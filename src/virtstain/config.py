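"""Structured pipeline configuration (YAML) with strict key validation.

One flat file with per-stage sections; unknown keys are rejected so typos
fail loudly, and the resolved config is echoed into every stage's output
directory for provenance.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .errors import ConfigurationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FixturesSection(_Strict):
    n_pairs: int = 4
    height: int = 192
    width: int = 192
    nucleus_density: float = 5.0
    nucleus_radius_range: tuple[float, float] = (3.0, 6.0)
    cytoplasm_fraction: float = 0.45
    noise_sd: float = 2.0
    misalign: bool = True


class PreprocessSection(_Strict):
    patch_size: int = 64
    stride: int = 32
    min_foreground: float = 0.05
    block_size: int = 51
    offset: float = 10.0
    ratio_threshold: float = 0.75
    ransac_tol_px: float = 3.0


class ModelSection(_Strict):
    preset: str = "tiny"  # 'tiny' (CPU desk scale) or 'full'
    embed_dim: int | None = None
    n_locations: int | None = None


class TrainSection(_Strict):
    iterations: int = 300
    batch_size: int = 1
    learning_rate: float = 2e-4
    checkpoint_every: int = 500
    adversarial_form: str = "log"
    lambda_gan: float = 1.0
    lambda_nce: float = 2.0
    lambda_idt: float = 1.0
    temperature: float = 0.07


class InferSection(_Strict):
    patch_size: int = 64
    checkpoint: str | None = None


class EvaluateSection(_Strict):
    extractor: str = "toy"
    subset_size: int = 100
    n_subsets: int = 10


class PipelineConfig(_Strict):
    seed: int = 0
    out_root: str = "runs/virtstain"
    fixtures: FixturesSection = Field(default_factory=FixturesSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    infer: InferSection = Field(default_factory=InferSection)
    evaluate: EvaluateSection = Field(default_factory=EvaluateSection)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config; ``overrides`` are applied on top (dotted keys)."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
        data = raw
    for key, val in (overrides or {}).items():
        cursor = data
        parts = key.split(".")
        for part in parts[:-1]:
            cursor = cursor.setdefault(part, {})
        cursor[parts[-1]] = val
    try:
        return PipelineConfig(**data)
    except Exception as exc:  # pydantic ValidationError names the offending key
        raise ConfigurationError(f"invalid configuration: {exc}") from exc


def echo_config(config: PipelineConfig, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config_used.yaml").write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=False)
    )
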