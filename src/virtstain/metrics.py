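"""Distribution distances between image sets: Fréchet distance and kernel MMD.

Both metrics operate on feature vectors extracted from each image.  The
production extractor in the literature is a pretrained Inception-v3 pool3
layer (2048-d, images resized to 299x299); because those weights cannot be
assumed present, the extractor is pluggable and the default desk-scale
path is a deterministic random-projection extractor that needs no
downloads.  The Fréchet distance fits a Gaussian (mean, covariance) to
each feature cloud; the kernel score is the unbiased squared maximum mean
discrepancy under the cubic polynomial kernel k(x, y) = (x.y/d + 1)^3,
averaged over random subsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import linalg
from skimage.transform import resize

from .errors import ConfigurationError, InputError
from .utils import load_image

COVARIANCE_JITTER = 1e-6


@dataclass
class FeatureDistribution:
    """Gaussian summary (mean, covariance) of an extracted feature cloud."""

    mean: np.ndarray
    covariance: np.ndarray
    n: int
    extractor_id: str

    @classmethod
    def from_features(cls, features: np.ndarray, extractor_id: str) -> "FeatureDistribution":
        features = np.asarray(features, dtype=float)
        if features.shape[0] < 2:
            raise InputError("need at least 2 samples to fit a feature distribution")
        cov = np.cov(features, rowvar=False)
        cov = (cov + cov.T) / 2.0
        return cls(mean=features.mean(axis=0), covariance=cov,
                   n=features.shape[0], extractor_id=extractor_id)


@dataclass
class MetricReport:
    fid: float
    kid_mean: float
    kid_std: float
    n_a: int
    n_b: int
    extractor_id: str
    config: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


class ToyFeatureExtractor:
    """Deterministic random-projection features; no pretrained weights.

    Images are resized to a small canvas, intensity-scaled to [0, 1], and
    projected by a fixed seeded Gaussian matrix applied to raw pixels and
    to local gradient magnitudes.  Bit-reproducible across calls.
    """

    def __init__(self, dim: int = 64, canvas: int = 24, seed: int = 1234):
        self.dim = dim
        self.canvas = canvas
        rng = np.random.default_rng(seed)
        n_in = canvas * canvas * 3 + canvas * canvas
        self.projection = rng.standard_normal((n_in, dim)) / np.sqrt(n_in)
        self.extractor_id = f"toy_rp_d{dim}_c{canvas}_s{seed}"

    def __call__(self, image: np.ndarray) -> np.ndarray:
        x = resize(image.astype(float) / 255.0, (self.canvas, self.canvas, 3),
                   anti_aliasing=True, preserve_range=True)
        gy, gx = np.gradient(x.mean(axis=2))
        gmag = np.hypot(gy, gx)
        vec = np.concatenate([x.ravel(), gmag.ravel()])
        return vec @ self.projection


def get_extractor(name: str, **kwargs):
    """Resolve an extractor by name: 'toy' or 'inception_pool3'."""
    if name == "toy":
        return ToyFeatureExtractor(**kwargs)
    if name == "inception_pool3":
        try:
            import torch  # noqa: F401  -- optional heavyweight path
            import torchvision  # noqa: F401
        except ImportError as exc:
            raise ConfigurationError(
                "the 'inception_pool3' extractor needs torch/torchvision with "
                "pretrained Inception-v3 weights; use extractor='toy' for a "
                "download-free deterministic alternative"
            ) from exc
        raise ConfigurationError(
            "inception_pool3 wiring requires pretrained weights at runtime; "
            "use extractor='toy' in this environment"
        )
    raise ConfigurationError(f"unknown extractor {name!r}; choose 'toy' or 'inception_pool3'")


def extract_features(images, extractor) -> np.ndarray:
    """One feature row per image (arrays or paths)."""
    rows = []
    for img in images:
        if isinstance(img, (str, Path)):
            img = load_image(img)
        rows.append(np.asarray(extractor(img), dtype=float))
    if not rows:
        raise InputError("no images to extract features from")
    return np.stack(rows)


def frechet_distance(dist_a: FeatureDistribution, dist_b: FeatureDistribution) -> float:
    """||mu_a - mu_b||^2 + tr(S_a + S_b - 2 (S_a S_b)^{1/2}), jittered."""
    if dist_a.extractor_id != dist_b.extractor_id:
        raise InputError(
            f"feature distributions come from different extractors: "
            f"{dist_a.extractor_id} vs {dist_b.extractor_id}"
        )
    mu_a, mu_b = dist_a.mean, dist_b.mean
    d = mu_a.shape[0]
    eye = np.eye(d) * COVARIANCE_JITTER
    s_a = dist_a.covariance + eye
    s_b = dist_b.covariance + eye
    covmean = linalg.sqrtm(s_a @ s_b)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    diff = mu_a - mu_b
    fid = float(diff @ diff + np.trace(s_a) + np.trace(s_b) - 2.0 * np.trace(covmean))
    return max(fid, 0.0)


def polynomial_kernel(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cubic polynomial kernel matrix k(x, y) = (x.y/d + 1)^3."""
    d = x.shape[1]
    return (x @ y.T / d + 1.0) ** 3


def _mmd2_unbiased(x: np.ndarray, y: np.ndarray) -> float:
    m, n = x.shape[0], y.shape[0]
    kxx = polynomial_kernel(x, x)
    kyy = polynomial_kernel(y, y)
    kxy = polynomial_kernel(x, y)
    sum_xx = (kxx.sum() - np.trace(kxx)) / (m * (m - 1))
    sum_yy = (kyy.sum() - np.trace(kyy)) / (n * (n - 1))
    return float(sum_xx + sum_yy - 2.0 * kxy.mean())


def kid(features_a: np.ndarray, features_b: np.ndarray, subset_size: int = 100,
        n_subsets: int = 10, seed: int = 0) -> tuple[float, float]:
    """Unbiased kernel MMD^2 averaged over seeded subsets -> (mean, std)."""
    if subset_size < 2:
        raise ConfigurationError("subset_size must be >= 2")
    n_a, n_b = features_a.shape[0], features_b.shape[0]
    if subset_size > min(n_a, n_b):
        raise ConfigurationError(
            f"subset_size {subset_size} exceeds sample counts ({n_a}, {n_b})"
        )
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_subsets):
        ia = rng.choice(n_a, size=subset_size, replace=False)
        ib = rng.choice(n_b, size=subset_size, replace=False)
        vals.append(_mmd2_unbiased(features_a[ia], features_b[ib]))
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.std())


def evaluate_sets(dir_a: str | Path, dir_b: str | Path, extractor=None,
                  subset_size: int = 100, n_subsets: int = 10, seed: int = 0,
                  report_path: str | Path | None = None) -> MetricReport:
    """FID and KID between two directories of PNG images."""
    extractor = extractor or ToyFeatureExtractor()
    paths_a = sorted(Path(dir_a).glob("*.png"))
    paths_b = sorted(Path(dir_b).glob("*.png"))
    if len(paths_a) < 2 or len(paths_b) < 2:
        raise InputError("each image set needs at least 2 images")
    feats_a = extract_features(paths_a, extractor)
    feats_b = extract_features(paths_b, extractor)
    fid = frechet_distance(
        FeatureDistribution.from_features(feats_a, extractor.extractor_id),
        FeatureDistribution.from_features(feats_b, extractor.extractor_id),
    )
    eff_subset = min(subset_size, len(paths_a), len(paths_b))
    kid_mean, kid_std = kid(feats_a, feats_b, subset_size=eff_subset,
                            n_subsets=n_subsets, seed=seed)
    report = MetricReport(fid=fid, kid_mean=kid_mean, kid_std=kid_std,
                          n_a=len(paths_a), n_b=len(paths_b),
                          extractor_id=extractor.extractor_id,
                          config={"subset_size": eff_subset, "n_subsets": n_subsets,
                                  "seed": seed})
    if report_path is not None:
        report.to_json(report_path)
    return report
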