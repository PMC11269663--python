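"""Synthetic paired unstained/stained tissue images with known ground truth.

Real slide pairs are scanned brightfield images of skin tissue before and
after H&E staining.  This module emulates their statistical structure at
desk scale: cytoplasm blobs from thresholded smooth noise, elliptical
nuclei placed by a Poisson process, a faint near-white "unstained"
appearance, and a deterministic stain oracle that recolors each tissue
class (hematoxylin-like blue-purple nuclei, eosin-like pink cytoplasm)
modulated by local texture.  Misalignment between the members of a pair is
applied as a known homography, so registration accuracy can be measured
exactly.

The stain mapping is decidable from local texture and class alone, which is
what makes the translation task learnable by a patch-level generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.transform import ProjectiveTransform, warp

from .errors import ConfigurationError, InputError
from .geometry import HomographyTransform

#: luminance range of the synthetic unstained (faint brightfield) images
UNSTAINED_LO, UNSTAINED_HI = 200.0, 255.0


@dataclass(frozen=True)
class SyntheticTissueSpec:
    """Parameters of one synthetic tissue canvas."""

    height: int = 256
    width: int = 256
    nucleus_density: float = 5.0  # expected nuclei per 1e4 px^2
    nucleus_radius_range: tuple[float, float] = (3.0, 6.0)
    cytoplasm_fraction: float = 0.35
    noise_sd: float = 2.0  # additive intensity noise on the 0..255 scale
    seed: int = 0

    def __post_init__(self):
        if self.height < 64 or self.width < 64:
            raise ConfigurationError(
                f"canvas must be at least 64x64, got {self.height}x{self.width}"
            )
        if not 0.0 <= self.cytoplasm_fraction <= 1.0:
            raise ConfigurationError("cytoplasm_fraction must lie in [0, 1]")
        if self.nucleus_density < 0:
            raise ConfigurationError("nucleus_density must be >= 0")
        lo, hi = self.nucleus_radius_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("nucleus_radius_range must be 0 < min <= max")


@dataclass(frozen=True)
class StainOracle:
    """Ground-truth class-conditional coloring for the synthetic stain."""

    nucleus_rgb: tuple[int, int, int] = (72, 61, 139)
    cytoplasm_rgb: tuple[int, int, int] = (244, 184, 196)
    background_rgb: tuple[int, int, int] = (248, 246, 246)
    blend_softness: float = 1.0  # edge-mixing width in px

    def __post_init__(self):
        for name in ("nucleus_rgb", "cytoplasm_rgb", "background_rgb"):
            rgb = getattr(self, name)
            if any(not 0 <= c <= 255 for c in rgb):
                raise ConfigurationError(f"{name} components must lie in [0, 255]")
        if any(c < 230 for c in self.background_rgb):
            raise ConfigurationError("background_rgb must be near-white (each channel >= 230)")


def generate_unstained_image(spec: SyntheticTissueSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate a faint brightfield-like canvas and its per-pixel class labels.

    Returns (image, label_map): an (H, W, 3) uint8 image and an (H, W) uint8
    map with 0 = background, 1 = cytoplasm, 2 = nucleus.  Deterministic in
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # cytoplasm blobs: threshold a smoothed noise field at the requested area fraction
    field = gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 16.0)
    if spec.cytoplasm_fraction >= 1.0:
        tissue = np.ones((h, w), dtype=bool)
    elif spec.cytoplasm_fraction <= 0.0:
        tissue = np.zeros((h, w), dtype=bool)
    else:
        cut = np.quantile(field, 1.0 - spec.cytoplasm_fraction)
        tissue = field > cut

    label = np.zeros((h, w), dtype=np.uint8)
    label[tissue] = 1

    # nuclei: homogeneous Poisson process of elliptical profiles
    n_nuclei = rng.poisson(spec.nucleus_density * h * w / 1e4)
    lo, hi = spec.nucleus_radius_range
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a, b = rng.uniform(lo, hi, size=2)
        theta = rng.uniform(0, np.pi)
        r = int(np.ceil(max(a, b))) + 1
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        label[y0:y1, x0:x1][inside] = 2

    # optical-density field: background 0, cytoplasm and nuclei textured
    texture = gaussian_filter(rng.standard_normal((h, w)), sigma=2.0)
    texture = (texture - texture.min()) / (np.ptp(texture) + 1e-12)
    density = np.zeros((h, w))
    density[label == 1] = 0.30 + 0.45 * texture[label == 1]
    density[label == 2] = 0.75 + 0.25 * texture[label == 2]

    lum = UNSTAINED_HI - (UNSTAINED_HI - UNSTAINED_LO) * density
    img = np.repeat(lum[:, :, None], 3, axis=2)
    img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), label


def apply_stain_oracle(image: np.ndarray, label_map: np.ndarray, oracle: StainOracle) -> np.ndarray:
    """Recolor an unstained canvas class-conditionally, preserving texture.

    Stain color is modulated multiplicatively by the local optical density
    recovered from the input luminance (darker tissue stains deeper), which
    preserves hue within each class.  Class edges are softened by a small
    Gaussian blur of width ``oracle.blend_softness``.
    """
    image = np.asarray(image)
    label_map = np.asarray(label_map)
    if image.shape[:2] != label_map.shape:
        raise InputError(
            f"label_map shape {label_map.shape} does not match image {image.shape[:2]}"
        )
    lum = image[..., :3].astype(float).mean(axis=2)
    density = np.clip((UNSTAINED_HI - lum) / (UNSTAINED_HI - UNSTAINED_LO), 0.0, 1.0)
    # multiplicative shade: denser tissue -> deeper (darker) stain, hue unchanged
    shade = np.clip(1.10 - 0.45 * density, 0.5, 1.0)

    out = np.empty(image.shape[:2] + (3,), dtype=float)
    out[:] = oracle.background_rgb
    for cls, rgb in ((1, oracle.cytoplasm_rgb), (2, oracle.nucleus_rgb)):
        m = label_map == cls
        out[m] = np.asarray(rgb, dtype=float) * shade[m, None]
    if oracle.blend_softness > 0:
        for c in range(3):
            out[..., c] = gaussian_filter(out[..., c], sigma=oracle.blend_softness, mode="nearest")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def perturb_geometry(image: np.ndarray, transform: HomographyTransform,
                     fill: tuple[int, int, int] = (248, 246, 246)) -> np.ndarray:
    """Warp an image by a forward homography, filling exposed areas.

    ``transform`` maps input pixel coordinates (x, y) to output coordinates;
    out-of-frame regions take the ``fill`` color.
    """
    image = np.asarray(image)
    if abs(np.linalg.det(transform.matrix)) < 1e-12:
        raise InputError("cannot warp by a singular transform")
    inv = ProjectiveTransform(matrix=np.linalg.inv(transform.matrix))
    src = image.astype(float)
    if src.ndim == 2:
        src = src[:, :, None]
        fill = (fill[0],)
    out = np.empty_like(src)
    for c in range(src.shape[2]):
        out[..., c] = warp(src[..., c], inv, order=1, cval=float(fill[c]),
                           mode="constant", preserve_range=True)
    if image.ndim == 2:
        out = out[..., 0]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def random_misalignment(rng: np.random.Generator, shape: tuple[int, int],
                        max_rotation_deg: float = 3.0, max_shift_px: float = 10.0,
                        projective_scale: float = 2e-6) -> HomographyTransform:
    """A small random homography of the kind slide re-mounting produces."""
    h, w = shape
    return HomographyTransform.from_params(
        rotation_deg=rng.uniform(-max_rotation_deg, max_rotation_deg),
        dx=rng.uniform(-max_shift_px, max_shift_px),
        dy=rng.uniform(-max_shift_px, max_shift_px),
        center=(w / 2.0, h / 2.0),
        projective=(rng.uniform(-projective_scale, projective_scale),
                    rng.uniform(-projective_scale, projective_scale)),
    )


def build_paired_dataset(spec: SyntheticTissueSpec, oracle: StainOracle, n_pairs: int,
                         misalign: bool, out_dir: str | Path) -> pd.DataFrame:
    """Write ``n_pairs`` unstained/stained PNG pairs plus labels and manifest.

    Each pair gets an independent child seed of ``spec.seed``.  When
    ``misalign`` is true the unstained image is warped by a random known
    homography whose row-major entries are stored in manifest columns
    h11..h33 (identity rows otherwise).  Returns the manifest, which is also
    written to ``out_dir/manifest.csv``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    seeds = np.random.SeedSequence(spec.seed).generate_state(2 * n_pairs) % (2**31)
    rows = []
    for i in range(n_pairs):
        pair_spec = replace(spec, seed=int(seeds[2 * i]))
        unstained, label = generate_unstained_image(pair_spec)
        stained = apply_stain_oracle(unstained, label, oracle)
        if misalign:
            rng = np.random.default_rng(int(seeds[2 * i + 1]))
            transform = random_misalignment(rng, label.shape)
            unstained = perturb_geometry(unstained, transform, fill=oracle.background_rgb)
        else:
            transform = HomographyTransform.identity()

        names = {
            "unstained_path": f"pair{i:03d}_unstained.png",
            "stained_path": f"pair{i:03d}_stained.png",
            "label_path": f"pair{i:03d}_labels.png",
        }
        Image.fromarray(unstained).save(out_dir / names["unstained_path"])
        Image.fromarray(stained).save(out_dir / names["stained_path"])
        Image.fromarray(label).save(out_dir / names["label_path"])
        row = {"pair_id": i, **names}
        row.update({f"h{r + 1}{c + 1}": transform.matrix[r, c] for r in range(3) for c in range(3)})
        rows.append(row)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False, float_format="%.10g")
    return manifest
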