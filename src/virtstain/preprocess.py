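"""Stage 1: foreground segmentation, registration, patching, filtering.

Unstained and stained slides of the same tissue are captured in different
mounting sessions, so the unstained image must be warped onto the stained
frame before the pair can be tiled.  Registration is feature-based: SIFT
keypoints on contrast-stretched grayscale, Lowe ratio matching, and a
RANSAC-fitted projective transform.  Tiling uses half-open row-major tiles
with reflect padding so every pixel of the slide is covered; patches that
are mostly background are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import exposure, morphology
from skimage.color import rgb2gray
from skimage.feature import SIFT, match_descriptors
from skimage.filters import threshold_local
from skimage.measure import ransac
from skimage.transform import ProjectiveTransform, warp

from .errors import ConfigurationError, InputError, RegistrationError
from .geometry import HomographyTransform

log = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 512
DEFAULT_STRIDE = 256
DEFAULT_MIN_FOREGROUND = 0.05


@dataclass
class ForegroundMask:
    """Boolean tissue mask plus its covered area fraction."""

    mask: np.ndarray
    foreground_fraction: float = field(init=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.foreground_fraction = float(self.mask.mean())


@dataclass
class PatchGrid:
    """Row-major half-open tiling [r, r+patch) x [c, c+patch)."""

    patch_size: int
    stride: int
    origins: list[tuple[int, int]]
    padded_shape: tuple[int, int]


@dataclass
class PatchRecord:
    pair_id: str
    origin: tuple[int, int]
    foreground_fraction: float
    unstained_patch_path: str | None = None
    stained_patch_path: str | None = None


def segment_foreground(image: np.ndarray, block_size: int = 51, offset: float = 10.0,
                       min_object_px: int = 256, opening_radius: int = 3) -> ForegroundMask:
    """Adaptive-threshold tissue segmentation on the grayscale image.

    A pixel is tissue when it is darker than its local mean by more than
    ``offset`` intensity levels (0..255 scale); small specks are removed by
    morphological opening and a component-size filter.
    """
    if block_size % 2 == 0 or block_size < 3:
        raise ConfigurationError(f"block_size must be odd and >= 3, got {block_size}")
    image = np.asarray(image)
    gray = rgb2gray(image) * 255.0 if image.ndim == 3 else image.astype(float)
    local_mean = threshold_local(gray, block_size=block_size, method="mean", offset=offset)
    mask = gray < local_mean
    mask = morphology.opening(mask, morphology.disk(opening_radius))
    labels, n = ndimage.label(mask)
    if n:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = sizes[labels] >= min_object_px
    return ForegroundMask(mask)


def _sift_keypoints(image: np.ndarray) -> SIFT:
    gray = rgb2gray(image) if image.ndim == 3 else image.astype(float)
    gray = exposure.rescale_intensity(gray.astype(float), out_range=(0.0, 1.0))
    det = SIFT()
    det.detect_and_extract(gray)
    return det


def register_pair(moving: np.ndarray, reference: np.ndarray, ratio_threshold: float = 0.75,
                  ransac_tol_px: float = 3.0, pair_id: str = "?",
                  seed: int = 0) -> tuple[HomographyTransform, np.ndarray]:
    """Estimate the homography warping ``moving`` onto ``reference``.

    Returns the transform (moving -> reference pixel coordinates) and the
    moving image resampled into the reference frame.  Raises
    :class:`RegistrationError` when fewer than 4 ratio-test matches survive
    or the RANSAC fit is degenerate.
    """
    for name, img in (("moving", moving), ("reference", reference)):
        if min(img.shape[:2]) < 128:
            raise InputError(f"{name} image must be at least 128x128, got {img.shape[:2]}")
    try:
        det_m = _sift_keypoints(moving)
        det_r = _sift_keypoints(reference)
    except RuntimeError as exc:  # skimage raises when no keypoints found
        raise RegistrationError(f"pair {pair_id}: keypoint detection failed ({exc})") from exc

    matches = match_descriptors(det_m.descriptors, det_r.descriptors,
                                max_ratio=ratio_threshold, cross_check=True)
    if len(matches) < 4:
        raise RegistrationError(
            f"pair {pair_id}: only {len(matches)} ratio-test matches (need >= 4)"
        )
    # skimage keypoints are (row, col); transforms act on (x, y)
    src = det_m.keypoints[matches[:, 0]][:, ::-1].astype(float)
    dst = det_r.keypoints[matches[:, 1]][:, ::-1].astype(float)
    model, inliers = ransac((src, dst), ProjectiveTransform, min_samples=4,
                            residual_threshold=ransac_tol_px, max_trials=1000, rng=seed)
    if model is None or inliers is None or inliers.sum() < 4 or not np.all(np.isfinite(model.params)):
        raise RegistrationError(f"pair {pair_id}: RANSAC homography fit is degenerate")
    log.info("pair %s: %d/%d keypoint matches, %d RANSAC inliers",
             pair_id, len(matches), min(len(det_m.keypoints), len(det_r.keypoints)),
             int(inliers.sum()))
    transform = HomographyTransform(model.params, inlier_count=int(inliers.sum()))

    inv = ProjectiveTransform(matrix=np.linalg.inv(transform.matrix))
    src_f = moving.astype(float)
    if src_f.ndim == 2:
        src_f = src_f[:, :, None]
    warped = np.stack(
        [warp(src_f[..., c], inv, order=1, cval=255.0, mode="constant", preserve_range=True)
         for c in range(src_f.shape[2])], axis=2)
    if moving.ndim == 2:
        warped = warped[..., 0]
    warped = np.clip(np.rint(warped), 0, 255).astype(np.uint8)
    return transform, warped


def plan_grid(shape: tuple[int, int], patch_size: int = DEFAULT_PATCH_SIZE,
              stride: int = DEFAULT_STRIDE) -> PatchGrid:
    """Tile a canvas with overlapping patches, padding up to the lattice."""
    if stride > patch_size:
        raise ConfigurationError(f"stride {stride} must not exceed patch_size {patch_size}")
    if stride <= 0 or patch_size <= 0:
        raise ConfigurationError("patch_size and stride must be positive")
    h, w = shape[:2]
    n_r = max(1, int(np.ceil((h - patch_size) / stride)) + 1)
    n_c = max(1, int(np.ceil((w - patch_size) / stride)) + 1)
    padded = ((n_r - 1) * stride + patch_size, (n_c - 1) * stride + patch_size)
    origins = [(r * stride, c * stride) for r in range(n_r) for c in range(n_c)]
    return PatchGrid(patch_size=patch_size, stride=stride, origins=origins, padded_shape=padded)


def pad_to_grid(image: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Reflect-pad an image on the bottom/right up to the grid's canvas."""
    h, w = image.shape[:2]
    ph, pw = grid.padded_shape
    widths = [(0, ph - h), (0, pw - w)] + [(0, 0)] * (image.ndim - 2)
    if ph == h and pw == w:
        return image
    return np.pad(image, widths, mode="reflect")


def extract_patches(unstained: np.ndarray, stained: np.ndarray, pair_id: str,
                    out_dir: str | Path, patch_size: int = DEFAULT_PATCH_SIZE,
                    stride: int = DEFAULT_STRIDE) -> list[PatchRecord]:
    """Cut the same overlapping grid out of both images of an aligned pair.

    Writes ``{pair_id}_r{row}_c{col}.png`` tiles into ``out_dir/unstained``
    and ``out_dir/stained`` and returns one record per grid origin (the
    foreground fraction is filled in by :func:`filter_background_patches`).
    """
    if unstained.shape[:2] != stained.shape[:2]:
        raise InputError(
            f"pair {pair_id}: image shapes differ {unstained.shape[:2]} vs {stained.shape[:2]}"
        )
    grid = plan_grid(unstained.shape[:2], patch_size, stride)
    pad_u = pad_to_grid(unstained, grid)
    pad_s = pad_to_grid(stained, grid)
    out_dir = Path(out_dir)
    (out_dir / "unstained").mkdir(parents=True, exist_ok=True)
    (out_dir / "stained").mkdir(parents=True, exist_ok=True)

    records = []
    for r, c in grid.origins:
        name = f"{pair_id}_r{r}_c{c}.png"
        tile_u = pad_u[r : r + patch_size, c : c + patch_size]
        tile_s = pad_s[r : r + patch_size, c : c + patch_size]
        path_u = out_dir / "unstained" / name
        path_s = out_dir / "stained" / name
        Image.fromarray(tile_u).save(path_u)
        Image.fromarray(tile_s).save(path_s)
        records.append(PatchRecord(pair_id=pair_id, origin=(r, c), foreground_fraction=1.0,
                                   unstained_patch_path=str(path_u),
                                   stained_patch_path=str(path_s)))
    return records


def filter_background_patches(records: list[PatchRecord], mask: ForegroundMask,
                              min_fraction: float = DEFAULT_MIN_FOREGROUND,
                              patch_size: int = DEFAULT_PATCH_SIZE) -> list[PatchRecord]:
    """Keep patches whose local tissue fraction is at least ``min_fraction``.

    The mask is zero-padded to cover edge tiles (padding counts as
    background).  Idempotent and order-independent; each surviving record
    carries its measured fraction.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ConfigurationError("min_fraction must lie in [0, 1]")
    m = mask.mask
    kept = []
    for rec in records:
        r, c = rec.origin
        tile = m[r : r + patch_size, c : c + patch_size]
        frac = float(tile.sum()) / float(patch_size * patch_size)
        if frac >= min_fraction:
            rec.foreground_fraction = frac
            kept.append(rec)
    return kept


def records_to_manifest(records: list[PatchRecord], path: str | Path) -> pd.DataFrame:
    rows = [
        {
            "pair_id": r.pair_id,
            "row": r.origin[0],
            "col": r.origin[1],
            "foreground_fraction": r.foreground_fraction,
            "unstained_patch_path": r.unstained_patch_path,
            "stained_patch_path": r.stained_patch_path,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.6g")
    return df
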