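"""Small shared helpers: image I/O and [-1, 1] model-domain conversion."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF as (H, W, 3) uint8."""
    img = np.asarray(Image.open(path).convert("RGB"))
    return img


def save_image(img: np.ndarray, path: str | Path) -> None:
    Image.fromarray(img).save(path)


def to_model(img: np.ndarray, dtype=np.float32) -> np.ndarray:
    """(H, W, 3) uint8 -> (1, H, W, 3) float in [-1, 1]."""
    x = img.astype(dtype) / 127.5 - 1.0
    return x[None]


def from_model(x: np.ndarray) -> np.ndarray:
    """(1, H, W, 3) or (H, W, 3) float in [-1, 1] -> (H, W, 3) uint8."""
    if x.ndim == 4:
        x = x[0]
    img = (np.clip(x, -1.0, 1.0) + 1.0) * 127.5
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
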