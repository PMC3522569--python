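"""Image and mask readers/writers (PNG/TIFF/JPEG via Pillow, RLE JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image


def load_image(path: str | Path) -> np.ndarray:
    """Load any PNG/TIFF/JPEG as an 8-bit H x W x 3 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def save_image(path: str | Path, img: np.ndarray) -> None:
    arr = np.asarray(img)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def save_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG with values 0/255."""
    Image.fromarray(np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8)).save(path)


def load_mask_png(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127


def save_mask_rle(path: str | Path, mask: np.ndarray) -> None:
    """Row-major run-length encoding: alternating run lengths, starting with False."""
    flat = np.asarray(mask, bool).ravel()
    # run boundaries; runs[0] counts leading False pixels (possibly 0)
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat.size and flat[0]:
        runs = [0] + runs
    payload = {"shape": list(mask.shape), "runs": runs}
    Path(path).write_text(json.dumps(payload))


def load_mask_rle(path: str | Path) -> np.ndarray:
    payload = json.loads(Path(path).read_text())
    shape = tuple(payload["shape"])
    runs = payload["runs"]
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for run in runs:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape(shape)
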