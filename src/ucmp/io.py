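"""Reading and writing the pipeline's file formats.

Images are plain 8-bit RGB PNG/TIFF rasters (no pyramid formats); boolean
masks are stored as 8-bit PNGs (0/255) with a JSON sidecar for scalar
ground truth; labeled masks as 16-bit PNGs; tabular data as UTF-8 comma CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "read_rgb_image",
    "write_rgb_image",
    "read_bool_mask",
    "write_bool_mask",
    "read_label_mask",
    "write_label_mask",
    "write_json",
    "read_json",
]


def read_rgb_image(path) -> np.ndarray:
    """Load a PNG/TIFF as an (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_rgb_image(path, img: np.ndarray) -> None:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) image")
    Image.fromarray(arr.astype(np.uint8), mode="RGB").save(path)


def read_bool_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 127


def write_bool_mask(path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(np.asarray(mask, dtype=bool), 255, 0)
                    .astype(np.uint8), mode="L").save(path)


def read_label_mask(path) -> np.ndarray:
    """Load a 16-bit label PNG as int32."""
    with Image.open(path) as im:
        return np.asarray(im, dtype=np.int32)


def write_label_mask(path, mask: np.ndarray) -> None:
    arr = np.asarray(mask)
    if arr.min() < 0 or arr.max() > 65535:
        raise ValueError("labels must fit in uint16")
    Image.fromarray(arr.astype(np.uint16), mode="I;16").save(path)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
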