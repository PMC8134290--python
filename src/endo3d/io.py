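"""File formats: 8-bit RGB PNGs, 16-bit normalized-depth PNGs, manifests.

Depth maps are stored as single-channel 16-bit greyscale PNGs holding the
normalized depth scaled to the full code range: code = round(n * 65535), so
code 0 is the far plane (25 mm) and code 65535 the near plane (0.01 mm).
The quantization step is 1/65535 in normalized units, i.e. about 4e-4 mm.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .simulator import DepthMap

__all__ = [
    "DepthFormatError",
    "write_rgb_png",
    "read_rgb_png",
    "write_depth_png",
    "read_depth_png",
    "load_manifest",
]

DEPTH_CODE_MAX = 65535


class DepthFormatError(ValueError):
    """Depth PNG is not a single-channel 16-bit image."""


def write_rgb_png(path, rgb: np.ndarray) -> None:
    """Write an H x W x 3 float image in [0, 1] as 8-bit PNG."""
    arr = np.clip(np.asarray(rgb, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255.0).round().astype(np.uint8), mode="RGB").save(path)


def read_rgb_png(path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "RGB":
        img = img.convert("RGB")
    return np.asarray(img, dtype=np.float64) / 255.0


def write_depth_png(path, depth: DepthMap) -> None:
    """Write a normalized DepthMap as a 16-bit greyscale PNG."""
    if depth.mode != "normalized":
        raise ValueError("write_depth_png expects a normalized DepthMap")
    codes = np.clip(depth.values, 0.0, 1.0) * DEPTH_CODE_MAX
    arr = codes.round().astype(np.uint16)
    Image.fromarray(arr).save(path)  # uint16 2-D array -> 16-bit greyscale


def read_depth_png(path) -> DepthMap:
    """Read a 16-bit greyscale depth PNG back to a normalized DepthMap."""
    img = Image.open(path)
    if img.mode not in ("I;16", "I;16B", "I"):
        raise DepthFormatError(
            f"{path}: expected a 16-bit single-channel PNG, got mode {img.mode!r}"
        )
    arr = np.asarray(img)
    if arr.dtype not in (np.uint16, np.int32):
        raise DepthFormatError(f"{path}: unexpected pixel dtype {arr.dtype}")
    if arr.ndim != 2:
        raise DepthFormatError(f"{path}: expected a single channel")
    if arr.dtype == np.int32 and (arr.min() < 0 or arr.max() > DEPTH_CODE_MAX):
        raise DepthFormatError(f"{path}: codes out of 16-bit range")
    return DepthMap(arr.astype(np.float64) / DEPTH_CODE_MAX, "normalized")


def load_manifest(dataset_dir) -> dict:
    """Load a simulator dataset manifest; paths resolved to the dataset dir."""
    d = Path(dataset_dir)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    for entry in manifest["entries"]:
        entry["rgb_path"] = str(d / entry["rgb"])
        entry["depth_path"] = str(d / entry["depth"])
    return manifest
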