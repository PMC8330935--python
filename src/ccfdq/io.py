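"""Raster and table I/O: 16-bit TIFF images, 1-bit PNG masks, CSV/YAML/JSON."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

U16_MAX = 65535


def quantize_u16(pixels: np.ndarray) -> np.ndarray:
    """Snap [0,1] floats onto the 16-bit grid (lossless TIFF round trips)."""
    return np.round(np.clip(pixels, 0.0, 1.0) * U16_MAX) / U16_MAX


def write_image_tiff(path: Path, pixels: np.ndarray) -> None:
    data = np.round(np.clip(pixels, 0.0, 1.0) * U16_MAX).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def read_image_tiff(path: Path) -> np.ndarray:
    data = tifffile.imread(str(path))
    if data.dtype != np.uint16:
        raise ValueError(f"{path}: expected 16-bit grayscale TIFF")
    return data.astype(np.float64) / U16_MAX


def write_depth_tiff(path: Path, depth_um: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(depth_um, dtype=np.float32))


def read_depth_tiff(path: Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float64)


def write_mask_png(path: Path, mask: np.ndarray) -> None:
    iio.imwrite(str(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def read_mask_png(path: Path) -> np.ndarray:
    return np.asarray(iio.imread(str(path))) > 127


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(path: Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: Path):
    return json.loads(Path(path).read_text())


def write_yaml(path: Path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path: Path):
    return yaml.safe_load(Path(path).read_text())
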