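"""Disk formats: 8-bit RGB TIFFs with JSON scale sidecars, PNG masks, YAML config."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

import imageio.v3 as iio
import numpy as np
import tifffile

from .ihc_quant import MontageImage

__all__ = [
    "write_rgb_tiff",
    "read_montage",
    "write_mask_png",
    "read_mask_png",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_rgb_tiff(path: str | Path, rgb: np.ndarray, pixel_size_um: float,
                   extra: Optional[dict[str, Any]] = None) -> None:
    """Write an RGB raster as 8-bit TIFF, pixel scale in a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(rgb, dtype=np.uint8), photometric="rgb")
    meta = {"pixel_size_um": float(pixel_size_um)}
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_montage(path: str | Path) -> tuple[MontageImage, dict[str, Any]]:
    """Read a TIFF + sidecar back into a MontageImage (and the raw metadata)."""
    path = Path(path)
    rgb = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return MontageImage(rgb=rgb, pixel_size=meta["pixel_size_um"]), meta


def write_mask_png(path: str | Path, mask: np.ndarray, mm_per_px: float,
                   extra: Optional[dict[str, Any]] = None) -> None:
    """Write a binary mask as PNG with the mm scale in a JSON sidecar."""
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    meta = {"mm_per_px": float(mm_per_px)}
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_mask_png(path: str | Path) -> tuple[np.ndarray, float, dict[str, Any]]:
    path = Path(path)
    mask = np.asarray(iio.imread(path)) > 127
    meta = json.loads(_sidecar(path).read_text())
    return mask, float(meta["mm_per_px"]), meta
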