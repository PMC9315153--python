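"""Serialization of Mueller images and parameter maps.

Mueller images are stored as 32-bit float multi-page TIFF stacks (16
pages in row-major element order m11, m12, ..., m44) with a JSON
sidecar carrying the pixel pitch and metadata; parameter maps go to
single-page TIFFs.  Tables are plain CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from polarscope.phantom import MuellerImage

__all__ = [
    "save_mueller_image",
    "load_mueller_image",
    "save_parameter_map",
    "load_parameter_map",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return None  # array-valued metadata (e.g. truth maps) is not serialized
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_mueller_image(img: MuellerImage, path) -> Path:
    """Write a Mueller image as a 16-page float32 TIFF plus JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    H, W = img.shape
    pages = np.moveaxis(img.mueller.reshape(H, W, 16), -1, 0).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "pixel_pitch_um": img.pixel_pitch_um,
        "meta": {k: _jsonable(v) for k, v in img.meta.items() if _jsonable(v) is not None},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_mueller_image(path) -> MuellerImage:
    """Read a Mueller image written by :func:`save_mueller_image`."""
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 16:
        raise ValueError(f"{path} is not a 16-page Mueller TIFF (shape {pages.shape})")
    H, W = pages.shape[1:]
    mueller = np.moveaxis(pages.astype(float), 0, -1).reshape(H, W, 4, 4)
    sidecar = _sidecar(path)
    pitch, meta = float("nan"), {}
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        pitch = float(data.get("pixel_pitch_um", float("nan")))
        meta = data.get("meta", {})
    return MuellerImage(mueller=mueller, pixel_pitch_um=pitch, meta=meta)


def save_parameter_map(values: np.ndarray, path) -> Path:
    """Write one float parameter map (D, delta or Delta) as a TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    return path


def load_parameter_map(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)
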