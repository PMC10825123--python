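"""Image and result-file plumbing: PNG/TIFF in, PNG/JSON/CSV out."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .detection import DetectionResult
from .vision import InvalidImageError


def read_image(path) -> np.ndarray:
    """Load an 8-bit grayscale or 24-bit RGB image (PNG or TIFF).

    Grayscale frames are promoted to RGB so the whole pipeline sees one
    input type; an alpha channel, if present, is dropped.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidImageError(f"{path}: unsupported image shape {arr.shape}")
    if arr.dtype != np.uint8:
        info = np.iinfo(arr.dtype) if arr.dtype.kind in "iu" else None
        scale = info.max if info else max(1.0, float(arr.max()))
        arr = np.clip(arr.astype(np.float64) / scale * 255.0, 0, 255).astype(np.uint8)
    return arr


def write_image(path, img: np.ndarray) -> None:
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        # binary {0,1} frames are stretched for visibility
        arr = (arr.astype(np.float64) * (255 if arr.max() <= 1 else 1)).clip(0, 255).astype(np.uint8)
    elif arr.max() <= 1:
        arr = arr * 255
    iio.imwrite(Path(path), arr)


def write_stage_images(result: DetectionResult, out_dir) -> dict[str, str]:
    """Dump the per-stage snapshots (gray, binary, filtered, dilated) as PNG,
    mirroring a step-by-step display of the recognition pipeline."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, img in result.stage_images.items():
        p = out_dir / f"{name}.png"
        write_image(p, img)
        paths[name] = str(p)
    return paths


def result_to_dict(result: DetectionResult, stage_paths: dict | None = None) -> dict:
    return {
        "success": result.success,
        "target": list(result.target) if result.target else None,
        "roi": dataclasses.asdict(result.roi) if result.roi else None,
        "particles": [dataclasses.asdict(p) for p in result.particles],
        "circles": [dataclasses.asdict(c) for c in result.circles],
        "stage_images": stage_paths or {},
    }


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
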