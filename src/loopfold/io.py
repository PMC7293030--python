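"""File formats: trace CSV, height-map TIFF/PNG with JSON sidecar, result JSON.

Traces are CSV with columns time_s, x_nm, y_nm, condition_label. Images are
float32 TIFF (heights in nm) or 16-bit PNG (scaled, scale recorded in the
sidecar); the JSON sidecar carries pixel size and any ground truth.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .afm import AFMImage
from .tpm import BeadTrace

PNG_SCALE = 1e-4  # nm per 16-bit count


def write_trace_csv(trace: BeadTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_trace_csv(path, tether_length_nm: float = np.nan) -> BeadTrace:
    return BeadTrace.from_frame(pd.read_csv(path), tether_length_nm)


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_afm_image(img: AFMImage, path, ground_truth=None) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.heights.astype(np.float32))
        meta = {"pixel_size_nm": img.pixel_size_nm, "format": "float32-nm"}
    elif path.suffix.lower() == ".png":
        counts = np.clip(np.rint(img.heights / PNG_SCALE), 0, 65535)
        Image.fromarray(counts.astype(np.uint16)).save(path)
        meta = {"pixel_size_nm": img.pixel_size_nm, "format": "uint16",
                "nm_per_count": PNG_SCALE}
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    if ground_truth is not None:
        meta["ground_truth"] = _jsonable(ground_truth)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_afm_image(path) -> AFMImage:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    if path.suffix.lower() in (".tif", ".tiff"):
        heights = tifffile.imread(path).astype(float)
    elif path.suffix.lower() == ".png":
        heights = np.asarray(Image.open(path), dtype=float) \
            * meta.get("nm_per_count", PNG_SCALE)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    return AFMImage(heights, meta["pixel_size_nm"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_json(obj, path) -> None:
    """Deterministic JSON (sorted keys, fixed layout) for reproducible runs."""
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True)
                          + "\n")
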