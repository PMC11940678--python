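"""Image and table I/O.

Frames travel as single-channel 8/16-bit TIFF or PNG with a JSON sidecar
(``<image>.json``) carrying the pixel pitch, acquisition metadata and,
for simulated frames, the ground truth.  Pixel intensities survive a
write/read round trip bit-exactly.  Per-cell parameter tables are CSV
with a stable column order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .optics import ShadowImage

__all__ = ["read_image", "write_image", "write_table", "CELL_TABLE_COLUMNS"]

CELL_TABLE_COLUMNS = [
    "image_id", "cell_id", "row", "col", "score",
    "ppd_um", "mmd_mean_um", "mmd_sd_um", "sharpness",
    "n_valid_angles", "flags",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(image: ShadowImage, path: str | Path,
                truth: list[dict] | None = None,
                extra_meta: dict | None = None) -> Path:
    """Write a frame as grayscale TIFF/PNG plus its JSON sidecar."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, image.pixels, photometric="minisblack")
    elif suffix == ".png":
        import imageio.v3 as iio
        iio.imwrite(path, image.pixels)
    else:
        raise ValueError(f"unsupported image format {suffix!r}; use TIFF or PNG")
    meta = {
        "pixel_pitch_um": image.pixel_pitch,
        "bit_depth": image.bit_depth,
        "channel_id": image.channel_id,
        "meta": _jsonable(image.meta),
    }
    if truth is not None:
        meta["ground_truth"] = _jsonable(truth)
    if extra_meta:
        meta.update(_jsonable(extra_meta))
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_image(path: str | Path,
               pixel_pitch: float | None = None) -> ShadowImage:
    """Read a grayscale TIFF/PNG frame.

    The pixel pitch comes from the JSON sidecar when present, else from
    the ``pixel_pitch`` argument; a missing pitch is an error (there is
    no safe default for a physical scale).  Multi-channel (color) input
    is rejected.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio
        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r}; use TIFF or PNG")
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name} has shape {arr.shape}; only single-channel "
            "grayscale images are supported")
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"{path.name}: unsupported dtype {arr.dtype}")
    meta: dict = {}
    channel_id = 0
    side = _sidecar(path)
    if side.exists():
        info = json.loads(side.read_text())
        pixel_pitch = info.get("pixel_pitch_um", pixel_pitch)
        channel_id = info.get("channel_id", 0)
        meta = info.get("meta", {})
        if "ground_truth" in info:
            meta["ground_truth"] = info["ground_truth"]
    if pixel_pitch is None:
        raise ValueError(
            f"{path.name}: pixel pitch unknown — provide a sidecar JSON or "
            "an explicit pixel_pitch")
    return ShadowImage(pixels=arr, pixel_pitch=float(pixel_pitch),
                       bit_depth=bit_depth, channel_id=channel_id, meta=meta)


def write_table(records, path: str | Path,
                columns: list[str] | None = None) -> Path:
    """Write records (DataFrame or list of dicts) as CSV with a stable
    column order and header."""
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if columns is None:
        columns = [c for c in CELL_TABLE_COLUMNS if c in df.columns]
        columns += [c for c in df.columns if c not in columns]
    df = df.reindex(columns=columns)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
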