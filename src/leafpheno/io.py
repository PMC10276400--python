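"""Reading and writing the pipeline's file formats.

Images are 8-bit RGB PNG; masks are single-channel 0/255 PNG; feature tables
are UTF-8 CSV with a header and '.' decimal; structured results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "read_image", "write_image", "read_mask", "write_mask",
    "read_features", "write_features", "write_json", "read_json",
]


def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[2] == 4:
        img = img[..., :3]
    return img.astype(np.uint8)


def write_image(path, image) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_mask(path, mask) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_features(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_jsonify))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
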