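"""PNG / CSV input-output helpers.

Images travel as 8-bit RGB PNG; masks as 8-bit single-channel PNG with
values {0, 255}, where 255 marks the target and maps to label 1 in memory.
Dataset manifests and measurement/evaluation reports are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import DataError
from .phantom import PhantomSample

__all__ = [
    "write_image_png",
    "read_image_png",
    "write_mask_png",
    "read_mask_png",
    "save_sample",
    "write_manifest",
    "read_manifest",
]

MENISCUS_SUFFIX = "_meniscus.png"
CCPR_SUFFIX = "_ccpr.png"
IMAGE_SUFFIX = ".png"


def write_image_png(path, image: np.ndarray) -> None:
    """Write an H×W×3 float image in [0, 1] as 8-bit RGB PNG."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8), mode="RGB").save(path)

def read_image_png(path) -> np.ndarray:
    """Read an RGB PNG into an H×W×3 float array in [0, 1]."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    except Exception as exc:
        raise DataError(f"cannot read image {path}: {exc}") from exc
    return arr / 255.0


def write_mask_png(path, mask: np.ndarray) -> None:
    """Write a binary mask as single-channel PNG with {0, 255}."""
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)


def read_mask_png(path) -> np.ndarray:
    """Read a mask PNG into a {0, 1} uint8 array (any value > 127 → 1)."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except Exception as exc:
        raise DataError(f"cannot read mask {path}: {exc}") from exc
    return (arr > 127).astype(np.uint8)


def save_sample(out_dir, sample_id: str, sample: PhantomSample) -> None:
    """Write one phantom: image plus its meniscus and CCPR masks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image_png(out / f"{sample_id}{IMAGE_SUFFIX}", sample.image)
    write_mask_png(out / f"{sample_id}{MENISCUS_SUFFIX}", sample.meniscus_mask)
    write_mask_png(out / f"{sample_id}{CCPR_SUFFIX}", sample.ring_mask)


def write_manifest(path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise DataError(f"cannot read manifest {path}: {exc}") from exc
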