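"""Image and manifest IO.

Images travel in memory as (H, W, 3) float arrays in [0, 1] with named
channels.  On disk they are single-file 3-channel 8-bit PNGs or 16-bit
multi-page TIFFs (one page per channel); channel names ride along in a text
metadata field and survive the round trip.  Quantization to the stored bit
depth is the only loss: writing, reading, and writing again is bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from PIL.PngImagePlugin import PngInfo

__all__ = ["read_image", "write_image", "read_manifest", "write_manifest"]

DEFAULT_CHANNELS = ("cytoplasm", "mitochondria", "nucleus")
_CHANNEL_KEY = "pdiff_channels"


def write_image(path, image: np.ndarray, channels=DEFAULT_CHANNELS) -> None:
    """Write a float [0, 1] (H, W, 3) image; format chosen by extension.

    ``.png`` stores 8-bit RGB; ``.tif``/``.tiff`` stores 16-bit pages, one
    per channel.
    """
    path = Path(path)
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got shape {image.shape}")
    if len(channels) != 3:
        raise ValueError("need exactly 3 channel names")
    image = np.clip(image, 0.0, 1.0)
    if path.suffix.lower() == ".png":
        arr = np.round(image * 255).astype(np.uint8)
        info = PngInfo()
        info.add_text(_CHANNEL_KEY, json.dumps(list(channels)))
        Image.fromarray(arr, mode="RGB").save(path, pnginfo=info)
    elif path.suffix.lower() in (".tif", ".tiff"):
        arr = np.round(image * 65535).astype(np.uint16)
        pages = np.transpose(arr, (2, 0, 1))
        tifffile.imwrite(
            path, pages, photometric="minisblack",
            description=json.dumps({_CHANNEL_KEY: list(channels)}),
        )
    else:
        raise ValueError(f"unsupported image format {path.suffix!r} (use .png or .tif)")


def read_image(path) -> tuple[np.ndarray, list[str]]:
    """Read an image back to float [0, 1] (H, W, 3) plus its channel names."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        with Image.open(path) as im:
            if im.mode != "RGB":
                raise ValueError(f"{path}: expected 3-channel RGB, got mode {im.mode!r}")
            arr = np.asarray(im, dtype=np.float64) / 255.0
            meta = im.text.get(_CHANNEL_KEY) if hasattr(im, "text") else None
        channels = json.loads(meta) if meta else list(DEFAULT_CHANNELS)
    elif path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            pages = tf.asarray()
            desc = tf.pages[0].description
        if pages.ndim == 2:
            raise ValueError(f"{path}: expected 3 channel pages, got a single page")
        if pages.shape[0] != 3:
            raise ValueError(f"{path}: expected 3 channel pages, got {pages.shape[0]}")
        if pages.dtype != np.uint16:
            raise ValueError(f"{path}: unsupported bit depth {pages.dtype}")
        arr = np.transpose(pages, (1, 2, 0)).astype(np.float64) / 65535.0
        channels = list(DEFAULT_CHANNELS)
        if desc:
            try:
                channels = json.loads(desc)[_CHANNEL_KEY]
            except (json.JSONDecodeError, KeyError, TypeError):
                pass
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    return arr, list(channels)


MANIFEST_COLUMNS = ("compound_id", "image_path", "role")
ROLES = ("train_img", "reserve_img", "generated_img")


def write_manifest(manifest: pd.DataFrame, path) -> None:
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    bad = set(manifest["role"]) - set(ROLES)
    if bad:
        raise ValueError(f"unknown manifest roles {sorted(bad)}")
    manifest[list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    df["compound_id"] = df["compound_id"].astype(str)
    return df
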