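"""Grayscale image reading/writing and structured run logging.

Images are represented throughout the package as 2-D ``float64`` numpy
arrays with intensities in [0, 1]. Files are 8- or 16-bit grayscale PNG or
TIFF; intensities are scaled linearly by the source bit depth's maximum
code value (255 or 65535). Multi-channel files are collapsed to grayscale
by the channel mean.
"""

from __future__ import annotations

import logging
import sys
import time
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import DimensionError, FormatError

__all__ = ["validate_image", "read_image", "write_image", "get_logger",
           "log_event"]

_PNG_SUFFIXES = {".png"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def validate_image(img: np.ndarray) -> np.ndarray:
    """Check the [0,1] 2-D intensity-grid invariants and return the array."""
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise DimensionError(f"expected a non-empty 2-D image, got shape {img.shape}")
    if not np.issubdtype(img.dtype, np.floating):
        raise DimensionError(f"expected float intensities, got dtype {img.dtype}")
    lo, hi = float(img.min()), float(img.max())
    if lo < 0.0 or hi > 1.0:
        raise DimensionError(f"intensities outside [0,1]: min={lo}, max={hi}")
    return img


def _to_unit(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:  # stray RGB(A): collapse by channel mean
        arr = arr.astype(np.float64).mean(axis=2)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = np.asarray(arr, dtype=np.float64)
    # float input from e.g. averaging uint channels: infer the code range
    peak = 255.0 if arr.max() <= 255.0 else 65535.0
    return arr / peak


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale PNG or TIFF into a [0,1] float image."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in _PNG_SUFFIXES:
        with Image.open(path) as im:
            if im.mode == "I;16":
                arr = np.asarray(im, dtype=np.uint16)
            elif im.mode in ("L", "I", "RGB", "RGBA", "LA"):
                if im.mode in ("RGBA", "LA"):
                    im = im.convert("RGB")
                arr = np.asarray(im)
                if arr.dtype == np.int32:  # PIL mode "I"
                    arr = arr.astype(np.uint16)
            else:
                raise FormatError(f"unsupported PNG mode {im.mode!r} in {path}")
    elif suffix in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
    else:
        raise FormatError(f"unsupported image format {suffix!r} (PNG/TIFF only)")
    img = np.clip(_to_unit(np.asarray(arr)), 0.0, 1.0)
    return validate_image(img)


def write_image(img: np.ndarray, path: str | Path, bit_depth: int = 8) -> Path:
    """Write a [0,1] image as 8- or 16-bit grayscale PNG/TIFF.

    Quantisation rounds half away from zero to the nearest code value, so a
    write-then-read round trip is exact to within ``1/(2**bit_depth - 1)``.
    """
    validate_image(img)
    path = Path(path)
    if bit_depth == 8:
        peak, dtype = 255, np.uint8
    elif bit_depth == 16:
        peak, dtype = 65535, np.uint16
    else:
        raise FormatError(f"bit_depth must be 8 or 16, got {bit_depth}")
    codes = np.floor(img * peak + 0.5).astype(dtype)
    suffix = path.suffix.lower()
    if suffix in _PNG_SUFFIXES:
        Image.fromarray(codes).save(path)  # uint8 -> L, uint16 -> I;16
    elif suffix in _TIFF_SUFFIXES:
        tifffile.imwrite(path, codes)
    else:
        raise FormatError(f"unsupported image format {suffix!r} (PNG/TIFF only)")
    return path


# -- structured logging ---------------------------------------------------

class _KVFormatter(logging.Formatter):
    def format(self, record):
        ts = time.strftime("%Y-%m-%dT%H:%M:%S", time.localtime(record.created))
        return f"ts={ts} level={record.levelname.lower()} {record.getMessage()}"


def get_logger(name: str = "medsrnet") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(_KVFormatter())
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


def log_event(logger: logging.Logger, event: str, **fields) -> None:
    """Emit one timestamped ``key=value`` record."""
    parts = [f"event={event}"]
    for k, v in fields.items():
        if isinstance(v, float):
            v = f"{v:.6g}"
        parts.append(f"{k}={v}")
    logger.info(" ".join(parts))
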