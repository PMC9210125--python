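"""Bicubic degradation, dihedral augmentation and paired-patch extraction.

LR/HR training pairs are constructed by bicubic downscaling of HR images.
The resampler uses the Keys cubic kernel with a = −0.5 on a pixel-centre
(align-corners-false) grid, with the kernel support widened by the scale
factor on downscale (antialiasing prefilter) — the dominant convention in
the super-resolution literature, pinned here so results are reproducible.

Augmentation is the 8-member dihedral orbit: the original, its three
right-angle rotations, and the horizontal flip of each — i.e. seven
additional versions per image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import validate_scale
from .errors import DimensionError
from .image_io import validate_image

__all__ = [
    "PairedSample",
    "resize_bicubic",
    "downscale_bicubic",
    "upsample_bicubic",
    "augment",
    "make_pairs",
    "extract_patches",
]


def _keys_cubic(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    t = np.abs(t)
    out = np.zeros_like(t)
    m1 = t <= 1.0
    m2 = (t > 1.0) & (t < 2.0)
    out[m1] = (a + 2) * t[m1] ** 3 - (a + 3) * t[m1] ** 2 + 1
    out[m2] = a * (t[m2] ** 3 - 5 * t[m2] ** 2 + 8 * t[m2] - 4)
    return out


def _resample_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic bicubic weight matrix mapping n_in → n_out samples."""
    scale = n_in / n_out
    filterscale = max(scale, 1.0)  # widen support on downscale (antialias)
    support = 2.0 * filterscale
    m = np.zeros((n_out, n_in))
    for i in range(n_out):
        center = (i + 0.5) * scale
        lo = max(0, int(np.floor(center - support + 0.5)))
        hi = min(n_in, int(np.floor(center + support + 0.5)))
        k = np.arange(lo, hi)
        w = _keys_cubic((k + 0.5 - center) / filterscale)
        m[i, lo:hi] = w / w.sum()
    return m


def resize_bicubic(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bicubic resampling to an arbitrary output size, clipped to [0,1]."""
    validate_image(img)
    mh = _resample_matrix(img.shape[0], out_h)
    mw = _resample_matrix(img.shape[1], out_w)
    return np.clip(mh @ img @ mw.T, 0.0, 1.0)


def downscale_bicubic(hr: np.ndarray, scale: int) -> np.ndarray:
    """Antialiased bicubic downscale by an integer factor; no implicit cropping."""
    r = validate_scale(scale)
    validate_image(hr)
    h, w = hr.shape
    if h % r or w % r:
        raise DimensionError(
            f"HR dimensions {h}x{w} not divisible by scale {r}")
    return resize_bicubic(hr, h // r, w // r)


def upsample_bicubic(lr: np.ndarray, scale: int) -> np.ndarray:
    """Bicubic upscale by an integer factor (also the weakest baseline method)."""
    r = validate_scale(scale)
    validate_image(lr)
    h, w = lr.shape
    return resize_bicubic(lr, h * r, w * r)


@dataclass(frozen=True)
class PairedSample:
    """An aligned (LR, HR) image pair related by bicubic downscaling."""

    lr: np.ndarray
    hr: np.ndarray
    scale: int

    def __post_init__(self):
        validate_scale(self.scale)
        validate_image(self.lr)
        validate_image(self.hr)
        if (self.hr.shape[0] != self.scale * self.lr.shape[0]
                or self.hr.shape[1] != self.scale * self.lr.shape[1]):
            raise DimensionError(
                f"HR shape {self.hr.shape} is not {self.scale}x LR shape "
                f"{self.lr.shape}")


def augment(img: np.ndarray) -> list[np.ndarray]:
    """The dihedral orbit: original, rot90/180/270, and their horizontal flips."""
    validate_image(img)
    rots = [np.rot90(img, k) for k in range(4)]
    return [np.ascontiguousarray(a) for a in rots + [np.fliplr(a) for a in rots]]


def make_pairs(hrs: list[np.ndarray], scale: int,
               augment_flag: bool = False) -> list[PairedSample]:
    """Build LR/HR pairs; with augmentation each HR yields 8 pairs."""
    r = validate_scale(scale)
    pairs = []
    for hr in hrs:
        variants = augment(hr) if augment_flag else [hr]
        for v in variants:
            pairs.append(PairedSample(lr=downscale_bicubic(v, r), hr=v, scale=r))
    return pairs


def extract_patches(pair: PairedSample, hr_patch: int, stride: int,
                    max_patches: int | None = None, seed: int = 0
                    ) -> list[PairedSample]:
    """Aligned HR/LR crops on a regular grid.

    HR offsets run over multiples of ``stride`` that are divisible by the
    scale (so each HR crop at (r·i, r·j) pairs with an LR crop at (i, j)).
    If the grid yields more than ``max_patches`` crops, a seeded subset is
    drawn without replacement, in stable order.
    """
    r = pair.scale
    h, w = pair.hr.shape
    if hr_patch % r:
        raise ValueError(f"hr_patch {hr_patch} not divisible by scale {r}")
    if hr_patch > h or hr_patch > w:
        raise ValueError(f"hr_patch {hr_patch} exceeds HR size {h}x{w}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    offs_y = [o for o in range(0, h - hr_patch + 1, stride) if o % r == 0]
    offs_x = [o for o in range(0, w - hr_patch + 1, stride) if o % r == 0]
    grid = [(oy, ox) for oy in offs_y for ox in offs_x]
    if max_patches is not None and len(grid) > max_patches:
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(grid), size=max_patches, replace=False))
        grid = [grid[i] for i in idx]
    lr_patch = hr_patch // r
    out = []
    for oy, ox in grid:
        hr_crop = pair.hr[oy:oy + hr_patch, ox:ox + hr_patch]
        lr_crop = pair.lr[oy // r:oy // r + lr_patch, ox // r:ox // r + lr_patch]
        out.append(PairedSample(lr=np.ascontiguousarray(lr_crop),
                                hr=np.ascontiguousarray(hr_crop), scale=r))
    return out
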