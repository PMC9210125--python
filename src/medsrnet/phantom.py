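"""Synthetic anatomy-like grayscale phantoms.

Every stage of the pipeline is exercisable without clinical data: phantoms
composite nested soft-edged ellipses (organ-like regions), small bright and
dark lesion discs, and a low-amplitude sinusoidal band texture on a uniform
background, then clip to [0, 1]. The recipe mimics CT slices only at the
level of sharp boundaries, compact blobs and mild texture — the features a
super-resolver must recover — and makes no claim of clinical realism.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import PhantomSpec
from .image_io import validate_image

__all__ = ["generate_phantom", "generate_dataset", "smooth_spec"]

_BACKGROUND = 0.35
_FIRST_ELLIPSE_CONTRAST = 0.35  # guarantees an edge step >= 0.2 after texture
_LESION_CONTRAST = 0.25


def _ellipse_mask(yy, xx, cy, cx, ay, ax, angle):
    ct, st = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render one phantom; bit-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    s = spec.size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    img = np.full((s, s), _BACKGROUND)

    for i in range(spec.n_ellipses):
        cy, cx = rng.uniform(0.25 * s, 0.75 * s, size=2)
        ay = rng.uniform(0.08 * s, 0.35 * s / (1 + 0.5 * i))
        ax = rng.uniform(0.08 * s, 0.35 * s / (1 + 0.5 * i))
        angle = rng.uniform(0, np.pi)
        if i == 0:
            delta = _FIRST_ELLIPSE_CONTRAST
        else:
            delta = rng.uniform(0.1, 0.2) * rng.choice([-1.0, 1.0])
        img[_ellipse_mask(yy, xx, cy, cx, ay, ax, angle)] += delta

    for _ in range(spec.n_lesions):
        cy, cx = rng.uniform(0.1 * s, 0.9 * s, size=2)
        radius = rng.uniform(0.015 * s, 0.05 * s)
        delta = _LESION_CONTRAST * rng.choice([-1.0, 1.0])
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] += delta

    if spec.texture_amplitude > 0:
        fy, fx = rng.uniform(2.0, 6.0, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        img += spec.texture_amplitude * np.sin(
            2 * np.pi * (fy * yy + fx * xx) / s + phase)

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="nearest")

    return validate_image(np.clip(img, 0.0, 1.0))


def _derived_seed(seed: int, index: int) -> int:
    """Order-stable per-image seed from a fixed hash of (seed, index)."""
    return int(np.random.SeedSequence((seed, index)).generate_state(1)[0] % (2 ** 31))


def generate_dataset(n: int, base_spec: PhantomSpec, seed: int) -> list[np.ndarray]:
    """Generate ``n`` phantoms with per-image seeds derived from (seed, index)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    from dataclasses import replace

    return [generate_phantom(replace(base_spec, seed=_derived_seed(seed, i)))
            for i in range(n)]


def smooth_spec(size: int = 128, seed: int = 0) -> PhantomSpec:
    """A low-frequency phantom recipe (heavy blur, no texture or lesions)."""
    return PhantomSpec(size=size, n_ellipses=3, n_lesions=0,
                       texture_amplitude=0.0, blur_sigma=size / 16, seed=seed)
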