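"""Training objectives and image-quality metrics.

The generator minimises a weighted sum of a pixelwise MSE content term and
an adversarial term, L_total = a1·L_MSE + a2·L_adv, where L_adv is the
mean of −log D(G(X)) over the batch (the sum form divided by batch size so
the magnitude is batch-invariant). The discriminator minimises the negated
min-max objective −E[log D(Y)] − E[log(1 − D(G(X)))].

PSNR uses peak 1 (intensities live in [0,1]); an exact pair is reported as
+inf. SSIM follows the original definition: 11×11 Gaussian window with
σ = 1.5, K1 = 0.01, K2 = 0.03, dynamic range 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.metrics import structural_similarity

from .config import LossWeights
from .errors import DimensionError, DomainError
from .image_io import validate_image

__all__ = [
    "LossBreakdown",
    "MetricReport",
    "content_loss",
    "adversarial_generator_loss",
    "discriminator_loss",
    "total_loss",
    "psnr",
    "ssim",
    "metric_report",
]

SSIM_WINDOW = 11


@dataclass(frozen=True)
class LossBreakdown:
    """Per-step loss components; ``total = a1*content + a2*adversarial``."""

    content: float
    adversarial: float
    total: float
    discriminator: float = 0.0


@dataclass(frozen=True)
class MetricReport:
    psnr: float
    ssim: float


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")


def content_loss(sr: np.ndarray, hr: np.ndarray) -> float:
    """Mean squared pixel difference (the 1/(r²WH) sum is exactly the mean)."""
    sr, hr = np.asarray(sr, dtype=np.float64), np.asarray(hr, dtype=np.float64)
    _check_same_shape(sr, hr)
    return float(np.mean((sr - hr) ** 2))


def _check_scores(scores: Sequence[float]) -> np.ndarray:
    arr = np.asarray(list(scores), dtype=np.float64)
    if arr.size == 0:
        raise DomainError("empty score batch")
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise DomainError("discriminator scores must lie strictly in (0, 1)")
    return arr


def adversarial_generator_loss(scores: Iterable[float]) -> float:
    """Batch mean of −log D(G(X)); zero in the perfect-fooling limit."""
    arr = _check_scores(scores)
    return float(np.mean(-np.log(arr)))


def discriminator_loss(real_scores: Iterable[float],
                       fake_scores: Iterable[float]) -> float:
    """−mean log D(real) − mean log(1 − D(fake))."""
    real = _check_scores(real_scores)
    fake = _check_scores(fake_scores)
    return float(-np.mean(np.log(real)) - np.mean(np.log(1.0 - fake)))


def total_loss(content: float, adversarial: float, weights: LossWeights,
               discriminator: float = 0.0) -> LossBreakdown:
    """Combine components into the weighted generator objective."""
    if not (math.isfinite(content) and math.isfinite(adversarial)):
        raise DomainError("loss components must be finite")
    return LossBreakdown(
        content=content,
        adversarial=adversarial,
        total=weights.a1 * content + weights.a2 * adversarial,
        discriminator=discriminator,
    )


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB with peak intensity 1."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    _check_same_shape(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(1.0 / mse)


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean local structural similarity (Gaussian 11×11 window, σ = 1.5)."""
    a, b = validate_image(a), validate_image(b)
    _check_same_shape(a, b)
    if min(a.shape) < SSIM_WINDOW:
        raise DimensionError(
            f"images smaller than the {SSIM_WINDOW}-pixel SSIM window")
    return float(structural_similarity(
        a, b, data_range=1.0, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03))


def metric_report(a: np.ndarray, b: np.ndarray) -> MetricReport:
    return MetricReport(psnr=psnr(a, b), ssim=ssim(a, b))
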