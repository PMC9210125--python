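"""SRGAN-style binary discriminator.

Eight 3×3 convolutional layers with channel counts rising from 64 to 512,
stride-2 convolutions (no pooling anywhere) halving the resolution four
times, batch normalisation after layers 2–8, then two dense layers and a
sigmoid producing the probability that the input is a real HR image. Plain
ReLU activations are used throughout. The sigmoid output is clamped to
[1e-7, 1 − 1e-7] so the log terms of the adversarial losses stay finite.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import DiscriminatorSpec
from .errors import DimensionError, SpecError
from .image_io import validate_image
from .nn import autograd as ag

__all__ = ["Discriminator", "build_discriminator", "discriminator_forward",
           "SCORE_EPS"]

SCORE_EPS = 1e-7


class Discriminator(nn.Module):
    def __init__(self, spec: DiscriminatorSpec, input_side: int, seed: int = 0):
        total = spec.total_stride
        if input_side % (total * 1) != 0 or input_side % 16 != 0:
            raise SpecError(
                f"input_side {input_side} must be divisible by 16")
        self.spec = spec
        self.input_side = input_side
        init = nn.Initializer(seed)
        in_ch = 1
        self.convs = []
        self.bns: list[nn.Module | None] = []
        side = input_side
        for i, (ch, stride) in enumerate(zip(spec.conv_channels,
                                             spec.conv_strides)):
            self.convs.append(nn.Conv2d(in_ch, ch, spec.kernel, init,
                                        stride=stride))
            self.bns.append(nn.BatchNorm2d(ch, init)
                            if (spec.batchnorm and i > 0) else None)
            side //= stride
            in_ch = ch
        self.final_side = side
        self.final_channels = in_ch
        self.dense1 = nn.Linear(in_ch * side * side, spec.dense_width, init)
        self.dense2 = nn.Linear(spec.dense_width, 1, init)

    def set_training(self, flag: bool) -> None:
        for bn in self.bns:
            if bn is not None:
                bn.training = flag

    def _act(self, x):
        if self.spec.activation == "leaky_relu":
            return ag.leaky_relu(x, 0.2)
        return ag.relu(x)

    def logits(self, x):
        for conv, bn in zip(self.convs, self.bns):
            x = conv(x)
            if bn is not None:
                x = bn(x)
            x = self._act(x)
        n = x.shape[0]
        x = ag.reshape(x, (n, -1))
        x = self._act(self.dense1(x))
        return self.dense2(x)

    def forward(self, x):
        """Probability batch, shape (N, 1), strictly inside (0, 1)."""
        return ag.clamp(ag.sigmoid(self.logits(x)), SCORE_EPS, 1.0 - SCORE_EPS)


def build_discriminator(spec: DiscriminatorSpec, input_side: int,
                        seed: int = 0) -> Discriminator:
    """Construct a seeded discriminator for a fixed input patch side."""
    return Discriminator(spec, input_side, seed=seed)


def discriminator_forward(disc: Discriminator, img: np.ndarray) -> float:
    """Score one image; deterministic for fixed parameters and input."""
    validate_image(img)
    if img.shape != (disc.input_side, disc.input_side):
        raise DimensionError(
            f"expected {disc.input_side}x{disc.input_side} input, "
            f"got {img.shape}")
    x = ag.Tensor(img.astype(np.float32)[None, None])
    with ag.no_grad():
        score = disc(x)
    return float(score.data[0, 0])
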