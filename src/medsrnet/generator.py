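"""The super-resolution generator.

A 4-stage, 4-stream multi-resolution trunk in the HRNet style: the input
(bicubically pre-upsampled to the target HR size) passes a bottleneck stem,
then parallel streams at full, 1/2, 1/4 and 1/8 resolution with channel
widths doubling as resolution halves. Each stage appends one lower stream
via a stride-2 convolution and runs exchange modules — per-stream residual
blocks followed by a cross-resolution fusion in which every stream receives
information from every other.

Aggregation departs from HRNetV2's bilinear upsampling: the three lower
streams are lifted back to full resolution by transposed convolutions with
(kernel, stride) pairs (5, 2), (7, 4) and (11, 8), concatenated with the
full-resolution stream (480 channels at the default widths) and reduced by
a single 1×1 prediction convolution.

Every convolutional layer is followed by ReLU, except fusion branch tips
(ReLU is applied after the fusion sum) and the final prediction layer.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import GeneratorSpec, validate_scale
from .degradation import upsample_bicubic
from .errors import DimensionError, GeometryError
from .image_io import validate_image
from .nn import autograd as ag

__all__ = [
    "deconv_geometry",
    "FuseBlock",
    "DeconvAggregation",
    "BilinearAggregation",
    "TopStreamAggregation",
    "MedSRGenerator",
    "build_generator",
    "generator_forward",
]

AGGREGATIONS = ("deconv", "bilinear", "top_stream")

# He-initialised residual branches and fusion branches are down-scaled at
# init so activation variance stays bounded through the deep trunk (the
# generator has no batch normalisation); the EDSR/ESRGAN convention.
RESIDUAL_SCALE = 0.1


def deconv_geometry(in_side: int, kernel: int, stride: int
                    ) -> tuple[int, int, int]:
    """Padding solution making a transposed convolution an exact ×stride map.

    Returns ``(padding, output_padding, out_side)`` with
    ``out = (in−1)·stride − 2·padding + kernel + output_padding = in·stride``.
    """
    if kernel <= stride:
        raise GeometryError(f"kernel {kernel} must exceed stride {stride}")
    op = (kernel - stride) % 2
    pad = (kernel - stride + op) // 2
    if not 0 <= op < stride:
        raise GeometryError(
            f"no exact geometry for kernel {kernel}, stride {stride}")
    return pad, op, in_side * stride


class Bottleneck(nn.Module):
    """1×1 → 3×3 → 1×1 residual unit with expansion 4 and ReLU throughout."""

    def __init__(self, in_ch: int, width: int, init: nn.Initializer):
        out_ch = 4 * width
        self.reduce = nn.Conv2d(in_ch, width, 1, init)
        self.conv = nn.Conv2d(width, width, 3, init)
        self.expand = nn.Conv2d(width, out_ch, 1, init)
        self.expand.weight.data *= RESIDUAL_SCALE
        self.project = (nn.Conv2d(in_ch, out_ch, 1, init)
                        if in_ch != out_ch else nn.Identity())

    def forward(self, x):
        y = ag.relu(self.reduce(x))
        y = ag.relu(self.conv(y))
        y = self.expand(y)
        return ag.relu(ag.add(y, self.project(x)))


class BasicBlock(nn.Module):
    """Two 3×3 convolutions with an identity skip; ReLU after the addition.

    Batch normalisation after each convolution is optional and off by
    default (the generator lists only convolutions and ReLU).
    """

    def __init__(self, ch: int, init: nn.Initializer,
                 batchnorm: bool = False):
        self.conv1 = nn.Conv2d(ch, ch, 3, init)
        self.conv2 = nn.Conv2d(ch, ch, 3, init)
        self.conv2.weight.data *= RESIDUAL_SCALE
        self.bn1 = nn.BatchNorm2d(ch, init) if batchnorm else None
        self.bn2 = nn.BatchNorm2d(ch, init) if batchnorm else None

    def forward(self, x):
        y = self.conv1(x)
        if self.bn1 is not None:
            y = self.bn1(y)
        y = self.conv2(ag.relu(y))
        if self.bn2 is not None:
            y = self.bn2(y)
        return ag.relu(ag.add(y, x))


class Stem(nn.Module):
    """Bottleneck units on the pre-upsampled input, then 3×3 down to widths[0]."""

    def __init__(self, spec: GeneratorSpec, init: nn.Initializer):
        units = []
        in_ch = 1
        for _ in range(spec.stem_units):
            units.append(Bottleneck(in_ch, spec.stem_width, init))
            in_ch = 4 * spec.stem_width
        self.units = units
        self.reduce = nn.Conv2d(in_ch, spec.widths[0], 3, init)

    def forward(self, x):
        for u in self.units:
            x = u(x)
        return ag.relu(self.reduce(x))


class FuseBlock(nn.Module):
    """Cross-resolution exchange: every stream receives every other stream.

    Downward paths (high → low resolution) chain stride-2 3×3 convolutions,
    one per resolution drop, widening channels level by level; upward paths
    (low → high) bilinearly interpolate then apply a 1×1 convolution. The
    target stream itself passes through unchanged, and ReLU is applied to
    the converted sum.
    """

    def __init__(self, widths: tuple[int, ...], init: nn.Initializer):
        self.widths = tuple(widths)
        n = len(widths)
        branches: list[list[nn.Module | None]] = []
        for k in range(n):  # target stream
            row: list[nn.Module | None] = []
            for j in range(n):  # source stream
                if j == k:
                    row.append(None)
                elif j < k:  # descend k−j levels
                    mods: list[nn.Module] = []
                    for step in range(j, k):
                        conv = nn.Conv2d(widths[step], widths[step + 1], 3,
                                         init, stride=2)
                        if step == k - 1:
                            conv.weight.data *= RESIDUAL_SCALE
                        mods.append(conv)
                        if step < k - 1:
                            mods.append(nn.ReLU())
                    row.append(nn.Sequential(*mods))
                else:  # ascend j−k levels
                    conv = nn.Conv2d(widths[j], widths[k], 1, init)
                    conv.weight.data *= RESIDUAL_SCALE
                    row.append(nn.Sequential(
                        nn.UpsampleBilinear(2 ** (j - k)), conv))
            branches.append(row)
        self.branches = branches

    def forward(self, streams):
        if len(streams) != len(self.widths):
            raise DimensionError(
                f"expected {len(self.widths)} streams, got {len(streams)}")
        out = []
        for k, row in enumerate(self.branches):
            acc = streams[k]
            for j, branch in enumerate(row):
                if branch is not None:
                    acc = ag.add(acc, branch(streams[j]))
            out.append(ag.relu(acc))
        return out


class ExchangeModule(nn.Module):
    """Per-stream residual blocks followed by one cross-resolution fusion."""

    def __init__(self, widths: tuple[int, ...], blocks: int,
                 init: nn.Initializer, batchnorm: bool = False):
        self.stream_blocks = [
            nn.Sequential(*[BasicBlock(w, init, batchnorm)
                            for _ in range(blocks)])
            for w in widths]
        self.fuse = FuseBlock(widths, init)

    def forward(self, streams):
        streams = [blk(s) for blk, s in zip(self.stream_blocks, streams)]
        return self.fuse(streams)


class DeconvAggregation(nn.Module):
    """Transposed-convolution lift of the lower streams, concat, 1×1 predict."""

    def __init__(self, spec: GeneratorSpec, init: nn.Initializer):
        self.deconvs = []
        for i, (k, s) in enumerate(zip(spec.deconv_kernels, spec.deconv_strides)):
            pad, op, _ = deconv_geometry(8, k, s)  # pad/op independent of side
            ch = spec.widths[i + 1]
            self.deconvs.append(nn.ConvTranspose2d(ch, ch, k, s, pad, op, init))
        self.concat_channels = sum(spec.widths)
        self.predict = nn.Conv2d(self.concat_channels, 1, 1, init)

    def forward(self, streams):
        top_shape = streams[0].shape
        lifted = [streams[0]]
        for deconv, s in zip(self.deconvs, streams[1:]):
            y = ag.relu(deconv(s))
            if y.shape[2:] != top_shape[2:]:
                raise DimensionError(
                    f"deconv output {y.shape[2:]} != top stream {top_shape[2:]}")
            lifted.append(y)
        return self.predict(ag.concat(lifted, axis=1))


class BilinearAggregation(nn.Module):
    """HRNetV2-style head: bilinear upsampling, concat, 1×1 predict."""

    def __init__(self, spec: GeneratorSpec, init: nn.Initializer):
        self.ups = [nn.UpsampleBilinear(2 ** (i + 1)) for i in range(3)]
        self.concat_channels = sum(spec.widths)
        self.predict = nn.Conv2d(self.concat_channels, 1, 1, init)

    def forward(self, streams):
        lifted = [streams[0]] + [up(s) for up, s in zip(self.ups, streams[1:])]
        return self.predict(ag.concat(lifted, axis=1))


class TopStreamAggregation(nn.Module):
    """HRNet-style head: predict from the full-resolution stream only."""

    def __init__(self, spec: GeneratorSpec, init: nn.Initializer):
        self.concat_channels = spec.widths[0]
        self.predict = nn.Conv2d(spec.widths[0], 1, 1, init)

    def forward(self, streams):
        return self.predict(streams[0])


_HEADS = {"deconv": DeconvAggregation, "bilinear": BilinearAggregation,
          "top_stream": TopStreamAggregation}


class MedSRGenerator(nn.Module):
    """Generator handle: stem + multi-resolution trunk + aggregation head."""

    def __init__(self, spec: GeneratorSpec, scale: int, seed: int = 0,
                 aggregation: str = "deconv"):
        validate_scale(scale)
        if aggregation not in _HEADS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        self.spec = spec
        self.scale = scale
        self.aggregation = aggregation
        init = nn.Initializer(seed)
        self.stem = Stem(spec, init)
        self.transitions = []
        self.stages = []
        for stage_idx, n_modules in enumerate(spec.stage_module_counts):
            n_streams = stage_idx + 2
            widths = spec.widths[:n_streams]
            self.transitions.append(
                nn.Sequential(nn.Conv2d(widths[-2], widths[-1], 3, init,
                                        stride=2), nn.ReLU()))
            self.stages.append([
                ExchangeModule(widths, spec.blocks_per_module, init,
                               batchnorm=spec.batchnorm)
                for _ in range(n_modules)])
        self.head = _HEADS[aggregation](spec, init)

    @property
    def stream_widths(self) -> tuple[int, ...]:
        return self.spec.widths

    def trunk(self, x):
        """Feature pyramid after all stages (list of 4 stream tensors)."""
        streams = [self.stem(x)]
        for transition, modules in zip(self.transitions, self.stages):
            streams.append(transition(streams[-1]))
            for m in modules:
                streams = m(streams)
        return streams

    def forward(self, x):
        """Map a pre-upsampled (N,1,S,S) batch to residual-free (N,1,S,S) output."""
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise DimensionError(
                f"pre-upsampled side {x.shape[2:]} must be divisible by 8")
        return self.head(self.trunk(x))


class SingleStreamGenerator(nn.Module):
    """A plain single-resolution residual generator (SRGAN-like baseline).

    Stem + residual blocks at the full resolution and width ``widths[0]``,
    with a 1×1 prediction head; no multi-resolution streams. Used as the
    reference point of the aggregation ablation.
    """

    def __init__(self, spec: GeneratorSpec, scale: int, seed: int = 0,
                 n_blocks: int = 8):
        validate_scale(scale)
        self.spec = spec
        self.scale = scale
        self.aggregation = "single_stream"
        init = nn.Initializer(seed)
        self.stem = Stem(spec, init)
        self.blocks = [BasicBlock(spec.widths[0], init) for _ in range(n_blocks)]
        self.head = TopStreamAggregation(spec, init)

    def forward(self, x):
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise DimensionError("pre-upsampled side must be divisible by 8")
        y = self.stem(x)
        for b in self.blocks:
            y = b(y)
        return self.head([y])


def build_generator(spec: GeneratorSpec, scale: int, seed: int = 0,
                    aggregation: str = "deconv") -> MedSRGenerator:
    """Construct a seeded generator for the given scale factor."""
    return MedSRGenerator(spec, scale, seed=seed, aggregation=aggregation)


def generator_forward(gen: MedSRGenerator, lr: np.ndarray,
                      scale: int | None = None) -> np.ndarray:
    """Super-resolve one LR image: bicubic pre-upsampling, trunk, clip to [0,1]."""
    r = validate_scale(scale if scale is not None else gen.scale)
    validate_image(lr)
    if (lr.shape[0] * r) % 8 or (lr.shape[1] * r) % 8:
        raise DimensionError(
            f"upsampled size {lr.shape[0] * r}x{lr.shape[1] * r} must be "
            "divisible by 8 (deepest stream stride)")
    up = upsample_bicubic(lr, r)
    x = ag.Tensor(up.astype(np.float32)[None, None])
    with ag.no_grad():
        y = gen(x)
    return np.clip(y.data[0, 0].astype(np.float64), 0.0, 1.0)
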