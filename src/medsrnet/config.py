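"""Run configuration: architecture, loss and training hyperparameters.

The defaults encode the published network: a 4-stage, 4-stream generator
with stream widths (32, 64, 128, 256), transposed-convolution aggregation
with kernels 5/7/11 at strides 2/4/8, an 8-layer 64→512 discriminator, and
Adam at 1e-4 halved every 50 epochs for 200 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .errors import ConfigError, SpecError

SUPPORTED_SCALES = (2, 4, 8)


def validate_scale(r: int) -> int:
    """Check the integer downsampling factor; only ×2, ×4 and ×8 are supported."""
    if r not in SUPPORTED_SCALES:
        raise ConfigError(f"scale: must be one of {SUPPORTED_SCALES}, got {r!r}")
    return int(r)


@dataclass(frozen=True)
class GeneratorSpec:
    """Hyperparameters of the multi-resolution generator trunk.

    ``widths`` are the channel counts of the four parallel streams and must
    double from one stream to the next (resolution halves while channels
    double). The stem applies ``stem_units`` bottleneck residual units of
    internal width ``stem_width`` (output ``4*stem_width`` channels) before a
    3×3 convolution reduces to ``widths[0]``. Stages 2–4 run
    ``stage_module_counts`` exchange modules of ``blocks_per_module`` basic
    residual blocks per stream, each block two 3×3 convolutions, followed by a
    cross-resolution fusion. Aggregation lifts the three lower streams back to
    full resolution with transposed convolutions of the given kernels/strides.
    """

    widths: tuple[int, int, int, int] = (32, 64, 128, 256)
    stem_units: int = 4
    stem_width: int = 64
    stage_module_counts: tuple[int, int, int] = (1, 4, 3)
    blocks_per_module: int = 4
    deconv_kernels: tuple[int, int, int] = (5, 7, 11)
    deconv_strides: tuple[int, int, int] = (2, 4, 8)
    batchnorm: bool = False
    input_mode: str = "pre_upsampled"

    # two 3x3 convolutions per basic residual block, by construction
    CONVS_PER_BLOCK = 2

    def __post_init__(self):
        if len(self.widths) != 4:
            raise SpecError(f"widths: expected 4 streams, got {len(self.widths)}")
        for k in range(3):
            if self.widths[k + 1] != 2 * self.widths[k]:
                raise SpecError(
                    "widths: channel count must double as resolution halves; "
                    f"got {self.widths}")
        n_lower = len(self.widths) - 1
        if len(self.deconv_kernels) != n_lower or len(self.deconv_strides) != n_lower:
            raise SpecError("deconv kernels/strides must cover the 3 lower streams")
        for k, s in zip(self.deconv_kernels, self.deconv_strides):
            if k <= s:
                raise SpecError(f"deconv kernel {k} must exceed stride {s}")
        if len(self.stage_module_counts) != 3:
            raise SpecError("stage_module_counts must list stages 2-4")
        if min(self.stem_units, self.stem_width, self.blocks_per_module) < 1:
            raise SpecError("stem/block counts must be >= 1")
        if min(self.stage_module_counts) < 1:
            raise SpecError("stage module counts must be >= 1")
        if self.input_mode != "pre_upsampled":
            raise SpecError(f"unsupported input_mode {self.input_mode!r}")

    @property
    def n_streams(self) -> int:
        return len(self.widths)

    def tiny(self) -> "GeneratorSpec":
        """A desk-scale variant (widths 8..64) preserving all invariants."""
        return replace(self, widths=(8, 16, 32, 64), stem_width=8)


@dataclass(frozen=True)
class DiscriminatorSpec:
    """SRGAN-style discriminator: 8 convolutions, two dense layers, sigmoid."""

    conv_channels: tuple[int, ...] = (64, 64, 128, 128, 256, 256, 512, 512)
    conv_strides: tuple[int, ...] = (1, 2, 1, 2, 1, 2, 1, 2)
    kernel: int = 3
    dense_width: int = 1024
    activation: str = "relu"
    batchnorm: bool = True

    def __post_init__(self):
        if len(self.conv_channels) != 8 or len(self.conv_strides) != 8:
            raise SpecError("discriminator needs exactly 8 convolutional layers")
        if any(c2 < c1 for c1, c2 in zip(self.conv_channels, self.conv_channels[1:])):
            raise SpecError("conv channel counts must be non-decreasing")
        if any(s not in (1, 2) for s in self.conv_strides):
            raise SpecError("conv strides must be 1 or 2")
        if self.activation not in ("relu", "leaky_relu"):
            raise SpecError(f"unsupported activation {self.activation!r}")

    @property
    def total_stride(self) -> int:
        out = 1
        for s in self.conv_strides:
            out *= s
        return out

    def tiny(self) -> "DiscriminatorSpec":
        return replace(self, conv_channels=(8, 8, 16, 16, 32, 32, 64, 64),
                       dense_width=64)


@dataclass(frozen=True)
class LossWeights:
    """Weights of the total generator objective a1·MSE + a2·adversarial."""

    a1: float = 1.0
    a2: float = 0.001

    def __post_init__(self):
        if self.a1 < 0 or self.a2 < 0 or self.a1 + self.a2 <= 0:
            raise ConfigError("loss weights must be non-negative and not both zero")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation schedule: Adam, stepwise-halved learning rate."""

    initial_lr: float = 1e-4
    halving_interval: int = 50
    total_epochs: int = 200
    batch_size: int = 16
    hr_patch: int = 96
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    mode: str = "gan"
    grad_clip: float | None = None
    mse_warmup_epochs: int = 0

    def __post_init__(self):
        if self.initial_lr <= 0:
            raise ConfigError("initial_lr must be positive")
        if self.total_epochs < 1 or self.batch_size < 1:
            raise ConfigError("total_epochs and batch_size must be >= 1")
        if self.halving_interval < 1:
            raise ConfigError("halving_interval must be >= 1")
        if self.hr_patch % 8 != 0:
            raise ConfigError("hr_patch must be divisible by 8")
        if self.mode not in ("gan", "mse_only"):
            raise ConfigError(f"mode must be 'gan' or 'mse_only', got {self.mode!r}")
        if self.seed < 0:
            raise ConfigError("seed must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic anatomy-like grayscale phantom.

    Square image of side ``size`` (multiple of 8, the deepest stream's
    stride), composited from nested soft ellipses, small bright/dark lesion
    blobs and a low-amplitude sinusoidal band texture, then optionally
    Gaussian-smoothed (``blur_sigma`` in pixels) and clipped to [0, 1].
    """

    size: int = 128
    n_ellipses: int = 4
    n_lesions: int = 6
    texture_amplitude: float = 0.06
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.size < 32 or self.size % 8 != 0:
            raise SpecError(f"size must be >= 32 and divisible by 8, got {self.size}")
        if not 0.0 <= self.texture_amplitude <= 0.5:
            raise SpecError("texture_amplitude must lie in [0, 0.5]")
        if self.n_ellipses < 0 or self.n_lesions < 0 or self.blur_sigma < 0:
            raise SpecError("counts and blur_sigma must be non-negative")


@dataclass(frozen=True)
class RunConfig:
    """Top-level run description: scale plus all component specs."""

    scale: int = 4
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 0

    def __post_init__(self):
        validate_scale(self.scale)
        if self.seed < 0:
            raise ConfigError("seed must be >= 0")


_SECTIONS = {
    "generator": GeneratorSpec,
    "discriminator": DiscriminatorSpec,
    "loss_weights": LossWeights,
    "training": TrainingConfig,
}

_TUPLE_FIELDS = {"widths", "stage_module_counts", "deconv_kernels",
                 "deconv_strides", "conv_channels", "conv_strides"}


def _build_section(cls, mapping, section: str):
    if not isinstance(mapping, dict):
        raise ConfigError(f"{section}: expected a mapping")
    known = {f.name for f in fields(cls)}
    for key in mapping:
        if key not in known:
            raise ConfigError(f"unknown key {section}.{key}")
    kwargs = {k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
              for k, v in mapping.items()}
    try:
        return cls(**kwargs)
    except (TypeError, SpecError, ConfigError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unspecified keys take the defaults.

    Unknown keys are rejected with the offending key named, as is any scale
    outside the supported {2, 4, 8}.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    top_known = {"scale", "seed"} | set(_SECTIONS)
    for key in raw:
        if key not in top_known:
            raise ConfigError(f"unknown key {key}")
    kwargs: dict = {}
    if "scale" in raw:
        kwargs["scale"] = validate_scale(raw["scale"])
    if "seed" in raw:
        kwargs["seed"] = raw["seed"]
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name], name)
    return RunConfig(**kwargs)
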