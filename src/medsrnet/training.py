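"""Alternating adversarial training of generator and discriminator.

One training step performs one discriminator update (on real HR patches
versus generated SR patches, detached from the generator) followed by one
generator update minimising a1·MSE + a2·(−log D(SR)). Both networks share
the stepwise learning-rate schedule: the initial rate is halved after every
``halving_interval`` epochs. In ``mse_only`` mode the discriminator is
never touched and the generator minimises the content term alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .config import (DiscriminatorSpec, GeneratorSpec, LossWeights,
                     TrainingConfig)
from .degradation import PairedSample, extract_patches, upsample_bicubic
from .discriminator import SCORE_EPS, Discriminator, build_discriminator
from .errors import NumericalError
from .generator import (MedSRGenerator, SingleStreamGenerator, build_generator,
                        generator_forward)
from .nn import Adam
from .nn import autograd as ag
from .objectives import LossBreakdown, metric_report

__all__ = [
    "EpochRecord",
    "TrainingLog",
    "TrainerState",
    "lr_at_epoch",
    "train_step",
    "train",
    "run_ablation",
    "save_checkpoint",
    "load_checkpoint",
    "ABLATION_VARIANTS",
]


def lr_at_epoch(config: TrainingConfig, epoch: int) -> float:
    """Learning rate at a given epoch: initial rate halved every interval."""
    if not 0 <= epoch < config.total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.total_epochs})")
    return config.initial_lr / (2 ** (epoch // config.halving_interval))


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    lr: float
    content: float
    adversarial: float
    total: float
    discriminator: float
    val_psnr: float
    val_ssim: float


@dataclass
class TrainingLog:
    records: list[EpochRecord] = field(default_factory=list)
    clamp_breaches: int = 0  # discriminator scores that hit the sigmoid clamp

    def to_rows(self) -> list[dict]:
        return [asdict(r) for r in self.records]


# -- tensor-space losses (autograd) --------------------------------------

def t_content_loss(sr: ag.Tensor, hr: ag.Tensor) -> ag.Tensor:
    return ag.tmean(ag.square(ag.sub(sr, hr)))


def t_adversarial_loss(scores: ag.Tensor) -> ag.Tensor:
    return ag.neg(ag.tmean(ag.log(scores)))


def t_discriminator_loss(real: ag.Tensor, fake: ag.Tensor) -> ag.Tensor:
    real_term = ag.neg(ag.tmean(ag.log(real)))
    fake_term = ag.neg(ag.tmean(ag.log(ag.sub(ag.Tensor(np.float32(1.0)), fake))))
    return ag.add(real_term, fake_term)


def _batch_arrays(batch: list[PairedSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a batch into pre-upsampled inputs and HR targets, NCHW float32."""
    xs = [upsample_bicubic(p.lr, p.scale) for p in batch]
    x = np.stack(xs).astype(np.float32)[:, None]
    y = np.stack([p.hr for p in batch]).astype(np.float32)[:, None]
    return x, y


def _clip_gradients(params, max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def _count_breaches(scores: np.ndarray) -> int:
    return int(np.sum((scores <= SCORE_EPS) | (scores >= 1.0 - SCORE_EPS)))


@dataclass
class TrainerState:
    """Generator/discriminator handles plus their Adam optimisers."""

    gen: MedSRGenerator | SingleStreamGenerator
    disc: Discriminator | None
    gen_opt: Adam
    disc_opt: Adam | None
    clamp_breaches: int = 0


def make_state(gen, disc, config: TrainingConfig) -> TrainerState:
    gen_opt = Adam(gen.parameters(), beta1=config.beta1, beta2=config.beta2)
    disc_opt = (Adam(disc.parameters(), beta1=config.beta1, beta2=config.beta2)
                if disc is not None else None)
    return TrainerState(gen=gen, disc=disc, gen_opt=gen_opt, disc_opt=disc_opt)


def train_step(state: TrainerState, batch: list[PairedSample],
               weights: LossWeights, lr: float, mode: str = "gan",
               grad_clip: float | None = None) -> LossBreakdown:
    """One alternating update; returns the loss breakdown of this step."""
    if not batch:
        raise ValueError("empty batch")
    x_np, y_np = _batch_arrays(batch)
    x, y = ag.Tensor(x_np), ag.Tensor(y_np)
    gen, disc = state.gen, state.disc

    sr = gen(x)
    disc_loss_val = 0.0
    adv_val = 0.0

    if mode == "gan":
        if disc is None or state.disc_opt is None:
            raise ValueError("gan mode requires a discriminator")
        # discriminator update on detached SR
        real_scores = disc(y)
        fake_scores = disc(sr.detach())
        state.clamp_breaches += (_count_breaches(real_scores.data)
                                 + _count_breaches(fake_scores.data))
        d_loss = t_discriminator_loss(real_scores, fake_scores)
        disc_loss_val = d_loss.item()
        if not np.isfinite(disc_loss_val):
            raise NumericalError(f"discriminator loss not finite: {disc_loss_val}")
        d_loss.backward()
        if grad_clip:
            _clip_gradients(disc.parameters(), grad_clip)
        state.disc_opt.step(lr)
        state.disc_opt.zero_grad()
        gen.zero_grad()

        # generator update (gradients flow through the updated discriminator)
        gen_scores = disc(sr)
        content = t_content_loss(sr, y)
        adv = t_adversarial_loss(gen_scores)
        adv_val = adv.item()
        total = ag.add(ag.mul(content, ag.Tensor(np.float32(weights.a1))),
                       ag.mul(adv, ag.Tensor(np.float32(weights.a2))))
    else:  # mse_only: discriminator untouched
        content = t_content_loss(sr, y)
        total = ag.mul(content, ag.Tensor(np.float32(weights.a1)))

    content_val = content.item()
    total_val = total.item()
    if not np.isfinite(total_val):
        raise NumericalError(
            f"generator loss not finite (content={content_val}, adv={adv_val})")
    total.backward()
    if grad_clip:
        _clip_gradients(gen.parameters(), grad_clip)
    state.gen_opt.step(lr)
    state.gen_opt.zero_grad()
    if disc is not None:
        for p in disc.parameters():  # drop stray grads from the gen pass
            p.zero_grad()

    return LossBreakdown(content=content_val, adversarial=adv_val,
                         total=total_val, discriminator=disc_loss_val)


def _patch_pool(pairs: list[PairedSample], hr_patch: int) -> list[PairedSample]:
    pool: list[PairedSample] = []
    for p in pairs:
        side = min(p.hr.shape)
        if hr_patch >= side:
            pool.append(p)
        else:
            pool.extend(extract_patches(p, hr_patch, hr_patch))
    return pool


def _split_validation(dataset: list[PairedSample], seed: int
                      ) -> tuple[list[PairedSample], list[PairedSample]]:
    """Hold out one pair per ten for validation; tiny sets validate on train."""
    n_val = len(dataset) // 10
    if n_val < 1:
        return list(dataset), list(dataset)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    val_idx = set(order[:n_val].tolist())
    train = [p for i, p in enumerate(dataset) if i not in val_idx]
    val = [p for i, p in enumerate(dataset) if i in val_idx]
    return train, val


def train(config: TrainingConfig, gen_spec: GeneratorSpec,
          disc_spec: DiscriminatorSpec | None, dataset: list[PairedSample],
          weights: LossWeights | None = None, aggregation: str = "deconv",
          out_dir: str | Path | None = None,
          ) -> tuple[MedSRGenerator, TrainingLog]:
    """Full training loop with seeded shuffling, logging and checkpointing.

    Returns the trained generator and the per-epoch log; when ``out_dir``
    is given, the best-validation-PSNR and final checkpoints are saved
    there as ``best.npz`` and ``last.npz``.
    """
    if not dataset:
        raise ValueError("empty dataset")
    weights = weights or LossWeights()
    scale = dataset[0].scale
    train_pairs, val_pairs = _split_validation(dataset, config.seed)
    pool = _patch_pool(train_pairs, config.hr_patch)

    gen = build_generator(gen_spec, scale, seed=config.seed,
                          aggregation=aggregation)
    mode = config.mode
    disc = None
    if mode == "gan":
        patch_side = min(pool[0].hr.shape)
        disc = build_discriminator(disc_spec or DiscriminatorSpec(),
                                   patch_side, seed=config.seed + 1)
    state = make_state(gen, disc, config)
    rng = np.random.default_rng(config.seed + 2)
    log = TrainingLog()
    best_psnr = -np.inf
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(config.total_epochs):
        lr = lr_at_epoch(config, epoch)
        step_mode = ("mse_only" if (mode == "gan"
                                    and epoch < config.mse_warmup_epochs)
                     else mode)
        order = rng.permutation(len(pool))
        sums = np.zeros(4)
        n_steps = 0
        for start in range(0, len(pool), config.batch_size):
            batch = [pool[i] for i in order[start:start + config.batch_size]]
            br = train_step(state, batch, weights, lr, mode=step_mode,
                            grad_clip=config.grad_clip)
            sums += (br.content, br.adversarial, br.total, br.discriminator)
            n_steps += 1
        means = sums / max(n_steps, 1)

        val_psnrs, val_ssims = [], []
        for p in val_pairs:
            sr_img = generator_forward(gen, p.lr)
            rep = metric_report(sr_img, p.hr)
            val_psnrs.append(rep.psnr)
            val_ssims.append(rep.ssim)
        finite = [v for v in val_psnrs if np.isfinite(v)]
        val_psnr = float(np.mean(finite)) if finite else np.inf
        val_ssim = float(np.mean(val_ssims))
        log.records.append(EpochRecord(
            epoch=epoch, lr=lr, content=float(means[0]),
            adversarial=float(means[1]), total=float(means[2]),
            discriminator=float(means[3]), val_psnr=val_psnr,
            val_ssim=val_ssim))
        if out_dir is not None and val_psnr >= best_psnr:
            best_psnr = val_psnr
            save_checkpoint(out_dir / "best.npz", gen)
    log.clamp_breaches = state.clamp_breaches
    if out_dir is not None:
        save_checkpoint(out_dir / "last.npz", gen)
        _write_log_csv(out_dir / "log.csv", log)
    return gen, log


def _write_log_csv(path: Path, log: TrainingLog) -> None:
    cols = ["epoch", "lr", "content", "adversarial", "total",
            "discriminator", "val_psnr", "val_ssim"]
    lines = [",".join(cols)]
    for r in log.to_rows():
        lines.append(",".join(repr(r[c]) for c in cols))
    path.write_text("\n".join(lines) + "\n")


# -- checkpointing --------------------------------------------------------

def save_checkpoint(path: str | Path, gen) -> Path:
    """Single-file archive holding the generator spec and all parameters."""
    path = Path(path)
    meta = {
        "spec": {k: list(v) if isinstance(v, tuple) else v
                 for k, v in asdict(gen.spec).items()},
        "scale": gen.scale,
        "aggregation": gen.aggregation,
    }
    state = {f"param/{k}": v for k, v in gen.state_dict().items()}
    np.savez(path, meta=np.bytes_(json.dumps(meta).encode()), **state)
    return path


def load_checkpoint(path: str | Path):
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    spec_kwargs = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in meta["spec"].items()}
    spec = GeneratorSpec(**spec_kwargs)
    if meta["aggregation"] == "single_stream":
        gen = SingleStreamGenerator(spec, meta["scale"])
    else:
        gen = build_generator(spec, meta["scale"],
                              aggregation=meta["aggregation"])
    gen.load_state_dict(state)
    return gen


# -- ablation harness -----------------------------------------------------

ABLATION_VARIANTS = ("srgan_baseline_agg", "hr_only_agg",
                     "bilinear_multires_agg", "deconv_agg",
                     "deconv_agg_plus_gan")

_VARIANT_SETUP = {
    # variant -> (generator kind, aggregation, training mode)
    "srgan_baseline_agg": ("single_stream", None, "gan"),
    "hr_only_agg": ("multires", "top_stream", "mse_only"),
    "bilinear_multires_agg": ("multires", "bilinear", "mse_only"),
    "deconv_agg": ("multires", "deconv", "mse_only"),
    "deconv_agg_plus_gan": ("multires", "deconv", "gan"),
}


def run_ablation(variants: list[str], config: TrainingConfig,
                 dataset: list[PairedSample],
                 gen_spec: GeneratorSpec | None = None,
                 disc_spec: DiscriminatorSpec | None = None,
                 weights: LossWeights | None = None):
    """Train each aggregation variant under identical seed and schedule.

    Only the aggregation head varies across the multi-resolution variants;
    the comparison isolates the contribution of deconvolution aggregation
    and of the adversarial term. Returns a pandas DataFrame with one row
    per variant (mean train-set PSNR, total and head parameter counts).
    """
    import pandas as pd

    from dataclasses import replace

    if not variants:
        raise ValueError("variants list is empty")
    unknown = [v for v in variants if v not in _VARIANT_SETUP]
    if unknown:
        raise ValueError(f"unknown variants: {unknown}")
    gen_spec = gen_spec or GeneratorSpec()
    rows = []
    for variant in variants:
        kind, aggregation, mode = _VARIANT_SETUP[variant]
        cfg = replace(config, mode=mode)
        if kind == "single_stream":
            gen = SingleStreamGenerator(gen_spec, dataset[0].scale,
                                        seed=cfg.seed)
            # train the baseline through the same loop via a tiny shim
            gen, log = _train_given(gen, cfg, disc_spec, dataset, weights)
        else:
            gen, log = train(cfg, gen_spec, disc_spec, dataset,
                             weights=weights, aggregation=aggregation)
        psnrs = [p for p in (metric_report(generator_forward(gen, s.lr),
                                           s.hr).psnr for s in dataset)
                 if np.isfinite(p)]
        rows.append({
            "variant": variant,
            "psnr": float(np.mean(psnrs)) if psnrs else np.inf,
            "n_parameters": gen.n_parameters(),
            "head_parameters": gen.head.n_parameters(),
        })
    return pd.DataFrame(rows)


def _train_given(gen, config: TrainingConfig,
                 disc_spec: DiscriminatorSpec | None,
                 dataset: list[PairedSample],
                 weights: LossWeights | None) -> tuple:
    """Run the epoch loop on an externally constructed generator."""
    weights = weights or LossWeights()
    train_pairs, _ = _split_validation(dataset, config.seed)
    pool = _patch_pool(train_pairs, config.hr_patch)
    disc = None
    if config.mode == "gan":
        disc = build_discriminator(disc_spec or DiscriminatorSpec(),
                                   min(pool[0].hr.shape), seed=config.seed + 1)
    state = make_state(gen, disc, config)
    rng = np.random.default_rng(config.seed + 2)
    log = TrainingLog()
    for epoch in range(config.total_epochs):
        lr = lr_at_epoch(config, epoch)
        order = rng.permutation(len(pool))
        for start in range(0, len(pool), config.batch_size):
            batch = [pool[i] for i in order[start:start + config.batch_size]]
            br = train_step(state, batch, weights, lr, mode=config.mode,
                            grad_clip=config.grad_clip)
        log.records.append(EpochRecord(
            epoch=epoch, lr=lr, content=br.content,
            adversarial=br.adversarial, total=br.total,
            discriminator=br.discriminator, val_psnr=np.nan, val_ssim=np.nan))
    log.clamp_breaches = state.clamp_breaches
    return gen, log
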