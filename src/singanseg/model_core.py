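"""Four-channel single-image GAN: per-scale WGAN-GP training, coarse to fine.

One generator/critic pair is trained per pyramid level on a single
four-channel sample (RGB + mask). Finished scales are frozen; each finer
scale refines the upsampled output of the chain below it, with fresh
noise injected at every level. A fixed-noise reconstruction path anchors
the chain to the training image and calibrates per-scale noise
amplitudes.

All grids in this module are channels-first ``(4, H, W)`` float32 in the
model domain.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, grad, mean_, mse, mul, neg, no_grad, pow_const, sqrt_, sub, sum_
from ._nn import Adam, Discriminator, Generator
from .io_types import ImagePyramid, PyramidConfig, resize_chw

__all__ = [
    "ScaleModelConfig",
    "TrainConfig",
    "CheckpointBundle",
    "TrainingDivergedError",
    "CheckpointError",
    "width_at",
    "init_scale_models",
    "generator_forward",
    "gradient_penalty",
    "critic_losses",
    "reconstruction_loss",
    "compute_noise_amplitude",
    "draw_noise",
    "train_pyramid",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1
N_CHANNELS = 4


class TrainingDivergedError(RuntimeError):
    """A non-finite loss was encountered during training."""


class CheckpointError(RuntimeError):
    """A checkpoint directory is missing files or has the wrong version."""


@dataclass(frozen=True)
class ScaleModelConfig:
    """Per-scale architecture: block count, feature width and its growth."""

    n_blocks: int = 5
    base_channels: int = 32
    kernel_size: int = 3
    channel_growth_every: int = 4
    max_channels: int = 128

    def __post_init__(self):
        if self.n_blocks < 3:
            raise ValueError("n_blocks must be >= 3")
        if self.base_channels < 8:
            raise ValueError("base_channels must be >= 8")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule for one pyramid of GANs.

    The paper's schedule is 2,000 epochs per scale, each epoch being one
    round of ``d_steps`` critic updates and ``g_steps`` generator updates
    on the single training image.
    """

    epochs_per_scale: int = 2000
    d_steps: int = 3
    g_steps: int = 3
    lr_g: float = 5e-4
    lr_d: float = 5e-4
    beta1: float = 0.5
    beta2: float = 0.999
    gp_weight: float = 0.1
    recon_weight: float = 10.0
    noise_amp_base: float = 0.1
    lr_decay_fraction: float = 0.8
    lr_decay_factor: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.epochs_per_scale < 1:
            raise ValueError("epochs_per_scale must be >= 1")
        for name in ("d_steps", "g_steps", "lr_g", "lr_d", "gp_weight", "recon_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CheckpointBundle:
    """Everything needed to regenerate samples from a trained pyramid."""

    pyramid_config: PyramidConfig
    scale_cfg: ScaleModelConfig
    train_cfg: TrainConfig
    shapes: list  # per-scale (H, W)
    sigmas: list  # per-scale noise amplitudes
    z_star: np.ndarray  # fixed reconstruction noise for the coarsest scale
    gen_states: list  # per-scale generator state dicts
    disc_states: list | None = None  # optional at inference
    history: list = field(default_factory=list)  # per-scale loss curves
    image_id: str = ""

    @property
    def n_scales(self) -> int:
        return len(self.gen_states)

    def __post_init__(self):
        n = len(self.gen_states)
        if not (len(self.shapes) == len(self.sigmas) == n):
            raise ValueError("inconsistent number of scales across bundle fields")

    def build_generator(self, i: int) -> Generator:
        gen = _make_generator(i, self.scale_cfg)
        gen.load_state_dict(self.gen_states[i])
        return gen

    def build_discriminator(self, i: int) -> Discriminator:
        if self.disc_states is None:
            raise CheckpointError("bundle was saved without discriminator states")
        disc = _make_discriminator(i, self.scale_cfg)
        disc.load_state_dict(self.disc_states[i])
        return disc


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def width_at(scale_index: int, cfg: ScaleModelConfig) -> int:
    """Feature width at a scale: base width doubling every few scales."""
    return min(
        cfg.base_channels * 2 ** (scale_index // cfg.channel_growth_every), cfg.max_channels
    )


def _make_generator(i: int, cfg: ScaleModelConfig, rng=None) -> Generator:
    rng = rng if rng is not None else np.random.default_rng(0)
    return Generator(N_CHANNELS, width_at(i, cfg), cfg.n_blocks, cfg.kernel_size, rng)


def _make_discriminator(i: int, cfg: ScaleModelConfig, rng=None) -> Discriminator:
    rng = rng if rng is not None else np.random.default_rng(0)
    return Discriminator(N_CHANNELS, width_at(i, cfg), cfg.n_blocks, cfg.kernel_size, rng)


def init_scale_models(
    scale_index: int,
    level_shape: tuple,
    cfg: ScaleModelConfig,
    rng: np.random.Generator,
    prev_gen: Generator | None = None,
    prev_disc: Discriminator | None = None,
) -> tuple:
    """Build the generator/critic pair for one scale.

    When the feature width is unchanged from the previous scale, weights
    are warm-started from the previous scale's trained states; across a
    width doubling a fresh random initialization is used.
    """
    h, w = level_shape
    margin = 2 * cfg.n_blocks * (cfg.kernel_size // 2)
    if min(h, w) <= margin:
        raise ValueError(f"level {level_shape} too small for {cfg.n_blocks} conv blocks")
    gen = _make_generator(scale_index, cfg, rng)
    disc = _make_discriminator(scale_index, cfg, rng)
    same_width = scale_index > 0 and width_at(scale_index, cfg) == width_at(scale_index - 1, cfg)
    if same_width and prev_gen is not None:
        gen.load_state_dict(prev_gen.state_dict())
    if same_width and prev_disc is not None:
        disc.load_state_dict(prev_disc.state_dict())
    return gen, disc


def generator_forward(gen: Generator, noise: np.ndarray, prior: np.ndarray | None = None) -> np.ndarray:
    """Run one generator on numpy grids: ``prior + residual``, clipped.

    ``prior`` defaults to zeros (the coarsest scale consumes noise only).
    """
    noise = np.asarray(noise, dtype=np.float32)
    if prior is None:
        prior = np.zeros_like(noise)
    prior = np.asarray(prior, dtype=np.float32)
    with no_grad():
        out = gen(Tensor(noise), Tensor(prior))
    return out.data


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _critic_mean(disc: Discriminator, x: Tensor) -> Tensor:
    return mean_(disc(x))


def gradient_penalty(
    disc: Discriminator,
    real: np.ndarray,
    fake: np.ndarray,
    gp_weight: float,
    rng: np.random.Generator,
) -> Tensor:
    """WGAN-GP penalty ``gp_weight * (||grad_x D(x_hat)|| - 1)^2``.

    ``x_hat`` is a single uniform-random interpolate of real and fake.
    The inner gradient is taken with graph construction on, so the
    returned Tensor supports the double backprop used in critic updates.
    """
    real = np.asarray(real)
    fake = np.asarray(fake)
    if real.shape != fake.shape:
        raise ValueError(f"real/fake shape mismatch: {real.shape} vs {fake.shape}")
    dt = np.result_type(real.dtype, fake.dtype)
    eps = dt.type(rng.uniform())
    xhat = Tensor((eps * real + (1 - eps) * fake).astype(dt), requires_grad=True)
    score = sum_(disc(xhat))
    (gx,) = grad(score, [xhat])
    norm = sqrt_(sum_(mul(gx, gx)))
    one = Tensor(np.asarray(1.0, dtype=norm.data.dtype))
    return mul(
        Tensor(np.asarray(gp_weight, dtype=norm.data.dtype)), pow_const(sub(norm, one), 2)
    )


def critic_losses(
    disc: Discriminator,
    real: np.ndarray,
    fake: np.ndarray,
    gp_weight: float,
    rng: np.random.Generator,
) -> tuple:
    """Wasserstein critic and adversarial generator losses.

    Returns ``(d_loss, g_adv_loss)`` where
    ``d_loss = mean D(fake) - mean D(real) + gradient_penalty`` and
    ``g_adv_loss = -mean D(fake)``.
    """
    real_t = Tensor(np.asarray(real))
    fake_t = Tensor(np.asarray(fake))
    d_fake = _critic_mean(disc, fake_t)
    d_real = _critic_mean(disc, real_t)
    gp = gradient_penalty(disc, real, fake, gp_weight, rng)
    d_loss = sub(d_fake, d_real) + gp
    return d_loss, neg(d_fake)


def reconstruction_loss(output: np.ndarray, target: np.ndarray, recon_weight: float) -> float:
    """Weighted mean squared error over all four channels."""
    output = np.asarray(output, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if output.shape != target.shape:
        raise ValueError(f"shape mismatch: {output.shape} vs {target.shape}")
    return float(recon_weight * np.mean((output - target) ** 2))


def compute_noise_amplitude(
    scale_index: int,
    reconstruction: np.ndarray | None,
    level: np.ndarray,
    noise_amp_base: float,
) -> float:
    """Per-scale noise amplitude: base x RMSE of the upsampled reconstruction.

    The coarsest scale uses amplitude 1 by convention.
    """
    if scale_index == 0:
        return 1.0
    rec = np.asarray(reconstruction, dtype=np.float64)
    lvl = np.asarray(level, dtype=np.float64)
    rmse = float(np.sqrt(np.mean((rec - lvl) ** 2)))
    return float(noise_amp_base * rmse)


def draw_noise(rng: np.random.Generator, scale_index: int, hw: tuple, sigma: float) -> np.ndarray:
    """Draw one noise map for a scale.

    Coarsest scale: independent Gaussian noise per channel. Finer scales:
    a single-channel spatial draw broadcast across all four channels.
    """
    h, w = hw
    if scale_index == 0:
        z = rng.standard_normal((N_CHANNELS, h, w))
    else:
        z = np.broadcast_to(rng.standard_normal((1, h, w)), (N_CHANNELS, h, w))
    return (z * sigma).astype(np.float32)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _sample_prior(gens, sigmas, shapes, upto, rng) -> np.ndarray:
    """Fresh-noise pass through the frozen scales below ``upto``."""
    if upto == 0:
        h, w = shapes[0]
        return np.zeros((N_CHANNELS, h, w), dtype=np.float32)
    x = None
    for j in range(upto):
        h, w = shapes[j]
        prior = np.zeros((N_CHANNELS, h, w), np.float32) if x is None else resize_chw(x, (h, w))
        z = draw_noise(rng, j, (h, w), sigmas[j])
        x = generator_forward(gens[j], z, prior)
    return resize_chw(x, shapes[upto])


def train_pyramid(
    pyramid: ImagePyramid,
    scale_cfg: ScaleModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    progress: bool = False,
    keep_discriminators: bool = True,
    log_every: int = 1,
) -> CheckpointBundle:
    """Train the GAN pyramid coarse to fine and return a loadable bundle.

    Each scale runs ``epochs_per_scale`` epochs of ``d_steps`` critic and
    ``g_steps`` generator updates (adversarial + weighted reconstruction
    MSE); the learning rate decays once at ``lr_decay_fraction`` of the
    epochs. Finished scales are frozen. Any non-finite loss aborts.
    """
    scale_cfg = scale_cfg or ScaleModelConfig()
    train_cfg = train_cfg or TrainConfig()
    rng = np.random.default_rng(train_cfg.seed)

    levels = [lvl.to_chw() for lvl in pyramid.levels]
    shapes = [l.shape[1:] for l in levels]

    gens: list[Generator] = []
    discs: list[Discriminator] = []
    sigmas: list[float] = []
    history: list[list] = []
    z_star: np.ndarray | None = None
    recon_prev: np.ndarray | None = None

    for i, real in enumerate(levels):
        h, w = shapes[i]
        gen, disc = init_scale_models(
            i, (h, w), scale_cfg, rng,
            prev_gen=gens[-1] if gens else None,
            prev_disc=discs[-1] if discs else None,
        )

        if i == 0:
            z_star = rng.standard_normal((N_CHANNELS, h, w)).astype(np.float32)
            rec_prior = np.zeros((N_CHANNELS, h, w), dtype=np.float32)
            rec_noise = z_star
            sigma = 1.0
        else:
            rec_prior = resize_chw(recon_prev, (h, w))
            sigma = compute_noise_amplitude(i, rec_prior, real, train_cfg.noise_amp_base)
            rec_noise = np.zeros((N_CHANNELS, h, w), dtype=np.float32)
        sigmas.append(sigma)

        real_t = Tensor(real)
        rec_prior_t = Tensor(rec_prior)
        rec_noise_t = Tensor(rec_noise)

        opt_d = Adam(disc.parameters(), lr=train_cfg.lr_d, betas=(train_cfg.beta1, train_cfg.beta2))
        opt_g = Adam(gen.parameters(), lr=train_cfg.lr_g, betas=(train_cfg.beta1, train_cfg.beta2))
        decay_at = int(train_cfg.lr_decay_fraction * train_cfg.epochs_per_scale)

        scale_hist = []
        for epoch in range(train_cfg.epochs_per_scale):
            if epoch == decay_at and train_cfg.epochs_per_scale > 1:
                opt_d.lr *= train_cfg.lr_decay_factor
                opt_g.lr *= train_cfg.lr_decay_factor

            d_loss_v = 0.0
            for _ in range(train_cfg.d_steps):
                prior = _sample_prior(gens, sigmas, shapes, i, rng)
                noise = draw_noise(rng, i, (h, w), sigma)
                fake = generator_forward(gen, noise, prior)
                d_fake = _critic_mean(disc, Tensor(fake))
                d_real = _critic_mean(disc, real_t)
                gp = gradient_penalty(disc, real, fake, train_cfg.gp_weight, rng)
                d_loss = sub(d_fake, d_real) + gp
                gd = grad(d_loss, disc.parameters())
                opt_d.step(gd)
                d_loss_v = float(d_loss.data)

            adv_v = rec_v = 0.0
            for _ in range(train_cfg.g_steps):
                prior_t = Tensor(_sample_prior(gens, sigmas, shapes, i, rng))
                noise_t = Tensor(draw_noise(rng, i, (h, w), sigma))
                fake_t = gen(noise_t, prior_t)
                adv = neg(_critic_mean(disc, fake_t))
                rec_t = gen(rec_noise_t, rec_prior_t)
                rec_mse = mse(rec_t, real_t)
                loss = adv + mul(Tensor(np.float32(train_cfg.recon_weight)), rec_mse)
                gg = grad(loss, gen.parameters())
                opt_g.step(gg)
                adv_v, rec_v = float(adv.data), float(rec_mse.data)

            if not (np.isfinite(d_loss_v) and np.isfinite(adv_v) and np.isfinite(rec_v)):
                raise TrainingDivergedError(
                    f"non-finite loss at scale {i}, epoch {epoch}: "
                    f"d={d_loss_v} adv={adv_v} recon={rec_v}"
                )
            if epoch % log_every == 0 or epoch == train_cfg.epochs_per_scale - 1:
                scale_hist.append(
                    {"epoch": epoch, "d_loss": d_loss_v, "g_adv": adv_v, "recon_mse": rec_v}
                )
            if progress and epoch % max(1, train_cfg.epochs_per_scale // 10) == 0:
                print(f"scale {i} epoch {epoch}: d={d_loss_v:.4f} recon={rec_v:.5f}")

        gens.append(gen)
        discs.append(disc)
        history.append(scale_hist)
        recon_prev = generator_forward(gen, rec_noise, rec_prior)

    return CheckpointBundle(
        pyramid_config=pyramid.config,
        scale_cfg=scale_cfg,
        train_cfg=train_cfg,
        shapes=[tuple(s) for s in shapes],
        sigmas=sigmas,
        z_star=z_star,
        gen_states=[g.state_dict() for g in gens],
        disc_states=[d.state_dict() for d in discs] if keep_discriminators else None,
        history=history,
        image_id=pyramid.levels[-1].provenance,
    )


# ---------------------------------------------------------------------------
# checkpoint persistence
# ---------------------------------------------------------------------------

def save_checkpoint(bundle: CheckpointBundle, path) -> None:
    """Write a bundle to a directory: one state file per scale + metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": CHECKPOINT_VERSION,
        "n_scales": bundle.n_scales,
        "shapes": [list(s) for s in bundle.shapes],
        "sigmas": [float(s) for s in bundle.sigmas],
        "pyramid_config": asdict(bundle.pyramid_config),
        "scale_cfg": asdict(bundle.scale_cfg),
        "train_cfg": asdict(bundle.train_cfg),
        "has_discriminators": bundle.disc_states is not None,
        "image_id": bundle.image_id,
        "history": bundle.history,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    np.save(path / "z_star.npy", bundle.z_star)
    for i in range(bundle.n_scales):
        arrays = {f"gen.{k}": v for k, v in bundle.gen_states[i].items()}
        if bundle.disc_states is not None:
            arrays.update({f"disc.{k}": v for k, v in bundle.disc_states[i].items()})
        np.savez(path / f"scale_{i:04d}.npz", **arrays)


def load_checkpoint(path) -> CheckpointBundle:
    """Load a bundle saved by :func:`save_checkpoint`.

    Raises :class:`CheckpointError` on version mismatch or missing scales.
    """
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise CheckpointError(f"no meta.json in {path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"checkpoint version {meta.get('version')} != supported {CHECKPOINT_VERSION}"
        )
    n = meta["n_scales"]
    gen_states, disc_states = [], []
    for i in range(n):
        f = path / f"scale_{i:04d}.npz"
        if not f.exists():
            raise CheckpointError(f"missing scale file {f.name}")
        with np.load(f) as z:
            gen_states.append(
                {k[len("gen."):]: z[k].copy() for k in z.files if k.startswith("gen.")}
            )
            ds = {k[len("disc."):]: z[k].copy() for k in z.files if k.startswith("disc.")}
            disc_states.append(ds)
    z_star_path = path / "z_star.npy"
    if not z_star_path.exists():
        raise CheckpointError("missing reconstruction noise z_star.npy")
    return CheckpointBundle(
        pyramid_config=PyramidConfig(**meta["pyramid_config"]),
        scale_cfg=ScaleModelConfig(**meta["scale_cfg"]),
        train_cfg=TrainConfig(**meta["train_cfg"]),
        shapes=[tuple(s) for s in meta["shapes"]],
        sigmas=list(meta["sigmas"]),
        z_star=np.load(z_star_path),
        gen_states=gen_states,
        disc_states=disc_states if meta["has_discriminators"] else None,
        history=meta.get("history", []),
        image_id=meta.get("image_id", ""),
    )
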