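"""Random sample generation from a trained checkpoint and mask diversity maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_types import FourChannelSample, resize_chw
from .model_core import CheckpointBundle, N_CHANNELS, draw_noise, generator_forward

__all__ = [
    "GenerationRequest",
    "DiversityMaps",
    "generate_samples",
    "reconstruct",
    "binarize_generated_mask",
    "mask_diversity",
]


@dataclass(frozen=True)
class GenerationRequest:
    """What to generate from a bundle.

    ``start_scale`` counts from the coarsest level (0 = fully random
    generation, the maximal-diversity setting used for the published
    synthetic sets); scales below it follow the fixed reconstruction path.
    """

    bundle: CheckpointBundle
    n_samples: int = 10
    start_scale: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0 <= self.start_scale < self.bundle.n_scales:
            raise ValueError(
                f"start_scale {self.start_scale} out of range [0, {self.bundle.n_scales})"
            )


@dataclass
class DiversityMaps:
    """Pixel-wise mean and standard deviation of a stack of masks."""

    mean_map: np.ndarray
    sd_map: np.ndarray
    n: int


def _run_chain(bundle: CheckpointBundle, gens, noise_fn) -> np.ndarray:
    x = None
    for i, (h, w) in enumerate(bundle.shapes):
        prior = (
            np.zeros((N_CHANNELS, h, w), dtype=np.float32)
            if x is None
            else resize_chw(x, (h, w))
        )
        x = generator_forward(gens[i], noise_fn(i, (h, w)), prior)
    return x


def generate_samples(req: GenerationRequest) -> list:
    """Draw ``n_samples`` four-channel samples at the finest resolution.

    Scales below ``start_scale`` reuse the stored reconstruction noise
    (z* at the coarsest scale, zero elsewhere); from ``start_scale``
    upward fresh noise is injected with the trained per-scale amplitudes.
    Deterministic under a fixed seed.
    """
    bundle = req.bundle
    rng = np.random.default_rng(req.seed)
    gens = [bundle.build_generator(i) for i in range(bundle.n_scales)]

    def noise_fn(i, hw):
        if i < req.start_scale:
            if i == 0:
                return bundle.z_star
            return np.zeros((N_CHANNELS, *hw), dtype=np.float32)
        return draw_noise(rng, i, hw, bundle.sigmas[i])

    out = []
    for k in range(req.n_samples):
        chw = _run_chain(bundle, gens, noise_fn)
        out.append(
            FourChannelSample.from_chw(chw, provenance=f"{bundle.image_id}#gen{k}")
        )
    return out


def reconstruct(bundle: CheckpointBundle) -> FourChannelSample:
    """Deterministic sample from the stored z* with zero noise above it."""
    if bundle.z_star is None:
        raise ValueError("bundle has no stored reconstruction noise")
    gens = [bundle.build_generator(i) for i in range(bundle.n_scales)]

    def noise_fn(i, hw):
        if i == 0:
            return bundle.z_star
        return np.zeros((N_CHANNELS, *hw), dtype=np.float32)

    chw = _run_chain(bundle, gens, noise_fn)
    return FourChannelSample.from_chw(chw, provenance=f"{bundle.image_id}#recon")


def binarize_generated_mask(sample: FourChannelSample) -> FourChannelSample:
    """Threshold the mask channel at the model-domain midpoint (0 -> +/-1)."""
    grid = sample.grid.copy()
    grid[:, :, 3] = np.where(grid[:, :, 3] >= 0.0, 1.0, -1.0)
    return FourChannelSample(grid, provenance=sample.provenance)


def mask_diversity(masks) -> DiversityMaps:
    """Pixel-wise mean and population SD of >= 2 stacked file-domain masks.

    Masks are 2-D arrays in {0, 255}; the maps quantify how much the
    generated lesion regions move between random samples.
    """
    masks = [np.asarray(m, dtype=np.float64) for m in masks]
    if len(masks) < 2:
        raise ValueError("need at least 2 masks")
    shape = masks[0].shape
    for m in masks:
        if m.shape != shape:
            raise ValueError(f"mask shape mismatch: {m.shape} vs {shape}")
    stack = np.stack(masks, axis=0)
    return DiversityMaps(
        mean_map=stack.mean(axis=0), sd_map=stack.std(axis=0, ddof=0), n=len(masks)
    )
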