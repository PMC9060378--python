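"""Procedural lesion-like four-channel samples for fully offline testing.

Each toy sample is a textured background with an elliptical lesion region
re-textured at a configurable contrast, plus the exact binary indicator
of that ellipse as the mask — structurally the same shape of problem as a
lesion photograph with an expert mask, at a size where a few-scale GAN
pyramid trains on one CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_types import FourChannelSample, resize_hwc, save_sample, stack_four_channel

__all__ = ["ToyLesionSpec", "make_toy_sample", "make_toy_dataset", "save_toy_dataset"]

TEXTURES = ("smooth-gradient", "perlin-like", "speckle")


@dataclass(frozen=True)
class ToyLesionSpec:
    """Geometry and texture of one synthetic lesion sample."""

    size: tuple = (64, 64)
    background_texture: str = "perlin-like"
    texture_scale: float = 8.0
    center: tuple = (32.0, 32.0)  # (row, col)
    axes: tuple = (14.0, 9.0)  # semi-axes (a, b) in pixels
    rotation: float = 0.0  # radians
    contrast: float = 0.7  # 0 = lesion invisible in RGB, 1 = full replacement
    seed: int = 0

    def __post_init__(self):
        if self.background_texture not in TEXTURES:
            raise ValueError(f"unknown texture {self.background_texture!r}")
        if min(self.axes) <= 0:
            raise ValueError("ellipse axes must be positive")


def _ellipse_extents(a: float, b: float, theta: float) -> tuple:
    """Axis-aligned half-extents (row, col) of a rotated ellipse."""
    ry = np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2)
    rx = np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)
    return ry, rx


def _ellipse_mask(size: tuple, center: tuple, axes: tuple, theta: float) -> np.ndarray:
    h, w = size
    cy, cx = center
    a, b = axes
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
    return (u * u + v * v) <= 1.0


def _texture(rng: np.random.Generator, size: tuple, kind: str, scale: float) -> np.ndarray:
    """One grayscale texture field in [0, 1]."""
    h, w = size
    if kind == "smooth-gradient":
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        t = (np.cos(theta) * xx / w + np.sin(theta) * yy / h)
        t = t + 0.15 * np.sin(2 * np.pi * xx / max(scale * 2, 4)) * np.sin(
            2 * np.pi * yy / max(scale * 2, 4)
        )
    elif kind == "perlin-like":
        t = np.zeros(size)
        amp = 1.0
        cells = 4
        for _ in range(3):
            g = rng.standard_normal((cells + 1, cells + 1))
            t = t + amp * resize_hwc(g, size)
            amp *= 0.5
            cells *= 2
    elif kind == "speckle":
        t = gaussian_filter(rng.standard_normal(size), sigma=max(scale / 8.0, 0.5))
    else:  # pragma: no cover - guarded by the spec dataclass
        raise ValueError(kind)
    t = t - t.min()
    rng_span = t.max()
    return t / rng_span if rng_span > 0 else np.zeros(size)


def make_toy_sample(spec: ToyLesionSpec) -> FourChannelSample:
    """Render one lesion-on-tissue sample with its exact ellipse mask.

    The mask is the pixel-center indicator of the ellipse regardless of
    ``contrast``, so a zero-contrast sample is a mask with no RGB signal.
    """
    h, w = spec.size
    ry, rx = _ellipse_extents(*spec.axes, spec.rotation)
    cy, cx = spec.center
    if cy - ry < 0 or cy + ry > h - 1 or cx - rx < 0 or cx + rx > w - 1:
        raise ValueError("ellipse extends outside the image")

    rng = np.random.default_rng(spec.seed)
    bg_tex = _texture(rng, spec.size, spec.background_texture, spec.texture_scale)
    lesion_tex = _texture(rng, spec.size, "speckle", spec.texture_scale / 2.0)

    # tissue-like base colors: reddish background, darker lesion
    bg_color = np.array([0.65, 0.40, 0.35]) + rng.uniform(-0.08, 0.08, 3)
    lesion_color = np.array([0.45, 0.25, 0.30]) + rng.uniform(-0.08, 0.08, 3)

    bg = bg_color[None, None, :] * (0.75 + 0.5 * bg_tex[:, :, None])
    lesion = lesion_color[None, None, :] * (0.65 + 0.7 * lesion_tex[:, :, None])

    ind = _ellipse_mask(spec.size, spec.center, spec.axes, spec.rotation)
    blend = spec.contrast * ind[:, :, None]
    rgb01 = np.clip(bg * (1.0 - blend) + lesion * blend, 0.0, 1.0)

    rgb = (rgb01 * 2.0 - 1.0).astype(np.float32)
    mask = np.where(ind, 1.0, -1.0).astype(np.float32)
    return stack_four_channel(rgb, mask, provenance=f"toy_seed{spec.seed}")


def make_toy_dataset(n: int, size: tuple = (64, 64), seed: int = 0) -> list:
    """Generate ``n`` independent toy samples with a right-skewed size mix.

    Lesion areas (as a percentage of the image) are drawn log-normally and
    clipped to [0.5%, 60%], mimicking the many-small / few-large lesion
    distribution of real polyp data; the sample median of true-pixel
    percentages sits below the mean.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    h, w = size
    rng = np.random.default_rng(seed)
    samples = []
    for k in range(n):
        pct = float(np.clip(np.exp(rng.normal(np.log(6.0), 0.8)), 0.5, 60.0))
        area = pct / 100.0 * h * w
        ratio = rng.uniform(0.45, 1.0)
        a = float(np.sqrt(area / (np.pi * ratio)))
        b = a * ratio
        cap = 0.42 * min(h, w)
        if max(a, b) > cap:
            shrink = cap / max(a, b)
            a, b = a * shrink, b * shrink
        theta = rng.uniform(0, np.pi)
        ry, rx = _ellipse_extents(a, b, theta)
        cy = rng.uniform(ry + 1, h - 2 - ry)
        cx = rng.uniform(rx + 1, w - 2 - rx)
        spec = ToyLesionSpec(
            size=size,
            background_texture=TEXTURES[k % len(TEXTURES)],
            texture_scale=float(rng.uniform(6, 12)),
            center=(cy, cx),
            axes=(a, b),
            rotation=float(theta),
            contrast=float(rng.uniform(0.4, 0.9)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        samples.append(make_toy_sample(spec))
    return samples


def save_toy_dataset(samples, out_dir) -> list:
    """Write samples in the images/masks directory layout; returns the ids."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    ids = []
    for i, s in enumerate(samples):
        sid = f"toy_{i:04d}"
        save_sample(s, out_dir / "images" / f"{sid}.png", out_dir / "masks" / f"{sid}.png")
        ids.append(sid)
    return ids
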