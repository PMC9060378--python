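"""Four-channel sample representation, normalization and image pyramids.

Two value domains are used throughout the package:

* **file domain** — 8-bit integers in ``[0, 255]``; masks are strictly
  binary (``0`` background, ``255`` foreground).
* **model domain** — floats in ``[-1, 1]`` obtained by the linear map
  ``v/127.5 - 1``; this matches the tanh-bounded generator outputs.

A :class:`FourChannelSample` stacks an RGB image (channels 0-2) with its
mask (channel 3) into one ``H x W x 4`` model-domain grid. Sizes are
reported ``(height, width)``, row-major with the origin top-left.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "AlignmentError",
    "FourChannelSample",
    "PyramidConfig",
    "ImagePyramid",
    "to_model_domain",
    "to_file_domain",
    "binarize_file_mask",
    "load_sample",
    "save_sample",
    "stack_four_channel",
    "split_four_channel",
    "build_pyramid",
    "resize_chw",
    "resize_hwc",
]

MASK_THRESHOLD = 128  # file-domain midpoint; >= is foreground


class AlignmentError(ValueError):
    """Image and mask spatial dimensions do not match."""


def to_model_domain(u8: np.ndarray) -> np.ndarray:
    """Map file-domain [0, 255] to model-domain [-1, 1] (float32)."""
    return (np.asarray(u8, dtype=np.float32) / 127.5) - 1.0


def to_file_domain(f: np.ndarray) -> np.ndarray:
    """Map model-domain [-1, 1] back to 8-bit [0, 255] with rounding."""
    return np.clip(np.rint((np.asarray(f, dtype=np.float64) + 1.0) * 127.5), 0, 255).astype(
        np.uint8
    )


def binarize_file_mask(u8: np.ndarray) -> np.ndarray:
    """Threshold an 8-bit mask at the midpoint: >= 128 -> 255, else 0."""
    return np.where(np.asarray(u8) >= MASK_THRESHOLD, 255, 0).astype(np.uint8)


@dataclass
class FourChannelSample:
    """An RGB image and its aligned mask stacked into one 4-channel grid.

    ``grid`` is ``(H, W, 4)`` float32 in the model domain; channel 3 is the
    (possibly continuous, e.g. freshly generated) mask channel.
    """

    grid: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or self.grid.shape[2] != 4:
            raise ValueError(f"expected (H, W, 4) grid, got {self.grid.shape}")

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    @property
    def size(self) -> tuple:
        return self.grid.shape[:2]

    @property
    def rgb(self) -> np.ndarray:
        return self.grid[:, :, :3]

    @property
    def mask_channel(self) -> np.ndarray:
        return self.grid[:, :, 3]

    def to_chw(self) -> np.ndarray:
        """Channels-first view for the model code."""
        return np.ascontiguousarray(self.grid.transpose(2, 0, 1))

    @classmethod
    def from_chw(cls, chw: np.ndarray, provenance: str = "") -> "FourChannelSample":
        return cls(np.ascontiguousarray(chw.transpose(1, 2, 0)), provenance)


def stack_four_channel(img: np.ndarray, mask: np.ndarray, provenance: str = "") -> FourChannelSample:
    """Stack a model-domain RGB image ``(H, W, 3)`` with a mask ``(H, W)``."""
    img = np.asarray(img, dtype=np.float32)
    mask = np.asarray(mask, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got {img.shape}")
    if mask.shape != img.shape[:2]:
        raise AlignmentError(f"mask shape {mask.shape} != image shape {img.shape[:2]}")
    return FourChannelSample(np.dstack([img, mask]), provenance)


def split_four_channel(sample: FourChannelSample) -> tuple:
    """Lossless inverse of :func:`stack_four_channel`.

    The mask channel is returned as-is (continuous in the model domain);
    thresholding is a separate, explicit operation.
    """
    if sample.grid.shape[2] != 4:
        raise ValueError("expected a 4-channel sample")
    return sample.rgb.copy(), sample.mask_channel.copy()


def load_sample(image_path, mask_path) -> FourChannelSample:
    """Read an RGB image + binary mask pair into a model-domain sample.

    The mask is binarized at the midpoint (>= 128 -> foreground) before
    normalization, so grey pixels in sloppy mask files are cleaned up.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    with Image.open(image_path) as im:
        rgb_u8 = np.asarray(im.convert("RGB"))
    with Image.open(mask_path) as im:
        mask_u8 = np.asarray(im.convert("L"))
    if mask_u8.shape != rgb_u8.shape[:2]:
        raise AlignmentError(
            f"mask {mask_u8.shape} does not align with image {rgb_u8.shape[:2]} "
            f"({image_path.name} / {mask_path.name})"
        )
    mask_u8 = binarize_file_mask(mask_u8)
    return stack_four_channel(
        to_model_domain(rgb_u8), to_model_domain(mask_u8), provenance=image_path.stem
    )


def save_sample(sample: FourChannelSample, image_path, mask_path) -> None:
    """Write the RGB channels and the (re-binarized) mask to 8-bit files.

    The mask is always written as a single-channel PNG containing only
    {0, 255}; the RGB format follows the image path's extension.
    """
    rgb_u8 = to_file_domain(sample.rgb)
    mask_u8 = binarize_file_mask(to_file_domain(sample.mask_channel))
    Image.fromarray(rgb_u8).save(image_path)
    if not str(mask_path).lower().endswith(".png"):
        raise ValueError("masks must be written as PNG to stay lossless")
    Image.fromarray(mask_u8, mode="L").save(mask_path)


# ---------------------------------------------------------------------------
# resizing / pyramids
# ---------------------------------------------------------------------------

def resize_hwc(arr: np.ndarray, hw: tuple) -> np.ndarray:
    """Bilinear resize of an (H, W, C) or (H, W) float array."""
    out = _sk_resize(
        np.asarray(arr, dtype=np.float32),
        hw,
        order=1,
        mode="reflect",
        anti_aliasing=False,
        preserve_range=True,
    )
    return out.astype(np.float32)


def resize_chw(arr: np.ndarray, hw: tuple) -> np.ndarray:
    """Bilinear resize of a channels-first (C, H, W) float array."""
    return np.ascontiguousarray(resize_hwc(arr.transpose(1, 2, 0), hw).transpose(2, 0, 1))


@dataclass(frozen=True)
class PyramidConfig:
    """Geometry of the multi-resolution pyramid.

    ``scale_factor`` is the nominal per-level downscale ratio; ``min_size``
    bounds the coarsest level's max dimension from below and ``max_size``
    caps the finest level's max dimension. Defaults follow the reference
    single-image GAN implementation.
    """

    scale_factor: float = 0.75
    min_size: int = 25
    max_size: int = 250

    def __post_init__(self):
        if not 0.0 < self.scale_factor < 1.0:
            raise ValueError("scale_factor must lie in (0, 1)")
        if not 0 < self.min_size <= self.max_size:
            raise ValueError("require 0 < min_size <= max_size")


@dataclass
class ImagePyramid:
    """Ordered rescalings of one sample, index 0 = coarsest."""

    levels: list
    config: PyramidConfig

    def __post_init__(self):
        sizes = [lvl.size for lvl in self.levels]
        for a, b in zip(sizes, sizes[1:]):
            if not (b[0] > a[0] or b[1] > a[1]):
                raise ValueError(f"pyramid level sizes must increase: {sizes}")

    @property
    def n_scales(self) -> int:
        return len(self.levels)

    @property
    def shapes(self) -> list:
        return [lvl.size for lvl in self.levels]


def _round(v: float) -> int:
    return int(math.floor(v + 0.5))


def pyramid_level_sizes(hw: tuple, config: PyramidConfig) -> list:
    """Level sizes (coarsest first) for an input of size ``hw`` after capping.

    The level count is ``N = 1 + ceil(log(min_size/capped)/log(scale_factor))``
    and the per-level ratio is then adjusted to ``(min_size/capped)^(1/(N-1))``
    so the coarsest level lands exactly on ``min_size`` while the finest level
    is the capped input; with the defaults a capped 250-pixel input yields the
    10-level (scales 0-9) layout.
    """
    h, w = hw
    m = max(h, w)
    if m > config.max_size:
        f = config.max_size / m
        h, w = _round(h * f), _round(w * f)
        m = max(h, w)
    if m < config.min_size:
        raise ValueError(f"input max dimension {m} below min_size {config.min_size}")
    if m == config.min_size:
        return [(h, w)]
    n = 1 + math.ceil(math.log(config.min_size / m) / math.log(config.scale_factor))
    eff = (config.min_size / m) ** (1.0 / (n - 1))
    sizes = []
    for i in range(n):
        f = eff ** (n - 1 - i)
        sizes.append((h, w) if i == n - 1 else (max(1, _round(h * f)), max(1, _round(w * f))))
    return sizes


def _binarize_mask_channel(grid: np.ndarray) -> np.ndarray:
    grid = grid.copy()
    grid[:, :, 3] = np.where(grid[:, :, 3] >= 0.0, 1.0, -1.0)
    return grid


def build_pyramid(sample: FourChannelSample, config: PyramidConfig | None = None) -> ImagePyramid:
    """Build the coarse-to-fine pyramid of a sample.

    All four channels are resized with the same bilinear kernel; the mask
    channel is re-binarized at the model-domain midpoint after every
    resize so each level carries a valid binary mask.
    """
    config = config or PyramidConfig()
    sizes = pyramid_level_sizes(sample.size, config)
    finest_hw = sizes[-1]
    base = sample.grid
    if finest_hw != sample.size:
        base = resize_hwc(base, finest_hw)
    base = _binarize_mask_channel(base)
    levels = []
    for i, hw in enumerate(sizes):
        if i == len(sizes) - 1:
            grid = base
        else:
            grid = _binarize_mask_channel(resize_hwc(base, hw))
        levels.append(FourChannelSample(grid, provenance=f"{sample.provenance}@{hw[0]}x{hw[1]}"))
    return ImagePyramid(levels=levels, config=config)
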