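"""Frechet-distance evaluation machinery and mask-distribution statistics.

``compute_fid`` fits one Gaussian per image *set* to pooled deep features
and reports the Frechet distance between the two fits. ``compute_sifid``
fits one Gaussian per *image* to the per-spatial-location feature vectors
of an early layer, and reports the per-pair distances — a dataset
compared against itself is numerically zero in both.

Feature extraction is pluggable. The standard choice is an Inception
network (pool3 features for FID, a pre-pooling tap for SIFID); those
require pretrained weights that cannot be downloaded offline, so a
seeded random-weight CNN backend provides the same interface for fully
offline operation. Distances are comparable only within one backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, avgpool2, no_grad, pad2d, relu
from ._nn import Conv2d, Module
from .io_types import resize_hwc, to_model_domain

__all__ = [
    "FeatureBackend",
    "GaussianStats",
    "FrechetReport",
    "frechet_distance",
    "dataset_feature_stats",
    "compute_fid",
    "fid_report",
    "sifid_pair",
    "compute_sifid",
    "sifid_report",
    "true_pixel_percentage",
    "percentage_histogram",
]


# ---------------------------------------------------------------------------
# feature backends
# ---------------------------------------------------------------------------

class _BackendNet(Module):
    def __init__(self, seed: int):
        rng = np.random.default_rng(seed)

        def conv(cin, cout):
            return Conv2d(cin, cout, 3, rng, w_std=float(np.sqrt(2.0 / (cin * 9))),
                          dtype=np.float32)

        self.c1 = conv(3, 8)
        self.c2 = conv(8, 16)
        self.c3 = conv(16, 16)

    def forward(self, x: Tensor) -> tuple:
        """Returns (early spatial tap, final spatial map)."""
        x = relu(self.c1(pad2d(x, 1)))
        x = avgpool2(x)
        early = x  # first-pooling-layer output: the SIFID tap
        x = relu(self.c2(pad2d(x, 1)))
        x = avgpool2(x)
        x = relu(self.c3(pad2d(x, 1)))
        return early, x


class FeatureBackend:
    """Deterministic feature provider for the Frechet metrics.

    ``deterministic-test`` is a seeded random-weight CNN requiring no
    downloads; ``inception-pool3`` / ``inception-early`` name the standard
    pretrained taps and raise offline. Images are resized to
    ``input_size`` (bilinear) before extraction, mirroring the standardized
    FID protocol's fixed input geometry.
    """

    def __init__(self, name: str = "deterministic-test", seed: int = 0, input_size: int = 64):
        if name in ("inception-pool3", "inception-early"):
            raise RuntimeError(
                f"backend {name!r} needs pretrained Inception weights, unavailable "
                "offline; use 'deterministic-test'"
            )
        if name != "deterministic-test":
            raise ValueError(f"unknown backend {name!r}")
        self.name = name
        self.input_size = int(input_size)
        self._net = _BackendNet(seed)
        self.pooled_dim = 16
        self.spatial_dim = 8

    def _prep(self, img: np.ndarray) -> np.ndarray:
        img = np.asarray(img)
        if img.ndim == 3 and img.shape[2] == 4:
            img = img[:, :, :3]
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"expected an (H, W, 3) image, got shape {img.shape}")
        if img.dtype == np.uint8:
            img = to_model_domain(img)
        img = np.asarray(img, dtype=np.float32)
        if img.shape[:2] != (self.input_size, self.input_size):
            img = resize_hwc(img, (self.input_size, self.input_size))
        return np.ascontiguousarray(img.transpose(2, 0, 1))

    def spatial_features(self, img: np.ndarray) -> np.ndarray:
        """Early-tap feature field, one vector per spatial location: (h*w, C)."""
        with no_grad():
            early, _ = self._net.forward(Tensor(self._prep(img)))
        c, h, w = early.data.shape
        return np.ascontiguousarray(early.data.reshape(c, h * w).T.astype(np.float64))

    def pooled_features(self, img: np.ndarray) -> np.ndarray:
        """Spatially averaged final-layer features: a (C,) vector."""
        with no_grad():
            _, final = self._net.forward(Tensor(self._prep(img)))
        return final.data.mean(axis=(1, 2)).astype(np.float64)


# ---------------------------------------------------------------------------
# Gaussian sufficient statistics and the Frechet distance
# ---------------------------------------------------------------------------

@dataclass
class GaussianStats:
    """Mean vector and covariance matrix fitted to feature vectors."""

    mu: np.ndarray
    cov: np.ndarray
    n: int

    @classmethod
    def from_features(cls, feats: np.ndarray) -> "GaussianStats":
        feats = np.asarray(feats, dtype=np.float64)
        if feats.ndim != 2 or feats.shape[0] < 2:
            raise ValueError("need an (n >= 2) x d feature matrix")
        return cls(
            mu=feats.mean(axis=0), cov=np.cov(feats, rowvar=False, ddof=1), n=feats.shape[0]
        )


@dataclass
class FrechetReport:
    """Per-set Frechet distances with their mean/SD aggregation."""

    per_set_values: list
    mean: float
    sd: float

    @classmethod
    def from_values(cls, values) -> "FrechetReport":
        v = [float(x) for x in values]
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        return cls(per_set_values=v, mean=float(np.mean(v)), sd=sd)


def _sym_sqrt(c: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition with clipping."""
    c = (c + c.T) / 2.0
    vals, vecs = np.linalg.eigh(c)
    floor = -tol * max(1.0, float(np.abs(vals).max(initial=1.0)))
    if vals.min(initial=0.0) < floor:
        raise ValueError(f"covariance is not PSD within tolerance (min eig {vals.min()})")
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def frechet_distance(a: GaussianStats, b: GaussianStats) -> float:
    """``||mu_a - mu_b||^2 + Tr(C_a + C_b - 2 (C_a C_b)^{1/2})``.

    Computed with the numerically symmetric form
    ``Tr((A^{1/2} B A^{1/2})^{1/2})`` via eigendecompositions.
    """
    mu_a, mu_b = np.asarray(a.mu, float), np.asarray(b.mu, float)
    if mu_a.shape != mu_b.shape:
        raise ValueError("dimension mismatch between Gaussian fits")
    ca = (np.asarray(a.cov, float) + np.asarray(a.cov, float).T) / 2.0
    cb = (np.asarray(b.cov, float) + np.asarray(b.cov, float).T) / 2.0
    sa = _sym_sqrt(ca)
    m = sa @ cb @ sa
    vals = np.linalg.eigvalsh((m + m.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    tr_sqrt = float(np.sum(np.sqrt(vals)))
    d2 = float(np.sum((mu_a - mu_b) ** 2))
    return d2 + float(np.trace(ca) + np.trace(cb)) - 2.0 * tr_sqrt


# ---------------------------------------------------------------------------
# FID
# ---------------------------------------------------------------------------

def dataset_feature_stats(images, backend: FeatureBackend) -> GaussianStats:
    """Gaussian fit to pooled backend features across a list of images."""
    images = list(images)
    if len(images) < 2:
        raise ValueError("need at least 2 images for a covariance estimate")
    feats = np.stack([backend.pooled_features(im) for im in images], axis=0)
    return GaussianStats.from_features(feats)


def compute_fid(real, fake, backend: FeatureBackend) -> float:
    """Frechet distance between pooled-feature Gaussians of two image sets."""
    return frechet_distance(
        dataset_feature_stats(real, backend), dataset_feature_stats(fake, backend)
    )


def fid_report(real, fake_sets, backend: FeatureBackend) -> FrechetReport:
    """FID of each generated set against the real set, with mean/SD."""
    real_stats = dataset_feature_stats(real, backend)
    values = [
        frechet_distance(real_stats, dataset_feature_stats(s, backend)) for s in fake_sets
    ]
    return FrechetReport.from_values(values)


# ---------------------------------------------------------------------------
# SIFID
# ---------------------------------------------------------------------------

def sifid_pair(real_img, fake_img, backend: FeatureBackend) -> float:
    """Single-image Frechet distance over per-location feature vectors."""
    fa = backend.spatial_features(real_img)
    fb = backend.spatial_features(fake_img)
    if fa.shape[0] < fa.shape[1] + 1:
        raise ValueError("feature map spatially too small for a covariance fit")
    return frechet_distance(GaussianStats.from_features(fa), GaussianStats.from_features(fb))


def compute_sifid(pairs, backend: FeatureBackend) -> FrechetReport:
    """Per-pair SIFID for one generated set.

    ``pairs`` is a list of (real image, fake image); the report carries
    the per-pair values with their mean/SD.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no image pairs given")
    return FrechetReport.from_values(
        [sifid_pair(r, f, backend) for r, f in pairs]
    )


def sifid_report(real_images, fake_sets, backend: FeatureBackend) -> FrechetReport:
    """Mean SIFID per generated set, aggregated over sets (Table-1 layout)."""
    per_set = []
    for s in fake_sets:
        if len(s) != len(real_images):
            raise ValueError("each generated set must pair 1:1 with the real images")
        per_set.append(compute_sifid(list(zip(real_images, s)), backend).mean)
    return FrechetReport.from_values(per_set)


# ---------------------------------------------------------------------------
# mask statistics
# ---------------------------------------------------------------------------

def true_pixel_percentage(mask: np.ndarray) -> float:
    """Foreground pixels as a percentage of all pixels of a binary mask."""
    mask = np.asarray(mask)
    values = np.unique(mask)
    if mask.dtype == bool:
        fg = mask
    elif set(values.tolist()) <= {0, 255}:
        fg = mask == 255
    else:
        raise ValueError(f"mask is not binary (values {values[:10]})")
    return 100.0 * float(fg.sum()) / fg.size


def percentage_histogram(values, bin_width: int = 5) -> np.ndarray:
    """Counts per half-open bin ``[lo, lo+bin_width)`` over [0, 100].

    The final bin is closed at 100 so every valid percentage lands in
    exactly one of the ``ceil(100/bin_width)`` bins; counts sum to n.
    """
    values = np.asarray(list(values), dtype=np.float64)
    if values.size and (values.min() < 0 or values.max() > 100):
        raise ValueError("percentages must lie in [0, 100]")
    nbins = math.ceil(100 / bin_width)
    counts = np.zeros(nbins, dtype=np.int64)
    for v in values:
        counts[min(int(v // bin_width), nbins - 1)] += 1
    return counts
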