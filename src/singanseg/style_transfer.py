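"""Style-transfer refinement of generated RGB images.

A third image is optimized to minimize a weighted sum of a content
distance (feature-map MSE against the generated image) and a style
distance (Gram-matrix MSE against the real image), following the classic
neural-style formulation. Optimization is quasi-Newton (L-BFGS) with the
pixels box-constrained to the model domain.

The default ``pretrained`` backend would be a VGG-19-style ImageNet
feature extractor; since pretrained weights cannot be downloaded in an
offline environment, a seeded random-weight CNN backend
(``deterministic-test``) provides the same interface and makes every
code path testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._autodiff import (
    Tensor,
    avgpool2,
    grad,
    matmul,
    mean_,
    mse,
    mul,
    no_grad,
    pad2d,
    relu,
    reshape,
    sub,
    transpose,
)
from ._nn import Conv2d, Module
from .io_types import FourChannelSample, resize_hwc

__all__ = [
    "StyleTransferConfig",
    "FeatureExtractor",
    "gram_matrix",
    "content_loss",
    "style_loss",
    "run_style_transfer",
    "transfer_sample",
]

DEFAULT_CONTENT_LAYERS = ("relu3",)
DEFAULT_STYLE_LAYERS = ("relu1", "relu2", "relu3", "relu4")


@dataclass(frozen=True)
class StyleTransferConfig:
    """Weights, step count and layer taps for the refinement stage.

    ``content_weight=1, style_weight=1000`` is the 1:1000 content:style
    ratio; the default step count is 1,000.
    """

    content_weight: float = 1.0
    style_weight: float = 1000.0
    steps: int = 1000
    content_layers: tuple = DEFAULT_CONTENT_LAYERS
    style_layers: tuple = DEFAULT_STYLE_LAYERS
    init_mode: str = "content"
    backend: str = "deterministic-test"
    backend_seed: int = 0

    def __post_init__(self):
        if self.content_weight < 0 or self.style_weight < 0:
            raise ValueError("weights must be >= 0")
        if self.content_weight == 0 and self.style_weight == 0:
            raise ValueError("content and style weights cannot both be 0")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.init_mode not in ("content", "noise"):
            raise ValueError("init_mode must be 'content' or 'noise'")


class _TestBackendNet(Module):
    """Small seeded random-weight CNN with four named taps."""

    def __init__(self, seed: int):
        rng = np.random.default_rng(seed)
        # He-style scaling keeps activations O(1) through depth
        def conv(cin, cout):
            c = Conv2d(cin, cout, 3, rng, w_std=float(np.sqrt(2.0 / (cin * 9))), dtype=np.float64)
            return c

        self.c1 = conv(3, 8)
        self.c2 = conv(8, 16)
        self.c3 = conv(16, 32)
        self.c4 = conv(32, 32)

    def taps(self, x: Tensor, wanted: set) -> dict:
        out = {}
        x = relu(self.c1(pad2d(x, 1)))
        if "relu1" in wanted:
            out["relu1"] = x
        x = avgpool2(x)
        x = relu(self.c2(pad2d(x, 1)))
        if "relu2" in wanted:
            out["relu2"] = x
        x = avgpool2(x)
        x = relu(self.c3(pad2d(x, 1)))
        if "relu3" in wanted:
            out["relu3"] = x
        x = relu(self.c4(pad2d(x, 1)))
        if "relu4" in wanted:
            out["relu4"] = x
        return out


class FeatureExtractor:
    """Fixed layered feature-map provider with named taps.

    backends:
      - ``deterministic-test``: seeded random-weight CNN, no downloads.
      - ``pretrained``: VGG-19-equivalent; unavailable offline and raises.
    """

    LAYER_NAMES = ("relu1", "relu2", "relu3", "relu4")

    def __init__(self, backend: str = "deterministic-test", seed: int = 0):
        if backend == "deterministic-test":
            self._net = _TestBackendNet(seed)
        elif backend == "pretrained":
            raise RuntimeError(
                "the pretrained VGG backend requires downloadable ImageNet weights, "
                "which are not available in this offline build; use "
                "backend='deterministic-test'"
            )
        else:
            raise ValueError(f"unknown backend {backend!r}")
        self.backend = backend

    def extract(self, x, layers) -> dict:
        """Feature taps for an image.

        ``x`` may be a ``(3, H, W)`` float64 numpy array or a Tensor (to
        keep the optimization graph alive).
        """
        wanted = set(layers)
        unknown = wanted - set(self.LAYER_NAMES)
        if unknown:
            raise KeyError(f"unknown feature taps: {sorted(unknown)}")
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        return self._net.taps(x, wanted)


def gram_matrix(features: Tensor | np.ndarray) -> Tensor:
    """Normalized Gram matrix ``F F^T / (C*H*W)`` of a CxHxW feature map."""
    if not isinstance(features, Tensor):
        features = Tensor(np.asarray(features, dtype=np.float64))
    c, h, w = features.data.shape
    f = reshape(features, (c, h * w))
    g = matmul(f, transpose(f, (1, 0)))
    return mul(g, Tensor(np.asarray(1.0 / (c * h * w), dtype=features.data.dtype)))


def content_loss(x_features: dict, content_features: dict) -> Tensor:
    """Sum over content taps of the feature-map MSE."""
    keys = sorted(content_features)
    if sorted(x_features.keys() & content_features.keys()) != keys:
        raise KeyError("content feature taps do not match")
    total = None
    for k in keys:
        term = mse(x_features[k], content_features[k])
        total = term if total is None else total + term
    return total


def style_loss(x_features: dict, style_features: dict) -> Tensor:
    """Sum over style taps of the Gram-matrix MSE."""
    keys = sorted(style_features)
    if sorted(x_features.keys() & style_features.keys()) != keys:
        raise KeyError("style feature taps do not match")
    total = None
    for k in keys:
        term = mse(gram_matrix(x_features[k]), gram_matrix(style_features[k]))
        total = term if total is None else total + term
    return total


def run_style_transfer(
    content: np.ndarray,
    style: np.ndarray,
    cfg: StyleTransferConfig | None = None,
    extractor: FeatureExtractor | None = None,
    seed: int = 0,
    return_history: bool = False,
):
    """Optimize a third image against content and style targets.

    ``content`` and ``style`` are model-domain ``(H, W, 3)`` arrays; the
    style image is resized to the content's size if needed. Returns the
    optimized image (and the per-iteration loss history on request).
    """
    cfg = cfg or StyleTransferConfig()
    extractor = extractor or FeatureExtractor(cfg.backend, cfg.backend_seed)
    content = np.asarray(content, dtype=np.float64)
    style = np.asarray(style, dtype=np.float64)
    if style.shape[:2] != content.shape[:2]:
        style = resize_hwc(style, content.shape[:2]).astype(np.float64)

    c_chw = np.ascontiguousarray(content.transpose(2, 0, 1))
    s_chw = np.ascontiguousarray(style.transpose(2, 0, 1))

    with no_grad():
        c_feats = {
            k: Tensor(v.data) for k, v in extractor.extract(c_chw, cfg.content_layers).items()
        }
        s_feats = {
            k: Tensor(v.data) for k, v in extractor.extract(s_chw, cfg.style_layers).items()
        }

    wanted = tuple(sorted(set(cfg.content_layers) | set(cfg.style_layers)))
    cw = cfg.content_weight
    sw = cfg.style_weight
    shape = c_chw.shape
    history: list[float] = []

    def objective(flat: np.ndarray):
        x = Tensor(flat.reshape(shape).copy(), requires_grad=True)
        feats = extractor.extract(x, wanted)
        loss = None
        if cw > 0:
            loss = mul(Tensor(np.float64(cw)), content_loss({k: feats[k] for k in cfg.content_layers}, c_feats))
        if sw > 0:
            sterm = mul(Tensor(np.float64(sw)), style_loss({k: feats[k] for k in cfg.style_layers}, s_feats))
            loss = sterm if loss is None else loss + sterm
        (gx,) = grad(loss, [x])
        val = float(loss.data)
        if not np.isfinite(val):
            raise FloatingPointError("non-finite style-transfer loss")
        return val, gx.data.ravel()

    if cfg.init_mode == "content":
        x0 = c_chw.ravel().copy()
    else:
        x0 = np.random.default_rng(seed).uniform(-1, 1, size=c_chw.size)

    callback = None
    if return_history:
        history.append(objective(x0)[0])
        callback = lambda xk: history.append(objective(xk)[0])

    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(-1.0, 1.0)] * x0.size,
        options={"maxiter": cfg.steps, "maxcor": 20, "ftol": 0.0, "gtol": 0.0},
        callback=callback,
    )
    out = np.clip(res.x.reshape(shape), -1.0, 1.0).transpose(1, 2, 0).astype(np.float32)
    if return_history:
        return out, history
    return out


def transfer_sample(
    generated: FourChannelSample,
    real: FourChannelSample,
    cfg: StyleTransferConfig | None = None,
    extractor: FeatureExtractor | None = None,
) -> FourChannelSample:
    """Refine a generated sample's RGB channels; the mask passes through.

    The generated RGB is the content, the real RGB the style. The mask
    channel is copied bit-identically (style transfer never touches it).
    """
    refined = run_style_transfer(generated.rgb, real.rgb, cfg=cfg, extractor=extractor)
    grid = np.dstack([refined, generated.mask_channel.copy()])
    return FourChannelSample(grid, provenance=f"{generated.provenance}#st")
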