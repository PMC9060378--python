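"""Neural-network building blocks on top of the autodiff engine.

Layout convention: activations are channels-first ``(C, H, W)`` single
samples (the single-image setting never batches).
"""

from __future__ import annotations

import numpy as np

from ._autodiff import (
    Tensor,
    add,
    as_tensor,
    broadcast_to,
    clip_,
    div,
    im2col,
    leaky_relu,
    matmul,
    mean_,
    mul,
    pad2d,
    reshape,
    sqrt_,
    sub,
    tanh_,
)


class Module:
    """Minimal parameter container with ordered, named state."""

    def _children(self):
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield name, v
            elif isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield f"{name}.{i}", m

    def parameters(self) -> list:
        ps = []
        for _, v in self._children():
            if isinstance(v, Tensor):
                ps.append(v)
            else:
                ps.extend(v.parameters())
        return ps

    def state_dict(self, prefix: str = "") -> dict:
        sd = {}
        for name, v in self._children():
            key = prefix + name
            if isinstance(v, Tensor):
                sd[key] = v.data.copy()
            else:
                sd.update(v.state_dict(key + "."))
        return sd

    def load_state_dict(self, sd: dict, prefix: str = "") -> None:
        for name, v in self._children():
            key = prefix + name
            if isinstance(v, Tensor):
                if key not in sd:
                    raise KeyError(f"missing parameter {key!r} in state dict")
                arr = np.asarray(sd[key])
                if arr.shape != v.data.shape:
                    raise ValueError(
                        f"shape mismatch for {key!r}: {arr.shape} vs {v.data.shape}"
                    )
                v.data = arr.astype(v.data.dtype).copy()
            else:
                v.load_state_dict(sd, key + ".")


class Conv2d(Module):
    """Valid (unpadded) 2-D convolution, stride 1, via im2col + matmul."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 w_std: float = 0.02, dtype=np.float32):
        self.cin, self.cout, self.k = cin, cout, k
        self.weight = Tensor(
            rng.normal(0.0, w_std, (cout, cin, k, k)).astype(dtype), requires_grad=True
        )
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        _, H, W = x.data.shape
        cols = im2col(x, self.k)
        w2 = reshape(self.weight, (self.cout, self.cin * self.k * self.k))
        out = reshape(matmul(w2, cols), (self.cout, H - self.k + 1, W - self.k + 1))
        return add(out, reshape(self.bias, (self.cout, 1, 1)))


class ChannelNorm(Module):
    """Per-channel normalization over spatial positions (batch-of-one norm)."""

    def __init__(self, c: int, rng: np.random.Generator, dtype=np.float32, eps: float = 1e-5):
        self.gamma = Tensor(
            (1.0 + rng.normal(0.0, 0.02, (c, 1, 1))).astype(dtype), requires_grad=True
        )
        self.beta = Tensor(np.zeros((c, 1, 1), dtype=dtype), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = mean_(x, axis=(1, 2), keepdims=True)
        xc = sub(x, mu)
        var = mean_(mul(xc, xc), axis=(1, 2), keepdims=True)
        xn = div(xc, sqrt_(add(var, as_tensor(self.eps, like=x))))
        return add(mul(xn, self.gamma), self.beta)


class ConvBlock(Module):
    """conv -> (norm) -> leaky ReLU."""

    def __init__(self, cin, cout, k, rng, norm: bool = True, slope: float = 0.2,
                 dtype=np.float32):
        self.conv = Conv2d(cin, cout, k, rng, dtype=dtype)
        self.norm = ChannelNorm(cout, rng, dtype=dtype) if norm else None
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        x = self.conv(x)
        if self.norm is not None:
            x = self.norm(x)
        return leaky_relu(x, self.slope)


class Generator(Module):
    """Residual single-scale generator.

    The input (noise + upsampled prior) is zero-padded once by the total
    receptive-field margin, pushed through ``n_blocks`` valid convolutions
    and a tanh head, and the result is added back onto the prior:

        out = clip(prior + tanh(net(pad(noise + prior))), -1, 1)

    With a zero tail the forward pass is the identity on its prior.
    """

    def __init__(self, channels: int, width: int, n_blocks: int, k: int,
                 rng: np.random.Generator):
        if n_blocks < 3:
            raise ValueError("n_blocks must be >= 3")
        self.pad = n_blocks * (k // 2)
        self.head = ConvBlock(channels, width, k, rng, norm=True)
        self.body = [ConvBlock(width, width, k, rng, norm=True) for _ in range(n_blocks - 2)]
        self.tail = Conv2d(width, channels, k, rng)

    def __call__(self, noise: Tensor, prior: Tensor) -> Tensor:
        if noise.data.shape != prior.data.shape:
            raise ValueError(
                f"noise/prior shape mismatch: {noise.data.shape} vs {prior.data.shape}"
            )
        x = pad2d(add(noise, prior), self.pad)
        x = self.head(x)
        for b in self.body:
            x = b(x)
        res = tanh_(self.tail(x))
        return clip_(add(prior, res), -1.0, 1.0)

    def zero_init_tail(self) -> None:
        self.tail.weight.data[:] = 0.0
        self.tail.bias.data[:] = 0.0


class Discriminator(Module):
    """Markovian critic: unpadded convolutions emitting a score map."""

    def __init__(self, channels: int, width: int, n_blocks: int, k: int,
                 rng: np.random.Generator):
        if n_blocks < 3:
            raise ValueError("n_blocks must be >= 3")
        self.head = ConvBlock(channels, width, k, rng, norm=False)
        self.body = [ConvBlock(width, width, k, rng, norm=True) for _ in range(n_blocks - 2)]
        self.tail = Conv2d(width, 1, k, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.head(x)
        for b in self.body:
            x = b(x)
        return self.tail(x)


class Adam:
    """Adam optimizer over a fixed parameter list (in-place updates)."""

    def __init__(self, params, lr: float = 5e-4, betas=(0.5, 0.999), eps: float = 1e-8):
        self._params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self._params]
        self._v = [np.zeros_like(p.data) for p in self._params]

    def step(self, grads) -> None:
        self.t += 1
        bias1 = 1.0 - self.b1 ** self.t
        bias2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self._params, grads, self._m, self._v):
            gd = g.data if isinstance(g, Tensor) else g
            m *= self.b1
            m += (1.0 - self.b1) * gd
            v *= self.b2
            v += (1.0 - self.b2) * gd * gd
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
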