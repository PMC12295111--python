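"""Configurable-depth U-Net on the numpy engine.

Encoder: ``depth`` blocks of (conv-BN-ReLU) x2, each followed by 2x2
average pooling (smoother maps than max pooling); a bottleneck block; a
mirrored decoder of nearest-neighbour upsampling + channel-halving conv,
skip concatenation and a conv block; a final 1x1 conv with per-pixel
softmax over the classes. All convolutions are zero-padded so the output
map has the input's spatial size. Input sides must be divisible by
``2**depth``.
"""

from __future__ import annotations

import numpy as np

from lvhquant.nn.layers import (
    AvgPool2D,
    BatchNorm2D,
    Conv2D,
    Layer,
    MaxPool2D,
    Param,
    PixelSoftmax,
    ReLU,
    Sequential,
)


class _ConvBlock(Sequential):
    def __init__(self, cin: int, cout: int, rng):
        super().__init__(
            [
                Conv2D(cin, cout, 3, padding="same", rng=rng),
                BatchNorm2D(cout),
                ReLU(),
                Conv2D(cout, cout, 3, padding="same", rng=rng),
                BatchNorm2D(cout),
                ReLU(),
            ]
        )


class _UpConv(Sequential):
    """Nearest-neighbour 2x upsample followed by a channel-halving conv."""

    def __init__(self, cin: int, cout: int, rng):
        from lvhquant.nn.layers import Upsample2D

        super().__init__([Upsample2D(), Conv2D(cin, cout, 3, padding="same", rng=rng)])


class UNet(Layer):
    def __init__(self, depth: int, base_filters: int = 16, in_channels: int = 1,
                 out_classes: int = 2, pooling: str = "average",
                 rng: np.random.Generator | None = None):
        if depth not in (3, 4, 5):
            raise ValueError(f"U-Net depth must be in {{3, 4, 5}}, got {depth}")
        rng = rng or np.random.default_rng()
        self.depth = depth
        pool_cls = AvgPool2D if pooling == "average" else MaxPool2D
        chans = [base_filters * 2 ** i for i in range(depth + 1)]
        self.enc = [_ConvBlock(in_channels if i == 0 else chans[i - 1], chans[i], rng)
                    for i in range(depth)]
        self.pools = [pool_cls() for _ in range(depth)]
        self.bottleneck = _ConvBlock(chans[depth - 1], chans[depth], rng)
        self.ups = [_UpConv(chans[i + 1], chans[i], rng) for i in reversed(range(depth))]
        self.dec = [_ConvBlock(2 * chans[i], chans[i], rng) for i in reversed(range(depth))]
        self.head = Conv2D(chans[0], out_classes, 1, padding=0, rng=rng)
        self.softmax = PixelSoftmax()
        self._modules: list[Layer] = (
            self.enc + self.pools + [self.bottleneck] + self.ups + self.dec
            + [self.head, self.softmax]
        )

    def params(self) -> list[Param]:
        out: list[Param] = []
        for m in self._modules:
            out.extend(m.params())
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def forward(self, x, training=False):
        if x.shape[2] % 2 ** self.depth or x.shape[3] % 2 ** self.depth:
            raise ValueError(
                f"input sides must be divisible by 2**depth={2 ** self.depth}, got {x.shape[2:]}"
            )
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h, training)
            skips.append(h)
            h = pool.forward(h, training)
        h = self.bottleneck.forward(h, training)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, training)
            h = dec.forward(np.concatenate([h, skip], axis=1), training)
        return self.softmax.forward(self.head.forward(h, training), training)

    def backward(self, grad):
        """Backpropagate a gradient w.r.t. the softmax output."""
        grad = self.head.backward(self.softmax.backward(grad))
        # decoder stages are stored deepest-first; undo them shallowest-first
        skip_grads = []  # aligned with skips: shallowest first
        for up, dec in zip(reversed(self.ups), reversed(self.dec)):
            g = dec.backward(grad)
            c_up = up.layers[-1].cout
            g_up, g_skip = g[:, :c_up], g[:, c_up:]
            skip_grads.append(g_skip)
            grad = up.backward(g_up)
        grad = self.bottleneck.backward(grad)
        for pool, blk, g_skip in zip(reversed(self.pools), reversed(self.enc),
                                     reversed(skip_grads)):
            grad = blk.backward(pool.backward(grad) + g_skip)
        return grad

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Hard per-pixel class map for a single 2-D image."""
        x = image[None, None].astype(float)
        probs = self.forward(x, training=False)
        return probs[0].argmax(axis=0)

    def get_state(self):
        state = [p.value.copy() for p in self.params()]
        for m in self._iter_bn():
            state.append(m.running_mean.copy())
            state.append(m.running_var.copy())
        return state

    def set_state(self, state):
        ps = self.params()
        for p, v in zip(ps, state[: len(ps)]):
            p.value = v.copy()
        i = len(ps)
        for m in self._iter_bn():
            m.running_mean = state[i].copy()
            m.running_var = state[i + 1].copy()
            i += 2

    def _iter_bn(self):
        for m in self._modules:
            if isinstance(m, Sequential):
                for l in m.layers:
                    if isinstance(l, BatchNorm2D):
                        yield l
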