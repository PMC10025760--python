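"""Forward-only DenseNet-121 feature extractor in NumPy.

Implements the standard DenseNet-121 topology (growth rate 32, block
configuration 6/12/24/16, bottleneck width 4x growth) up to and including the
global average pool over the final feature map, i.e. the penultimate layer of
the usual classifier.  Weights are randomly initialized (He scaling) from a
seed; batch-norm layers act at their initialization point (unit scale, zero
shift, unit running variance), which is the appropriate state for an untrained
instance.  The extractor is used for architecture parity checks and as a
random-projection backbone; it is not trainable.
"""

from __future__ import annotations

import numpy as np

from .nn import _im2col

GROWTH = 32
BLOCK_CONFIG = (6, 12, 24, 16)
INIT_FEATURES = 64
PENULTIMATE_DIM = 1024


def _conv(x, W, stride=1, pad=0):
    """x: (n,c,h,w); W: (c*k*k, c_out) with k inferred."""
    c = x.shape[1]
    k = int(round(np.sqrt(W.shape[0] / c)))
    cols, oh, ow = _im2col(x, k, stride, pad)
    return (cols @ W).transpose(0, 3, 1, 2)


def _maxpool(x, k, stride, pad):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                   constant_values=-np.inf)
    out_h = (x.shape[2] - k) // stride + 1
    out_w = (x.shape[3] - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    win = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, out_h, out_w, k, k),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    return win.max(axis=(4, 5))


def _avgpool2(x):
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _relu(x):
    return np.maximum(x, 0.0)


def _he(rng, fan_in, c_out):
    return (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(
        np.float32
    )


class DenseNet121Features:
    """Randomly initialized DenseNet-121 backbone (feature extractor only)."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.stem = _he(rng, 1 * 7 * 7, INIT_FEATURES)
        self.blocks: list[list[tuple[np.ndarray, np.ndarray]]] = []
        self.transitions: list[np.ndarray] = []
        ch = INIT_FEATURES
        for i, n_layers in enumerate(BLOCK_CONFIG):
            block = []
            for _ in range(n_layers):
                w1 = _he(rng, ch, 4 * GROWTH)           # 1x1 bottleneck
                w2 = _he(rng, 4 * GROWTH * 9, GROWTH)   # 3x3 conv, pad 1
                block.append((w1, w2))
                ch += GROWTH
            self.blocks.append(block)
            if i < len(BLOCK_CONFIG) - 1:
                self.transitions.append(_he(rng, ch, ch // 2))
                ch //= 2
        self.feature_dim = ch
        assert self.feature_dim == PENULTIMATE_DIM

    def forward(self, images: np.ndarray) -> np.ndarray:
        """images: (n, h, w) or (n, 1, h, w) grayscale, h, w >= 32 -> (n, 1024)."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2] < 32 or x.shape[3] < 32:
            raise ValueError("densenet121 requires images of at least 32x32 pixels")
        x = _relu(_conv(x, self.stem, stride=2, pad=3))
        x = _maxpool(x, 3, 2, 1)
        for i, block in enumerate(self.blocks):
            feats = [x]
            for w1, w2 in block:
                h = np.concatenate(feats, axis=1)
                h = _conv(_relu(h), w1)              # 1x1
                h = _conv(_relu(h), w2, pad=1)       # 3x3
                feats.append(h)
            x = np.concatenate(feats, axis=1)
            if i < len(self.transitions):
                x = _conv(_relu(x), self.transitions[i])
                x = _avgpool2(x)
        x = _relu(x)
        return x.mean(axis=(2, 3)).astype(np.float64)

    def all_params(self) -> list[np.ndarray]:
        out = [self.stem]
        for block in self.blocks:
            for w1, w2 in block:
                out.extend([w1, w2])
        out.extend(self.transitions)
        return out
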