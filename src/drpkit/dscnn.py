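"""Decimal-scaled Inception-style deep feature extractor (numpy).

Each block convolves the input at three receptive fields (1x1, 3x3, 5x5)
in parallel, decimal-scales every pre-activation response map so its
maximum magnitude falls below one, applies ReLU, concatenates the branch
channels, and downsamples with 2x2 average pooling followed by a
learnable linear channel map. A global average pool and a linear layer
produce the penultimate feature vector; a softmax head on top is used
for fold-internal pretraining, after which the penultimate vector serves
as the deep feature block.

Convolution filters are drawn from a seeded He-style initializer; in
``mini_mode`` (56x56 input, two blocks, penultimate width 64) a forward
pass is desk-scale on one CPU. The head is a multinomial logistic
regression fitted on training-fold features only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .featex import ds_scale

KERNEL_SIZES = (1, 3, 5)


@dataclass
class DSCNNConfig:
    block_channels: Sequence[int] = (8, 8)  # per-branch channels per block
    penultimate_width: int = 64
    input_size: int = 56
    mini_mode: bool = True
    seed: int = 0
    learning_rate: float = 0.1
    epochs: int = 200
    batch_size: int = 64

    def __post_init__(self) -> None:
        if self.penultimate_width < 8:
            raise ValueError("penultimate width must be >= 8")
        if not self.mini_mode and self.input_size < 56:
            raise ValueError("full mode expects input size >= 56")


@dataclass
class DSCNNParams:
    config: DSCNNConfig
    conv_weights: list[dict[int, np.ndarray]] = field(default_factory=list)
    channel_maps: list[np.ndarray] = field(default_factory=list)
    proj: Optional[np.ndarray] = None
    head: Optional[object] = None  # fitted softmax head (logistic regression)

    @property
    def trained(self) -> bool:
        return self.head is not None


def init_params(config: DSCNNConfig) -> DSCNNParams:
    """Seeded He-style initialization of all fixed network weights."""
    rng = np.random.default_rng(config.seed)
    params = DSCNNParams(config=config)
    in_ch = 3
    for width in config.block_channels:
        block = {}
        for k in KERNEL_SIZES:
            fan_in = k * k * in_ch
            block[k] = rng.standard_normal((width, in_ch, k, k)) * np.sqrt(
                2.0 / fan_in
            )
        params.conv_weights.append(block)
        out_ch = width * len(KERNEL_SIZES)
        params.channel_maps.append(
            rng.standard_normal((out_ch, out_ch)) * np.sqrt(1.0 / out_ch)
        )
        in_ch = out_ch
    params.proj = rng.standard_normal(
        (in_ch, config.penultimate_width)
    ) * np.sqrt(1.0 / in_ch)
    return params


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padding 2D convolution, (H, W, Cin) x (Cout, Cin, k, k)."""
    k = w.shape[-1]
    pad = k // 2
    xp = np.pad(x, ((pad, pad), (pad, pad), (0, 0)))
    patches = sliding_window_view(xp, (k, k), axis=(0, 1))  # H, W, C, k, k
    return np.einsum("hwckl,ockl->hwo", patches, w, optimize=True)


def _avg_pool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    return x[: h2 * 2, : w2 * 2].reshape(h2, 2, w2, 2, c).mean(axis=(1, 3))


def forward_features(
    tensor: np.ndarray, params: DSCNNParams, instrumentation: Optional[list] = None
) -> np.ndarray:
    """Penultimate feature vector for one fused tensor (H, W, 3).

    ``instrumentation``, if given, collects the max magnitude of every
    decimal-scaled pre-activation map (all must be < 1).
    """
    x = np.asarray(tensor, dtype=float)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) tensor")
    for block, cmap in zip(params.conv_weights, params.channel_maps):
        branches = []
        for k in KERNEL_SIZES:
            z = _conv_same(x, block[k])
            z = ds_scale(z)
            if instrumentation is not None:
                instrumentation.append(float(np.abs(z).max(initial=0.0)))
            branches.append(np.maximum(z, 0.0))
        x = np.concatenate(branches, axis=2)
        x = _avg_pool2(x) @ cmap
    pooled = x.mean(axis=(0, 1))
    feat = ds_scale(pooled @ params.proj)
    if instrumentation is not None:
        instrumentation.append(float(np.abs(feat).max(initial=0.0)))
    return np.maximum(feat, 0.0)


def dscnn_features(
    tensors: Sequence[np.ndarray],
    params: DSCNNParams,
    require_trained: bool = False,
) -> np.ndarray:
    """Deep feature matrix (n_samples x penultimate width)."""
    if require_trained and not params.trained:
        raise ValueError("network head has not been trained")
    return np.array([forward_features(t, params) for t in tensors])


def fit_head(
    params: DSCNNParams, features: np.ndarray, labels: np.ndarray
) -> DSCNNParams:
    """Fit the softmax pretraining head on training-fold features only."""
    from sklearn.linear_model import LogisticRegression

    head = LogisticRegression(max_iter=500, random_state=params.config.seed)
    head.fit(np.asarray(features), np.asarray(labels))
    params.head = head
    return params


def predict_proba(params: DSCNNParams, features: np.ndarray) -> np.ndarray:
    """Softmax class probabilities of the pretraining head (rows sum to 1)."""
    if not params.trained:
        raise ValueError("network head has not been trained")
    return params.head.predict_proba(np.asarray(features))
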