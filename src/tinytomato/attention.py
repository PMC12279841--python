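"""CSAM: split-channel multi-attention for occluded-fruit feature maps.

The block halves the input channels, runs channel attention (shared-MLP
squeeze over global max- and average-pooled descriptors) followed by
non-local spatial attention (embedded-Gaussian affinity over all position
pairs) on one half, merges the untouched half back in by elementwise
summation, and restores the original channel count with a 1×1 projection.

The printed definition of this block merges the channel-attention weights
into the map by *summation* (broadcast add), not the multiplicative gating
of CBAM-style blocks; that literal form is the default here, with
``channel_merge="mul"`` available as the conventional alternative.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import ConfigurationError

__all__ = [
    "split_halves",
    "ChannelAttention",
    "NonLocalSpatialAttention",
    "CSAM",
]


def split_halves(x):
    """Split (N, C, H, W) into two (N, C/2, H, W) maps; concatenation inverts it."""
    data = x.data if isinstance(x, nn.Tensor) else np.asarray(x)
    c = data.shape[1]
    if c % 2:
        raise ConfigurationError(f"channel count must be even to split, got {c}")
    h = c // 2
    return x[:, :h], x[:, h:]


class ChannelAttention(nn.Module):
    """Per-channel attention weights CA = σ(MLP(maxpool) + MLP(avgpool)).

    The two-layer MLP (reduction ratio r) is shared between the pooled
    descriptors.  The weight vector lies strictly in (0, 1) per channel and
    is merged into the map by broadcast addition (default) or multiplication.
    """

    def __init__(self, channels: int, reduction: int = 16, merge: str = "add", rng=None):
        super().__init__()
        if channels % reduction:
            raise ConfigurationError(
                f"reduction ratio {reduction} must divide channel count {channels}"
            )
        if merge not in ("add", "mul"):
            raise ConfigurationError(f"channel_merge must be 'add' or 'mul', got {merge!r}")
        self.merge = merge
        self.fc1 = nn.Conv2d(channels, channels // reduction, k=1, bias=True, rng=rng)
        self.fc2 = nn.Conv2d(channels // reduction, channels, k=1, bias=True, rng=rng)

    def weights(self, x):
        mx = self.fc2(nn.relu(self.fc1(nn.global_max_pool(x))))
        av = self.fc2(nn.relu(self.fc1(nn.global_avg_pool(x))))
        return nn.sigmoid(mx + av)

    def forward(self, x):
        ca = self.weights(x)
        return x + ca if self.merge == "add" else x * ca


class NonLocalSpatialAttention(nn.Module):
    """Embedded-Gaussian non-local block over all spatial position pairs.

    Query/key/value are 1×1 projections θ, ω, g; the affinity
    f(x_i, x_j) = h(x)·softmax_j(θ_iᵀ ω_j) is row-stochastic, and the
    response aggregates g over positions: F_i = (1/C(x)) Σ_j f(x_i,x_j) g(x_j).
    With the softmax form the normalizer C(x) is 1 (already normalized);
    ``normalizer="count"`` divides by the number of positions instead.  The
    modulation h(x) defaults to the constant 1.  The output is returned with
    a residual addition, so the block preserves shape and is
    position-permutation equivariant (it has no positional encoding).
    """

    def __init__(self, channels: int, normalizer: str = "softmax", rng=None):
        super().__init__()
        if normalizer not in ("softmax", "count"):
            raise ConfigurationError(f"normalizer must be 'softmax' or 'count', got {normalizer!r}")
        self.normalizer = normalizer
        self.wq = nn.Conv2d(channels, channels, k=1, bias=False, rng=rng)
        self.wk = nn.Conv2d(channels, channels, k=1, bias=False, rng=rng)
        self.wv = nn.Conv2d(channels, channels, k=1, bias=False, rng=rng)

    def affinity(self, x):
        """Row-stochastic (N, HW, HW) attention matrix."""
        shape = x.data.shape if isinstance(x, nn.Tensor) else x.shape
        n, c, h, w = shape
        theta = self.wq(x).reshape(n, c, h * w)
        omega = self.wk(x).reshape(n, c, h * w)
        logits = theta.swapaxes(1, 2) @ omega
        return nn.softmax(logits, axis=-1)

    def response(self, x):
        shape = x.data.shape if isinstance(x, nn.Tensor) else x.shape
        n, c, h, w = shape
        aff = self.affinity(x)
        g = self.wv(x).reshape(n, c, h * w)
        out = aff @ g.swapaxes(1, 2)                 # (N, HW, C)
        if self.normalizer == "count":
            out = out * (1.0 / (h * w))
        return out.swapaxes(1, 2).reshape(n, c, h, w)

    def forward(self, x):
        return self.response(x) + x


class CSAM(nn.Module):
    """Full pipeline: split → channel attention → spatial attention → merge.

    F_out = restore(F_b ⊕ F_a2), where F_a2 is the attended first half and
    F_b the untouched second half; ⊕ is elementwise summation and `restore`
    is the 1×1 projection mapping C/2 back to C channels.  With
    ``zero_init_restore=True`` and the residual bypass (default on), the
    block is the identity at initialization, so it can be inserted into a
    trained host without changing its function.
    """

    def __init__(self, channels: int, reduction: int | None = None,
                 channel_merge: str = "add", normalizer: str = "softmax",
                 residual: bool = True, zero_init_restore: bool = False, rng=None):
        super().__init__()
        if channels % 2:
            raise ConfigurationError(f"CSAM needs an even channel count, got {channels}")
        half = channels // 2
        if reduction is None:
            reduction = 16 if half % 16 == 0 else max(d for d in (8, 4, 2, 1) if half % d == 0)
        self.channel_att = ChannelAttention(half, reduction=reduction, merge=channel_merge, rng=rng)
        self.spatial_att = NonLocalSpatialAttention(half, normalizer=normalizer, rng=rng)
        self.restore = nn.Conv2d(half, channels, k=1, bias=True, rng=rng)
        if zero_init_restore:
            self.restore.weight.data[...] = 0.0
            self.restore.bias.data[...] = 0.0
        self.residual = residual

    def forward(self, x):
        fa, fb = split_halves(x)
        fa1 = self.channel_att(fa)
        fa2 = self.spatial_att(fa1)
        out = self.restore(fb + fa2)
        return out + x if self.residual else out


def make_attention(kind: str, channels: int, rng=None, **kwargs):
    """Pluggable attention factory for neck stages.

    Only ``csam`` (and ``none``) are implemented; other published blocks
    (se, cbam, gam, scse) are reserved interface names.
    """
    if kind in ("none", None):
        return None
    if kind == "csam":
        return CSAM(channels, rng=rng, **kwargs)
    if kind in ("se", "cbam", "gam", "scse"):
        raise NotImplementedError(f"attention kind {kind!r} is an interface stub")
    raise ConfigurationError(f"unknown attention kind {kind!r}")
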