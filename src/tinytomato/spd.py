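"""Space-to-depth (SPD) rearrangement and the SPD + non-strided-conv block.

Space-to-depth replaces strided downsampling: the ``scale²`` phase-shifted
sub-grids of the input are sampled losslessly and stacked along channels, so
spatial resolution drops by ``scale`` while every activation value is kept.
A stride-1 convolution then mixes the rearranged channels down to the target
count.  Because no value is discarded before the convolution, fine detail
from few-pixel objects survives the downsampling step.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import ConfigurationError

__all__ = ["space_to_depth", "depth_to_space", "SPDConv"]


def _phase_order(scale: int):
    # row-major over offsets: (0,0), (0,1), ..., (1,0), (1,1), ...
    return [(i, j) for i in range(scale) for j in range(scale)]


def space_to_depth(x, scale: int):
    """Rearrange (N, C, H, W) → (N, scale²·C, H/scale, W/scale).

    Pure permutation of values: sub-map ``p = i·scale + j`` holds the samples
    at row offset ``i``, column offset ``j``; sub-maps are concatenated along
    channels in row-major phase order.  Works on arrays and autodiff tensors.
    """
    if scale < 1:
        raise ConfigurationError(f"scale must be >= 1, got {scale}")
    if scale == 1:
        return x
    is_tensor = isinstance(x, nn.Tensor)
    data = x.data if is_tensor else np.asarray(x)
    n, c, h, w = data.shape
    if h % scale or w % scale:
        raise ConfigurationError(f"spatial size ({h}, {w}) not divisible by scale {scale}")
    if not is_tensor:
        parts = [data[:, :, i::scale, j::scale] for i, j in _phase_order(scale)]
        return np.concatenate(parts, axis=1)
    parts = [x[:, :, i::scale, j::scale] for i, j in _phase_order(scale)]
    return nn.concatenate(parts, axis=1)


def depth_to_space(y, scale: int):
    """Exact inverse of :func:`space_to_depth`."""
    if scale == 1:
        return y
    y = np.asarray(y.data if isinstance(y, nn.Tensor) else y)
    n, c2, ho, wo = y.shape
    if c2 % (scale * scale):
        raise ConfigurationError(f"channel count {c2} not divisible by scale² = {scale * scale}")
    c = c2 // (scale * scale)
    out = np.empty((n, c, ho * scale, wo * scale), dtype=y.dtype)
    for p, (i, j) in enumerate(_phase_order(scale)):
        out[:, :, i::scale, j::scale] = y[:, p * c:(p + 1) * c]
    return out


class SPDConv(nn.Module):
    """Downsampling block: space-to-depth followed by a stride-1 convolution.

    The convolution must have ``out_channels < scale²·in_channels`` — the
    block compresses the rearranged channels, it never strides over pixels.
    ``strict=False`` relaxes the compression check for the image stem, where
    a wide first stage can exceed scale²·3 RGB channels.
    """

    def __init__(self, in_channels: int, out_channels: int, scale: int = 2,
                 kernel_size: int = 3, strict: bool = True, rng=None):
        super().__init__()
        expanded = scale * scale * in_channels
        if strict and scale > 1 and out_channels >= expanded:
            raise ConfigurationError(
                f"out_channels ({out_channels}) must be < scale²·in_channels ({expanded})"
            )
        self.scale = scale
        self.conv = nn.ConvBNAct(expanded, out_channels, k=kernel_size, stride=1, rng=rng)

    def forward(self, x):
        return self.conv(space_to_depth(x, self.scale))
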