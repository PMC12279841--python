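"""Lightweight backbone blocks: Ghost / RepGhost modules and bottlenecks,
the C2f stage container with pluggable bottleneck kinds, and the DASPPF
pooling block.

Ghost modules generate half of their output channels with a dense 1×1
convolution ("intrinsic" maps) and the other half with a cheap depthwise
operation ("ghost" maps), cutting parameters roughly in half versus a dense
convolution.  RepGhost modules instead use structural reparameterization: a
training-time graph of a depthwise convolution branch plus a
normalization-only shortcut, merged by addition, which folds algebraically
into a single depthwise convolution for deployment (:meth:`RepGhostModule.fuse`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, FusionStateError

__all__ = [
    "BlockSpec",
    "DasppfSpec",
    "GhostModule",
    "RepGhostModule",
    "GhostBottleneck",
    "RepGhostBottleneck",
    "StandardBottleneck",
    "C2f",
    "DASPPF",
    "fuse_model",
    "unfuse_model",
]

BOTTLENECK_KINDS = ("standard", "ghost", "repghost")


@dataclass
class BlockSpec:
    """Serializable description of one C2f stage."""

    in_channels: int
    out_channels: int
    bottleneck_kind: str = "repghost"
    expansion: float = 0.5
    dw_kernel: int = 3
    n_bottlenecks: int = 1

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be >= 1")
        if self.bottleneck_kind not in BOTTLENECK_KINDS:
            raise ConfigurationError(
                f"unknown bottleneck kind {self.bottleneck_kind!r}; choose from {BOTTLENECK_KINDS}"
            )
        if self.n_bottlenecks < 1:
            raise ConfigurationError("n_bottlenecks must be >= 1")


@dataclass
class DasppfSpec:
    """Configuration of the DASPPF block.

    Defaults: reduce to half the input channels, dilated 3×3 branches at
    rates (1, 3, 5), three cascaded 5×5 average pools, and a global-average
    branch broadcast back over the grid.
    """

    reduced_channels: int | None = None
    dilation_rates: tuple = (1, 3, 5)
    pool_kernel: int = 5
    n_pools: int = 3
    include_global_pool: bool = True

    def __post_init__(self):
        rates = tuple(self.dilation_rates)
        if len(rates) == 0 or any(r < 1 for r in rates):
            raise ConfigurationError("dilation rates must be >= 1")
        if list(rates) != sorted(set(rates)):
            raise ConfigurationError("dilation rates must be strictly increasing")
        self.dilation_rates = rates


class GhostModule(nn.Module):
    """Dense 1×1 primary convolution + cheap depthwise ghost maps, concatenated."""

    def __init__(self, in_channels: int, out_channels: int, ratio: int = 2,
                 dw_kernel: int = 3, act: bool = True, rng=None):
        super().__init__()
        if out_channels % ratio:
            raise ConfigurationError(
                f"out_channels ({out_channels}) must be divisible by expansion ratio ({ratio})"
            )
        self.intrinsic_channels = out_channels // ratio
        self.primary = nn.ConvBNAct(in_channels, self.intrinsic_channels, k=1, act=act, rng=rng)
        self.cheap = nn.ModuleList([
            _DWBNAct(self.intrinsic_channels, dw_kernel, act=act, rng=rng)
            for _ in range(ratio - 1)
        ])

    def forward(self, x):
        intrinsic = self.primary(x)
        ghosts = [op(intrinsic) for op in self.cheap]
        return nn.concatenate([intrinsic, *ghosts], axis=1)


class _DWBNAct(nn.Module):
    def __init__(self, c, k=3, dilation=1, act=True, rng=None):
        super().__init__()
        self.dw = nn.DepthwiseConv2d(c, k=k, dilation=dilation, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c)
        self.act = act

    def forward(self, x):
        y = self.bn(self.dw(x))
        return nn.silu(y) if self.act else y


class RepGhostModule(nn.Module):
    """Reparameterized cheap-feature module.

    Train mode: primary 1×1 convolution, then two parallel branches on the
    intrinsic maps — depthwise 3×3 + BN, and a normalization-only shortcut —
    merged by addition and activated.  Deploy mode (after :meth:`fuse`):
    the two branches collapse into one depthwise convolution with bias.
    """

    def __init__(self, in_channels: int, out_channels: int, dw_kernel: int = 3,
                 act: bool = True, rng=None):
        super().__init__()
        self.dw_kernel = dw_kernel
        self.act = act
        self.primary = nn.ConvBNAct(in_channels, out_channels, k=1, act=act, rng=rng)
        self.dw = nn.DepthwiseConv2d(out_channels, k=dw_kernel, bias=False, rng=rng)
        self.dw_bn = nn.BatchNorm2d(out_channels)
        self.shortcut_bn = nn.BatchNorm2d(out_channels)
        self.deployed = False
        self.fused_weight: np.ndarray | None = None
        self.fused_bias: np.ndarray | None = None

    def forward(self, x):
        y = self.primary(x)
        if self.deployed:
            if self.fused_weight is None:
                raise FusionStateError("deploy-mode forward requested before fuse()")
            out = nn.depthwise_conv2d(y, nn.Tensor(self.fused_weight), nn.Tensor(self.fused_bias),
                                      padding=self.dw_kernel // 2)
        else:
            out = self.dw_bn(self.dw(y)) + self.shortcut_bn(y)
        return nn.silu(out) if self.act else out

    def fuse(self):
        """Fold the depthwise+BN branch and the BN shortcut into one kernel."""
        if self.training:
            raise FusionStateError("normalization statistics must be frozen (eval mode) before fusing")
        k = self.dw_kernel
        c = self.dw.weight.data.shape[0]

        def bn_scale_shift(bn):
            s = bn.gamma.data / np.sqrt(bn.running_var + bn.eps)
            return s, bn.beta.data - s * bn.running_mean

        s1, b1 = bn_scale_shift(self.dw_bn)
        kernel = self.dw.weight.data * s1[:, None, None]
        bias = b1.copy()
        s2, b2 = bn_scale_shift(self.shortcut_bn)
        kernel[:, k // 2, k // 2] += s2
        bias += b2
        self.fused_weight = kernel.astype(np.float32)
        self.fused_bias = bias.astype(np.float32)
        self.deployed = True
        return self.fused_weight, self.fused_bias

    def unfuse(self):
        self.deployed = False


class StandardBottleneck(nn.Module):
    def __init__(self, c: int, rng=None):
        super().__init__()
        self.cv1 = nn.ConvBNAct(c, c, k=3, rng=rng)
        self.cv2 = nn.ConvBNAct(c, c, k=3, rng=rng)

    def forward(self, x):
        return x + self.cv2(self.cv1(x))


class GhostBottleneck(nn.Module):
    def __init__(self, c: int, dw_kernel: int = 3, rng=None):
        super().__init__()
        self.g1 = GhostModule(c, c, dw_kernel=dw_kernel, act=True, rng=rng)
        self.g2 = GhostModule(c, c, dw_kernel=dw_kernel, act=False, rng=rng)

    def forward(self, x):
        return x + self.g2(self.g1(x))


class RepGhostBottleneck(nn.Module):
    """Residual bottleneck of two RepGhost modules with reduced mid channels."""

    def __init__(self, c: int, mid_ratio: float = 0.25, dw_kernel: int = 3, rng=None):
        super().__init__()
        mid = max(2, int(round(c * mid_ratio)))
        self.r1 = RepGhostModule(c, mid, dw_kernel=dw_kernel, act=True, rng=rng)
        self.r2 = RepGhostModule(mid, c, dw_kernel=dw_kernel, act=False, rng=rng)

    def forward(self, x):
        return x + self.r2(self.r1(x))


def _make_bottleneck(kind: str, c: int, dw_kernel: int, rng):
    if kind == "standard":
        return StandardBottleneck(c, rng=rng)
    if kind == "ghost":
        return GhostBottleneck(c, dw_kernel=dw_kernel, rng=rng)
    if kind == "repghost":
        return RepGhostBottleneck(c, dw_kernel=dw_kernel, rng=rng)
    raise ConfigurationError(f"unknown bottleneck kind {kind!r}; choose from {BOTTLENECK_KINDS}")


class C2f(nn.Module):
    """Split–process–concatenate stage container.

    A 1×1 convolution expands to two hidden halves; `n` bottlenecks of the
    configured kind chain on the second half, every intermediate output is
    kept, and a final 1×1 convolution maps the concatenation to
    ``out_channels`` (independent of `n`).
    """

    def __init__(self, in_channels: int, out_channels: int, n: int = 1,
                 kind: str = "repghost", expansion: float = 0.5,
                 dw_kernel: int = 3, rng=None):
        super().__init__()
        if n < 1:
            raise ConfigurationError("n_bottlenecks must be >= 1")
        self.hidden = max(2, int(out_channels * expansion))
        self.cv1 = nn.ConvBNAct(in_channels, 2 * self.hidden, k=1, rng=rng)
        self.bottlenecks = nn.ModuleList([
            _make_bottleneck(kind, self.hidden, dw_kernel, rng) for _ in range(n)
        ])
        self.cv2 = nn.ConvBNAct((2 + n) * self.hidden, out_channels, k=1, rng=rng)

    @classmethod
    def from_spec(cls, spec: BlockSpec, rng=None) -> "C2f":
        return cls(spec.in_channels, spec.out_channels, n=spec.n_bottlenecks,
                   kind=spec.bottleneck_kind, expansion=spec.expansion,
                   dw_kernel=spec.dw_kernel, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        h = self.hidden
        parts = [y[:, :h], y[:, h:]]
        for b in self.bottlenecks:
            parts.append(b(parts[-1]))
        return self.cv2(nn.concatenate(parts, axis=1))


class DASPPF(nn.Module):
    """Dilated atrous spatial pyramid pooling with average-pool fusion.

    Branches over a channel-reduced map: dilated 3×3 convolutions at the
    configured rates, cascaded average pools (pyramid-pooling topology with
    average in place of max), and an optional global-average branch
    broadcast back over the grid; everything is concatenated and fused by a
    1×1 projection.  Average pooling softens the contribution of redundant
    high-activation regions while the dilated branches grow the receptive
    field without losing resolution.  Spatial size is always preserved.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 spec: DasppfSpec | None = None, rng=None):
        super().__init__()
        self.spec = spec or DasppfSpec()
        r = self.spec.reduced_channels or max(2, in_channels // 2)
        self.reduce = nn.ConvBNAct(in_channels, r, k=1, rng=rng)
        self.dilated = nn.ModuleList([
            nn.ConvBNAct(r, r, k=3, dilation=d, rng=rng) for d in self.spec.dilation_rates
        ])
        n_branches = 1 + len(self.spec.dilation_rates) + self.spec.n_pools + int(self.spec.include_global_pool)
        self.fuse = nn.ConvBNAct(n_branches * r, out_channels, k=1, rng=rng)

    def forward(self, x):
        base = self.reduce(x)
        branches = [base] + [conv(base) for conv in self.dilated]
        pooled = base
        for _ in range(self.spec.n_pools):
            pooled = nn.avg_pool2d(pooled, self.spec.pool_kernel)
            branches.append(pooled)
        if self.spec.include_global_pool:
            g = nn.global_avg_pool(base)
            shape = base.data.shape if isinstance(base, nn.Tensor) else base.shape
            branches.append(g + np.zeros(shape, dtype=np.float32))
        return self.fuse(nn.concatenate(branches, axis=1))


def fuse_model(module: nn.Module):
    """Fuse every RepGhost module below `module` into deploy parameterization."""
    for m in module.modules():
        if isinstance(m, RepGhostModule):
            m.fuse()
    return module


def unfuse_model(module: nn.Module):
    for m in module.modules():
        if isinstance(m, RepGhostModule):
            m.unfuse()
    return module
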