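"""Configurable small-object detector assembly.

The backbone downsamples exclusively through space-to-depth + stride-1
convolution blocks (never by strided convolution), runs a C2f stage of the
configured bottleneck kind at each level, and ends in a DASPPF pooling
block.  A top-down neck fuses levels, CSAM attention sits at configurable
neck junctions, and one anchor-free head per stride — including the
stride-4 head that sees few-pixel fruit — predicts per-cell class scores
and direct box offsets.  Box regression is deliberately direct (center
offsets + log-size), so the Gaussian-Wasserstein loss acts on boxes exactly
as defined, not on a discretized distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .attention import CSAM
from .blocks import C2f, DASPPF, DasppfSpec
from .boxes import BoundingBox, iou
from .data import Detection
from .errors import ConfigurationError
from .spd import SPDConv

__all__ = ["ModelSpec", "DetectionModel", "build_model", "decode_and_nms",
           "count_parameters", "nms", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelSpec:
    """Structural description of the detector.

    ``width`` scales ``base_channels``; head strides must be ascending
    powers of two and divide the input size.  The default toy scale
    (160 px, width 0.25) runs forward and backward comfortably on one CPU.
    """

    input_size: int = 160
    num_classes: int = 3
    width: float = 0.25
    base_channels: tuple = (32, 64, 128, 256, 256)
    bottleneck: str = "repghost"
    n_bottlenecks: int = 1
    strides: tuple = (4, 8, 16, 32)
    attention: str = "csam"
    attention_strides: tuple = (16, 32)
    spd_kernel: int = 3
    channel_merge: str = "add"

    def __post_init__(self):
        s = tuple(self.strides)
        if any(b & (b - 1) for b in s) or list(s) != sorted(s) or len(set(s)) != len(s):
            raise ConfigurationError("strides must be ascending distinct powers of 2")
        if self.input_size % max(s):
            raise ConfigurationError(
                f"input size {self.input_size} must be divisible by max stride {max(s)}")
        self.strides = s

    def channels(self) -> list[int]:
        return [max(4, 2 * round(c * self.width / 2)) for c in self.base_channels]


class _Head(nn.Module):
    def __init__(self, c: int, num_classes: int, rng=None):
        super().__init__()
        self.stem = nn.ConvBNAct(c, c, k=3, rng=rng)
        self.out = nn.Conv2d(c, num_classes + 4, k=1, bias=True, rng=rng)
        # start class logits at a low prior so early BCE is stable
        self.out.bias.data[:num_classes] = -4.0

    def forward(self, x):
        return self.out(self.stem(x))


class DetectionModel(nn.Module):
    """Backbone + neck + per-stride heads, built from a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        c = spec.channels()
        kind, n, k = spec.bottleneck, spec.n_bottlenecks, spec.spd_kernel

        self.stem = SPDConv(3, c[0], scale=2, kernel_size=k, strict=False, rng=rng)  # stride 2
        self.down2 = SPDConv(c[0], c[1], scale=2, kernel_size=k, rng=rng)      # stride 4
        self.stage2 = C2f(c[1], c[1], n=n, kind=kind, rng=rng)
        self.down3 = SPDConv(c[1], c[2], scale=2, kernel_size=k, rng=rng)      # stride 8
        self.stage3 = C2f(c[2], c[2], n=n, kind=kind, rng=rng)
        self.down4 = SPDConv(c[2], c[3], scale=2, kernel_size=k, rng=rng)      # stride 16
        self.stage4 = C2f(c[3], c[3], n=n, kind=kind, rng=rng)
        self.down5 = SPDConv(c[3], c[4], scale=2, kernel_size=k, rng=rng)      # stride 32
        self.stage5 = C2f(c[4], c[4], n=n, kind=kind, rng=rng)
        self.sppf = DASPPF(c[4], c[4], DasppfSpec(), rng=rng)

        self.fuse4 = C2f(c[4] + c[3], c[3], n=n, kind=kind, rng=rng)
        self.fuse3 = C2f(c[3] + c[2], c[2], n=n, kind=kind, rng=rng)
        self.fuse2 = C2f(c[2] + c[1], c[1], n=n, kind=kind, rng=rng)

        level_c = {4: c[1], 8: c[2], 16: c[3], 32: c[4]}
        self.attn = {}
        attn_list = []
        if spec.attention == "csam":
            for s in spec.attention_strides:
                m = CSAM(level_c[s], channel_merge=spec.channel_merge,
                         residual=True, zero_init_restore=True, rng=rng)
                self.attn[s] = m
                attn_list.append(m)
        self._attn_modules = nn.ModuleList(attn_list)
        self.heads = nn.ModuleList([_Head(level_c[s], spec.num_classes, rng=rng)
                                    for s in spec.strides])

    def forward(self, x) -> dict:
        """Input (N, 3, H, W) → dict stride → raw grid (N, nc+4, H/s, W/s)."""
        x = nn.as_tensor(x)
        p2 = self.stage2(self.down2(self.stem(x)))
        p3 = self.stage3(self.down3(p2))
        p4 = self.stage4(self.down4(p3))
        p5 = self.sppf(self.stage5(self.down5(p4)))

        t4 = self.fuse4(nn.concatenate([nn.upsample_nearest(p5, 2), p4], axis=1))
        t3 = self.fuse3(nn.concatenate([nn.upsample_nearest(t4, 2), p3], axis=1))
        feats = {8: t3, 16: t4, 32: p5}
        if 4 in self.spec.strides:
            feats[4] = self.fuse2(nn.concatenate([nn.upsample_nearest(t3, 2), p2], axis=1))
        for s, m in self.attn.items():
            if s in feats:
                feats[s] = m(feats[s])
        return {s: head(feats[s]) for s, head in zip(self.spec.strides, self.heads)}

    def predict(self, images: np.ndarray, conf_threshold: float = 0.25,
                nms_iou: float = 0.7) -> list[list[Detection]]:
        """Run eval-mode inference on (N, H, W, 3) uint8 images."""
        was_training = self.training
        self.eval()
        x = np.ascontiguousarray(images.astype(np.float32).transpose(0, 3, 1, 2) / 255.0)
        with nn.no_grad():
            grids = self.forward(x)
        if was_training:
            self.train()
        raw = {s: g.data for s, g in grids.items()}
        return [decode_and_nms({s: g[i:i + 1] for s, g in raw.items()},
                               self.spec, conf_threshold, nms_iou)
                for i in range(images.shape[0])]


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> DetectionModel:
    return DetectionModel(spec or ModelSpec(), seed=seed)


def count_parameters(model: nn.Module) -> int:
    """Number of weights the model's forward actually uses.

    In deploy mode a fused RepGhost module carries one depthwise kernel and
    bias in place of its train-time branch parameters (depthwise kernel plus
    two normalization layers), so fusing strictly reduces the count.
    """
    from .blocks import RepGhostModule

    excluded: set[int] = set()
    fused = 0
    for m in model.modules():
        if isinstance(m, RepGhostModule) and m.deployed:
            for branch in (m.dw, m.dw_bn, m.shortcut_bn):
                excluded.update(id(p) for _, p in branch.named_parameters())
            fused += m.fused_weight.size + m.fused_bias.size
    total = sum(p.size for _, p in model.named_parameters() if id(p) not in excluded)
    return int(total + fused)


def decode_grid(grid: np.ndarray, stride: int, num_classes: int, input_size: int):
    """Raw grid (1, nc+4, H, W) → (boxes (M,4) cxcywh px, scores (M, nc))."""
    _, ch, h, w = grid.shape
    g = grid[0]
    cls = 1.0 / (1.0 + np.exp(-g[:num_classes]))
    tx, ty, tw, th = g[num_classes], g[num_classes + 1], g[num_classes + 2], g[num_classes + 3]
    gx, gy = np.meshgrid(np.arange(w), np.arange(h))
    xc = (gx + 1.0 / (1.0 + np.exp(-tx))) * stride
    yc = (gy + 1.0 / (1.0 + np.exp(-ty))) * stride
    bw = np.exp(np.clip(tw, -6, 6)) * stride
    bh = np.exp(np.clip(th, -6, 6)) * stride
    boxes = np.stack([xc, yc, bw, bh], axis=-1).reshape(-1, 4)
    # clip to image bounds in corner space, keeping extents positive
    x1 = np.clip(boxes[:, 0] - boxes[:, 2] / 2, 0, input_size)
    y1 = np.clip(boxes[:, 1] - boxes[:, 3] / 2, 0, input_size)
    x2 = np.clip(boxes[:, 0] + boxes[:, 2] / 2, 0, input_size)
    y2 = np.clip(boxes[:, 1] + boxes[:, 3] / 2, 0, input_size)
    boxes = np.stack([(x1 + x2) / 2, (y1 + y2) / 2,
                      np.maximum(x2 - x1, 1e-3), np.maximum(y2 - y1, 1e-3)], axis=-1)
    return boxes, cls.reshape(num_classes, -1).T


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(int(i))
        rest = order[~suppressed[order] & (order != i)]
        if rest.size:
            ious = iou(np.tile(boxes[i], (rest.size, 1)), boxes[rest])
            suppressed[rest[ious > iou_threshold]] = True
    return keep


def decode_and_nms(grids: dict, spec: ModelSpec, conf_threshold: float = 0.25,
                   nms_iou: float = 0.7) -> list[Detection]:
    """Decode one image's raw grids, threshold, and apply class-wise NMS.

    Returned detections are sorted by confidence; no surviving same-class
    pair overlaps above `nms_iou`.
    """
    if not (0 <= conf_threshold <= 1 and 0 <= nms_iou <= 1):
        raise ConfigurationError("thresholds must lie in [0, 1]")
    all_boxes, all_scores, all_cls = [], [], []
    for s, grid in grids.items():
        g = grid.data if isinstance(grid, nn.Tensor) else grid
        boxes, scores = decode_grid(g, s, spec.num_classes, spec.input_size)
        conf = scores.max(axis=1)
        cls = scores.argmax(axis=1)
        m = conf >= conf_threshold
        all_boxes.append(boxes[m])
        all_scores.append(conf[m])
        all_cls.append(cls[m])
    boxes = np.concatenate(all_boxes) if all_boxes else np.zeros((0, 4))
    scores = np.concatenate(all_scores) if all_scores else np.zeros(0)
    cls = np.concatenate(all_cls) if all_cls else np.zeros(0, dtype=int)
    dets: list[Detection] = []
    for c in np.unique(cls):
        idx = np.flatnonzero(cls == c)
        for j in nms(boxes[idx], scores[idx], nms_iou):
            k = idx[j]
            dets.append(Detection(int(c), BoundingBox(*boxes[k]), float(min(scores[k], 1.0))))
    dets.sort(key=lambda d: -d.confidence)
    return dets


# --------------------------------------------------------------------------- #
# checkpoints: flat name → array mapping plus a copy of the spec
# --------------------------------------------------------------------------- #

def save_checkpoint(path, model: DetectionModel):
    state = model.state_dict()
    spec_json = json.dumps({**asdict(model.spec),
                            "strides": list(model.spec.strides),
                            "base_channels": list(model.spec.base_channels),
                            "attention_strides": list(model.spec.attention_strides)})
    np.savez(path, __spec__=np.frombuffer(spec_json.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> DetectionModel:
    with np.load(path) as z:
        spec_dict = json.loads(bytes(z["__spec__"]).decode())
        for key in ("strides", "base_channels", "attention_strides"):
            spec_dict[key] = tuple(spec_dict[key])
        model = DetectionModel(ModelSpec(**spec_dict))
        model.load_state_dict({k: z[k] for k in z.files if k != "__spec__"})
    return model
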