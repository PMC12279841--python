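"""Seeded synthetic occluded-tomato scenes with YOLO-txt / VOC-XML labels.

The generator emulates the structure of a greenhouse cherry-tomato dataset:
640×640 RGB images, three ripeness classes (green / red / yellow fruit)
with strong class imbalance, fruit instances down to a few pixels across,
and four occlusion difficulty categories — extreme tiny fruit, mutual
shading between classes, branch/stalk shading, and leaf shading.  Fruits
are rendered as radially shaded ellipses in class-specific hue bands;
leaf blobs and branch strokes are drawn *after* the fruit, so occlusion
tags and visible-area fractions are recomputable from the stored geometry.

Everything is deterministic given the config seed.  Also provided: the
six-operation augmentation suite applied as a random combination of three
(exposure, rotation, blur, brightness, mirror, noise), CopyPaste instance
transplanting for class rebalancing, and a 3:1:1-style dataset writer.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

from .boxes import BoundingBox
from .data import CLASS_NAMES, Annotation

logger = logging.getLogger(__name__)

__all__ = [
    "SceneConfig",
    "generate_scene",
    "augment",
    "copy_paste",
    "make_dataset",
    "write_yolo_labels",
    "read_yolo_labels",
    "write_voc_xml",
    "read_voc_xml",
    "tiny_rich_config",
]

# mean fruit colors per class (RGB); shading modulates them radially
_CLASS_COLORS = {
    0: np.array([110, 160, 70], dtype=float),    # green fruit
    1: np.array([205, 60, 45], dtype=float),     # red fruit
    2: np.array([230, 190, 60], dtype=float),    # yellow fruit
}
_LEAF_COLOR = np.array([45, 95, 40], dtype=float)
_BRANCH_COLOR = np.array([95, 70, 40], dtype=float)


@dataclass
class SceneConfig:
    """Recipe for one synthetic scene.

    Per-class instance count ranges default to the strong imbalance of a
    real greenhouse crop (green ≫ red > yellow).  ``tiny_fraction`` of the
    fruit are forced below ``tiny_threshold`` px box side.
    """

    image_size: int = 640
    count_ranges: dict = field(default_factory=lambda: {
        "gtomato": (6, 14), "rtomato": (1, 4), "ytomato": (0, 3),
    })
    radius_range: tuple = (3.0, 26.0)
    tiny_fraction: float = 0.3
    tiny_threshold: float = 8.0
    leaf_count_range: tuple = (4, 10)
    branch_count_range: tuple = (1, 4)
    overlap_prob: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.radius_range[0] >= self.radius_range[1]:
            raise ValueError("radius range must satisfy min < max")
        for name, (lo, hi) in self.count_ranges.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"bad count range for {name}: ({lo}, {hi})")
        if not (0.0 <= self.tiny_fraction <= 1.0 and 0.0 <= self.overlap_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")


def tiny_rich_config(image_size: int = 160, seed: int = 0) -> SceneConfig:
    """A scene recipe dominated by tiny (≤ 8 px) instances, for small-object studies."""
    return SceneConfig(
        image_size=image_size,
        count_ranges={"gtomato": (3, 6), "rtomato": (1, 3), "ytomato": (0, 2)},
        radius_range=(2.0, 8.0),
        tiny_fraction=0.6,
        leaf_count_range=(1, 3),
        branch_count_range=(0, 2),
        overlap_prob=0.15,
        seed=seed,
    )


# --------------------------------------------------------------------------- #
# rendering
# --------------------------------------------------------------------------- #

def _background(rng: np.random.Generator, s: int) -> np.ndarray:
    coarse = rng.uniform(0.0, 1.0, size=(max(s // 32, 2), max(s // 32, 2), 3))
    zoom = s / coarse.shape[0]
    tex = ndimage.zoom(coarse, (zoom, zoom, 1), order=1)[:s, :s]
    base = np.array([60, 75, 50], dtype=float)
    img = base + 40.0 * (tex - 0.5) + rng.normal(0, 4, size=(s, s, 3))
    return np.clip(img, 0, 255)


def _ellipse_mask(s: int, xc: float, yc: float, rx: float, ry: float) -> np.ndarray:
    x0, x1 = max(int(xc - rx) - 1, 0), min(int(xc + rx) + 2, s)
    y0, y1 = max(int(yc - ry) - 1, 0), min(int(yc + ry) + 2, s)
    mask = np.zeros((s, s), dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return mask
    ys, xs = np.mgrid[y0:y1, x0:x1]
    # pixel centers at integer + 0.5 in corner-origin continuous coordinates
    d2 = ((xs + 0.5 - xc) / rx) ** 2 + ((ys + 0.5 - yc) / ry) ** 2
    mask[y0:y1, x0:x1] = d2 <= 1.0
    return mask


def _draw_ellipse(img: np.ndarray, mask: np.ndarray, xc: float, yc: float,
                  rx: float, ry: float, color: np.ndarray, rng: np.random.Generator):
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return
    d2 = ((xs + 0.5 - xc) / rx) ** 2 + ((ys + 0.5 - yc) / ry) ** 2
    shade = 0.55 + 0.45 * np.sqrt(np.clip(1.0 - d2, 0.0, 1.0))
    jitter = rng.normal(0, 6, size=3)
    img[ys, xs] = np.clip(shade[:, None] * (color + jitter)[None, :], 0, 255)


def _branch_mask(rng: np.random.Generator, s: int) -> np.ndarray:
    x0, y0 = rng.uniform(0, s, size=2)
    ang = rng.uniform(0, 2 * np.pi)
    length = rng.uniform(0.4 * s, 1.2 * s)
    width = rng.uniform(1.0, max(2.0, s / 80.0))
    x1, y1 = x0 + length * np.cos(ang), y0 + length * np.sin(ang)
    ys, xs = np.mgrid[0:s, 0:s]
    px, py = xs + 0.5 - x0, ys + 0.5 - y0
    dx, dy = x1 - x0, y1 - y0
    t = np.clip((px * dx + py * dy) / (dx * dx + dy * dy), 0.0, 1.0)
    dist2 = (px - t * dx) ** 2 + (py - t * dy) ** 2
    return dist2 <= width ** 2


def generate_scene(cfg: SceneConfig) -> tuple[np.ndarray, list[Annotation]]:
    """Render one scene.  Returns (uint8 H×W×3 image, annotations).

    Deterministic: the same config (including seed) yields a byte-identical
    image and identical labels.
    """
    rng = np.random.default_rng(cfg.seed)
    s = cfg.image_size
    img = _background(rng, s)

    fruits = []  # (class_id, xc, yc, rx, ry, mask)
    for class_id, name in enumerate(CLASS_NAMES):
        lo, hi = cfg.count_ranges.get(name, (0, 0))
        n = int(rng.integers(lo, hi + 1))
        for _ in range(n):
            tiny = rng.uniform() < cfg.tiny_fraction
            if tiny:
                rx = rng.uniform(max(cfg.radius_range[0], 1.5),
                                 min(cfg.tiny_threshold / 2.0, cfg.radius_range[1]))
            else:
                rx = rng.uniform(*cfg.radius_range)
            ry = rx * rng.uniform(0.9, 1.1)
            placed = False
            for _attempt in range(20):
                near_other = fruits and rng.uniform() < cfg.overlap_prob
                if near_other:
                    ox, oy, orx = fruits[int(rng.integers(len(fruits)))][1:4]
                    xc = np.clip(ox + rng.uniform(-1.2, 1.2) * (orx + rx), rx + 1, s - rx - 1)
                    yc = np.clip(oy + rng.uniform(-1.2, 1.2) * (orx + rx), ry + 1, s - ry - 1)
                else:
                    xc = rng.uniform(rx + 1, s - rx - 1)
                    yc = rng.uniform(ry + 1, s - ry - 1)
                crowd = any((xc - f[1]) ** 2 + (yc - f[2]) ** 2 < (0.6 * (rx + f[3])) ** 2
                            for f in fruits) and not near_other
                if not crowd:
                    placed = True
                    break
            if not placed:
                logger.debug("dropped a %s instance after bounded retries", name)
                continue
            mask = _ellipse_mask(s, xc, yc, rx, ry)
            _draw_ellipse(img, mask, xc, yc, rx, ry, _CLASS_COLORS[class_id], rng)
            fruits.append((class_id, float(xc), float(yc), float(rx), float(ry), mask))

    # occluders drawn after fruits
    leaf_masks, branch_masks = [], []
    for _ in range(int(rng.integers(cfg.branch_count_range[0], cfg.branch_count_range[1] + 1))):
        m = _branch_mask(rng, s)
        img[m] = np.clip(_BRANCH_COLOR + rng.normal(0, 5, size=3), 0, 255)
        branch_masks.append(m)
    for _ in range(int(rng.integers(cfg.leaf_count_range[0], cfg.leaf_count_range[1] + 1))):
        rx = rng.uniform(0.03 * s, 0.10 * s)
        ry = rx * rng.uniform(0.5, 1.6)
        xc, yc = rng.uniform(0, s, size=2)
        m = _ellipse_mask(s, xc, yc, rx, ry)
        _draw_ellipse(img, m, xc, yc, rx, ry, _LEAF_COLOR, rng)
        leaf_masks.append(m)

    occluded = np.zeros((s, s), dtype=bool)
    for m in leaf_masks + branch_masks:
        occluded |= m
    # later-drawn fruit also occludes earlier fruit
    annotations = []
    for i, (class_id, xc, yc, rx, ry, mask) in enumerate(fruits):
        area = int(mask.sum())
        if area == 0:
            continue
        cover_by_fruit = np.zeros((s, s), dtype=bool)
        for j in range(i + 1, len(fruits)):
            cover_by_fruit |= fruits[j][5]
        visible = mask & ~occluded & ~cover_by_fruit
        vis_frac = visible.sum() / area
        if vis_frac <= 0.05:
            logger.debug("dropping a fully occluded instance")
            continue
        w, h = 2.0 * rx, 2.0 * ry
        tag = classify_occlusion(
            box_side=max(w, h),
            tiny_threshold=cfg.tiny_threshold,
            class_overlap=int((mask & cover_by_fruit).sum()),
            stalk_overlap=int(sum((mask & m).sum() for m in branch_masks)),
            leaf_overlap=int(sum((mask & m).sum() for m in leaf_masks)),
        )
        annotations.append(Annotation(
            class_id=class_id,
            box=BoundingBox(xc, yc, w, h),
            occlusion=tag,
            visible_fraction=float(min(vis_frac, 1.0)),
        ))
    return img.astype(np.uint8), annotations


def classify_occlusion(box_side: float, tiny_threshold: float,
                       class_overlap: int, stalk_overlap: int, leaf_overlap: int) -> str:
    """Difficulty tag: tiny when the box side is at or below the threshold,
    otherwise the occluder kind with the largest pixel overlap (leaf wins ties)."""
    if box_side <= tiny_threshold:
        return "tiny"
    overlaps = {"leaf_shading": leaf_overlap, "stalk_shading": stalk_overlap,
                "class_shading": class_overlap}
    best = max(overlaps, key=lambda k: overlaps[k])
    return best if overlaps[best] > 0 else "none"


# --------------------------------------------------------------------------- #
# augmentation (six operations, a random combination of three per image)
# --------------------------------------------------------------------------- #

AUGMENT_OPS = ("exposure", "rotation", "blur", "brightness", "mirror", "noise")


def _rotate90_box(box: BoundingBox, s: int, k: int) -> BoundingBox:
    """Clockwise right-angle rotation in corner-origin continuous coordinates:
    one step maps (x, y) → (s − y, x) and swaps width/height."""
    xc, yc, w, h = box.xc, box.yc, box.w, box.h
    for _ in range(k % 4):
        xc, yc, w, h = s - yc, xc, h, w
    return BoundingBox(xc, yc, w, h)


def apply_op(name: str, image: np.ndarray, anns: list[Annotation],
             rng: np.random.Generator) -> tuple[np.ndarray, list[Annotation]]:
    img = image.astype(float)
    s = image.shape[0]
    if name == "exposure":
        gamma = rng.uniform(0.7, 1.4)
        img = 255.0 * (img / 255.0) ** gamma
    elif name == "brightness":
        img = img * rng.uniform(0.7, 1.3)
    elif name == "blur":
        sigma = rng.uniform(0.5, 1.5)
        img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
    elif name == "noise":
        img = img + rng.normal(0, rng.uniform(2, 8), size=img.shape)
    elif name == "mirror":
        img = img[:, ::-1]
        anns = [Annotation(a.class_id, BoundingBox(s - a.box.xc, a.box.yc, a.box.w, a.box.h),
                           a.occlusion, a.visible_fraction) for a in anns]
    elif name == "rotation":
        k = int(rng.integers(1, 4))
        img = np.rot90(img, k=-k, axes=(0, 1))
        new = []
        for a in anns:
            b = _rotate90_box(a.box, s, k)
            if not (0 <= b.xc <= s and 0 <= b.yc <= s):
                logger.debug("annotation left the frame after rotation; dropped")
                continue
            new.append(Annotation(a.class_id, b, a.occlusion, a.visible_fraction))
        anns = new
    else:
        raise ValueError(f"unknown augmentation op {name!r}")
    return np.clip(img, 0, 255).astype(np.uint8), anns


def augment(image: np.ndarray, anns: list[Annotation],
            rng: np.random.Generator, n_ops: int = 3):
    """Apply a random combination of `n_ops` of the six operations, in random order."""
    chosen = rng.choice(len(AUGMENT_OPS), size=n_ops, replace=False)
    for idx in chosen:
        image, anns = apply_op(AUGMENT_OPS[idx], image, anns, rng)
    return image, anns


# --------------------------------------------------------------------------- #
# CopyPaste rebalancing
# --------------------------------------------------------------------------- #

def copy_paste(donor: tuple[np.ndarray, list[Annotation]],
               host: tuple[np.ndarray, list[Annotation]],
               classes: tuple[int, ...] = (1, 2),
               rng: np.random.Generator | None = None,
               max_overlap: float = 0.9):
    """Transplant instances of the requested (rare) classes from donor to host.

    Paste locations are drawn so that no more than `max_overlap` of the new
    box is covered by existing host boxes.  Returns the augmented host image
    and its extended annotation list.
    """
    rng = rng or np.random.default_rng()
    donor_img, donor_anns = donor
    host_img, host_anns = host
    host_img = host_img.copy()
    host_anns = list(host_anns)
    s = host_img.shape[0]
    sources = [a for a in donor_anns if a.class_id in classes]
    if not sources:
        logger.info("copy_paste: donor holds no instance of classes %s; no-op", classes)
        return host_img, host_anns

    def covered_fraction(box: BoundingBox) -> float:
        x1, y1, x2, y2 = box.corners
        cover = np.zeros((max(int(np.ceil(y2 - y1)), 1), max(int(np.ceil(x2 - x1)), 1)), dtype=bool)
        for a in host_anns:
            bx1, by1, bx2, by2 = a.box.corners
            ix1, iy1 = max(x1, bx1), max(y1, by1)
            ix2, iy2 = min(x2, bx2), min(y2, by2)
            if ix2 > ix1 and iy2 > iy1:
                cover[int(iy1 - y1):int(np.ceil(iy2 - y1)), int(ix1 - x1):int(np.ceil(ix2 - x1))] = True
        return cover.mean()

    for a in sources:
        bx1, by1, bx2, by2 = a.box.corners
        px0, py0 = int(np.floor(bx1)), int(np.floor(by1))
        px1, py1 = int(np.ceil(bx2)), int(np.ceil(by2))
        px0, py0 = max(px0, 0), max(py0, 0)
        px1, py1 = min(px1, donor_img.shape[1]), min(py1, donor_img.shape[0])
        patch = donor_img[py0:py1, px0:px1]
        ph, pw = patch.shape[:2]
        if ph < 1 or pw < 1 or ph >= s or pw >= s:
            continue
        ys, xs = np.mgrid[0:ph, 0:pw]
        pmask = (((xs + 0.5 - pw / 2) / (pw / 2)) ** 2 + ((ys + 0.5 - ph / 2) / (ph / 2)) ** 2) <= 1.0
        for _attempt in range(20):
            nx0 = int(rng.integers(0, s - pw))
            ny0 = int(rng.integers(0, s - ph))
            new_box = BoundingBox(nx0 + pw / 2.0, ny0 + ph / 2.0, float(a.box.w), float(a.box.h))
            if covered_fraction(new_box) <= max_overlap:
                region = host_img[ny0:ny0 + ph, nx0:nx0 + pw]
                region[pmask] = patch[pmask]
                host_anns.append(Annotation(a.class_id, new_box, a.occlusion, a.visible_fraction))
                break
    return host_img, host_anns


# --------------------------------------------------------------------------- #
# label serialization
# --------------------------------------------------------------------------- #

def write_yolo_labels(path, anns: list[Annotation], image_size: int):
    """Write `class cx cy w h` lines, coordinates normalized to [0,1], 6 decimals."""
    lines = []
    for a in anns:
        b = a.box
        lines.append(f"{a.class_id} {b.xc / image_size:.6f} {b.yc / image_size:.6f} "
                     f"{b.w / image_size:.6f} {b.h / image_size:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path, image_size: int) -> list[Annotation]:
    anns = []
    text = Path(path).read_text()
    for line in text.strip().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        cid = int(parts[0])
        xc, yc, w, h = (float(v) * image_size for v in parts[1:5])
        anns.append(Annotation(cid, BoundingBox(xc, yc, w, h)))
    return anns


def write_voc_xml(path, anns: list[Annotation], image_size: int, filename: str = "scene.png"):
    """Pascal-VOC XML dialect (corner coordinates in pixels)."""
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = filename
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(image_size)
    ET.SubElement(size, "height").text = str(image_size)
    ET.SubElement(size, "depth").text = "3"
    for a in anns:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = CLASS_NAMES[a.class_id]
        ET.SubElement(obj, "difficult").text = "1" if a.occlusion != "none" else "0"
        bb = ET.SubElement(obj, "bndbox")
        x1, y1, x2, y2 = a.box.corners
        ET.SubElement(bb, "xmin").text = f"{x1:.2f}"
        ET.SubElement(bb, "ymin").text = f"{y1:.2f}"
        ET.SubElement(bb, "xmax").text = f"{x2:.2f}"
        ET.SubElement(bb, "ymax").text = f"{y2:.2f}"
    ET.ElementTree(root).write(path)


def read_voc_xml(path) -> list[Annotation]:
    root = ET.parse(path).getroot()
    anns = []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        cid = CLASS_NAMES.index(name)
        bb = obj.find("bndbox")
        x1, y1 = float(bb.findtext("xmin")), float(bb.findtext("ymin"))
        x2, y2 = float(bb.findtext("xmax")), float(bb.findtext("ymax"))
        anns.append(Annotation(cid, BoundingBox.from_corners(x1, y1, x2, y2)))
    return anns


# --------------------------------------------------------------------------- #
# dataset writer
# --------------------------------------------------------------------------- #

def _image_seed(base_seed: int, index: int) -> int:
    return int((base_seed * 100003 + index * 7919 + 13) % (2 ** 31))


def make_dataset(cfg: SceneConfig, n_images: int, out_dir,
                 split_ratio=(3, 1, 1)) -> dict:
    """Write a train/val/test tree of PNG scenes plus YOLO-txt labels.

    Split sizes follow the given ratio; a YAML manifest records the config,
    per-image seeds, and per-split class counts so the tree can be
    regenerated bit-exactly.
    """
    if any(r <= 0 for r in split_ratio):
        raise ValueError("split ratios must be positive")
    out = Path(out_dir)
    total = sum(split_ratio)
    n_train = round(n_images * split_ratio[0] / total)
    n_val = round(n_images * split_ratio[1] / total)
    n_test = n_images - n_train - n_val
    sizes = {"train": n_train, "val": n_val, "test": n_test}
    manifest = {"seed": cfg.seed, "n_images": n_images, "split_ratio": list(split_ratio),
                "config": {**asdict(cfg), "count_ranges": {k: list(v) for k, v in cfg.count_ranges.items()},
                           "radius_range": list(cfg.radius_range),
                           "leaf_count_range": list(cfg.leaf_count_range),
                           "branch_count_range": list(cfg.branch_count_range)},
                "splits": {}}
    index = 0
    for split, n in sizes.items():
        (out / "images" / split).mkdir(parents=True, exist_ok=True)
        (out / "labels" / split).mkdir(parents=True, exist_ok=True)
        class_counts = {name: 0 for name in CLASS_NAMES}
        images = []
        for _ in range(n):
            seed_i = _image_seed(cfg.seed, index)
            scene_cfg = SceneConfig(**{**asdict(cfg), "seed": seed_i})
            img, anns = generate_scene(scene_cfg)
            stem = f"scene_{index:05d}"
            Image.fromarray(img).save(out / "images" / split / f"{stem}.png")
            write_yolo_labels(out / "labels" / split / f"{stem}.txt", anns, cfg.image_size)
            for a in anns:
                class_counts[CLASS_NAMES[a.class_id]] += 1
            images.append({"stem": stem, "seed": seed_i, "n_instances": len(anns)})
            index += 1
        manifest["splits"][split] = {"n_images": n, "class_counts": class_counts,
                                     "images": images}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest


def load_split(dataset_dir, split: str) -> list[tuple[np.ndarray, list[Annotation]]]:
    """Read back a split written by :func:`make_dataset`."""
    root = Path(dataset_dir)
    out = []
    for img_path in sorted((root / "images" / split).glob("*.png")):
        img = np.asarray(Image.open(img_path))
        label = root / "labels" / split / (img_path.stem + ".txt")
        anns = read_yolo_labels(label, img.shape[0]) if label.exists() else []
        out.append((img, anns))
    return out
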