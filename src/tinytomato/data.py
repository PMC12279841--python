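"""Shared detection/annotation record types.

The three ripeness classes follow greenhouse harvesting practice: unripe
(green), ripe (red), and intermediate (yellow) fruit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import BoundingBox

CLASS_NAMES = ("gtomato", "rtomato", "ytomato")

OCCLUSION_TAGS = ("none", "tiny", "class_shading", "stalk_shading", "leaf_shading")


@dataclass(frozen=True)
class Detection:
    """A predicted object: class id, box, confidence."""

    class_id: int
    box: BoundingBox
    confidence: float

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class Annotation:
    """A ground-truth object: class id, box, occlusion difficulty tag."""

    class_id: int
    box: BoundingBox
    occlusion: str = "none"
    visible_fraction: float = 1.0

    def __post_init__(self):
        if self.occlusion not in OCCLUSION_TAGS:
            raise ValueError(f"unknown occlusion tag {self.occlusion!r}")
        if not (0.0 < self.visible_fraction <= 1.0):
            raise ValueError("visible fraction must lie in (0, 1]")


def boxes_array(items) -> np.ndarray:
    """Stack the boxes of detections/annotations into an (n, 4) cxcywh array."""
    if not items:
        return np.zeros((0, 4))
    return np.stack([it.box.to_array() for it in items])
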