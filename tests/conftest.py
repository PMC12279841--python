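import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_box_pairs(rng):
    """1000 aligned pairs of valid boxes with varied scales and offsets."""
    n = 1000
    a = np.empty((n, 4))
    a[:, :2] = rng.uniform(0, 100, size=(n, 2))
    a[:, 2:] = rng.uniform(0.5, 60, size=(n, 2))
    b = a + rng.normal(0, 5, size=(n, 4))
    b[:, 2:] = np.abs(b[:, 2:]) + 0.5
    return a, b


def rasterized_iou(box_a, box_b, resolution: int = 1):
    """Pixel-set IoU oracle: count unit cells (or subcells) inside each box.

    Boxes are (xc, yc, w, h) in continuous pixel units with corner-aligned
    coordinates; for integer-sided, integer-aligned boxes this count is exact.
    """
    def cells(b):
        xc, yc, w, h = b
        x1, y1, x2, y2 = xc - w / 2, yc - h / 2, xc + w / 2, yc + h / 2
        r = resolution
        xs = np.arange(int(np.floor(x1 * r)), int(np.ceil(x2 * r)))
        ys = np.arange(int(np.floor(y1 * r)), int(np.ceil(y2 * r)))
        # a subcell belongs to the box if its center is inside
        cx = (xs + 0.5) / r
        cy = (ys + 0.5) / r
        inside_x = xs[(cx > x1) & (cx < x2)]
        inside_y = ys[(cy > y1) & (cy < y2)]
        return {(x, y) for x in inside_x for y in inside_y}

    sa, sb = cells(box_a), cells(box_b)
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)
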