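"""Box geometry and loss-family tests, anchored on independent oracles:
rasterized pixel-set IoU counting, term-by-term hand evaluation, the full
matrix Bures–Wasserstein formula, and finite-difference gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import sqrtm

from tinytomato import nn
from tinytomato.boxes import (
    BoundingBox,
    GaussianBox,
    LossConfig,
    box_to_gaussian,
    ciou_loss,
    cxcywh_to_xyxy,
    diou_loss,
    eiou_loss,
    ewdiou_loss,
    giou_loss,
    iou,
    iou_family_loss,
    nwd_similarity,
    sensitivity_curve,
    siou_loss,
    wasserstein2_sq,
    wasserstein2_sq_boxes,
    xyxy_to_cxcywh,
)
from tinytomato.errors import ConfigurationError, InvalidBoxError

from conftest import rasterized_iou

finite_box = st.tuples(
    st.floats(-50, 50), st.floats(-50, 50), st.floats(0.5, 40), st.floats(0.5, 40)
)


class TestBoundingBox:
    def test_corner_round_trip_is_exact(self):
        b = BoundingBox(12.25, -3.5, 7.0, 2.5)
        assert BoundingBox.from_corners(*b.corners) == b

    @pytest.mark.parametrize("w,h", [(0, 4), (4, 0), (-1, 4), (4, -2)])
    def test_non_positive_extent_rejected(self, w, h):
        with pytest.raises(InvalidBoxError):
            BoundingBox(0, 0, w, h)

    def test_array_corner_conversion_round_trip(self, random_box_pairs):
        a, _ = random_box_pairs
        np.testing.assert_allclose(xyxy_to_cxcywh(cxcywh_to_xyxy(a)), a, atol=1e-12)


class TestIoU:
    def test_identity_and_disjoint(self):
        a = np.array([[2.0, 2, 4, 4]])
        assert iou(a, a)[0] == 1.0
        assert iou(a, np.array([[20.0, 20, 4, 4]]))[0] == 0.0

    @pytest.mark.parametrize("side,shift,expected", [
        (4, 1, 12 / 20), (4, 3, 4 / 28), (45, 1, 1980 / 2070), (45, 3, 1890 / 2160),
    ])
    def test_unit_shift_matches_closed_form_and_raster_oracle(self, side, shift, expected):
        a = np.array([[side / 2, side / 2, side, side]])
        b = a.copy()
        b[0, 0] += shift
        val = iou(a, b)[0]
        assert val == pytest.approx(expected, abs=1e-12)
        assert val == pytest.approx(rasterized_iou(a[0], b[0]), abs=1e-12)

    def test_symmetry_on_random_pairs(self, random_box_pairs):
        a, b = random_box_pairs
        np.testing.assert_allclose(iou(a, b), iou(b, a), atol=1e-12)

    def test_agrees_with_raster_oracle_on_integer_boxes(self, rng):
        for _ in range(25):
            a = np.array([*rng.integers(5, 20, 2), *rng.integers(1, 10, 2)], dtype=float)
            b = np.array([*rng.integers(5, 20, 2), *rng.integers(1, 10, 2)], dtype=float)
            # integer-aligned: center must land on integer or half-integer grid
            a[:2] += a[2:] / 2
            b[:2] += b[2:] / 2
            assert iou(a[None], b[None])[0] == pytest.approx(rasterized_iou(a, b), abs=1e-9)

    def test_invalid_box_raises(self):
        with pytest.raises(InvalidBoxError):
            iou(np.array([[0.0, 0, 0, 4]]), np.array([[0.0, 0, 4, 4]]))


class TestLossFamilies:
    @pytest.mark.parametrize("family", ["giou", "diou", "ciou", "siou", "eiou", "ewdiou", "iou"])
    def test_zero_at_identity(self, family, random_box_pairs):
        a, _ = random_box_pairs
        vals = iou_family_loss(a, a, family)
        np.testing.assert_allclose(vals, 0.0, atol=1e-9)

    def test_positive_when_different(self, random_box_pairs):
        a, b = random_box_pairs
        different = np.abs(a - b).sum(axis=1) > 1e-9
        for family in ("giou", "diou", "ciou", "eiou", "ewdiou"):
            vals = np.asarray(iou_family_loss(a, b, family))
            assert np.all(vals[different] > 0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError):
            iou_family_loss(np.zeros((1, 4)) + 1, np.zeros((1, 4)) + 1, "mystery")

    def test_ciou_equals_diou_at_equal_aspect_ratio(self, rng):
        a = np.array([[10.0, 10, 6, 3]])
        b = np.array([[14.0, 8, 12, 6]])  # same w/h ratio
        assert ciou_loss(a, b)[0] == pytest.approx(diou_loss(a, b)[0], abs=1e-12)

    def test_giou_matches_term_by_term_hand_evaluation(self):
        # disjoint 2×2 boxes at (1,1) and (5,1): enclosure 6×2
        a, b = np.array([[1.0, 1, 2, 2]]), np.array([[5.0, 1, 2, 2]])
        union, enclosure = 8.0, 12.0
        expected = 1.0 - 0.0 + (enclosure - union) / enclosure
        assert giou_loss(a, b)[0] == pytest.approx(expected, abs=1e-12)

    def test_eiou_worked_example(self):
        a, b = np.array([[2.0, 2, 4, 4]]), np.array([[3.0, 2, 4, 4]])
        # 1 − 0.6 + 1/(25+16) + 0 + 0
        assert eiou_loss(a, b)[0] == pytest.approx(0.4 + 1 / 41, abs=1e-12)

    def test_eiou_increases_with_width_gap(self):
        base = np.array([[10.0, 10, 8, 8]])
        losses = [eiou_loss(base, np.array([[10.0, 10, 8 + d, 8]]))[0] for d in (1, 2, 4, 8)]
        assert np.all(np.diff(losses) > 0)

    @given(a=finite_box, b=finite_box)
    @settings(max_examples=200, deadline=None)
    def test_siou_and_eiou_nonnegative_and_finite(self, a, b):
        va = eiou_loss(np.array([a]), np.array([b]))[0]
        vb = siou_loss(np.array([a]), np.array([b]))[0]
        assert np.isfinite(va) and va >= -1e-9
        assert np.isfinite(vb) and vb >= -1e-9


class TestGaussianModel:
    def test_worked_example(self):
        g = box_to_gaussian(np.array([[2.0, 2, 4, 4]]))
        np.testing.assert_allclose(g.mu, [[2, 2]])
        np.testing.assert_allclose(g.var, [[4, 4]])

    def test_unit_box_gives_identity_covariance(self):
        g = box_to_gaussian(np.array([[0.0, 0, 2, 2]]))
        np.testing.assert_allclose(g.covariance()[0], np.eye(2))

    def test_inscribed_ellipse_has_unit_mahalanobis_form(self, rng):
        b = np.array([5.0, -3, 7, 2.5])
        g = box_to_gaussian(b[None])
        t = rng.uniform(0, 2 * np.pi, 64)
        pts = np.stack([b[0] + (b[2] / 2) * np.cos(t), b[1] + (b[3] / 2) * np.sin(t)], axis=1)
        diff = pts - g.mu[0]
        maha = np.sum(diff ** 2 / g.var[0], axis=1)
        np.testing.assert_allclose(maha, 1.0, atol=1e-12)

    def test_non_positive_variance_rejected(self):
        with pytest.raises(InvalidBoxError):
            GaussianBox(mu=np.zeros(2), var=np.array([1.0, 0.0]))


class TestWasserstein:
    def test_identity_and_pure_translation(self):
        a = np.array([[3.0, 4, 6, 2]])
        ga = box_to_gaussian(a)
        assert wasserstein2_sq(ga, ga)[0] == 0.0
        b = a.copy()
        b[0, 0] += 1.0
        assert wasserstein2_sq(ga, box_to_gaussian(b))[0] == pytest.approx(1.0, abs=1e-12)

    def test_printed_forms_agree(self, random_box_pairs):
        """The (w,h)-difference form and the 4-vector squared-distance form are
        the same function, to 1e-9 over 1000 random pairs."""
        a, b = random_box_pairs
        form_a = wasserstein2_sq(box_to_gaussian(a), box_to_gaussian(b))
        pa = np.concatenate([a[:, :2], a[:, 2:] / 2], axis=1)
        pb = np.concatenate([b[:, :2], b[:, 2:] / 2], axis=1)
        form_b = np.sum((pa - pb) ** 2, axis=1)
        np.testing.assert_allclose(form_a, form_b, atol=1e-9)
        np.testing.assert_allclose(form_a, wasserstein2_sq_boxes(a, b), atol=1e-9)

    def test_matches_general_bures_trace_formula(self, random_box_pairs):
        """Independent oracle: W₂² = ‖m1−m2‖² + Tr(Σ1+Σ2−2(Σ2^½ Σ1 Σ2^½)^½)
        evaluated with dense matrix square roots."""
        a, b = random_box_pairs
        ga, gb = box_to_gaussian(a), box_to_gaussian(b)
        ours = wasserstein2_sq(ga, gb)
        for i in range(0, 1000, 37):
            s1, s2 = ga.covariance()[i], gb.covariance()[i]
            root = sqrtm(sqrtm(s2) @ s1 @ sqrtm(s2))
            ref = np.sum((ga.mu[i] - gb.mu[i]) ** 2) + np.trace(s1 + s2 - 2 * root)
            assert ours[i] == pytest.approx(float(np.real(ref)), abs=1e-9)

    def test_symmetry(self, random_box_pairs):
        a, b = random_box_pairs
        ga, gb = box_to_gaussian(a), box_to_gaussian(b)
        np.testing.assert_allclose(wasserstein2_sq(ga, gb), wasserstein2_sq(gb, ga), atol=1e-12)


class TestNWD:
    def test_identity_is_one_and_unit_distance_value(self):
        g = box_to_gaussian(np.array([[2.0, 2, 4, 4]]))
        assert nwd_similarity(g, g, M=3.7)[0] == 1.0
        g2 = box_to_gaussian(np.array([[3.0, 2, 4, 4]]))
        assert nwd_similarity(g, g2, M=1.0)[0] == pytest.approx(np.exp(-1), abs=1e-12)

    def test_monotone_in_M(self, random_box_pairs):
        a, b = random_box_pairs
        ga, gb = box_to_gaussian(a), box_to_gaussian(b)
        s1 = nwd_similarity(ga, gb, M=1.0)
        s2 = nwd_similarity(ga, gb, M=2.0)
        different = wasserstein2_sq(ga, gb) > 1e-12
        assert np.all(s2[different] > s1[different])

    def test_invalid_M_rejected(self):
        g = box_to_gaussian(np.array([[0.0, 0, 2, 2]]))
        with pytest.raises(ConfigurationError):
            nwd_similarity(g, g, M=0.0)


class TestLossConfig:
    def test_defaults_are_the_tuned_blend(self):
        cfg = LossConfig()
        assert (cfg.lambda1, cfg.lambda2, cfg.M) == (0.7, 0.3, 1.0)

    @pytest.mark.parametrize("kw", [
        {"lambda1": 0.5, "lambda2": 0.3},
        {"lambda1": 1.2, "lambda2": -0.2},
        {"M": 0.0},
        {"M": -1.0},
        {"family": "nope"},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            LossConfig(**kw)


class TestEWDIoU:
    def test_worked_example(self):
        a, b = np.array([[2.0, 2, 4, 4]]), np.array([[3.0, 2, 4, 4]])
        expected = 0.7 * (0.4 + 1 / 41) + 0.3 * (1 - np.exp(-1))
        assert ewdiou_loss(a, b)[0] == pytest.approx(expected, abs=1e-9)

    def test_reduces_to_eiou_bitwise_when_lambda1_is_one(self, random_box_pairs):
        a, b = random_box_pairs
        cfg = LossConfig(lambda1=1.0, lambda2=0.0)
        assert np.array_equal(np.asarray(ewdiou_loss(a, b, cfg)), np.asarray(eiou_loss(a, b)))

    def test_reduces_to_wasserstein_term_when_lambda1_is_zero(self, random_box_pairs):
        a, b = random_box_pairs
        cfg = LossConfig(lambda1=0.0, lambda2=1.0)
        expected = 1 - np.exp(-wasserstein2_sq_boxes(a, b) / cfg.M)
        np.testing.assert_allclose(ewdiou_loss(a, b, cfg), expected, atol=1e-9)

    def test_sqrt_exponent_variant(self):
        a, b = np.array([[2.0, 2, 4, 4]]), np.array([[3.0, 2, 4, 4]])
        cfg = LossConfig(lambda1=0.0, lambda2=1.0, squared_exponent=False)
        assert ewdiou_loss(a, b, cfg)[0] == pytest.approx(1 - np.exp(-1.0), abs=1e-6)

    def test_wrong_family_rejected(self):
        with pytest.raises(ConfigurationError):
            ewdiou_loss(np.ones((1, 4)), np.ones((1, 4)), LossConfig(family="ciou", lambda1=1, lambda2=0))

    def test_analytic_gradient_matches_finite_differences(self, rng):
        """Differentiability: autodiff gradients agree with central differences
        to 1e-4 at random non-degenerate points."""
        cfg = LossConfig()
        for _ in range(10):
            a = rng.uniform(5, 20, 4)
            b = a + rng.uniform(-2, 2, 4)
            b[2:] = np.abs(b[2:]) + 3
            ta = nn.Tensor(a[None].astype(np.float64), requires_grad=True)
            ewdiou_loss(ta, b[None], cfg).sum().backward()
            grad = ta.grad.ravel()
            eps = 1e-6
            for i in range(4):
                ap, am = a.copy(), a.copy()
                ap[i] += eps
                am[i] -= eps
                num = (ewdiou_loss(ap[None], b[None], cfg)[0]
                       - ewdiou_loss(am[None], b[None], cfg)[0]) / (2 * eps)
                assert grad[i] == pytest.approx(num, abs=1e-4)


class TestSensitivityCurve:
    def test_iou_series_match_raster_oracle(self):
        np.testing.assert_allclose(sensitivity_curve(4, [1, 3], "iou"), [12 / 20, 4 / 28], atol=1e-12)
        np.testing.assert_allclose(sensitivity_curve(45, [1, 3], "iou"),
                                   [1980 / 2070, 1890 / 2160], atol=1e-12)

    def test_zero_shift_is_identity_for_both_metrics(self):
        assert sensitivity_curve(4, [0], "iou")[0] == 1.0
        assert sensitivity_curve(4, [0], "nwd_similarity")[0] == 1.0

    def test_empty_shift_list_gives_empty_series(self):
        assert sensitivity_curve(4, [], "iou").size == 0

    @pytest.mark.parametrize("shift", [1, 3])
    def test_gaussian_term_is_less_size_biased_than_iou(self, shift):
        """For equal pixel shift, the relative degradation (1−NWD)/(1−IoU) is
        smaller for a 4 px box than a 45 px box: the Wasserstein similarity
        treats sizes alike where IoU collapses for the small box."""
        ratios = {}
        for side in (4, 45):
            i = sensitivity_curve(side, [shift], "iou")[0]
            nwd = sensitivity_curve(side, [shift], "nwd_similarity")[0]
            ratios[side] = (1 - nwd) / (1 - i)
        assert ratios[4] < ratios[45]
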