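"""Unit and property tests for the GLCM and the 22 textural features."""

import numpy as np
import pytest

from neolus import (FEATURE_GROUPS, FEATURE_ORDER, DegenerateGLCMError,
                    all_features, compute_glcm, feature_names, feature_vector,
                    group_columns, marginal_statistics)
from neolus.exceptions import ValidationError

from reference_glcm import brute_features, brute_glcm

# 4x4 image, every row [0, 0, 1, 1] after L=2 quantization
STRIPE = np.tile(np.array([0, 0, 128, 128], dtype=np.uint8), (4, 1))


def glcm_from_P(P):
    """Wrap a hand-built probability matrix for the feature functions."""
    from neolus.glcm import GLCM
    P = np.asarray(P, dtype=float)
    return GLCM(P=P, raw_counts=P, levels=P.shape[0], offset=(0, 2))


class TestComputeGLCM:
    def test_horizontal_stripe_pairs(self):
        g = compute_glcm(STRIPE, None, offset=(0, 2), levels=2)
        assert g.raw_counts.sum() == 8
        np.testing.assert_allclose(g.P, [[0, 1], [0, 0]])

    def test_vertical_stripe_pairs(self):
        g = compute_glcm(STRIPE, None, offset=(2, 0), levels=2)
        np.testing.assert_allclose(g.P, [[0.5, 0], [0, 0.5]])

    def test_constant_image_single_entry(self):
        g = compute_glcm(np.full((6, 6), 200, dtype=np.uint8), None, levels=256)
        assert g.P.sum() == pytest.approx(1.0)
        assert g.P[200, 200] == pytest.approx(1.0)

    def test_mask_restricts_pairs(self):
        img = np.arange(16, dtype=np.uint8).reshape(4, 4)
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, :] = True  # only row 0 -> only horizontal pairs survive
        g = compute_glcm(img, mask, offset=(0, 2), levels=16)
        assert g.raw_counts.sum() == 2  # (0,2) and (1,3)
        with pytest.raises(DegenerateGLCMError):
            compute_glcm(img, mask, offset=(2, 0), levels=16)

    def test_offset_larger_than_frame(self):
        with pytest.raises(DegenerateGLCMError):
            compute_glcm(np.zeros((3, 3), dtype=np.uint8), None, offset=(5, 0))

    def test_levels_must_divide_256(self):
        with pytest.raises(ValidationError):
            compute_glcm(STRIPE, None, levels=10)


class TestMarginals:
    def test_diagonal_P(self):
        m = marginal_statistics(glcm_from_P([[0.5, 0], [0, 0.5]]))
        assert m.mu_x == m.mu_y == pytest.approx(0.5)
        assert m.sigma_x == m.sigma_y == pytest.approx(0.5)
        np.testing.assert_allclose(m.sum_dist, [0.5, 0, 0.5])
        np.testing.assert_allclose(m.diff_dist, [1.0, 0])

    def test_off_diagonal_P(self):
        m = marginal_statistics(glcm_from_P([[0, 1], [0, 0]]))
        np.testing.assert_allclose(m.p_x, [1, 0])
        np.testing.assert_allclose(m.p_y, [0, 1])
        assert (m.mu_x, m.mu_y, m.sigma_x) == (0.0, 1.0, 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_distributions_are_normalized(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        m = marginal_statistics(compute_glcm(img, None, levels=8))
        for dist in (m.p_x, m.p_y, m.sum_dist, m.diff_dist):
            assert dist.sum() == pytest.approx(1.0, abs=1e-12)


class TestHandComputedFeatures:
    def test_diagonal_two_level(self):
        f = all_features(glcm_from_P([[0.5, 0], [0, 0.5]]))
        assert f["H"] == pytest.approx(np.log(2))
        assert f["A"] == pytest.approx(0.5)
        assert f["CO2"] == 0 and f["D"] == 0 and f["CO1"] == 0
        assert f["HO"] == pytest.approx(1.0)
        assert f["M"] == pytest.approx(0.5)
        assert f["AC"] == pytest.approx(0.5)
        assert f["C1"] == pytest.approx(1.0) and f["C2"] == pytest.approx(1.0)
        assert f["SA"] == pytest.approx(1.0)
        assert f["SH"] == pytest.approx(np.log(2))
        assert f["DH"] == 0 and f["DV"] == 0

    def test_single_off_diagonal_entry(self):
        f = all_features(glcm_from_P([[0, 1], [0, 0]]))
        assert f["A"] == 1 and f["H"] == 0 and f["M"] == 1
        assert f["CO2"] == 1 and f["D"] == 1 and f["CO1"] == 1
        assert f["HO"] == pytest.approx(0.5)
        assert f["INV"] == pytest.approx(0.5)
        assert f["DH"] == 0

    def test_constant_image_degenerate_conventions(self):
        f = all_features(compute_glcm(np.full((8, 8), 77, dtype=np.uint8), None))
        assert f["H"] == 0 and f["SH"] == 0 and f["DH"] == 0
        assert f["A"] == 1 and f["M"] == 1
        assert f["CO2"] == 0 and f["D"] == 0
        assert f["C1"] == 0 and f["C2"] == 0 and f["IC2"] == 0 and f["MCC"] == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("offset", [(0, 2), (2, 0), (0, 1), (1, 1)])
    def test_matches_brute_force_on_random_images(self, offset):
        rng = np.random.default_rng(42)
        for _ in range(50):
            img = rng.integers(0, 256, (8, 8), dtype=np.uint8)
            P_ref = brute_glcm(img, np.ones((8, 8), dtype=bool), offset, 8)
            g = compute_glcm(img, None, offset=offset, levels=8)
            np.testing.assert_allclose(g.P, P_ref, atol=1e-12)
            ref = brute_features(P_ref)
            ours = all_features(g)
            for name in FEATURE_ORDER:
                assert ours[name] == pytest.approx(ref[name], abs=1e-10), name

    @pytest.mark.parametrize("seed", range(10))
    def test_internal_identities(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (10, 10), dtype=np.uint8)
        f = all_features(compute_glcm(img, None, levels=16))
        assert f["CO1"] == pytest.approx(f["CO2"], abs=1e-10)
        assert f["C1"] == pytest.approx(f["C2"], abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_feature_bounds(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (10, 10), dtype=np.uint8)
        f = all_features(compute_glcm(img, None, levels=8))
        assert 0 <= f["A"] <= 1
        assert f["H"] >= 0
        assert abs(f["C1"]) <= 1 + 1e-12


class TestSymmetry:
    def test_leftright_reflection_transposes_horizontal_glcm(self):
        rng = np.random.default_rng(7)
        img = rng.integers(0, 256, (9, 9), dtype=np.uint8)
        g = compute_glcm(img, None, offset=(0, 2), levels=8)
        g_flip = compute_glcm(img[:, ::-1], None, offset=(0, 2), levels=8)
        np.testing.assert_allclose(g_flip.P, g.P.T, atol=1e-12)
        f, f_flip = all_features(g), all_features(g_flip)
        for name in ("CO2", "D", "HO", "A", "H", "M"):
            assert f_flip[name] == pytest.approx(f[name], abs=1e-10)


class TestFeatureVector:
    def test_length_and_names(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (64, 64), dtype=np.uint8)
        vec = feature_vector(img, None)
        assert vec.shape == (44,)
        assert np.isfinite(vec).all()
        assert len(feature_names()) == 44

    def test_group_sizes_and_columns(self):
        assert tuple(len(FEATURE_GROUPS[g]) for g in (1, 2, 3)) == (10, 7, 5)
        assert len(group_columns("all")) == 44
        assert len(group_columns(2)) == 14
        cols = group_columns(1) + group_columns(2) + group_columns(3)
        assert sorted(cols) == list(range(44))
        with pytest.raises(ValidationError):
            group_columns(5)

    def test_horizontal_stripes_show_vertical_contrast(self):
        # horizontal bands -> gray changes along rows, not along columns
        img = np.tile(np.repeat(np.array([30, 220], dtype=np.uint8), 2), 16)
        img = np.tile(img[:, None], (1, 64)).astype(np.uint8)
        vec = feature_vector(img, None)
        names = feature_names()
        co2_h = vec[names.index("CO2_h")]
        co2_v = vec[names.index("CO2_v")]
        assert co2_v > co2_h
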