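"""Shape descriptors, co-occurrence texture statistics, and feature fusion."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kernelspec import (build_feature_table, chain_perimeter, circularity, glcm,
                        glcm_stats, morphology, texture_features)
from kernelspec.features import (FeatureTable, MORPH_NAMES, TEXTURE_NAMES,
                                 standardize)
from kernelspec.hypercube import Hypercube
from kernelspec.segmentation import KernelRegion, SpectrumMatrix


def _ellipse_region(a=20.0, b=12.0, size=None, angle=0.0):
    size = size or int(2 * max(a, b) + 6)
    yy, xx = np.mgrid[0:size, 0:size] - size / 2.0
    u = xx * np.cos(angle) + yy * np.sin(angle)
    v = -xx * np.sin(angle) + yy * np.cos(angle)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    rr, cc = np.nonzero(mask)
    bbox = (rr.min(), cc.min(), rr.max() + 1, cc.max() + 1)
    return KernelRegion(mask[bbox[0]:bbox[2], bbox[1]:bbox[3]], tuple(int(x) for x in bbox), 0)


class TestMorphology:
    def test_circle_closed_form_circularity_is_one(self):
        for r in (0.5, 1.0, 2.0, 4.0):
            assert circularity(math.pi * r * r, 2 * math.pi * r) == 1.0

    def test_square_closed_form_circularity(self):
        a = 3.0
        assert circularity(a * a, 4 * a) == pytest.approx(math.pi / 4, abs=1e-12)

    def test_rasterized_ellipse_axes_and_solidity(self):
        feats = morphology(_ellipse_region(a=40.0, b=20.0))
        assert feats.aspect_ratio == pytest.approx(2.0, abs=0.05)
        # discrete solidity of this raster (pixelized convex hull) is 0.9721
        assert feats.solidity >= 0.97
        assert feats.area == pytest.approx(math.pi * 40 * 20, rel=0.02)
        assert feats.roundness == pytest.approx(0.5, abs=0.05)   # b/a for an ellipse

    def test_translation_invariance(self):
        reg = _ellipse_region(a=15.0, b=9.0)
        shifted = KernelRegion(reg.mask.copy(),
                               (reg.bbox[0] + 7, reg.bbox[1] + 3,
                                reg.bbox[2] + 7, reg.bbox[3] + 3), 1)
        a, b = morphology(reg), morphology(shifted)
        np.testing.assert_allclose(a.as_array(), b.as_array())

    def test_scaling_laws_for_area_and_perimeter(self):
        """Doubling an ellipse scales area ~4x and perimeter ~2x (within 5%)."""
        small, big = _ellipse_region(a=12.0, b=8.0), _ellipse_region(a=24.0, b=16.0)
        assert big.area / small.area == pytest.approx(4.0, rel=0.05)
        p_small = chain_perimeter(small.mask)
        p_big = chain_perimeter(big.mask)
        assert p_big / p_small == pytest.approx(2.0, rel=0.05)

    def test_chain_perimeter_of_axis_aligned_square(self):
        mask = np.ones((9, 9), bool)
        assert chain_perimeter(mask) == pytest.approx(4 * 8)   # 4*(side-1) steps

    def test_descriptor_ranges_on_kernel_like_shapes(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            reg = _ellipse_region(a=rng.uniform(12, 20), b=rng.uniform(9, 13),
                                  angle=rng.uniform(0, np.pi))
            f = morphology(reg)
            assert 0 < f.circularity <= 1.05
            assert 0 < f.roundness <= 1.05
            assert 0 < f.solidity <= 1.05
            assert f.aspect_ratio >= 1.0

    def test_degenerate_region_rejected(self):
        line = KernelRegion(np.ones((1, 10), bool), (0, 0, 1, 10), 0)
        with pytest.raises(ValueError, match="degenerate"):
            morphology(line)

    def test_five_features(self):
        assert len(MORPH_NAMES) == 5
        assert morphology(_ellipse_region()).as_array().shape == (5,)


HAND_IMAGE = np.array([[0, 0, 1], [0, 1, 1], [1, 1, 1]])


def hand_glcm_0deg():
    """Horizontal pairs of HAND_IMAGE, enumerated by hand: rows give ordered
    (left,right) pairs (0,0),(0,1) / (0,1),(1,1) / (1,1),(1,1); symmetric
    accumulation then yields counts [[2,2],[2,6]] over 12."""
    return np.array([[2.0, 2.0], [2.0, 6.0]]) / 12.0


class TestGlcm:
    def test_hand_enumerated_fixture(self):
        P = glcm(HAND_IMAGE, displacement=1, angle=0, levels=2)
        np.testing.assert_allclose(P, hand_glcm_0deg(), atol=1e-15)

    def test_hand_computed_statistics(self):
        P = hand_glcm_0deg()
        energy, contrast, corr, entropy = glcm_stats(P)
        # independent hand computation from the enumerated matrix
        assert energy == pytest.approx((4 + 4 + 4 + 36) / 144.0, abs=1e-12)
        assert contrast == pytest.approx(4.0 / 12.0, abs=1e-12)
        p = np.array([2, 2, 2, 6]) / 12.0
        assert entropy == pytest.approx(float(-(p * np.log2(p)).sum()), abs=1e-12)
        mu = 8.0 / 12.0
        var = mu - mu**2                      # binary marginal
        cov = 6.0 / 12.0 - mu**2
        assert corr == pytest.approx(cov / var, abs=1e-12)

    def test_constant_image_degenerate_stats(self):
        P = glcm(np.full((4, 4), 3), levels=5)
        assert P[3, 3] == 1.0 and P.sum() == 1.0
        energy, contrast, corr, entropy = glcm_stats(P)
        assert (energy, contrast, corr, entropy) == (1.0, 0.0, 0.0, 0.0)

    def test_checkerboard_alternates(self):
        img = np.indices((6, 6)).sum(axis=0) % 2
        P = glcm(img, angle=0, levels=2)
        assert P[0, 0] == 0.0 and P[1, 1] == 0.0
        assert P[0, 1] + P[1, 0] == pytest.approx(1.0)

    def test_uniform_matrix_closed_forms(self):
        L = 8
        P = np.full((L, L), 1.0 / L**2)
        energy, _, _, entropy = glcm_stats(P)
        assert energy == pytest.approx(1.0 / L**2, abs=1e-12)
        assert entropy == pytest.approx(2 * np.log2(L), abs=1e-12)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            glcm_stats(np.ones((3, 3)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500), angle=st.sampled_from([0, 45, 90, 135]))
    def test_always_normalized_and_symmetric(self, seed, angle):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 8, size=(7, 9))
        mask = rng.random((7, 9)) < 0.8
        mask[3:5, 3:6] = True                    # guarantee valid pairs
        P = glcm(img, mask, displacement=1, angle=angle, levels=8)
        assert abs(P.sum() - 1.0) <= 1e-9
        np.testing.assert_allclose(P, P.T, atol=1e-15)

    def test_agrees_with_skimage_on_full_frame(self):
        """Cross-check against skimage's graycomatrix on maskless input."""
        from skimage.feature import graycomatrix
        rng = np.random.default_rng(0)
        img = rng.integers(0, 16, size=(12, 14)).astype(np.uint8)
        for angle, rad in [(0, 0.0), (90, np.pi / 2)]:
            ref = graycomatrix(img, [1], [rad], levels=16, symmetric=True,
                               normed=True)[:, :, 0, 0]
            np.testing.assert_allclose(glcm(img, angle=angle, levels=16), ref,
                                       atol=1e-12)


def _texture_cube(images, mask):
    """Stack 2-D images into a calibrated cube plus a region over the mask."""
    data = np.stack(images, axis=2).astype(float)
    cube = Hypercube(data, np.linspace(400, 1000, data.shape[2]), calibrated=True)
    rr, cc = np.nonzero(mask)
    bbox = (0, 0, mask.shape[0], mask.shape[1])
    return cube, KernelRegion(mask, bbox, 0)


class TestTextureFeatures:
    def test_identical_bands_have_zero_sd(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, size=(12, 12))
        mask = np.ones((12, 12), bool)
        cube, reg = _texture_cube([img] * 5, mask)
        f = texture_features(cube, reg, band_range=(1, 5))
        assert f.energy_sd == f.contrast_sd == f.correlation_sd == f.entropy_sd == 0.0
        single = texture_features(cube, reg, band_range=(3, 3))
        np.testing.assert_allclose(f.as_array()[:4], single.as_array()[:4])

    def test_two_band_mean_and_sd_arithmetic(self):
        rng = np.random.default_rng(2)
        img1, img2 = rng.uniform(0, 1, size=(2, 10, 10))
        mask = np.ones((10, 10), bool)
        cube, reg = _texture_cube([img1, img2], mask)
        c1 = texture_features(cube, reg, band_range=(1, 1)).contrast_mean
        c2 = texture_features(cube, reg, band_range=(2, 2)).contrast_mean
        both = texture_features(cube, reg, band_range=(1, 2))
        assert both.contrast_mean == pytest.approx((c1 + c2) / 2, abs=1e-12)
        assert both.contrast_sd == pytest.approx(np.std([c1, c2], ddof=1), abs=1e-12)

    def test_eight_features(self):
        rng = np.random.default_rng(3)
        cube, reg = _texture_cube(list(rng.uniform(0, 1, size=(4, 9, 9))),
                                  np.ones((9, 9), bool))
        assert texture_features(cube, reg, band_range=(1, 4)).as_array().shape == (8,)
        assert len(TEXTURE_NAMES) == 8

    def test_fast_path_matches_reference_glcm_on_masked_kernel(self, one_batch):
        cube, truth, _ = one_batch
        reg = truth[0]["region"]
        r0, c0, r1, c1 = reg.bbox
        band = 200                                  # 1-based 201
        crop = cube.data[r0:r1, c0:c1, band]
        vals = crop[reg.mask]
        q = np.clip(((crop - vals.min()) / (vals.max() - vals.min()) * 64).astype(int), 0, 63)
        ref = np.mean([glcm_stats(glcm(q, reg.mask, 1, a, levels=64))
                       for a in (0, 45, 90, 135)], axis=0)
        got = texture_features(cube, reg, band_range=(band + 1, band + 1)).as_array()[:4]
        np.testing.assert_allclose(got, ref, atol=1e-10)

    def test_band_range_validation(self, one_batch):
        cube, truth, _ = one_batch
        with pytest.raises(ValueError, match="band_range"):
            texture_features(cube, truth[0]["region"], band_range=(51, 9999))


class TestFeatureTable:
    def _spectra(self, n=6, bands=10):
        rng = np.random.default_rng(0)
        return SpectrumMatrix(rng.normal(size=(n, bands)), np.linspace(430, 980, bands),
                              labels=np.array(["a", "b"] * (n // 2)))

    def test_morphology_only_has_five_columns(self):
        sm = self._spectra()
        table = build_feature_table(morph=np.ones((6, 5)), include="morphology",
                                    labels=sm.labels)
        assert table.X.shape == (6, 5)
        assert table.groups == ["morphology"]

    def test_selected_plus_image_width(self):
        sm = self._spectra()
        table = build_feature_table(
            spectra=sm, selection=[1, 4, 7], morph=np.ones((6, 5)),
            texture=np.zeros((6, 8)),
            include=("spectral_selected", "morphology", "texture"))
        assert table.X.shape[1] == 3 + 13

    def test_standardization_from_training_rows_only(self):
        sm = self._spectra(n=8)
        table = build_feature_table(spectra=sm, include="spectral_full")
        train = np.arange(5)
        scaled = standardize(table, train)
        np.testing.assert_allclose(scaled.X[train].mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(scaled.X[train].std(axis=0), 1, atol=1e-12)
        assert not np.allclose(scaled.X[5:].std(axis=0), 1)

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="morphology"):
            build_feature_table(include="morphology", labels=np.array(["a"]))

    def test_csv_round_trip(self, tmp_path):
        sm = self._spectra()
        table = build_feature_table(spectra=sm, morph=np.ones((6, 5)),
                                    include=("spectral_full", "morphology"))
        table.to_csv(tmp_path / "t.csv")
        back = FeatureTable.from_csv(tmp_path / "t.csv")
        np.testing.assert_allclose(back.X, table.X)
        assert list(back.labels) == list(table.labels)
        assert back.groups == table.groups
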