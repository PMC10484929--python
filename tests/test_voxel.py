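"""Brain masking, percentile noise sigma, band-pass and voxel classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from scipy.stats import norm

from brainfrac.atlas import Atlas
from brainfrac.types import ImageStack
from brainfrac.voxel import (
    VoxelClassifierParams,
    bandpass,
    brain_mask,
    classify_positive,
    estimate_noise_sigma,
    regional_volume_fraction,
)
from brainfrac import synthetic as syn

PARAMS = VoxelClassifierParams(mask_threshold=50.0)


class TestBrainMask:
    def test_empty_mask_raises(self):
        stack = ImageStack(np.zeros((4, 16, 16)))
        with pytest.raises(ValueError, match="threshold"):
            brain_mask(stack, VoxelClassifierParams(mask_threshold=1.0))

    def test_constant_stack_gives_full_mask(self):
        stack = ImageStack(np.full((4, 16, 16), 100.0))
        mask = brain_mask(stack, PARAMS)
        assert mask.all()

    def test_ellipsoid_volume_close_to_analytic(self):
        # full-size phantom: the sigma-10 mask blur is negligible against the
        # ~50-voxel semi-axes (a smaller ellipsoid would be eroded)
        spec = syn.PhantomSpec3D()
        autofluo, _, _ = syn.generate_brain_volume(spec)
        mask = brain_mask(autofluo, VoxelClassifierParams(mask_threshold=100.0))
        a, b, c = spec.brain_semiaxes_vx
        analytic = 4 / 3 * np.pi * a * b * c
        assert mask.sum() == pytest.approx(analytic, rel=0.05)

    def test_requires_threshold(self):
        with pytest.raises(ValueError, match="mask_threshold"):
            brain_mask(ImageStack(np.ones((2, 4, 4))), VoxelClassifierParams())


class TestNoiseSigma:
    def test_constant_inside_mask_is_zero(self):
        stack = ImageStack(np.full((2, 8, 8), 7.0))
        assert estimate_noise_sigma(stack, np.ones((2, 8, 8), bool), PARAMS) == 0.0

    def test_enumerated_percentiles(self):
        # values 0..100: (P84 - P16)/2 = (84 - 16)/2 = 34 with linear interp
        data = np.arange(101, dtype=float).reshape(1, 1, 101)
        sigma = estimate_noise_sigma(ImageStack(data), np.ones((1, 1, 101), bool), PARAMS)
        assert sigma == 34.0

    def test_gaussian_matches_analytic_quantiles(self):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 5.0, 10**6).reshape(100, 100, 100)
        sigma = estimate_noise_sigma(
            ImageStack(data), np.ones(data.shape, bool), PARAMS
        )
        # z_{0.84} = 0.9945: the percentile band slightly underestimates sigma
        assert sigma == pytest.approx(5 * norm.ppf(0.84), rel=0.03)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            estimate_noise_sigma(ImageStack(np.ones((2, 4, 4))), np.zeros((2, 4, 4), bool), PARAMS)


class TestBandpass:
    def test_constant_maps_to_zero(self):
        out = bandpass(ImageStack(np.full((3, 32, 32), 500.0)), PARAMS)
        assert np.abs(out).max() < 1e-9 * 500.0

    def test_linearity(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0, 10, (2, 32, 32))
        a = 3.7
        out1 = bandpass(ImageStack(a * stack), PARAMS)
        out2 = a * bandpass(ImageStack(stack), PARAMS)
        assert np.allclose(out1, out2, atol=1e-9)

    def test_impulse_response_matches_dense_convolution(self):
        """Oracle: explicit dense convolution of the two Gaussian kernels on
        a 65x65 patch."""
        n = 65
        impulse = np.zeros((1, n, n))
        impulse[0, n // 2, n // 2] = 1.0
        out = bandpass(ImageStack(impulse), PARAMS)

        g1 = np.zeros((n, n))
        g1[n // 2, n // 2] = 1.0
        g1 = ndimage.gaussian_filter(g1, 1.0)
        g6 = np.zeros((n, n))
        g6[n // 2, n // 2] = 1.0
        g6 = ndimage.gaussian_filter(g6, 6.0)
        from scipy.signal import fftconvolve

        expected_peak = (g1 - fftconvolve(g1, g6, mode="same"))[n // 2, n // 2]
        assert out[0, n // 2, n // 2] == pytest.approx(expected_peak, rel=1e-6)


class TestClassify:
    def test_no_positive_on_zeros(self):
        filt = np.zeros((2, 8, 8))
        assert not classify_positive(filt, 1.0, np.ones((2, 8, 8), bool), PARAMS).any()

    def test_monotone_in_k_sigma(self, small_spec):
        spec = small_spec.with_fractions({5: 0.02, 6: 0.01})
        _, antibody, truth = syn.generate_brain_volume(spec)
        filt = bandpass(antibody, PARAMS)
        p2 = classify_positive(filt, 10.0, truth.atlas, VoxelClassifierParams(mask_threshold=1, k_sigma=2))
        p3 = classify_positive(filt, 10.0, truth.atlas, VoxelClassifierParams(mask_threshold=1, k_sigma=3))
        assert (p3 & ~p2).sum() == 0

    def test_bright_blob_centers_detected_and_noise_controlled(self, small_spec):
        """Planted blobs of amplitude 50 sigma are all hit at their centers;
        on a pure-noise volume the positive rate stays near the Gaussian tail
        expectation for the band-passed threshold."""
        from dataclasses import replace

        spec = replace(small_spec, blob_amplitude=500.0, region_fractions=((5, 0.01),))
        _, antibody, truth = syn.generate_brain_volume(spec)
        filt = bandpass(antibody, PARAMS)
        pos = classify_positive(filt, 10.0, truth.atlas, PARAMS)
        # every truth voxel well inside a blob is detected
        core = ndimage.binary_erosion(truth.positive_mask, iterations=1)
        assert pos[core].all()
        # pure noise: false-positive rate after band-pass is far below the
        # raw-threshold tail because filtering shrinks the noise sigma
        rng = np.random.default_rng(8)
        noise = ImageStack(rng.normal(0, 10.0, (16, 64, 64)))
        fp = classify_positive(bandpass(noise, PARAMS), 10.0, np.ones((16, 64, 64), bool), PARAMS)
        assert fp.mean() <= norm.sf(2 * norm.ppf(0.84)) * 1.5


class TestRegionalFraction:
    def _atlas(self):
        labels = np.zeros((2, 8, 8), np.int32)
        labels[:, :4] = 3
        labels[:, 4:] = 4
        regions = pd.DataFrame({"id": [3, 4], "name": ["left", "right"]})
        return Atlas(labels=labels, regions=regions)

    def test_full_region_is_100pct(self):
        atlas = self._atlas()
        positive = atlas.labels == 3
        table = regional_volume_fraction(positive, atlas)
        row = table[table.region_id == 3].iloc[0]
        assert row.volume_fraction_pct == 100.0
        assert table[table.region_id == 4].iloc[0].volume_fraction_pct == 0.0

    def test_no_positive_all_zero(self):
        atlas = self._atlas()
        table = regional_volume_fraction(np.zeros(atlas.labels.shape, bool), atlas)
        assert (table.volume_fraction_pct == 0).all()

    def test_checkerboard_half(self):
        atlas = self._atlas()
        z, y, x = np.indices(atlas.labels.shape)
        positive = ((z + y + x) % 2 == 0) & (atlas.labels == 3)
        table = regional_volume_fraction(positive, atlas)
        size = (atlas.labels == 3).sum()
        assert table[table.region_id == 3].iloc[0].volume_fraction_pct == pytest.approx(
            50.0, abs=100.0 / size
        )

    def test_whole_brain_additivity(self, small_spec):
        spec = small_spec.with_fractions({1: 0.01, 5: 0.02})
        _, _, truth = syn.generate_brain_volume(spec)
        table = regional_volume_fraction(truth.positive_mask, truth.atlas)
        brain_row = table[table.region_id == 0].iloc[0]
        region_rows = table[table.region_id != 0]
        assert brain_row.positive_voxels == region_rows.positive_voxels.sum()
        assert brain_row.total_voxels == region_rows.total_voxels.sum()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            regional_volume_fraction(np.zeros((1, 2, 2), bool), self._atlas())
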