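"""Shearlet transform: tight-frame round trip, shift equivariance, windows."""

import numpy as np
import pytest

from medfuse import build_shear_filter_bank, decompose, reconstruct
from medfuse.lsist import SubbandPyramid


class TestRoundTrip:
    @pytest.mark.parametrize("size", [64, 96, 128])
    @pytest.mark.parametrize("scales,dps", [(2, (4, 8)), (3, (8, 8, 16)), (4, (4, 8, 8, 16))])
    def test_reconstruction_error(self, size, scales, dps):
        x = np.random.default_rng(size + scales).random((size, size))
        err = np.abs(reconstruct(decompose(x, scales, dps)) - x).max()
        assert err < 1e-4

    def test_rectangular_images(self):
        x = np.random.default_rng(0).random((64, 96))
        assert np.abs(reconstruct(decompose(x, 2, (4, 8))) - x).max() < 1e-4

    def test_constant_image_has_no_highpass_energy(self):
        p = decompose(np.full((64, 64), 0.37), 2, (4, 8))
        assert max(np.abs(b).max() for bands in p.high for b in bands) < 1e-8
        assert np.allclose(p.low, 0.37, atol=1e-8)

    def test_low_only_pyramid_reconstructs_constant(self):
        p = decompose(np.full((64, 64), 0.0), 2, (4, 4))
        p.low[:] = 0.7
        assert np.allclose(reconstruct(p), 0.7, atol=1e-8)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x, y = rng.random((64, 64)), rng.random((64, 64))
        px, py = decompose(x, 2, (4, 8)), decompose(y, 2, (4, 8))
        mix = SubbandPyramid(
            low=2 * px.low - 0.5 * py.low,
            high=[
                [2 * bx - 0.5 * by for bx, by in zip(sx, sy)]
                for sx, sy in zip(px.high, py.high)
            ],
            scales=2,
            directions_per_scale=(4, 8),
        )
        assert np.allclose(reconstruct(mix), 2 * x - 0.5 * y, atol=1e-8)


class TestShiftEquivariance:
    def test_circular_shift_commutes(self):
        x = np.random.default_rng(2).random((128, 128))
        p = decompose(x, 3, (8, 8, 16))
        ps = decompose(np.roll(x, (5, -3), axis=(0, 1)), 3, (8, 8, 16))
        for bands, bands_s in zip(p.high + [[p.low]], ps.high + [[ps.low]]):
            for b, bs in zip(bands, bands_s):
                assert np.abs(np.roll(b, (5, -3), axis=(0, 1)) - bs).max() < 1e-6


class TestFilterBank:
    def test_partition_of_unity(self):
        bank = build_shear_filter_bank(64, 96, 3, (8, 8, 16))
        assert bank.partition_deviation() < 1e-6

    def test_two_directions_are_cone_pair(self):
        bank = build_shear_filter_bank(64, 64, 1, (2,))
        w0, w1 = bank.frequency_windows[0]
        # the two half-plane wedges map onto each other under a 90-degree
        # rotation of the spectrum (transposition for symmetric windows)
        assert np.allclose(w1, w0.T, atol=1e-12)

    def test_angular_profile_consistent_across_sizes(self):
        small = build_shear_filter_bank(64, 64, 1, (8,)).frequency_windows[0]
        large = build_shear_filter_bank(128, 128, 1, (8,)).frequency_windows[0]
        # matching normalized frequencies: bin k at 64 <-> bin 2k at 128
        idx = np.arange(64)
        sub = large[:, ::2, ::2][:, idx, :][:, :, idx]
        assert np.abs(small - sub).max() < 1e-3

    def test_directional_selectivity_of_grating(self):
        h = w = 128
        yy, xx = np.mgrid[0:h, 0:w]
        theta = np.deg2rad(30)
        g = 0.5 + 0.4 * np.cos(2 * np.pi * 0.25 * (np.cos(theta) * xx + np.sin(theta) * yy))
        p = decompose(g, 3, (8, 8, 16))
        energies = [float(np.sum(b**2)) for b in p.high[2]]
        assert sum(sorted(energies)[-2:]) / sum(energies) > 0.8


class TestFrameEnergy:
    def test_energy_ratio_is_stable(self):
        ratios = []
        for seed in range(3):
            x = np.random.default_rng(seed).random((96, 96))
            p = decompose(x, 3, (8, 8, 16))
            e = np.sum(p.low**2) + sum(np.sum(b**2) for bands in p.high for b in bands)
            ratios.append(e / np.sum(x**2))
        assert all(0.9 < r < 1.3 for r in ratios)


class TestValidation:
    def test_non_power_of_two_directions(self):
        with pytest.raises(ValueError):
            decompose(np.zeros((64, 64)), 2, (4, 6))

    def test_scale_count_mismatch(self):
        with pytest.raises(ValueError):
            decompose(np.zeros((64, 64)), 3, (4, 8))

    def test_image_too_small_for_scales(self):
        with pytest.raises(ValueError):
            decompose(np.zeros((8, 8)), 4, (2, 2, 2, 2))

    def test_reconstruct_rejects_mismatched_shapes(self):
        p = decompose(np.zeros((64, 64)), 2, (4, 4))
        p.high[0][0] = np.zeros((32, 32))
        with pytest.raises(ValueError):
            reconstruct(p)
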