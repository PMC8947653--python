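"""Siamese clarity network and the decision-map fusion steps."""

import numpy as np
import pytest
from scipy import ndimage

from medfuse import (
    NetworkConfig,
    NetworkWeights,
    consistency_verify,
    feature_detect,
    fuse_hf,
    generate_patch_pairs,
    generate_phantom_pair,
    initial_segment,
    refine_decision,
    train_network,
)


def majority_vote_oracle(b, window=8):
    """Loop majority vote; even windows extend one extra pixel toward lower
    indices; exact ties keep the original value."""
    half_lo = window // 2
    half_hi = window - half_lo - 1
    bp = np.pad(b, (half_lo, half_hi), mode="symmetric")
    out = np.empty_like(b)
    for y in range(b.shape[0]):
        for x in range(b.shape[1]):
            win = bp[y : y + window, x : x + window]
            ones = win.sum()
            if ones > window * window / 2:
                out[y, x] = 1.0
            elif ones < window * window / 2:
                out[y, x] = 0.0
            else:
                out[y, x] = b[y, x]
    return out


class TestTraining:
    def test_deterministic_final_loss(self):
        pairs = generate_patch_pairs(500, 16, (1.0, 3.0), seed=8)
        cfg = NetworkConfig(epochs=1, seed=4)
        w1 = train_network(pairs, cfg)
        w2 = train_network(pairs, cfg)
        assert abs(w1.training_metrics["final_loss"] - w2.training_metrics["final_loss"]) < 1e-6
        assert all(np.array_equal(w1.params[k], w2.params[k]) for k in w1.params)

    def test_untrained_network_is_at_chance(self):
        pairs = generate_patch_pairs(600, 16, (1.0, 3.0), seed=9)
        w = train_network(pairs, NetworkConfig(epochs=0, seed=5))
        assert 0.35 <= w.training_metrics["holdout_accuracy"] <= 0.65

    def test_trained_network_separates_sharp_from_blur(self, quick_weights):
        assert quick_weights.training_metrics["holdout_accuracy"] >= 0.9

    def test_invalid_inputs(self):
        small = generate_patch_pairs(600, 8, (1.0, 2.0), seed=0)
        with pytest.raises(ValueError):
            train_network(small)
        few = generate_patch_pairs(100, 16, (1.0, 2.0), seed=0)
        with pytest.raises(ValueError):
            train_network(few)
        with pytest.raises(ValueError):
            NetworkConfig(conv_filters=(32, 64, 128))

    def test_checkpoint_roundtrip(self, quick_weights, tmp_path):
        path = tmp_path / "weights.npz"
        quick_weights.save(path)
        loaded = NetworkWeights.load(path)
        assert loaded.training_seed == quick_weights.training_seed
        assert loaded.training_metrics == quick_weights.training_metrics
        assert all(np.array_equal(loaded.params[k], quick_weights.params[k]) for k in loaded.params)


@pytest.fixture(scope="module")
def band_pair():
    img, _ = generate_phantom_pair(96, 0.0, 0.0, seed=1)
    band = img - ndimage.gaussian_filter(img, 2.0)
    return band, ndimage.gaussian_filter(band, 2.5)


class TestFeatureDetect:
    def test_sharp_band_scores_high(self, quick_weights, band_pair):
        sharp, blurred = band_pair
        m = feature_detect(quick_weights, sharp, blurred)
        assert m.shape == sharp.shape
        assert m.min() >= 0 and m.max() <= 1
        assert m.mean() > 0.7

    def test_swapped_arguments_score_low(self, quick_weights, band_pair):
        sharp, blurred = band_pair
        assert feature_detect(quick_weights, blurred, sharp).mean() < 0.3

    def test_shape_and_size_validation(self, quick_weights, rng):
        with pytest.raises(ValueError):
            feature_detect(quick_weights, rng.random((32, 32)), rng.random((32, 33)))
        with pytest.raises(ValueError):
            feature_detect(quick_weights, rng.random((8, 8)), rng.random((8, 8)))

    def test_fused_band_keeps_sharp_energy(self, quick_weights, band_pair):
        """Full decision chain on a (sharp, blurred) pair: the fused band's
        energy stays within 5% of the sharp band's energy."""
        sharp, blurred = band_pair
        guide, _ = generate_phantom_pair(96, 0.0, 0.0, seed=1)
        m = feature_detect(quick_weights, sharp, blurred)
        dm = refine_decision(consistency_verify(initial_segment(m)), guide)
        fused = fuse_hf(dm, sharp, blurred)
        assert np.sum(fused**2) == pytest.approx(np.sum(sharp**2), rel=0.05)


class TestInitialSegment:
    def test_threshold_is_strict(self):
        m = np.array([[0.6, 0.5], [0.49, 0.0]])
        assert np.array_equal(initial_segment(m), [[1.0, 0.0], [0.0, 0.0]])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            initial_segment(np.array([[1.2]]))


class TestConsistencyVerify:
    def test_all_ones_preserved(self):
        assert np.array_equal(consistency_verify(np.ones((32, 32))), np.ones((32, 32)))

    def test_isolated_pixel_removed(self):
        b = np.zeros((64, 64))
        b[30, 30] = 1.0
        assert np.array_equal(consistency_verify(b), np.zeros((64, 64)))

    def test_half_plane_nearly_preserved(self):
        b = np.zeros((32, 32))
        b[:, 16:] = 1.0
        out = consistency_verify(b)
        changed = np.flatnonzero((out != b).any(axis=0))
        assert len(changed) == 0 or (changed.max() - changed.min() + 1) <= 4
        assert np.array_equal(out[:, :12], b[:, :12])
        assert np.array_equal(out[:, 20:], b[:, 20:])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_majority_oracle(self, seed):
        b = (np.random.default_rng(seed).random((24, 24)) > 0.4).astype(float)
        assert np.array_equal(consistency_verify(b), majority_vote_oracle(b))

    def test_idempotent_in_interior(self):
        b = (np.random.default_rng(3).random((40, 40)) > 0.3).astype(float)
        once = consistency_verify(b)
        twice = consistency_verify(once)
        assert np.array_equal(once[8:-8, 8:-8], twice[8:-8, 8:-8])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            consistency_verify(np.full((8, 8), 0.5))


class TestRefineAndFuse:
    def test_constant_map_preserved(self):
        dm = refine_decision(np.full((20, 20), 0.3), np.full((20, 20), 0.6))
        assert np.allclose(dm, 0.3, atol=1e-12)

    def test_endpoints_select_sources(self, rng):
        ch, dh = rng.standard_normal((16, 16)), rng.standard_normal((16, 16))
        assert np.array_equal(fuse_hf(np.ones_like(ch), ch, dh), ch)
        assert np.array_equal(fuse_hf(np.zeros_like(ch), ch, dh), dh)

    def test_midpoint_arithmetic(self):
        ch, dh = np.full((4, 4), 2.0), np.full((4, 4), 4.0)
        assert np.allclose(fuse_hf(np.full((4, 4), 0.5), ch, dh), 3.0)

    def test_identical_bands_fixed_point(self, rng):
        ch = rng.standard_normal((16, 16))
        dm = rng.random((16, 16))
        assert np.allclose(fuse_hf(dm, ch, ch.copy()), ch, atol=1e-12)

    def test_convex_combination_bounds(self, rng):
        ch, dh = rng.standard_normal((16, 16)), rng.standard_normal((16, 16))
        fused = fuse_hf(rng.random((16, 16)), ch, dh)
        assert (fused >= np.minimum(ch, dh) - 1e-12).all()
        assert (fused <= np.maximum(ch, dh) + 1e-12).all()

    def test_validation(self, rng):
        with pytest.raises(ValueError):
            fuse_hf(np.full((8, 8), 1.5), rng.random((8, 8)), rng.random((8, 8)))
        with pytest.raises(ValueError):
            refine_decision(rng.random((8, 8)), rng.random((8, 9)))
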