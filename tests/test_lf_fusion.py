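"""Local-energy fusion rules against an independent scalar loop oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medfuse import EnergyConfig, fuse_lf, local_energy, salience


def oracle_fuse_lf(lc, ld, cfg):
    """Per-pixel re-implementation with explicit loops (symmetric borders)."""
    t = np.asarray(cfg.template)
    lcp = np.pad(lc, 1, mode="symmetric")
    ldp = np.pad(ld, 1, mode="symmetric")
    h, w = lc.shape
    out = np.empty((h, w))
    for y in range(h):
        for x in range(w):
            enc = end = cross = 0.0
            for m in range(3):
                for n in range(3):
                    c = lcp[y + m, x + n]
                    d = ldp[y + m, x + n]
                    enc += c * c * t[m, n]
                    end += d * d * t[m, n]
                    cross += c * d * t[m, n]
            s = 1.0 if enc + end < 1e-12 else 2.0 * cross / (enc + end)
            if s > cfg.threshold:
                ac = cfg.alpha_max if enc >= end else cfg.alpha_min
                out[y, x] = ac * lc[y, x] + (1 - ac) * ld[y, x]
            else:
                out[y, x] = lc[y, x] if enc >= end else ld[y, x]
    return out


class TestLocalEnergy:
    def test_constant_band_ones_template(self):
        en = local_energy(np.full((8, 8), 2.0))
        assert np.allclose(en, 36.0)  # 9 window terms x 2^2

    def test_zero_band(self):
        assert np.allclose(local_energy(np.zeros((8, 8))), 0.0)

    def test_single_impulse(self):
        band = np.zeros((5, 5))
        band[2, 2] = 1.0
        en = local_energy(band)
        expected = np.zeros((5, 5))
        expected[1:4, 1:4] = 1.0
        assert np.array_equal(en, expected)

    def test_too_small_band(self):
        with pytest.raises(ValueError):
            local_energy(np.zeros((2, 5)))


class TestSalience:
    def test_identical_bands_give_one(self, rng):
        lc = rng.random((10, 10)) + 0.1
        en = local_energy(lc)
        assert np.allclose(salience(lc, lc, en, en), 1.0)

    def test_zero_second_band_gives_zero(self, rng):
        lc = rng.random((10, 10)) + 0.1
        ld = np.zeros_like(lc)
        s = salience(lc, ld, local_energy(lc), local_energy(ld))
        assert np.allclose(s, 0.0)

    def test_doubled_band_gives_four_fifths(self, rng):
        lc = rng.random((10, 10)) + 0.1
        ld = 2.0 * lc
        s = salience(lc, ld, local_energy(lc), local_energy(ld))
        assert np.allclose(s, 0.8)


class TestFuseLf:
    def test_identical_bands_unchanged(self, rng):
        lc = rng.random((12, 12))
        assert np.allclose(fuse_lf(lc, lc.copy()), lc)

    def test_anticorrelated_bands_select_higher_energy(self, rng):
        lc = rng.standard_normal((8, 8))
        ld = -lc
        cfg = EnergyConfig()
        assert np.allclose(fuse_lf(lc, ld, cfg), oracle_fuse_lf(lc, ld, cfg), atol=1e-12)

    def test_degenerate_alpha_collapses_to_selection(self, rng):
        lc = rng.random((8, 8)) + 0.5
        ld = lc + 0.01 * rng.standard_normal((8, 8))
        cfg = EnergyConfig(alpha_min=0.0, alpha_max=1.0)
        enc, end = local_energy(lc, cfg), local_energy(ld, cfg)
        fused = fuse_lf(lc, ld, cfg)
        assert np.array_equal(fused, np.where(enc >= end, lc, ld))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lc = rng.standard_normal((8, 8))
        # mix correlated and independent halves so both modes occur
        ld = np.where(rng.random((8, 8)) < 0.5, lc + 0.01 * rng.standard_normal((8, 8)),
                      rng.standard_normal((8, 8)))
        cfg = EnergyConfig()
        assert np.allclose(fuse_lf(lc, ld, cfg), oracle_fuse_lf(lc, ld, cfg), atol=1e-12)

    def test_swap_symmetry_where_energies_differ(self, rng):
        lc = rng.standard_normal((10, 10))
        ld = rng.standard_normal((10, 10))
        cfg = EnergyConfig()
        enc, end = local_energy(lc, cfg), local_energy(ld, cfg)
        f1, f2 = fuse_lf(lc, ld, cfg), fuse_lf(ld, lc, cfg)
        differ = np.abs(enc - end) > 1e-12
        assert np.allclose(f1[differ], f2[differ])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_convexity_and_selection_bounds(self, seed):
        rng = np.random.default_rng(seed)
        lc = rng.standard_normal((6, 6))
        ld = rng.standard_normal((6, 6))
        fused = fuse_lf(lc, ld)
        lo = np.minimum(lc, ld) - 1e-12
        hi = np.maximum(lc, ld) + 1e-12
        assert ((fused >= lo) & (fused <= hi)).all()

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            EnergyConfig(alpha_min=0.4, alpha_max=0.7)
        with pytest.raises(ValueError):
            EnergyConfig(template=np.ones((5, 5)))
        with pytest.raises(ValueError):
            EnergyConfig(threshold=1.5)
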