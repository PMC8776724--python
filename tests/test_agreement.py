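"""Dice overlap and Bland-Altman statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from couinaud import LiverMask, bland_altman, dice, simulate_recovery
from couinaud.agreement import LOA_MULTIPLIER


def _mask(grid):
    return LiverMask(grid=np.asarray(grid, dtype=np.uint8),
                     affine=np.eye(4))


def _cube(n, lo, hi):
    g = np.zeros((n, n, n), dtype=np.uint8)
    g[lo:hi, lo:hi, lo:hi] = 1
    return g


class TestDice:
    def test_identity(self):
        m = _mask(_cube(10, 2, 8))
        assert dice(m, m).dice == 1.0

    def test_disjoint(self):
        a = _mask(_cube(10, 0, 3))
        b = _mask(_cube(10, 5, 9))
        assert dice(a, b).dice == 0.0

    def test_half_overlap(self):
        a = np.zeros((10, 10, 10), dtype=np.uint8)
        b = np.zeros((10, 10, 10), dtype=np.uint8)
        a.ravel()[:100] = 1
        b.ravel()[50:150] = 1  # |A| = |B| = 100, |A n B| = 50
        res = dice(_mask(a), _mask(b))
        assert res.dice == 0.5
        assert res.intersection_voxels == 50

    def test_symmetry_random_masks(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            a = _mask((rng.random((8, 8, 8)) > 0.5))
            b = _mask((rng.random((8, 8, 8)) > 0.5))
            assert dice(a, b).dice == dice(b, a).dice
            assert 0.0 <= dice(a, b).dice <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dice(_mask(_cube(10, 2, 8)), _mask(_cube(8, 2, 6)))

    def test_affine_mismatch_rejected(self):
        a = _mask(_cube(10, 2, 8))
        b = LiverMask(grid=_cube(10, 2, 8),
                      affine=np.diag([2.0, 1.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="affine"):
            dice(a, b)

    def test_both_empty_selection_rejected(self, default_labels):
        with pytest.raises(ValueError, match="empty"):
            dice(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)))

    def test_per_segment_dice_on_labelmaps(self, default_labels):
        res = dice(default_labels, default_labels, segment=41)
        assert res.dice == 1.0
        assert res.size_a == int(np.count_nonzero(default_labels.grid == 41))


class TestBlandAltman:
    def test_absolute_mode_unit_differences(self):
        pairs = [(1.0, 2.0), (2.0, 2.0), (3.0, 2.0)]  # d = {-1, 0, +1}
        res = bland_altman(pairs, mode="absolute")
        assert res.bias == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(-1.96)
        assert res.loa_high == pytest.approx(1.96)

    def test_percent_mode_worked_example(self):
        pairs = [(102, 98), (100, 100), (99, 101)]  # d = {+4, 0, -2}
        res = bland_altman(pairs, mode="percent")
        assert res.bias == pytest.approx(0.6667, abs=5e-5)
        assert res.sd_diff == pytest.approx(3.0551, abs=5e-5)
        assert res.loa_low == pytest.approx(-5.321, abs=5e-4)
        assert res.loa_high == pytest.approx(6.655, abs=5e-4)

    def test_identical_pairs_zero_loa(self):
        pairs = [(5.0, 5.0)] * 4
        res = bland_altman(pairs, mode="absolute")
        assert (res.bias, res.sd_diff) == (0.0, 0.0)
        assert (res.loa_low, res.loa_high) == (0.0, 0.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3"):
            bland_altman([(1, 2), (2, 3)])

    def test_zero_pair_mean_rejected_in_percent_mode(self):
        with pytest.raises(ValueError, match="zero pair mean"):
            bland_altman([(1.0, -1.0), (2.0, 2.0), (3.0, 3.0)],
                         mode="percent")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           shift=st.floats(-50.0, 50.0))
    def test_antisymmetry_and_translation(self, seed, shift):
        rng = np.random.default_rng(seed)
        pairs = rng.uniform(50.0, 150.0, size=(8, 2))
        fwd = bland_altman(pairs, mode="absolute")
        rev = bland_altman(pairs[:, ::-1], mode="absolute")
        assert rev.bias == pytest.approx(-fwd.bias, abs=1e-9)
        assert rev.loa_low == pytest.approx(-fwd.loa_high, abs=1e-9)
        assert rev.loa_high == pytest.approx(-fwd.loa_low, abs=1e-9)
        shifted = bland_altman(np.column_stack([pairs[:, 0] + shift,
                                                pairs[:, 1]]),
                               mode="absolute")
        assert shifted.bias == pytest.approx(fwd.bias + shift, abs=1e-9)
        assert shifted.sd_diff == pytest.approx(fwd.sd_diff, abs=1e-9)

    def test_loa_invariant(self):
        rng = np.random.default_rng(5)
        pairs = rng.uniform(50.0, 150.0, size=(20, 2))
        res = bland_altman(pairs, mode="percent")
        assert res.loa_low == pytest.approx(
            res.bias - LOA_MULTIPLIER * res.sd_diff)
        assert res.loa_high == pytest.approx(
            res.bias + LOA_MULTIPLIER * res.sd_diff)
        assert res.loa_low <= res.bias <= res.loa_high


class TestSimulateRecovery:
    def test_zero_sd_recovers_bias_exactly_up_to_curvature(self):
        # with sd = 0 every pair gives the same percent difference
        # bias/(1 - bias/200) = 2/0.99, the mean-denominator curvature
        # of the proportional error model; recovery is exact, every rep
        out = simulate_recovery(bias_pct=2.0, sd_pct=0.0, n=10, seed=1,
                                reps=3)
        assert out["bias_mean"] == pytest.approx(2.0 / 0.99, abs=1e-9)
        assert np.allclose(out["biases"], out["biases"][0])

    def test_large_n_recovery(self):
        out = simulate_recovery(bias_pct=2.0, sd_pct=2.0, n=10_000, seed=3,
                                reps=1)
        assert out["bias_mean"] == pytest.approx(2.0, abs=0.1)
        assert out["loa_low_mean"] == pytest.approx(-1.92, abs=0.15)
        assert out["loa_high_mean"] == pytest.approx(5.92, abs=0.15)

    def test_small_sample_ci_coverage(self):
        # bias 0, sd 2, n = 10: ~95% of reps have
        # |recovered bias| < 1.96 * 2 / sqrt(10)
        out = simulate_recovery(bias_pct=0.0, sd_pct=2.0, n=10, seed=9,
                                reps=400)
        halfwidth = 1.96 * 2.0 / np.sqrt(10)
        frac = np.mean(np.abs(out["biases"]) < halfwidth)
        assert 0.90 <= frac <= 0.99

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_recovery(0.0, -1.0, 10, seed=0)
        with pytest.raises(ValueError):
            simulate_recovery(0.0, 1.0, 2, seed=0)

    def test_plot_writes_file(self, tmp_path):
        from couinaud import plot_bland_altman
        rng = np.random.default_rng(2)
        pairs = rng.uniform(900, 1100, size=(10, 2))
        res = bland_altman(pairs, mode="percent")
        out = tmp_path / "ba.png"
        plot_bland_altman(pairs, res, out_path=out)
        assert out.stat().st_size > 0
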