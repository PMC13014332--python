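"""Overlap metrics (Tanimoto/Dice/volume similarity) and ICC agreement."""

import numpy as np
import pytest

from cestpipe import (
    MaskPair,
    categorize_icc,
    dice,
    icc,
    overlap_report,
    tanimoto,
    volume_ratio,
)

from oracles import icc2_anova


def _pair(a, b):
    return MaskPair(np.asarray(a, bool), np.asarray(b, bool))


def _random_pair(rng, shape=(12, 12, 2)):
    while True:
        a = rng.random(shape) < rng.uniform(0.05, 0.5)
        b = rng.random(shape) < rng.uniform(0.05, 0.5)
        if a.any() and b.any():
            return _pair(a, b)


class TestOverlapMetrics:
    def test_identical_masks(self, rng):
        m = rng.random((8, 8, 2)) < 0.3
        m[0, 0, 0] = True
        p = _pair(m, m)
        assert tanimoto(p) == 100.0 and dice(p) == 1.0 and volume_ratio(p) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 1), bool)
        b = np.zeros((4, 4, 1), bool)
        a[0], b[1] = True, True
        p = _pair(a, b)
        assert tanimoto(p) == 0.0 and dice(p) == 0.0

    def test_counting_example(self):
        # |A| = |B| = 4, 2 shared -> T = 2/6, D = 1/2
        a = np.zeros((3, 3, 1), bool)
        b = np.zeros((3, 3, 1), bool)
        a.flat[[0, 1, 2, 3]] = True
        b.flat[[2, 3, 4, 5]] = True
        p = _pair(a, b)
        assert tanimoto(p) == pytest.approx(100 * 2 / 6, abs=0.01)
        assert dice(p) == pytest.approx(0.5)

    def test_volume_ratio_counting(self):
        a = np.zeros((20, 1, 1), bool)
        b = np.zeros((20, 1, 1), bool)
        a[:8], b[:10] = True, True
        assert volume_ratio(_pair(a, b)) == pytest.approx(0.8)

    def test_empty_inputs_rejected(self):
        empty = np.zeros((2, 2, 1), bool)
        full = ~empty
        with pytest.raises(ValueError):
            tanimoto(_pair(empty, empty))
        with pytest.raises(ValueError):
            dice(_pair(empty, empty))
        with pytest.raises(ValueError):
            volume_ratio(_pair(full, empty))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            _pair(np.ones((2, 2, 1), bool), np.ones((3, 2, 1), bool))

    def test_dice_tanimoto_identity_on_random_pairs(self, rng):
        """D = 2T/(1+T) for every mask pair (T as a fraction)."""
        for _ in range(100):
            p = _random_pair(rng)
            t = tanimoto(p) / 100.0
            assert dice(p) == pytest.approx(2 * t / (1 + t), abs=1e-12)

    def test_symmetry_and_padding_invariance(self, rng):
        p = _random_pair(rng)
        q = MaskPair(p.mask_b, p.mask_a)
        assert tanimoto(p) == tanimoto(q)
        assert dice(p) == dice(q)
        assert volume_ratio(p) == volume_ratio(q)
        # adding voxels outside both masks changes nothing
        pad = MaskPair(
            np.pad(p.mask_a, 2), np.pad(p.mask_b, 2)
        )
        assert tanimoto(pad) == tanimoto(p) and dice(pad) == dice(p)

    def test_growing_intersection_never_decreases_overlap(self, rng):
        a = np.zeros((10, 10, 1), bool)
        b = np.zeros((10, 10, 1), bool)
        a[:5] = True
        b[5:] = True
        b_voxels = list(zip(*np.nonzero(a)))
        prev_d, prev_t = dice(_pair(a, b)), tanimoto(_pair(a, b))
        for vox in b_voxels[:20]:
            # move one B voxel into the intersection, |B| fixed
            outside = list(zip(*np.nonzero(b & ~a)))
            if not outside:
                break
            b[outside[0]] = False
            b[vox] = True
            d, t = dice(_pair(a, b)), tanimoto(_pair(a, b))
            assert d >= prev_d - 1e-12 and t >= prev_t - 1e-12
            prev_d, prev_t = d, t

    def test_report_consistency(self, rng):
        p = _random_pair(rng)
        r = overlap_report(p)
        assert r.tanimoto_pct / 100 == pytest.approx(r.dice / (2 - r.dice))
        assert 0 < r.volume_ratio <= 1


class TestICC:
    def test_perfect_repeat_is_excellent(self):
        col = np.array([3.0, 5.0, 7.0, 2.0, 9.0, 4.0])
        rep = icc(np.column_stack([col, col]))
        assert rep.icc == pytest.approx(1.0, abs=1e-9)
        assert rep.category == "excellent"

    def test_independent_columns_near_zero(self, rng):
        table = rng.standard_normal((10_000, 2))
        rep = icc(table)
        assert abs(rep.icc) < 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_anova_oracle(self, seed):
        """Two-way mean-squares oracle on small integer tables."""
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 10, size=(6, 2)).astype(float)
        if table.std() == 0:
            table[0, 0] += 1
        assert icc(table).icc == pytest.approx(icc2_anova(table), abs=1e-10)

    def test_row_permutation_invariant(self, rng):
        table = rng.normal(5, 2, size=(12, 3))
        perm = rng.permutation(12)
        assert icc(table).icc == pytest.approx(icc(table[perm]).icc, abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(20):
            t = rng.normal(size=(5, 3))
            assert -1.0 <= icc(t).icc <= 1.0

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            icc(np.full((5, 2), 3.0))

    def test_table_shape_and_missing_cells_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((1, 2)))
        bad = np.ones((4, 2))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc(bad)


class TestCategories:
    @pytest.mark.parametrize(
        "value,category",
        [
            (0.96, "excellent"),
            (0.99, "excellent"),
            (0.74, "good"),
            (0.63, "good"),
            (0.67, "good"),
            (0.70, "good"),
            (0.80, "good"),       # right-closed: 0.8 is good, not excellent
            (0.38, "fair"),
            (0.34, "fair"),
            (0.40, "fair"),       # right-closed: 0.4 is fair
            (0.55, "moderate"),
            (0.20, "poor"),
            (-0.3, "poor"),
        ],
    )
    def test_thresholds(self, value, category):
        assert categorize_icc(value) == category

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_icc(1.2)
        with pytest.raises(ValueError):
            categorize_icc(-1.5)
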