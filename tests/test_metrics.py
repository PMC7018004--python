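"""Asymmetry indices and individual/global statistics."""

import numpy as np
import pytest

from floretgen.errors import EmptyDatasetError
from floretgen.fixtures import caterpillar
from floretgen.metrics import (
    dataset_stats,
    individual_stats,
    length_weighted_asymmetry,
    partition_asymmetries,
    van_pelt_asymmetry,
)
from floretgen.morphology import Floret, Segment, build_floret

from conftest import random_topology


class TestWorkedExamples:
    def test_trivial_scores_zero(self, fixtures):
        assert van_pelt_asymmetry(fixtures["trivial"]) == 0.0
        assert length_weighted_asymmetry(fixtures["trivial"]) == 0.0

    def test_balanced_tree_scores_zero(self, fixtures):
        assert van_pelt_asymmetry(fixtures["perfect7"]) == 0.0
        assert length_weighted_asymmetry(fixtures["perfect7"]) == 0.0

    def test_five_segment_weighted_example(self, fixtures):
        # F(root): t=(1,2), w=(4,1) -> A_pw = 2|2-4|/(1*5) = 0.8;
        # the lower cherry contributes 0; mean over 2 internal nodes = 0.4
        assert length_weighted_asymmetry(fixtures["asym5"]) == pytest.approx(0.4)
        assert van_pelt_asymmetry(fixtures["asym5"]) == pytest.approx(0.5)

    def test_equal_lengths_same_topology(self, fixtures):
        # all lengths 1: A_pw(F(root)) = 2|2-1|/(1*2) = 1 -> A_w = 0.5 = A_p
        assert length_weighted_asymmetry(fixtures["equal5"]) == pytest.approx(0.5)
        assert van_pelt_asymmetry(fixtures["equal5"]) == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [2, 3, 4, 8, 32])
    def test_caterpillar_formula(self, k):
        # partitions (k-1,1)...(2,1) score 1 each, the final (1,1) cherry
        # scores 0: mean over k-1 branch points = (k-2)/(k-1) -> 1 as k grows
        f = caterpillar(k)
        assert van_pelt_asymmetry(f) == pytest.approx((k - 2) / (k - 1))

    def test_caterpillar_is_maximal_for_its_size(self, rng):
        cat = van_pelt_asymmetry(caterpillar(8))
        for _ in range(50):
            f = random_topology(rng, 7, lengths="equal")
            assert van_pelt_asymmetry(f) <= cat + 1e-12


class TestIndexProperties:
    def test_equal_lengths_reduce_weighted_to_van_pelt(self, rng):
        for _ in range(200):
            f = random_topology(rng, int(rng.integers(1, 15)), lengths="equal")
            assert length_weighted_asymmetry(f) == pytest.approx(
                van_pelt_asymmetry(f), abs=1e-12
            )

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(100):
            f = random_topology(rng, int(rng.integers(0, 15)))
            assert 0.0 <= van_pelt_asymmetry(f) <= 1.0
            assert 0.0 <= length_weighted_asymmetry(f) <= 1.0

    def test_scale_invariance(self, rng):
        for scale in (0.1, 7.3, 1000.0):
            for _ in range(20):
                f = random_topology(rng, int(rng.integers(1, 10)))
                scaled = Floret(
                    [Segment(s.id, s.parent_id, s.length * scale) for s in f]
                )
                assert length_weighted_asymmetry(scaled) == pytest.approx(
                    length_weighted_asymmetry(f)
                )

    def test_child_order_invariance(self, rng):
        for _ in range(30):
            f = random_topology(rng, int(rng.integers(1, 10)))
            segs = list(f)
            # rebuild with all sibling groups given in reversed order
            swapped = Floret(reversed(segs))
            assert van_pelt_asymmetry(swapped) == pytest.approx(van_pelt_asymmetry(f))
            assert length_weighted_asymmetry(swapped) == pytest.approx(
                length_weighted_asymmetry(f)
            )

    def test_clamp_keeps_extreme_weight_ratio_in_bounds(self):
        # t=(2,1) with a huge terminal-side weight: raw A_pw would be ~4
        f = build_floret(
            [(1, None, 1.0), (2, 1, 1000.0), (3, 1, 1.0),
             (4, 3, 1.0), (5, 3, 1.0)]
        )
        parts = partition_asymmetries(f)
        root_row = parts[parts.segment_id == 1].iloc[0]
        assert root_row.clamped
        assert root_row.a_pw == 1.0
        assert 0.0 <= length_weighted_asymmetry(f) <= 1.0


class TestIndividualStats:
    def test_trivial(self, fixtures):
        st = individual_stats(fixtures["trivial"])
        assert st.n_segments == 1
        assert st.mean_len == 10.0
        assert st.sd_len == 0.0
        assert st.mean_depth == 1.0
        assert st.max_depth == 1
        assert st.van_pelt_asymmetry == 0.0
        assert st.length_weighted_asymmetry == 0.0

    def test_three_segment(self, fixtures):
        st = individual_stats(fixtures["y3"])
        assert st.mean_len == pytest.approx(22 / 3)
        assert st.mean_depth == pytest.approx(5 / 3)
        assert st.max_depth == 2
        assert st.van_pelt_asymmetry == 0.0

    def test_five_segment_depths(self, fixtures):
        st = individual_stats(fixtures["asym5"])
        assert st.mean_depth == pytest.approx((1 + 2 + 2 + 3 + 3) / 5)
        assert st.max_depth == 3

    def test_sample_sd_and_logs(self):
        f = build_floret([(1, None, 2.0), (2, 1, 4.0), (3, 1, 8.0)])
        st = individual_stats(f)
        lens = np.array([2.0, 4.0, 8.0])
        assert st.sd_len == pytest.approx(np.std(lens, ddof=1))
        assert st.mean_loglen == pytest.approx(np.mean(np.log(lens)))
        assert st.sd_loglen == pytest.approx(np.std(np.log(lens), ddof=1))


class TestDatasetStats:
    def test_single_trivial_floret(self, fixtures):
        ds = dataset_stats([fixtures["trivial"]])
        assert list(ds.pooled_lengths) == [10.0]
        assert ds.summary["mean_vp_asymmetry"] == 0.0
        assert ds.summary["trivial_fraction"] == 1.0

    def test_empty_dataset_raises(self):
        with pytest.raises(EmptyDatasetError):
            dataset_stats([])

    def test_pooled_count_identity(self, fixtures, rng):
        florets = [random_topology(rng, int(rng.integers(0, 6))) for _ in range(40)]
        ds = dataset_stats(florets)
        assert ds.pooled_lengths.size == sum(f.n_segments for f in florets)
        assert ds.n_trivial + int((ds.per_floret["n_segments"] > 1).sum()) == ds.n_florets

    def test_trivial_dilution_identities(self, rng):
        """Overall means are NT means diluted by the trivial fraction.

        E.g. 260 trivial of 426 florets with NT mean asymmetry 0.39
        gives overall 166*0.39/426 ~ 0.152; the same bookkeeping must
        hold exactly on any synthetic dataset.
        """
        florets = [random_topology(rng, int(rng.integers(1, 8))) for _ in range(60)]
        florets += [random_topology(rng, 0) for _ in range(90)]
        ds = dataset_stats(florets)
        s = ds.summary
        n, n_nt = s["n_florets"], s["n_florets"] - s["n_trivial"]
        assert s["mean_vp_asymmetry"] == pytest.approx(
            n_nt * s["mean_vp_asymmetry_nt"] / n
        )
        expected_depth = (s["n_trivial"] * 1.0 + n_nt * s["mean_depth_nt"]) / n
        assert s["mean_depth"] == pytest.approx(expected_depth)
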