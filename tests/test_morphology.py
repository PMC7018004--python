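"""Floret construction, validation, traversal and I/O."""

import numpy as np
import pytest

from floretgen import errors
from floretgen.morphology import (
    Floret,
    Segment,
    build_floret,
    counts,
    depths,
    read_segment_table,
    read_swc,
    subfloret,
    write_segment_table,
    write_swc,
)

from conftest import random_topology


class TestBuildFloret:
    def test_trivial(self):
        f = build_floret([(1, None, 10.0)])
        assert f.n_segments == 1
        assert f.is_trivial
        assert f.root_id == 1

    def test_smallest_nontrivial(self):
        f = build_floret([(1, None, 10), (2, 1, 5), (3, 1, 7)])
        assert f.n_segments == 3
        assert f.n_terminals == 2
        assert f.n_internal == 1

    @pytest.mark.parametrize(
        "rows, exc",
        [
            ([(1, None, 1), (1, None, 2)], errors.DuplicateIdError),
            ([(1, None, 1), (2, None, 1)], errors.MultipleRootsError),
            ([(1, None, 10), (2, 1, 5)], errors.UnaryBranchPointError),
            ([(1, None, 1), (2, 1, 1), (3, 1, 1), (4, 9, 1)],
             errors.OrphanParentError),
            ([(1, None, 1), (2, 1, 1), (3, 1, 1), (4, 1, 1)],
             errors.NonBinaryBranchingError),
            ([(1, 2, 1), (2, 1, 1)], errors.MissingRootError),
            ([], errors.MissingRootError),
        ],
    )
    def test_invalid_trees_rejected(self, rows, exc):
        with pytest.raises(exc):
            build_floret(rows)

    def test_cycle_detected(self):
        # root exists, but 2<->3 reference each other off the tree
        segs = [Segment(1, None, 1.0), Segment(2, 3, 1.0), Segment(3, 2, 1.0)]
        with pytest.raises(errors.CycleError):
            Floret(segs)

    def test_negative_length_rejected(self):
        with pytest.raises(errors.MorphologyError):
            build_floret([(1, None, -1.0)])

    def test_zero_length_allowed_but_not_finalized(self):
        f = build_floret([(1, None, 0.0)])
        with pytest.raises(errors.SegmentTooShortError):
            f.finalize()

    def test_finalize_passes_above_floor(self):
        f = build_floret([(1, None, 1.0)])
        assert f.finalize() is f


class TestTraversal:
    def test_subfloret_of_root_is_whole_tree(self, fixtures):
        f = fixtures["asym5"]
        sub = subfloret(f, f.root_id)
        assert sorted(sub.lengths) == sorted(f.lengths)

    def test_subfloret_of_terminal_is_trivial(self, fixtures):
        f = fixtures["y3"]
        sub = subfloret(f, 2)
        assert sub.is_trivial
        assert sub.segment(2).length == 5.0

    def test_subfloret_internal_node(self, fixtures):
        sub = subfloret(fixtures["asym5"], 3)
        assert sub.n_segments == 3
        assert sub.root_id == 3
        assert sorted(sub.lengths) == [1.0, 1.0, 1.0]

    def test_subfloret_unknown_id(self, fixtures):
        with pytest.raises(errors.UnknownSegmentError):
            subfloret(fixtures["y3"], 99)

    def test_depths_examples(self, fixtures):
        assert depths(fixtures["trivial"]) == {1: 1}
        assert sorted(depths(fixtures["y3"]).values()) == [1, 2, 2]
        assert sorted(depths(fixtures["perfect7"]).values()) == [1, 2, 2, 3, 3, 3, 3]

    def test_counts_examples(self, fixtures):
        assert counts(fixtures["trivial"]) == (1, 1, 10.0, 10.0)
        c = counts(fixtures["y3"])
        assert c.n_segments == 3 and c.n_terminals == 2
        assert c.mean_length == pytest.approx(22 / 3)
        assert c.total_length == pytest.approx(22.0)
        c5 = counts(fixtures["asym5"])
        assert c5 == (5, 3, pytest.approx(9 / 5), pytest.approx(9.0))

    def test_binary_tree_arithmetic_property(self, rng):
        for _ in range(25):
            f = random_topology(rng, int(rng.integers(0, 12)))
            assert f.n_terminals - f.n_internal == 1
            assert f.n_segments == 2 * f.n_terminals - 1

    def test_subfloret_partition_property(self, rng):
        f = random_topology(rng, 10)
        for sid in f.preorder():
            kids = f.children(sid)
            total = sum(f.subfloret(k).n_segments for k in kids)
            assert total == f.subfloret(sid).n_segments - 1


class TestSWC:
    def test_straight_polyline_is_trivial_floret(self, tmp_path):
        swc = tmp_path / "line.swc"
        swc.write_text(
            "1 2 0 0 0 0.5 -1\n2 2 0 0 1 0.5 1\n3 2 0 0 2 0.5 2\n"
        )
        (floret,) = read_swc(swc)
        assert floret.is_trivial
        assert floret.segment(floret.root_id).length == pytest.approx(2.0)

    def test_y_shape(self, tmp_path):
        lines = ["1 2 0 0 0 0.5 -1"]
        # vertical stem of 3 points, then two arms of 5 points each
        for i in range(2, 4):
            lines.append(f"{i} 2 0 0 {i - 1} 0.5 {i - 1}")
        idx = 4
        for dx in (-1, 1):
            par = 3
            for j in range(1, 6):
                lines.append(f"{idx} 2 {dx * j} 0 {2 + j} 0.5 {par}")
                par = idx
                idx += 1
        (floret,) = read_swc(_write(tmp_path, lines))
        assert floret.n_segments == 3
        root = floret.segment(floret.root_id)
        assert root.length == pytest.approx(2.0)
        arm = np.sqrt(2.0) * 5
        for sid in floret.terminal_ids():
            assert floret.segment(sid).length == pytest.approx(arm)

    def test_nonbinary_branching_rejected(self, tmp_path):
        lines = ["1 2 0 0 0 0.5 -1"]
        for i, dx in zip(range(2, 5), (-1, 0, 1)):
            lines.append(f"{i} 2 {dx} 0 1 0.5 1")
        with pytest.raises(errors.NonBinaryBranchingError):
            read_swc(_write(tmp_path, lines))

    def test_malformed_rejected(self, tmp_path):
        swc = tmp_path / "bad.swc"
        swc.write_text("1 2 0 0 0 0.5\n")
        with pytest.raises(errors.MalformedSWCError):
            read_swc(swc)

    def test_round_trip_preserves_lengths_and_topology(self, tmp_path, rng):
        florets = [random_topology(rng, int(rng.integers(0, 8))) for _ in range(6)]
        out = tmp_path / "rt.swc"
        write_swc(florets, out)
        back = read_swc(out)
        assert len(back) == len(florets)
        for orig, rt in zip(florets, back):
            assert np.allclose(sorted(orig.lengths), sorted(rt.lengths), atol=1e-6)
            orig_depths = sorted(orig.depths().values())
            assert orig_depths == sorted(rt.depths().values())


class TestSegmentTable:
    def test_round_trip(self, tmp_path, fixtures):
        path = tmp_path / "segments.csv"
        florets = [fixtures["asym5"], fixtures["y3"], fixtures["trivial"]]
        write_segment_table(florets, path)
        back = read_segment_table(path)
        assert len(back) == 3
        for orig, rt in zip(florets, back):
            assert np.allclose(sorted(orig.lengths), sorted(rt.lengths))

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(errors.MissingColumnError):
            read_segment_table(path)

    def test_custom_columns_and_root_markers(self, tmp_path):
        path = tmp_path / "custom.csv"
        path.write_text("sid,pid,len\n1,none,10\n2,1,5\n3,1,7\n")
        (floret,) = read_segment_table(
            path, columns={"segment": "sid", "parent": "pid", "length": "len"}
        )
        assert floret.n_segments == 3

    def test_invalid_tree_propagates(self, tmp_path):
        path = tmp_path / "unary.csv"
        path.write_text(
            "floret_id,segment_id,parent_id,length\n1,1,-1,10\n1,2,1,5\n"
        )
        with pytest.raises(errors.UnaryBranchPointError):
            read_segment_table(path)


def _write(tmp_path, lines):
    swc = tmp_path / "t.swc"
    swc.write_text("\n".join(lines) + "\n")
    return swc
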