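import numpy as np
import pytest

from ssetop.structure_io import (
    ChainModel,
    ChainResidue,
    SequenceSegment,
    SkeletonGrid,
    Stick,
    StructureError,
    extract_segments,
    extract_sticks,
    read_annotation,
    read_chain,
    read_segments,
    read_skeleton,
    read_sticks,
    write_chain_pdb,
    write_segments,
    write_skeleton,
    write_sticks,
)
from ssetop.synthetic_fixtures import make_bundle, rasterize_skeleton


class TestReadChain:
    def test_round_trip_minimal_chain(self, straight_chain, tmp_path):
        path = tmp_path / "chain.pdb"
        write_chain_pdb(straight_chain, path)
        back = read_chain(path, "A")
        assert len(back) == len(straight_chain)
        for a, b in zip(back.residues, straight_chain.residues):
            assert a.index == b.index
            np.testing.assert_allclose(a.ca, b.ca, atol=1e-3)

    def test_missing_chain_lists_available(self, straight_chain, tmp_path):
        path = tmp_path / "chain.pdb"
        write_chain_pdb(straight_chain, path)
        with pytest.raises(StructureError, match="A"):
            read_chain(path, "Z")

    def test_synthetic_bundle_residue_count(self, tmp_path):
        bundle = make_bundle(3, 0, seed=4)
        path = tmp_path / "bundle.pdb"
        write_chain_pdb(bundle.chain, path)
        assert len(read_chain(path, "A")) == len(bundle.chain)

    def test_annotation_round_trip(self, straight_chain, tmp_path):
        path = tmp_path / "chain.pdb"
        ann = [("H", 1, 6), ("E", 9, 12)]
        write_chain_pdb(straight_chain, path, ann)
        assert read_annotation(path, "A") == [("H", 1, 6), ("E", 9, 12)]


class TestExtractSegments:
    @pytest.mark.parametrize(
        "annotation,expected_types",
        [
            ([("H", 1, 5)], []),                     # 5-residue helix dropped
            ([("H", 1, 6), ("E", 10, 12)], ["H", "E"]),  # at the length minima
            ([("E", 1, 2)], []),                     # 2-residue strand dropped
            ([], []),
        ],
    )
    def test_minimum_length_filter(self, annotation, expected_types):
        segs = extract_segments(annotation)
        assert [s.sse_type for s in segs] == expected_types
        assert [s.order_index for s in segs] == list(range(1, len(segs) + 1))

    def test_overlapping_spans_rejected(self):
        with pytest.raises(StructureError, match="overlap"):
            extract_segments([("H", 1, 10), ("H", 8, 20)])

    def test_idempotent(self):
        ann = [("H", 1, 8), ("E", 12, 16), ("H", 20, 30)]
        once = extract_segments(ann)
        twice = extract_segments(
            [(s.sse_type, s.first_res, s.last_res) for s in once]
        )
        assert once == twice


class TestExtractSticks:
    def test_centroid_arithmetic(self):
        cas = [np.array(p) for p in [(0, 0, 0), (3, 0, 0), (0, 3, 0),
                                     (0, 0, 4), (3, 0, 4), (0, 3, 4)]]
        chain = ChainModel("A", [
            ChainResidue(i + 1, "A", ca) for i, ca in enumerate(cas)
        ])
        stick = extract_sticks(chain, [SequenceSegment(1, "H", 1, 6)])[0]
        np.testing.assert_allclose(stick.p0, [1, 1, 0])
        np.testing.assert_allclose(stick.p1, [1, 1, 4])

    def test_degenerate_stick_rejected(self):
        chain = ChainModel("A", [
            ChainResidue(1, "A", np.array([0.0, 0.0, 0.0])),
            ChainResidue(2, "A", np.array([0.0, 0.0, 1.0])),
            ChainResidue(3, "A", np.array([0.0, 0.0, 2.0])),
        ])
        with pytest.raises(StructureError, match="degenerate"):
            extract_sticks(chain, [SequenceSegment(1, "E", 1, 3)])

    def test_too_few_residues_rejected(self, straight_chain):
        with pytest.raises(StructureError, match=">= 3"):
            extract_sticks(straight_chain, [SequenceSegment(1, "E", 1, 2)])

    def test_helices_ordered_before_strands(self, straight_chain):
        segs = [SequenceSegment(1, "E", 1, 4), SequenceSegment(2, "H", 5, 12)]
        sticks = extract_sticks(straight_chain, segs)
        assert [s.sse_type for s in sticks] == ["H", "E"]
        assert [s.stick_index for s in sticks] == [1, 2]

    def test_ideal_helix_endpoints_near_axis(self):
        bundle = make_bundle(2, 0, seed=9)
        for stick in bundle.sticks:
            a0, a1 = bundle.axis_endpoints[stick.stick_index]
            assert np.linalg.norm(stick.p0 - a0) < 1.0
            assert np.linalg.norm(stick.p1 - a1) < 1.0

    def test_output_count_matches_segments(self, straight_chain):
        segs = [SequenceSegment(1, "H", 1, 6), SequenceSegment(2, "E", 8, 12)]
        assert len(extract_sticks(straight_chain, segs)) == len(segs)


class TestSkeletonIO:
    def test_all_zero_map(self, tmp_path):
        grid = SkeletonGrid(np.zeros((4, 4, 4)), [1.0] * 3, [0.0] * 3)
        path = tmp_path / "zero.mrc"
        write_skeleton(grid, path)
        assert read_skeleton(path).count_foreground() == 0

    def test_single_voxel_coordinate(self, tmp_path):
        occ = np.zeros((5, 6, 7))
        occ[1, 2, 3] = 1
        grid = SkeletonGrid(occ, [2.0, 2.0, 2.0], [10.0, -4.0, 0.0])
        path = tmp_path / "one.mrc"
        write_skeleton(grid, path)
        back = read_skeleton(path)
        assert back.count_foreground() == 1
        np.testing.assert_allclose(back.foreground_coords()[0], [12.0, 0.0, 6.0])

    def test_rasterized_bundle_round_trip(self, tmp_path):
        bundle = make_bundle(3, 0, seed=2)
        grid = rasterize_skeleton(bundle)
        path = tmp_path / "skel.mrc"
        write_skeleton(grid, path)
        assert read_skeleton(path).count_foreground() == grid.count_foreground()

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(StructureError, match="spacing"):
            SkeletonGrid(np.zeros((2, 2, 2)), [1.0, 0.0, 1.0], [0.0] * 3)


class TestStickTables:
    def test_round_trip_identity(self, tmp_path):
        sticks = [
            Stick(1, "H", np.array([0.0, 1.5, 2.25]), np.array([3.0, 1.5, 9.0])),
            Stick(2, "H", np.array([10.0, 0.0, 0.0]), np.array([10.0, 0.0, 9.0])),
            Stick(3, "E", np.array([-1.0, -2.0, -3.0]), np.array([4.0, 5.0, 6.0])),
        ]
        path = tmp_path / "sticks.tsv"
        write_sticks(sticks, path)
        back = read_sticks(path)
        assert len(back) == 3
        for a, b in zip(back, sticks):
            assert (a.stick_index, a.sse_type) == (b.stick_index, b.sse_type)
            np.testing.assert_allclose(a.p0, b.p0, atol=1e-4)
            np.testing.assert_allclose(a.p1, b.p1, atol=1e-4)

    def test_bad_type_token_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("1\tX\t0\t0\t0\t1\t1\t1\n")
        with pytest.raises(StructureError, match="type token"):
            read_sticks(path)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("1\tH\t0\t0\t0\n")
        with pytest.raises(StructureError, match=":1"):
            read_sticks(path)

    def test_strand_before_helix_reordered(self, tmp_path):
        path = tmp_path / "swapped.tsv"
        path.write_text(
            "1\tE\t0\t0\t0\t1\t1\t1\n2\tH\t5\t5\t5\t9\t9\t9\n"
        )
        back = read_sticks(path)
        assert [s.sse_type for s in back] == ["H", "E"]
        assert [s.stick_index for s in back] == [1, 2]

    def test_segment_table_round_trip(self, tmp_path):
        segs = [SequenceSegment(1, "H", 3, 12), SequenceSegment(2, "E", 20, 24)]
        path = tmp_path / "segments.tsv"
        write_segments(segs, path)
        assert read_segments(path) == segs
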