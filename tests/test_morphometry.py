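"""SWC parsing, segment decomposition, summaries and the depth correlate."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hippophys.errors import DataError, SWCParseError
from hippophys.morphometry import (
    MorphologyTree,
    SWCNode,
    decompose_segments,
    depth_feature_correlation,
    read_swc,
    summarize_morphology,
    write_swc,
)
from hippophys.synthgen import MorphoGenParams, generate_morphology


def _tree(rows) -> MorphologyTree:
    return MorphologyTree({r[0]: SWCNode(*r) for r in rows})


@pytest.fixture
def y_tree() -> MorphologyTree:
    """Soma -> branch at (0,100,0) -> tips at (30,140,0) and (0,180,0).

    Segment lengths 100, 50, 80 µm; total 230; maximal path 180."""
    return _tree([
        (1, 1, 0.0, 0.0, 0.0, 6.0, -1),
        (2, 3, 0.0, 100.0, 0.0, 0.6, 1),
        (3, 3, 30.0, 140.0, 0.0, 0.6, 2),
        (4, 3, 0.0, 180.0, 0.0, 0.6, 2),
    ])


class TestSWCIO:
    def test_two_node_file(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("# comment\n1 1 0 0 0 5 -1\n2 3 0 10 0 1 1\n")
        tree = read_swc(p)
        assert len(tree.nodes) == 2
        assert tree.root.id == 1

    def test_round_trip_preserves_coordinates(self, tmp_path, y_tree):
        p = tmp_path / "y.swc"
        write_swc(y_tree, p)
        back = read_swc(p)
        assert set(back.nodes) == set(y_tree.nodes)
        for nid, n in y_tree.nodes.items():
            b = back.nodes[nid]
            assert (b.x, b.y, b.z) == pytest.approx((n.x, n.y, n.z), abs=1e-6)
            assert b.parent == n.parent

    def test_generated_round_trip_identity(self, tmp_path):
        gen = generate_morphology(MorphoGenParams(n_stems=2), seed=12)
        p1, p2 = tmp_path / "a.swc", tmp_path / "b.swc"
        write_swc(gen.tree, p1)
        write_swc(read_swc(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_parent_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 0 10 0 1 99\n")
        with pytest.raises(SWCParseError, match="missing parent"):
            read_swc(p)

    def test_duplicate_id_is_parse_error_naming_line(self, tmp_path):
        p = tmp_path / "dup.swc"
        p.write_text("1 1 0 0 0 5 -1\n1 3 0 10 0 1 1\n")
        with pytest.raises(SWCParseError, match=":2"):
            read_swc(p)

    def test_cycle_is_parse_error(self, tmp_path):
        p = tmp_path / "cyc.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 0 1 0 1 3\n3 3 0 2 0 1 2\n")
        with pytest.raises(SWCParseError, match="cycle"):
            read_swc(p)


class TestSegments:
    def test_unbranched_neurite_single_segment(self):
        tree = _tree([
            (1, 1, 0.0, 0.0, 0.0, 6.0, -1),
            (2, 3, 0.0, 40.0, 0.0, 0.6, 1),
            (3, 3, 0.0, 100.0, 0.0, 0.6, 2),
        ])
        table = decompose_segments(tree)
        assert table.n_segments == 1
        assert table.total_length == pytest.approx(100.0)

    def test_y_tree_hand_computed(self, y_tree):
        table = decompose_segments(y_tree)
        lengths = sorted(s.path_length for s in table.segments)
        assert lengths == pytest.approx([50.0, 80.0, 100.0])
        assert table.total_length == pytest.approx(230.0)

    def test_collinear_subdivision_invariance(self, y_tree):
        nodes = dict(y_tree.nodes)
        # insert a pass-through point halfway up the trunk
        nodes[5] = SWCNode(5, 3, 0.0, 50.0, 0.0, 0.6, 1)
        nodes[2] = SWCNode(2, 3, 0.0, 100.0, 0.0, 0.6, 5)
        subdivided = MorphologyTree(nodes)
        a = decompose_segments(y_tree)
        b = decompose_segments(subdivided)
        assert b.n_segments == a.n_segments
        assert b.total_length == pytest.approx(a.total_length)
        assert sorted(s.path_length for s in b.segments) == pytest.approx(
            sorted(s.path_length for s in a.segments)
        )

    def test_axon_excluded_by_default(self, y_tree):
        nodes = dict(y_tree.nodes)
        nodes[10] = SWCNode(10, 2, 0.0, -30.0, 0.0, 0.5, 1)  # axon stem
        tree = MorphologyTree(nodes)
        assert decompose_segments(tree).n_segments == 3
        assert decompose_segments(tree, include_axon=True).n_segments == 4


class TestSummary:
    def test_y_tree_summary(self, y_tree):
        s = summarize_morphology(y_tree)
        assert s.n_segments == 3
        assert s.total_length == pytest.approx(230.0)
        assert s.maximal_length == pytest.approx(180.0)
        assert s.max_segment_length == pytest.approx(100.0)
        assert s.max_branch_order == 2
        assert s.maximal_length <= s.total_length

    def test_isometry_invariance(self, y_tree):
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        shift = np.array([12.0, -5.0, 40.0])
        nodes = {}
        for nid, n in y_tree.nodes.items():
            p = rot @ n.xyz + shift
            nodes[nid] = SWCNode(nid, n.type, *p, n.radius, n.parent)
        moved = MorphologyTree(nodes)
        a, b = summarize_morphology(y_tree), summarize_morphology(moved)
        assert b.n_segments == a.n_segments
        assert b.total_length == pytest.approx(a.total_length, abs=1e-9)
        assert b.maximal_length == pytest.approx(a.maximal_length, abs=1e-9)

    def test_soma_only_tree_is_empty_summary(self):
        s = summarize_morphology(_tree([(1, 1, 0.0, 0.0, 0.0, 6.0, -1)]))
        assert s.empty
        assert s.n_segments == 0 and s.total_length == 0.0

    def test_removing_terminal_segment_decrements_count(self, y_tree):
        # removing tip 3 merges its sibling's segment with the trunk: 3 -> 1
        nodes = {k: v for k, v in y_tree.nodes.items() if k != 3}
        assert summarize_morphology(MorphologyTree(nodes)).n_segments == 1
        # with a trifurcation, removing one tip leaves the others intact: 4 -> 3
        nodes = dict(y_tree.nodes)
        nodes[6] = SWCNode(6, 3, -30.0, 140.0, 0.0, 0.6, 2)
        assert summarize_morphology(MorphologyTree(nodes)).n_segments == 4
        del nodes[6]
        assert summarize_morphology(MorphologyTree(nodes)).n_segments == 3

    @pytest.mark.parametrize("seed", [10, 20, 30])
    def test_generator_ground_truth_reproduced(self, seed):
        gen = generate_morphology(
            MorphoGenParams(branch_probability=0.015, n_stems=3), seed=seed
        )
        s = summarize_morphology(gen.tree)
        assert s.n_segments == gen.n_segments
        assert s.total_length == pytest.approx(gen.total_length, abs=1e-6)
        assert s.maximal_length == pytest.approx(gen.maximal_length, abs=1e-6)


class TestDepthCorrelation:
    def test_perfectly_monotone_pairs(self):
        rho, p = depth_feature_correlation([(0.1, 10.0), (0.3, 20.0), (0.5, 25.0),
                                            (0.9, 40.0)])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)  # both extreme orderings

    def test_reversed_ranks(self):
        rho, _ = depth_feature_correlation([(0.1, 300.0), (0.5, 200.0),
                                            (0.7, 150.0), (0.9, 100.0)])
        assert rho == pytest.approx(-1.0)

    def test_constant_feature_undefined(self):
        with pytest.raises(DataError):
            depth_feature_correlation([(0.1, 5.0), (0.2, 5.0), (0.3, 5.0), (0.4, 5.0)])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DataError):
            depth_feature_correlation([(0.1, 1.0), (0.2, 2.0), (0.3, 3.0)])

    def test_exact_p_matches_large_sample_direction(self):
        rng = np.random.default_rng(3)
        depth = rng.uniform(0, 1, 8)
        feat = 100.0 + 200.0 * depth + rng.normal(0, 10.0, 8)
        rho, p_exact = depth_feature_correlation(list(zip(depth, feat)))
        assert rho > 0
        assert 0.0 < p_exact <= 1.0

    def test_slope_sign_recovered_across_seeds(self):
        """Cells generated with a depth-dependent R_m slope: the recovered
        correlation sign matches the generating slope in >=95% of seeds."""
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            depth = rng.uniform(0, 1, 12)
            rm = 80.0 + 120.0 * depth + rng.normal(0, 30.0, 12)
            rho, _ = depth_feature_correlation(list(zip(depth, rm)))
            hits += rho > 0
        assert hits / n_seeds >= 0.95
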