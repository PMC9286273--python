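import numpy as np
import pytest

from nadder.arbor import (CurveBundle, NeuronTree, SWCNode, arbor_local_3d_scale,
                          decompose_tree, plane_crossings, read_swc,
                          write_swc)


def make_tree(rows):
    """rows: (id, x, y, z, parent)."""
    return NeuronTree({r[0]: SWCNode(r[0], 3, (float(r[1]), float(r[2]),
                                               float(r[3])), 1.0, r[4])
                       for r in rows})


@pytest.fixture
def y_tree():
    """Root at origin, stem along x, two arms splitting at x = 50."""
    rows = [(1, 0, 0, 0, -1)]
    nid = 2
    for i in range(1, 51):           # stem
        rows.append((nid, i, 0, 0, nid - 1)); nid += 1
    arm1_start = nid
    for i in range(1, 41):           # arm up
        rows.append((nid, 50, i, 0, 51 if i == 1 else nid - 1)); nid += 1
    for i in range(1, 41):           # arm down
        rows.append((nid, 50, -i, 0, 51 if i == 1 else nid - 1)); nid += 1
    return make_tree(rows)


class TestSWCIO:
    def test_toy_round_trip(self, tmp_path):
        tree = make_tree([(1, 0, 0, 0, -1), (2, 1, 0, 0, 1),
                          (3, 0, 1, 0, 1)])
        path = tmp_path / "toy.swc"
        write_swc(tree, path)
        back = read_swc(path)
        assert len(back.nodes) == 3
        assert back.root == 1
        assert sorted(back.leaves()) == [2, 3]
        for nid in tree.nodes:
            assert back.nodes[nid].xyz == tree.nodes[nid].xyz
            assert back.nodes[nid].parent == tree.nodes[nid].parent

    def test_missing_parent_errors(self):
        with pytest.raises(ValueError, match="missing parent"):
            make_tree([(1, 0, 0, 0, -1), (2, 1, 0, 0, 99)])

    def test_multiple_roots_error(self):
        with pytest.raises(ValueError, match="exactly one root"):
            make_tree([(1, 0, 0, 0, -1), (2, 1, 0, 0, -1)])

    def test_non_numeric_field_errors(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 3 0 0 0 1 -1\n2 3 x 0 0 1 1\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_swc(path)

    def test_wrong_column_count_errors(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 3 0 0 0 -1\n")
        with pytest.raises(ValueError, match="7 columns"):
            read_swc(path)

    def test_comments_ignored(self, tmp_path):
        path = tmp_path / "c.swc"
        path.write_text("# header\n1 1 0 0 0 1 -1  # root\n"
                        "2 3 5 0 0 1 1\n")
        assert len(read_swc(path).nodes) == 2


def random_binary_tree(rng, n_nodes=80):
    rows = [(1, 0.0, 0.0, 0.0, -1)]
    n_children = {1: 0}
    for nid in range(2, n_nodes + 1):
        candidates = [i for i, c in n_children.items() if c < 2]
        parent = int(rng.choice(candidates))
        px, py, pz = next(r[1:4] for r in rows if r[0] == parent)
        step = rng.normal(scale=3.0, size=3)
        rows.append((nid, px + step[0], py + step[1], pz + step[2], parent))
        n_children[parent] += 1
        n_children[nid] = 0
    return make_tree(rows)


class TestDecomposeTree:
    def test_y_tree_leaf_mode(self, y_tree):
        bundle = decompose_tree(y_tree, "leaf")
        assert len(bundle) == 2
        for path in bundle.node_paths:
            assert path[0] == y_tree.root
        # both curves share the 51-node stem
        assert bundle.node_paths[0][:51] == bundle.node_paths[1][:51]

    def test_y_tree_node_mode(self, y_tree):
        bundle = decompose_tree(y_tree, "node")
        assert len(bundle) == 3

    def test_leaf_count_oracle_random_trees(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            tree = random_binary_tree(rng)
            bundle = decompose_tree(tree, "leaf")
            assert len(bundle) == len(tree.leaves())

    def test_leaf_mode_covers_every_edge(self):
        tree = random_binary_tree(np.random.default_rng(32))
        covered = set()
        for path in decompose_tree(tree, "leaf").node_paths:
            covered |= set(zip(path, path[1:]))
        expected = {(p, c) for p, c in tree.edges()}
        assert covered == expected

    def test_node_mode_covers_every_edge_exactly_once(self):
        tree = random_binary_tree(np.random.default_rng(33))
        seen = []
        for path in decompose_tree(tree, "node").node_paths:
            seen.extend(zip(path, path[1:]))
        assert len(seen) == len(set(seen)) == len(tree.edges())

    def test_node_mode_conserves_total_length(self):
        tree = random_binary_tree(np.random.default_rng(34))
        bundle = decompose_tree(tree, "node")
        assert sum(c.length for c in bundle.curves) == \
            pytest.approx(tree.total_length(), rel=1e-6)

    def test_longest_mode_covers_every_edge_exactly_once(self):
        tree = random_binary_tree(np.random.default_rng(35))
        seen = []
        for path in decompose_tree(tree, "longest").node_paths:
            seen.extend(zip(path, path[1:]))
        assert len(seen) == len(set(seen)) == len(tree.edges())

    def test_unknown_mode_errors(self, y_tree):
        with pytest.raises(ValueError):
            decompose_tree(y_tree, "spaghetti")


class TestArborLocalScale:
    def test_straight_neurite_all_minimum(self):
        rows = [(1, 0, 0, 0, -1)] + [(i, (i - 1) * 2.0, 0, 0, i - 1)
                                     for i in range(2, 52)]
        tree = make_tree(rows)
        df = arbor_local_3d_scale(tree, max_scale=60.0, n_scales=6)
        grid_min = 1.0
        assert np.allclose(df["local3d_um"].dropna(), grid_min)
        assert "local3d" in tree.annotations

    def test_y_tree_stem_std_zero(self, y_tree):
        df = arbor_local_3d_scale(y_tree, max_scale=60.0, n_scales=6)
        stem = df[df.node_id <= 51]
        # the two root->leaf curves agree on the shared planar stem
        assert (stem["n_curves"] == 2).all()
        assert np.nanmax(stem["local3d_std"]) == pytest.approx(0.0, abs=1e-9)

    def test_mean_close_to_per_curve_values(self, y_tree):
        """>= 80% of nodes within one grid step of their own curve's value."""
        from nadder.geometry import resample_curve, Curve3D
        from nadder.localscale import curve_local_3d_scale
        df = arbor_local_3d_scale(y_tree, max_scale=60.0, n_scales=6)
        merged = dict(zip(df.node_id, df.local3d_um))
        step = np.diff(np.linspace(1, 60, 6))[0]
        ok = total = 0
        for path in decompose_tree(y_tree, "leaf").node_paths:
            curve = resample_curve(Curve3D(y_tree.positions(path)), 1.0)
            prof = curve_local_3d_scale(curve, 60.0, 6)
            node_u = Curve3D(y_tree.positions(path)).arc_length
            idx = np.clip(np.searchsorted(curve.arc_length, node_u), 0,
                          curve.n_points - 1)
            for nid, i in zip(path, idx):
                total += 1
                ok += abs(merged[nid] - prof.values[i]) <= step + 1e-9
        assert ok / total >= 0.8

    def test_short_branch_filtered(self):
        # leaf 3 um from the branch point duplicates its sibling path
        rows = [(1, 0, 0, 0, -1)] + \
               [(i, (i - 1) * 1.0, 0, 0, i - 1) for i in range(2, 32)] + \
               [(i, 30.0 + (i - 31) * 1.0, 2.0, 0, i - 1)
                for i in range(32, 52)] + \
               [(52, 30.0, 1.5, 0, 31), (53, 30.0, 3.0, 0, 52)]
        tree = make_tree(rows)
        df = arbor_local_3d_scale(tree, max_scale=30.0, n_scales=4,
                                  min_branch_length=5.0)
        assert df.loc[df.node_id == 53, "n_curves"].item() == 0


class TestPlaneCrossings:
    def test_single_segment_crossing(self):
        tree = make_tree([(1, -5, 0, 0, -1), (2, 5, 0, 0, 1)])
        rep = plane_crossings(tree, "x", 0.0)
        assert rep.n_crossings == 1

    def test_zigzag_three_crossings(self):
        xs = [-2, 2, -2, 2]
        rows = [(1, xs[0], 0, 0, -1)] + \
               [(i + 1, xs[i], i * 5.0, 0, i) for i in range(1, 4)]
        rep = plane_crossings(make_tree(rows), "x", 0.0)
        assert rep.n_crossings == 3

    def test_touch_without_crossing_not_counted(self):
        tree = make_tree([(1, -5, 0, 0, -1), (2, 0, 1, 0, 1),
                          (3, -5, 2, 0, 2)])
        assert plane_crossings(tree, "x", 0.0).n_crossings == 0

    def test_matches_brute_force_edge_scan(self):
        rng = np.random.default_rng(36)
        tree = random_binary_tree(rng)
        rep = plane_crossings(tree, "z", 0.5)
        brute = sum(
            1 for p, c in tree.edges()
            if (tree.nodes[p].xyz[2] - 0.5) * (tree.nodes[c].xyz[2] - 0.5) < 0)
        assert rep.n_crossings == brute

    def test_window_segments_within_band(self, y_tree):
        rep = plane_crossings(y_tree, "y", 0.0, window=10.0)
        assert rep.window_segments
        for seg in rep.window_segments:
            assert np.all(np.abs(seg.points[:, 1]) <= 10.0)

    def test_bad_axis_errors(self, y_tree):
        with pytest.raises(ValueError):
            plane_crossings(y_tree, "w", 0.0)
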