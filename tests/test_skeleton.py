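"""Skeletonization, pruning, punctate classification, sphere fits,
junction untangling, and geodesic end distances."""

from collections import deque
from itertools import combinations

import numpy as np
import pytest

from conftest import make_tube, random_curved_centerline
from polkadots.preprocess import BinaryVolume
from polkadots.skeleton import (
    NO_END,
    Skeleton,
    _build_graph,
    classify_punctate,
    end_distances,
    filament_length,
    fit_sphere_radius,
    prune_spurs,
    skeleton_from_path,
    skeletonize,
    untangle_junctions,
)


class TestSkeletonize:
    def test_single_voxel(self):
        occ = np.zeros((5, 5, 5), dtype=bool)
        occ[2, 2, 2] = True
        sk = skeletonize(BinaryVolume(occ))
        assert sk.n_nodes == 1 and len(sk.edges) == 0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            skeletonize(BinaryVolume(np.zeros((4, 4, 4), dtype=bool)))

    def test_disconnected_raises(self):
        occ = np.zeros((9, 9, 9), dtype=bool)
        occ[1, 1, 1] = occ[7, 7, 7] = True
        with pytest.raises(ValueError):
            skeletonize(BinaryVolume(occ))

    def test_straight_tube_single_path(self):
        line = np.array([[0.0, 0.0, float(i)] for i in range(30)])
        vol, pts = make_tube(line, radius=2)
        sk = prune_spurs(skeletonize(vol))
        deg = sk.degree
        assert deg.max() <= 2
        assert (deg == 1).sum() == 2
        assert abs(sk.n_nodes - 30) <= 2
        # skeleton nodes lie on the true centerline to within one voxel
        d = np.abs(sk.coords[:, :2] - pts[0, :2]).max()
        assert d <= 1.0

    def test_torus_keeps_one_cycle(self):
        zz, yy, xx = np.mgrid[0:40, 0:40, 0:40]
        d = (np.sqrt((yy - 20) ** 2 + (xx - 20) ** 2) - 12) ** 2 + (zz - 20) ** 2
        sk = skeletonize(BinaryVolume(d <= 16))
        # one cycle: Euler characteristic nodes - edges == 0, no endpoints
        assert sk.n_nodes == len(sk.edges)
        assert len(sk.end_nodes) == 0


def _path_with_spur(main_len=20, spur_len=5):
    path = [[5, 5, i] for i in range(main_len)]
    spur = [[5, 5 + j, main_len // 2] for j in range(1, spur_len + 1)]
    return _build_graph(np.vstack([path, spur]), 25.0), main_len, spur_len


class TestPruneSpurs:
    def test_five_voxel_spur_removed_six_kept(self):
        sk5, main_len, _ = _path_with_spur(spur_len=5)
        assert prune_spurs(sk5).n_nodes == main_len
        sk6, main_len, _ = _path_with_spur(spur_len=6)
        assert prune_spurs(sk6).n_nodes == main_len + 6

    def test_spur_free_path_is_fixpoint(self):
        sk = skeleton_from_path([[0, 0, i] for i in range(4)])
        out = prune_spurs(sk)
        assert out.n_nodes == 4

    def test_nested_spurs_pruned_to_main_path(self):
        # a 4-voxel spur carrying its own 3-voxel side spur: the first pass
        # eats the outer spur, the next pass the rest
        main = [[5, 5, i] for i in range(25)]
        spur = [[5, 5 + j, 12] for j in range(1, 5)]
        spur2 = [[5, 7, 12 + j] for j in range(1, 4)]
        sk = _build_graph(np.vstack([main, spur, spur2]), 25.0)
        out = prune_spurs(sk)
        assert out.n_nodes == 25
        assert out.degree.max() <= 2

    def test_never_disconnects(self, rng):
        line = random_curved_centerline(rng, 60, 8.0)
        vol, _ = make_tube(line, radius=2)
        sk = skeletonize(vol)
        out = prune_spurs(sk)
        # still a single connected component
        from scipy.sparse.csgraph import connected_components

        n, _ = connected_components(out.adjacency(), directed=False)
        assert n == 1


class TestClassifyPunctate:
    @pytest.mark.parametrize("n,expected", [(4, "P"), (6, "filament"),
                                            (100, "filament")])
    def test_node_count_threshold(self, n, expected):
        sk = skeleton_from_path([[0, 0, i] for i in range(n)])
        assert classify_punctate(sk) == expected

    def test_single_voxel_is_punctate(self):
        sk = skeleton_from_path([[3, 3, 3]])
        assert classify_punctate(sk) == "P"


class TestSphereFit:
    def test_circle_radius_exact(self):
        th = np.linspace(0, np.pi / 3, 11)
        pts = np.column_stack([10 * np.cos(th), 10 * np.sin(th), np.zeros(11)])
        assert abs(fit_sphere_radius(pts) - 10.0) < 1e-6

    def test_collinear_returns_infinity(self):
        pts = np.column_stack([np.arange(11.0), 2 * np.arange(11.0),
                               np.zeros(11)])
        assert np.isinf(fit_sphere_radius(pts))

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            fit_sphere_radius(np.zeros((3, 3)))

    def test_noisy_circle_matches_geometric_fit(self):
        from scipy.optimize import least_squares

        local = np.random.default_rng(77)
        th = np.linspace(0, 2 * np.pi / 3, 11)
        pts = np.column_stack([10 * np.cos(th), 10 * np.sin(th), np.zeros(11)])
        pts = pts + local.normal(0, 0.2, pts.shape)

        def geometric(pts):
            c0 = pts.mean(axis=0)

            def resid(p):
                return np.linalg.norm(pts - p[:3], axis=1) - p[3]

            sol = least_squares(resid, np.r_[c0, 10.0])
            return abs(sol.x[3])

        r_alg = fit_sphere_radius(pts, collinear_tol=1e-9)
        r_geo = geometric(pts)
        assert abs(r_alg - r_geo) / r_geo < 0.02


def _has_both_ends(path: Skeleton, ends, tol=2):
    return all(np.min(np.abs(path.coords - e).max(axis=1)) <= tol for e in ends)


class TestUntangle:
    def test_simple_path_unchanged(self):
        sk = skeleton_from_path([[0, 0, i] for i in range(12)])
        paths, res = untangle_junctions(sk)
        assert len(paths) == 1 and res == []
        assert paths[0].n_nodes == 12

    def test_right_angle_crossing_reconstructed(self):
        a = [[20, 20, i] for i in range(10, 31)]
        b = [[20, 10 + j, 20] for j in range(21)]
        sk = _build_graph(np.unique(np.vstack([a, b]), axis=0), 25.0)
        paths, res = untangle_junctions(sk)
        assert sorted(p.n_nodes for p in paths) == [21, 21]
        assert _has_both_ends(paths[0], [a[0], a[-1]]) or \
            _has_both_ends(paths[0], [b[0], b[-1]])
        # the junction voxel is shared by both output paths
        j = np.array([20, 20, 20])
        assert all((np.abs(p.coords - j).max(axis=1) == 0).any() for p in paths)

    def test_crossing_matches_exhaustive_enumeration(self):
        # independent oracle: enumerate the 3 perfect pairings of the 4 arms
        # and score each by the implementation's pair energies
        a = [[20, 20, i] for i in range(10, 31)]
        b = [[20, 10 + j, 20] for j in range(21)]
        sk = _build_graph(np.unique(np.vstack([a, b]), axis=0), 25.0)
        _, res = untangle_junctions(sk)
        assert len(res) == 1
        e = res[0].pair_energies
        pairings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
        best = min(pairings, key=lambda pr: sum(e[p] for p in pr))
        assert set(res[0].selected) == set(best)

    def test_t_junction_joins_collinear_branches(self):
        main = [[20, 20, i] for i in range(10, 31)]
        stub = [[20, 20 + j, 20] for j in range(1, 9)]
        sk = _build_graph(np.vstack([main, stub]), 25.0)
        paths, _ = untangle_junctions(sk)
        sizes = sorted(p.n_nodes for p in paths)
        assert sizes == [8, 21]
        long_path = max(paths, key=lambda p: p.n_nodes)
        assert _has_both_ends(long_path, [main[0], main[-1]])


def _bfs_end_distance(skel: Skeleton):
    nbrs = skel.neighbor_lists()
    dist = np.full(skel.n_nodes, np.inf)
    q = deque()
    for e in skel.end_nodes:
        dist[e] = 0
        q.append(int(e))
    while q:
        u = q.popleft()
        for v in nbrs[u]:
            if dist[v] > dist[u] + 1:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def _random_tree_skeleton(rng, n=50):
    """Random abstract tree; coordinates spread out so geometry is irrelevant."""
    coords = [(0, 0, 0)]
    edges = []
    for i in range(1, n):
        parent = int(rng.integers(i))
        coords.append((i * 3, int(rng.integers(100)), int(rng.integers(100))))
        edges.append((parent, i))
    return Skeleton(np.array(coords), np.array(edges), 25.0)


class TestEndDistances:
    def test_endpoints_zero(self):
        sk = skeleton_from_path([[0, 0, i] for i in range(7)])
        d = end_distances(sk)
        assert d[0] == 0 and d[-1] == 0

    def test_center_of_eleven_node_path(self):
        sk = skeleton_from_path([[0, 0, i] for i in range(11)])
        d = end_distances(sk)
        assert d[5] == 5

    def test_random_tree_matches_bfs_oracle(self, rng):
        for _ in range(5):
            sk = _random_tree_skeleton(rng)
            np.testing.assert_array_equal(end_distances(sk),
                                          _bfs_end_distance(sk))

    def test_cycle_gets_no_end_sentinel(self):
        n = 12
        coords = [[0, int(10 * np.cos(2 * np.pi * i / n)) + 20,
                   int(10 * np.sin(2 * np.pi * i / n)) + 20] for i in range(n)]
        edges = [(i, (i + 1) % n) for i in range(n)]
        sk = Skeleton(np.array(coords), np.array(edges), 25.0)
        assert np.all(end_distances(sk) == NO_END)

    def test_one_lipschitz_along_edges(self, rng):
        line = random_curved_centerline(rng, 80, 8.0)
        vol, _ = make_tube(line, radius=2)
        sk = prune_spurs(skeletonize(vol))
        d = end_distances(sk)
        for a, b in sk.edges:
            assert abs(d[a] - d[b]) <= 1.0 + 1e-12


class TestFilamentLength:
    def test_single_node_zero(self):
        lv, nm = filament_length(skeleton_from_path([[1, 1, 1]]))
        assert lv == 0 and nm == 0

    def test_41_node_path_is_one_micron(self):
        sk = skeleton_from_path([[0, 0, i] for i in range(41)])
        lv, nm = filament_length(sk)
        assert lv == 40
        assert nm == pytest.approx(1000.0)

    def test_branched_input_raises(self):
        sk, *_ = _path_with_spur(spur_len=8)
        with pytest.raises(ValueError):
            filament_length(sk)

    def test_curved_filament_within_ten_percent_of_truth(self, rng):
        from polkadots.contacts import measure_structure

        for _ in range(5):
            L = int(rng.uniform(40, 120))
            line = random_curved_centerline(rng, L, 6.0)
            vol, _ = make_tube(line, radius=2)
            m = measure_structure(vol)
            assert abs(m.length_nm / 25.0 - L) / L < 0.10
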