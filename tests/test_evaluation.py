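"""Bundle measures, overlap metrics, connectomes, and graph summaries,
each checked against small exhaustive oracles."""

import itertools

import numpy as np
import pytest

from cornn.evaluation import (
    Connectome,
    build_connectome,
    bundle_adjacency,
    bundle_measures,
    connectome_correlation,
    graph_measures,
    mdf,
    percent_difference,
    resample_streamline,
    traversal_mask,
    voxel_dice,
)
from cornn.grids import ImageGrid


@pytest.fixture
def grid2mm():
    return ImageGrid(np.zeros((20, 20, 20, 1)), np.diag([2.0, 2.0, 2.0, 1.0]))


def _line(start, end, n):
    return np.linspace(start, end, n)


class TestBundleMeasures:
    def test_straight_ten_point_streamline(self, grid2mm):
        s = _line([4.0, 10, 10], [13.0, 10, 10], 10)  # 9 mm, gamma = 1
        m = bundle_measures([s], grid2mm)
        assert np.isclose(m.mean_length, 9.0)
        assert np.isclose(m.mean_span, 9.0)
        assert m.streamline_count == 1

    def test_span_below_length_for_curved(self, grid2mm):
        t = np.linspace(0, np.pi, 30)
        s = np.stack([10 + 5 * np.cos(t), 10 + 5 * np.sin(t), np.full(30, 10.0)],
                     axis=1)
        m = bundle_measures([s], grid2mm)
        assert m.mean_span < m.mean_length

    def test_volume_counts_traversed_voxels(self, grid2mm):
        # along-x path through exactly 5 voxel centers at 2 mm -> 40 mm^3
        s = _line([8.0, 10.0, 10.0], [16.0, 10.0, 10.0], 9)
        m = bundle_measures([s], grid2mm)
        assert np.isclose(m.volume, 5 * 8.0)

    def test_single_voxel_surface_area(self, grid2mm):
        s = np.array([[10.0, 10.0, 10.0], [10.4, 10.0, 10.0]])
        m = bundle_measures([s], grid2mm)
        assert np.isclose(m.surface_area, 6 * 4.0)  # 6 faces x (2 mm)^2

    def test_empty_bundle_flagged(self, grid2mm):
        m = bundle_measures([], grid2mm)
        assert m.streamline_count == 0
        assert np.isnan(m.mean_length)


class TestDice:
    def test_identical_bundles(self, grid2mm, rng):
        b = [np.cumsum(rng.standard_normal((10, 3)), axis=0) + 20]
        assert voxel_dice(b, b, grid2mm) == 1.0

    def test_disjoint_masks(self, grid2mm):
        a = [_line([4.0, 4, 4], [10.0, 4, 4], 5)]
        b = [_line([4.0, 30, 30], [10.0, 30, 30], 5)]
        assert voxel_dice(a, b, grid2mm) == 0.0

    def test_half_overlap_arithmetic(self, grid2mm):
        # masks of 4 and 4 voxels overlapping in 2 -> dice 0.5
        a = [_line([8.0, 10.0, 10.0], [14.0, 10.0, 10.0], 7)]  # voxels x=4..7
        b = [_line([12.0, 10.0, 10.0], [18.0, 10.0, 10.0], 7)]  # voxels x=6..9
        assert np.isclose(voxel_dice(a, b, grid2mm), 0.5)

    def test_symmetry(self, grid2mm, rng):
        a = [np.cumsum(rng.standard_normal((8, 3)), axis=0) + 20]
        b = [np.cumsum(rng.standard_normal((8, 3)), axis=0) + 20]
        assert voxel_dice(a, b, grid2mm) == voxel_dice(b, a, grid2mm)


class TestBundleAdjacency:
    def test_self_distance_zero(self, rng):
        b = [np.cumsum(rng.standard_normal((12, 3)), axis=0) for _ in range(4)]
        assert bundle_adjacency(b, b) == 0.0

    def test_parallel_offset(self):
        a = [_line([0.0, 0, 0], [10.0, 0, 0], 11)]
        b = [_line([0.0, 2.0, 0], [10.0, 2.0, 0], 11)]
        assert np.isclose(bundle_adjacency(a, b), 2.0)

    def test_flip_invariance_of_mdf(self, rng):
        a = resample_streamline(np.cumsum(rng.standard_normal((9, 3)), 0), 20)
        b = resample_streamline(np.cumsum(rng.standard_normal((9, 3)), 0), 20)
        assert np.isclose(mdf(a, b), mdf(a, b[::-1]))

    def test_matches_double_loop_oracle(self, rng):
        bundle_a = [np.cumsum(rng.standard_normal((7, 3)), 0) for _ in range(5)]
        bundle_b = [np.cumsum(rng.standard_normal((9, 3)), 0) for _ in range(4)]
        got = bundle_adjacency(bundle_a, bundle_b, n_resample=15)
        ra = [resample_streamline(s, 15) for s in bundle_a]
        rb = [resample_streamline(s, 15) for s in bundle_b]
        d = np.array([[mdf(x, y) for y in rb] for x in ra])
        expected = 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())
        assert abs(got - expected) < 1e-9

    def test_symmetry(self, rng):
        a = [np.cumsum(rng.standard_normal((7, 3)), 0) for _ in range(3)]
        b = [np.cumsum(rng.standard_normal((7, 3)), 0) for _ in range(3)]
        assert np.isclose(bundle_adjacency(a, b), bundle_adjacency(b, a))


class TestConnectome:
    def _parcels(self):
        p = np.zeros((20, 20, 20), dtype=np.int64)
        p[0:3] = 1  # x in [0, 6) mm
        p[17:20] = 2  # x in [34, 40) mm
        p[:, 0:3] = 3
        return p

    def test_count_and_mean_length(self, grid2mm):
        parcels = self._parcels()
        tract = [
            _line([2.0, 20, 20], [36.0, 20, 20], 11),  # parcel 1 -> 2
            _line([2.0, 22, 20], [36.0, 22, 20], 21),
            _line([2.0, 24, 20], [36.0, 24, 20], 31),
        ]
        c = build_connectome(tract, parcels, grid2mm)
        i, j = list(c.labels).index(1), list(c.labels).index(2)
        assert c.count_matrix[i, j] == 3
        assert np.isclose(c.length_matrix[i, j], 34.0)
        assert np.array_equal(c.count_matrix, c.count_matrix.T)
        assert np.all(np.diag(c.count_matrix) == 0)

    def test_same_parcel_endpoints_excluded(self, grid2mm):
        parcels = self._parcels()
        loop = _line([2.0, 20, 20], [4.0, 20, 20], 5)  # both ends in parcel 1
        c = build_connectome([loop], parcels, grid2mm)
        assert c.count_matrix.sum() == 0

    def test_unlabeled_endpoint_dropped(self, grid2mm):
        parcels = self._parcels()
        s = _line([2.0, 20, 20], [20.0, 20, 20], 7)  # one end unlabeled
        c = build_connectome([s], parcels, grid2mm)
        assert c.count_matrix.sum() == 0

    def test_empty_tractogram(self, grid2mm):
        c = build_connectome([], self._parcels(), grid2mm)
        assert c.count_matrix.sum() == 0


class TestConnectomeCorrelation:
    def _conn(self, m):
        m = np.asarray(m, dtype=float)
        return Connectome(labels=np.arange(len(m)), count_matrix=m,
                          length_matrix=m)

    def test_self_correlation_is_one(self, rng):
        m = rng.integers(0, 10, (5, 5))
        m = np.triu(m, 1) + np.triu(m, 1).T
        assert np.isclose(connectome_correlation(self._conn(m), self._conn(m)), 1.0)

    def test_affine_invariance(self, rng):
        m = rng.integers(0, 10, (5, 5))
        m = np.triu(m, 1) + np.triu(m, 1).T
        assert np.isclose(
            connectome_correlation(self._conn(m), self._conn(2 * m + 5)), 1.0
        )

    def test_matches_textbook_formula(self, rng):
        a = rng.integers(0, 20, (6, 6))
        b = rng.integers(0, 20, (6, 6))
        a = np.triu(a, 1) + np.triu(a, 1).T
        b = np.triu(b, 1) + np.triu(b, 1).T
        got = connectome_correlation(self._conn(a), self._conn(b))
        iu = np.triu_indices(6, 1)
        x, y = a[iu].astype(float), b[iu].astype(float)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / (
            np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
        )
        assert abs(got - expected) < 1e-12

    def test_zero_variance_flagged(self):
        m = np.zeros((4, 4))
        assert np.isnan(connectome_correlation(self._conn(m), self._conn(m)))


def _exhaustive_modularity(w):
    """Max Newman modularity over all partitions of <= 8 nodes."""
    n = len(w)
    m2 = w.sum()  # = 2m
    k = w.sum(axis=1)
    best = -np.inf
    # enumerate set partitions via restricted growth strings
    def partitions(i, groups):
        if i == n:
            yield groups
            return
        for g in range(len(groups)):
            yield from partitions(i + 1, [s | {i} if j == g else s
                                          for j, s in enumerate(groups)])
        yield from partitions(i + 1, groups + [{i}])

    for part in partitions(1, [{0}]):
        q = 0.0
        for s in part:
            for i in s:
                for j in s:
                    q += w[i, j] - k[i] * k[j] / m2
        best = max(best, q / m2)
    return best


class TestGraphMeasures:
    def test_two_cliques_modularity_half(self):
        w = np.zeros((6, 6))
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i, j in itertools.combinations(grp, 2):
                w[i, j] = w[j, i] = 1.0
        c = Connectome(labels=np.arange(6), count_matrix=w, length_matrix=w)
        got = graph_measures(c)
        assert np.isclose(got["max_modularity"], 0.5, atol=1e-9)
        assert np.isclose(got["max_modularity"], _exhaustive_modularity(w), atol=1e-9)

    def test_modularity_matches_exhaustive_on_random_graph(self, rng):
        n = 6
        w = (rng.random((n, n)) > 0.5).astype(float)
        w = np.triu(w, 1)
        w = w + w.T
        w[0, 1] = w[1, 0] = 1.0  # ensure at least one edge
        c = Connectome(labels=np.arange(n), count_matrix=w, length_matrix=w)
        got = graph_measures(c)["max_modularity"]
        assert got <= _exhaustive_modularity(w) + 1e-9
        assert got >= _exhaustive_modularity(w) - 0.05  # heuristic near-optimal

    def test_path_graph_betweenness_and_cpl(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        c = Connectome(labels=np.arange(3), count_matrix=w, length_matrix=w)
        got = graph_measures(c)
        # middle node lies on the single 0-2 shortest path; normalized
        # betweenness over (n-1)(n-2)/2 = 1 pair -> mean (0 + 1 + 0) / 3
        assert np.isclose(got["avg_betweenness_centrality"], 1.0 / 3.0)
        assert np.isclose(got["characteristic_path_length"], 4.0 / 3.0)

    def test_complete_unit_graph_cpl_one(self):
        n = 5
        w = np.ones((n, n)) - np.eye(n)
        c = Connectome(labels=np.arange(n), count_matrix=w, length_matrix=w)
        assert np.isclose(graph_measures(c)["characteristic_path_length"], 1.0)

    def test_empty_graph_flagged(self):
        c = Connectome(labels=np.array([]), count_matrix=np.zeros((0, 0)),
                       length_matrix=np.zeros((0, 0)))
        got = graph_measures(c)
        assert np.isnan(got["max_modularity"])


class TestPercentDifference:
    @pytest.mark.parametrize("x,ref,expected", [(5.0, 5.0, 0.0),
                                                (7.5, 5.0, 50.0),
                                                (4.25, 5.0, 15.0)])
    def test_values(self, x, ref, expected):
        assert np.isclose(percent_difference(x, ref), expected)

    def test_zero_reference_flagged(self):
        assert np.isnan(percent_difference(1.0, 0.0))
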