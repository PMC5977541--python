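"""Architecture feature families: tessellation, tree, neighbor, cluster-graph
and orientation co-occurrence statistics, with independent geometric oracles."""

import itertools

import numpy as np
import pytest

from nucmorph.architecture import (
    CCGParams,
    architecture_feature_names,
    architecture_vector,
    build_ccg,
    ccg_features,
    core_features,
    delaunay_features,
    kth_nn_distances,
    mst_edge_lengths,
    mst_features,
    neighbor_counts_within,
    nn_features,
    voronoi_features,
)
from nucmorph.errors import UndefinedFeatureError
from nucmorph.synthetic import SyntheticPhenotype, synthesize_patch
from nucmorph.types import NucleusRecord


def unit_grid(n, origin=1.0):
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    return np.column_stack([xs.ravel() + origin, ys.ravel() + origin])


# ---------------------------------------------------------------------------
# Voronoi
# ---------------------------------------------------------------------------

class TestVoronoi:
    def test_unit_grid_interior_cells_are_congruent(self):
        feats = voronoi_features(unit_grid(6), (0, 0, 7, 7))
        assert feats[:4] == pytest.approx([1.0, 0.0, 1.0, 0.0])  # area statset
        assert feats[4:8] == pytest.approx([4.0, 0.0, 1.0, 0.0])  # perimeter

    def test_jitter_increases_area_disorder(self, rng):
        grid = unit_grid(8)
        jittered = grid + rng.uniform(-0.25, 0.25, size=grid.shape)
        regular = voronoi_features(grid, (0, 0, 9, 9))
        noisy = voronoi_features(jittered, (0, 0, 9, 9))
        assert noisy[3] > regular[3]

    def test_collinear_points_are_undefined(self):
        pts = np.column_stack([np.arange(6, dtype=float), np.zeros(6)])
        with pytest.raises(UndefinedFeatureError):
            voronoi_features(pts, (0, 0, 10, 10))


# ---------------------------------------------------------------------------
# Delaunay
# ---------------------------------------------------------------------------

class TestDelaunay:
    def test_unit_right_triangle_side_lengths(self):
        pts = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        feats = delaunay_features(pts)
        assert feats[0] == pytest.approx((2 + np.sqrt(2)) / 3)
        assert feats[4] == pytest.approx(0.5)  # single triangle area

    @pytest.mark.parametrize("seed", range(10))
    def test_triangle_count_obeys_euler_relation(self, seed):
        # number of Delaunay triangles = 2n - 2 - h (h = hull vertices)
        import scipy.spatial as spatial

        rng = np.random.default_rng(seed)
        pts = rng.random((rng.integers(5, 30), 2)) * 100
        tri = spatial.Delaunay(pts)
        h = len(spatial.ConvexHull(pts).vertices)
        assert len(tri.simplices) == 2 * len(pts) - 2 - h

    def test_equilateral_lattice_has_zero_side_disorder(self):
        # rhombic patch of the triangular lattice: every triangle incl. the
        # hull ones is equilateral
        rows = []
        for i in range(5):
            for j in range(5):
                rows.append([j + 0.5 * i, i * np.sqrt(3) / 2])
        feats = delaunay_features(np.array(rows))
        assert feats[3] <= 1e-9


# ---------------------------------------------------------------------------
# MST
# ---------------------------------------------------------------------------

def _prufer_tree_length(pts, seq):
    """Total edge length of the labeled tree decoded from a Prufer sequence."""
    n = len(pts)
    degree = np.ones(n, dtype=int)
    for v in seq:
        degree[v] += 1
    total = 0.0
    seq = list(seq)
    leaves = sorted(i for i in range(n) if degree[i] == 1)
    import heapq

    heapq.heapify(leaves)
    for v in seq:
        leaf = heapq.heappop(leaves)
        total += float(np.hypot(*(pts[leaf] - pts[v])))
        degree[leaf] -= 1
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, v)
    u, v = [i for i in range(n) if degree[i] == 1][:2]
    total += float(np.hypot(*(pts[u] - pts[v])))
    return total


def exhaustive_mst_length(pts):
    """Minimum spanning tree length by enumerating all n^(n-2) labeled trees."""
    n = len(pts)
    if n == 2:
        return float(np.hypot(*(pts[0] - pts[1])))
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        best = min(best, _prufer_tree_length(pts, seq))
    return best


class TestMST:
    def test_collinear_unit_spacing(self):
        pts = np.array([[0, 0], [1, 0], [2, 0]], dtype=float)
        assert mst_features(pts) == pytest.approx([1.0, 0.0, 1.0, 0.0])

    def test_edge_count_is_n_minus_one(self, rng):
        pts = rng.random((15, 2)) * 50
        assert len(mst_edge_lengths(pts)) == 14

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_spanning_tree_minimum(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((int(rng.integers(3, 7)), 2)) * 100
        assert np.sum(mst_edge_lengths(pts)) == pytest.approx(
            exhaustive_mst_length(pts), rel=1e-9
        )


# ---------------------------------------------------------------------------
# Nearest neighbors
# ---------------------------------------------------------------------------

class TestNearestNeighbors:
    def test_grid_counts_and_low_disorder(self):
        pts = unit_grid(10)
        counts = neighbor_counts_within(pts, 1.5)
        interior = counts[
            (pts[:, 0] > 1) & (pts[:, 0] < 10) & (pts[:, 1] > 1) & (pts[:, 1] < 10)
        ]
        assert np.all(interior == interior[0])
        feats = nn_features(pts, (0, 0, 11, 11))
        assert feats[2] <= 0.1  # disorder of counts in the 10 px radius

    def test_radius_below_minimal_spacing_gives_zero_counts(self):
        pts = unit_grid(4) * 30
        feats = nn_features(pts, (0, 0, 200, 200))
        assert feats[0] == 0.0  # 10 px radius: no neighbors within reach

    def test_third_neighbor_distance_on_grid_interior(self):
        pts = unit_grid(10)
        d3 = kth_nn_distances(pts, 3)
        interior = (pts[:, 0] > 1) & (pts[:, 0] < 10) & (pts[:, 1] > 1) & (pts[:, 1] < 10)
        assert np.all(d3[interior] == pytest.approx(1.0))

    def test_too_few_points_is_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            nn_features(unit_grid(2), (0, 0, 10, 10))


# ---------------------------------------------------------------------------
# Cell cluster graph
# ---------------------------------------------------------------------------

class TestCCG:
    def test_edge_rule_at_defaults(self):
        # d^(-0.5) > 0.2 iff d < 25 px
        near = build_ccg(np.array([[0.0, 0.0], [10.0, 0.0]]))
        far = build_ccg(np.array([[0.0, 0.0], [100.0, 0.0]]))
        assert len(near.edges) == 1
        assert len(far.edges) == 0
        assert CCGParams().distance_threshold == pytest.approx(25.0)

    def test_deterministic(self, rng):
        pts = rng.random((30, 2)) * 200
        g1, g2 = build_ccg(pts), build_ccg(pts)
        assert np.array_equal(g1.edges, g2.edges)

    def test_triangle_graph_statistics(self):
        g = build_ccg(np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 8.0]]))
        feats = ccg_features(g)
        names = architecture_feature_names()[51:90]
        stats = dict(zip(names, feats))
        assert stats["CCG: Clustering Coefficient C"] == 1.0
        assert stats["CCG: Clustering Coefficient D"] == 1.0
        assert stats["CCG: Clustering Coefficient E"] == 1.0
        assert stats["CCG: diameter"] == 1.0

    def test_path_graph_statistics(self):
        g = build_ccg(np.array([[0.0, 0.0], [20.0, 0.0], [40.0, 0.0]]))
        feats = dict(zip(architecture_feature_names()[51:90], ccg_features(g)))
        assert feats["CCG: Clustering Coefficient C"] == 0.0
        assert feats["CCG: number of end nodes"] == 2.0
        assert feats["CCG: number of central nodes"] == 1.0

    def test_isolated_nodes(self):
        pts = np.array([[0, 0], [100, 0], [0, 100], [100, 100], [200, 200]], dtype=float)
        feats = dict(zip(architecture_feature_names()[51:90], ccg_features(build_ccg(pts))))
        assert feats["CCG: number of connected components"] == 5.0
        assert feats["CCG: fraction of isolated nodes"] == 1.0
        assert feats["CCG: graph density"] == 0.0


# ---------------------------------------------------------------------------
# Orientation co-occurrence
# ---------------------------------------------------------------------------

def _oriented_nuclei(orientations, spacing=10.0):
    t = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    nuclei = []
    for i, ang in enumerate(orientations):
        cx, cy = (i % 5) * spacing + 20, (i // 5) * spacing + 20
        nuclei.append(
            NucleusRecord(
                id=i + 1,
                boundary=np.column_stack([cx + 5 * np.cos(t), cy + 5 * np.sin(t)]),
                orientation_deg=float(ang),
            )
        )
    return nuclei


class TestCOrE:
    def test_identical_orientations_are_perfectly_ordered(self):
        nuclei = _oriented_nuclei([45.0] * 10)
        feats = core_features(nuclei)
        names = architecture_feature_names()[90:116]
        stats = dict(zip(names, feats))
        assert stats["COrE: Entropy (CCG)"] == 0.0
        assert stats["COrE: Energy (CCG)"] == 1.0
        assert stats["COrE: Contrast Energy (CCG)"] == 0.0

    def test_uniform_orientations_approach_max_entropy(self, rng):
        # uniform bins on a dense proximity graph: entropy near log2(64)
        n = 500
        orientations = rng.uniform(0, 180, n)
        t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        nuclei = []
        for i in range(n):
            cx, cy = rng.uniform(20, 80), rng.uniform(20, 80)
            nuclei.append(
                NucleusRecord(
                    id=i + 1,
                    boundary=np.column_stack([cx + 2 * np.cos(t), cy + 2 * np.sin(t)]),
                    orientation_deg=float(orientations[i]),
                )
            )
        feats = dict(zip(architecture_feature_names()[90:116], core_features(nuclei)))
        assert feats["COrE: Entropy (40 Pixel Radius)"] == pytest.approx(6.0, rel=0.05)

    def test_coherent_patches_have_lower_entropy(self):
        from dataclasses import replace

        coherent = SyntheticPhenotype(orientation_kappa=8.0, axis_ratio_mean=1.8)
        incoherent = replace(coherent, orientation_kappa=0.0)
        wins = total = 0
        for seed in range(100):
            pc, _ = synthesize_patch(coherent, 448, "a", "p", np.random.default_rng(seed))
            pi, _ = synthesize_patch(incoherent, 448, "a", "p", np.random.default_rng(seed))
            nc = pc.compartment_nuclei("epithelial")
            ni = pi.compartment_nuclei("epithelial")
            if len(nc) < 5 or len(ni) < 5:
                continue
            total += 1
            wins += core_features(nc)[8] < core_features(ni)[8]
        assert total >= 90
        assert wins / total >= 0.95


# ---------------------------------------------------------------------------
# Full vector and invariances
# ---------------------------------------------------------------------------

def _grid_nuclei(n=5, spacing=18.0, offset=30.0, jitter=0.0, seed=0):
    t = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    jrng = np.random.default_rng(seed)
    nuclei = []
    for i in range(n * n):
        cx = (i % n) * spacing + offset + jrng.uniform(-jitter, jitter)
        cy = (i // n) * spacing + offset + jrng.uniform(-jitter, jitter)
        nuclei.append(
            NucleusRecord(
                id=i + 1,
                boundary=np.column_stack([cx + 5 * np.cos(t), cy + 5 * np.sin(t)]),
                orientation_deg=float((i * 37) % 180),
            )
        )
    return nuclei


class TestArchitectureVector:
    def test_length_and_names(self):
        names = architecture_feature_names()
        assert len(names) == 116
        assert len(set(names)) == 116
        vec = architecture_vector(_grid_nuclei(), (0, 0, 200, 200))
        assert vec.shape == (116,)
        assert np.isfinite(vec).all()

    def test_below_min_nuclei_is_all_nan(self):
        vec = architecture_vector(_grid_nuclei()[:4], (0, 0, 200, 200))
        assert np.isnan(vec).all()

    def test_deterministic(self):
        nuclei = _grid_nuclei()
        v1 = architecture_vector(nuclei, (0, 0, 200, 200))
        v2 = architecture_vector(nuclei, (0, 0, 200, 200))
        assert np.array_equal(v1, v2)

    def test_translation_invariance(self):
        # jittered grid: a perfectly cocircular grid makes the Delaunay
        # triangulation non-unique, which is a tie case, not a shift effect
        nuclei = _grid_nuclei(jitter=2.0)
        base = architecture_vector(nuclei, (0, 0, 200, 200))
        shifted = [
            NucleusRecord(
                id=n.id, boundary=n.boundary + np.array([7.0, -5.0]),
                orientation_deg=n.orientation_deg,
            )
            for n in nuclei
        ]
        moved = architecture_vector(shifted, (7.0, -5.0, 207.0, 195.0))
        assert np.allclose(base, moved, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("angle_deg", [90.0, 33.0])
    def test_rotation_invariance_of_length_statistics(self, rng, angle_deg):
        pts = rng.random((40, 2)) * 150 + 20
        th = np.radians(angle_deg)
        rot = pts @ np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]).T
        for fn in (mst_features, delaunay_features):
            assert np.allclose(fn(pts), fn(rot), rtol=1e-6)
        g1, g2 = build_ccg(pts), build_ccg(rot)
        assert np.allclose(np.sort(g1.lengths), np.sort(g2.lengths), rtol=1e-6)
        c1 = neighbor_counts_within(pts, 40.0)
        c2 = neighbor_counts_within(rot, 40.0)
        assert np.array_equal(np.sort(c1), np.sort(c2))
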