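"""Nuclear architecture features (116 per compartment).

Families, in catalog order:

* Voronoi diagram statistics (12): cell area, cell perimeter, cell chord
  length, each summarized as mean / std / min-max ratio / disorder over
  the cells lying strictly inside the patch.
* Delaunay triangulation statistics (8): edge length and triangle area.
* Minimum spanning tree statistics (4): Euclidean MST edge lengths.
* Nearest-neighbor / density statistics (27): neighbor counts within
  10..50 px radii, distance to the 3rd/5th/7th nearest neighbor,
  global density and 1-NN distance.
* Cell cluster graph statistics (39): a sparse graph connecting nuclei
  by a distance-decay rule, summarized by degree, eccentricity, path,
  clustering, component, edge-length, and adjacency-spectrum measures.
* Cell orientation co-occurrence entropy (26): second-order statistics
  of the co-occurrence of quantized nuclear orientations among
  neighboring nuclei, for the CCG edge set and a 40 px proximity graph.

All operations are deterministic. Coincident centroids (closer than
1e-6 px) are merged before any graph construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.spatial as spatial
from scipy.sparse.csgraph import minimum_spanning_tree

from nucmorph.errors import UndefinedFeatureError
from nucmorph.stats import disorder, minmax_ratio, statset
from nucmorph.types import NucleusRecord

logger = logging.getLogger(__name__)

NN_RADII_PX = (10, 20, 30, 40, 50)
NN_KS = (3, 5, 7)
N_ORIENTATION_BINS = 8  # 22.5 degree bins on [0, 180)
CORE_PROXIMITY_RADIUS_PX = 40.0
MIN_NUCLEI = 5


@dataclass(frozen=True)
class CCGParams:
    """Cell-cluster-graph construction: connect u,v iff d(u,v)^(-alpha) > r.

    Equivalently d(u,v) < r^(-1/alpha); at the defaults alpha=0.5, r=0.2
    nuclei closer than 25 px are connected.
    """

    alpha: float = 0.5
    r: float = 0.2

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (0 < self.r < 1):
            raise ValueError("r must lie in (0, 1)")

    @property
    def distance_threshold(self) -> float:
        return self.r ** (-1.0 / self.alpha)


@dataclass(frozen=True)
class NeighborGraph:
    """Undirected graph on centroid indices with Euclidean edge lengths."""

    n_vertices: int
    edges: np.ndarray  # (m, 2) int index pairs, u < v
    lengths: np.ndarray  # (m,) float

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        for (u, v), w in zip(self.edges, self.lengths):
            g.add_edge(int(u), int(v), length=float(w))
        return g


def merge_coincident(centroids: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Drop points closer than `tol` to an earlier point (logged)."""
    pts = np.asarray(centroids, dtype=float)
    if len(pts) < 2:
        return pts
    tree = spatial.cKDTree(pts)
    pairs = tree.query_pairs(r=tol)
    if not pairs:
        return pts
    drop = {max(u, v) for u, v in pairs}
    logger.info("merged %d coincident centroid(s)", len(drop))
    return pts[[i for i in range(len(pts)) if i not in drop]]


# ---------------------------------------------------------------------------
# Voronoi / Delaunay / MST
# ---------------------------------------------------------------------------

def _interior_voronoi_cells(pts: np.ndarray, bounds) -> list[np.ndarray]:
    xmin, ymin, xmax, ymax = bounds
    try:
        vor = spatial.Voronoi(pts)
    except Exception as exc:  # QhullError on degenerate input
        raise UndefinedFeatureError(f"degenerate Voronoi diagram: {exc}") from exc
    cells = []
    for region_idx in vor.point_region:
        region = vor.regions[region_idx]
        if not region or -1 in region:
            continue
        verts = vor.vertices[region]
        if (
            np.all(verts[:, 0] > xmin)
            and np.all(verts[:, 0] < xmax)
            and np.all(verts[:, 1] > ymin)
            and np.all(verts[:, 1] < ymax)
        ):
            cells.append(verts)
    return cells


def _polygon_area_perimeter(verts: np.ndarray) -> tuple[float, float]:
    x, y = verts[:, 0], verts[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    perim = float(np.sum(np.hypot(np.diff(x, append=x[0]), np.diff(y, append=y[0]))))
    return float(area), perim


def voronoi_features(centroids: np.ndarray, bounds) -> list[float]:
    """12 statistics over Voronoi cells strictly inside `bounds` (xmin, ymin, xmax, ymax).

    Cells touching or crossing the patch boundary are dropped: clipped or
    unbounded cells would bias the area statistics.
    """
    pts = merge_coincident(centroids)
    if len(pts) < 5:
        raise UndefinedFeatureError("Voronoi features need >= 5 centroids")
    cells = _interior_voronoi_cells(pts, bounds)
    if len(cells) < 5:
        raise UndefinedFeatureError(
            f"only {len(cells)} interior Voronoi cells (need >= 5)"
        )
    areas, perims, chords = [], [], []
    for verts in cells:
        a, p = _polygon_area_perimeter(verts)
        areas.append(a)
        perims.append(p)
        d = spatial.distance.pdist(verts)
        chords.extend(d.tolist())
    out = []
    for vals in (areas, perims, chords):
        out.extend(statset(vals).as_tuple())
    return out


def delaunay_features(centroids: np.ndarray) -> list[float]:
    """8 statistics: Delaunay edge lengths and triangle areas."""
    pts = merge_coincident(centroids)
    if len(pts) < 3:
        raise UndefinedFeatureError("Delaunay features need >= 3 centroids")
    try:
        tri = spatial.Delaunay(pts)
    except Exception as exc:
        raise UndefinedFeatureError(f"degenerate Delaunay triangulation: {exc}") from exc
    if len(tri.simplices) == 0:
        raise UndefinedFeatureError("empty Delaunay triangulation")
    edges = set()
    areas = []
    for simplex in tri.simplices:
        a, b, c = pts[simplex]
        u, v = b - a, c - a
        areas.append(0.5 * abs(u[0] * v[1] - u[1] * v[0]))
        for i in range(3):
            u, v = sorted((simplex[i], simplex[(i + 1) % 3]))
            edges.add((u, v))
    lengths = [float(np.hypot(*(pts[u] - pts[v]))) for u, v in sorted(edges)]
    return list(statset(lengths).as_tuple()) + list(statset(areas).as_tuple())


def mst_edge_lengths(centroids: np.ndarray) -> np.ndarray:
    """Edge lengths of the exact Euclidean MST over the complete graph."""
    pts = merge_coincident(centroids)
    if len(pts) < 2:
        raise UndefinedFeatureError("MST needs >= 2 centroids")
    dist = spatial.distance.squareform(spatial.distance.pdist(pts))
    mst = minimum_spanning_tree(sp.csr_matrix(dist))
    lengths = np.asarray(mst[mst.nonzero()]).ravel()
    return np.sort(lengths)


def mst_features(centroids: np.ndarray) -> list[float]:
    """4 statistics of Euclidean MST edge lengths."""
    return list(statset(mst_edge_lengths(centroids)).as_tuple())


# ---------------------------------------------------------------------------
# Nearest neighbors / density
# ---------------------------------------------------------------------------

def neighbor_counts_within(pts: np.ndarray, radius: float) -> np.ndarray:
    """Per-point number of other points within `radius` (exclusive of self)."""
    tree = spatial.cKDTree(pts)
    counts = tree.query_ball_point(pts, r=radius, return_length=True)
    return np.asarray(counts) - 1


def kth_nn_distances(pts: np.ndarray, k: int) -> np.ndarray:
    """Per-point Euclidean distance to the k-th nearest other point."""
    tree = spatial.cKDTree(pts)
    dist, _ = tree.query(pts, k=k + 1)
    return dist[:, k]


def nn_features(centroids: np.ndarray, bounds) -> list[float]:
    """27 nearest-neighbor and density statistics.

    (a) neighbor counts within 10/20/30/40/50 px: mean, std, disorder;
    (b) distance to the 3rd/5th/7th nearest neighbor: mean, std, disorder;
    (c) density n/area, mean and std of the 1-NN distance.
    """
    pts = merge_coincident(centroids)
    if len(pts) < max(NN_KS) + 1:
        raise UndefinedFeatureError(
            f"nearest-neighbor features need >= {max(NN_KS) + 1} centroids"
        )
    out = []
    for r in NN_RADII_PX:
        counts = neighbor_counts_within(pts, float(r)).astype(float)
        out.extend([float(np.mean(counts)), float(np.std(counts)), disorder(counts)])
    for k in NN_KS:
        d = kth_nn_distances(pts, k)
        out.extend([float(np.mean(d)), float(np.std(d)), disorder(d)])
    xmin, ymin, xmax, ymax = bounds
    area = (xmax - xmin) * (ymax - ymin)
    d1 = kth_nn_distances(pts, 1)
    out.extend([len(pts) / area, float(np.mean(d1)), float(np.std(d1))])
    return out


# ---------------------------------------------------------------------------
# Cell cluster graph
# ---------------------------------------------------------------------------

def build_proximity_graph(centroids: np.ndarray, radius: float) -> NeighborGraph:
    """Graph connecting all centroid pairs closer than `radius`."""
    pts = merge_coincident(centroids)
    tree = spatial.cKDTree(pts)
    pairs = sorted(tree.query_pairs(r=radius))
    edges = np.array(pairs, dtype=int).reshape(-1, 2)
    lengths = (
        np.hypot(*(pts[edges[:, 0]] - pts[edges[:, 1]]).T)
        if len(edges)
        else np.empty(0)
    )
    return NeighborGraph(n_vertices=len(pts), edges=edges, lengths=lengths)


def build_ccg(centroids: np.ndarray, params: CCGParams = CCGParams()) -> NeighborGraph:
    """Cell cluster graph: edge (u, v) iff d(u, v)^(-alpha) > r.

    The decay rule is applied deterministically as a distance threshold
    d < r^(-1/alpha) rather than sampled per edge, for reproducibility.
    """
    pts = merge_coincident(centroids)
    if len(pts) < 2:
        raise UndefinedFeatureError("cell cluster graph needs >= 2 centroids")
    return build_proximity_graph(pts, params.distance_threshold)


def _eccentricity_block(g: nx.Graph) -> dict[str, float]:
    """Eccentricity / path statistics on the largest component, plus the
    90th-percentile variants (over the 90% of nodes with smallest
    eccentricity)."""
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = g.subgraph(comps[0])
    ecc = np.array(sorted(nx.eccentricity(giant).values()), dtype=float)
    n90 = max(1, int(np.floor(0.9 * len(ecc))))
    ecc90 = ecc[:n90]
    if giant.number_of_nodes() > 1:
        lengths = []
        nodes = list(giant.nodes())
        spl = dict(nx.all_pairs_shortest_path_length(giant))
        for i, u in enumerate(nodes):
            for v in nodes[i + 1 :]:
                lengths.append(spl[u][v])
        lengths = np.array(lengths, dtype=float)
        apl, apl_std = float(np.mean(lengths)), float(np.std(lengths))
    else:
        apl, apl_std = 0.0, 0.0
    return {
        "ecc_mean": float(np.mean(ecc)),
        "ecc_std": float(np.std(ecc)),
        "diameter": float(np.max(ecc)),
        "radius": float(np.min(ecc)),
        "ecc90_mean": float(np.mean(ecc90)),
        "diameter90": float(np.max(ecc90)),
        "radius90": float(np.min(ecc90)),
        "apl": apl,
        "apl_std": apl_std,
    }


def _spectral_block(g: nx.Graph) -> dict[str, float]:
    n = g.number_of_nodes()
    if n == 0:
        return {k: 0.0 for k in ("spectral_radius", "second_eigen", "energy", "n_distinct", "eigen_exponent")}
    adj = nx.to_numpy_array(g, weight=None)
    eig = np.linalg.eigvalsh(adj)
    mags = np.sort(np.abs(eig))[::-1]
    distinct = 1
    for a, b in zip(np.sort(eig)[:-1], np.sort(eig)[1:]):
        if b - a > 1e-8:
            distinct += 1
    top = mags[: max(2, n // 2)]
    top = top[top > 1e-12]
    if len(top) >= 2:
        slope = float(np.polyfit(np.log(np.arange(1, len(top) + 1)), np.log(top), 1)[0])
    else:
        slope = 0.0
    return {
        "spectral_radius": float(mags[0]),
        "second_eigen": float(mags[1]) if n > 1 else 0.0,
        "energy": float(np.sum(mags)),
        "n_distinct": float(distinct),
        "eigen_exponent": slope,
    }


def ccg_features(graph: NeighborGraph) -> list[float]:
    """39 cell-cluster-graph statistics (see module docstring)."""
    g = graph.to_networkx()
    n = g.number_of_nodes()
    if n < 1:
        raise UndefinedFeatureError("graph features need >= 1 vertex")
    m = g.number_of_edges()
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    degrees = np.array([d for _, d in g.degree()], dtype=float)

    ecc = _eccentricity_block(g)

    # clustering coefficients: C = global transitivity, D = mean local over
    # all nodes (isolated -> 0), E = mean local over nodes of degree >= 2
    transitivity = nx.transitivity(g)
    local = nx.clustering(g)
    d_coeff = float(np.mean(list(local.values()))) if local else 0.0
    deg2 = [local[v] for v in g.nodes() if g.degree(v) >= 2]
    e_coeff = float(np.mean(deg2)) if deg2 else 0.0

    comps = list(nx.connected_components(g))
    comp_sizes = np.array([len(c) for c in comps], dtype=float)
    giant_ratio = float(np.max(comp_sizes)) / n
    isolated = int(np.sum(degrees == 0))
    end_nodes = int(np.sum(degrees == 1))
    central = 0
    for comp in comps:
        sub = g.subgraph(comp)
        sub_ecc = nx.eccentricity(sub)
        sub_radius = min(sub_ecc.values())
        central += sum(1 for v in comp if sub_ecc[v] == sub_radius)

    lengths = np.asarray(graph.lengths, dtype=float)
    if len(lengths) == 0:
        logger.info("edgeless graph: edge-length statistics set to 0")
        edge_stats = [0.0] * 6
    else:
        mu_len = float(np.mean(lengths))
        sd_len = float(np.std(lengths))
        # a spread at rounding-noise scale is a constant edge set
        if sd_len > 1e-9 * max(abs(mu_len), 1.0):
            z = (lengths - mu_len) / sd_len
            sk, ku = float(np.mean(z**3)), float(np.mean(z**4) - 3.0)
        else:
            sk, ku = 0.0, 0.0
        edge_stats = [mu_len, sd_len, minmax_ratio(lengths), disorder(lengths), sk, ku]

    spec = _spectral_block(g)

    return [
        float(n),
        float(m),
        density,
        float(np.mean(degrees)),
        float(np.std(degrees)),
        disorder(degrees),
        ecc["ecc_mean"],
        ecc["ecc_std"],
        ecc["diameter"],
        ecc["radius"],
        ecc["ecc90_mean"],
        ecc["diameter90"],
        ecc["radius90"],
        ecc["apl"],
        ecc["apl_std"],
        float(transitivity),
        d_coeff,
        e_coeff,
        float(len(comps)),
        giant_ratio,
        float(np.mean(comp_sizes)),
        float(np.std(comp_sizes)),
        float(isolated),
        isolated / n,
        float(end_nodes),
        end_nodes / n,
        float(central),
        central / n,
        *edge_stats,
        spec["spectral_radius"],
        spec["second_eigen"],
        spec["energy"],
        spec["n_distinct"],
        spec["eigen_exponent"],
    ]


# ---------------------------------------------------------------------------
# Cell orientation co-occurrence entropy (COrE)
# ---------------------------------------------------------------------------

def orientation_bins(orientations_deg: np.ndarray) -> np.ndarray:
    """Quantize angles on [0, 180) into 8 bins of 22.5 degrees."""
    wrapped = np.mod(orientations_deg, 180.0)
    return np.minimum(
        (wrapped / (180.0 / N_ORIENTATION_BINS)).astype(int), N_ORIENTATION_BINS - 1
    )


def cooccurrence_matrix(bins: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Symmetric normalized co-occurrence of orientation bins over graph edges."""
    mat = np.zeros((N_ORIENTATION_BINS, N_ORIENTATION_BINS))
    for u, v in edges:
        mat[bins[u], bins[v]] += 1.0
        mat[bins[v], bins[u]] += 1.0
    total = mat.sum()
    if total > 0:
        mat /= total
    return mat


def _haralick_stats(p: np.ndarray) -> list[float]:
    """13 second-order statistics of a normalized co-occurrence matrix.

    Order: contrast energy, contrast inverse moment, contrast average,
    contrast variance, contrast entropy, intensity average, intensity
    variance, intensity entropy, entropy, energy, correlation,
    information measure 1, information measure 2. Logs are base 2;
    0*log(0) := 0; statistics with a zero denominator are set to 0.
    """
    if p.sum() == 0:
        return [0.0] * 13
    nb = p.shape[0]
    i, j = np.meshgrid(np.arange(nb), np.arange(nb), indexing="ij")
    diff = np.abs(i - j)
    # contrast block: distribution over k = |i - j|
    q = np.array([p[diff == k].sum() for k in range(nb)])
    ks = np.arange(nb)
    contrast_energy = float(np.sum(ks**2 * q))
    contrast_inverse_moment = float(np.sum(p / (1.0 + (i - j) ** 2)))
    contrast_average = float(np.sum(ks * q))
    contrast_variance = float(np.sum((ks - contrast_average) ** 2 * q))
    contrast_entropy = float(-np.sum(q[q > 0] * np.log2(q[q > 0])))
    # intensity block: distribution over m = i + j
    s = np.array([p[(i + j) == m].sum() for m in range(2 * nb - 1)])
    ms = np.arange(2 * nb - 1)
    intensity_average = float(np.sum(ms * s))
    intensity_variance = float(np.sum((ms - intensity_average) ** 2 * s))
    intensity_entropy = float(-np.sum(s[s > 0] * np.log2(s[s > 0])))
    entropy = float(-np.sum(p[p > 0] * np.log2(p[p > 0])))
    energy = float(np.sum(p**2))
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float(np.sum(np.arange(nb) * px))
    muy = float(np.sum(np.arange(nb) * py))
    sigx = float(np.sqrt(np.sum((np.arange(nb) - mux) ** 2 * px)))
    sigy = float(np.sqrt(np.sum((np.arange(nb) - muy) ** 2 * py)))
    if sigx > 0 and sigy > 0:
        correlation = float((np.sum(i * j * p) - mux * muy) / (sigx * sigy))
    else:
        correlation = 0.0
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))
    pxy = np.outer(px, py)
    mask = p > 0
    hxy1 = float(-np.sum(p[mask] * np.log2(np.where(pxy[mask] > 0, pxy[mask], 1.0))))
    maskxy = pxy > 0
    hxy2 = float(-np.sum(pxy[maskxy] * np.log2(pxy[maskxy])))
    denom = max(hx, hy)
    info1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    info2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))
    return [
        contrast_energy,
        contrast_inverse_moment,
        contrast_average,
        contrast_variance,
        contrast_entropy,
        intensity_average,
        intensity_variance,
        intensity_entropy,
        entropy,
        energy,
        correlation,
        info1,
        info2,
    ]


def core_features(
    nuclei: list[NucleusRecord],
    centroids: np.ndarray | None = None,
    ccg_params: CCGParams = CCGParams(),
) -> list[float]:
    """26 orientation co-occurrence statistics: 13 for the CCG edge set,
    13 for the 40 px proximity graph."""
    if len(nuclei) < MIN_NUCLEI:
        raise UndefinedFeatureError("orientation features need >= 5 nuclei")
    if any(n.orientation_deg is None for n in nuclei):
        raise UndefinedFeatureError("every nucleus needs an orientation")
    if centroids is None:
        centroids = np.array([n.centroid for n in nuclei])
    orientations = np.array([n.orientation_deg for n in nuclei])
    bins = orientation_bins(orientations)
    out = []
    for graph in (
        build_ccg(centroids, ccg_params),
        build_proximity_graph(centroids, CORE_PROXIMITY_RADIUS_PX),
    ):
        if len(graph.edges) == 0:
            logger.info("orientation graph has no edges; statistics set to 0")
            out.extend([0.0] * 13)
        else:
            out.extend(_haralick_stats(cooccurrence_matrix(bins, graph.edges)))
    return out


# ---------------------------------------------------------------------------
# Catalog and the 116-feature vector
# ---------------------------------------------------------------------------

_STAT_NAMES = ("Mean", "Standard Deviation", "Min/Max Ratio", "Disorder")

_CCG_NAMES = [
    "CCG: number of nodes",
    "CCG: number of edges",
    "CCG: graph density",
    "CCG: mean degree",
    "CCG: standard deviation degree",
    "CCG: disorder of degree",
    "CCG: mean eccentricity",
    "CCG: standard deviation eccentricity",
    "CCG: diameter",
    "CCG: radius",
    "CCG: mean eccentricity 90%",
    "CCG: diameter 90%",
    "CCG: radius 90%",
    "CCG: average path length",
    "CCG: standard deviation path length",
    "CCG: Clustering Coefficient C",
    "CCG: Clustering Coefficient D",
    "CCG: Clustering Coefficient E",
    "CCG: number of connected components",
    "CCG: giant component ratio",
    "CCG: mean component size",
    "CCG: standard deviation component size",
    "CCG: number of isolated nodes",
    "CCG: fraction of isolated nodes",
    "CCG: number of end nodes",
    "CCG: fraction of end nodes",
    "CCG: number of central nodes",
    "CCG: fraction of central nodes",
    "CCG: mean edge length",
    "CCG: standard deviation edge length",
    "CCG: min/max ratio edge length",
    "CCG: disorder of edge length",
    "CCG: skewness edge length",
    "CCG: kurtosis edge length",
    "CCG: spectral radius",
    "CCG: second largest eigenvalue",
    "CCG: graph energy",
    "CCG: number of distinct eigenvalues",
    "CCG: eigen exponent",
]

_CORE_STAT_NAMES = [
    "Contrast Energy",
    "Contrast Inverse Moment",
    "Contrast Average",
    "Contrast Variance",
    "Contrast Entropy",
    "Intensity Average",
    "Intensity Variance",
    "Intensity Entropy",
    "Entropy",
    "Energy",
    "Correlation",
    "Information Measure 1",
    "Information Measure 2",
]


def architecture_feature_names() -> list[str]:
    """The 116 architecture feature names, in catalog order."""
    names = []
    for quantity in ("Cell Area", "Cell Perimeter", "Cell Chord Length"):
        names.extend(f"Arch: Voronoi: {stat} {quantity}" for stat in _STAT_NAMES)
    for quantity in ("Side Length", "Triangle Area"):
        names.extend(f"Arch: Delaunay: {stat} {quantity}" for stat in _STAT_NAMES)
    names.extend(f"Arch: MST: {stat} Edge Length" for stat in _STAT_NAMES)
    for r in NN_RADII_PX:
        names.append(f"Arch: Avg. Nearest Neighbors in a {r} Pixel Radius")
        names.append(f"Arch: Standard Deviation of Nearest Neighbors in a {r} Pixel Radius")
        names.append(f"Arch: Disorder of Nearest Neighbors in a {r} Pixel Radius")
    for k in NN_KS:
        names.append(f"Arch: Avg. Distance to {k} Nearest Neighbors")
        names.append(f"Arch: Standard Deviation Distance to {k} Nearest Neighbors")
        names.append(f"Arch: Disorder of Distance to {k} Nearest Neighbors")
    names.append("Arch: Nuclear Density")
    names.append("Arch: Avg. Nearest Neighbor Distance")
    names.append("Arch: Standard Deviation Nearest Neighbor Distance")
    names.extend(_CCG_NAMES)
    for variant in ("CCG", "40 Pixel Radius"):
        names.extend(f"COrE: {stat} ({variant})" for stat in _CORE_STAT_NAMES)
    assert len(names) == 116
    return names


N_ARCHITECTURE_FEATURES = 116


def architecture_vector(
    nuclei: list[NucleusRecord],
    bounds,
    min_nuclei: int = MIN_NUCLEI,
    ccg_params: CCGParams = CCGParams(),
) -> np.ndarray:
    """116 architecture features for one compartment of a patch.

    Families whose preconditions fail (too few usable points, degenerate
    geometry) yield NaN for that family; fewer than `min_nuclei` nuclei
    yields an all-NaN vector.
    """
    out = np.full(N_ARCHITECTURE_FEATURES, np.nan)
    if len(nuclei) < min_nuclei:
        return out
    centroids = np.array([n.centroid for n in nuclei])
    blocks = [
        (0, 12, lambda: voronoi_features(centroids, bounds)),
        (12, 20, lambda: delaunay_features(centroids)),
        (20, 24, lambda: mst_features(centroids)),
        (24, 51, lambda: nn_features(centroids, bounds)),
        (51, 90, lambda: ccg_features(build_ccg(centroids, ccg_params))),
        (90, 116, lambda: core_features(nuclei, centroids, ccg_params)),
    ]
    for lo, hi, fn in blocks:
        try:
            out[lo:hi] = fn()
        except UndefinedFeatureError as exc:
            logger.info("architecture family [%d:%d] undefined: %s", lo, hi, exc)
    return out
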