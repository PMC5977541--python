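"""Per-nucleus shape descriptors (25) and their compartment aggregation (100),
plus assembly of the full per-patch feature vector (432 or 216 pooled).

Descriptors per nucleus, in catalog order: area ratio, perimeter ratio,
distance ratio, radial standard deviation and variance, smoothness,
length/width ratio, the seven Hu invariant moments, fractal dimension of
the boundary, and ten normalized Fourier descriptors.

Geometric moments of the filled polygon are computed exactly (triangle
decomposition against the origin with closed-form simplex integrals), so
the Hu invariants are rotation/translation invariant to machine
precision. Radial and Fourier descriptors are computed on a 128-point
equal-arc-length resampling of the boundary, which removes any
dependence on vertex density.
"""

from __future__ import annotations

import logging
from math import comb, factorial

import numpy as np
import shapely
import shapely.geometry as geom

from nucmorph.architecture import (
    CCGParams,
    architecture_feature_names,
    architecture_vector,
)
from nucmorph.errors import InvalidParameterError, ParseError
from nucmorph.stats import minmax_ratio
from nucmorph.types import EPITHELIAL, STROMAL, NucleusRecord, Patch

logger = logging.getLogger(__name__)

N_RESAMPLE = 128
N_FOURIER = 10
FRACTAL_GRID = 128
MIN_NUCLEI = 5

DESCRIPTOR_NAMES = (
    ["Area Ratio", "Perimeter Ratio", "Distance Ratio",
     "Radial Standard Deviation", "Radial Variance", "Smoothness",
     "Length/Width Ratio"]
    + [f"Invariant Moment {i}" for i in range(1, 8)]
    + ["Fractal Dimension"]
    + [f"Fourier Descriptor {i}" for i in range(1, 11)]
)
N_DESCRIPTORS = 25
_AGG_NAMES = ("Mean", "Standard Deviation", "Median", "Min/Max Ratio")


# ---------------------------------------------------------------------------
# Exact polygon moments
# ---------------------------------------------------------------------------

def _oriented_vertices(polygon) -> np.ndarray:
    poly = polygon if isinstance(polygon, geom.Polygon) else geom.Polygon(polygon)
    if not poly.is_valid:
        raise ParseError("polygon is not simple")
    if poly.area <= 0:
        raise InvalidParameterError("polygon has zero area")
    poly = shapely.geometry.polygon.orient(poly, sign=1.0)  # CCW
    verts = np.asarray(poly.exterior.coords)[:-1]
    return verts


_MOMENT_ORDERS = [
    (0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2), (3, 0), (2, 1), (1, 2), (0, 3)
]
# per (p, q): list of (k, l, coefficient) for the simplex-integral expansion
_MOMENT_COEFFS = {
    (p, q): [
        (
            k,
            l,
            comb(p, k) * comb(q, l) * factorial(k + l) * factorial(p + q - k - l)
            / factorial(p + q + 2),
        )
        for k in range(p + 1)
        for l in range(q + 1)
    ]
    for (p, q) in _MOMENT_ORDERS
}


def _raw_moments(verts: np.ndarray) -> dict[tuple[int, int], float]:
    """Exact raw moments m_pq (p + q <= 3) of the CCW polygon.

    Decomposes the polygon into signed triangles (origin, v_i, v_{i+1})
    and integrates the expanded binomial over the unit simplex.
    """
    b = np.roll(verts, -1, axis=0)
    ax, ay = verts[:, 0], verts[:, 1]
    bx, by = b[:, 0], b[:, 1]
    cross = ax * by - ay * bx
    out = {}
    for pq, terms in _MOMENT_COEFFS.items():
        p, q = pq
        acc = np.zeros(len(ax))
        for k, l, coef in terms:
            acc += coef * ax**k * bx ** (p - k) * ay**l * by ** (q - l)
        out[pq] = float(np.sum(cross * acc))
    return out


def polygon_moment(verts: np.ndarray, p: int, q: int) -> float:
    """Exact raw moment m_pq = integral of x^p y^q over the CCW polygon."""
    return _raw_moments(np.asarray(verts, dtype=float))[(p, q)]


def central_moments(polygon) -> dict[tuple[int, int], float]:
    """Exact central moments mu_pq of the filled polygon, p + q <= 3."""
    verts = _oriented_vertices(polygon)
    raw = _raw_moments(verts)
    cx = raw[(1, 0)] / raw[(0, 0)]
    cy = raw[(0, 1)] / raw[(0, 0)]
    return _raw_moments(verts - np.array([cx, cy]))


def _hu_from_central(mu: dict[tuple[int, int], float]) -> np.ndarray:
    m00 = mu[(0, 0)]

    def eta(p, q):
        return mu[(p, q)] / m00 ** (1 + (p + q) / 2.0)

    n20, n02, n11 = eta(2, 0), eta(0, 2), eta(1, 1)
    n30, n03, n21, n12 = eta(3, 0), eta(0, 3), eta(2, 1), eta(1, 2)
    h1 = n20 + n02
    h2 = (n20 - n02) ** 2 + 4 * n11**2
    h3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    h4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    h5 = (n30 - 3 * n12) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) + (3 * n21 - n03) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    h6 = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (
        n30 + n12
    ) * (n21 + n03)
    h7 = (3 * n21 - n03) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) - (n30 - 3 * n12) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    return np.array([h1, h2, h3, h4, h5, h6, h7])


def hu_moments(polygon) -> np.ndarray:
    """The seven Hu invariant moments of the filled polygon (exact)."""
    return _hu_from_central(central_moments(polygon))


def nucleus_orientation(polygon) -> float:
    """Principal-axis angle of the filled polygon, degrees in [0, 180)."""
    mu = central_moments(polygon)
    angle = 0.5 * np.arctan2(2.0 * mu[(1, 1)], mu[(2, 0)] - mu[(0, 2)])
    deg = float(np.mod(np.degrees(angle), 180.0))
    return 0.0 if deg >= 180.0 - 1e-9 else deg


# ---------------------------------------------------------------------------
# Boundary resampling and descriptors
# ---------------------------------------------------------------------------

def _resample_ring(ring: np.ndarray, cum: np.ndarray, n_points: int) -> np.ndarray:
    targets = np.linspace(0.0, cum[-1], n_points, endpoint=False)
    x = np.interp(targets, cum, ring[:, 0])
    y = np.interp(targets, cum, ring[:, 1])
    return np.column_stack([x, y])


def resample_boundary(polygon, n_points: int = N_RESAMPLE) -> np.ndarray:
    """`n_points` equally spaced (by arc length) points along the CCW boundary."""
    verts = _oriented_vertices(polygon)
    ring = np.vstack([verts, verts[:1]])
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(ring, axis=0).T))])
    return _resample_ring(ring, cum, n_points)


def fractal_dimension(boundary_pts: np.ndarray, grid: int = FRACTAL_GRID) -> float:
    """Box-counting dimension of the rasterized boundary over 5 dyadic scales."""
    pts = boundary_pts - boundary_pts.min(axis=0)
    extent = pts.max()
    if extent == 0:
        return 0.0
    scaled = pts / extent * (grid - 1)
    img = np.zeros((grid, grid), dtype=bool)
    ring = np.vstack([scaled, scaled[:1]])
    seg = np.hypot(*np.diff(ring, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    # sample the boundary densely (4 samples per traversed pixel) so every
    # crossed cell is marked without per-segment line drawing
    n_samples = max(256, int(4 * cum[-1]))
    t = np.linspace(0.0, cum[-1], n_samples)
    xs = np.clip(np.rint(np.interp(t, cum, ring[:, 0])).astype(int), 0, grid - 1)
    ys = np.clip(np.rint(np.interp(t, cum, ring[:, 1])).astype(int), 0, grid - 1)
    img[ys, xs] = True
    sizes = [1, 2, 4, 8, 16]
    counts = []
    for s in sizes:
        reduced = img.reshape(grid // s, s, grid // s, s).any(axis=(1, 3))
        counts.append(reduced.sum())
    slope = np.polyfit(np.log(1.0 / np.array(sizes, dtype=float)),
                       np.log(np.array(counts, dtype=float)), 1)[0]
    return float(slope)


def length_width_ratio(polygon) -> float:
    """Major/minor principal-axis length ratio from exact second moments."""
    return _lw_from_central(central_moments(polygon))


def _lw_from_central(mu: dict[tuple[int, int], float]) -> float:
    m00 = mu[(0, 0)]
    cov = np.array(
        [[mu[(2, 0)] / m00, mu[(1, 1)] / m00], [mu[(1, 1)] / m00, mu[(0, 2)] / m00]]
    )
    eigvals = np.linalg.eigvalsh(cov)
    lo, hi = max(eigvals[0], 0.0), max(eigvals[1], 0.0)
    if lo == 0.0:
        raise InvalidParameterError("degenerate polygon: zero minor axis")
    return float(np.sqrt(hi / lo))


def fourier_descriptors(boundary_pts: np.ndarray, n: int = N_FOURIER) -> np.ndarray:
    """Magnitudes of harmonics 1..n of the centered complex boundary,
    normalized by the magnitude of harmonic 1."""
    z = boundary_pts[:, 0] + 1j * boundary_pts[:, 1]
    z = z - z.mean()
    coeffs = np.fft.fft(z)
    mags = np.abs(coeffs[1 : n + 1])
    ref = mags[0]
    if ref == 0:
        return np.zeros(n)
    return mags / ref


def shape_descriptors(polygon) -> np.ndarray:
    """The 25 shape descriptors for one nucleus polygon."""
    verts = _oriented_vertices(polygon)  # one validation pass
    raw = _raw_moments(verts)
    area = raw[(0, 0)]
    cx, cy = raw[(1, 0)] / area, raw[(0, 1)] / area
    ring = np.vstack([verts, verts[:1]])
    seg = np.hypot(*np.diff(ring, axis=0).T)
    perimeter = float(np.sum(seg))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    pts = _resample_ring(ring, cum, N_RESAMPLE)
    radial = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    r_max = float(np.max(radial))
    r_eq = np.sqrt(area / np.pi)
    area_ratio = area / (np.pi * r_max**2)
    perimeter_ratio = perimeter / (2.0 * np.pi * r_eq)
    distance_ratio = float(np.mean(radial)) / r_max
    radial_std = float(np.std(radial))
    radial_var = float(np.var(radial))
    neighbors_avg = 0.5 * (np.roll(radial, 1) + np.roll(radial, -1))
    smoothness = float(np.mean(np.abs(radial - neighbors_avg)))
    mu_central = _raw_moments(verts - np.array([cx, cy]))
    lw = _lw_from_central(mu_central)
    hu = _hu_from_central(mu_central)
    fd = fractal_dimension(pts)
    fds = fourier_descriptors(pts)
    return np.concatenate(
        [
            [area_ratio, perimeter_ratio, distance_ratio, radial_std, radial_var,
             smoothness, lw],
            hu,
            [fd],
            fds,
        ]
    )


# ---------------------------------------------------------------------------
# Aggregation and the patch feature vector
# ---------------------------------------------------------------------------

def shape_feature_names() -> list[str]:
    """The 100 aggregated shape feature names, in catalog order."""
    names = []
    for descriptor in DESCRIPTOR_NAMES:
        names.extend(f"Shape: {agg} {descriptor}" for agg in _AGG_NAMES)
    assert len(names) == 100
    return names


N_SHAPE_FEATURES = 100


def shape_vector(nuclei: list[NucleusRecord], min_nuclei: int = MIN_NUCLEI) -> np.ndarray:
    """100 aggregated shape features (4 statistics x 25 descriptors) for a
    compartment; all-NaN below `min_nuclei` nuclei."""
    if len(nuclei) < min_nuclei:
        return np.full(N_SHAPE_FEATURES, np.nan)
    rows = np.array([shape_descriptors(n.boundary) for n in nuclei])
    out = np.empty(N_SHAPE_FEATURES)
    for d in range(N_DESCRIPTORS):
        col = rows[:, d]
        out[4 * d : 4 * d + 4] = [
            float(np.mean(col)),
            float(np.std(col)),
            float(np.median(col)),
            minmax_ratio(col),
        ]
    return out


def compartment_feature_names() -> list[str]:
    """216 names: architecture then shape, without compartment prefix."""
    return architecture_feature_names() + shape_feature_names()


def patch_feature_names(mode: str = "separated") -> list[str]:
    """Catalog names: 432 for separated mode (EP then ST halves), 216 for
    pooled mode (ALL prefix)."""
    base = compartment_feature_names()
    if mode == "separated":
        return [f"EP: {n}" for n in base] + [f"ST: {n}" for n in base]
    if mode == "pooled":
        return [f"ALL: {n}" for n in base]
    raise ValueError(f"unknown mode {mode!r}")


def _compartment_vector(
    nuclei: list[NucleusRecord], bounds, min_nuclei: int, ccg_params: CCGParams
) -> np.ndarray:
    arch = architecture_vector(nuclei, bounds, min_nuclei=min_nuclei, ccg_params=ccg_params)
    shp = shape_vector(nuclei, min_nuclei=min_nuclei)
    return np.concatenate([arch, shp])


def patch_feature_vector(
    patch: Patch,
    mode: str = "separated",
    min_nuclei: int = MIN_NUCLEI,
    ccg_params: CCGParams = CCGParams(),
) -> tuple[np.ndarray, bool]:
    """Feature vector for one patch.

    separated mode: [EP architecture 116 | EP shape 100 | ST architecture
    116 | ST shape 100] = 432 values; pooled mode computes the same 216
    features over all nuclei ignoring compartment.

    Returns (vector, excluded): `excluded` is True when any compartment
    falls below `min_nuclei` (its half is NaN) and the patch should be
    left out of modeling.
    """
    bounds = (0.0, 0.0, patch.width_px, patch.height_px)
    if mode == "pooled":
        vec = _compartment_vector(patch.nuclei, bounds, min_nuclei, ccg_params)
    elif mode == "separated":
        ep = patch.compartment_nuclei(EPITHELIAL)
        st = patch.compartment_nuclei(STROMAL)
        vec = np.concatenate(
            [
                _compartment_vector(ep, bounds, min_nuclei, ccg_params),
                _compartment_vector(st, bounds, min_nuclei, ccg_params),
            ]
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    excluded = bool(np.any(np.isnan(vec)))
    if excluded:
        logger.info("patch %s flagged for exclusion (NaN features)", patch.patch_id)
    return vec, excluded
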