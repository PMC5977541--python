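"""Seeded synthetic nuclei cohorts.

Emulates 40x H&E image patches containing epithelial nuclear nests
embedded in stroma, with tunable architectural disorder, nuclear
pleomorphism, and orientation coherence. Epithelial centroids follow a
parent-offspring (Thomas-type) cluster process — Poisson parents,
Gaussian offspring — because tumor epithelium organizes into nests and
this is the simplest point process with an explicit disorder dial.
Stromal centroids follow a homogeneous Poisson process restricted to
the region outside the epithelial nests. Each nucleus boundary is an
ellipse with a sampled axis ratio and a von Mises orientation, radially
perturbed by a low-order harmonic whose amplitude controls boundary
irregularity (pleomorphism).

Intensities are per mm^2; at 40x we adopt 0.25 um/px, i.e. 4000 px/mm.
All outputs are fully determined by (config, seed): per-patch sub-seeds
are derived by hashing (seed, patient index, patch index, attempt) with
numpy's SeedSequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import shapely.geometry as geom
import skimage.draw

from nucmorph.errors import GenerationError, InvalidParameterError
from nucmorph.types import EPITHELIAL, STROMAL, NucleusRecord, Patch, PatientCase

logger = logging.getLogger(__name__)

PX_PER_MM = 4000.0  # 0.25 um/px at 40x
N_BOUNDARY_VERTICES = 48
RETRY_BUDGET = 20
MIN_NUCLEI_PER_COMPARTMENT = 5


@dataclass(frozen=True)
class SyntheticPhenotype:
    """Morphological parameters of one risk-like phenotype.

    cluster_intensity: expected epithelial nests per mm^2.
    cluster_spread: within-nest centroid dispersion, px.
    nuclei_per_cluster_mean: expected nuclei per nest.
    stromal_intensity: expected stromal nuclei per mm^2 of free area.
    placement_jitter: uniform positional noise added to centroids, px.
    axis_ratio_mean/sd: nuclear major/minor axis ratio distribution.
    boundary_irregularity: radial perturbation amplitude, fraction of radius.
    orientation_kappa: von Mises concentration of orientations (0 = uniform).
    mean_radius_px: nuclear equivalent radius.
    """

    cluster_intensity: float = 700.0
    cluster_spread: float = 25.0
    nuclei_per_cluster_mean: float = 8.0
    stromal_intensity: float = 6000.0
    placement_jitter: float = 2.0
    axis_ratio_mean: float = 1.5
    axis_ratio_sd: float = 0.2
    boundary_irregularity: float = 0.08
    orientation_kappa: float = 0.5
    mean_radius_px: float = 8.0

    def validate(self):
        vals = [
            self.cluster_intensity, self.cluster_spread, self.nuclei_per_cluster_mean,
            self.stromal_intensity, self.placement_jitter, self.axis_ratio_mean,
            self.axis_ratio_sd, self.boundary_irregularity, self.orientation_kappa,
            self.mean_radius_px,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError("phenotype parameters must be finite")
        if any(v < 0 for v in vals):
            raise InvalidParameterError("phenotype parameters must be non-negative")
        if self.axis_ratio_mean < 1:
            raise InvalidParameterError("axis_ratio_mean must be >= 1")
        if not (0 <= self.boundary_irregularity <= 0.5):
            raise InvalidParameterError("boundary_irregularity must lie in [0, 0.5]")


def low_risk_phenotype() -> SyntheticPhenotype:
    """Ordered, coherent architecture with regular nuclei."""
    return SyntheticPhenotype(
        cluster_spread=15.0,
        boundary_irregularity=0.02,
        axis_ratio_mean=1.3,
        axis_ratio_sd=0.1,
        orientation_kappa=3.0,
    )


def high_risk_phenotype() -> SyntheticPhenotype:
    """Disordered architecture with pleomorphic, incoherently oriented nuclei."""
    return SyntheticPhenotype(
        cluster_spread=45.0,
        boundary_irregularity=0.25,
        axis_ratio_mean=1.8,
        axis_ratio_sd=0.4,
        orientation_kappa=0.0,
    )


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_patients_per_class: int = 30
    patches_per_patient: int = 10
    patch_size_px: int = 448
    low_phenotype: SyntheticPhenotype = field(default_factory=low_risk_phenotype)
    high_phenotype: SyntheticPhenotype = field(default_factory=high_risk_phenotype)
    # integer ODx score intervals per class; categories derive from the
    # low <= 17 / 31 <= high categorization rule, keeping labels and
    # scores consistent by construction
    odx_score_ranges: dict = field(
        default_factory=lambda: {"low": (0, 17), "high": (31, 60)}
    )
    mbr_score_ranges: dict = field(
        default_factory=lambda: {"low": (4, 5), "high": (8, 9)}
    )
    # optional per-class stromal phenotypes (None -> same as the class phenotype)
    low_stromal_phenotype: SyntheticPhenotype | None = None
    high_stromal_phenotype: SyntheticPhenotype | None = None
    # relative (log-normal) inter-patient variability of the continuous
    # phenotype parameters; real cohorts are heterogeneous, and without
    # this any parameter gap between classes is trivially separable
    patient_heterogeneity: float = 0.2
    min_nuclei: int = MIN_NUCLEI_PER_COMPARTMENT
    seed: int = 0


def _subseed_rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def _jitter_phenotype(
    pheno: SyntheticPhenotype, rng: np.random.Generator, heterogeneity: float
) -> SyntheticPhenotype:
    """Log-normal per-patient perturbation of the continuous parameters."""
    if heterogeneity <= 0:
        return pheno
    f = lambda: float(np.exp(rng.normal(0.0, heterogeneity)))
    return replace(
        pheno,
        cluster_spread=pheno.cluster_spread * f(),
        nuclei_per_cluster_mean=pheno.nuclei_per_cluster_mean * f(),
        stromal_intensity=pheno.stromal_intensity * f(),
        boundary_irregularity=min(0.5, pheno.boundary_irregularity * f()),
        axis_ratio_mean=1.0 + (pheno.axis_ratio_mean - 1.0) * f(),
        axis_ratio_sd=pheno.axis_ratio_sd * f(),
        orientation_kappa=pheno.orientation_kappa * f(),
    )


def sample_centroids(
    phenotype: SyntheticPhenotype,
    patch_size_px: int,
    compartment: str,
    seed: int | np.random.Generator,
    epithelium_mask: np.ndarray | None = None,
):
    """Sample nuclear centroids for one compartment of one patch.

    Epithelial centroids come from the Thomas process; the returned
    epithelium mask is the union of the nests' convex hulls dilated by
    the nuclear radius plus spread margin. Stromal centroids come from a
    homogeneous Poisson process thinned to the region outside the given
    epithelium mask.

    Returns (points (n, 2), epithelium_mask uint8 HxW with 255 inside).
    """
    phenotype.validate()
    if patch_size_px <= 0:
        raise InvalidParameterError("patch_size_px must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    size = int(patch_size_px)
    area_mm2 = (size / PX_PER_MM) ** 2

    if compartment == EPITHELIAL:
        n_parents = rng.poisson(phenotype.cluster_intensity * area_mm2)
        parents = rng.uniform(0, size, size=(n_parents, 2))
        pts = []
        hulls = []
        for parent in parents:
            n_off = rng.poisson(phenotype.nuclei_per_cluster_mean)
            if n_off == 0:
                continue
            off = parent + rng.normal(0.0, phenotype.cluster_spread, size=(n_off, 2))
            off += rng.uniform(
                -phenotype.placement_jitter, phenotype.placement_jitter, size=off.shape
            )
            off = off[
                (off[:, 0] >= 0) & (off[:, 0] < size)
                & (off[:, 1] >= 0) & (off[:, 1] < size)
            ]
            if len(off) == 0:
                continue
            pts.append(off)
            margin = phenotype.mean_radius_px + 0.25 * phenotype.cluster_spread + 2.0
            hulls.append(geom.MultiPoint(off.tolist()).convex_hull.buffer(margin))
        points = np.vstack(pts) if pts else np.empty((0, 2))
        mask = _rasterize_regions(hulls, size)
        return points, mask

    if compartment == STROMAL:
        if epithelium_mask is None:
            epithelium_mask = np.zeros((size, size), dtype=np.uint8)
        n = rng.poisson(phenotype.stromal_intensity * area_mm2)
        pts = rng.uniform(0, size, size=(n, 2))
        pts += rng.uniform(
            -phenotype.placement_jitter, phenotype.placement_jitter, size=pts.shape
        )
        pts = pts[
            (pts[:, 0] >= 0) & (pts[:, 0] < size)
            & (pts[:, 1] >= 0) & (pts[:, 1] < size)
        ]
        cols = np.clip(pts[:, 0].astype(int), 0, size - 1)
        rows = np.clip(pts[:, 1].astype(int), 0, size - 1)
        outside = epithelium_mask[rows, cols] == 0
        return pts[outside], epithelium_mask

    raise InvalidParameterError(f"unknown compartment {compartment!r}")


def _rasterize_regions(regions, size: int) -> np.ndarray:
    mask = np.zeros((size, size), dtype=np.uint8)
    for region in regions:
        merged = region if region.geom_type == "Polygon" else region.convex_hull
        coords = np.asarray(merged.exterior.coords)
        rr, cc = skimage.draw.polygon(coords[:, 1], coords[:, 0], shape=mask.shape)
        mask[rr, cc] = 255
    return mask


def synthesize_nucleus_boundary(
    center,
    phenotype: SyntheticPhenotype,
    seed: int | np.random.Generator,
    n_vertices: int = N_BOUNDARY_VERTICES,
):
    """One nucleus boundary: a perturbed ellipse around `center`.

    The ellipse preserves the phenotype's equivalent radius (area
    ~ pi r^2), has axis ratio ~ N(mean, sd) clipped to >= 1, orientation
    from a von Mises law on the half-circle, and a single low-order
    harmonic radial perturbation of relative amplitude
    boundary_irregularity. Returns (polygon (n, 2), orientation_deg).
    """
    phenotype.validate()
    if phenotype.mean_radius_px <= 0:
        raise InvalidParameterError("mean_radius_px must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ratio = max(1.0, rng.normal(phenotype.axis_ratio_mean, phenotype.axis_ratio_sd))
    if phenotype.orientation_kappa > 0:
        theta = float(np.mod(rng.vonmises(0.0, phenotype.orientation_kappa) / 2.0, np.pi))
    else:
        theta = float(rng.uniform(0.0, np.pi))
    r = phenotype.mean_radius_px
    a, b = r * np.sqrt(ratio), r / np.sqrt(ratio)
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    harmonic = rng.integers(2, 5)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    rho = 1.0 + phenotype.boundary_irregularity * np.cos(harmonic * t + phase)
    x = a * rho * np.cos(t)
    y = b * rho * np.sin(t)
    ct, st = np.cos(theta), np.sin(theta)
    poly = np.column_stack([x * ct - y * st, x * st + y * ct]) + np.asarray(center)
    orientation_deg = float(np.degrees(theta)) % 180.0
    return poly, orientation_deg


def synthesize_patch(
    phenotype: SyntheticPhenotype,
    patch_size_px: int,
    patch_id: str,
    patient_id: str,
    rng: np.random.Generator,
    stromal_phenotype: SyntheticPhenotype | None = None,
) -> tuple[Patch, np.ndarray]:
    """One patch: epithelial nests plus surrounding stroma.

    `stromal_phenotype`, when given, drives the stromal compartment
    (placement and nuclear morphology) independently of the epithelial
    one — used by the compartment-separation ablation, where only
    stromal shape differs between classes.

    Returns (patch, epithelium_mask)."""
    st_pheno = stromal_phenotype if stromal_phenotype is not None else phenotype
    ep_pts, mask = sample_centroids(phenotype, patch_size_px, EPITHELIAL, rng)
    st_pts, _ = sample_centroids(
        st_pheno, patch_size_px, STROMAL, rng, epithelium_mask=mask
    )
    size = int(patch_size_px)
    # keep centroids away from the border so boundaries stay inside the patch
    margin = 2.2 * max(phenotype.mean_radius_px, st_pheno.mean_radius_px)
    ep_pts = ep_pts[np.all((ep_pts >= margin) & (ep_pts <= size - margin), axis=1)]
    st_pts = st_pts[np.all((st_pts >= margin) & (st_pts <= size - margin), axis=1)]
    nuclei = []
    nid = 1
    for pts, compartment in ((ep_pts, EPITHELIAL), (st_pts, STROMAL)):
        pheno = phenotype if compartment == EPITHELIAL else st_pheno
        for center in pts:
            boundary, orientation = synthesize_nucleus_boundary(center, pheno, rng)
            nuclei.append(
                NucleusRecord(
                    id=nid,
                    boundary=boundary,
                    compartment=compartment,
                    orientation_deg=orientation,
                )
            )
            nid += 1
    patch = Patch(
        patch_id=patch_id,
        patient_id=patient_id,
        width_px=float(size),
        height_px=float(size),
        nuclei=nuclei,
    )
    return patch, mask


def generate_cohort(config: SyntheticCohortConfig) -> list[PatientCase]:
    """A labelled synthetic cohort: every patient's patches share that
    patient's phenotype; ODx and mBR scores are drawn uniformly from the
    class intervals; patches below `min_nuclei` per compartment are
    regenerated (bounded retries)."""
    from nucmorph.pipeline import categorize_mbr, categorize_odx

    cases = []
    patient_idx = 0
    for cls, phenotype, stromal_phenotype in (
        ("low", config.low_phenotype, config.low_stromal_phenotype),
        ("high", config.high_phenotype, config.high_stromal_phenotype),
    ):
        phenotype.validate()
        for _ in range(config.n_patients_per_class):
            rng = _subseed_rng(config.seed, patient_idx, 0xFACE)
            odx_lo, odx_hi = config.odx_score_ranges[cls]
            mbr_lo, mbr_hi = config.mbr_score_ranges[cls]
            odx = int(rng.integers(odx_lo, odx_hi + 1))
            mbr = int(rng.integers(mbr_lo, mbr_hi + 1))
            pid = f"P{patient_idx:03d}"
            patient_pheno = _jitter_phenotype(phenotype, rng, config.patient_heterogeneity)
            patient_stromal = (
                _jitter_phenotype(stromal_phenotype, rng, config.patient_heterogeneity)
                if stromal_phenotype is not None
                else None
            )
            patches = []
            for patch_idx in range(config.patches_per_patient):
                patch = None
                for attempt in range(RETRY_BUDGET):
                    sub = _subseed_rng(config.seed, patient_idx, patch_idx, attempt)
                    candidate, _ = synthesize_patch(
                        patient_pheno,
                        config.patch_size_px,
                        patch_id=f"{pid}_patch{patch_idx:02d}",
                        patient_id=pid,
                        rng=sub,
                        stromal_phenotype=patient_stromal,
                    )
                    n_ep = len(candidate.compartment_nuclei(EPITHELIAL))
                    n_st = len(candidate.compartment_nuclei(STROMAL))
                    if n_ep >= config.min_nuclei and n_st >= config.min_nuclei:
                        patch = candidate
                        break
                if patch is None:
                    raise GenerationError(
                        f"could not satisfy min_nuclei={config.min_nuclei} per "
                        f"compartment for the {cls!r} phenotype after "
                        f"{RETRY_BUDGET} retries"
                    )
                patches.append(patch)
            cases.append(
                PatientCase(
                    patient_id=pid,
                    odx_score=odx,
                    odx_category=categorize_odx(odx),
                    mbr_score=mbr,
                    mbr_category=categorize_mbr(mbr),
                    patches=patches,
                    phenotype_class=cls,
                )
            )
            patient_idx += 1
    return cases


def render_patch(
    patch: Patch, noise_sd: float = 3.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Render a patch as an RGB image with a pixel-accurate label mask.

    Nuclei are filled in a hematoxylin-like dark purple on an eosin-like
    pink background, with mild additive Gaussian noise (`noise_sd` = 0
    disables it). Returns (rgb uint8 HxWx3, labels uint16 HxW)."""
    h, w = int(patch.height_px), int(patch.width_px)
    background = np.array([235, 180, 200], dtype=float)
    nucleus_color = np.array([90, 55, 135], dtype=float)
    rgb = np.tile(background, (h, w, 1))
    labels = np.zeros((h, w), dtype=np.uint16)
    for nuc in patch.nuclei:
        rr, cc = skimage.draw.polygon(
            nuc.boundary[:, 1], nuc.boundary[:, 0], shape=(h, w)
        )
        rgb[rr, cc] = nucleus_color
        labels[rr, cc] = nuc.id
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rgb = rgb + rng.normal(0.0, noise_sd, size=rgb.shape)
    return np.clip(rgb, 0, 255).astype(np.uint8), labels


def null_config(**overrides) -> SyntheticCohortConfig:
    """A null-effect cohort: identical phenotypes in both classes."""
    pheno = SyntheticPhenotype()
    cfg = SyntheticCohortConfig(low_phenotype=pheno, high_phenotype=pheno)
    return replace(cfg, **overrides)


def stromal_shape_only_config(**overrides) -> SyntheticCohortConfig:
    """A cohort whose classes differ only in stromal nuclear shape.

    Both classes share one phenotype for the epithelium and for stromal
    placement; the high class's stromal nuclei are more irregular and
    more elongated. Used by the compartment-separation ablation: the
    shape signal lives purely in the stroma, so pooling all nuclei
    dilutes it with unchanged epithelial nuclei.
    """
    # stroma kept a minority compartment and the shape gap kept moderate so
    # neither feature mode saturates: the contrast of interest is the gap
    # between modes, not ceiling performance of both. The shared epithelial
    # irregularity sits at the midpoint of the two stromal values so that
    # pooled within-patch dispersion statistics are equal in both classes
    # by construction — pooling can only see the diluted mean shift, which
    # is the compartment-separation effect being measured.
    shared = SyntheticPhenotype(stromal_intensity=3000.0, boundary_irregularity=0.105)
    st_low = replace(shared, boundary_irregularity=0.08)
    st_high = replace(shared, boundary_irregularity=0.13)
    cfg = SyntheticCohortConfig(
        low_phenotype=shared,
        high_phenotype=shared,
        low_stromal_phenotype=st_low,
        high_stromal_phenotype=st_high,
    )
    return replace(cfg, **overrides)
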