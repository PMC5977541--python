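"""Core data containers: a segmented nucleus, an image patch, a patient case.

Coordinate convention: pixel units, 0-based, x to the right, y down.
Rasters use the half-open convention — pixel (row i, col j) covers the
square [j, j+1) x [i, i+1), so polygon coordinates live on the pixel
grid's continuous plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely.geometry as geom

from nucmorph.errors import ParseError

EPITHELIAL = "epithelial"
STROMAL = "stromal"
UNKNOWN = "unknown"
COMPARTMENTS = (EPITHELIAL, STROMAL, UNKNOWN)


def _close_ring(boundary: np.ndarray) -> np.ndarray:
    if not np.array_equal(boundary[0], boundary[-1]):
        boundary = np.vstack([boundary, boundary[:1]])
    return boundary


@dataclass
class NucleusRecord:
    """One segmented nucleus: simple closed polygon plus derived scalars."""

    id: int
    boundary: np.ndarray  # (n, 2) float array of (x, y); ring closure optional
    compartment: str = UNKNOWN
    orientation_deg: float | None = None  # principal-axis angle in [0, 180)
    centroid: tuple[float, float] = field(init=False)
    area_px2: float = field(init=False)
    perimeter_px: float = field(init=False)

    def __post_init__(self):
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2 or len(self.boundary) < 3:
            raise ParseError(f"nucleus {self.id}: boundary must be an (n>=3, 2) array")
        if not np.all(np.isfinite(self.boundary)):
            raise ParseError(f"nucleus {self.id}: non-finite boundary coordinates")
        if self.compartment not in COMPARTMENTS:
            raise ParseError(f"nucleus {self.id}: unknown compartment {self.compartment!r}")
        poly = geom.Polygon(_close_ring(self.boundary))
        if (not poly.is_valid) or poly.area <= 0.0:
            raise ParseError(f"nucleus {self.id}: polygon is not simple or has zero area")
        self.centroid = (poly.centroid.x, poly.centroid.y)
        self.area_px2 = float(poly.area)
        self.perimeter_px = float(poly.exterior.length)

    @property
    def polygon(self) -> geom.Polygon:
        return geom.Polygon(_close_ring(self.boundary))


@dataclass
class Patch:
    """A 40x field of segmented nuclei tied to one patient."""

    patch_id: str
    patient_id: str
    width_px: float
    height_px: float
    nuclei: list[NucleusRecord] = field(default_factory=list)
    magnification_tag: str = "40x"

    def __post_init__(self):
        if not self.patient_id:
            raise ParseError("patch requires a non-empty patient_id")
        for nuc in self.nuclei:
            x, y = nuc.centroid
            if not (0 <= x <= self.width_px and 0 <= y <= self.height_px):
                raise ParseError(
                    f"nucleus {nuc.id} centroid ({x:.1f}, {y:.1f}) outside "
                    f"{self.width_px}x{self.height_px} patch {self.patch_id}"
                )

    def compartment_nuclei(self, compartment: str) -> list[NucleusRecord]:
        return [n for n in self.nuclei if n.compartment == compartment]

    def centroids(self, compartment: str | None = None) -> np.ndarray:
        nucs = self.nuclei if compartment is None else self.compartment_nuclei(compartment)
        if not nucs:
            return np.empty((0, 2))
        return np.array([n.centroid for n in nucs])


@dataclass
class PatientCase:
    """One patient: risk scores, derived categories, and their patches."""

    patient_id: str
    odx_score: int
    odx_category: str
    mbr_score: int | None = None
    mbr_category: str | None = None
    patches: list[Patch] = field(default_factory=list)
    cohort: str = "train"
    phenotype_class: str | None = None  # ground-truth class for synthetic cases
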