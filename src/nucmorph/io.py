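"""Reading and writing nuclei representations, a classical segmentation
stand-in, and epithelium/stroma compartment assignment.

Nuclei travel as GeoJSON FeatureCollections (Polygon features with id,
compartment, orientation properties; patch metadata as foreign members)
or as integer label masks. The classical segmentation path (stain
separation -> Otsu -> watershed) lets the pipeline run end-to-end on
rendered images; externally produced label masks can be ingested
unchanged through `label_mask_to_polygons`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path as FSPath

import numpy as np
import scipy.ndimage as ndi
import shapely
import shapely.geometry as geom
import skimage.color
import skimage.draw
import skimage.filters
import skimage.measure
import skimage.morphology
import skimage.segmentation

from nucmorph.errors import ParseError
from nucmorph.types import EPITHELIAL, STROMAL, UNKNOWN, NucleusRecord, Patch

logger = logging.getLogger(__name__)

DEFAULT_AREA_MIN_PX2 = 40.0  # sub-nuclear debris threshold at 40x
DEFAULT_HMIN_PX = 2.0  # h-minima suppression depth for watershed splitting


def write_nuclei(patch: Patch, path) -> None:
    """Write a patch as a GeoJSON FeatureCollection."""
    features = []
    for nuc in patch.nuclei:
        ring = nuc.boundary.tolist()
        if ring[0] != ring[-1]:
            ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "id": nuc.id,
                    "compartment": nuc.compartment,
                    "orientation_deg": nuc.orientation_deg,
                },
            }
        )
    doc = {
        "type": "FeatureCollection",
        "patch_id": patch.patch_id,
        "patient_id": patch.patient_id,
        "width_px": patch.width_px,
        "height_px": patch.height_px,
        "magnification_tag": patch.magnification_tag,
        "features": features,
    }
    FSPath(path).write_text(json.dumps(doc))


def read_nuclei(path, format: str = "geojson") -> Patch:
    """Read a patch from GeoJSON or from a label-mask image file."""
    if format == "label_mask":
        import skimage.io

        mask = skimage.io.imread(path).astype(np.int64)
        records = label_mask_to_polygons(mask)
        return Patch(
            patch_id=FSPath(path).stem,
            patient_id="unknown",
            width_px=float(mask.shape[1]),
            height_px=float(mask.shape[0]),
            nuclei=records,
        )
    if format != "geojson":
        raise ValueError(f"unknown format {format!r}")
    doc = json.loads(FSPath(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ParseError(f"{path}: expected a GeoJSON FeatureCollection")
    nuclei = []
    for idx, feature in enumerate(doc.get("features", [])):
        try:
            geometry = feature["geometry"]
            if geometry["type"] != "Polygon":
                raise ParseError(f"feature {idx}: expected Polygon geometry")
            ring = np.asarray(geometry["coordinates"][0], dtype=float)
            props = feature.get("properties", {})
            nuclei.append(
                NucleusRecord(
                    id=int(props.get("id", idx + 1)),
                    boundary=ring,
                    compartment=props.get("compartment", UNKNOWN) or UNKNOWN,
                    orientation_deg=props.get("orientation_deg"),
                )
            )
        except ParseError as exc:
            raise ParseError(f"{path}: feature {idx}: {exc}") from exc
    return Patch(
        patch_id=doc.get("patch_id", FSPath(path).stem),
        patient_id=doc.get("patient_id", "unknown"),
        width_px=float(doc.get("width_px", 0) or _extent(nuclei, 0)),
        height_px=float(doc.get("height_px", 0) or _extent(nuclei, 1)),
        nuclei=nuclei,
        magnification_tag=doc.get("magnification_tag", "40x"),
    )


def _extent(nuclei, axis: int) -> float:
    if not nuclei:
        return 1.0
    return float(max(np.max(n.boundary[:, axis]) for n in nuclei)) + 1.0


def label_mask_to_polygons(mask: np.ndarray) -> list[NucleusRecord]:
    """One NucleusRecord per distinct positive label, sorted by label.

    Boundaries are traced at pixel resolution as the union of the
    label's pixel squares under the half-open raster convention, so a
    10x10 block of one label yields a polygon of area exactly 100 px^2.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2 or not np.issubdtype(mask.dtype, np.integer):
        raise ParseError("label mask must be a 2-D integer raster")
    if mask.min() < 0:
        raise ParseError("label mask must be non-negative")
    records = []
    for label in np.unique(mask):
        if label == 0:
            continue
        rows, cols = np.nonzero(mask == label)
        squares = [
            geom.box(float(c), float(r), float(c) + 1.0, float(r) + 1.0)
            for r, c in zip(rows, cols)
        ]
        merged = shapely.union_all(squares)
        if merged.geom_type == "MultiPolygon":
            merged = max(merged.geoms, key=lambda g: g.area)
            logger.info("label %d is disconnected; keeping largest part", label)
        boundary = np.asarray(merged.exterior.coords)[:-1]
        records.append(NucleusRecord(id=int(label), boundary=boundary))
    return records


def polygons_to_label_mask(patch: Patch) -> np.ndarray:
    """Rasterize a patch's nuclei into a uint16 label mask (later ids win)."""
    h, w = int(patch.height_px), int(patch.width_px)
    mask = np.zeros((h, w), dtype=np.uint16)
    for nuc in patch.nuclei:
        rr, cc = skimage.draw.polygon(nuc.boundary[:, 1], nuc.boundary[:, 0], shape=(h, w))
        mask[rr, cc] = nuc.id
    return mask


def segment_nuclei_classical(
    rgb: np.ndarray,
    area_min: float = DEFAULT_AREA_MIN_PX2,
    hmin: float = DEFAULT_HMIN_PX,
) -> np.ndarray:
    """Classical nucleus segmentation of an H&E-like RGB image.

    Color deconvolution to the hematoxylin channel with skimage's fixed
    stain vectors, global Otsu threshold, hole filling, removal of
    objects smaller than `area_min` px^2, then a distance-transform
    watershed seeded by h-maxima (depth `hmin`) to split touching
    nuclei. Deterministic; labels are consecutive from 1.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ParseError("segmentation expects an HxWx3 RGB image")
    hed = skimage.color.rgb2hed(rgb)
    hema = hed[:, :, 0]
    if hema.max() == hema.min():
        return np.zeros(rgb.shape[:2], dtype=np.int32)
    thresh = skimage.filters.threshold_otsu(hema)
    binary = hema > thresh
    binary = ndi.binary_fill_holes(binary)
    # objects strictly smaller than area_min px^2 are debris
    binary = skimage.morphology.remove_small_objects(binary, max_size=int(area_min) - 1)
    if not binary.any():
        return np.zeros(rgb.shape[:2], dtype=np.int32)
    distance = ndi.distance_transform_edt(binary)
    peaks = skimage.morphology.h_maxima(distance, hmin)
    markers, _ = ndi.label(peaks)
    labels = skimage.segmentation.watershed(-distance, markers, mask=binary)
    return skimage.segmentation.relabel_sequential(labels)[0].astype(np.int32)


def assign_compartment(
    nuclei: list[NucleusRecord], epithelium_mask: np.ndarray
) -> list[NucleusRecord]:
    """Assign each nucleus to epithelium or stroma against a binary mask.

    A nucleus is epithelial iff more than 50% of its covered pixels fall
    inside the mask; an exact tie falls back to the centroid-in-mask
    rule. No nucleus is left unknown. Mutates and returns the records.
    """
    mask = np.asarray(epithelium_mask) > 0
    h, w = mask.shape
    for nuc in nuclei:
        x, y = nuc.centroid
        if not (0 <= x < w and 0 <= y < h):
            raise ParseError(
                f"nucleus {nuc.id} centroid outside the {w}x{h} epithelium mask"
            )
        rr, cc = skimage.draw.polygon(nuc.boundary[:, 1], nuc.boundary[:, 0], shape=(h, w))
        if len(rr) == 0:
            rr = np.array([min(int(y), h - 1)])
            cc = np.array([min(int(x), w - 1)])
        inside = float(np.count_nonzero(mask[rr, cc]))
        frac = inside / len(rr)
        if frac > 0.5:
            nuc.compartment = EPITHELIAL
        elif frac < 0.5:
            nuc.compartment = STROMAL
        else:
            nuc.compartment = (
                EPITHELIAL if mask[min(int(y), h - 1), min(int(x), w - 1)] else STROMAL
            )
    return nuclei
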