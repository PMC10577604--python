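"""Tissue/follicle geometry and compartment-wise cell densities.

A tile's tissue is segmented from its DAPI plane (Otsu threshold followed
by morphological cleanup); follicles arrive as expert-drawn polygon
annotations (GeoJSON, μm coordinates). The intra-follicular compartment is
the union of follicles intersected with tissue, the inter-follicular
compartment the remaining tissue. A point on a follicle boundary counts as
intra (closed-polygon convention). Densities are reported as cells per
1000 μm², pooled per patient by summing counts and areas over tiles
before taking the ratio.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon, box, mapping, shape
from shapely.validation import make_valid
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "CompartmentGeometry",
    "segment_tissue",
    "mask_to_polygon",
    "load_follicle_annotations",
    "write_follicles_geojson",
    "assign_compartments",
    "cell_density",
]


@dataclass
class CompartmentGeometry:
    """Tissue polygon + follicle polygons for one tile, all in μm."""

    tissue: Polygon | MultiPolygon
    follicles: list[Polygon] = field(default_factory=list)
    tile_id: str = "tile_0"
    tissue_mask: np.ndarray | None = None
    um_per_pixel: float | None = None

    @property
    def intra(self):
        if not self.follicles:
            return Polygon()
        return shapely.union_all(self.follicles).intersection(self.tissue)

    @property
    def inter(self):
        return self.tissue.difference(self.intra)

    @property
    def areas_um2(self) -> dict[str, float]:
        intra = self.intra
        return {"tissue": self.tissue.area, "intra": intra.area, "inter": self.tissue.area - intra.area}

    def compartment_polygon(self, compartment: str):
        if compartment == "intra":
            return self.intra
        if compartment == "inter":
            return self.inter
        raise ValueError(f"compartment must be 'intra' or 'inter', got {compartment!r}")

    @classmethod
    def full_tile(cls, width_um: float, height_um: float, follicles=(), tile_id: str = "tile_0"):
        """Geometry for a tile whose whole extent is tissue (synthetic scenes)."""
        return cls(box(0.0, 0.0, width_um, height_um), list(follicles), tile_id)


def mask_to_polygon(mask: np.ndarray, um_per_pixel: float) -> Polygon | MultiPolygon:
    """Vectorise a binary mask into μm-frame polygons (even-odd holes)."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    polys = []
    for c in contours:
        # contour coords are (row, col) on the padded grid
        xy = np.column_stack([(c[:, 1] - 1.0 + 0.5), (c[:, 0] - 1.0 + 0.5)]) * um_per_pixel
        if len(xy) >= 4:
            p = Polygon(xy)
            if p.is_valid and p.area > 0:
                polys.append(p)
    if not polys:
        raise ValueError("no tissue detected")
    polys.sort(key=lambda p: p.area, reverse=True)
    shells, holes = [], []
    for p in polys:
        depth = sum(1 for q in polys if q is not p and q.contains(p))
        (shells if depth % 2 == 0 else holes).append(p)
    region = shapely.union_all(shells)
    for h in holes:
        region = region.difference(h)
    return region


def segment_tissue(dapi: np.ndarray, um_per_pixel: float, min_area_um2: float = 500.0,
                   threshold: float | None = None, closing_radius_px: int = 2):
    """Segment tissue from a single-channel DAPI image.

    Otsu threshold (or a fixed one) → binary closing → hole filling →
    small-object removal. Returns (mask, polygon in μm). Raises when no
    tissue survives the cleanup.
    """
    if dapi.ndim != 2:
        raise ValueError("segment_tissue expects a single-channel image")
    thr = threshold_otsu(dapi) if threshold is None else threshold
    mask = dapi > thr
    if not mask.any():
        raise ValueError("no tissue detected")
    mask = morphology.closing(mask, morphology.disk(closing_radius_px))
    mask = morphology.remove_small_holes(mask, max_size=int(min_area_um2 / um_per_pixel**2))
    mask = morphology.remove_small_objects(mask, max_size=int(min_area_um2 / um_per_pixel**2))
    if not mask.any():
        raise ValueError("no tissue detected")
    return mask, mask_to_polygon(mask, um_per_pixel)


def load_follicle_annotations(path) -> list[Polygon]:
    """Read follicle polygons from a GeoJSON FeatureCollection (μm frame).

    Self-intersecting rings are repaired when possible; overlapping
    follicles are unioned with a warning.
    """
    with open(path) as fh:
        gj = json.load(fh)
    polys: list[Polygon] = []
    for feat in gj.get("features", []):
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            geom = make_valid(geom)
            warnings.warn("repaired an invalid follicle polygon")
        if geom.is_empty:
            raise ValueError("follicle polygon is empty after repair")
        if isinstance(geom, MultiPolygon):
            polys.extend(geom.geoms)
        elif isinstance(geom, Polygon):
            polys.append(geom)
        else:
            raise ValueError(f"unsupported follicle geometry type {geom.geom_type}")
    # union overlapping follicles
    merged = shapely.union_all(polys) if polys else Polygon()
    parts = list(merged.geoms) if isinstance(merged, MultiPolygon) else ([merged] if not merged.is_empty else [])
    if len(parts) < len(polys):
        warnings.warn(f"{len(polys) - len(parts)} overlapping follicle(s) merged")
    return parts


def write_follicles_geojson(follicles: list[Polygon], path, tile_id: str = "tile_0") -> None:
    features = [
        {"type": "Feature", "geometry": mapping(p), "properties": {"tile_id": tile_id, "units": "um"}}
        for p in follicles
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def assign_compartments(cell_map: pd.DataFrame, geometry: CompartmentGeometry,
                        warn_exclusion_rate: float = 0.2) -> pd.DataFrame:
    """Label each cell intra / inter / excluded (outside tissue).

    Boundary points count as inside (shapely `intersects`, closed sets).
    Returns a copy with a 'compartment' column; a high exclusion rate
    triggers a warning.
    """
    out = cell_map.copy()
    x = out["x_um"].to_numpy(dtype=float)
    y = out["y_um"].to_numpy(dtype=float)
    in_tissue = shapely.intersects_xy(geometry.tissue, x, y)
    if geometry.follicles:
        foll = shapely.union_all(geometry.follicles)
        in_foll = shapely.intersects_xy(foll, x, y)
    else:
        in_foll = np.zeros(len(out), dtype=bool)
    comp = np.where(~in_tissue, "excluded", np.where(in_foll, "intra", "inter"))
    out["compartment"] = comp
    n_excl = int((comp == "excluded").sum())
    if len(out) and n_excl / len(out) > warn_exclusion_rate:
        warnings.warn(f"{n_excl}/{len(out)} cells fall outside the tissue mask")
    return out


def cell_density(cell_map: pd.DataFrame, geometries: dict[str, CompartmentGeometry],
                 phenotype: str, compartment: str) -> pd.DataFrame:
    """Per-patient density of a phenotype in a compartment (cells/1000 μm²).

    Counts and areas are summed over each patient's tiles before the
    ratio. `cell_map` needs patient_id, tile_id and an assigned
    'compartment' column. A patient whose pooled area is zero gets NaN.
    """
    from .panels import phenotype_mask

    if compartment not in ("intra", "inter"):
        raise ValueError("compartment must be 'intra' or 'inter'")
    sel = cell_map[phenotype_mask(cell_map, phenotype) & (cell_map["compartment"] == compartment)]
    counts = sel.groupby(["patient_id", "tile_id"]).size()
    tile_patient = cell_map[["patient_id", "tile_id"]].drop_duplicates()
    rows = []
    for pid, grp in tile_patient.groupby("patient_id"):
        n = 0
        area = 0.0
        for tid in grp["tile_id"]:
            area += geometries[tid].areas_um2[compartment]
            n += int(counts.get((pid, tid), 0))
        dens = 1000.0 * n / area if area > 0 else float("nan")
        rows.append((pid, phenotype, compartment, n, area, dens))
    return pd.DataFrame(rows, columns=["patient_id", "phenotype", "compartment", "n_cells", "area_um2", "density"])
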