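"""Quadrat tessellation, Morisita-Horn co-localization, nearest neighbours.

Each tissue compartment is divided into quadrats: the Voronoi cells of a
hexagonal seed lattice (default pitch 50 μm) clipped to the compartment.
Counting two phenotypes per quadrat yields paired count vectors for the
Morisita-Horn overlap index

    MH(x, y) = 2 Σ x_i y_i / [(Σx_i²/X² + Σy_i²/Y²) · X · Y],   X = Σx_i, Y = Σy_i,

which is 0 for spatially segregated and 1 for identically distributed
populations. Per-patient values concatenate quadrat vectors over the
patient's tiles (constant quadrat scale) rather than averaging per-tile
indices. Nearest-neighbour profiles report, for every reference-phenotype
cell, the closest candidate cell (self excluded, per-tile search) and its
distance.

A point's Voronoi cell is by definition the region nearer to its seed than
to any other, so quadrat membership of a cell is computed exactly by
nearest-seed lookup (KD-tree); polygon clipping is only needed for areas
and export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import Polygon

from .compartments import CompartmentGeometry
from .panels import phenotype_mask

__all__ = [
    "QuadratTessellation",
    "hex_lattice",
    "tessellate_compartment",
    "quadrat_counts",
    "morisita_horn",
    "MHResult",
    "colocalization",
    "NNResult",
    "nearest_neighbor_profile",
]


@dataclass
class QuadratTessellation:
    tile_id: str
    compartment: str
    seeds: np.ndarray  # (m, 2) seed positions whose Voronoi cells meet the compartment
    polygons: list[Polygon] | None  # clipped Voronoi cells, aligned with seeds
    areas_um2: np.ndarray | None
    compartment_area_um2: float


def hex_lattice(bounds: tuple[float, float, float, float], pitch: float) -> np.ndarray:
    """Hexagonal seed lattice (nearest-neighbour distance = pitch) inside bounds.

    Rows are pitch*sqrt(3)/2 apart, alternate rows offset by pitch/2;
    the lattice is inset half a pitch from the bounding box so boundary
    quadrats are not degenerate slivers.
    """
    minx, miny, maxx, maxy = bounds
    dy = pitch * np.sqrt(3.0) / 2.0
    pts = []
    row = 0
    y = miny + dy / 2.0
    while y <= maxy:
        off = (pitch / 2.0) if (row % 2) else 0.0
        x = minx + pitch / 2.0 + off
        while x <= maxx:
            pts.append((x, y))
            x += pitch
        y += dy
        row += 1
    return np.array(pts) if pts else np.empty((0, 2))


def _voronoi_polygons(seeds: np.ndarray) -> list[Polygon]:
    """Finite Voronoi polygons of `seeds`, using a far ghost ring to bound them."""
    minx, miny = seeds.min(axis=0)
    maxx, maxy = seeds.max(axis=0)
    span = max(maxx - minx, maxy - miny, 1.0) * 10.0
    cx, cy = (minx + maxx) / 2.0, (miny + maxy) / 2.0
    ang = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    ghosts = np.column_stack([cx + span * np.cos(ang), cy + span * np.sin(ang)])
    vor = Voronoi(np.vstack([seeds, ghosts]))
    polys = []
    for i in range(len(seeds)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            polys.append(None)  # pragma: no cover - ghost ring keeps cells finite
        else:
            polys.append(Polygon(vor.vertices[region]))
    return polys


def tessellate_compartment(geometry: CompartmentGeometry, compartment: str,
                           seed_spacing: float = 50.0, build_polygons: bool = True) -> QuadratTessellation:
    """Voronoi-quadrat tessellation of one compartment.

    Seeds are a hexagonal lattice of pitch `seed_spacing` over the
    compartment's bounding box; Voronoi cells are clipped to the
    compartment and empty quadrats dropped. With ``build_polygons=False``
    only the seeds are kept (exact for counting, much faster) and the
    retained seeds are those nearest to at least one lattice sample of the
    compartment — counts are unaffected because a cell's quadrat is its
    nearest seed either way.
    """
    if seed_spacing <= 0:
        raise ValueError("seed_spacing must be > 0")
    region = geometry.compartment_polygon(compartment)
    if region.is_empty or region.area <= 0:
        raise ValueError(f"compartment {compartment!r} has zero area")
    seeds = hex_lattice(region.bounds, seed_spacing)
    if len(seeds) == 0:
        warnings.warn("compartment smaller than one quadrat: single-quadrat tessellation")
        p = region.representative_point()
        seeds = np.array([[p.x, p.y]])
    if build_polygons:
        polys = _voronoi_polygons(seeds)
        keep, kept_polys, areas = [], [], []
        for i, p in enumerate(polys):
            if p is None:
                continue
            clipped = p.intersection(region)
            if not clipped.is_empty and clipped.area > 0:
                keep.append(i)
                kept_polys.append(clipped)
                areas.append(clipped.area)
        if len(keep) <= 1:
            warnings.warn("compartment smaller than one quadrat: single-quadrat tessellation")
        return QuadratTessellation(geometry.tile_id, compartment, seeds[keep],
                                   kept_polys, np.array(areas), region.area)
    # fast path: keep every seed; empty quadrats receive no cells and do not
    # perturb Morisita-Horn (0-0 pairs contribute nothing)
    return QuadratTessellation(geometry.tile_id, compartment, seeds, None, None, region.area)


def quadrat_counts(tess: QuadratTessellation, xy: np.ndarray) -> np.ndarray:
    """Cells-per-quadrat by exact nearest-seed assignment."""
    counts = np.zeros(len(tess.seeds), dtype=int)
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    if len(xy):
        _, idx = cKDTree(tess.seeds).query(xy)
        np.add.at(counts, idx, 1)
    return counts


def morisita_horn(x_counts, y_counts) -> float:
    """Morisita-Horn overlap of two quadrat count vectors (0..1).

    Returns NaN when either population is empty.
    """
    x = np.asarray(x_counts, dtype=float)
    y = np.asarray(y_counts, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be non-negative")
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        return float("nan")
    # denominator written so both addends swap under x <-> y: the result is
    # bit-identical either way round
    denom = (x * x).sum() * Y / X + (y * y).sum() * X / Y
    return float(2.0 * (x * y).sum() / denom)


@dataclass
class MHResult:
    patient_id: str
    compartment: str
    phenotype_a: str
    phenotype_b: str
    mh: float
    n_quadrats: int
    total_a: int
    total_b: int
    reason: str | None = None  # why mh is missing, if it is


def colocalization(cell_map: pd.DataFrame, phenotype_a: str, phenotype_b: str,
                   tessellations: dict[str, QuadratTessellation], compartment: str) -> list[MHResult]:
    """Per-patient Morisita-Horn co-localization of two phenotypes.

    Each tile is tessellated separately; a patient's quadrat count vectors
    are concatenated across tiles, then fed to `morisita_horn`. Patients
    with either phenotype absent from the compartment get a flagged
    missing value.
    """
    cm = cell_map[cell_map["compartment"] == compartment]
    mask_a = phenotype_mask(cm, phenotype_a)
    mask_b = phenotype_mask(cm, phenotype_b)
    results = []
    for pid, grp in cm.groupby("patient_id", sort=True):
        xs, ys = [], []
        for tid, tgrp in grp.groupby("tile_id", sort=True):
            tess = tessellations[tid]
            if tess.compartment != compartment:
                raise ValueError("tessellation compartment mismatch")
            loc = cm.index.get_indexer(tgrp.index)
            pts = tgrp[["x_um", "y_um"]].to_numpy()
            xs.append(quadrat_counts(tess, pts[mask_a[loc]]))
            ys.append(quadrat_counts(tess, pts[mask_b[loc]]))
        x = np.concatenate(xs) if xs else np.zeros(0)
        y = np.concatenate(ys) if ys else np.zeros(0)
        X, Y = int(x.sum()), int(y.sum())
        if X == 0 or Y == 0:
            results.append(MHResult(pid, compartment, phenotype_a, phenotype_b, float("nan"),
                                    len(x), X, Y, reason="phenotype absent in compartment"))
        else:
            results.append(MHResult(pid, compartment, phenotype_a, phenotype_b,
                                    morisita_horn(x, y), len(x), X, Y))
    return results


@dataclass
class NNResult:
    reference: str
    compartment: str
    per_cell: pd.DataFrame  # cell_id, tile_id, nn_cell_id, nn_phenotype, nn_distance_um
    summary: pd.DataFrame  # nn_phenotype, n, median_um, q1_um, q3_um


def nearest_neighbor_profile(cell_map: pd.DataFrame, reference: str,
                             candidates: list[str], compartment: str) -> NNResult | None:
    """For each reference-phenotype cell, the nearest candidate cell.

    The search is Euclidean within each tile (distances never cross tile
    boundaries); a cell matching both reference and a candidate phenotype
    is excluded from being its own neighbour, so distances are strictly
    positive. Each candidate cell is labelled with the first candidate
    phenotype it matches, in the order given. Returns None when no
    candidate cells exist in the compartment.
    """
    cm = cell_map[cell_map["compartment"] == compartment]
    ref_mask = phenotype_mask(cm, reference)
    cand_label = np.array([""] * len(cm), dtype=object)
    cand_mask = np.zeros(len(cm), dtype=bool)
    for lab in reversed(candidates):  # earlier labels take precedence
        m = phenotype_mask(cm, lab)
        cand_label[m] = lab
        cand_mask |= m
    if not cand_mask.any() or not ref_mask.any():
        return None
    rows = []
    for tid, tgrp in cm.groupby("tile_id", sort=True):
        loc = cm.index.get_indexer(tgrp.index)
        refs = tgrp[ref_mask[loc]]
        cands = tgrp[cand_mask[loc]]
        if len(refs) == 0 or len(cands) == 0:
            continue
        labels = cand_label[loc][cand_mask[loc]]
        tree = cKDTree(cands[["x_um", "y_um"]].to_numpy())
        ref_xy = refs[["x_um", "y_um"]].to_numpy()
        dists, idxs = tree.query(ref_xy, k=min(2, len(cands)))
        dists = np.atleast_2d(dists.T).T
        idxs = np.atleast_2d(idxs.T).T
        cand_ids = cands["cell_id"].to_numpy()
        for r, (cid, xy) in enumerate(zip(refs["cell_id"], ref_xy)):
            pick = None
            for kk in range(dists.shape[1]):
                if cand_ids[idxs[r, kk]] != cid:
                    pick = kk
                    break
            if pick is None:
                continue  # the only candidate is the reference cell itself
            j = idxs[r, pick]
            rows.append((cid, tid, cand_ids[j], labels[j], float(dists[r, pick])))
    if not rows:
        return None
    per_cell = pd.DataFrame(rows, columns=["cell_id", "tile_id", "nn_cell_id", "nn_phenotype", "nn_distance_um"])
    summary = (
        per_cell.groupby("nn_phenotype")["nn_distance_um"]
        .agg(n="size", median_um="median",
             q1_um=lambda s: s.quantile(0.25), q3_um=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return NNResult(reference, compartment, per_cell, summary)
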