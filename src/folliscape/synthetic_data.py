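"""Synthetic scene and cohort generation.

Emulates the three inputs of a compartment-aware multiplexed-IF study of
follicular lymphoma, none of which are publicly deposited for real tissue:

* per-marker "deconvoluted" tiles (2-channel images: DAPI + positive stain),
* ground-truth cell maps with controlled spatial structure — homogeneous
  Poisson placement per compartment plus an optional Thomas-style
  parent/offspring coupling between phenotype pairs that creates tunable
  spatial co-localization,
* a survival-linked cohort: per-patient spatial parameters with random
  effects, time-to-progression drawn from an exponential proportional-
  hazards model on the true (generator-level) features, administrative
  censoring, and a 3-level FLIPI-style risk category.

Coordinates are continuous micrometres, origin at the tile's top-left,
y increasing downward (image convention).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.affinity import rotate, scale
from shapely.geometry import Point, Polygon, box, mapping

from .panels import PANELS, canonical_label, parse_label

__all__ = [
    "SceneConfig",
    "CohortConfig",
    "GroundTruth",
    "generate_cell_map",
    "render_deconvoluted_tiles",
    "generate_cohort",
    "write_truth_csv",
    "write_follicles_geojson",
    "write_clinical_csv",
]


@dataclass
class SceneConfig:
    """Parameters of one synthetic tile.

    Densities are cells per 1000 μm², given per phenotype label as
    (intra-follicular, inter-follicular). ``coupling`` maps a phenotype
    pair (A, B) to (kappa, sigma_um): a fraction kappa of B cells are
    placed as Gaussian offspring (scale sigma_um) of random A parents in
    the same compartment.
    """

    width_um: float = 1338.0
    height_um: float = 1000.0
    um_per_pixel: float = 0.5
    panel: str = "t_cell"
    n_follicles: int = 3
    follicle_radius_range: tuple[float, float] = (120.0, 250.0)
    phenotype_densities: dict[str, tuple[float, float]] = field(default_factory=dict)
    coupling: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    background_level: float = 0.05
    noise_sd: float = 0.02
    blob_radius_um: float = 3.0
    intensity_jitter: float = 0.15
    min_separation_um: float = 0.0  # hard-core radius between nuclei; 0 = pure Poisson
    seed: int = 0
    max_placement_attempts: int = 5000

    def __post_init__(self):
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be > 0")
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("tile dimensions must be > 0")
        if self.panel not in PANELS:
            raise ValueError(f"unknown panel {self.panel!r}; options: {sorted(PANELS)}")
        for label, (d_in, d_out) in self.phenotype_densities.items():
            parse_label(label)
            if d_in < 0 or d_out < 0:
                raise ValueError(f"negative density for {label!r}")
        for (a, b), (kappa, sigma) in self.coupling.items():
            if not 0.0 <= kappa <= 1.0:
                raise ValueError(f"coupling kappa for ({a},{b}) must be in [0,1]")
            if sigma <= 0:
                raise ValueError("coupling sigma must be > 0")

    @property
    def markers(self) -> list[str]:
        return PANELS[self.panel]


@dataclass
class GroundTruth:
    """A generated tile: cell table, follicle polygons, true densities.

    ``cells`` columns: tile_id, x_um, y_um, one ``<marker>_pos`` boolean per
    panel marker, phenotype (canonical label).
    """

    cells: pd.DataFrame
    follicles: list[Polygon]
    config: SceneConfig
    true_densities: dict[tuple[str, str], float]  # (phenotype, compartment) -> cells/1000um2
    tile_id: str = "tile_0"

    @property
    def tile_polygon(self) -> Polygon:
        return box(0.0, 0.0, self.config.width_um, self.config.height_um)

    @property
    def intra_polygon(self):
        if not self.follicles:
            return Polygon()
        return shapely.union_all(self.follicles).intersection(self.tile_polygon)

    @property
    def inter_polygon(self):
        return self.tile_polygon.difference(self.intra_polygon)


def _place_follicles(cfg: SceneConfig, rng: np.random.Generator) -> list[Polygon]:
    """Rejection-sample non-overlapping ellipses fully inside the tile."""
    follicles: list[Polygon] = []
    attempts = 0
    lo, hi = cfg.follicle_radius_range
    while len(follicles) < cfg.n_follicles:
        if attempts >= cfg.max_placement_attempts:
            raise RuntimeError(
                f"could not place {cfg.n_follicles} non-overlapping follicles "
                f"of radius {cfg.follicle_radius_range} μm in a "
                f"{cfg.width_um}x{cfg.height_um} μm tile after {attempts} attempts"
            )
        attempts += 1
        r = rng.uniform(lo, hi)
        ratio = rng.uniform(0.7, 1.0)
        angle = rng.uniform(0.0, 180.0)
        if 2 * r >= cfg.width_um or 2 * r >= cfg.height_um:
            raise RuntimeError("follicle radius exceeds tile size")
        cx = rng.uniform(r, cfg.width_um - r)
        cy = rng.uniform(r, cfg.height_um - r)
        ell = scale(Point(cx, cy).buffer(1.0, quad_segs=48), r, r * ratio)
        ell = rotate(ell, angle, origin=(cx, cy))
        if any(ell.intersects(f) for f in follicles):
            continue
        follicles.append(ell)
    return follicles


def _sample_uniform_in(region, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in a shapely region by bounding-box rejection."""
    if n == 0 or region.is_empty:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = region.bounds
    out = np.empty((0, 2))
    # expected acceptance rate = area / bbox area
    rate = max(region.area / ((maxx - minx) * (maxy - miny)), 1e-3)
    while len(out) < n:
        m = int((n - len(out)) / rate * 1.3) + 16
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(region, xs, ys)
        out = np.vstack([out, np.column_stack([xs[keep], ys[keep]])])
    return out[:n]


def generate_cell_map(config: SceneConfig, tile_id: str = "tile_0") -> GroundTruth:
    """Generate one tile's ground-truth cell map.

    Follicles are placed by rejection sampling (non-overlapping ellipses);
    each phenotype is a homogeneous Poisson process per compartment at its
    configured density; coupled phenotypes get a Thomas-style fraction of
    offspring cells around parents of the partner phenotype. Deterministic
    given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    follicles = _place_follicles(config, rng) if config.n_follicles > 0 else []
    tile = box(0.0, 0.0, config.width_um, config.height_um)
    intra = shapely.union_all(follicles).intersection(tile) if follicles else Polygon()
    inter = tile.difference(intra)
    regions = {"intra": intra, "inter": inter}

    coupled_children = {b: (a, k, s) for (a, b), (k, s) in config.coupling.items()}
    labels = list(config.phenotype_densities)
    # parents first so offspring can attach
    labels.sort(key=lambda lb: (lb in coupled_children, lb))

    points: dict[str, dict[str, np.ndarray]] = {}
    true_densities: dict[tuple[str, str], float] = {}
    for label in labels:
        d_intra, d_inter = config.phenotype_densities[label]
        points[label] = {}
        for comp, dens in (("intra", d_intra), ("inter", d_inter)):
            region = regions[comp]
            true_densities[(label, comp)] = dens
            area = region.area
            n = rng.poisson(dens * area / 1000.0) if area > 0 and dens > 0 else 0
            if label in coupled_children and n > 0:
                parent_label, kappa, sigma = coupled_children[label]
                parents = points.get(parent_label, {}).get(comp, np.empty((0, 2)))
                n_off = rng.binomial(n, kappa) if len(parents) else 0
                pts = [_sample_uniform_in(region, n - n_off, rng)]
                if n_off:
                    idx = rng.integers(0, len(parents), n_off)
                    off = parents[idx] + rng.normal(0.0, sigma, size=(n_off, 2))
                    # resample offspring that left the compartment
                    for i in range(n_off):
                        tries = 0
                        while not shapely.contains_xy(region, off[i, 0], off[i, 1]) and tries < 100:
                            off[i] = parents[idx[i]] + rng.normal(0.0, sigma, size=2)
                            tries += 1
                        if tries >= 100:
                            off[i] = parents[idx[i]]
                    pts.append(off)
                pts = np.vstack(pts)
            else:
                pts = _sample_uniform_in(region, n, rng)
            points[label][comp] = pts

    if config.min_separation_um > 0:
        # hard-core thinning across all phenotypes (nuclei cannot overlap);
        # candidates are visited in random order so no phenotype is
        # preferentially retained
        r2 = config.min_separation_um**2
        entries = [
            (label, comp, i)
            for label in labels
            for comp in ("intra", "inter")
            for i in range(len(points[label][comp]))
        ]
        order = rng.permutation(len(entries))
        accepted = np.empty((0, 2))
        keep: dict[tuple[str, str], list[int]] = {}
        for k in order:
            label, comp, i = entries[k]
            p = points[label][comp][i]
            if len(accepted) == 0 or np.min(((accepted - p) ** 2).sum(axis=1)) >= r2:
                accepted = np.vstack([accepted, p[None]])
                keep.setdefault((label, comp), []).append(i)
        for label in labels:
            for comp in ("intra", "inter"):
                idx = sorted(keep.get((label, comp), []))
                points[label][comp] = points[label][comp][idx]

    markers = config.markers
    rows = []
    for label in labels:
        constraints = parse_label(label)
        positivity = {m: constraints.get(m, False) for m in markers}
        canon = canonical_label(positivity, markers)
        for comp in ("intra", "inter"):
            for x, y in points[label][comp]:
                rows.append((tile_id, x, y, *[positivity[m] for m in markers], canon))
    cells = pd.DataFrame(rows, columns=["tile_id", "x_um", "y_um", *[f"{m}_pos" for m in markers], "phenotype"])
    cells.insert(0, "cell_id", [f"{tile_id}_c{i}" for i in range(len(cells))])
    return GroundTruth(cells=cells, follicles=follicles, config=config, true_densities=true_densities, tile_id=tile_id)


def _gaussian_blob(sigma_px: float) -> np.ndarray:
    r = max(int(np.ceil(3 * sigma_px)), 1)
    ax = np.arange(-r, r + 1)
    xx, yy = np.meshgrid(ax, ax)
    return np.exp(-(xx**2 + yy**2) / (2.0 * sigma_px**2))


def render_deconvoluted_tiles(
    truth: GroundTruth, config: SceneConfig | None = None, noise: bool = True
) -> dict[str, np.ndarray]:
    """Render one 2-channel image per panel marker.

    Channel 0 is DAPI (every cell gets a nuclear blob), channel 1 the
    positive stain (only marker-positive cells). Blobs are Gaussian with
    sigma = blob_radius/2; additive Gaussian background noise on top of a
    constant background level when ``noise`` is True. Cell centres are
    rasterised half-up onto the pixel grid.
    """
    cfg = config or truth.config
    upp = cfg.um_per_pixel
    if cfg.blob_radius_um / upp < 1.0:
        raise ValueError("blob radius below one pixel: cells unresolvable at this resolution")
    h = int(round(cfg.height_um / upp))
    w = int(round(cfg.width_um / upp))
    sigma_px = (cfg.blob_radius_um / upp) / 2.0
    kern = _gaussian_blob(sigma_px)
    r = kern.shape[0] // 2

    cells = truth.cells
    px = np.floor(cells["x_um"].to_numpy() / upp + 0.5).astype(int).clip(0, w - 1)
    py = np.floor(cells["y_um"].to_numpy() / upp + 0.5).astype(int).clip(0, h - 1)
    rng = np.random.default_rng(cfg.seed + 1)
    amps = 1.0 + rng.normal(0.0, cfg.intensity_jitter, size=len(cells))
    amps = np.clip(amps, 0.3, None)

    def paint(mask: np.ndarray) -> np.ndarray:
        img = np.zeros((h, w))
        for x, y, a in zip(px[mask], py[mask], amps[mask]):
            y0, y1 = max(y - r, 0), min(y + r + 1, h)
            x0, x1 = max(x - r, 0), min(x + r + 1, w)
            img[y0:y1, x0:x1] = np.maximum(
                img[y0:y1, x0:x1], a * kern[r - (y - y0) : r + (y1 - y), r - (x - x0) : r + (x1 - x)]
            )
        return img

    all_mask = np.ones(len(cells), dtype=bool)
    dapi = paint(all_mask)
    out: dict[str, np.ndarray] = {}
    for marker in cfg.markers:
        pos = cells[f"{marker}_pos"].to_numpy(dtype=bool)
        stain = paint(pos)
        img = np.stack([dapi, stain])
        if noise:
            img = img + cfg.background_level + rng.normal(0.0, cfg.noise_sd, size=img.shape)
            img = np.clip(img, 0.0, None)
        out[marker] = img.astype(np.float32)
    return out


@dataclass
class CohortConfig:
    """Parameters of a synthetic patient cohort.

    ``hazard_spec`` maps a *true-feature* name to a log-hazard coefficient
    applied to the cohort-standardised feature; features available are
    ``density_<label>_<compartment>`` for every configured phenotype and
    ``coloc_<A>__<B>`` (the per-patient coupling strength kappa) for every
    coupled pair. TTP is exponential with rate
    baseline_hazard * exp(sum beta_j z_j), censored at the horizon.
    """

    n_patients: int = 32
    tiles_per_patient: int = 4
    scene: SceneConfig = field(default_factory=SceneConfig)
    density_log_sd: float = 0.35  # between-patient lognormal random effect
    kappa_range: tuple[float, float] = (0.05, 0.95)
    hazard_spec: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.2  # events / year
    censor_horizon_years: float = 12.0
    flipi_probs: tuple[float, float, float] = (0.094, 0.5, 0.406)
    treatment_probs: tuple[float, float] = (0.813, 0.187)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.censor_horizon_years <= 0:
            raise ValueError("censoring horizon must be > 0")
        if abs(sum(self.flipi_probs) - 1.0) > 1e-9:
            raise ValueError("FLIPI probabilities must sum to 1")


FLIPI_LEVELS = ["low", "intermediate", "high"]
TREATMENTS = ["R-CHOP", "R-CVP"]


def true_feature_names(cfg: CohortConfig) -> list[str]:
    names = []
    for label in cfg.scene.phenotype_densities:
        for comp in ("intra", "inter"):
            names.append(f"density_{label}_{comp}")
    for a, b in cfg.scene.coupling:
        names.append(f"coloc_{a}__{b}")
    return names


def generate_cohort(
    config: CohortConfig, scenes: bool = True
) -> tuple[dict[str, list[GroundTruth]], pd.DataFrame]:
    """Generate a survival-linked cohort.

    Returns (scenes_by_patient, clinical table). The clinical table carries
    patient_id, ttp_years, event, flipi, treatment plus the TRUE generator
    features as ``true_<name>`` columns. With ``scenes=False`` only the
    clinical table is populated (scenes_by_patient empty) — used when only
    the survival linkage is under study.
    """
    rng = np.random.default_rng(config.seed)
    names = true_feature_names(config)
    unknown = set(config.hazard_spec) - set(names)
    if unknown:
        raise ValueError(f"hazard_spec names not generated by this scene config: {sorted(unknown)}")

    feats = np.empty((config.n_patients, len(names)))
    per_patient_scene_params: list[tuple[dict, dict]] = []
    for i in range(config.n_patients):
        dens_mult = {
            label: rng.lognormal(0.0, config.density_log_sd)
            for label in config.scene.phenotype_densities
        }
        kappas = {
            pair: rng.uniform(*config.kappa_range) for pair in config.scene.coupling
        }
        per_patient_scene_params.append((dens_mult, kappas))
        vals = []
        for label, (d_in, d_out) in config.scene.phenotype_densities.items():
            vals += [d_in * dens_mult[label], d_out * dens_mult[label]]
        vals += [kappas[p] for p in config.scene.coupling]
        feats[i] = vals

    sd = feats.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (feats - feats.mean(axis=0)) / sd
    beta = np.array([config.hazard_spec.get(n, 0.0) for n in names])
    hazard = config.baseline_hazard * np.exp(z @ beta)
    t_event = rng.exponential(1.0 / hazard)
    event = t_event <= config.censor_horizon_years
    ttp = np.minimum(t_event, config.censor_horizon_years)
    ttp = np.maximum(ttp, 1e-4)
    if not event.any():
        warnings.warn("cohort is entirely censored under this configuration")

    flipi = rng.choice(FLIPI_LEVELS, size=config.n_patients, p=config.flipi_probs)
    treatment = rng.choice(TREATMENTS, size=config.n_patients, p=config.treatment_probs)
    clinical = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(config.n_patients)],
            "ttp_years": ttp,
            "event": event.astype(int),
            "flipi": flipi,
            "treatment": treatment,
        }
    )
    for j, n in enumerate(names):
        clinical[f"true_{n}"] = feats[:, j]

    scenes_by_patient: dict[str, list[GroundTruth]] = {}
    if scenes:
        for i, pid in enumerate(clinical["patient_id"]):
            dens_mult, kappas = per_patient_scene_params[i]
            densities = {
                label: (d_in * dens_mult[label], d_out * dens_mult[label])
                for label, (d_in, d_out) in config.scene.phenotype_densities.items()
            }
            coupling = {
                pair: (kappas[pair], sigma)
                for pair, (_, sigma) in config.scene.coupling.items()
            }
            tiles = []
            for t in range(config.tiles_per_patient):
                scfg_kwargs = {
                    **{k: getattr(config.scene, k) for k in (
                        "width_um", "height_um", "um_per_pixel", "panel", "n_follicles",
                        "follicle_radius_range", "background_level", "noise_sd",
                        "blob_radius_um", "intensity_jitter", "max_placement_attempts",
                    )},
                    "phenotype_densities": densities,
                    "coupling": coupling,
                    "seed": int(rng.integers(0, 2**31 - 1)),
                }
                truth = generate_cell_map(SceneConfig(**scfg_kwargs), tile_id=f"{pid}_t{t}")
                truth.cells.insert(0, "patient_id", pid)
                tiles.append(truth)
            scenes_by_patient[pid] = tiles
    return scenes_by_patient, clinical


# ---------------------------------------------------------------------------
# writers


def write_truth_csv(truths: list[GroundTruth], path) -> None:
    pd.concat([t.cells for t in truths], ignore_index=True).to_csv(path, index=False)


def write_follicles_geojson(truth: GroundTruth, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"tile_id": truth.tile_id, "units": "um"},
        }
        for poly in truth.follicles
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_clinical_csv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False)


def write_tiles_tiff(truth: GroundTruth, out_dir, config: SceneConfig | None = None) -> list:
    """Render and write one 2-channel TIFF per marker: <tile_id>_<marker>.tif."""
    import pathlib

    import tifffile

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for marker, img in render_deconvoluted_tiles(truth, config).items():
        p = out / f"{truth.tile_id}_{marker}.tif"
        tifffile.imwrite(p, img)
        paths.append(p)
    return paths
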