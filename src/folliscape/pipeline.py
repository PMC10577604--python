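"""End-to-end orchestration: config, stages, manifest, validation.

A run is a pure function of (inputs, config, seed): the manifest records
the config snapshot, per-artifact SHA-256 checksums, timestamps and every
statistics-affecting warning, so identical runs reproduce identical
checksums for deterministic stages.

Stages: synth → compartments → spatial → prognosis, with detect/phenotype
available for image-based runs. A stage is skipped when its output is
supplied externally (e.g. a user-provided cell-map CSV).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import compartments as comp
from . import prognosis as prog
from . import spatial_stats as sps
from . import synthetic_data as synth
from .panels import PANELS

__all__ = ["StageToggles", "RunConfig", "run_pipeline", "validate_cellmap"]


class StageToggles(BaseModel):
    synth: bool = True
    detect: bool = False
    phenotype: bool = False
    compartments: bool = True
    spatial: bool = True
    prognosis: bool = True


class RunConfig(BaseModel):
    """Validated run configuration (YAML-loadable).

    Defaults mirror the documented module defaults, so a bare config
    reproduces documented behaviour.
    """

    out_dir: str
    seed: int = 0
    stages: StageToggles = Field(default_factory=StageToggles)
    panel: str = "t_cell"
    cellmap_csv: str | None = None  # external cell map: skips synth ground truth
    clinical_csv: str | None = None
    n_patients: int = 20
    tiles_per_patient: int = 2
    tile_width_um: float = 600.0
    tile_height_um: float = 600.0
    n_follicles: int = 2
    follicle_radius_min_um: float = 80.0
    follicle_radius_max_um: float = 150.0
    phenotype_densities: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "CD8+FOXP3+": (0.5, 1.5),
            "CD4+CD8+": (0.5, 1.5),
            "CD4+": (2.0, 3.0),
            "FOXP3+": (1.0, 1.5),
        }
    )
    coloc_pairs: list[tuple[str, str]] = Field(default_factory=lambda: [("CD8+FOXP3+", "CD4+CD8+")])
    coupling_sigma_um: float = 15.0
    hazard_spec: dict[str, float] = Field(default_factory=dict)
    baseline_hazard: float = 0.15
    censor_horizon_years: float = 12.0
    seed_spacing_um: float = 50.0
    merge_radius_um: float = 5.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_cellmap(csv_path, panel: str = "t_cell") -> tuple[pd.DataFrame | None, list[str]]:
    """Schema-check a cell-map CSV; returns (frame or None, issue list).

    Issues carry 1-based data-row numbers; malformed rows are reported,
    never silently dropped.
    """
    issues: list[str] = []
    try:
        df = pd.read_csv(csv_path)
    except Exception as exc:  # unreadable / unparsable
        return None, [f"unreadable CSV: {exc}"]
    required = ["tile_id", "x_um", "y_um"]
    marker_cols = [f"{m}_pos" for m in PANELS[panel]]
    for c in required + marker_cols:
        if c not in df.columns:
            issues.append(f"missing column {c!r}")
    if issues:
        return None, issues
    for c in ("x_um", "y_um"):
        vals = pd.to_numeric(df[c], errors="coerce")
        for i in np.nonzero(~np.isfinite(vals.to_numpy()))[0]:
            issues.append(f"row {i + 1}: non-finite {c}")
        for i in np.nonzero((vals < 0).to_numpy())[0]:
            issues.append(f"row {i + 1}: negative coordinate {c}")
    for c in marker_cols:
        ok = df[c].isin([True, False, 0, 1, "True", "False"])
        for i in np.nonzero(~ok.to_numpy())[0]:
            issues.append(f"row {i + 1}: non-boolean value in {c}")
    if "cell_id" in df.columns:
        dup = df["cell_id"].duplicated()
        for i in np.nonzero(dup.to_numpy())[0]:
            issues.append(f"row {i + 1}: duplicate cell_id {df['cell_id'].iloc[i]!r}")
    return (df if not issues else None), issues


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.model_dump(mode="json"),
        "package_version": __import__("folliscape").__version__,
        "started": datetime.datetime.now().isoformat(),
        "stages": {},
        "warnings": [],
        "checksums": {},
    }
    captured: list[str] = []

    def note_artifact(name: str, path: Path):
        manifest["checksums"][name] = _sha256(path)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        scenes_by_patient: dict[str, list[synth.GroundTruth]] = {}
        clinical = None
        cell_map = None

        if config.cellmap_csv is not None:
            cell_map, issues = validate_cellmap(config.cellmap_csv, config.panel)
            if cell_map is None:
                raise ValueError("invalid cell map: " + "; ".join(issues))
            clinical = pd.read_csv(config.clinical_csv) if config.clinical_csv else None
            manifest["stages"]["synth"] = "skipped (external cell map)"
        elif config.stages.synth:
            scene = synth.SceneConfig(
                width_um=config.tile_width_um, height_um=config.tile_height_um,
                panel=config.panel, n_follicles=config.n_follicles,
                follicle_radius_range=(config.follicle_radius_min_um, config.follicle_radius_max_um),
                phenotype_densities=config.phenotype_densities,
                coupling={tuple(p): (0.5, config.coupling_sigma_um) for p in config.coloc_pairs},
                seed=config.seed,
            )
            cohort = synth.CohortConfig(
                n_patients=config.n_patients, tiles_per_patient=config.tiles_per_patient,
                scene=scene, hazard_spec=config.hazard_spec,
                baseline_hazard=config.baseline_hazard,
                censor_horizon_years=config.censor_horizon_years, seed=config.seed,
            )
            scenes_by_patient, clinical = synth.generate_cohort(cohort)
            all_truths = [t for tiles in scenes_by_patient.values() for t in tiles]
            synth.write_truth_csv(all_truths, out / "cellmap.csv")
            synth.write_clinical_csv(clinical, out / "clinical.csv")
            note_artifact("cellmap.csv", out / "cellmap.csv")
            note_artifact("clinical.csv", out / "clinical.csv")
            cell_map = pd.concat([t.cells for t in all_truths], ignore_index=True)
            manifest["stages"]["synth"] = f"{len(scenes_by_patient)} patients, {len(cell_map)} cells"

        geometries: dict[str, comp.CompartmentGeometry] = {}
        densities = None
        if config.stages.compartments and cell_map is not None:
            if scenes_by_patient:
                for tiles in scenes_by_patient.values():
                    for t in tiles:
                        geometries[t.tile_id] = comp.CompartmentGeometry(
                            t.tile_polygon, t.follicles, t.tile_id
                        )
            else:
                # external cell map without geometry: whole tiles are tissue, no follicles
                for tid in cell_map["tile_id"].unique():
                    geometries[tid] = comp.CompartmentGeometry.full_tile(
                        config.tile_width_um, config.tile_height_um, tile_id=tid
                    )
            parts = []
            for tid, grp in cell_map.groupby("tile_id", sort=False):
                parts.append(comp.assign_compartments(grp, geometries[tid]))
            cell_map = pd.concat(parts, ignore_index=True)
            dens_frames = []
            for label in config.phenotype_densities:
                for c in ("intra", "inter"):
                    dens_frames.append(comp.cell_density(cell_map, geometries, label, c))
            densities = pd.concat(dens_frames, ignore_index=True)
            densities.to_csv(out / "densities.csv", index=False)
            note_artifact("densities.csv", out / "densities.csv")
            manifest["stages"]["compartments"] = f"{len(geometries)} tiles"

        mh_df = None
        if config.stages.spatial and cell_map is not None and geometries:
            mh_rows = []
            for compartment in ("intra", "inter"):
                if all(g.areas_um2[compartment] <= 0 for g in geometries.values()):
                    warnings.warn(f"no {compartment}-follicular tissue: compartment skipped")
                    continue
                tess = {
                    tid: sps.tessellate_compartment(g, compartment, config.seed_spacing_um,
                                                    build_polygons=False)
                    for tid, g in geometries.items()
                }
                for a, b in config.coloc_pairs:
                    for r in sps.colocalization(cell_map, a, b, tess, compartment):
                        mh_rows.append({
                            "patient_id": r.patient_id, "compartment": r.compartment,
                            "pair": f"{a}:{b}", "mh": r.mh, "n_quadrats": r.n_quadrats,
                        })
            mh_df = pd.DataFrame(mh_rows)
            mh_df.to_csv(out / "colocalization.csv", index=False)
            note_artifact("colocalization.csv", out / "colocalization.csv")
            manifest["stages"]["spatial"] = f"{len(mh_df)} MH values"

        if config.stages.prognosis and clinical is not None:
            features = build_patient_features(densities, mh_df)
            table = clinical.merge(features, on="patient_id", how="left")
            feature_cols = [c for c in features.columns if c != "patient_id"]
            results = prog.run_association_suite(table, feature_cols)
            results.to_csv(out / "associations.csv", index=False)
            table.to_csv(out / "patient_features.csv", index=False)
            note_artifact("associations.csv", out / "associations.csv")
            note_artifact("patient_features.csv", out / "patient_features.csv")
            manifest["stages"]["prognosis"] = f"{len(results)} feature tests"

        captured = [str(w.message) for w in caught]

    manifest["warnings"] = captured
    manifest["finished"] = datetime.datetime.now().isoformat()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def measure_cohort_features(scenes_by_patient: dict, coloc_pairs: list[tuple[str, str]],
                            phenotypes: list[str] | None = None,
                            seed_spacing_um: float = 25.0,
                            compartments_used: tuple[str, ...] = ("inter",)) -> pd.DataFrame:
    """Measure per-patient spatial features from generated scenes.

    Runs compartment assignment, density pooling and quadrat-based
    Morisita-Horn per patient; returns a wide per-patient table with
    ``density_<label>_<comp>`` and ``coloc_<A>__<B>_<comp>`` columns.
    """
    from . import spatial_stats as sps_mod

    rows = []
    for pid, tiles in scenes_by_patient.items():
        cm = pd.concat([t.cells for t in tiles], ignore_index=True)
        geoms = {
            t.tile_id: comp.CompartmentGeometry(t.tile_polygon, t.follicles, t.tile_id)
            for t in tiles
        }
        cm = pd.concat(
            [comp.assign_compartments(g, geoms[tid]) for tid, g in cm.groupby("tile_id", sort=False)],
            ignore_index=True,
        )
        if phenotypes is None:
            phenotypes = sorted(set(tiles[0].config.phenotype_densities))
        rec: dict = {"patient_id": pid}
        for c in compartments_used:
            for label in phenotypes:
                d = comp.cell_density(cm, geoms, label, c)
                rec[f"density_{label}_{c}"] = float(d["density"].iloc[0])
            tess = {
                tid: sps_mod.tessellate_compartment(g, c, seed_spacing_um, build_polygons=False)
                for tid, g in geoms.items()
            }
            for a, b in coloc_pairs:
                res = sps_mod.colocalization(cm, a, b, tess, c)[0]
                rec[f"coloc_{a}__{b}_{c}"] = res.mh
        rows.append(rec)
    return pd.DataFrame(rows)


def build_patient_features(densities: pd.DataFrame | None, mh: pd.DataFrame | None) -> pd.DataFrame:
    """Wide per-patient feature table from tidy density and MH frames."""
    frames = []
    if densities is not None:
        d = densities.copy()
        d["feature"] = "density_" + d["phenotype"] + "_" + d["compartment"]
        frames.append(d.pivot(index="patient_id", columns="feature", values="density"))
    if mh is not None and len(mh):
        m = mh.copy()
        m["feature"] = "coloc_" + m["pair"].str.replace(":", "__") + "_" + m["compartment"]
        frames.append(m.pivot(index="patient_id", columns="feature", values="mh"))
    if not frames:
        raise ValueError("no features to assemble")
    return pd.concat(frames, axis=1).reset_index()
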