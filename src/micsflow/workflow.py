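"""Configuration-driven pipeline orchestration.

A single run config wires the stages (synthesize → image processing →
segmentation → expression → phenotyping → neighborhood → report) into a
run directory of CSV/TIFF outputs plus a manifest recording the seed,
the config hash, per-stage counts, and a content hash for every output
file.  Runs are deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, Field, field_validator

from . import expression, imaging, neighborhood, panel, phenotyping, segmentation, synth

log = logging.getLogger(__name__)

STAGES = ("synth", "process", "segment", "express", "phenotype", "neighborhood", "report")


class ValidationError(ValueError):
    """Config-level failure detected before any computation."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class SynthConfig(BaseModel):
    n_cells: int = 250
    width_px: int = 640
    height_px: int = 640
    # rendering pitch for synthetic scenes; coarser than the instrument's
    # 0.106 µm/px so that desk-scale scenes hold a few hundred cells
    pixel_size_um: float = 0.5
    noise_sd: float = 0.1
    exposures_ms: tuple[float, ...] = (10.0,)
    spatial_layout: str = "random"


class CropConfig(BaseModel):
    top_bottom_px: int = 0
    left_right_px: int = 0


class NuclearConfig(BaseModel):
    min_diameter_um: float = 4.0
    max_diameter_um: float = 20.0
    detection_sensitivity: float = 0.5
    separation_force: float = 0.5
    smoothing_sigma_px: float = 1.5


class DonutConfig(BaseModel):
    donut_width_um: float = 2.0
    detection_sensitivity: float = 0.5


class NormalizationConfig(BaseModel):
    lower_pct: float = 1.0
    upper_pct: float = 99.0
    arcsinh_cofactor: float = 1.0


class PhenotypeConfig(BaseModel):
    schema_name: str = "main_populations"
    thresholds: dict[str, float] = Field(default_factory=dict)


class NeighborhoodConfig(BaseModel):
    anchor_population: str = "T cells"
    radii_um: tuple[float, ...] = (5.0, 25.0)
    profile_markers: tuple[str, ...] = ()


class RunConfig(BaseModel):
    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    panel_csv: str | None = None  # None = bundled panel
    input_stack_dir: str | None = None  # None = synthesize
    synth: SynthConfig = Field(default_factory=SynthConfig)
    crop: CropConfig = Field(default_factory=CropConfig)
    nuclear: NuclearConfig = Field(default_factory=NuclearConfig)
    donut: DonutConfig = Field(default_factory=DonutConfig)
    normalization: NormalizationConfig = Field(default_factory=NormalizationConfig)
    phenotype: PhenotypeConfig = Field(default_factory=PhenotypeConfig)
    neighborhood: NeighborhoodConfig = Field(default_factory=NeighborhoodConfig)
    log_level: str = "INFO"

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v):
        unknown = [s for s in v if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        return v

    def validate_paths(self) -> None:
        if self.panel_csv is not None and not Path(self.panel_csv).exists():
            raise ValidationError(f"panel CSV not found: {self.panel_csv}")
        if self.input_stack_dir is not None and not Path(self.input_stack_dir).exists():
            raise ValidationError(f"input stack dir not found: {self.input_stack_dir}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml

            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
        return cls.model_validate(doc)


def demo_cell_types(
    phenotypes: Mapping[str, set[str]] | None = None,
    proportions: Mapping[str, float] | None = None,
) -> tuple[synth.CellType, ...]:
    """Cell types whose marker profiles realize the defining phenotypes
    of the main-population schema (defaults), with tonsil-like mixture
    proportions."""
    phenotypes = dict(
        phenotyping.MAIN_POPULATION_PHENOTYPES if phenotypes is None else phenotypes
    )
    if proportions is None:
        proportions = {
            "T cells": 0.25, "B cells": 0.20, "Plasma cells": 0.06,
            "NK cells": 0.03, "Monocytes": 0.04, "mDC": 0.05, "pDC": 0.02,
            "Granulocytes": 0.04, "Mast cells": 0.02, "MDSC": 0.03,
            "Macrophages": 0.08, "Endothelial": 0.05, "Epithelial": 0.05,
            "Fibroblasts": 0.04, "Platelets": 0.02, "Erythrocytes": 0.02,
        }
    markers = sorted(set().union(*phenotypes.values()))
    return tuple(
        synth.CellType(
            label=lbl,
            proportion=proportions[lbl],
            marker_profile=synth.profile(pos, markers),
        )
        for lbl, pos in phenotypes.items()
    )


def demo_spec(config: RunConfig) -> synth.TissueSpec:
    return synth.TissueSpec(
        width_px=config.synth.width_px,
        height_px=config.synth.height_px,
        pixel_size_um=config.synth.pixel_size_um,
        n_cells=config.synth.n_cells,
        cell_types=demo_cell_types(),
        spatial_layout=config.synth.spatial_layout,  # type: ignore[arg-type]
        noise_sd=config.synth.noise_sd,
        exposures_ms=config.synth.exposures_ms,
        seed=config.seed,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Run:
    """A pipeline run over one run directory."""

    def __init__(self, config: RunConfig):
        config.validate_paths()
        self.config = config
        self.run_dir = Path(config.out_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self.counts: dict[str, int] = {}

    # -- stage implementations -------------------------------------------

    def stage_synth(self) -> None:
        spec = demo_spec(self.config)
        stack, truth = synth.generate_tissue(spec)
        stack.write(self.run_dir / "stack")
        truth.cells.to_csv(self.run_dir / "ground_truth_cells.csv", index=False)
        tifffile.imwrite(
            self.run_dir / "ground_truth_nuclei.tif",
            truth.nucleus_labels.astype(np.int32),
        )
        self.counts["synth_cells"] = len(truth.cells)

    def stage_process(self) -> None:
        stack_dir = self.config.input_stack_dir or self.run_dir / "stack"
        stack = imaging.ImageStack.read(stack_dir)
        result = imaging.stitch_tiles(stack)
        crop = imaging.CropSpec(
            self.config.crop.top_bottom_px, self.config.crop.left_right_px
        )
        mosaic_dir = self.run_dir / "mosaics"
        mosaic_dir.mkdir(exist_ok=True)
        stains = {
            k: m for k, m in result.mosaics.items() if k.kind in ("stain", "dapi")
        }
        bleaches = {
            (k.cycle, k.channel): m
            for k, m in result.mosaics.items()
            if k.kind == "bleach"
        }
        n_px = 0
        for key, mosaic in sorted(stains.items(), key=lambda kv: (kv[0].cycle, kv[0].channel)):
            if key.kind == "stain":
                bleach = bleaches.get((key.cycle, key.channel))
                if bleach is not None:
                    mosaic = imaging.subtract_bleach(mosaic, bleach)
            if crop.top_bottom_px or crop.left_right_px:
                mosaic = imaging.crop_to_dapi(mosaic, crop)
            name = "DAPI" if key.kind == "dapi" else key.channel
            tifffile.imwrite(mosaic_dir / f"{name}.tif", mosaic.astype(np.float32))
            n_px = mosaic.size
        pd.DataFrame(result.pairwise_shifts).to_csv(
            self.run_dir / "stitch_shifts.csv", index=False
        )
        self.counts["mosaic_pixels"] = n_px

    def _pixel_size(self) -> float:
        stack_dir = self.config.input_stack_dir or self.run_dir / "stack"
        index = json.loads((Path(stack_dir) / "stack_index.json").read_text())
        return index["pixel_size_um"]

    def stage_segment(self) -> None:
        dapi = tifffile.imread(self.run_dir / "mosaics" / "DAPI.tif")
        px = self._pixel_size()
        seg = segmentation.segment(
            dapi,
            segmentation.NuclearDetectionParams(**self.config.nuclear.model_dump()),
            segmentation.DonutParams(**self.config.donut.model_dump()),
            pixel_size_um=px,
        )
        dtype = np.uint16 if seg.n_cells() < 65536 else np.int32
        tifffile.imwrite(self.run_dir / "nucleus_labels.tif", seg.nucleus_labels.astype(dtype))
        tifffile.imwrite(self.run_dir / "cell_labels.tif", seg.cell_labels.astype(dtype))
        geometry = segmentation.summarize_cells(seg)
        geometry.to_csv(self.run_dir / "cell_geometry.csv", index=False)
        self.counts["segmented_cells"] = seg.n_cells()

    def _load_segmentation(self) -> segmentation.SegmentationResult:
        return segmentation.SegmentationResult(
            tifffile.imread(self.run_dir / "nucleus_labels.tif").astype(np.int32),
            tifffile.imread(self.run_dir / "cell_labels.tif").astype(np.int32),
            self._pixel_size(),
        )

    def stage_express(self) -> None:
        seg = self._load_segmentation()
        mosaic_dir = self.run_dir / "mosaics"
        mosaics = {
            p.stem: tifffile.imread(p)
            for p in sorted(mosaic_dir.glob("*.tif"))
            if p.stem != "DAPI"
        }
        geometry = pd.read_csv(self.run_dir / "cell_geometry.csv")
        cells = expression.extract_expression(mosaics, seg, geometry)
        cells = expression.normalize(
            cells,
            expression.NormalizationParams(**self.config.normalization.model_dump()),
        )
        px = self._pixel_size()
        cells["cx_um"] = cells["cx_px"] * px
        cells["cy_um"] = cells["cy_px"] * px
        cells.to_csv(self.run_dir / "cell_table.csv", index=False, float_format="%.9g")
        self.counts["expressed_cells"] = len(cells)

    def stage_phenotype(self) -> None:
        cells = pd.read_csv(self.run_dir / "cell_table.csv")
        schema = phenotyping.builtin_schema(self.config.phenotype.schema_name)
        cells = phenotyping.apply_schema(
            cells, schema, thresholds=self.config.phenotype.thresholds or None,
            column="label_main",
        )
        cells.to_csv(self.run_dir / "cell_table.csv", index=False, float_format="%.9g")
        comp = phenotyping.composition(cells, "label_main", schema.unassigned_label)
        comp.to_csv(self.run_dir / "composition_main.csv", index=False, float_format="%.9g")
        self.counts["annotated_cells"] = int(
            (cells["label_main"] != schema.unassigned_label).sum()
        )

    def stage_neighborhood(self) -> None:
        cells = pd.read_csv(self.run_dir / "cell_table.csv")
        cfg = self.config.neighborhood
        for radius in cfg.radii_um:
            query = neighborhood.NeighborhoodQuery(
                anchor_population=cfg.anchor_population, radius_um=radius
            )
            res = neighborhood.radius_query(cells, query, label_column="label_main")
            tag = f"r{radius:g}um"
            res.edges.to_csv(
                self.run_dir / f"neighbors_{tag}.csv", index=False, float_format="%.9g"
            )
            comp = neighborhood.intersect_populations(cells, res.pooled, "label_main")
            comp.to_csv(
                self.run_dir / f"neighborhood_composition_{tag}.csv",
                index=False, float_format="%.9g",
            )
            if cfg.profile_markers:
                prof = neighborhood.neighbor_expression_profile(
                    cells, res.pooled, "label_main", cfg.profile_markers
                )
                prof.to_csv(
                    self.run_dir / f"neighborhood_profiles_{tag}.csv",
                    index=False, float_format="%.9g",
                )
        self.counts["neighborhood_radii"] = len(cfg.radii_um)

    def stage_report(self) -> None:
        export_report(self.run_dir)

    # -- driver -----------------------------------------------------------

    def execute(self) -> Path:
        for stage in STAGES:
            if stage not in self.config.stages:
                continue
            log.info("running stage %s", stage)
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:  # persist partial outputs, then abort
                self._write_manifest(failed_stage=stage, error=str(exc))
                raise StageError(stage, exc) from exc
        self._write_manifest()
        return self.run_dir

    def _write_manifest(self, failed_stage: str | None = None, error: str | None = None):
        cfg_json = json.dumps(self.config.model_dump(), sort_keys=True, default=str)
        files = {
            str(p.relative_to(self.run_dir)): _sha256(p)
            for p in sorted(self.run_dir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        }
        manifest = {
            "seed": self.config.seed,
            "config": json.loads(cfg_json),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "stage_counts": self.counts,
            "files": files,
        }
        if failed_stage:
            manifest["failed_stage"] = failed_stage
            manifest["error"] = error
        (self.run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    return Run(config).execute()


def export_report(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Summary tables + plots from a completed run.

    Writes a composition bar chart per schema and quartile ("violin")
    summary tables per neighborhood comparison; neighborhood sections
    are omitted without error when that stage did not run.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    comp_path = run_dir / "composition_main.csv"
    if not comp_path.exists():
        raise FileNotFoundError(
            "report requires the phenotype stage output (composition_main.csv)"
        )
    report_dir = run_dir / "report"
    report_dir.mkdir(exist_ok=True)
    out: dict[str, pd.DataFrame] = {}

    comp = pd.read_csv(comp_path)
    out["composition"] = comp
    plotted = comp.dropna(subset=["fraction"])
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(plotted["label"], plotted["fraction"])
    ax.set_ylabel("fraction of labeled cells")
    ax.tick_params(axis="x", rotation=75)
    fig.tight_layout()
    fig.savefig(report_dir / "composition_main.png", dpi=120)
    plt.close(fig)

    cell_path = run_dir / "cell_table.csv"
    if cell_path.exists():
        cells = pd.read_csv(cell_path)
        norm_cols = [c for c in cells.columns if c.endswith("__cell__norm")]
        if norm_cols and "label_main" in cells.columns:
            summary = (
                cells.melt(
                    id_vars=["label_main"], value_vars=norm_cols,
                    var_name="marker", value_name="value",
                )
                .assign(marker=lambda d: d["marker"].str.replace("__cell__norm", "", regex=False))
                .groupby(["label_main", "marker"])["value"]
                .describe(percentiles=[0.25, 0.5, 0.75])
                .reset_index()
            )
            summary.to_csv(report_dir / "expression_summary.csv", index=False,
                           float_format="%.9g")
            out["expression_summary"] = summary

    for comp_file in sorted(run_dir.glob("neighborhood_composition_*.csv")):
        tag = comp_file.stem.replace("neighborhood_composition_", "")
        ncomp = pd.read_csv(comp_file)
        out[f"neighborhood_{tag}"] = ncomp
        plotted = ncomp.dropna(subset=["fraction"])
        fig, ax = plt.subplots(figsize=(7, 3.5))
        ax.bar(plotted["label"], plotted["fraction"])
        ax.set_ylabel(f"fraction of neighbors ({tag})")
        ax.tick_params(axis="x", rotation=75)
        fig.tight_layout()
        fig.savefig(report_dir / f"neighborhood_{tag}.png", dpi=120)
        plt.close(fig)
    return out
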