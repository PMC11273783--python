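"""End-to-end pipeline orchestration with caching and provenance.

``run_pipeline`` drives tiling -> stain deconvolution -> segmentation ->
feature extraction -> case aggregation -> pruning -> MI selection ->
nested-CV SVM from a single :class:`PipelineConfig`, writing stage outputs
under an output directory.  The heavy per-case feature stage is cached as
CSV: a rerun on the same output directory skips completed cases and
reproduces the identical report (one global seed fixes cohort synthesis, MI
jitter, and fold shuffling).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from .aggregation import aggregate_case, build_case_matrix, prune_features
from .errors import ConfigurationError, StageError
from .modeling import (ModelReport, SelectionConfig, SvmConfig, TrainedModels,
                       train_both_kernels)
from .segmentation import segment_tile
from .stains import build_stain_matrix, tile_to_stains
from .synthetic import CohortSpec, SyntheticCohort, generate_cohort
from .tiling import RgbTile, filter_tiles, tissue_fraction

log = logging.getLogger("pathomics")


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, serializable to JSON/YAML.

    ``min_fold_area`` scales with tile area when left as a fraction
    (``fold_area_fraction`` of tile pixels).
    """

    output_dir: str = "pathomics_out"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    tile_size: int | None = None          # None: use cohort.tile_size
    tissue_threshold: float = 0.5
    stain_hematoxylin: tuple = (0.650, 0.704, 0.286)
    stain_eosin: tuple = (0.072, 0.990, 0.105)
    fold_area_fraction: float = 0.0025    # 2500 px on a 1000 px tile
    min_nucleus_diameter: float = 8.0
    max_nucleus_diameter: float = 60.0
    lambda_reg: float = 0.05
    h_min: float = 2.0
    n_rings: int = 4
    zernike_degree: int = 9
    glcm_levels: int = 8
    granularity_scales: int = 16
    neighbor_distance: float = 5.0
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.cohort, dict):
            self.cohort = CohortSpec(**self.cohort)
        if isinstance(self.selection, dict):
            self.selection = SelectionConfig(**self.selection)
        if isinstance(self.svm, dict):
            self.svm = SvmConfig(**self.svm)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        import inspect

        known = set(inspect.signature(cls).parameters)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def apply_seed(config: PipelineConfig, seed: int) -> PipelineConfig:
    """Propagate one global seed to every stochastic stage."""
    from dataclasses import replace

    return replace(
        config, seed=seed,
        cohort=replace(config.cohort, seed=seed),
        selection=replace(config.selection, seed=seed),
        svm=replace(config.svm, seed=seed))


def process_tile(tile: RgbTile, config: PipelineConfig):
    """Stains -> segmentation -> features for one tile."""
    matrix = build_stain_matrix(config.stain_hematoxylin, config.stain_eosin)
    pair = tile_to_stains(tile.pixels, matrix)
    min_fold_area = max(1, int(config.fold_area_fraction * tile.pixels.shape[0]
                               * tile.pixels.shape[1]))
    seg = segment_tile(pair, min_fold_area=min_fold_area,
                       min_diameter=config.min_nucleus_diameter,
                       max_diameter=config.max_nucleus_diameter,
                       lambda_reg=config.lambda_reg, h_min=config.h_min,
                       tile_ref=(tile.case_id, tile.grid_row, tile.grid_col))
    img, nuc, cyto = feat.extract_tile_features(
        tile, pair, seg, n_rings=config.n_rings,
        zernike_degree=config.zernike_degree, glcm_levels=config.glcm_levels,
        n_scales=config.granularity_scales,
        neighbor_distance=config.neighbor_distance)
    return img, nuc, cyto, seg


def extract_case_features(case_id: str, label: int, tiles: list[RgbTile],
                          config: PipelineConfig) -> pd.Series:
    """Tissue-filter a case's tiles and aggregate its feature vector."""
    kept = filter_tiles(tiles, min_fraction=config.tissue_threshold)
    if not kept:
        # keep the case with its single best tile rather than dropping it
        fracs = [tissue_fraction(t) for t in tiles]
        kept = [tiles[int(np.argmax(fracs))]]
        log.warning("case %s: no tile passed the %.0f%% tissue filter; "
                    "keeping the best tile", case_id, 100 * config.tissue_threshold)
    imgs, nucs, cytos = [], [], []
    for tile in kept:
        try:
            img, nuc, cyto, _ = process_tile(tile, config)
        except Exception as exc:  # noqa: BLE001 - rewrap with context
            raise StageError("features",
                             f"{case_id}/r{tile.grid_row}c{tile.grid_col}",
                             str(exc)) from exc
        imgs.append(img)
        nucs.append(nuc)
        cytos.append(cyto)
    return aggregate_case(case_id, label, imgs, nucs, cytos)


def cohort_case_matrix(cohort: SyntheticCohort, config: PipelineConfig,
                       cache_dir: Path | None = None) -> pd.DataFrame:
    """Aggregated cases x features matrix for a synthetic cohort.

    Per-case vectors are cached as CSV under ``cache_dir`` when given;
    cached cases are loaded instead of recomputed.
    """
    vectors, labels = [], []
    for case in cohort.cases:
        label = 1 if case.label == "responder" else 0
        cache = (cache_dir / f"{case.case_id}.csv") if cache_dir else None
        if cache is not None and cache.exists():
            s = pd.read_csv(cache, index_col=0,
                            float_precision="round_trip").iloc[:, 0]
            s.name = case.case_id
            log.info("case %s: loaded cached features", case.case_id)
        else:
            tiles = [t for t, _ in case.tiles]
            s = extract_case_features(case.case_id, label, tiles, config)
            if cache is not None:
                cache.parent.mkdir(parents=True, exist_ok=True)
                # %.17g round-trips doubles exactly; the rerun must be bitwise
                s.to_frame("value").to_csv(cache, float_format="%.17g")
            log.info("case %s: %d features", case.case_id, len(s))
        vectors.append(s)
        labels.append(label)
    return build_case_matrix(vectors, labels)


@dataclass
class PipelineResult:
    models: TrainedModels
    case_matrix: pd.DataFrame
    pruned_matrix: pd.DataFrame
    prune_report: pd.DataFrame
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full synthetic-cohort pipeline; artifacts under ``output_dir``.

    Re-entrant: per-case feature CSVs and the final report are cached by
    config hash, so a rerun skips completed stages and reproduces the same
    numbers.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    cache_dir = outdir / f"features_{chash}"

    log.info("generating cohort (%d + %d cases, seed %d)",
             config.cohort.n_responders, config.cohort.n_nonresponders,
             config.cohort.seed)
    cohort = generate_cohort(config.cohort)
    matrix = cohort_case_matrix(cohort, config, cache_dir=cache_dir)
    matrix.to_csv(outdir / "case_matrix.csv")

    pruned, prune_report = prune_features(matrix)
    prune_report.to_csv(outdir / "prune_report.csv", index=False)

    X = pruned.drop(columns=["label"]).to_numpy(dtype=float)
    y = pruned["label"].to_numpy(dtype=int)
    names = [c for c in pruned.columns if c != "label"]
    models = train_both_kernels(X, y, config.svm, config.selection, names)

    manifest = {
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": config.seed,
        "n_cases": len(matrix),
        "n_features_raw": matrix.shape[1] - 1,
        "n_features_pruned": pruned.shape[1] - 1,
        "stats_per_feature": 12,
        "outputs": ["case_matrix.csv", "prune_report.csv",
                    "report_linear.json", "report_rbf.json", "metrics.csv"],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    (outdir / "report_linear.json").write_text(models.linear.to_json(indent=2))
    (outdir / "report_rbf.json").write_text(models.rbf.to_json(indent=2))
    models.table().to_csv(outdir / "metrics.csv", index=False)
    return PipelineResult(models=models, case_matrix=matrix,
                          pruned_matrix=pruned, prune_report=prune_report,
                          manifest=manifest)
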