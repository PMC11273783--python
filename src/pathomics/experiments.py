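"""Canned experiment conditions: the scaled-down synthetic study.

The full-scale defaults (44 + 35 cases, 1000 px tiles) mirror the cohort the
pipeline is designed for, but validation experiments run at a reduced scale
chosen once for this package: 10 + 10 cases, one 144 px tile per case, 7
nuclei per tile with a 4 px mean radius, 10% tissue-fold probability, and a
granularity spectrum truncated to 8 scales.  Class effect sizes are injected
as an increment (in px) to the responder nuclear radius; zero effect means
identical classes.

These helpers are the single source of those conditions for the test-bench
experiments (null calibration, effect-size response), so every consumer sees
the same cohort.
"""

from __future__ import annotations

from dataclasses import replace

from .modeling import SelectionConfig, SvmConfig
from .pipeline import PipelineConfig, cohort_case_matrix
from .synthetic import CohortSpec, generate_cohort

SMALL_TILE = 144
SMALL_NUCLEI = 7
SMALL_RADIUS = 4.0
SMALL_CASES = (10, 10)


def small_cohort_spec(effect_px: float = 0.0, seed: int = 0,
                      **overrides) -> CohortSpec:
    """Scaled-down cohort; ``effect_px`` is added to responder nucleus radius."""
    kw = dict(
        n_responders=SMALL_CASES[0], n_nonresponders=SMALL_CASES[1],
        tiles_per_case=1, tile_size=SMALL_TILE, nuclei_per_tile=SMALL_NUCLEI,
        nucleus_radius_mean=(SMALL_RADIUS + effect_px, SMALL_RADIUS),
        nucleus_eccentricity=0.6, texture_noise_sd=0.05,
        fold_probability=0.1, background_fraction=0.3, seed=seed)
    kw.update(overrides)
    return CohortSpec(**kw)


def small_config(effect_px: float = 0.0, seed: int = 0,
                 **cohort_overrides) -> PipelineConfig:
    """Pipeline configuration matched to the scaled-down cohort geometry."""
    return PipelineConfig(
        cohort=small_cohort_spec(effect_px=effect_px, seed=seed,
                                 **cohort_overrides),
        fold_area_fraction=0.012,       # ~250 px on a 144 px tile
        min_nucleus_diameter=5.0, max_nucleus_diameter=30.0,
        granularity_scales=8,
        selection=SelectionConfig(mode="top_k", top_k=100, seed=seed),
        svm=SvmConfig(kernel="linear", seed=seed),
        seed=seed)


def cohort_case_data(config: PipelineConfig):
    """(X, y, feature_names) of the pruned case matrix for a config."""
    from .aggregation import prune_features

    cohort = generate_cohort(config.cohort)
    matrix = cohort_case_matrix(cohort, config)
    pruned, _ = prune_features(matrix)
    X = pruned.drop(columns=["label"]).to_numpy(dtype=float)
    y = pruned["label"].to_numpy(dtype=int)
    names = [c for c in pruned.columns if c != "label"]
    return X, y, names


def cohort_auc(effect_px: float = 0.0, seed: int = 0, kernel: str = "linear",
               **cohort_overrides) -> float:
    """Mean outer-fold AUC of the nested-CV SVM on one scaled-down cohort."""
    from .modeling import nested_cv

    config = small_config(effect_px=effect_px, seed=seed, **cohort_overrides)
    X, y, names = cohort_case_data(config)
    rep = nested_cv(X, y, replace(config.svm, kernel=kernel),
                    config.selection, names)
    return rep.auc_mean
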