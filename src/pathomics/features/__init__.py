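"""Feature extraction: per-object and per-tile quantitative families.

Object features (nuclei measured on the hematoxylin OD channel, cytoplasm on
the eosin OD channel): intensity, radial intensity distribution, Haralick
texture, Zernike shape magnitudes, geometric shape, and (nuclei only)
neighborhood features.  Image-level features per tile: Haralick texture and
granularity of each stain channel, stain colocalization, channel intensity
summaries, and image-quality scores.

:func:`extract_tile_features` assembles everything for one segmented tile;
:func:`feature_manifest` documents every emitted column (family, compartment,
parameters) so downstream aggregation and selection have stable column
identity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..segmentation import LabelMask, TileSegmentation
from ..stains import StainPair
from ..tiling import RgbTile
from .objects import (intensity_features, neighbor_features, radial_distribution,
                      shape_features, zernike_shape, zernike_magnitudes,
                      zernike_indices)
from .texture import (HARALICK_NAMES, colocalization, focus_score, glcm,
                      granularity_spectrum, haralick, haralick_from_glcm,
                      haralick_per_object, image_quality, quantize)

__all__ = [
    "intensity_features", "radial_distribution", "shape_features",
    "zernike_shape", "zernike_magnitudes", "zernike_indices",
    "neighbor_features", "haralick", "haralick_from_glcm", "glcm", "quantize",
    "haralick_per_object", "granularity_spectrum", "colocalization",
    "image_quality", "focus_score", "HARALICK_NAMES",
    "object_feature_table", "image_feature_row", "extract_tile_features",
    "feature_manifest",
]


def object_feature_table(mask: LabelMask, intensity_image: np.ndarray,
                         compartment: str, n_rings: int = 4,
                         zernike_degree: int = 9, glcm_levels: int = 8,
                         neighbor_distance: float = 5.0) -> pd.DataFrame:
    """All per-object families for one compartment of one tile.

    Columns are prefixed ``{compartment}_{family}_{measure}``.  Neighborhood
    features are emitted for nuclei only.
    """
    parts = [
        intensity_features(mask, intensity_image, prefix=f"{compartment}_intensity"),
        radial_distribution(mask, intensity_image, n_rings=n_rings,
                            prefix=f"{compartment}_radial"),
        haralick_per_object(mask, intensity_image, levels=glcm_levels,
                            prefix=f"{compartment}_haralick"),
        shape_features(mask, prefix=f"{compartment}_shape"),
        zernike_shape(mask, max_degree=zernike_degree,
                      prefix=f"{compartment}_zernike"),
    ]
    if compartment == "nuclei":
        parts.append(neighbor_features(mask, expand_distance=neighbor_distance,
                                       prefix=f"{compartment}_neighbors"))
    return pd.concat(parts, axis=1)


def image_feature_row(tile: RgbTile, pair: StainPair,
                      fold_mask: np.ndarray | None = None,
                      glcm_levels: int = 8, n_scales: int = 16) -> pd.DataFrame:
    """One row of tile-level features (texture, intensity, granularity,
    colocalization, quality)."""
    tissue = pair.total_od > 0.1
    if fold_mask is not None:
        tissue &= ~np.asarray(fold_mask)
    row: dict[str, float] = {}
    for name, chan in (("h", pair.h_channel), ("e", pair.e_channel)):
        hf = haralick(chan, levels=glcm_levels)
        for fname, v in zip(HARALICK_NAMES, hf):
            row[f"image_haralick_{name}_{fname}"] = float(v)
        spec = granularity_spectrum(chan, n_scales=n_scales)
        for i, v in enumerate(spec, start=1):
            row[f"image_granularity_{name}_{i}"] = float(v)
        row[f"image_intensity_{name}_mean"] = float(chan.mean())
        row[f"image_intensity_{name}_std"] = float(chan.std())
        row[f"image_intensity_{name}_median"] = float(np.median(chan))
    coloc = colocalization(pair.h_channel, pair.e_channel,
                           region=tissue if tissue.any() else None)
    for k, v in coloc.items():
        row[f"image_coloc_{k}"] = v
    for k, v in image_quality(tile.pixels).items():
        row[f"image_quality_{k}"] = v
    row["image_area_occupied_fraction"] = float(tissue.mean())
    return pd.DataFrame([row])


def extract_tile_features(tile: RgbTile, pair: StainPair, seg: TileSegmentation,
                          n_rings: int = 4, zernike_degree: int = 9,
                          glcm_levels: int = 8, n_scales: int = 16,
                          neighbor_distance: float = 5.0):
    """(image_row, nuclei_table, cytoplasm_table) for one segmented tile."""
    img = image_feature_row(tile, pair, fold_mask=seg.fold_mask,
                            glcm_levels=glcm_levels, n_scales=n_scales)
    nuc = object_feature_table(seg.nuclei, pair.h_channel, "nuclei",
                               n_rings=n_rings, zernike_degree=zernike_degree,
                               glcm_levels=glcm_levels,
                               neighbor_distance=neighbor_distance)
    # objects whose cytoplasm is empty are absent from the cytoplasm table
    cyto = object_feature_table(seg.cytoplasm, pair.e_channel, "cytoplasm",
                                n_rings=n_rings, zernike_degree=zernike_degree,
                                glcm_levels=glcm_levels)
    return img, nuc, cyto


def feature_manifest(columns: list[str]) -> pd.DataFrame:
    """Parse ``compartment_family_measure`` column names into a manifest."""
    rows = []
    for col in columns:
        parts = col.split("_", 2)
        compartment = parts[0]
        family = parts[1] if len(parts) > 1 else ""
        measure = parts[2] if len(parts) > 2 else ""
        rows.append({"column": col, "compartment": compartment,
                     "family": family, "measure": measure})
    return pd.DataFrame(rows, columns=["column", "compartment", "family", "measure"])
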