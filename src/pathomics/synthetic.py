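"""Seeded synthetic H&E cohort generator with exact ground truth.

Generates tiles that look enough like hematoxylin-and-eosin histology for the
whole pipeline to be exercised: elliptical nuclei (hematoxylin-rich) inside
cytoplasm rings (eosin-rich), embedded in lightly eosinophilic stroma, with
blank glass background, optional double-thickness "tissue fold" patches
(doubled stain concentration), per-pixel Gaussian OD noise and a smooth
low-frequency modulation field that gives texture features something to
measure.  RGB is rendered by Beer-Lambert mixing:

    I = I0 * 10 ** -(c_H * s_H + c_E * s_E)      (per RGB channel)

A two-class cohort (responder / non-responder) is produced where the classes
may differ in nuclear radius, eccentricity, and OD noise; effect sizes are
fully controllable, including zero (identical classes).  Every tile comes
with exact label masks for nuclei and whole cells, so segmentation and
feature code can be validated against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GenerationError
from .stains import build_stain_matrix
from .tiling import RgbTile

RESPONDER = "responder"
NONRESPONDER = "nonresponder"

# Stain concentrations (OD units) of each synthetic compartment.  Chosen so
# every compartment of a doubled-OD fold is heavier than any unfolded one:
# doubled stroma (0.74 total) clears normal cytoplasm (0.50 total).
NUCLEUS_CH, NUCLEUS_CE = 0.85, 0.15
CYTOPLASM_CH, CYTOPLASM_CE = 0.10, 0.40
STROMA_CH, STROMA_CE = 0.05, 0.32


def _per_class(value) -> tuple[float, float]:
    """Normalize a scalar or (responder, nonresponder) pair to a pair."""
    if np.isscalar(value):
        return float(value), float(value)
    a, b = value
    return float(a), float(b)


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-class cohort.

    Per-class parameters (``nucleus_radius_mean``, ``nucleus_eccentricity``,
    ``texture_noise_sd``) accept a scalar (both classes identical — zero
    effect size) or a ``(responder, nonresponder)`` pair.

    Defaults mirror the study cohort shape: 44 responders vs 35
    non-responders, 1000 px tiles, with identical classes until an effect
    size is requested.
    """

    n_responders: int = 44
    n_nonresponders: int = 35
    tiles_per_case: int = 2
    tile_size: int = 1000
    nuclei_per_tile: int = 120
    nucleus_radius_mean: float | tuple[float, float] = 7.0
    nucleus_eccentricity: float | tuple[float, float] = 0.6
    texture_noise_sd: float | tuple[float, float] = 0.05
    fold_probability: float = 0.1
    background_fraction: float = 0.3
    cell_scale: float = 1.6           # cell ellipse = nucleus ellipse scaled by this
    radius_sd_fraction: float = 0.12  # nucleus radius sd, as fraction of the mean
    modulation_amplitude: float = 0.5 # low-frequency OD modulation (relative)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_responders", "n_nonresponders", "tiles_per_case",
                     "tile_size", "nuclei_per_tile"):
            if getattr(self, name) < 0:
                raise GenerationError(f"{name} must be >= 0")
        for name in ("fold_probability", "background_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name} must be in [0, 1], got {v}")
        for name in ("nucleus_radius_mean", "nucleus_eccentricity", "texture_noise_sd"):
            pair = _per_class(getattr(self, name))
            if min(pair) < 0:
                raise GenerationError(f"{name} must be non-negative")

    def class_params(self, class_label: str) -> dict:
        idx = 0 if class_label == RESPONDER else 1
        return {
            "radius_mean": _per_class(self.nucleus_radius_mean)[idx],
            "eccentricity": _per_class(self.nucleus_eccentricity)[idx],
            "noise_sd": _per_class(self.texture_noise_sd)[idx],
        }


@dataclass
class GroundTruth:
    """Exact per-tile ground truth emitted alongside each rendered tile."""

    nuclei_mask: np.ndarray          # int labels, 0 = background
    cell_mask: np.ndarray            # int labels matching nuclei labels
    fold_mask: np.ndarray            # bool
    tissue_fraction: float
    case_label: str
    ch_map: np.ndarray | None = None  # hematoxylin concentration field (OD)
    ce_map: np.ndarray | None = None  # eosin concentration field (OD)


def beer_lambert_mix(ch_map: np.ndarray, ce_map: np.ndarray,
                     stain_matrix: np.ndarray | None = None,
                     i0: float = 255.0) -> np.ndarray:
    """Render concentration fields to float RGB via Beer-Lambert mixing."""
    if stain_matrix is None:
        stain_matrix = build_stain_matrix()
    conc = np.stack([np.asarray(ch_map, float), np.asarray(ce_map, float)], axis=-1)
    od = conc @ np.asarray(stain_matrix, float)
    return i0 * np.power(10.0, -od)


def _smooth_field(shape, rng, sigma_frac=0.125) -> np.ndarray:
    """Standardized low-frequency Gaussian random field (Perlin-style)."""
    noise = rng.standard_normal(shape)
    field_ = ndimage.gaussian_filter(noise, sigma=max(shape) * sigma_frac)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _tissue_region(size: int, background_fraction: float, rng) -> np.ndarray:
    """Smooth boolean tissue region covering exactly 1-background_fraction."""
    if background_fraction <= 0:
        return np.ones((size, size), dtype=bool)
    if background_fraction >= 1:
        return np.zeros((size, size), dtype=bool)
    f = _smooth_field((size, size), rng)
    thresh = np.quantile(f, background_fraction)
    return f >= thresh


def _ellipse_mask(size, center, a, b, theta) -> np.ndarray:
    """Boolean raster of an ellipse (semi-axes a, b, rotation theta)."""
    rr, cc = np.mgrid[0:size, 0:size]
    dr, dc = rr - center[0], cc - center[1]
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_tile(spec: CohortSpec, class_label: str, rng: np.random.Generator,
                keep_concentrations: bool = False) -> tuple[RgbTile, GroundTruth]:
    """Render one synthetic tile and its exact ground truth.

    Nuclei are placed by rejection sampling so that whole cells never
    overlap; exceeding the retry budget (1000 tries per nucleus) raises
    :class:`GenerationError`.
    """
    size = spec.tile_size
    p = spec.class_params(class_label)
    tissue = _tissue_region(size, spec.background_fraction, rng)

    nuclei_mask = np.zeros((size, size), dtype=np.int32)
    cell_mask = np.zeros((size, size), dtype=np.int32)
    placed = []  # (center_r, center_c, cell_circumradius)

    for k in range(1, spec.nuclei_per_tile + 1):
        ok = False
        for _ in range(1000):
            r = max(1.5, rng.normal(p["radius_mean"],
                                    spec.radius_sd_fraction * p["radius_mean"]))
            ecc = min(p["eccentricity"], 0.95)
            # area-preserving semi-axes: a*b = r^2, b/a = sqrt(1 - ecc^2)
            ratio = np.sqrt(1.0 - ecc ** 2)
            a = r / np.sqrt(ratio)
            b = r * np.sqrt(ratio)
            theta = rng.uniform(0, np.pi)
            ca = a * spec.cell_scale
            margin = int(np.ceil(ca)) + 1
            if 2 * margin >= size:
                continue
            cr = rng.integers(margin, size - margin)
            cc = rng.integers(margin, size - margin)
            if not tissue[cr, cc]:
                continue
            # conservative disjointness: circumradii must not touch
            if any((cr - pr) ** 2 + (cc - pc) ** 2 <= (ca + pca + 1.0) ** 2
                   for pr, pc, pca in placed):
                continue
            nuc = _ellipse_mask(size, (cr, cc), a, b, theta)
            cell = _ellipse_mask(size, (cr, cc), ca, b * spec.cell_scale, theta)
            nuclei_mask[nuc] = k
            cell_mask[cell] = k
            tissue |= cell
            placed.append((cr, cc, ca))
            ok = True
            break
        if not ok:
            raise GenerationError(
                f"could not place nucleus {k}/{spec.nuclei_per_tile} "
                f"within the retry budget (tile {size} px)")

    ch = np.where(tissue, STROMA_CH, 0.0)
    ce = np.where(tissue, STROMA_CE, 0.0)
    ch[cell_mask > 0] = CYTOPLASM_CH
    ce[cell_mask > 0] = CYTOPLASM_CE
    ch[nuclei_mask > 0] = NUCLEUS_CH
    ce[nuclei_mask > 0] = NUCLEUS_CE

    # texture: smooth multiplicative modulation + per-pixel OD noise, tissue only
    if spec.modulation_amplitude > 0:
        mod = 1.0 + 0.1 * spec.modulation_amplitude * _smooth_field((size, size), rng,
                                                                    sigma_frac=0.05)
        ch = np.where(tissue, ch * mod, ch)
        ce = np.where(tissue, ce * mod, ce)
    if p["noise_sd"] > 0:
        ch = ch + np.where(tissue, rng.normal(0, p["noise_sd"], (size, size)), 0.0)
        ce = ce + np.where(tissue, rng.normal(0, p["noise_sd"], (size, size)), 0.0)

    fold_mask = np.zeros((size, size), dtype=bool)
    if rng.random() < spec.fold_probability and tissue.any():
        fa = size * np.sqrt(0.05) / np.sqrt(np.pi)  # ~5% tile area
        # center the patch on a tissue pixel so the visible fold is real
        tr, tc = np.nonzero(tissue)
        pick = rng.integers(0, tr.size)
        fold_mask = _ellipse_mask(size, (tr[pick], tc[pick]),
                                  fa * rng.uniform(0.8, 1.2),
                                  fa * rng.uniform(0.8, 1.2), rng.uniform(0, np.pi))
        fold_mask &= tissue
        ch = np.where(fold_mask, 2.0 * ch, ch)
        ce = np.where(fold_mask, 2.0 * ce, ce)

    ch = np.maximum(ch, 0.0)
    ce = np.maximum(ce, 0.0)
    rgb = np.clip(np.rint(beer_lambert_mix(ch, ce)), 0, 255).astype(np.uint8)

    truth = GroundTruth(
        nuclei_mask=nuclei_mask, cell_mask=cell_mask, fold_mask=fold_mask,
        tissue_fraction=float(tissue.mean()), case_label=class_label,
        ch_map=ch if keep_concentrations else None,
        ce_map=ce if keep_concentrations else None)
    return RgbTile(pixels=rgb), truth


@dataclass
class SyntheticCase:
    case_id: str
    label: str  # responder / nonresponder
    tiles: list[tuple[RgbTile, GroundTruth]] = field(default_factory=list)


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    cases: list[SyntheticCase]

    @property
    def label_table(self) -> pd.DataFrame:
        """case_id plus binary label (1 = responder / treatment effective)."""
        return pd.DataFrame({
            "case_id": [c.case_id for c in self.cases],
            "label": [1 if c.label == RESPONDER else 0 for c in self.cases],
        })


def generate_cohort(spec: CohortSpec, keep_concentrations: bool = False) -> SyntheticCohort:
    """Generate the full two-class cohort, deterministically from ``spec.seed``.

    Each case draws from an independent child stream of the seed sequence, so
    the output is bitwise reproducible and insensitive to generation order.
    """
    n_total = spec.n_responders + spec.n_nonresponders
    if n_total == 0:
        raise GenerationError("cohort has zero cases")
    if (spec.n_responders == 0) != (spec.n_nonresponders == 0):
        raise GenerationError("one class has zero cases; both classes required")

    labels = [RESPONDER] * spec.n_responders + [NONRESPONDER] * spec.n_nonresponders
    streams = np.random.SeedSequence(spec.seed).spawn(n_total)
    cases = []
    for i, (label, ss) in enumerate(zip(labels, streams)):
        rng = np.random.default_rng(ss)
        case = SyntheticCase(case_id=f"case_{i:03d}", label=label)
        for j in range(spec.tiles_per_case):
            tile, truth = render_tile(spec, label, rng,
                                      keep_concentrations=keep_concentrations)
            tile.case_id = case.case_id
            tile.grid_row, tile.grid_col = 0, j
            case.tiles.append((tile, truth))
        cases.append(case)
    return SyntheticCohort(spec=spec, cases=cases)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write tiles (PNG), ground-truth masks (16-bit TIFF), the label table
    (CSV) and a manifest (JSON) under ``outdir``; returns the manifest path."""
    import imageio.v3 as iio
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for case in cohort.cases:
        cdir = outdir / case.case_id
        cdir.mkdir(exist_ok=True)
        for tile, truth in case.tiles:
            stem = f"tile_r{tile.grid_row}_c{tile.grid_col}"
            iio.imwrite(cdir / f"{stem}.png", tile.pixels)
            tifffile.imwrite(cdir / f"{stem}_nuclei.tif",
                             truth.nuclei_mask.astype(np.uint16))
            tifffile.imwrite(cdir / f"{stem}_cells.tif",
                             truth.cell_mask.astype(np.uint16))
            entries.append({"case_id": case.case_id, "label": case.label,
                            "tile": f"{case.case_id}/{stem}.png",
                            "tissue_fraction": truth.tissue_fraction})
    cohort.label_table.to_csv(outdir / "labels.csv", index=False)
    manifest = outdir / "manifest.json"
    spec_dict = asdict(cohort.spec)
    manifest.write_text(json.dumps({"spec": spec_dict, "tiles": entries}, indent=2,
                                   default=float))
    return manifest
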