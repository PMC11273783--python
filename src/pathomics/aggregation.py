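"""Case-level aggregation of tile and object features, and feature pruning.

Object rows are pooled across all of a case's tiles *before* statistics are
taken — a nucleus contributes to the case distribution no matter which tile
it was segmented in — and likewise the tile-level rows form one pooled
population per case.  Each pooled feature column is summarized by 12
distributional statistics: mean, median, standard deviation, and the nine
interior deciles (10th..90th percentile, linear-interpolation quantiles).

Pruning drops exact duplicate columns (first by manifest order wins) and
near-zero-variance columns (variance < 1e-10 after median scaling), with a
report naming every dropped column and the reason.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import PathomicsError

DECILES = tuple(range(10, 100, 10))
STAT_NAMES = ("mean", "median", "std") + tuple(f"d{d}" for d in DECILES)
N_STATS = len(STAT_NAMES)  # 12


def _column_stats(values: np.ndarray) -> list[float]:
    """The 12 statistics of one pooled feature column."""
    v = np.asarray(values, dtype=float)
    out = [float(v.mean()), float(np.median(v)), float(v.std())]
    out += [float(q) for q in np.percentile(v, DECILES)]
    return out


def aggregate_pooled(pooled: pd.DataFrame, prefix: str = "") -> dict[str, float]:
    """Aggregate one pooled table into ``{column}_{stat}`` scalars.

    Each column is sorted before the statistics are taken, so the result is
    bitwise invariant to the order in which tiles and objects were pooled
    (floating-point summation is not associative).
    """
    arr = np.sort(pooled.to_numpy(dtype=float), axis=0)
    stats = np.vstack([arr.mean(axis=0), np.median(arr, axis=0),
                       arr.std(axis=0), np.percentile(arr, DECILES, axis=0)])
    out: dict[str, float] = {}
    for j, col in enumerate(pooled.columns):
        for i, stat in enumerate(STAT_NAMES):
            out[f"{prefix}{col}_{stat}"] = float(stats[i, j])
    return out


def aggregate_case(case_id: str, label: int,
                   image_rows: list[pd.DataFrame],
                   nuclei_tables: list[pd.DataFrame],
                   cytoplasm_tables: list[pd.DataFrame]) -> pd.Series:
    """One case's aggregated feature vector.

    A compartment with zero objects across the whole case contributes
    all-zero aggregates plus a raised ``{compartment}_empty_flag``; the flag
    columns are always present so the matrix stays rectangular.
    """
    if not image_rows:
        raise PathomicsError(f"case {case_id}: no tiles to aggregate")
    values: dict[str, float] = {}
    pooled_img = pd.concat(image_rows, ignore_index=True)
    values.update(aggregate_pooled(pooled_img))
    for name, tables in (("nuclei", nuclei_tables), ("cytoplasm", cytoplasm_tables)):
        nonempty = [t for t in tables if len(t)]
        if nonempty:
            pooled = pd.concat(nonempty, ignore_index=True)
            values.update(aggregate_pooled(pooled))
            values[f"{name}_empty_flag"] = 0.0
        else:
            cols = tables[0].columns if tables else []
            for col in cols:
                for stat in STAT_NAMES:
                    values[f"{col}_{stat}"] = 0.0
            values[f"{name}_empty_flag"] = 1.0
    s = pd.Series(values, name=case_id)
    s.attrs["label"] = int(label)
    return s


def build_case_matrix(case_vectors: list[pd.Series],
                      labels: list[int]) -> pd.DataFrame:
    """Stack case vectors into a cases x features matrix with a ``label``
    column appended last."""
    mat = pd.DataFrame(case_vectors)
    mat = mat.fillna(0.0)
    mat["label"] = [int(l) for l in labels]
    return mat


def prune_features(matrix: pd.DataFrame, variance_floor: float = 1e-10
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop duplicate and near-constant feature columns.

    Variance is measured after dividing each column by its median magnitude
    (columns with zero median are left unscaled), so the floor is scale-free.
    Returns ``(reduced_matrix, report)``; the report lists every dropped
    column with its reason.  Raises if nothing survives.
    """
    if len(matrix) < 2:
        raise PathomicsError("pruning needs at least 2 cases")
    label = matrix["label"] if "label" in matrix.columns else None
    X = matrix.drop(columns=["label"], errors="ignore")
    dropped: list[tuple[str, str]] = []
    keep: list[str] = []
    seen: dict[bytes, str] = {}
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        med = np.median(np.abs(v))
        scaled = v / med if med > 0 else v
        if np.var(scaled) < variance_floor:
            dropped.append((col, "low_variance"))
            continue
        key = v.tobytes()
        if key in seen:
            dropped.append((col, f"duplicate_of:{seen[key]}"))
            continue
        seen[key] = col
        keep.append(col)
    if not keep:
        raise PathomicsError("all feature columns were pruned")
    out = X[keep].copy()
    if label is not None:
        out["label"] = label
    report = pd.DataFrame(dropped, columns=["column", "reason"])
    return out, report


def feature_correlation_report(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix of a pruned case matrix, ordered
    image -> nuclei -> cytoplasm, plus per-family |r| distribution summaries.
    """
    X = matrix.drop(columns=["label"], errors="ignore")
    order_key = {"image": 0, "nuclei": 1, "cytoplasm": 2}
    cols = sorted(X.columns,
                  key=lambda c: (order_key.get(c.split("_", 1)[0], 3), c))
    corr = X[cols].corr()
    fam = {}
    for c in cols:
        parts = c.split("_", 2)
        fam.setdefault((parts[0], parts[1] if len(parts) > 1 else ""), []).append(c)
    rows = []
    for (compartment, family), members in fam.items():
        if len(members) < 2:
            continue
        sub = corr.loc[members, members].to_numpy()
        tri = np.abs(sub[np.triu_indices(len(members), k=1)])
        rows.append({"compartment": compartment, "family": family,
                     "n_features": len(members),
                     "mean_abs_r": float(np.nanmean(tri)),
                     "median_abs_r": float(np.nanmedian(tri)),
                     "max_abs_r": float(np.nanmax(tri))})
    return corr, pd.DataFrame(rows)
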