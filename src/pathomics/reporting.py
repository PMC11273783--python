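"""Figures and tables from model reports: ROC curves, confusion matrices,
metric tables, and the feature-correlation heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import PathomicsError
from .modeling import ModelReport, roc_points


def metric_table(reports: dict[str, ModelReport]) -> pd.DataFrame:
    """AUC / Accuracy / Precision / Recall / F-Score rows per model."""
    rows = []
    for name, rep in reports.items():
        m = rep.metrics
        rows.append({"Model Type": name, "AUC": round(rep.auc_mean, 4),
                     "Accuracy": round(m["accuracy"], 4),
                     "Precision": round(m["precision"], 4),
                     "Recall": round(m["recall"], 4),
                     "F-Score": round(m["f_score"], 4)})
    return pd.DataFrame(rows)


def plot_roc(reports: dict[str, ModelReport], path: str | Path) -> Path:
    """Pooled outer-fold ROC curves, one per model, on a single figure."""
    if not reports:
        raise PathomicsError("no reports to plot")
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, rep in reports.items():
        pts = roc_points(rep)
        ax.plot(pts[:, 0], pts[:, 1],
                label=f"{name} (AUC {rep.auc_mean:.4f} ± {rep.auc_std:.4f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_confusion(report: ModelReport, path: str | Path) -> Path:
    """2x2 confusion-matrix heatmap at decision threshold 0."""
    if not report.per_fold_auc:
        raise PathomicsError("report has no folds")
    c = report.confusion
    mat = np.array([[c["tp"], c["fn"]], [c["fp"], c["tn"]]])
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(mat, cmap="Blues")
    for (i, j), v in np.ndenumerate(mat):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks([0, 1], ["Pred. effective", "Pred. invalid"])
    ax.set_yticks([0, 1], ["True effective", "True invalid"])
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_correlation_heatmap(corr: pd.DataFrame, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.to_numpy(), cmap="Greens", vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title("Feature correlation (image / nuclei / cytoplasm)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def make_report(reports: dict[str, ModelReport], outdir: str | Path,
                corr: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write the figure/table bundle for one or more trained models."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {"metrics": outdir / "metrics_table.csv",
           "roc": plot_roc(reports, outdir / "roc.png")}
    metric_table(reports).to_csv(out["metrics"], index=False)
    for name, rep in reports.items():
        out[f"confusion_{name}"] = plot_confusion(
            rep, outdir / f"confusion_{name.lower()}.png")
        pts = roc_points(rep)
        pd.DataFrame(pts, columns=["fpr", "tpr", "threshold"]).to_csv(
            outdir / f"roc_points_{name.lower()}.csv", index=False)
    if corr is not None:
        out["heatmap"] = plot_correlation_heatmap(corr, outdir / "correlation.png")
    return out
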