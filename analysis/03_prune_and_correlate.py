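"""Prune duplicate/low-variance features and examine feature correlations.

Reads results/case_matrix.csv, drops uninformative columns, writes the
pruned matrix, a pruning report, the Pearson correlation matrix (ordered
image -> nuclei -> cytoplasm) with its heatmap, and per-family correlation
summaries.
"""

from pathlib import Path

import pandas as pd

from pathomics.aggregation import feature_correlation_report, prune_features
from pathomics.reporting import plot_correlation_heatmap

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    matrix = pd.read_csv(RESULTS / "case_matrix.csv", index_col=0,
                         float_precision="round_trip")
    pruned, report = prune_features(matrix)
    pruned.to_csv(RESULTS / "case_matrix_pruned.csv", float_format="%.17g")
    report.to_csv(RESULTS / "prune_report.csv", index=False)
    corr, families = feature_correlation_report(pruned)
    corr.to_csv(RESULTS / "feature_correlation.csv")
    families.to_csv(RESULTS / "family_correlation_summary.csv", index=False)
    plot_correlation_heatmap(corr, RESULTS / "correlation_heatmap.png")
    n_dup = (report["reason"].str.startswith("duplicate")).sum()
    n_lv = (report["reason"] == "low_variance").sum()
    print(f"pruned {len(report)} columns ({n_dup} duplicates, "
          f"{n_lv} low-variance); {pruned.shape[1] - 1} features remain")
    print("strongest within-family correlations:")
    print(families.sort_values("mean_abs_r", ascending=False)
          .head(5).to_string(index=False))


if __name__ == "__main__":
    main()
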