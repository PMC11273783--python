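"""Render the final figure/table bundle: ROC curves, confusion matrices,
and the metric table for both SVM kernels."""

import json
from pathlib import Path

from pathomics.modeling import ModelReport
from pathomics.reporting import make_report

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    reports = {}
    for name, fname in (("Linear", "report_linear.json"),
                        ("Gaussian", "report_rbf.json")):
        reports[name] = ModelReport(
            **json.loads((RESULTS / fname).read_text()))
    paths = make_report(reports, RESULTS / "figures")
    for key, path in paths.items():
        print(f"{key}: {path}")


if __name__ == "__main__":
    main()
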