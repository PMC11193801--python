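"""Task-selectivity: does one outcome's tract model transfer to the other?

Builds the transfer models (each outcome regressed on the tracts selected
for the other outcome), compares their R^2 with the original models', and
runs the Cox and J non-nested tests in both directions.
"""

import json
from pathlib import Path

import pandas as pd

from wmlearn.io_formats import write_report
from wmlearn.model_selection import SelectionResult
from wmlearn.transfer import run_transfer_analysis

RESULTS = Path("results")


def _load(name: str) -> SelectionResult:
    doc = json.loads((RESULTS / f"selection_{name}.json").read_text())["results"]
    return SelectionResult(**doc)


def main() -> None:
    features = pd.read_csv(RESULTS / "feature_table.tsv", sep="\t", index_col="participant_id")
    outcomes = pd.read_csv(RESULTS / "outcomes.tsv", sep="\t", index_col="participant_id")
    keep = outcomes.index[~outcomes["excluded"]]
    features = features.loc[keep]
    out = pd.DataFrame(
        {
            "drawing": outcomes.loc[keep, "drawing_slope"],
            "recognition": outcomes.loc[keep, "recognition_accuracy"],
        }
    )
    report = run_transfer_analysis(out, _load("drawing"), _load("recognition"), features)
    write_report(report, RESULTS / "transfer.json")

    for outcome, r2 in report["original_r2"].items():
        print(f"original {outcome} model R^2 = {r2:.4f}")
    for direction, r2 in report["transfer_r2"].items():
        print(f"transfer R^2 ({direction}) = {r2:.4f}  [{report['status'][direction]}]")
    for res in report["tests"]:
        print(f"{res.method:5s} {res.direction}: stat={res.statistic:+.4f} p={res.p:.4g}")


if __name__ == "__main__":
    main()
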