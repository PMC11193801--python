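"""Relaxed-lasso tract selection for both learning outcomes.

Standardizes the 22 tract-FA predictors, runs the lasso path with
leave-one-out cross-validation to pick the penalty, refits OLS on the
selected support (removing shrinkage bias), and prints a model summary per
outcome plus the complementary marginal regressions.
"""

from pathlib import Path

import pandas as pd

from wmlearn.io_formats import write_report
from wmlearn.model_selection import marginal_regressions, select_model

RESULTS = Path("results")


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

    for name in ("drawing", "recognition"):
        result = select_model(features, out[name], name)
        write_report(result, RESULTS / f"selection_{name}.json")
        print(f"{name} model (n={result.n_used}, lambda={result.chosen_lambda:.4g}):")
        if result.selected_tracts:
            for tract, beta, se in zip(result.selected_tracts, result.beta, result.se):
                print(f"  {tract:12s} beta={beta:+.4f} se={se:.4f}")
        else:
            print("  (empty support)")
        print(f"  OLS R^2 = {result.r2:.4f}")

    marginal = marginal_regressions(features, out)
    marginal.to_csv(RESULTS / "marginal_regressions.tsv", sep="\t", index=False)
    sig = marginal[marginal["significant"]]
    print(f"marginal regressions: {len(sig)}/{len(marginal)} significant at alpha=0.05")
    for _, row in sig.iterrows():
        print(f"  {row['tract']:12s} -> {row['outcome']:11s} "
              f"beta={row['beta']:+.4g} p={row['p']:.4f}")


if __name__ == "__main__":
    main()
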