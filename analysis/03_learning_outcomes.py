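"""Behavioral outcomes: drawing-learning slope and recognition accuracy.

Reads the trial tables, removes +-3 SD outlier trials per participant, fits
the per-participant OLS slope of draw duration over repetition, scores 2-AFC
accuracy over responded trials, checks for a speed-accuracy trade-off, and
applies the QC + chance-accuracy exclusion rules.
"""

from pathlib import Path

import pandas as pd

from wmlearn.behavior import (
    apply_exclusions,
    compute_drawing_learning,
    compute_recognition_learning,
    speed_accuracy_check,
)
from wmlearn.io_formats import read_draw_trials, read_qc_table, read_recognition_trials, write_report

DATA = Path("scratch/dataset")
RESULTS = Path("results")


def main() -> None:
    draw = read_draw_trials(DATA / "draw_trials.tsv")
    recog = read_recognition_trials(DATA / "recognition_trials.tsv")
    qc = read_qc_table(DATA / "qc.tsv")

    drawing = compute_drawing_learning(draw)
    recognition = compute_recognition_learning(recog)
    beta, p = speed_accuracy_check(recognition)
    exclusions = apply_exclusions(qc, recognition)

    table = pd.DataFrame(
        {
            "participant_id": [d.participant_id for d in drawing],
            "drawing_slope": [d.slope for d in drawing],
            "n_outlier_trials_removed": [d.n_outlier_trials_removed for d in drawing],
            "recognition_accuracy": [r.accuracy for r in recognition],
            "mean_rt": [r.mean_rt for r in recognition],
            "excluded": [e.excluded for e in exclusions],
            "exclusion_reasons": [",".join(e.reasons) for e in exclusions],
        }
    )
    table.to_csv(RESULTS / "outcomes.tsv", sep="\t", index=False)
    write_report({"speed_accuracy": {"beta": beta, "p": p}, "exclusions": exclusions},
                 RESULTS / "exclusions.json")

    n_excl = sum(e.excluded for e in exclusions)
    print(f"{len(drawing)} participants; mean slope "
          f"{table['drawing_slope'].mean():.4f} s/rep, mean accuracy "
          f"{table['recognition_accuracy'].mean():.3f}")
    print(f"speed-accuracy trade-off: beta={beta:.3f}, p={p:.3f}")
    print(f"excluded {n_excl} participants "
          f"({sum('recognition_chance' in e.reasons for e in exclusions)} at chance accuracy)")


if __name__ == "__main__":
    main()
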