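"""Simulate the synthetic study and write it out in the real pipeline's formats.

Generates a 48-participant cohort: per participant one synthetic FA volume
(NIfTI) containing one tube per tract whose FA equals the cohort-drawn value,
one streamline bundle (TCK) per tract, trial-level drawing and recognition
tables, and a QC table.  Ground truth (drawn features, latent outcomes, true
predictor supports) goes to results/ so later steps can report recovery.

Binary data land in scratch/dataset/ (regenerable); text tables in results/.
"""

from pathlib import Path

import numpy as np

from wmlearn.io_formats import (
    write_draw_trials,
    write_qc_table,
    write_recognition_trials,
    write_scalar_volume,
    write_streamlines,
)
from wmlearn.pipeline import GeometryConfig, _participant_geometry, _tract_layout
from wmlearn.synthetic import (
    CohortSimConfig,
    simulate_cohort,
    simulate_draw_trials,
    simulate_qc,
    simulate_recognition_trials,
)

SEED = 20240622
DATA = Path("scratch/dataset")
RESULTS = Path("results")


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cfg = CohortSimConfig(n_participants=48, seed=SEED)
    features, latents, truth = simulate_cohort(cfg)

    geo = GeometryConfig()
    layout = _tract_layout(cfg.tract_names, geo.tract_length)
    geo_rng = np.random.default_rng(SEED + 1)
    for pid in features.index:
        pdir = DATA / pid
        pdir.mkdir(parents=True, exist_ok=True)
        volume, bundles = _participant_geometry(
            pid, features.loc[pid], layout, geo, seed=int(geo_rng.integers(2**31 - 1))
        )
        write_scalar_volume(volume, pdir / "fa.nii.gz")
        for tract, bundle in bundles.items():
            write_streamlines(bundle, pdir / f"{tract}.tck")

    draw, trial_truth = simulate_draw_trials(latents, cfg)
    recog = simulate_recognition_trials(latents, cfg)
    qc = simulate_qc(list(features.index), seed=SEED + 2)
    write_draw_trials(draw, DATA / "draw_trials.tsv")
    write_recognition_trials(recog, DATA / "recognition_trials.tsv")
    write_qc_table(qc, DATA / "qc.tsv")

    features.to_csv(RESULTS / "true_features.tsv", sep="\t")
    latents.to_csv(RESULTS / "true_latents.tsv", sep="\t")
    print(f"simulated {len(features)} participants x {len(cfg.tract_names)} tracts")
    print(f"true drawing support: {truth.true_support_drawing}")
    print(f"true recognition support: {truth.true_support_recognition}")
    print(f"{len(draw)} drawing trials ({len(trial_truth.outlier_trials)} planted outliers), "
          f"{len(recog)} recognition trials")
    print(f"data under {DATA}/, truth tables under {RESULTS}/")


if __name__ == "__main__":
    main()
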