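"""Generator contracts: planted structure, moments, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wmlearn.synthetic import (
    BundleSimConfig,
    CohortSimConfig,
    FaFieldSpec,
    centerline_points,
    simulate_bundle,
    simulate_cohort,
    simulate_draw_trials,
    simulate_fa_volume,
    simulate_qc,
    simulate_recognition_trials,
)
from wmlearn.io_formats import sample_trilinear
from tests.conftest import curved_control_points


class TestBundles:
    def test_zero_jitter_degenerates_to_centerline(self, control_points):
        cfg = BundleSimConfig(
            centerline_control_points=control_points,
            n_streamlines=5,
            points_per_streamline=50,
            radial_jitter_sd=0.0,
            seed=0,
        )
        bundle, _ = simulate_bundle(cfg)
        center = centerline_points(control_points, 50)
        for s in bundle.streamlines:
            np.testing.assert_allclose(s, center, atol=1e-9)

    def test_planted_outliers_recorded_and_far(self, control_points):
        cfg = BundleSimConfig(
            centerline_control_points=control_points,
            n_streamlines=100,
            radial_jitter_sd=1.0,
            n_planted_outliers=3,
            outlier_offset=10.0,
            seed=3,
        )
        bundle, truth = simulate_bundle(cfg)
        assert len(truth.outlier_streamlines) == 3
        center = centerline_points(control_points, cfg.points_per_streamline)
        for idx in truth.outlier_streamlines:
            mean_dist = np.linalg.norm(bundle.streamlines[idx] - center, axis=1).mean()
            assert mean_dist >= 9.0

    def test_dispersion_monotone_in_jitter(self, control_points):
        def mean_pairwise(jitter, seed):
            cfg = BundleSimConfig(
                centerline_control_points=control_points,
                n_streamlines=20,
                points_per_streamline=30,
                radial_jitter_sd=jitter,
                seed=seed,
            )
            bundle, _ = simulate_bundle(cfg)
            arr = np.stack(bundle.streamlines)
            total, count = 0.0, 0
            for i in range(len(arr)):
                for j in range(i + 1, len(arr)):
                    total += np.linalg.norm(arr[i] - arr[j], axis=1).mean()
                    count += 1
            return total / count

        means = {
            jitter: np.mean([mean_pairwise(jitter, s) for s in range(50)])
            for jitter in (0.5, 1.0, 2.0)
        }
        assert means[0.5] < means[1.0] < means[2.0]

    def test_deterministic_given_seed(self, control_points):
        cfg = dict(
            centerline_control_points=control_points, n_streamlines=10, seed=11
        )
        b1, t1 = simulate_bundle(BundleSimConfig(**cfg))
        b2, t2 = simulate_bundle(BundleSimConfig(**cfg))
        for a, b in zip(b1.streamlines, b2.streamlines):
            np.testing.assert_array_equal(a, b)
        assert t1.outlier_streamlines == t2.outlier_streamlines

    def test_too_few_control_points(self):
        with pytest.raises(ValueError):
            BundleSimConfig(centerline_control_points=np.zeros((3, 3)))


class TestFaVolume:
    def test_constant_field(self):
        spec = FaFieldSpec(shape=(10, 10, 10), affine=np.eye(4), background=0.37)
        vol = simulate_fa_volume(spec)
        values, oob = sample_trilinear(vol, np.array([[4.5, 3.2, 6.8]]))
        assert not oob.any()
        np.testing.assert_allclose(values, 0.37, atol=1e-12)

    def test_gradient_field_value(self):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        spec = FaFieldSpec(
            shape=(60, 5, 5), affine=affine, gradient=(0.3, np.array([0.001, 0, 0]))
        )
        vol = simulate_fa_volume(spec)
        value, oob = sample_trilinear(vol, np.array([100.0, 4.0, 4.0]))
        assert not oob
        assert value == pytest.approx(0.4, abs=1e-10)

    def test_tube_value_on_centerline(self, control_points):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-10.0, -20.0, -20.0]
        spec = FaFieldSpec(
            shape=(60, 25, 25),
            affine=affine,
            background=0.1,
            tube_radius=6.0,  # 3 voxels
            tubes={"t": (control_points, 0.55)},
        )
        vol = simulate_fa_volume(spec)
        center = centerline_points(control_points, 40)
        values, oob = sample_trilinear(vol, center)
        assert not oob.any()
        assert values.min() >= 0.5

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            FaFieldSpec(shape=(5, 5, 5), affine=np.eye(4), tube_radius=0.0)


class TestCohort:
    def test_noiseless_uncorrelated_r2_is_one(self):
        cfg = CohortSimConfig(
            n_participants=50,
            correlation=0.0,
            target_r2_drawing=None,
            slope_noise_sd=0.0,
            seed=1,
        )
        features, latents, truth = simulate_cohort(cfg)
        X = features[truth.true_support_drawing].to_numpy()
        X = np.column_stack([np.ones(len(X)), X])
        y = latents["draw_slope"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        ssr = float(((y - X @ beta) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        assert 1 - ssr / sst == pytest.approx(1.0, abs=1e-12)

    def test_feature_moments_converge(self):
        cfg = CohortSimConfig(n_participants=10000, correlation=0.3, seed=2)
        features, _, _ = simulate_cohort(cfg)
        corr = np.corrcoef(features.to_numpy().T)
        off = corr[~np.eye(22, dtype=bool)]
        assert abs(off.mean() - 0.3) < 0.02
        sds = features.std(ddof=1)
        assert np.allclose(sds, cfg.fa_sd, atol=0.002)

    def test_target_r2_calibration(self):
        cfg = CohortSimConfig(n_participants=5000, target_r2_drawing=0.12, seed=3)
        features, latents, truth = simulate_cohort(cfg)
        X = features[truth.true_support_drawing].to_numpy()
        X = np.column_stack([np.ones(len(X)), X])
        y = latents["draw_slope"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r2 = 1 - ((y - X @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert abs(r2 - 0.12) < 0.03

    def test_nonpositive_definite_rejected(self):
        with pytest.raises(ValueError):
            CohortSimConfig(correlation=-0.2)


class TestDrawTrials:
    def _latents(self, n=3, slope=-0.02, intercept=2.0):
        df = pd.DataFrame(
            {"draw_intercept": intercept, "draw_slope": slope},
            index=[f"p{i}" for i in range(n)],
        )
        df.index.name = "participant_id"
        return df

    def test_noise_free_slope_exact(self):
        cfg = CohortSimConfig(
            symbol_sd=0.0, trial_noise_sd=0.0, trial_outlier_prob=0.0, seed=4
        )
        trials, _ = simulate_draw_trials(self._latents(), cfg)
        for _, sub in trials.groupby("participant_id"):
            fit = stats.linregress(sub["repetition"], sub["draw_duration"])
            assert fit.slope == pytest.approx(-0.02, abs=1e-12)

    def test_default_trial_count(self):
        # 40 symbols x 10 repetitions = 400 drawing trials per participant
        cfg = CohortSimConfig(seed=5)
        trials, _ = simulate_draw_trials(self._latents(2), cfg)
        assert (trials.groupby("participant_id").size() == 400).all()

    def test_planted_outliers_detectable(self):
        # tripled trials exceed the participant's mean + 3 SD in >= 95% of runs
        hits = total = 0
        for seed in range(200):
            cfg = CohortSimConfig(trial_noise_sd=0.25, trial_outlier_prob=0.01, seed=seed)
            trials, truth = simulate_draw_trials(self._latents(1), cfg, seed=seed)
            d = trials["draw_duration"]
            threshold = d.mean() + 3 * d.std(ddof=1)
            planted = {c for _, c in truth.outlier_trials}
            if not planted:
                continue
            flagged = set(trials.loc[d > threshold, "chronological_index"])
            hits += len(planted & flagged)
            total += len(planted)
        assert total > 0
        assert hits / total >= 0.95

    def test_degenerate_durations_rejected(self):
        cfg = CohortSimConfig(seed=6)
        with pytest.raises(ValueError):
            simulate_draw_trials(self._latents(slope=-0.5, intercept=1.0), cfg)


class TestRecognitionTrials:
    def _latents(self, p):
        df = pd.DataFrame(
            {"draw_intercept": 2.0, "draw_slope": -0.02, "p_correct": p}, index=["p0"]
        )
        df.index.name = "participant_id"
        return df

    def test_perfect_accuracy(self):
        cfg = CohortSimConfig(timeout_prob=0.0, seed=7)
        trials = simulate_recognition_trials(self._latents(1 - 1e-12), cfg)
        assert trials["correct"].astype(bool).all()

    def test_default_trial_count(self):
        # 40 targets + 40 distractors = 80 recognition trials
        cfg = CohortSimConfig(seed=8)
        trials = simulate_recognition_trials(self._latents(0.7), cfg)
        assert len(trials) == 80
        assert trials["is_target"].sum() == 40

    def test_binomial_consistency(self):
        cfg = CohortSimConfig(n_symbols=1000, n_distractors=1000, timeout_prob=0.0, seed=9)
        trials = simulate_recognition_trials(self._latents(0.7), cfg)
        k = int(trials["correct"].astype(bool).sum())
        lo, hi = stats.binom.interval(0.99, 2000, 0.7)
        assert lo <= k <= hi

    def test_invalid_accuracy_rejected(self):
        cfg = CohortSimConfig(seed=10)
        with pytest.raises(ValueError):
            simulate_recognition_trials(self._latents(1.0), cfg)


class TestQc:
    def test_planted_failures_violate_exactly_one_rule(self):
        pids = [f"p{i}" for i in range(10)]
        spec = {"p1": "snr", "p4": "motion", "p7": "artifact"}
        qc = simulate_qc(pids, spec, seed=0).set_index("participant_id")
        assert qc.loc["p1", "snr"] < 15 and qc.loc["p1", "fd"] <= 2
        assert qc.loc["p4", "fd"] > 2 and qc.loc["p4", "snr"] >= 15
        assert bool(qc.loc["p7", "artifact_flag"])
        clean = qc.drop(["p1", "p4", "p7"])
        assert (clean["snr"] >= 15).all() and (clean["fd"] <= 2).all()
        assert not clean["artifact_flag"].any()

    def test_no_failures_all_pass(self):
        qc = simulate_qc([f"p{i}" for i in range(20)], None, seed=1)
        assert (qc["snr"] >= 15).all() and (qc["fd"] <= 2).all()
        assert not qc["artifact_flag"].any()
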