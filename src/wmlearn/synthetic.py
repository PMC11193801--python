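"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the study design this pipeline analyzes: a cohort of
participants scanned once (giving one mean-FA value per tract from tube-like
streamline bundles), who then practice drawing 40 unfamiliar symbols in 10
repetition blocks and finish with an 80-trial old/new 2-AFC recognition
test.  Drawing learning is generated as a linear function of a small true
subset of tracts plus noise; recognition accuracy is generated from a
different true subset with negative sign on the logit scale.  Everything
that downstream stages are supposed to recover (outlier streamlines,
outlier trials, true predictor supports, latent slopes and accuracies) is
recorded in :class:`GroundTruth`.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .io_formats import Bundle, ScalarVolume

__all__ = [
    "DEFAULT_TRACTS",
    "BundleSimConfig",
    "CohortSimConfig",
    "FaFieldSpec",
    "GroundTruth",
    "simulate_bundle",
    "simulate_fa_volume",
    "simulate_cohort",
    "simulate_draw_trials",
    "simulate_recognition_trials",
    "simulate_qc",
]

# 11 association tracts per hemisphere: dorsal (SLF1and2, SLF3), ventral
# (ILF, IFOF), the arcuate, the four posterior-vertical-pathway tracts
# (pArc, TPC, MDLFang, MDLFspl), and two vertical control tracts (VOF, FAT).
DEFAULT_TRACTS = [
    f"{h}_{t}"
    for h in ("L", "R")
    for t in (
        "SLF1and2", "SLF3", "ILF", "IFOF", "Arc",
        "pArc", "TPC", "MDLFang", "MDLFspl", "VOF", "FAT",
    )
]


@dataclass
class GroundTruth:
    """Planted structure that downstream stages should recover."""

    outlier_streamlines: list[int] = field(default_factory=list)
    outlier_trials: list[tuple[str, int]] = field(default_factory=list)
    true_support_drawing: list[str] = field(default_factory=list)
    true_support_recognition: list[str] = field(default_factory=list)
    latents: Optional[pd.DataFrame] = None
    tract_values: Optional[dict] = None


# ---------------------------------------------------------------------------
# Streamline bundles


@dataclass
class BundleSimConfig:
    """Tube-like bundle around a smooth centerline.

    Per-streamline dispersion is a constant radial offset drawn uniformly in
    a disk whose component SD is ``radial_jitter_sd`` (bounded support: real
    fascicles have a finite cross-section, and a bounded inlier distribution
    makes the 4-SD cleaning rule separate planted outliers cleanly).  Small
    per-node Gaussian noise is added on top.  Planted outliers are displaced
    by ``outlier_offset`` mm perpendicular to the centerline.
    """

    centerline_control_points: np.ndarray
    n_streamlines: int = 100
    points_per_streamline: int = 100
    radial_jitter_sd: float = 1.0
    node_noise_sd: Optional[float] = None  # default: 5% of radial_jitter_sd
    n_planted_outliers: int = 0
    outlier_offset: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.centerline_control_points = np.asarray(self.centerline_control_points, float)
        if self.centerline_control_points.ndim != 2 or self.centerline_control_points.shape[1] != 3:
            raise ValueError("centerline_control_points must be (m, 3)")
        if self.centerline_control_points.shape[0] < 4:
            raise ValueError("need at least 4 centerline control points")
        if self.radial_jitter_sd < 0:
            raise ValueError("radial_jitter_sd must be >= 0")
        if self.n_planted_outliers > 0 and self.outlier_offset <= 0:
            raise ValueError("outlier_offset must be > 0 when planting outliers")
        if self.node_noise_sd is None:
            self.node_noise_sd = 0.05 * self.radial_jitter_sd


def centerline_points(
    control_points: np.ndarray, n_points: int, oversample: int = 20
) -> np.ndarray:
    """Cubic interpolation through control points, arc-length resampled."""
    cp = np.asarray(control_points, float)
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))])
    spline = CubicSpline(chord, cp, axis=0)
    dense_t = np.linspace(0.0, chord[-1], oversample * len(cp) * 4)
    dense = spline(dense_t)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n_points)
    return np.column_stack([np.interp(targets, cum, dense[:, a]) for a in range(3)])


def _normal_frame(centerline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to the mean tangent."""
    tangent = centerline[-1] - centerline[0]
    norm = np.linalg.norm(tangent)
    if norm == 0:
        tangent = np.array([1.0, 0.0, 0.0])
    else:
        tangent = tangent / norm
    helper = np.array([0.0, 0.0, 1.0])
    if abs(tangent @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(tangent, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(tangent, e1)
    return e1, e2


def simulate_bundle(
    cfg: BundleSimConfig,
    tract_name: str = "synthetic",
    hemisphere: str = "",
    participant_id: str = "sim",
) -> tuple[Bundle, GroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    center = centerline_points(cfg.centerline_control_points, cfg.points_per_streamline)
    e1, e2 = _normal_frame(center)
    disk_radius = 2.0 * cfg.radial_jitter_sd  # uniform disk with component sd = jitter sd
    streamlines = []
    n = cfg.n_streamlines
    outliers = sorted(rng.choice(n, size=cfg.n_planted_outliers, replace=False).tolist())
    for i in range(n):
        r = disk_radius * np.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * np.pi)
        offset = r * (np.cos(theta) * e1 + np.sin(theta) * e2)
        if i in outliers:
            phi = rng.uniform(0.0, 2.0 * np.pi)
            offset = offset + cfg.outlier_offset * (np.cos(phi) * e1 + np.sin(phi) * e2)
        pts = center + offset[None, :]
        if cfg.node_noise_sd > 0:
            pts = pts + rng.normal(0.0, cfg.node_noise_sd, size=pts.shape)
        streamlines.append(pts)
    bundle = Bundle(
        tract_name=tract_name,
        hemisphere=hemisphere,
        participant_id=participant_id,
        streamlines=streamlines,
    )
    return bundle, GroundTruth(outlier_streamlines=outliers)


# ---------------------------------------------------------------------------
# Scalar (FA) volumes


@dataclass
class FaFieldSpec:
    """Piecewise scalar field: background plus tract tubes, or a gradient.

    ``tubes`` maps a label to ``(centerline_points, value)``; voxels whose
    centers lie within ``tube_radius`` mm of a centerline take that tube's
    value.  If ``gradient`` is set, the field is ``a + g . x`` (mm) instead.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    background: float = 0.0
    tube_radius: float = 6.0
    tubes: dict = field(default_factory=dict)
    gradient: Optional[tuple[float, np.ndarray]] = None  # (a, g) -> a + g.x

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, float)
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be > 0")


def simulate_fa_volume(spec: FaFieldSpec) -> ScalarVolume:
    shape = tuple(spec.shape)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    world = vox @ spec.affine[:3, :3].T + spec.affine[:3, 3]
    if spec.gradient is not None:
        a, g = spec.gradient
        values = a + world @ np.asarray(g, float)
        return ScalarVolume(values.reshape(shape), spec.affine, background=spec.background)
    values = np.full(vox.shape[0], spec.background, dtype=float)
    voxel_size = np.linalg.norm(spec.affine[:3, :3], axis=0).min()
    for _, (centerline, value) in spec.tubes.items():
        cl = np.asarray(centerline, float)
        n_dense = max(2, int(np.ceil(4 * np.linalg.norm(cl[-1] - cl[0]) / voxel_size)))
        dense = centerline_points(cl, n_dense) if len(cl) >= 4 else cl
        tree = cKDTree(dense)
        # restrict the query to the tube's bounding box for speed
        lo = dense.min(axis=0) - spec.tube_radius - voxel_size
        hi = dense.max(axis=0) + spec.tube_radius + voxel_size
        box = np.all((world >= lo) & (world <= hi), axis=1)
        idx = np.nonzero(box)[0]
        if idx.size == 0:
            continue
        dist, _ = tree.query(world[idx], k=1)
        values[idx[dist <= spec.tube_radius]] = value
    return ScalarVolume(values.reshape(shape), spec.affine, background=spec.background)


# ---------------------------------------------------------------------------
# Cohort features and learning outcomes


@dataclass
class CohortSimConfig:
    """Study-scale generative model for features, outcomes, and trials.

    Defaults mirror the emulated study: 60 participants, 22 tracts with
    equicorrelated FA, drawing learning driven positively by L_pArc and
    L_SLF3 (population R^2 0.118), recognition accuracy driven negatively by
    L_MDLFspl and L_TPC on the logit scale, 40 symbols x 10 repetitions of
    drawing, and 40 targets + 40 distractors at recognition.
    """

    n_participants: int = 60
    tract_names: list[str] = field(default_factory=lambda: list(DEFAULT_TRACTS))
    fa_mean: Optional[dict] = None      # tract -> mean FA (default 0.38..0.55 spread)
    fa_sd: float = 0.035
    correlation: float = 0.3            # equicorrelation rho of tract FA
    true_coefficients_drawing: dict = field(
        default_factory=lambda: {"L_pArc": 0.2118, "L_SLF3": 0.1772}
    )
    true_coefficients_recognition: dict = field(
        default_factory=lambda: {"L_MDLFspl": -0.629, "L_TPC": -0.4025}
    )
    target_r2_drawing: Optional[float] = 0.118
    slope_noise_sd: float = 1.0         # standardized-outcome noise when no target R^2
    slope_intercept: float = -0.030     # s/repetition, mean drawing-learning slope
    slope_scale: float = 0.010          # s/repetition per standardized outcome unit
    accuracy_intercept_logit: float = 1.0
    # Latent logit variance budget: total latent sd and the fraction explained
    # by the true tracts.  With target_r2_recognition set, the recognition
    # coefficients act as relative weights rescaled to that fraction; with
    # None they are used verbatim and no latent noise is added.
    target_r2_recognition: Optional[float] = 0.1
    accuracy_logit_sd: float = 0.375
    draw_intercept_mean: float = 2.2    # s, mean initial draw duration
    draw_intercept_sd: float = 0.3
    symbol_sd: float = 0.1              # s, per-symbol difficulty effect
    trial_noise_sd: float = 0.25        # s, residual trial noise
    trial_time_limit: float = 4.0       # s
    trial_floor: float = 0.2            # s
    n_symbols: int = 40
    n_repetitions: int = 10
    n_distractors: int = 40
    trial_outlier_prob: float = 0.01
    timeout_prob: float = 0.05
    rt_median: float = 0.55             # s, median 2-AFC reaction time
    rt_log_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must be in [0, 1)")
        for p in (self.trial_outlier_prob, self.timeout_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        unknown = (
            set(self.true_coefficients_drawing)
            | set(self.true_coefficients_recognition)
        ) - set(self.tract_names)
        if unknown:
            raise ValueError(f"true coefficients on unknown tracts {sorted(unknown)}")
        if self.fa_mean is None:
            spread = np.linspace(0.38, 0.55, len(self.tract_names))
            self.fa_mean = dict(zip(self.tract_names, spread))
        if self.target_r2_drawing is not None and not 0 < self.target_r2_drawing < 1:
            raise ValueError("target_r2_drawing must be in (0, 1)")
        if self.target_r2_recognition is not None and not 0 < self.target_r2_recognition < 1:
            raise ValueError("target_r2_recognition must be in (0, 1)")


def _equicorrelation_cholesky(p: int, rho: float) -> np.ndarray:
    corr = np.full((p, p), rho)
    np.fill_diagonal(corr, 1.0)
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc


def signal_variance(beta: np.ndarray, rho: float) -> float:
    """Var of beta . z under unit-variance equicorrelated z."""
    s1 = float(np.sum(beta))
    s2 = float(np.sum(beta**2))
    return (1 - rho) * s2 + rho * s1**2


def simulate_cohort(cfg: CohortSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw the cohort feature matrix and latent learning outcomes.

    Returns ``(features, latents, truth)``: features is participants x tracts
    raw FA; latents has one row per participant with the latent drawing
    intercept/slope and recognition accuracy ``p_correct``.
    """
    rng = np.random.default_rng(cfg.seed)
    tracts = list(cfg.tract_names)
    p = len(tracts)
    n = cfg.n_participants
    chol = _equicorrelation_cholesky(p, cfg.correlation)
    z = rng.standard_normal((n, p)) @ chol.T  # standardized features
    mu = np.array([cfg.fa_mean[t] for t in tracts])
    features = pd.DataFrame(
        mu[None] + cfg.fa_sd * z,
        index=[f"sub-{i + 1:03d}" for i in range(n)],
        columns=tracts,
    )
    features.index.name = "participant_id"

    beta_d = np.array([cfg.true_coefficients_drawing.get(t, 0.0) for t in tracts])
    var_sig = signal_variance(beta_d, cfg.correlation)
    if cfg.target_r2_drawing is not None and var_sig > 0:
        r2 = cfg.target_r2_drawing
        eps_sd = np.sqrt(var_sig * (1 - r2) / r2)
    else:
        eps_sd = cfg.slope_noise_sd
    signal_d = z @ beta_d
    eps = rng.normal(0.0, eps_sd, size=n) if eps_sd > 0 else np.zeros(n)
    slope = cfg.slope_intercept + cfg.slope_scale * (signal_d + eps)

    alpha = np.array([cfg.true_coefficients_recognition.get(t, 0.0) for t in tracts])
    var_sig_r = signal_variance(alpha, cfg.correlation)
    if cfg.target_r2_recognition is not None and var_sig_r > 0:
        r2r = cfg.target_r2_recognition
        alpha = alpha * np.sqrt(r2r) * cfg.accuracy_logit_sd / np.sqrt(var_sig_r)
        nu_sd = np.sqrt(1 - r2r) * cfg.accuracy_logit_sd
        nu = rng.normal(0.0, nu_sd, size=n)
    else:
        nu = np.zeros(n)
    logit = cfg.accuracy_intercept_logit + z @ alpha + nu
    p_correct = 1.0 / (1.0 + np.exp(-logit))

    intercepts = rng.normal(cfg.draw_intercept_mean, cfg.draw_intercept_sd, size=n)
    intercepts = np.clip(intercepts, 0.5, None)

    latents = pd.DataFrame(
        {
            "participant_id": features.index,
            "draw_intercept": intercepts,
            "draw_slope": slope,
            "p_correct": p_correct,
        }
    ).set_index("participant_id")
    truth = GroundTruth(
        true_support_drawing=sorted(cfg.true_coefficients_drawing),
        true_support_recognition=sorted(cfg.true_coefficients_recognition),
        latents=latents,
    )
    return features, latents, truth


def simulate_draw_trials(
    latents: pd.DataFrame, cfg: CohortSimConfig, seed: Optional[int] = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Trial-level drawing durations with planted outlier trials.

    duration(i, s, r) = a_i + b_i * r + u_s + eps, clipped to
    (trial_floor, trial_time_limit]; with probability ``trial_outlier_prob``
    a trial's duration is tripled (then clipped) and recorded in the truth.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    n_rep, n_sym = cfg.n_repetitions, cfg.n_symbols
    bad = latents["draw_intercept"] + latents["draw_slope"] * n_rep <= 0
    if bad.any():
        raise ValueError(
            f"degenerate durations for participant(s) {list(latents.index[bad])}"
        )
    frames = []
    outliers: list[tuple[str, int]] = []
    n_total = n_rep * n_sym
    reps = np.repeat(np.arange(1, n_rep + 1), n_sym)
    chrono = np.arange(1, n_total + 1)
    for pid, row in latents.iterrows():
        a_i, b_i = row["draw_intercept"], row["draw_slope"]
        u = rng.normal(0.0, cfg.symbol_sd, size=n_sym)
        order = np.concatenate([rng.permutation(n_sym) for _ in range(n_rep)])
        noise = rng.normal(0.0, cfg.trial_noise_sd, size=n_total)
        is_out = rng.uniform(size=n_total) < cfg.trial_outlier_prob
        d = a_i + b_i * reps + u[order] + noise
        d = np.where(is_out, 3.0 * d, d)
        d = np.clip(d, cfg.trial_floor + 1e-9, cfg.trial_time_limit)
        outliers.extend((str(pid), int(c)) for c in chrono[is_out])
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": str(pid),
                    "symbol_id": order + 1,
                    "repetition": reps,
                    "chronological_index": chrono,
                    "draw_duration": d,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return df, GroundTruth(outlier_trials=outliers)


def simulate_recognition_trials(
    latents: pd.DataFrame, cfg: CohortSimConfig, seed: Optional[int] = None
) -> pd.DataFrame:
    """Trial-level 2-AFC old/new responses with timeouts.

    Targets are symbols 1..n_symbols, distractors the next n_distractors.
    Each responded trial is correct with the participant's latent
    probability; timeouts (no response) occur with ``timeout_prob`` and have
    undefined correctness and RT.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    p = latents["p_correct"].to_numpy()
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("latent accuracy must be strictly inside (0, 1)")
    frames = []
    n_trials = cfg.n_symbols + cfg.n_distractors
    for pid, p_i in zip(latents.index, p):
        symbols = np.arange(1, n_trials + 1)
        order = rng.permutation(n_trials)
        responded = rng.uniform(size=n_trials) >= cfg.timeout_prob
        correct = rng.uniform(size=n_trials) < p_i
        rt = np.minimum(
            cfg.rt_median * np.exp(rng.normal(0.0, cfg.rt_log_sd, size=n_trials)), 1.0
        )
        sym = symbols[order]
        resp = responded[order]
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": str(pid),
                    "symbol_id": sym,
                    "is_target": sym <= cfg.n_symbols,
                    "responded": resp,
                    "correct": pd.array(
                        np.where(resp, correct[order], None), dtype="boolean"
                    ),
                    "rt": np.where(resp, rt[order], np.nan),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_qc(
    participant_ids, failure_spec: Optional[dict] = None, seed: int = 0
) -> pd.DataFrame:
    """QC table; planted failures violate exactly the intended rule.

    ``failure_spec`` maps participant -> one of {"snr", "motion", "artifact"}.
    All other participants pass every rule by construction.
    """
    rng = np.random.default_rng(seed)
    failure_spec = failure_spec or {}
    unknown_modes = set(failure_spec.values()) - {"snr", "motion", "artifact"}
    if unknown_modes:
        raise ValueError(f"unknown failure mode(s) {sorted(unknown_modes)}")
    rows = []
    for pid in participant_ids:
        snr = rng.uniform(18.0, 35.0)
        fd = rng.uniform(0.1, 1.5)
        artifact = False
        mode = failure_spec.get(pid)
        if mode == "snr":
            snr = rng.uniform(8.0, 14.5)
        elif mode == "motion":
            fd = rng.uniform(2.2, 4.0)
        elif mode == "artifact":
            artifact = True
        rows.append((str(pid), snr, fd, artifact))
    return pd.DataFrame(rows, columns=["participant_id", "snr", "fd", "artifact_flag"])
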