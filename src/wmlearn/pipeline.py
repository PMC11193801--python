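"""End-to-end orchestration: simulate -> profile -> learn -> select -> transfer.

A single config object (YAML-loadable, unknown keys rejected) drives the
run; one global seed deterministically derives every stage seed, so two runs
with the same config and seed produce byte-identical reports.

The default synthetic run is fully geometric: for each participant a
synthetic FA volume is built with one tube per tract whose value is that
participant's cohort-drawn FA, plus a streamline bundle along each tube.
The tractometry stage then recovers the feature matrix from geometry before
the statistical stages run, so the whole pipeline is exercised end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, fields, is_dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (
    apply_exclusions,
    compute_drawing_learning,
    compute_recognition_learning,
    speed_accuracy_check,
)
from .io_formats import report_json, write_qc_table, write_draw_trials, write_recognition_trials
from .model_selection import marginal_regressions, select_model
from .synthetic import (
    DEFAULT_TRACTS,
    BundleSimConfig,
    CohortSimConfig,
    FaFieldSpec,
    simulate_bundle,
    simulate_cohort,
    simulate_draw_trials,
    simulate_fa_volume,
    simulate_qc,
    simulate_recognition_trials,
)
from .tractometry import build_feature_table, bundle_to_profile, profile_mean
from .transfer import run_transfer_analysis

__all__ = ["PipelineConfig", "ProfileConfig", "BehaviorConfig", "SelectionConfig",
           "GeometryConfig", "SimulationConfig", "parse_config", "run_pipeline"]


logger = logging.getLogger("wmlearn.pipeline")


class ConfigError(ValueError):
    pass


@dataclass
class ProfileConfig:
    n_nodes: int = 200
    trim: int = 20
    clean_sd: float = 4.0
    min_len: float = 10.0
    max_len: float = 200.0
    kernel: str = "gaussian"

    def validate(self) -> None:
        if 2 * self.trim >= self.n_nodes:
            raise ConfigError("profile.trim: 2*trim must be < n_nodes")
        if self.kernel not in ("gaussian", "inverse_distance"):
            raise ConfigError(f"profile.kernel: unknown kernel {self.kernel!r}")
        if not 0 < self.min_len < self.max_len:
            raise ConfigError("profile length bounds must satisfy 0 < min < max")


@dataclass
class BehaviorConfig:
    outlier_sd: float = 3.0
    index: str = "repetition"

    def validate(self) -> None:
        if self.index not in ("repetition", "chronological"):
            raise ConfigError(f"behavior.index: unknown mode {self.index!r}")
        if self.outlier_sd <= 0:
            raise ConfigError("behavior.outlier_sd must be > 0")


@dataclass
class SelectionConfig:
    n_grid: int = 100
    decades: float = 4.0
    standardization: str = "sd"

    def validate(self) -> None:
        if self.standardization not in ("sd", "variance"):
            raise ConfigError("selection.standardization must be 'sd' or 'variance'")
        if self.n_grid < 2 or self.decades <= 0:
            raise ConfigError("selection grid parameters out of bounds")


@dataclass
class GeometryConfig:
    enabled: bool = True
    n_streamlines: int = 30
    points_per_streamline: int = 60
    radial_jitter_sd: float = 1.0
    tube_radius: float = 6.0
    voxel_size: float = 2.0
    tract_length: float = 100.0

    def validate(self) -> None:
        if self.tube_radius <= 0 or self.voxel_size <= 0:
            raise ConfigError("geometry tube_radius and voxel_size must be > 0")
        if self.n_streamlines < 5:
            raise ConfigError("geometry.n_streamlines must be >= 5 for cleaning")


@dataclass
class SimulationConfig:
    enabled: bool = True
    n_participants: int = 60
    correlation: float = 0.3
    target_r2_drawing: Optional[float] = 0.118
    target_r2_recognition: Optional[float] = 0.1
    true_coefficients_drawing: dict = field(
        default_factory=lambda: {"L_pArc": 0.2118, "L_SLF3": 0.1772}
    )
    true_coefficients_recognition: dict = field(
        default_factory=lambda: {"L_MDLFspl": -0.629, "L_TPC": -0.4025}
    )
    qc_failures: dict = field(default_factory=dict)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)

    def validate(self) -> None:
        if self.n_participants < 8:
            raise ConfigError("simulation.n_participants must be >= 8")
        self.geometry.validate()


@dataclass
class PipelineConfig:
    tracts: list[str] = field(default_factory=lambda: list(DEFAULT_TRACTS))
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0

    def validate(self) -> None:
        if not self.tracts:
            raise ConfigError("tracts must be nonempty")
        bad = set(self.simulation.true_coefficients_drawing) | set(
            self.simulation.true_coefficients_recognition
        )
        if bad - set(self.tracts):
            raise ConfigError(f"true coefficients reference unknown tracts {sorted(bad - set(self.tracts))}")
        for block in (self.profile, self.behavior, self.selection, self.simulation):
            block.validate()


def _from_dict(cls, data: dict, path: str = ""):
    if not is_dataclass(cls):
        return data
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown config key(s) {sorted(unknown)} at {path or 'top level'}")
    kwargs = {}
    for key, value in data.items():
        f = known[key]
        if is_dataclass(f.type) or f.name in ("profile", "behavior", "selection", "simulation", "geometry"):
            sub_cls = {
                "profile": ProfileConfig,
                "behavior": BehaviorConfig,
                "selection": SelectionConfig,
                "simulation": SimulationConfig,
                "geometry": GeometryConfig,
            }[f.name]
            if not isinstance(value, dict):
                raise ConfigError(f"config key {key} must be a mapping")
            kwargs[key] = _from_dict(sub_cls, value, f"{path}.{key}" if path else key)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def parse_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; empty file -> all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    cfg = _from_dict(PipelineConfig, data)
    cfg.validate()
    return cfg


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


# ---------------------------------------------------------------------------
# Geometry stage


def _tract_layout(tracts: list[str], length: float) -> dict[str, np.ndarray]:
    """Straight-tube layout: one (y, z) lattice slot per tract, axis along x."""
    spacing = 18.0
    layout = {}
    per_row = 5
    for i, tract in enumerate(tracts):
        y = spacing * (i % per_row)
        z = spacing * (i // per_row)
        xs = np.linspace(10.0, 10.0 + length, 4)
        layout[tract] = np.column_stack([xs, np.full(4, y), np.full(4, z)])
    return layout


def _participant_geometry(
    pid: str,
    fa_values: pd.Series,
    layout: dict[str, np.ndarray],
    geo: GeometryConfig,
    seed: int,
):
    """Synthetic FA volume (one tube per tract) + bundles along the tubes."""
    tracts = list(layout)
    max_pos = max(cp[:, 1:].max() for cp in layout.values())
    margin = geo.tube_radius + 4 * geo.voxel_size
    lo = np.array([10.0 - margin, -margin, -margin])
    hi = np.array([10.0 + geo.tract_length + margin, max_pos + margin, max_pos + margin])
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / geo.voxel_size)) + 1 for a in range(3))
    affine = np.diag([geo.voxel_size] * 3 + [1.0])
    affine[:3, 3] = lo
    spec = FaFieldSpec(
        shape=shape,
        affine=affine,
        background=0.05,
        tube_radius=geo.tube_radius,
        tubes={t: (layout[t], float(fa_values[t])) for t in tracts},
    )
    volume = simulate_fa_volume(spec)
    rng = np.random.default_rng(seed)
    bundles = {}
    for t in tracts:
        cfg = BundleSimConfig(
            centerline_control_points=layout[t],
            n_streamlines=geo.n_streamlines,
            points_per_streamline=geo.points_per_streamline,
            radial_jitter_sd=geo.radial_jitter_sd,
            seed=int(rng.integers(2**31 - 1)),
        )
        bundle, _ = simulate_bundle(
            cfg, tract_name=t,
            hemisphere="left" if t.startswith("L_") else "right",
            participant_id=pid,
        )
        bundles[t] = bundle
    return volume, bundles


# ---------------------------------------------------------------------------
# Full run


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline and return (and optionally write) the report."""
    cfg.validate()
    if not cfg.simulation.enabled:
        raise ConfigError("file-based runs go through the CLI stage commands; "
                          "run_pipeline requires the simulation block")
    seeds = np.random.SeedSequence(cfg.seed).generate_state(6) % (2**31 - 1)
    sim = cfg.simulation
    cohort_cfg = CohortSimConfig(
        n_participants=sim.n_participants,
        tract_names=list(cfg.tracts),
        correlation=sim.correlation,
        true_coefficients_drawing=dict(sim.true_coefficients_drawing),
        true_coefficients_recognition=dict(sim.true_coefficients_recognition),
        target_r2_drawing=sim.target_r2_drawing,
        target_r2_recognition=sim.target_r2_recognition,
        seed=int(seeds[0]),
    )
    features_true, latents, truth = simulate_cohort(cohort_cfg)
    logger.info("stage=simulate participants=%d tracts=%d", len(features_true), len(cfg.tracts))
    report: dict = {
        "software_version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "stages": {},
    }
    report["stages"]["simulate"] = {
        "n_participants": int(len(features_true)),
        "true_support_drawing": truth.true_support_drawing,
        "true_support_recognition": truth.true_support_recognition,
    }

    # --- tractometry: recover the feature matrix from geometry ------------
    if sim.geometry.enabled:
        layout = _tract_layout(list(cfg.tracts), sim.geometry.tract_length)
        geo_rng = np.random.default_rng(int(seeds[1]))
        means: dict[str, dict[str, float]] = {}
        for pid in features_true.index:
            volume, bundles = _participant_geometry(
                pid, features_true.loc[pid], layout, sim.geometry,
                seed=int(geo_rng.integers(2**31 - 1)),
            )
            means[pid] = {}
            for t, bundle in bundles.items():
                profile, _removed = bundle_to_profile(
                    bundle, volume,
                    n_nodes=cfg.profile.n_nodes,
                    min_mm=cfg.profile.min_len, max_mm=cfg.profile.max_len,
                    sd_threshold=cfg.profile.clean_sd, kernel=cfg.profile.kernel,
                )
                means[pid][t] = profile_mean(profile, cfg.profile.trim, cfg.profile.n_nodes)
            logger.info("stage=profile participant=%s tracts=%d", pid, len(means[pid]))
        feature_table = build_feature_table(means, list(cfg.tracts))
        recovery_err = float(np.nanmax(np.abs(feature_table.to_numpy() - features_true.to_numpy())))
        report["stages"]["profile"] = {
            "n_bundles": int(len(feature_table) * len(cfg.tracts)),
            "max_feature_recovery_error": recovery_err,
        }
    else:
        feature_table = features_true.copy()
        report["stages"]["profile"] = {"n_bundles": 0, "source": "simulated features used directly"}

    # --- behavior ----------------------------------------------------------
    draw_trials, trial_truth = simulate_draw_trials(latents, cohort_cfg, seed=int(seeds[2]))
    recog_trials = simulate_recognition_trials(latents, cohort_cfg, seed=int(seeds[3]))
    qc = simulate_qc(list(features_true.index), sim.qc_failures, seed=int(seeds[4]))

    drawing = compute_drawing_learning(draw_trials, cfg.behavior.outlier_sd, cfg.behavior.index)
    recognition = compute_recognition_learning(recog_trials)
    sa_beta, sa_p = speed_accuracy_check(recognition)
    logger.info("stage=learn draw_trials=%d recognition_trials=%d participants=%d",
                len(draw_trials), len(recog_trials), len(drawing))
    report["stages"]["learn"] = {
        "n_draw_trials": int(len(draw_trials)),
        "n_recognition_trials": int(len(recog_trials)),
        "n_planted_outlier_trials": len(trial_truth.outlier_trials),
        "n_outlier_trials_removed": int(sum(d.n_outlier_trials_removed for d in drawing)),
        "speed_accuracy_beta": sa_beta,
        "speed_accuracy_p": sa_p,
    }

    # --- exclusions --------------------------------------------------------
    exclusions = apply_exclusions(qc, recognition)
    excluded = {e.participant_id for e in exclusions if e.excluded}
    reasons: dict[str, int] = {}
    for e in exclusions:
        for r in e.reasons:
            reasons[r] = reasons.get(r, 0) + 1
    keep = [p for p in feature_table.index if p not in excluded]
    logger.info("stage=exclusions excluded=%d kept=%d", len(excluded), len(keep))
    report["stages"]["exclusions"] = {
        "n_excluded": len(excluded),
        "reason_counts": reasons,
        "reports": exclusions,
    }

    outcomes = pd.DataFrame(
        {
            "drawing": {d.participant_id: d.slope for d in drawing},
            "recognition": {r.participant_id: r.accuracy for r in recognition},
        }
    ).loc[keep]
    features_kept = feature_table.loc[keep]

    # --- selection ---------------------------------------------------------
    sel_drawing = select_model(
        features_kept, outcomes["drawing"], "drawing",
        mode=cfg.selection.standardization,
        n_grid=cfg.selection.n_grid, decades=cfg.selection.decades,
    )
    sel_recognition = select_model(
        features_kept, outcomes["recognition"], "recognition",
        mode=cfg.selection.standardization,
        n_grid=cfg.selection.n_grid, decades=cfg.selection.decades,
    )
    logger.info("stage=select drawing_support=%d recognition_support=%d",
                len(sel_drawing.selected_tracts), len(sel_recognition.selected_tracts))
    marginal = marginal_regressions(features_kept, outcomes)
    report["stages"]["select"] = {
        "drawing": sel_drawing,
        "recognition": sel_recognition,
        "n_marginal_models": int(len(marginal)),
        "marginal_significant": marginal[marginal["significant"]][
            ["tract", "outcome", "beta", "p"]
        ],
    }

    # --- transfer ----------------------------------------------------------
    report["stages"]["transfer"] = run_transfer_analysis(
        outcomes, sel_drawing, sel_recognition, features_kept
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        feature_table.to_csv(out / "feature_table.tsv", sep="\t")
        outcomes.to_csv(out / "outcomes.tsv", sep="\t")
        write_draw_trials(draw_trials, out / "draw_trials.tsv")
        write_recognition_trials(recog_trials, out / "recognition_trials.tsv")
        write_qc_table(qc, out / "qc.tsv")
        marginal.to_csv(out / "marginal_regressions.tsv", sep="\t", index=False)
        (out / "run_report.json").write_text(report_json(report) + "\n")
    return report
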