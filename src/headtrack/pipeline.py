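"""Seeded end-to-end runs: simulate -> CCG -> Kalman fit -> population stats.

Every stage writes plain CSV/JSON into the run directory and can be re-run
standalone from the previous stage's files; :func:`run_pipeline` composes
them with no hidden state.  Sub-seeds are derived from the master seed by a
documented counter scheme (see :func:`headtrack.observer.make_dataset`), so
identical config + seed gives byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ccg import analyze_recordings, exclude_participants, summaries_to_frame
from .kalman import DEFAULT_Q_DEG2, fit_R
from .observer import (
    CONDITIONS,
    DEFAULT_CONDITION_PARAMS,
    PLANT_PARAMS,
    ObserverConfig,
    TrialRecording,
    make_dataset,
)
from .popstats import BootstrapConfig, bootstrap_contrasts, fit_summary_lmm, frame_level_lmm
from .stimulus import GeneratorConfig, generate_plant_field

__all__ = ["PipelineConfig", "run_pipeline", "load_recordings", "save_recordings"]

RECORDING_COLUMNS = [
    "participant_id",
    "speed",
    "density",
    "frame_index",
    "time_s",
    "presented_heading_deg",
    "response_heading_deg",
]


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; defaults echo the experiment
    (90 s runs, 200 ms / 20 deg steps, SLOW 0.4-0.6 and FAST 2-3 m/s,
    SPARSE 100 vs DENSE 5,000 plants in 10,000 m^2, CCG grid 0-3 s in
    ~50 ms, Kalman Q = 400 deg^2 with a 1 s lag)."""

    n_participants: int = 6
    master_seed: int = 0
    rate_hz: float = 90.0
    duration_s: float = 90.0
    step_s: float = 0.2
    step_sd_deg: float = 20.0
    boundary_radius_m: float = 50.0
    plant_area_m2: float = 10_000.0
    r_jitter_lognorm_sd: float = 0.15
    lag_jitter_sd_s: float = 0.08
    r_run_jitter_lognorm_sd: float = 0.15
    lag_run_jitter_sd_s: float = 0.08
    condition_params: dict = field(
        default_factory=lambda: {
            f"{s}-{d}": {
                "R_deg2": p.R_deg2,
                "lag_s": p.lag_s,
                "motor_sd_deg": p.motor_sd_deg,
            }
            for (s, d), p in DEFAULT_CONDITION_PARAMS.items()
        }
    )
    max_lag_s: float = 3.0
    lag_step_s: float = 0.05
    kalman_Q_deg2: float = DEFAULT_Q_DEG2
    kalman_lag_s: float = 1.0
    kalman_use_ccg_lag: bool = True  # use each recording's lag of least error
    kalman_variance_model: str = "innovation"
    bootstrap_n_reps: int = 200
    bootstrap_frame_fraction: float = 0.25
    bootstrap_participant_fraction: float = 0.5
    out_dir: str = "headtrack_run"

    def observer_params(self) -> dict[tuple[str, str], ObserverConfig]:
        out = {}
        for key, p in self.condition_params.items():
            speed, density = key.split("-")
            out[(speed, density)] = ObserverConfig(
                R_deg2=float(p["R_deg2"]),
                lag_s=float(p["lag_s"]),
                motor_sd_deg=float(p.get("motor_sd_deg", 0.0)),
            )
        missing = [c for c in CONDITIONS if c not in out]
        if missing:
            raise ValueError(f"condition_params missing conditions: {missing}")
        return out

    def generator_template(self) -> GeneratorConfig:
        return GeneratorConfig(
            duration_s=self.duration_s,
            step_s=self.step_s,
            step_sd_deg=self.step_sd_deg,
            boundary_radius_m=self.boundary_radius_m,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def save_recordings(recordings, path) -> None:
    """Write recordings as one long CSV (schema in RECORDING_COLUMNS)."""
    pd.concat([r.to_frame() for r in recordings], ignore_index=True).to_csv(path, index=False)


def load_recordings(path) -> list[TrialRecording]:
    """Load and validate recordings from the long-CSV schema.

    Malformed input is rejected with the offending column (and a wrap hint
    for out-of-range headings).
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"recording CSV missing columns: {missing}")
    for col in ("presented_heading_deg", "response_heading_deg"):
        bad = df.index[(df[col] < 0) | (df[col] >= 360)]
        if len(bad):
            raise ValueError(
                f"column {col}: heading outside [0, 360) at row {bad[0]} "
                f"(value {df.loc[bad[0], col]}); wrap headings with wrap_deg first"
            )
    out = []
    for (pid, speed, density), g in df.groupby(
        ["participant_id", "speed", "density"], sort=True
    ):
        g = g.sort_values("frame_index")
        t = g["time_s"].to_numpy(float)
        if len(t) < 2:
            raise ValueError(f"recording {pid}/{speed}-{density} has <2 frames")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError(
                f"column time_s: not strictly increasing at fixed spacing for "
                f"{pid}/{speed}-{density}"
            )
        out.append(
            TrialRecording(
                participant_id=str(pid),
                speed=str(speed),
                density=str(density),
                rate_hz=1.0 / dt[0],
                time_s=t,
                presented_heading_deg=g["presented_heading_deg"].to_numpy(float),
                response_heading_deg=g["response_heading_deg"].to_numpy(float),
            )
        )
    return out


def _contrast_dict(c) -> dict:
    return {
        "estimate": c.estimate,
        "ci_low": c.ci_low,
        "ci_high": c.ci_high,
        "significant": c.significant,
        "coding": c.intercept_reference,
    }


def _jsonable(obj):
    """Coerce numpy scalars for json.dumps."""
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _log(log_path: Path, lines: list[str], msg: str) -> None:
    lines.append(msg)
    log_path.write_text("\n".join(lines) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages into ``cfg.out_dir`` and return the report dict.

    Stages abort with a stage-named error; files from completed stages stay
    on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    log_path = out / "run.log"
    cfg.to_yaml(out / "config.yaml")
    cfg_hash = hashlib.sha256((out / "config.yaml").read_bytes()).hexdigest()[:16]

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            _log(log_path, log_lines, f"stage {name}: FAILED ({exc})")
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        _log(log_path, log_lines, f"stage {name}: ok in {time.perf_counter() - t0:.2f} s")
        return result

    # --- simulate ---------------------------------------------------------
    def _simulate():
        recordings, truth = make_dataset(
            cfg.n_participants,
            condition_params=cfg.observer_params(),
            gen=cfg.generator_template(),
            master_seed=cfg.master_seed,
            rate_hz=cfg.rate_hz,
            r_jitter_lognorm_sd=cfg.r_jitter_lognorm_sd,
            lag_jitter_sd_s=cfg.lag_jitter_sd_s,
            r_run_jitter_lognorm_sd=cfg.r_run_jitter_lognorm_sd,
            lag_run_jitter_sd_s=cfg.lag_run_jitter_sd_s,
        )
        save_recordings(recordings, out / "recordings.csv")
        truth.to_csv(out / "ground_truth.csv", index=False)
        for density, (n, min_d) in PLANT_PARAMS.items():
            fld = generate_plant_field(
                n,
                cfg.plant_area_m2,
                min_d,
                seed=cfg.master_seed + {"SPARSE": 1, "DENSE": 2}[density],
            )
            fld.to_frame().to_csv(out / f"plants_{density}.csv", index=False)
        return recordings

    recordings = stage("simulate", _simulate)

    # --- ccg --------------------------------------------------------------
    def _ccg():
        profiles, summaries = analyze_recordings(recordings, cfg.max_lag_s, cfg.lag_step_s)
        pd.concat([p.to_frame() for p in profiles], ignore_index=True).to_csv(
            out / "ccg_profiles.csv", index=False
        )
        kept, excluded, report = exclude_participants(summaries)
        summaries_to_frame(summaries).to_csv(out / "ccg_summaries.csv", index=False)
        report.to_csv(out / "exclusions.csv", index=False)
        kept_ids = {s.participant_id for s in kept}
        kept_recs = [r for r in recordings if r.participant_id in kept_ids]
        return kept, kept_recs, report

    kept_summaries, kept_recordings, exclusion_report = stage("ccg", _ccg)

    # --- kalman -----------------------------------------------------------
    def _kalman():
        lag_map = {
            (s.participant_id, s.speed, s.density): s.lag_of_least_error_s
            for s in kept_summaries
        }
        rows = []
        for rec in kept_recordings:
            lag = (
                lag_map[(rec.participant_id, rec.speed, rec.density)]
                if cfg.kalman_use_ccg_lag
                else cfg.kalman_lag_s
            )
            fit = fit_R(
                rec,
                Q_deg2=cfg.kalman_Q_deg2,
                lag_s=lag,
                variance_model=cfg.kalman_variance_model,
            )
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "speed": rec.speed,
                    "density": rec.density,
                    "R_hat_deg2": fit.R_hat_deg2,
                    "R_hat_sd_deg": fit.R_hat_sd_deg,
                    "neg_log_lik": fit.neg_log_lik,
                    "lag_used_s": fit.lag_used_s,
                    "variance_model": fit.variance_model,
                    "converged": fit.converged,
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(out / "kalman_fits.csv", index=False)
        return df

    kalman_fits = stage("kalman", _kalman)

    # --- stats ------------------------------------------------------------
    def _stats():
        report: dict = {"summary_lmm": {}, "bootstrap": {}, "frame_level_lmm": {}}
        for dv in ("lag_of_least_error_s", "normalized_least_error"):
            res = fit_summary_lmm(kept_summaries, dv)
            report["summary_lmm"][dv] = {
                "intercept": res.intercept,
                "re_structure": res.re_structure,
                "converged": res.converged,
                "contrasts": {t: _contrast_dict(c) for t, c in res.contrasts.items()},
            }
        boot = bootstrap_contrasts(
            kept_recordings,
            BootstrapConfig(
                n_reps=cfg.bootstrap_n_reps,
                frame_fraction=cfg.bootstrap_frame_fraction,
                participant_fraction=cfg.bootstrap_participant_fraction,
                seed=cfg.master_seed,
            ),
            max_lag_s=cfg.max_lag_s,
            lag_step_s=cfg.lag_step_s,
        )
        boot.distributions.to_csv(out / "bootstrap_distributions.csv", index=False)
        report["bootstrap"] = {
            dv: {t: _contrast_dict(c) for t, c in terms.items()}
            for dv, terms in boot.contrasts.items()
        }
        report["bootstrap"]["n_reps_used"] = boot.n_reps_used
        report["bootstrap"]["n_reps_failed"] = boot.n_reps_failed
        report["bootstrap"]["re_structures"] = boot.re_structures.to_dict()
        fl = frame_level_lmm(kept_recordings, kept_summaries)
        report["frame_level_lmm"] = {
            "intercept": fl["intercept"],
            "re_structure": fl["re_structure"],
            "converged": fl["converged"],
            "contrasts": {t: _contrast_dict(c) for t, c in fl["contrasts"].items()},
        }
        (out / "contrasts.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=_jsonable))
        return report

    stats_report = stage("stats", _stats)

    manifest = {
        "headtrack_version": __version__,
        "config_sha256_16": cfg_hash,
        "master_seed": cfg.master_seed,
        "n_participants": cfg.n_participants,
        "excluded_participants": exclusion_report["participant_id"].tolist()
        if len(exclusion_report)
        else [],
        "outputs": sorted({p.name for p in out.iterdir() if p.is_file()} | {"manifest.json"}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=_jsonable))
    return {
        "manifest": manifest,
        "stats": stats_report,
        "kalman_fits": kalman_fits,
        "out_dir": str(out),
    }
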