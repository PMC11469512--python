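"""Synthetic participants: a steady-state Kalman observer with response lag
and motor noise, driving the heading response recorded at the frame rate.

This is stage 2 of the synthetic data path (stage 1 is the random-walk
stimulus in :mod:`headtrack.stimulus`).  The observer runs on the 200 ms
step grid where the stimulus random walk (and hence the process variance Q)
is defined: each step it takes a noisy measurement of the presented heading
(sensory noise variance R, deg^2) and moves its internal estimate a fraction
K of the prediction error toward it.  The joystick response is the internal
estimate delayed by a response lag, held at the frame rate, plus white
Gaussian motor noise per frame (optionally low-pass filtered to mimic
joystick inertia).

Datasets built by :func:`make_dataset` mirror the experiment's 2x2
within-participant design — every participant contributes one 90 s run per
speed (SLOW, FAST) x density (SPARSE, DENSE) cell, each on an independently
seeded trajectory — and come with a ground-truth table for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .angles import wrap_deg
from .kalman import predict_update, steady_state
from .stimulus import GeneratorConfig, HeadingTrajectory, generate_heading_path, resample_to_frames

__all__ = [
    "ObserverConfig",
    "TrialRecording",
    "SPEED_LEVELS",
    "DENSITY_LEVELS",
    "CONDITIONS",
    "SPEED_RANGES_MPS",
    "PLANT_PARAMS",
    "DEFAULT_CONDITION_PARAMS",
    "simulate_observer",
    "make_dataset",
]

SPEED_LEVELS = ("SLOW", "FAST")
DENSITY_LEVELS = ("SPARSE", "DENSE")
CONDITIONS = tuple((s, d) for s in SPEED_LEVELS for d in DENSITY_LEVELS)

#: Simulated self-motion speed ranges per speed condition (m/s).
SPEED_RANGES_MPS = {"SLOW": (0.4, 0.6), "FAST": (2.0, 3.0)}

#: Plant-field parameters per density condition: (n plants, min distance m)
#: in a 10,000 m^2 area.  The density levels differ by plant count (100 vs
#: 5,000); the minimum distance only prevents clumping.  Note 100 plants
#: cannot be packed at 15 m separation into 10,000 m^2 (the hexagonal bound
#: is ~51), so the SPARSE field uses a feasible 5 m spacing at that density.
PLANT_PARAMS = {"SPARSE": (100, 5.0), "DENSE": (5000, 1.0)}


@dataclass(frozen=True)
class ObserverConfig:
    """Ground-truth parameters of one simulated participant x condition.

    ``R_deg2`` is the sensory-noise variance of the heading measurement,
    ``lag_s`` the response delay between internal estimate and joystick, and
    ``motor_sd_deg`` the SD of white per-frame motor noise.
    """

    R_deg2: float
    lag_s: float = 1.0
    motor_sd_deg: float = 0.0
    motor_lowpass_hz: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.R_deg2 < 0 or self.lag_s < 0 or self.motor_sd_deg < 0:
            raise ValueError("R_deg2, lag_s and motor_sd_deg must be non-negative")


@dataclass
class TrialRecording:
    """One participant x condition frame series of presented vs response heading."""

    participant_id: str
    speed: str
    density: str
    rate_hz: float
    time_s: np.ndarray
    presented_heading_deg: np.ndarray
    response_heading_deg: np.ndarray

    def __post_init__(self):
        if self.speed not in SPEED_LEVELS:
            raise ValueError(f"speed must be one of {SPEED_LEVELS}, got {self.speed!r}")
        if self.density not in DENSITY_LEVELS:
            raise ValueError(f"density must be one of {DENSITY_LEVELS}, got {self.density!r}")
        dt = np.diff(self.time_s)
        if len(dt) and not np.allclose(dt, 1.0 / self.rate_hz, rtol=1e-6, atol=1e-9):
            raise ValueError("time_s must increase at 1/rate_hz spacing")
        for name in ("presented_heading_deg", "response_heading_deg"):
            h = getattr(self, name)
            if np.any(h < 0) or np.any(h >= 360):
                raise ValueError(f"{name} must lie in [0, 360); wrap headings first")

    @property
    def condition(self) -> tuple[str, str]:
        return (self.speed, self.density)

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "speed": self.speed,
                "density": self.density,
                "frame_index": np.arange(self.n_frames),
                "time_s": self.time_s,
                "presented_heading_deg": self.presented_heading_deg,
                "response_heading_deg": self.response_heading_deg,
            }
        )


def simulate_observer(
    traj: HeadingTrajectory,
    obs: ObserverConfig,
    Q_deg2: float | None = None,
    rate_hz: float = 90.0,
    participant_id: str = "p000",
    speed: str = "SLOW",
    density: str = "SPARSE",
) -> TrialRecording:
    """Simulate one participant's response to a generated trajectory.

    At each 200 ms step the observer measures ``y = wrap(heading + N(0,
    sqrt(R)))`` and updates its estimate with the steady-state gain K
    implied by Q and R (K = 1 when R = 0).  The response frame series is the
    estimate delayed by ``lag_s`` (zero-order hold; frames earlier than the
    lag hold the initial estimate) plus per-frame motor noise, wrapped.
    """
    if Q_deg2 is None:
        Q_deg2 = traj.config.step_sd_deg**2
    if Q_deg2 <= 0 and obs.R_deg2 > 0:
        raise ValueError("Q_deg2 must be positive when R_deg2 > 0")
    rng = np.random.default_rng(obs.seed)
    n = traj.n_steps
    K = 1.0 if obs.R_deg2 == 0 else steady_state(Q_deg2, obs.R_deg2).K

    meas_noise = rng.normal(0.0, np.sqrt(obs.R_deg2), n) if obs.R_deg2 > 0 else np.zeros(n)
    y = wrap_deg(traj.heading_deg + meas_noise)
    x_hat = np.empty(n)
    x_hat[0] = traj.heading_deg[0]
    for t in range(1, n):
        x_hat[t] = predict_update(x_hat[t - 1], y[t], K)

    frames = resample_to_frames(traj, rate_hz)
    step_s = traj.config.step_s
    # response at frame time tau reads the estimate from step floor((tau - lag)/step)
    src = np.floor((frames.time_s - obs.lag_s) / step_s + 1e-9).astype(int)
    src = np.clip(src, 0, n - 1)
    response = x_hat[src]
    if obs.motor_sd_deg > 0:
        noise = rng.normal(0.0, obs.motor_sd_deg, len(response))
        if obs.motor_lowpass_hz is not None:
            # first-order (exponential) smoothing of the motor noise,
            # gain-compensated so the stationary SD stays motor_sd_deg
            alpha = 1.0 - np.exp(-2.0 * np.pi * obs.motor_lowpass_hz / rate_hz)
            sm = np.empty_like(noise)
            acc = 0.0
            for i, v in enumerate(noise):
                acc += alpha * (v - acc)
                sm[i] = acc
            sd = sm.std()
            noise = sm * (obs.motor_sd_deg / sd) if sd > 0 else sm
        response = response + noise
    return TrialRecording(
        participant_id=participant_id,
        speed=speed,
        density=density,
        rate_hz=rate_hz,
        time_s=frames.time_s,
        presented_heading_deg=frames.heading_deg,
        response_heading_deg=np.asarray(wrap_deg(response)),
    )


def _default_condition_params() -> dict[tuple[str, str], ObserverConfig]:
    """Ground-truth observer parameters emulating the study's effect pattern.

    Response lags follow the reported lag-of-least-error contrasts (reference
    cell ~1.18 s, FAST ~0.32 s faster, DENSE ~0.17 s faster).  Sensory-noise
    SDs are set above heading-discrimination thresholds (the study's fits
    exceeded 10 deg) with FAST and DENSE less noisy, and motor noise at 8 deg
    SD stands in for joystick variability.
    """
    sd = {
        ("SLOW", "SPARSE"): 25.0,
        ("FAST", "SPARSE"): 18.0,
        ("SLOW", "DENSE"): 21.0,
        ("FAST", "DENSE"): 15.0,
    }
    lag = {
        ("SLOW", "SPARSE"): 1.18,
        ("FAST", "SPARSE"): 0.86,
        ("SLOW", "DENSE"): 1.01,
        ("FAST", "DENSE"): 0.69,
    }
    return {
        c: ObserverConfig(R_deg2=sd[c] ** 2, lag_s=lag[c], motor_sd_deg=8.0) for c in CONDITIONS
    }


DEFAULT_CONDITION_PARAMS = _default_condition_params()


def _subseed(master_seed: int, counter: int) -> int:
    """Deterministic sub-seed: hash (master_seed, counter) into [0, 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), int(counter)])
    return int(ss.generate_state(1)[0] % (2**31))


def make_dataset(
    n_participants: int,
    condition_params: dict[tuple[str, str], ObserverConfig] | None = None,
    gen: GeneratorConfig | None = None,
    master_seed: int = 0,
    rate_hz: float = 90.0,
    r_jitter_lognorm_sd: float = 0.0,
    lag_jitter_sd_s: float = 0.0,
    r_run_jitter_lognorm_sd: float = 0.0,
    lag_run_jitter_sd_s: float = 0.0,
    speed_ranges: dict[str, tuple[float, float]] | None = None,
) -> tuple[list[TrialRecording], pd.DataFrame]:
    """Simulate a full 2x2 within-participant dataset with known ground truth.

    Each participant gets four recordings (one per condition), each on an
    independently seeded trajectory whose speed range matches the speed
    condition (override per level via ``speed_ranges``; mapping both levels
    to the same range makes the stimulus process identical across
    conditions, as a calibration null requires — the underlying experiment
    likewise randomized trajectories over conditions).  Optional
    per-participant jitter (multiplicative lognormal on R, additive normal
    on lag, shared across that participant's conditions) gives mixed models
    genuine random effects; the ``*_run_jitter_*`` variants draw
    independently per recording, emulating the substantial run-to-run
    variability continuous-tracking performance shows within a participant.

    Returns the recordings and a ground-truth table (one row per recording:
    true R, lag, motor SD and the seeds used).
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    params = dict(condition_params) if condition_params is not None else dict(DEFAULT_CONDITION_PARAMS)
    missing = [c for c in CONDITIONS if c not in params]
    if missing:
        raise ValueError(f"condition_params missing conditions: {missing}")
    template = gen if gen is not None else GeneratorConfig()
    ranges = dict(SPEED_RANGES_MPS) if speed_ranges is None else dict(speed_ranges)

    jit_rng = np.random.default_rng(_subseed(master_seed, 0))
    recordings: list[TrialRecording] = []
    truth_rows = []
    counter = 1
    for i in range(n_participants):
        pid = f"p{i + 1:03d}"
        r_fac = float(jit_rng.lognormal(0.0, r_jitter_lognorm_sd)) if r_jitter_lognorm_sd > 0 else 1.0
        lag_off = float(jit_rng.normal(0.0, lag_jitter_sd_s)) if lag_jitter_sd_s > 0 else 0.0
        for speed, density in CONDITIONS:
            base = params[(speed, density)]
            traj_seed = _subseed(master_seed, counter)
            obs_seed = _subseed(master_seed, counter + 1)
            counter += 2
            r_run = (
                float(jit_rng.lognormal(0.0, r_run_jitter_lognorm_sd))
                if r_run_jitter_lognorm_sd > 0
                else 1.0
            )
            lag_run = (
                float(jit_rng.normal(0.0, lag_run_jitter_sd_s))
                if lag_run_jitter_sd_s > 0
                else 0.0
            )
            cfg = replace(template, speed_range_mps=ranges[speed], seed=traj_seed)
            obs = replace(
                base,
                R_deg2=base.R_deg2 * r_fac * r_run,
                lag_s=max(0.0, base.lag_s + lag_off + lag_run),
                seed=obs_seed,
            )
            traj = generate_heading_path(cfg)
            rec = simulate_observer(
                traj,
                obs,
                Q_deg2=cfg.step_sd_deg**2,
                rate_hz=rate_hz,
                participant_id=pid,
                speed=speed,
                density=density,
            )
            recordings.append(rec)
            truth_rows.append(
                {
                    "participant_id": pid,
                    "speed": speed,
                    "density": density,
                    "R_deg2": obs.R_deg2,
                    "lag_s": obs.lag_s,
                    "motor_sd_deg": obs.motor_sd_deg,
                    "traj_seed": traj_seed,
                    "obs_seed": obs_seed,
                }
            )
    return recordings, pd.DataFrame(truth_rows)
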