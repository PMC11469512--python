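"""Synthetic random-walk heading stimulus and plant-field generator.

Emulates the self-motion stimulus of a VR heading-tracking experiment: the
observer translates (no rotation) through a plane of plants, with a new
heading drawn every 200 ms from a Gaussian step distribution (SD 20 deg)
around the previous heading, starting "forwards" (180 deg).  If a step would
carry the observer outside a circular boundary, 180 deg is added to the newly
chosen heading so the path turns back (a single reflection; the generator
errors if that is ever insufficient).  Translation speed is redrawn uniformly
from the condition's speed range on the same 200 ms grid.

Coordinate convention (documented once, used everywhere): top-down 2D plane,
heading measured clockwise from -y, so 180 deg points along +y ("forwards"):
``dx = v*dt*sin(h)``, ``dy = -v*dt*cos(h)``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import wrap_deg

__all__ = [
    "GeneratorConfig",
    "HeadingTrajectory",
    "PlantField",
    "generate_heading_path",
    "generate_plant_field",
    "resample_to_frames",
    "FrameSeries",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random-walk heading stimulus.

    Defaults are the experiment's values: 90 s runs, a heading change every
    200 ms with SD 20 deg, start heading 180 deg (forwards), and the SLOW
    condition's speed range 0.4-0.6 m/s.  ``boundary_radius_m`` defaults to
    50 m, the radius consistent with the 10,000 m^2 plant area.
    """

    duration_s: float = 90.0
    step_s: float = 0.2
    step_sd_deg: float = 20.0
    start_heading_deg: float = 180.0
    boundary_radius_m: float = 50.0
    speed_range_mps: tuple[float, float] = (0.4, 0.6)
    seed: int = 0

    def __post_init__(self):
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not self.step_s > 0:
            raise ValueError("step_s must be positive")
        if self.step_sd_deg < 0:
            raise ValueError("step_sd_deg must be non-negative")
        lo, hi = self.speed_range_mps
        if not (0 < lo <= hi):
            raise ValueError("speed_range_mps must satisfy 0 < min <= max")
        if self.boundary_radius_m <= 0:
            raise ValueError("boundary_radius_m must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_s / self.step_s))


@dataclass
class HeadingTrajectory:
    """One generated random-walk stimulus at 200 ms step resolution.

    Positions are the observer's location at the *end* of each step;
    ``reflected`` marks steps where the boundary rule replaced the drawn
    heading change ``delta`` by ``delta + 180``.
    """

    config: GeneratorConfig
    step_index: np.ndarray
    time_s: np.ndarray
    heading_deg: np.ndarray
    speed_mps: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray
    reflected: np.ndarray

    @property
    def n_steps(self) -> int:
        return len(self.step_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step_index": self.step_index,
                "time_s": self.time_s,
                "heading_deg": self.heading_deg,
                "speed_mps": self.speed_mps,
                "x_m": self.x_m,
                "y_m": self.y_m,
                "reflected": self.reflected.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        cfg = self.config
        header = (
            "# heading random-walk trajectory; heading clockwise from -y "
            "(180 deg = +y, forwards)\n"
            f"# duration_s={cfg.duration_s} step_s={cfg.step_s} "
            f"step_sd_deg={cfg.step_sd_deg} start_heading_deg={cfg.start_heading_deg} "
            f"boundary_radius_m={cfg.boundary_radius_m} "
            f"speed_range_mps={cfg.speed_range_mps[0]},{cfg.speed_range_mps[1]} "
            f"seed={cfg.seed}\n"
        )
        buf = io.StringIO()
        self.to_frame().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(header)
            fh.write(buf.getvalue())


@dataclass
class PlantField:
    """Random plant placement: n points in a square, minimum pairwise distance."""

    points: np.ndarray  # (n, 2) x_m, y_m
    area_m2: float
    min_dist_m: float
    seed: int

    @property
    def n(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x_m": self.points[:, 0], "y_m": self.points[:, 1]})


@dataclass
class FrameSeries:
    """A zero-order-hold resampling of a step series onto a frame clock."""

    rate_hz: float
    time_s: np.ndarray
    heading_deg: np.ndarray


def _displacement(heading_deg: float, speed: float, dt: float) -> np.ndarray:
    h = np.deg2rad(heading_deg)
    return np.array([speed * dt * np.sin(h), -speed * dt * np.cos(h)])


def generate_heading_path(config: GeneratorConfig) -> HeadingTrajectory:
    """Generate one random-walk heading trajectory.

    Per step: draw the heading change ``delta ~ N(0, step_sd_deg^2)``, then
    the speed ``~ U(speed_range)``; if the candidate end-of-step position
    leaves the circular boundary, use ``heading + delta + 180`` instead and
    flag the step as reflected.  Same seed, same config -> bit-identical
    output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_steps
    dt = config.step_s
    heading = np.empty(n)
    speed = np.empty(n)
    pos = np.zeros((n, 2))
    reflected = np.zeros(n, dtype=bool)

    h = float(wrap_deg(config.start_heading_deg))
    p = np.zeros(2)
    for t in range(n):
        if t == 0:
            cand = h
        else:
            delta = rng.normal(0.0, config.step_sd_deg)
            cand = float(wrap_deg(h + delta))
        v = rng.uniform(*config.speed_range_mps)
        p_new = p + _displacement(cand, v, dt)
        if np.hypot(*p_new) > config.boundary_radius_m:
            cand = float(wrap_deg(cand + 180.0))
            p_new = p + _displacement(cand, v, dt)
            reflected[t] = True
            if np.hypot(*p_new) > config.boundary_radius_m:
                raise RuntimeError(
                    "reflected step still leaves the boundary "
                    f"(radius {config.boundary_radius_m} m, speed {v:.3f} m/s, "
                    f"step {t}); boundary too small for this speed range"
                )
        h, p = cand, p_new
        heading[t] = h
        speed[t] = v
        pos[t] = p

    return HeadingTrajectory(
        config=config,
        step_index=np.arange(n),
        time_s=np.arange(n) * dt,
        heading_deg=heading,
        speed_mps=speed,
        x_m=pos[:, 0],
        y_m=pos[:, 1],
        reflected=reflected,
    )


def generate_plant_field(
    n: int,
    area_m2: float = 10_000.0,
    min_dist_m: float = 15.0,
    seed: int = 0,
    max_attempts: int | None = None,
) -> PlantField:
    """Place ``n`` plants uniformly in a square of ``area_m2``, rejecting
    candidates closer than ``min_dist_m`` to an accepted plant.

    Uses a spatial hash grid so dense fields (5,000 plants at 1 m spacing in
    10,000 m^2) stay fast.  A bounded attempt budget guards against
    infeasible parameter combinations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if area_m2 <= 0 or min_dist_m < 0:
        raise ValueError("area_m2 must be positive and min_dist_m non-negative")
    # crude disk-packing feasibility heuristic (vacuous for a single plant)
    if n > 1 and n * np.pi * (min_dist_m / 2.0) ** 2 >= area_m2:
        warnings.warn(
            f"plant field may be infeasible: {n} plants with min distance "
            f"{min_dist_m} m in {area_m2} m^2",
            stacklevel=2,
        )
    if max_attempts is None:
        max_attempts = max(10_000, 500 * n)

    rng = np.random.default_rng(seed)
    side = float(np.sqrt(area_m2))
    half = side / 2.0
    cell = max(min_dist_m, 1e-9)
    grid: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((n, 2))
    accepted = 0
    attempts = 0
    while accepted < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"plant-field attempt budget exhausted after {attempts} draws: "
                f"n={n}, area_m2={area_m2}, min_dist_m={min_dist_m}"
            )
        attempts += 1
        cand = rng.uniform(-half, half, size=2)
        ci, cj = int(cand[0] // cell), int(cand[1] // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for idx in grid.get((ci + di, cj + dj), ()):
                    if np.hypot(*(pts[idx] - cand)) < min_dist_m:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[accepted] = cand
            grid.setdefault((ci, cj), []).append(accepted)
            accepted += 1
    return PlantField(points=pts, area_m2=area_m2, min_dist_m=min_dist_m, seed=seed)


def resample_to_frames(traj: HeadingTrajectory, rate_hz: float) -> FrameSeries:
    """Zero-order-hold the step-level heading onto a frame clock.

    Each frame carries the heading of the step whose half-open window
    ``[t, t + step_s)`` contains the frame time; a frame landing exactly on a
    step boundary carries the new step's heading.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    n_frames = int(round(traj.config.duration_s * rate_hz))
    times = np.arange(n_frames) / rate_hz
    # nudge against float droop so boundary frames pick the new step
    idx = np.floor(times / traj.config.step_s + 1e-9).astype(int)
    idx = np.clip(idx, 0, traj.n_steps - 1)
    return FrameSeries(rate_hz=rate_hz, time_s=times, heading_deg=traj.heading_deg[idx])
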