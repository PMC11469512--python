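"""Random-walk stimulus generator: step statistics, boundary reflection,
plant fields, and frame resampling."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from headtrack.angles import signed_diff_deg, wrap_deg
from headtrack.stimulus import (
    GeneratorConfig,
    generate_heading_path,
    generate_plant_field,
    resample_to_frames,
)


def test_zero_variance_walk_stays_forwards():
    cfg = GeneratorConfig(step_sd_deg=0.0, boundary_radius_m=1e6, seed=0)
    traj = generate_heading_path(cfg)
    assert np.all(traj.heading_deg == 180.0)
    assert not traj.reflected.any()


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(duration_s=-1)
    with pytest.raises(ValueError):
        GeneratorConfig(speed_range_mps=(0.6, 0.4))
    with pytest.raises(ValueError):
        GeneratorConfig(step_sd_deg=-5)


def test_trajectory_invariants(default_trajectory):
    traj = default_trajectory
    cfg = traj.config
    assert traj.n_steps == round(cfg.duration_s / cfg.step_s) == 450
    assert np.all(np.hypot(traj.x_m, traj.y_m) <= cfg.boundary_radius_m + 1e-9)
    lo, hi = cfg.speed_range_mps
    assert np.all((traj.speed_mps >= lo) & (traj.speed_mps <= hi))
    assert np.all((traj.heading_deg >= 0) & (traj.heading_deg < 360))


def test_seed_reproducibility():
    a = generate_heading_path(GeneratorConfig(seed=5))
    b = generate_heading_path(GeneratorConfig(seed=5))
    c = generate_heading_path(GeneratorConfig(seed=6))
    assert np.array_equal(a.heading_deg, b.heading_deg)
    assert np.array_equal(a.x_m, b.x_m)
    assert not np.array_equal(a.heading_deg, c.heading_deg)


def test_step_sd_recovered_from_pooled_walks():
    """Pooled non-reflected heading changes recover the 20 deg step SD."""
    deltas = []
    for seed in range(25):
        traj = generate_heading_path(GeneratorConfig(seed=seed))
        d = signed_diff_deg(traj.heading_deg[1:], traj.heading_deg[:-1])
        deltas.append(d[~traj.reflected[1:]])
    deltas = np.concatenate(deltas)
    assert len(deltas) >= 10_000
    assert abs(deltas.mean()) < 1.0
    assert deltas.std(ddof=1) == pytest.approx(20.0, rel=0.02)


def test_reflection_flags_match_independent_candidate_check():
    """Reflected steps are exactly those whose unreflected candidate position
    would exit the boundary (independent re-integration of the path)."""
    cfg = GeneratorConfig(boundary_radius_m=5.0, speed_range_mps=(2.0, 3.0), seed=3)
    traj = generate_heading_path(cfg)
    assert traj.reflected.sum() > 0  # tight boundary must actually reflect
    dt = cfg.step_s
    pos = np.zeros(2)
    for t in range(traj.n_steps):
        h = traj.heading_deg[t]
        v = traj.speed_mps[t]
        # the heading that was drawn before any reflection was applied
        cand = wrap_deg(h - 180.0) if traj.reflected[t] else h
        rad = np.deg2rad(cand)
        cand_pos = pos + np.array([v * dt * np.sin(rad), -v * dt * np.cos(rad)])
        exits = np.hypot(*cand_pos) > cfg.boundary_radius_m
        assert exits == bool(traj.reflected[t])
        rad = np.deg2rad(h)
        pos = pos + np.array([v * dt * np.sin(rad), -v * dt * np.cos(rad)])
        assert np.allclose(pos, [traj.x_m[t], traj.y_m[t]])


def test_impossible_boundary_raises():
    with pytest.raises(RuntimeError):
        generate_heading_path(
            GeneratorConfig(boundary_radius_m=0.05, speed_range_mps=(2.0, 3.0), seed=0)
        )


@pytest.mark.parametrize(
    "n, area, min_dist",
    [(100, 10_000.0, 5.0), (20, 10_000.0, 15.0), (5000, 10_000.0, 1.0), (1, 25.0, 100.0)],
)
def test_plant_field_spacing(n, area, min_dist):
    field = generate_plant_field(n, area, min_dist, seed=2)
    assert field.n == n
    half = np.sqrt(area) / 2
    assert np.all(np.abs(field.points) <= half)
    if n > 1:
        assert pdist(field.points).min() >= min_dist


def test_plant_field_infeasible_errors():
    with pytest.warns(UserWarning):
        with pytest.raises(RuntimeError):
            generate_plant_field(100, 100.0, 10.0, seed=0, max_attempts=20_000)


def test_overpacked_field_raises():
    """100 points at 15 m separation exceed the packing capacity of a
    10,000 m^2 square (hexagonal bound ~51), so the generator must refuse
    rather than loop forever."""
    with pytest.warns(UserWarning):
        with pytest.raises(RuntimeError, match="budget"):
            generate_plant_field(100, 10_000.0, 15.0, seed=0, max_attempts=60_000)


def test_plant_field_reproducible():
    a = generate_plant_field(50, 10_000.0, 5.0, seed=9)
    b = generate_plant_field(50, 10_000.0, 5.0, seed=9)
    assert np.array_equal(a.points, b.points)


def test_resample_frame_count_and_hold(default_trajectory):
    frames = resample_to_frames(default_trajectory, 90.0)
    assert len(frames.heading_deg) == 8100
    # a frame exactly on a step boundary carries the new step's heading
    assert frames.heading_deg[18] == default_trajectory.heading_deg[1]
    assert frames.heading_deg[17] == default_trajectory.heading_deg[0]


def test_resample_roundtrip_recovers_steps(default_trajectory):
    """De-duplicating consecutive equal values of the frame series recovers
    the step sequence (modulo equal adjacent steps)."""
    frames = resample_to_frames(default_trajectory, 90.0)
    f = frames.heading_deg
    dedup_frames = f[np.r_[True, f[1:] != f[:-1]]]
    s = default_trajectory.heading_deg
    dedup_steps = s[np.r_[True, s[1:] != s[:-1]]]
    assert np.array_equal(dedup_frames, dedup_steps)
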