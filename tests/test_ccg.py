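"""Cross-correlogram analysis: lag grids, profiles against a brute-force
oracle, normalization, valley extraction, and the border-exclusion rule."""

import numpy as np
import pytest

from headtrack.angles import abs_diff_deg, wrap_deg
from headtrack.ccg import (
    CCGProfile,
    CCGSummary,
    exclude_participants,
    lag_error_matrix,
    lag_error_profile,
    lag_grid_offsets,
    normalize_profile,
    summarize,
)
from headtrack.observer import TrialRecording


def _make_recording(presented, response, rate_hz=90.0, pid="p001"):
    n = len(presented)
    return TrialRecording(
        participant_id=pid,
        speed="SLOW",
        density="SPARSE",
        rate_hz=rate_hz,
        time_s=np.arange(n) / rate_hz,
        presented_heading_deg=np.asarray(wrap_deg(presented)),
        response_heading_deg=np.asarray(wrap_deg(response)),
    )


def _random_walk(n, seed, sd=2.0):
    rng = np.random.default_rng(seed)
    return np.asarray(wrap_deg(180 + np.cumsum(rng.normal(0, sd, n))))


def test_lag_grid_spans_and_spacing():
    offsets = lag_grid_offsets(90.0, max_lag_s=3.0, lag_step_s=0.05)
    assert offsets[0] == 0
    assert offsets[-1] == 270
    assert len(offsets) == 61
    # ~50 ms steps realized as whole frames
    assert np.all(np.diff(offsets) >= 4)
    assert np.all(np.diff(offsets) <= 5)


def test_pure_shift_has_zero_error_at_its_lag():
    pres = _random_walk(2000, seed=0)
    shift = 45  # 0.5 s at 90 Hz
    resp = np.r_[np.full(shift, pres[0]), pres[:-shift]]
    prof = lag_error_profile(_make_recording(pres, resp))
    i = np.flatnonzero(np.isclose(prof.lag_s, 0.5))[0]
    assert prof.mean_abs_error_deg[i] == pytest.approx(0.0, abs=1e-6)
    others = np.delete(prof.mean_abs_error_deg, i)
    assert np.all(others > 0)
    assert summarize(prof).lag_of_least_error_s == pytest.approx(0.5)


def test_identical_series_minimum_at_zero_lag():
    pres = _random_walk(1500, seed=1)
    s = summarize(lag_error_profile(_make_recording(pres, pres.copy())))
    assert s.lag_of_least_error_s == 0.0
    assert s.at_border


def test_profile_matches_bruteforce_oracle():
    """Vectorized profile equals a naive per-frame recomputation on a short
    fixture."""
    rate = 90.0
    pres = _random_walk(450, seed=2)  # 5 s
    resp = _random_walk(450, seed=3)
    rec = _make_recording(pres, resp, rate)
    prof = lag_error_profile(rec, max_lag_s=3.0, lag_step_s=0.05)
    for lag, got in zip(prof.lag_s, prof.mean_abs_error_deg):
        o = int(round(lag * rate))
        vals = [
            abs_diff_deg(pres[t - o], resp[t]) for t in range(len(pres)) if t - o >= 0
        ]
        assert got == pytest.approx(np.mean(vals), abs=1e-9)


def test_short_recording_rejected():
    pres = _random_walk(100, seed=4)
    with pytest.raises(ValueError, match="shorter"):
        lag_error_profile(_make_recording(pres, pres))


def test_lag_error_matrix_consistent_with_profile():
    pres = _random_walk(900, seed=5)
    resp = _random_walk(900, seed=6)
    rec = _make_recording(pres, resp)
    prof = lag_error_profile(rec)
    lag_s, E = lag_error_matrix(rec)
    assert np.allclose(lag_s, prof.lag_s)
    assert np.allclose(np.nanmean(E, axis=1), prof.mean_abs_error_deg, atol=1e-4)


def test_normalization_properties():
    pres = _random_walk(1200, seed=7)
    resp = _random_walk(1200, seed=8)
    prof = lag_error_profile(_make_recording(pres, resp))
    norm = normalize_profile(prof)
    assert norm.normalized_error.max() == pytest.approx(1.0)
    assert np.all(norm.normalized_error > 0)
    # scale invariance
    scaled = CCGProfile(
        lag_s=prof.lag_s,
        mean_abs_error_deg=prof.mean_abs_error_deg * 3.7,
        normalized_error=None,
        participant_id="p",
        speed="SLOW",
        density="SPARSE",
    )
    assert np.allclose(
        normalize_profile(scaled).normalized_error, norm.normalized_error
    )
    # argmin preserved
    assert np.argmin(norm.normalized_error) == np.argmin(prof.mean_abs_error_deg)


def test_all_zero_profile_rejected():
    prof = CCGProfile(
        lag_s=np.arange(5) * 0.05,
        mean_abs_error_deg=np.zeros(5),
        normalized_error=None,
        participant_id="p",
        speed="SLOW",
        density="SPARSE",
    )
    with pytest.raises(ValueError, match="degenerate"):
        normalize_profile(prof)


@pytest.mark.parametrize(
    "errors, expected_lag, expected_border",
    [
        ([3, 2, 1, 2, 3, 4, 5], 0.10, False),  # unique interior minimum
        ([7, 6, 5, 4, 3, 2, 1], 0.30, True),  # strictly decreasing -> border
        ([3, 2, 1, 2, 1, 2, 3], 0.10, False),  # tie -> smaller lag
        ([1, 1, 1, 1, 1, 1, 1], 0.00, True),  # flat -> lag 0, border
    ],
)
def test_summarize_valley_rules(errors, expected_lag, expected_border):
    prof = CCGProfile(
        lag_s=np.arange(7) * 0.05,
        mean_abs_error_deg=np.asarray(errors, float),
        normalized_error=None,
        participant_id="p",
        speed="SLOW",
        density="SPARSE",
    )
    s = summarize(prof)
    assert s.lag_of_least_error_s == pytest.approx(expected_lag)
    assert s.at_border == expected_border
    assert s.normalized_least_error == pytest.approx(min(errors) / max(errors))


def _summary(pid, speed, density, lag, border):
    return CCGSummary(
        participant_id=pid,
        speed=speed,
        density=density,
        lag_of_least_error_s=lag,
        normalized_least_error=0.5,
        raw_least_error_deg=40.0,
        at_border=border,
    )


def test_exclusion_removes_whole_participant():
    summaries = []
    for pid, borders in [("p001", [False] * 4), ("p002", [False, True, False, False])]:
        for (speed, density), b in zip(
            [("SLOW", "SPARSE"), ("SLOW", "DENSE"), ("FAST", "SPARSE"), ("FAST", "DENSE")],
            borders,
        ):
            summaries.append(_summary(pid, speed, density, 0.0 if b else 1.0, b))
    kept, excluded, report = exclude_participants(summaries)
    assert {s.participant_id for s in kept} == {"p001"}
    assert len(excluded) == 4  # all four conditions of p002 removed
    assert report.participant_id.tolist() == ["p002"]
    assert "border" in report.reason.iloc[0]


def test_flat_profile_participant_is_excluded():
    """A participant who did not track (exactly flat lag-error profile, the
    limit of random responding) lands on the border via the tie-break and is
    excluded."""
    flat = CCGProfile(
        lag_s=np.arange(61) * 0.05,
        mean_abs_error_deg=np.full(61, 90.0),
        normalized_error=None,
        participant_id="p009",
        speed="SLOW",
        density="SPARSE",
    )
    s = summarize(flat)
    assert s.lag_of_least_error_s == 0.0 and s.at_border
    kept, excluded, _ = exclude_participants([s])
    assert not kept and excluded
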