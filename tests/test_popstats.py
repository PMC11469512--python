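"""Population-level contrasts: ground-truth recovery, coding conventions,
the subsampling bootstrap, and the frame-level variability model."""

import numpy as np
import pytest

from headtrack.ccg import analyze_recordings, summaries_to_frame
from headtrack.observer import CONDITIONS, ObserverConfig, make_dataset
from headtrack.popstats import (
    SUMMARY_DVS,
    BootstrapConfig,
    bootstrap_contrasts,
    fit_summary_lmm,
    frame_level_lmm,
)


def _dataset(n_participants, params, master_seed, **kw):
    recs, _ = make_dataset(
        n_participants, condition_params=params, master_seed=master_seed, **kw
    )
    _, summaries = analyze_recordings(recs)
    return recs, summaries


@pytest.fixture(scope="module")
def lag_effect_dataset():
    """FAST responds 0.3 s faster than SLOW; density has no effect."""
    params = {
        c: ObserverConfig(
            R_deg2=225.0, lag_s=1.0 if c[0] == "SLOW" else 0.7, motor_sd_deg=8.0
        )
        for c in CONDITIONS
    }
    return _dataset(20, params, master_seed=101, lag_jitter_sd_s=0.05)


@pytest.fixture(scope="module")
def null_dataset():
    params = {c: ObserverConfig(R_deg2=400.0, lag_s=1.0, motor_sd_deg=8.0) for c in CONDITIONS}
    return _dataset(6, params, master_seed=202)


def test_lag_contrast_recovers_injected_effect(lag_effect_dataset):
    _, summaries = lag_effect_dataset
    res = fit_summary_lmm(summaries, "lag_of_least_error_s")
    c = res.contrasts["FAST_vs_SLOW"]
    assert c.estimate == pytest.approx(-0.3, abs=0.1)
    assert c.significant and c.ci_high < 0
    assert abs(res.contrasts["DENSE_vs_SPARSE"].estimate) < 0.1
    assert res.intercept == pytest.approx(1.0, abs=0.15)


def test_null_dataset_contrasts_near_zero(null_dataset):
    _, summaries = null_dataset
    for dv, tol in [("lag_of_least_error_s", 0.15), ("normalized_least_error", 0.05)]:
        res = fit_summary_lmm(summaries, dv)
        for c in res.contrasts.values():
            assert abs(c.estimate) < tol


def test_relabeling_speed_flips_contrast_sign(lag_effect_dataset):
    _, summaries = lag_effect_dataset
    df = summaries_to_frame(summaries)
    res = fit_summary_lmm(df, "lag_of_least_error_s")
    swapped = df.assign(speed=df.speed.map({"SLOW": "FAST", "FAST": "SLOW"}))
    res_swapped = fit_summary_lmm(swapped, "lag_of_least_error_s")
    assert res_swapped.contrasts["FAST_vs_SLOW"].estimate == pytest.approx(
        -res.contrasts["FAST_vs_SLOW"].estimate, abs=1e-8
    )


def test_unknown_dv_rejected(null_dataset):
    with pytest.raises(ValueError):
        fit_summary_lmm(null_dataset[1], "nonexistent_dv")


def test_degenerate_bootstrap_reproduces_full_fit(null_dataset):
    """frame_fraction = participant_fraction = 1 with one repetition is the
    full-data analysis."""
    recs, summaries = null_dataset
    boot = bootstrap_contrasts(
        recs,
        BootstrapConfig(n_reps=1, frame_fraction=1.0, participant_fraction=1.0, seed=0),
    )
    for dv in SUMMARY_DVS:
        full = fit_summary_lmm(summaries, dv)
        for term, c in boot.contrasts[dv].items():
            assert c.estimate == pytest.approx(
                full.contrasts[term].estimate, abs=2e-3
            )


def test_bootstrap_detects_injected_lag_advantage(lag_effect_dataset):
    recs, _ = lag_effect_dataset
    boot = bootstrap_contrasts(recs, BootstrapConfig(n_reps=60, seed=5))
    c = boot.contrasts["lag_of_least_error_s"]["FAST_vs_SLOW"]
    assert c.ci_high < 0 and c.significant
    assert boot.n_reps_failed == 0
    dist = boot.distribution("lag_of_least_error_s", "FAST_vs_SLOW")
    assert len(dist) == 60
    assert np.all(dist < 0)


def test_bootstrap_ci_widens_with_smaller_frame_fraction(null_dataset):
    """Percentile CIs widen (in expectation) as the per-repetition frame
    subsample shrinks."""
    recs, _ = null_dataset
    widths = {}
    for frac in (0.8, 0.05):
        w = []
        for seed in range(4):
            boot = bootstrap_contrasts(
                recs, BootstrapConfig(n_reps=60, frame_fraction=frac, seed=seed)
            )
            c = boot.contrasts["lag_of_least_error_s"]["FAST_vs_SLOW"]
            w.append(c.ci_high - c.ci_low)
        widths[frac] = np.mean(w)
    assert widths[0.05] > widths[0.8]


def test_full_data_estimate_inside_bootstrap_ci():
    """The full-data contrast lies inside its own bootstrap CI in at least
    90% of synthetic replicates."""
    inside = total = 0
    for syn in range(8):
        recs, summaries = _dataset(
            8,
            None,  # default condition params carry the effect pattern
            master_seed=900 + syn,
            r_jitter_lognorm_sd=0.15,
            lag_jitter_sd_s=0.08,
        )
        boot = bootstrap_contrasts(recs, BootstrapConfig(n_reps=80, seed=950 + syn))
        for dv in SUMMARY_DVS:
            full = fit_summary_lmm(summaries, dv)
            for term, c in boot.contrasts[dv].items():
                total += 1
                inside += c.ci_low <= full.contrasts[term].estimate <= c.ci_high
    assert inside / total >= 0.90


def test_bootstrap_config_validation():
    with pytest.raises(ValueError):
        BootstrapConfig(frame_fraction=0.0)
    with pytest.raises(ValueError):
        BootstrapConfig(n_reps=0)


def test_frame_level_contrast_tracks_sensory_noise():
    """Much noisier SLOW observers produce a negative FAST contrast in the
    frame-level absolute-error model."""
    params = {
        c: ObserverConfig(
            R_deg2=900.0 if c[0] == "SLOW" else 100.0, lag_s=1.0, motor_sd_deg=5.0
        )
        for c in CONDITIONS
    }
    recs, summaries = _dataset(6, params, master_seed=303)
    res = frame_level_lmm(recs, summaries)
    c = res["contrasts"]["FAST_vs_SLOW"]
    assert c.estimate < 0 and c.ci_high < 0
    assert res["n_obs"] > 100_000


def test_frame_level_dv_aggregates_to_summary_raw_error(null_dataset):
    """Averaging the frame-level DV within participant x condition recovers
    the summary table's raw least error."""
    import pandas as pd

    from headtrack.angles import abs_diff_deg

    recs, summaries = null_dataset
    sdf = summaries_to_frame(summaries)
    for rec in recs:
        row = sdf[
            (sdf.participant_id == rec.participant_id)
            & (sdf.speed == rec.speed)
            & (sdf.density == rec.density)
        ].iloc[0]
        o = int(round(row.lag_of_least_error_s * rec.rate_hz))
        dv = abs_diff_deg(
            rec.presented_heading_deg[: rec.n_frames - o] if o else rec.presented_heading_deg,
            rec.response_heading_deg[o:],
        )
        assert np.mean(dv) == pytest.approx(row.raw_least_error_deg, abs=1e-4)
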