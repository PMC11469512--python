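"""Cross-correlogram (lag-of-least-error) analysis of tracking recordings.

For each candidate lag on a grid from 0 to 3 s (~50 ms spacing, realized as
the nearest whole number of frames at the recording's own frame rate), the
presented heading is shifted back by that lag and the mean absolute angular
error against the response is computed over the usable frames (frames whose
shifted stimulus index would be negative are dropped; no padding).  The
profile is normalized by its own maximum so participants and conditions are
comparable; its minimum yields the two per-recording summary measures:

* lag of least error (s) — how fast the participant responds, and
* normalized least error in (0, 1] — how variable their tracking is.

Participants whose lag of least error sits on either border of the grid (0 s
or the maximum lag) in any condition did not track the stimulus (random or
flow-aligned responding) and are excluded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .angles import abs_diff_deg

__all__ = [
    "CCGProfile",
    "CCGSummary",
    "lag_grid_offsets",
    "lag_error_profile",
    "lag_error_matrix",
    "normalize_profile",
    "summarize",
    "analyze_recordings",
    "exclude_participants",
]


@dataclass
class CCGProfile:
    """Mean absolute angular error as a function of stimulus-response lag."""

    lag_s: np.ndarray
    mean_abs_error_deg: np.ndarray
    normalized_error: np.ndarray | None
    participant_id: str
    speed: str
    density: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "speed": self.speed,
                "density": self.density,
                "lag_s": self.lag_s,
                "mean_abs_error_deg": self.mean_abs_error_deg,
                "normalized_error": (
                    self.normalized_error
                    if self.normalized_error is not None
                    else np.full(len(self.lag_s), np.nan)
                ),
            }
        )


@dataclass
class CCGSummary:
    """The extracted valley of one profile."""

    participant_id: str
    speed: str
    density: str
    lag_of_least_error_s: float
    normalized_least_error: float
    raw_least_error_deg: float
    at_border: bool


def lag_grid_offsets(rate_hz: float, max_lag_s: float = 3.0, lag_step_s: float = 0.05) -> np.ndarray:
    """Integer frame offsets realizing the lag grid at this frame rate.

    Offsets are the nearest whole frames to multiples of ``lag_step_s``
    (duplicates collapsed), so the grid reproduces ~50 ms spacing at any
    recording rate.
    """
    if rate_hz <= 0 or max_lag_s <= 0 or lag_step_s <= 0:
        raise ValueError("rate_hz, max_lag_s and lag_step_s must be positive")
    n = int(round(max_lag_s / lag_step_s))
    offsets = np.unique(np.round(np.arange(n + 1) * lag_step_s * rate_hz).astype(int))
    return offsets


def lag_error_profile(
    trial,
    max_lag_s: float = 3.0,
    lag_step_s: float = 0.05,
) -> CCGProfile:
    """Mean absolute angular error per lag for one recording.

    ``error(lag) = mean_t abs_diff(presented(t - lag), response(t))`` over
    frames with ``t - lag >= 0``.
    """
    offsets = lag_grid_offsets(trial.rate_hz, max_lag_s, lag_step_s)
    n = trial.n_frames
    if n <= offsets[-1]:
        raise ValueError(
            f"recording has {n} frames, shorter than the maximum lag "
            f"({offsets[-1]} frames at {trial.rate_hz} Hz)"
        )
    pres = trial.presented_heading_deg
    resp = trial.response_heading_deg
    errs = np.empty(len(offsets))
    for i, o in enumerate(offsets):
        errs[i] = np.mean(abs_diff_deg(pres[: n - o], resp[o:])) if o else np.mean(
            abs_diff_deg(pres, resp)
        )
    return CCGProfile(
        lag_s=offsets / trial.rate_hz,
        mean_abs_error_deg=errs,
        normalized_error=None,
        participant_id=trial.participant_id,
        speed=trial.speed,
        density=trial.density,
    )


def lag_error_matrix(trial, max_lag_s: float = 3.0, lag_step_s: float = 0.05):
    """Per-frame absolute errors for every lag on the grid, as a
    (n_lags, n_frames) float32 matrix with NaN where ``t - lag < 0``.

    ``nanmean`` over (a subset of) columns reproduces :func:`lag_error_profile`
    on that subset — the workhorse behind the frame-subsampling bootstrap.
    """
    offsets = lag_grid_offsets(trial.rate_hz, max_lag_s, lag_step_s)
    n = trial.n_frames
    if n <= offsets[-1]:
        raise ValueError("recording shorter than the maximum lag")
    pres = trial.presented_heading_deg
    resp = trial.response_heading_deg
    E = np.full((len(offsets), n), np.nan, dtype=np.float32)
    for i, o in enumerate(offsets):
        E[i, o:] = abs_diff_deg(pres[: n - o], resp[o:])
    return offsets / trial.rate_hz, E


def normalize_profile(p: CCGProfile) -> CCGProfile:
    """Divide the error profile by its maximum, yielding values in (0, 1]."""
    mx = float(np.max(p.mean_abs_error_deg))
    if mx <= 0:
        raise ValueError("degenerate profile: zero error at every lag, cannot normalize")
    return replace(p, normalized_error=p.mean_abs_error_deg / mx)


def summarize(p: CCGProfile) -> CCGSummary:
    """Extract the valley: its lag (ties break toward the smaller lag) and
    depth, raw and normalized; flag minima on the grid border."""
    prof = p if p.normalized_error is not None else normalize_profile(p)
    i = int(np.argmin(prof.mean_abs_error_deg))  # np.argmin returns first tie
    return CCGSummary(
        participant_id=prof.participant_id,
        speed=prof.speed,
        density=prof.density,
        lag_of_least_error_s=float(prof.lag_s[i]),
        normalized_least_error=float(prof.normalized_error[i]),
        raw_least_error_deg=float(prof.mean_abs_error_deg[i]),
        at_border=bool(i == 0 or i == len(prof.lag_s) - 1),
    )


def analyze_recordings(
    recordings,
    max_lag_s: float = 3.0,
    lag_step_s: float = 0.05,
) -> tuple[list[CCGProfile], list[CCGSummary]]:
    """Run profile -> normalize -> summarize over a list of recordings."""
    profiles = [
        normalize_profile(lag_error_profile(r, max_lag_s, lag_step_s)) for r in recordings
    ]
    return profiles, [summarize(p) for p in profiles]


def summaries_to_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in summaries],
            "speed": [s.speed for s in summaries],
            "density": [s.density for s in summaries],
            "lag_of_least_error_s": [s.lag_of_least_error_s for s in summaries],
            "normalized_least_error": [s.normalized_least_error for s in summaries],
            "raw_least_error_deg": [s.raw_least_error_deg for s in summaries],
            "at_border": [s.at_border for s in summaries],
        }
    )


def exclude_participants(summaries) -> tuple[list[CCGSummary], list[CCGSummary], pd.DataFrame]:
    """Apply the border-exclusion rule.

    A participant whose lag of least error lies on the grid border in *any*
    condition is removed with all their conditions.  Returns (kept summaries,
    excluded summaries, report of who was excluded and why).
    """
    flagged: dict[str, list[tuple[str, str, float]]] = {}
    for s in summaries:
        if s.at_border:
            flagged.setdefault(s.participant_id, []).append(
                (s.speed, s.density, s.lag_of_least_error_s)
            )
    kept = [s for s in summaries if s.participant_id not in flagged]
    excluded = [s for s in summaries if s.participant_id in flagged]
    report = pd.DataFrame(
        [
            {
                "participant_id": pid,
                "reason": "lag of least error on grid border",
                "conditions": "; ".join(f"{sp}-{de} @ {lag:.3f}s" for sp, de, lag in conds),
            }
            for pid, conds in sorted(flagged.items())
        ]
    )
    return kept, excluded, report
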