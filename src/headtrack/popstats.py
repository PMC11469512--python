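"""Population-level inference on tracking summaries.

Three procedures, all sharing the fixed-effect structure
``dv ~ Speed + Density`` with by-participant random intercepts and slopes
(treatment coding, SLOW and SPARSE as reference levels, so the intercept
estimates the SLOW-SPARSE cell mean and both reported difference contrasts
are negative when FAST / DENSE improve performance):

* :func:`fit_summary_lmm` — the mixed model on per-participant x condition
  cross-correlogram summaries (lag of least error, or normalized least
  error).
* :func:`bootstrap_contrasts` — the manual subsampling bootstrap: many
  repetitions, each re-running the full CCG analysis on a random half of the
  participants and a random quarter of each recording's frames, refitting
  the mixed model, and collecting the two difference contrasts; the 2.5th
  and 97.5th percentiles of each contrast form its 95% CI.
* :func:`frame_level_lmm` — the frame-level variability model: absolute
  angular error at each participant x condition's lag of least error, on
  every recorded frame, as dependent variable.

Small (sub)samples often cannot support correlated random slopes, so fits
walk a simplification ladder — correlated slopes, then uncorrelated slopes,
then random intercept only — recording which structure was used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lmm import fit_reml
from .angles import abs_diff_deg
from .ccg import lag_error_matrix, summaries_to_frame

__all__ = [
    "ContrastEstimate",
    "LmmResult",
    "BootstrapConfig",
    "BootstrapResult",
    "fit_summary_lmm",
    "bootstrap_contrasts",
    "frame_level_lmm",
]

TERMS = ("FAST_vs_SLOW", "DENSE_vs_SPARSE")
SUMMARY_DVS = ("lag_of_least_error_s", "normalized_least_error")
_CODING_NOTE = "treatment coding; intercept = SLOW-SPARSE cell mean"


@dataclass
class ContrastEstimate:
    """A fixed-effect difference contrast with its 95% CI."""

    term: str
    estimate: float
    ci_low: float
    ci_high: float
    significant: bool
    intercept_reference: str = _CODING_NOTE


@dataclass
class LmmResult:
    dv: str
    intercept: float
    contrasts: dict[str, ContrastEstimate]
    re_structure: str  # "correlated" | "uncorrelated" | "intercept_only"
    converged: bool
    n_obs: int


@dataclass(frozen=True)
class BootstrapConfig:
    """Subsampling scheme of the bootstrapped CCG analysis: each repetition
    uses ``frame_fraction`` of the frames of ``participant_fraction`` of the
    participants (both drawn without replacement)."""

    n_reps: int = 1000
    frame_fraction: float = 0.25
    participant_fraction: float = 0.5
    seed: int = 0
    max_failure_fraction: float = 0.10

    def __post_init__(self):
        if not (0 < self.frame_fraction <= 1 and 0 < self.participant_fraction <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class BootstrapResult:
    contrasts: dict[str, dict[str, ContrastEstimate]]  # dv -> term -> estimate
    distributions: pd.DataFrame  # rep_index, dv, term, estimate
    n_reps_used: int
    n_reps_failed: int
    re_structures: pd.Series  # counts of ladder rungs used

    def distribution(self, dv: str, term: str) -> np.ndarray:
        d = self.distributions
        return d.loc[(d.dv == dv) & (d.term == term), "estimate"].to_numpy()


def _design(df: pd.DataFrame) -> np.ndarray:
    speed_f = (df["speed"].to_numpy() == "FAST").astype(float)
    density_f = (df["density"].to_numpy() == "DENSE").astype(float)
    return np.column_stack([np.ones(len(df)), speed_f, density_f])


def _fit_ladder(endog, exog, groups, warm=None):
    """Fit the mixed model, simplifying the random-effects structure until a
    converged fit with finite fixed effects is obtained (correlated slopes,
    then uncorrelated slopes, then random intercept only).

    Returns (fe_params, fe_bse, structure, converged); the last rung's
    result is returned (flagged unconverged) if nothing converges.
    """
    endog = np.asarray(endog, float)
    # a constant response (common for the grid-valued lag DV under null
    # conditions) has no variance to model: intercept = the constant,
    # contrasts exactly zero
    if np.ptp(endog) <= 1e-12 * max(1.0, np.abs(endog).max()):
        p = exog.shape[1]
        fe = np.zeros(p)
        fe[0] = endog[0]
        return fe, np.zeros(p), "constant_dv", True
    attempts = []
    last = None
    for structure in ("correlated", "uncorrelated", "intercept_only"):
        try:
            theta0 = warm.get(structure) if warm is not None else None
            fit = fit_reml(endog, exog, groups, structure, theta0=theta0)
        except (np.linalg.LinAlgError, ValueError) as exc:
            attempts.append((structure, repr(exc)))
            continue
        ok = bool(fit.converged and np.all(np.isfinite(fit.fe_params)))
        if ok and warm is not None:
            warm[structure] = fit.theta
        last = (fit.fe_params, fit.fe_bse, structure, ok)
        if ok:
            return last
    if last is not None:
        return last
    raise RuntimeError(f"mixed model failed at every random-effects structure: {attempts}")


def _as_summary_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries
    return summaries_to_frame(list(summaries))


def fit_summary_lmm(summaries, dv: str = "lag_of_least_error_s") -> LmmResult:
    """Mixed model on CCG summaries: ``dv ~ Speed + Density`` with
    by-participant random intercepts and slopes; Wald 95% CIs.

    ``dv`` is ``"lag_of_least_error_s"`` or ``"normalized_least_error"``
    (``"lag_of_least_error"`` / ``"raw_least_error_deg"`` accepted too).
    """
    df = _as_summary_frame(summaries)
    if dv == "lag_of_least_error":  # spec-facing alias
        dv = "lag_of_least_error_s"
    if dv not in df.columns:
        raise ValueError(f"unknown dependent variable {dv!r}")
    n_part = df["participant_id"].nunique()
    if n_part < 2:
        raise ValueError("need at least 2 participants")
    X = _design(df)
    fe, bse, structure, converged = _fit_ladder(
        df[dv].to_numpy(float), X, df["participant_id"].to_numpy()
    )
    z = 1.959963984540054
    contrasts = {}
    for i, term in enumerate(TERMS, start=1):
        lo, hi = fe[i] - z * bse[i], fe[i] + z * bse[i]
        contrasts[term] = ContrastEstimate(
            term=term,
            estimate=float(fe[i]),
            ci_low=float(lo),
            ci_high=float(hi),
            significant=bool(lo > 0 or hi < 0),
        )
    return LmmResult(
        dv=dv,
        intercept=float(fe[0]),
        contrasts=contrasts,
        re_structure=structure,
        converged=converged,
        n_obs=len(df),
    )


def _subsample_summary_rows(sampled, frame_fraction, rng):
    """One bootstrap repetition's CCG summary table: per sampled recording,
    subsample frames, recompute the lag-error profile, extract its valley.

    Exploits the structure of the lag-error matrix: the frames a lag cannot
    use are exactly those below its offset, so a zero-filled sum plus a
    count correction reproduces the nanmean over the subsample.
    """
    rows = []
    for pid, recs in sampled:
        for speed, density, lag_s, offsets, E0 in recs:
            n = E0.shape[1]
            k = max(1, int(round(frame_fraction * n)))
            ind = np.zeros(n, dtype=np.float32)
            if k < n:
                ind[rng.choice(n, size=k, replace=False)] = 1.0
            else:
                ind[:] = 1.0
            sums = E0 @ ind  # per-lag error sum over the subsampled frames
            below = np.concatenate(([0.0], np.cumsum(ind)))  # frames drawn before t
            counts = k - below[offsets].astype(int)
            valid = counts > 0
            if valid.sum() < 2:
                return None  # degenerate subsample; caller counts a failure
            errs = np.full(len(offsets), np.inf)
            errs[valid] = sums[valid] / counts[valid]
            if not np.max(errs[valid]) > 0:
                return None
            i = int(np.argmin(errs))
            mx = float(np.max(errs[valid]))
            rows.append(
                {
                    "participant_id": pid,
                    "speed": speed,
                    "density": density,
                    "lag_of_least_error_s": float(lag_s[i]),
                    "normalized_least_error": float(errs[i] / mx),
                }
            )
    return pd.DataFrame(rows)


def bootstrap_contrasts(
    recordings,
    cfg: BootstrapConfig | None = None,
    max_lag_s: float = 3.0,
    lag_step_s: float = 0.05,
    dvs=SUMMARY_DVS,
) -> BootstrapResult:
    """The manual subsampling bootstrap of the CCG analysis.

    Border-excluded participants are expected to be removed already.
    Repetitions whose mixed model fails outright are skipped and counted; if
    more than ``cfg.max_failure_fraction`` fail the run errors out.
    """
    cfg = cfg or BootstrapConfig()
    by_part: dict[str, list] = {}
    for rec in recordings:
        lag_s, E = lag_error_matrix(rec, max_lag_s, lag_step_s)
        offsets = np.round(lag_s * rec.rate_hz).astype(int)
        E0 = np.nan_to_num(E, nan=0.0)
        by_part.setdefault(rec.participant_id, []).append(
            (rec.speed, rec.density, lag_s, offsets, E0)
        )
    pids = sorted(by_part)
    if len(pids) < 2:
        raise ValueError("need at least 2 participants")
    m = max(2, int(round(cfg.participant_fraction * len(pids))))
    m = min(m, len(pids))

    rng = np.random.default_rng(cfg.seed)
    warm_starts: dict[str, dict] = {}
    dist_rows = []
    structures = []
    failed = 0
    for rep in range(cfg.n_reps):
        chosen = rng.choice(len(pids), size=m, replace=False) if m < len(pids) else np.arange(len(pids))
        sampled = [(pids[i], by_part[pids[i]]) for i in sorted(chosen)]
        df = _subsample_summary_rows(sampled, cfg.frame_fraction, rng)
        if df is None:
            failed += 1
            continue
        X = _design(df)
        groups = df["participant_id"].to_numpy()
        ok_rep = True
        rep_rows = []
        for dv in dvs:
            try:
                fe, _, structure, _ = _fit_ladder(
                    df[dv].to_numpy(float), X, groups, warm=warm_starts.setdefault(dv, {})
                )
            except RuntimeError:
                ok_rep = False
                break
            structures.append(structure)
            for i, term in enumerate(TERMS, start=1):
                rep_rows.append(
                    {"rep_index": rep, "dv": dv, "term": term, "estimate": float(fe[i])}
                )
        if ok_rep:
            dist_rows.extend(rep_rows)
        else:
            failed += 1
    if failed > cfg.max_failure_fraction * cfg.n_reps:
        raise RuntimeError(
            f"{failed}/{cfg.n_reps} bootstrap repetitions failed "
            f"(> {cfg.max_failure_fraction:.0%} allowed)"
        )
    dist = pd.DataFrame(dist_rows)
    contrasts: dict[str, dict[str, ContrastEstimate]] = {}
    for dv in dvs:
        contrasts[dv] = {}
        for term in TERMS:
            vals = dist.loc[(dist.dv == dv) & (dist.term == term), "estimate"].to_numpy()
            lo, hi = np.percentile(vals, [2.5, 97.5])
            contrasts[dv][term] = ContrastEstimate(
                term=term,
                estimate=float(np.mean(vals)),
                ci_low=float(lo),
                ci_high=float(hi),
                significant=bool(lo > 0 or hi < 0),
            )
    return BootstrapResult(
        contrasts=contrasts,
        distributions=dist,
        n_reps_used=cfg.n_reps - failed,
        n_reps_failed=failed,
        re_structures=pd.Series(structures, dtype=object).value_counts(),
    )


def frame_level_lmm(recordings, summaries) -> dict[str, object]:
    """Frame-level variability model: per-frame absolute angular error at
    each participant x condition's lag of least error, same fixed/random
    structure as the summary model; Wald 95% CIs.

    Returns a dict with the intercept, the two contrasts, the random-effects
    structure used, and the assembled frame table's size.
    """
    sdf = _as_summary_frame(summaries)
    lag_map = {
        (r.participant_id, r.speed, r.density): r.lag_of_least_error_s
        for r in sdf.itertuples()
    }
    frames = []
    for rec in recordings:
        key = (rec.participant_id, rec.speed, rec.density)
        if key not in lag_map:
            raise ValueError(f"no CCG summary for recording {key}")
        o = int(round(lag_map[key] * rec.rate_hz))
        err = abs_diff_deg(
            rec.presented_heading_deg[: rec.n_frames - o] if o else rec.presented_heading_deg,
            rec.response_heading_deg[o:],
        )
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": rec.participant_id,
                    "speed": rec.speed,
                    "density": rec.density,
                    "abs_error_deg": err,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    X = _design(df)
    fe, bse, structure, converged = _fit_ladder(
        df["abs_error_deg"].to_numpy(float), X, df["participant_id"].to_numpy()
    )
    z = 1.959963984540054
    contrasts = {
        term: ContrastEstimate(
            term=term,
            estimate=float(fe[i]),
            ci_low=float(fe[i] - z * bse[i]),
            ci_high=float(fe[i] + z * bse[i]),
            significant=bool(fe[i] - z * bse[i] > 0 or fe[i] + z * bse[i] < 0),
        )
        for i, term in enumerate(TERMS, start=1)
    }
    return {
        "dv": "abs_error_at_lag_of_least_error_deg",
        "intercept": float(fe[0]),
        "contrasts": contrasts,
        "re_structure": structure,
        "converged": converged,
        "n_obs": len(df),
    }
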