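"""Single-trial start/stop extraction under the low-high-low model.

Within a trial the press train is segmented into a low-rate, a high-rate
and a low-rate period by choosing the ordered pair (t1, t2) that
maximizes

    I(t1, t2) = t1'*(r - r1) + (t2 - t1)*(r2 - r) + (T' - t2')*(r - r3)

where primes are times measured from the window start, T' is the window
length, r the overall press rate in the window and r1/r2/r3 the rates in
the three segments.  Candidate transition points are the in-window press
times plus the window edges; the search is exhaustive, with ties broken
by earliest start, then earliest stop.  Presses at t1 or t2 count toward
the middle (high) segment.

Trials lacking temporal control are flagged by conservative criteria on
the segment rates and on whether (start, stop) straddle the criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import analysis_window
from .records import TrialRecord


class SingleTrialError(ValueError):
    pass


@dataclass
class StartStopEstimate:
    start: float
    stop: float
    r1: float
    r2: float
    r3: float
    overall_rate: float
    index_value: float
    valid: bool = True
    exclusion_reason: str | None = None
    relax_start: bool = False


@dataclass
class ExclusionCriteria:
    """Temporal-control exclusion thresholds.

    A trial is kept iff the high-state rate exceeds the overall rate, the
    flanking rates are at most ``f`` times the high rate, and the
    estimated start/stop straddle the criterion.  ``f`` defaults to 0.5.
    """

    f: float = 0.5

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise SingleTrialError("f must be positive")


def extract_start_stop(
    trial: TrialRecord,
    window: tuple[float, float] | None = None,
    relax_start: bool = False,
) -> StartStopEstimate:
    """Exhaustively maximize the segmentation index over candidate pairs."""
    if window is None:
        window = analysis_window(trial.trial_type)
    ws, we = window
    if ws < 0 or we > trial.trial_duration:
        # FI trials are shorter than probe trials; a window that extends
        # past the trial would silently bias the third segment's rate.
        raise SingleTrialError(
            f"window ({ws}, {we}) outside trial of duration {trial.trial_duration}"
        )
    span = we - ws
    presses = trial.press_times
    presses = presses[(presses >= ws) & (presses <= we)]
    n = presses.size
    if n == 0:
        nan = float("nan")
        return StartStopEstimate(
            nan, nan, 0.0, 0.0, 0.0, 0.0, 0.0,
            valid=False, exclusion_reason="no presses", relax_start=relax_start,
        )

    r = n / span
    cand = np.unique(np.concatenate([[ws], presses, [we]]))
    # counts strictly before / at-or-before each candidate
    n_lt = np.searchsorted(presses, cand, side="left").astype(float)
    n_le = np.searchsorted(presses, cand, side="right").astype(float)

    # The index decomposes into a t1 term and a t2 term:
    #   I = [r*t1' - c1] + [c1 + c2 - r*(t2'-t1')] + [r*(T'-t2') - c3]
    #     = 2*(r*(t1-ws) - n_lt(t1)) - 2*(r*(t2-ws) - n_le(t2))
    f1 = r * (cand - ws) - n_lt  # start term (maximize)
    f2 = r * (cand - ws) - n_le  # stop term (minimize)
    index = 2.0 * (f1[:, None] - f2[None, :])
    index[np.tril_indices_from(index)] = -np.inf  # require t1 < t2

    best = np.max(index)
    i, j = np.argwhere(index == best)[0]  # row-major: earliest t1, then t2
    t1, t2 = float(cand[i]), float(cand[j])

    c1 = float(n_lt[i])
    c2 = float(n_le[j] - n_lt[i])
    c3 = float(n - n_le[j])
    r1 = c1 / (t1 - ws) if t1 > ws else 0.0
    r2 = c2 / (t2 - t1)
    r3 = c3 / (we - t2) if t2 < we else 0.0
    return StartStopEstimate(
        start=t1,
        stop=t2,
        r1=r1,
        r2=r2,
        r3=r3,
        overall_rate=r,
        index_value=float(best),
        relax_start=relax_start,
    )


def exclude_no_temporal_control(
    est: StartStopEstimate,
    criteria: ExclusionCriteria | None = None,
    criterion_T: float = 40.0,
) -> StartStopEstimate:
    """Annotate an estimate with the temporal-control validity flag.

    With ``est.relax_start`` set (the FEAR PIN case, where the distracter
    disrupts early responding) the start-related clauses — the pre-start
    rate bound and ``start < criterion`` — are skipped.
    """
    criteria = criteria or ExclusionCriteria()
    if est.exclusion_reason == "no presses":
        return est
    reason = None
    if not est.r2 > est.overall_rate:
        reason = "no high state"
    elif not est.relax_start and est.r1 > criteria.f * est.r2:
        reason = "high pre-start rate"
    elif est.r3 > criteria.f * est.r2:
        reason = "high post-stop rate"
    elif not est.relax_start and not est.start < criterion_T:
        reason = "start at or after criterion"
    elif not est.stop > criterion_T:
        reason = "stop at or before criterion"
    est.valid = reason is None
    est.exclusion_reason = reason
    return est


def estimates_frame(
    trials: list[TrialRecord],
    criteria: ExclusionCriteria | None = None,
    criterion_T: float = 40.0,
    relax_start_fear_pin: bool = True,
) -> pd.DataFrame:
    """Extract, screen and tabulate start/stop estimates for probe trials.

    FI trials are skipped (no low-high-low structure is expected once the
    reward terminates the trial).  PIN trials in the FEAR group are
    analyzed in the post-noise window with start criteria relaxed.
    """
    rows = []
    for tr in trials:
        if tr.trial_type == "FI":
            continue
        relax = relax_start_fear_pin and tr.group == "FEAR" and tr.trial_type == "PIN"
        est = extract_start_stop(tr, relax_start=relax)
        est = exclude_no_temporal_control(est, criteria, criterion_T)
        rows.append(
            {
                "subject": tr.subject_id,
                "group": tr.group,
                "drug": tr.drug,
                "trial_type": tr.trial_type,
                "trial_index": tr.trial_index,
                "start": est.start,
                "stop": est.stop,
                "r1": est.r1,
                "r2": est.r2,
                "r3": est.r3,
                "index_value": est.index_value,
                "valid": est.valid,
                "exclusion_reason": est.exclusion_reason or "",
            }
        )
    return pd.DataFrame(rows)


def summarize_start_stop(frame: pd.DataFrame) -> pd.DataFrame:
    """Per subject x drug x trial_type: mean start/stop and their CVs.

    CV = sample SD / mean over valid trials; cells with fewer than two
    valid trials report CVs as missing.
    """
    valid = frame[frame["valid"]]
    out = []
    for (subj, drug, ttype), cell in valid.groupby(
        ["subject", "drug", "trial_type"], sort=True
    ):
        n = len(cell)
        row = {
            "subject": subj,
            "drug": drug,
            "trial_type": ttype,
            "n_valid": n,
            "mean_start": cell["start"].mean(),
            "mean_stop": cell["stop"].mean(),
        }
        if n >= 2:
            row["cv_start"] = cell["start"].std(ddof=1) / cell["start"].mean()
            row["cv_stop"] = cell["stop"].std(ddof=1) / cell["stop"].mean()
        else:
            row["cv_start"] = np.nan
            row["cv_stop"] = np.nan
        out.append(row)
    return pd.DataFrame(out)
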