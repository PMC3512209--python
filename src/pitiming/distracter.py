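"""Peak-time delays between distracter (PIN) and plain (PI) probe trials,
classified against the analytic run/stop/reset benchmarks.

If the internal clock ignores a noise distracter of duration d1 presented
d2 seconds into the trial, the fitted peak time is unchanged (run,
delay 0).  If it pauses during the noise the peak is delayed by d1
(stop).  If it restarts from zero at noise offset the delay is d1 + d2
(reset).  Delays significantly beyond d1 + d2 indicate an over-reset:
timing resources remain diverted after the distracter ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .curves import GaussLinFit


class DelayError(ValueError):
    pass


def benchmark_delays(d1: float, d2: float) -> dict[str, float]:
    """Analytic delay benchmarks: run = 0, stop = d1, reset = d1 + d2."""
    if d1 < 0 or d2 < 0:
        raise DelayError("d1 and d2 must be non-negative")
    return {"run": 0.0, "stop": d1, "reset": d1 + d2}


@dataclass
class DelayResult:
    subject_id: str
    drug: str
    delay: float
    benchmarks: dict[str, float]


@dataclass
class DelayClassification:
    label: str
    n: int
    mean_delay: float
    tests: dict[str, dict]  # benchmark -> {t, df, p}


def compute_delay(
    fits_pin: dict[str, GaussLinFit],
    fits_pi: dict[str, GaussLinFit],
    d1: float = 5.0,
    d2: float = 5.0,
    drug: str = "SAL",
) -> tuple[list[DelayResult], list[str]]:
    """Per-subject delay = t0(PIN) - t0(PI), seconds.

    Subjects missing from either mapping or with a non-converged fit are
    dropped; the second return value lists them with reasons.
    """
    bench = benchmark_delays(d1, d2)
    results, dropped = [], []
    for subj in sorted(set(fits_pin) | set(fits_pi)):
        if subj not in fits_pin or subj not in fits_pi:
            dropped.append(f"{subj}: unmatched across trial types")
            continue
        fpin, fpi = fits_pin[subj], fits_pi[subj]
        if not (fpin.converged and fpi.converged):
            dropped.append(f"{subj}: fit did not converge")
            continue
        if not (fpin.peak_resolved and fpi.peak_resolved):
            dropped.append(f"{subj}: peak not resolvable within the window")
            continue
        results.append(
            DelayResult(subj, drug, float(fpin.t0 - fpi.t0), dict(bench))
        )
    if not results:
        raise DelayError("no matched subjects with converged fits")
    return results, dropped


def classify_delay(
    delays: np.ndarray | list[float],
    benchmarks: dict[str, float],
    alpha: float = 0.05,
    tolerance: float = 2.0,
) -> DelayClassification:
    """Label a sample of per-subject delays as run/stop/reset/over_reset.

    One-sample t-tests compare the sample against each benchmark.  The
    sample is an over_reset if significantly greater (one-sided) than the
    reset benchmark; a run if not different from 0; otherwise the nearest
    of the remaining benchmarks provided the two-sided test against it is
    not rejected; else indeterminate.  With a single subject, the nearest
    benchmark within ``tolerance`` seconds is used (over_reset if beyond
    reset, else indeterminate).
    """
    x = np.asarray(delays, dtype=float)
    n = x.size
    if n == 0:
        raise DelayError("empty delay sample")
    mean = float(x.mean())
    if n < 2:
        if tolerance is None:
            raise DelayError("single subject requires a tolerance")
        nearest = min(benchmarks, key=lambda k: abs(mean - benchmarks[k]))
        if abs(mean - benchmarks[nearest]) <= tolerance:
            label = nearest
        elif mean > benchmarks["reset"]:
            label = "over_reset"
        else:
            label = "indeterminate"
        return DelayClassification(label, n, mean, {})

    tests = {}
    for name, mu in benchmarks.items():
        t, p = sps.ttest_1samp(x, mu)
        tests[name] = {"t": float(t), "df": n - 1, "p": float(p), "mu": mu}
    # one-sided p for exceeding the full reset
    t_reset = tests["reset"]["t"]
    p_greater = float(sps.ttest_1samp(x, benchmarks["reset"], alternative="greater").pvalue)
    tests["reset"]["p_greater"] = p_greater

    if p_greater < alpha:
        label = "over_reset"
    elif tests["run"]["p"] >= alpha:
        label = "run"
    else:
        nearest = min(benchmarks, key=lambda k: abs(mean - benchmarks[k]))
        if nearest == "run":
            label = "indeterminate"  # nearest 0 but reliably different from it
        elif tests[nearest]["p"] >= alpha:
            label = nearest
        else:
            label = "indeterminate"
    return DelayClassification(label, n, mean, tests)
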