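"""Trial-averaged response-rate curves and Gaussian + linear peak fits.

Presses from PI/PIN probe trials are binned (4-s bins by default) over a
100-s analysis window — (0, 100) s for PI trials, (20, 120) s for trials
with the noise distracter — and averaged over trials to give a mean
response-rate function per subject.  The function is then fit by

    R(t) = a * exp(-(t - t0)^2 / (2 b^2)) + c * t + d0

by nonlinear least squares; ``t0`` estimates the peak (subjective
criterion) time, ``b`` the timing precision (Gaussian SD), and the model
value at the maximum the peak rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .records import TrialRecord

DEFAULT_BIN_WIDTH = 4.0
WINDOW_LENGTH = 100.0
PIN_WINDOW_OFFSET = 20.0


class CurveError(ValueError):
    pass


def analysis_window(trial_type: str) -> tuple[float, float]:
    """Analysis window for curve fitting: (0, 100) s for PI trials,
    (20, 120) s for PIN trials.  FI trials are not curve-fit."""
    if trial_type == "PI":
        return (0.0, WINDOW_LENGTH)
    if trial_type == "PIN":
        return (PIN_WINDOW_OFFSET, PIN_WINDOW_OFFSET + WINDOW_LENGTH)
    raise CurveError(f"no analysis window for trial_type {trial_type!r}")


@dataclass
class BinnedCurve:
    """Mean response rate (presses/s) in fixed-width bins over a window."""

    window_start: float
    window_end: float
    bin_width: float
    bin_centers: np.ndarray
    mean_rate: np.ndarray
    n_trials: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.mean_rate = np.asarray(self.mean_rate, dtype=float)
        if np.any(self.mean_rate < 0):
            raise CurveError("mean_rate must be non-negative")


def bin_presses(
    trials: list[TrialRecord],
    window: tuple[float, float],
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> BinnedCurve:
    """Average press counts over trials into a rate curve.

    Bin ``b``'s value is (total presses in ``b`` across trials) /
    (n_trials * bin_width).  Bins are half-open [lo, hi); the last bin is
    closed so a press exactly at the window end is counted.
    """
    if not trials:
        raise CurveError("no trials")
    lo, hi = window
    if hi <= lo:
        raise CurveError("window_end must exceed window_start")
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for trial in trials:
        t = trial.press_times
        t = t[(t >= lo) & (t <= hi)]
        idx = np.minimum(((t - lo) // bin_width).astype(int), n_bins - 1)
        np.add.at(counts, idx, 1.0)
    rate = counts / (len(trials) * bin_width)
    centers = lo + bin_width * (np.arange(n_bins) + 0.5)
    return BinnedCurve(lo, hi, bin_width, centers, rate, len(trials))


def normalize_max_percent(curve: BinnedCurve) -> BinnedCurve:
    """Rescale so the maximum bin reads 100 (max-percent normalization)."""
    peak = float(np.max(curve.mean_rate))
    if peak <= 0:
        raise CurveError("cannot normalize an all-zero curve")
    return BinnedCurve(
        curve.window_start,
        curve.window_end,
        curve.bin_width,
        curve.bin_centers.copy(),
        curve.mean_rate * (100.0 / peak),
        curve.n_trials,
        normalized=True,
    )


@dataclass
class GaussLinFit:
    """Gaussian + linear fit of a response-rate curve.

    ``t0`` is the peak time (timing accuracy), ``b`` the Gaussian SD
    (timing precision; ``fwhm`` = 2.3548 b), ``peak_rate`` the model value
    at ``t0``.
    """

    a: float
    t0: float
    b: float
    c: float
    d0: float
    sse: float
    r2: float
    converged: bool
    peak_rate: float
    reason: str = ""
    peak_resolved: bool = True

    @property
    def fwhm(self) -> float:
        return 2.0 * np.sqrt(2.0 * np.log(2.0)) * self.b


def gauss_linear(t, a, t0, b, c, d0):
    """Model: a Gaussian bump of SD b centered at t0 on a linear ramp."""
    return a * np.exp(-((t - t0) ** 2) / (2.0 * b**2)) + c * t + d0


def _failed_fit(reason: str) -> GaussLinFit:
    nan = float("nan")
    return GaussLinFit(
        nan, nan, nan, nan, nan, nan, nan, False, nan, reason, peak_resolved=False
    )


def fit_gaussian_linear(
    curve: BinnedCurve, init: tuple | None = None
) -> GaussLinFit:
    """Least-squares fit of the Gaussian + linear model to a binned curve.

    Initialization: ``t0`` at the argmax bin, ``a`` at the rate range,
    ``b`` at one sixth of the window, ``c = 0``, ``d0`` at the minimum
    rate; on failure a small multi-start grid over t0 and b is tried.
    Never raises on a fit failure — ``converged`` is False with a reason.
    """
    t = curve.bin_centers
    y = curve.mean_rate
    if t.size < 6:
        raise CurveError("need at least 6 bins to fit 5 parameters")
    span = curve.window_end - curve.window_start
    if np.ptp(y) == 0:
        return _failed_fit("degenerate curve: all bins equal")

    if init is not None:
        starts = [tuple(init)]
        fallback: list[tuple] = []
    else:
        t0_hat = float(t[int(np.argmax(y))])
        a_hat = float(np.max(y) - np.min(y))
        d_hat = float(np.min(y))
        starts = [(a_hat, t0_hat, span / 6.0, 0.0, d_hat)]
        # fallback grid (3 peak locations x 3 widths), tried only if the
        # data-driven start fails to converge
        fallback = [
            (a_hat, curve.window_start + frac * span, span / bfac, 0.0, d_hat)
            for frac in (0.3, 0.5, 0.7)
            for bfac in (12.0, 6.0, 3.0)
        ]

    lo_b = curve.window_start - curve.bin_width
    hi_b = curve.window_end + curve.bin_width
    # a and d0 are non-negative: the response rate is a non-negative
    # quantity and the Gaussian component models a peak, not a trough.
    bounds = (
        [0.0, lo_b, 1e-6, -np.inf, 0.0],
        [np.inf, hi_b, np.inf, np.inf, np.inf],
    )

    def try_start(p0: tuple) -> GaussLinFit | None:
        p0 = (p0[0], np.clip(p0[1], lo_b, hi_b), max(p0[2], 1e-3), p0[3], p0[4])
        try:
            popt, _ = curve_fit(
                gauss_linear, t, y, p0=p0, bounds=bounds, maxfev=20000,
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except (RuntimeError, ValueError):
            return None
        resid = y - gauss_linear(t, *popt)
        sse = float(resid @ resid)
        a, t0, b, c, d0 = (float(v) for v in popt)
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else float("nan")
        return GaussLinFit(
            a=a,
            t0=t0,
            b=abs(b),
            c=c,
            d0=d0,
            sse=sse,
            r2=r2,
            converged=True,
            peak_rate=float(gauss_linear(t0, a, t0, abs(b), c, d0)),
        )

    best: GaussLinFit | None = None
    for p0 in starts:
        fit = try_start(p0)
        if fit is not None and (best is None or fit.sse < best.sse):
            best = fit
    if best is None:
        for p0 in fallback:
            fit = try_start(p0)
            if fit is not None and (best is None or fit.sse < best.sse):
                best = fit
    if best is None:
        return _failed_fit("all starts failed to converge")
    # A peak-time estimate is only meaningful when the Gaussian component
    # is resolvable within the analysis window: its +-1 SD core must lie
    # inside the window and its width must exceed half a bin.  Fits
    # violating this describe a shoulder or a sub-bin spike, not a peak.
    best.peak_resolved = (
        curve.window_start + best.b <= best.t0 <= curve.window_end - best.b
        and best.b >= curve.bin_width / 2.0
    )
    return best


def fit_trials(
    trials: list[TrialRecord],
    trial_type: str,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> GaussLinFit:
    """Convenience: window -> bin -> fit for one subject's probe trials."""
    subset = [tr for tr in trials if tr.trial_type == trial_type]
    window = analysis_window(trial_type)
    return fit_gaussian_linear(bin_presses(subset, window, bin_width))
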