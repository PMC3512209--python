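"""Freezing scores around the distracter and inter-observer agreement.

Freezing (immobility, the index of conditioned fear) is scored as binary
observations in fixed-width bins (2.5 s).  Scores are summarized as the
percentage of frozen bins in labeled windows before, during, and after
the noise; two observers' series are compared by percent agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import FreezingSeries


class FreezingError(ValueError):
    pass


@dataclass
class FreezingSummary:
    windows: list[tuple[str, float, float]]  # (label, lo, hi) seconds
    percent_freezing: dict[str, float]
    n_series: int
    group: str


def default_windows(
    series: FreezingSeries, post_window: float = 60.0, pre_window: float = 60.0
) -> list[tuple[str, float, float]]:
    """Windows: ``pre_window`` s before onset, the noise itself, then
    consecutive ``post_window``-s windows to the end of the series."""
    onset, offset = series.event_markers
    windows = [
        ("before", max(0.0, onset - pre_window), onset),
        ("during", onset, offset),
    ]
    k, t = 1, offset
    while t < series.duration - 1e-9:
        hi = min(t + post_window, series.duration)
        windows.append((f"after-{k}", t, hi))
        t, k = hi, k + 1
    return windows


def percent_freezing(
    series: FreezingSeries,
    windows: list[tuple[str, float, float]] | None = None,
) -> FreezingSummary:
    """Percent frozen bins per window; bins are assigned to a window by
    bin-center membership in [lo, hi)."""
    if windows is None:
        windows = default_windows(series)
    centers = series.bin_centers()
    percents = {}
    for label, lo, hi in windows:
        mask = (centers >= lo) & (centers < hi)
        if not mask.any():
            raise FreezingError(f"window {label!r} contains no bins")
        percents[label] = 100.0 * float(series.bins[mask].mean())
    return FreezingSummary(windows, percents, 1, series.group)


def mean_percent_freezing(
    series_list: list[FreezingSeries],
    windows: list[tuple[str, float, float]] | None = None,
) -> pd.DataFrame:
    """Per-window mean (and SEM over series) percent freezing by group."""
    rows = []
    for s in series_list:
        summary = percent_freezing(s, windows)
        for label, pct in summary.percent_freezing.items():
            rows.append({"group": s.group, "window": label, "percent": pct})
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["group", "window"], sort=False)["percent"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count")
        .reset_index()
    )
    return out


def percent_agreement(series_a: FreezingSeries, series_b: FreezingSeries) -> float:
    """Percent of bins on which two observers agree."""
    if series_a.n_bins != series_b.n_bins:
        raise FreezingError("series differ in length")
    if series_a.bin_width != series_b.bin_width:
        raise FreezingError("series differ in bin width")
    return 100.0 * float(np.mean(series_a.bins == series_b.bins))
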