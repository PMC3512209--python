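"""Core data records: trials of lever presses and binned freezing series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRIAL_TYPES = ("FI", "PI", "PIN")
GROUPS = ("FEAR", "CTRL")
DRUGS = ("SAL", "NOM")


class RecordError(ValueError):
    """A record violates one of its structural invariants."""


@dataclass
class TrialRecord:
    """One trial's press train plus design labels and, for synthetic
    trials, the latent ground truth (never read by analysis stages).

    Times are seconds from the onset of the to-be-timed signal.
    """

    subject_id: str
    session_id: str
    trial_index: int
    trial_type: str
    group: str
    drug: str
    trial_duration: float
    press_times: np.ndarray
    noise_onset: float | None = None
    noise_duration: float | None = None
    latent_start: float | None = None
    latent_stop: float | None = None
    reward_time: float | None = None
    stop_truncated: bool = False

    def __post_init__(self) -> None:
        self.press_times = np.asarray(self.press_times, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise RecordError(f"unknown trial_type {self.trial_type!r}")
        if self.group not in GROUPS:
            raise RecordError(f"unknown group {self.group!r}")
        if self.drug not in DRUGS:
            raise RecordError(f"unknown drug {self.drug!r}")
        if self.trial_duration <= 0:
            raise RecordError("trial_duration must be positive")
        t = self.press_times
        if t.size:
            if np.any(np.diff(t) < 0):
                raise RecordError("press_times must be nondecreasing")
            if t[0] < 0 or t[-1] > self.trial_duration:
                raise RecordError(
                    "press_times must lie within [0, trial_duration]"
                )
        has_noise = self.noise_onset is not None or self.noise_duration is not None
        if (self.trial_type == "PIN") != has_noise:
            raise RecordError("noise fields present iff trial_type == 'PIN'")
        if self.latent_start is not None and self.latent_stop is not None:
            if not self.latent_start < self.latent_stop:
                raise RecordError("latent_start must precede latent_stop")

    @property
    def n_presses(self) -> int:
        return int(self.press_times.size)


@dataclass
class FreezingSeries:
    """Binary freezing observations in fixed-width bins.

    ``event_markers`` holds the noise onset/offset times (seconds from the
    start of the series).
    """

    bin_width: float
    bins: np.ndarray
    event_markers: tuple[float, float]
    series_id: str = ""
    group: str = "CTRL"

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=bool)
        if self.bin_width <= 0:
            raise RecordError("bin_width must be positive")
        if self.bins.size == 0:
            raise RecordError("bins must be nonempty")
        if self.group not in GROUPS:
            raise RecordError(f"unknown group {self.group!r}")

    @property
    def n_bins(self) -> int:
        return int(self.bins.size)

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width
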