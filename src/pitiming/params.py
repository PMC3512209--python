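"""Parameter containers for the synthetic behavioral generator.

The generator emulates steady-state performance on a 40-s peak-interval
(PI) task: sessions mix reinforced fixed-interval (FI) trials,
non-reinforced PI probe trials lasting three times the criterion, and PI
trials with a brief task-irrelevant noise distracter (PIN).  Single-trial
responding follows a low-high-low profile with normally distributed
start/stop times whose spread scales with the criterion (scalar timing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

DISTRACTER_MODES = ("run", "stop", "reset", "over_reset")


class ParameterError(ValueError):
    """A generator parameter violates its documented constraint."""


@dataclass
class GeneratorParams:
    """Parameters of the synthetic session generator.

    Attributes
    ----------
    criterion_T:
        Reinforced fixed interval, seconds.
    pi_trial_factor:
        PI/PIN trial duration as a multiple of ``criterion_T``.
    n_fi, n_pi, n_pin:
        Trial counts per session (defaults mirror a 20/14/6 session).
    noise_onset_d2, noise_duration_d1:
        Distracter placement in PIN trials: onset ``d2`` seconds into the
        trial, lasting ``d1`` seconds.
    start_frac, stop_frac:
        Mean latent start/stop of the high-rate state as fractions of the
        criterion.
    cv_start, cv_stop:
        Coefficients of variation of the latent start/stop times.
    rate_low, rate_high:
        Poisson press rates (presses/s) in the low and high states.
    distracter_mode:
        Clock behavior during the distracter: ``run`` (ignore), ``stop``
        (pause for d1), ``reset`` (restart: d1 + d2), or ``over_reset``
        (reset plus an exponential extra delay).
    salience_lambda:
        Mean (seconds) of the exponential extra delay under ``over_reset``;
        larger values model more salient distracters holding attentional
        resources after the noise ends.
    p_no_control:
        Probability that a trial lacks temporal control (uniform pressing
        at ``rate_low`` with no latent start/stop).
    iti_mean, iti_jitter:
        Inter-trial interval, seconds (uniform on mean ± jitter).
    seed:
        Generator seed; fixing it fixes every press time.
    """

    criterion_T: float = 40.0
    pi_trial_factor: float = 3.0
    n_fi: int = 20
    n_pi: int = 14
    n_pin: int = 6
    noise_onset_d2: float = 5.0
    noise_duration_d1: float = 5.0
    start_frac: float = 0.7
    stop_frac: float = 1.4
    cv_start: float = 0.2
    cv_stop: float = 0.2
    rate_low: float = 0.1
    rate_high: float = 1.5
    distracter_mode: str = "run"
    salience_lambda: float = 0.0
    p_no_control: float = 0.2
    iti_mean: float = 120.0
    iti_jitter: float = 30.0
    fi_grace: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.start_frac < 1:
            raise ParameterError("start_frac must lie in (0, 1)")
        if self.stop_frac <= 1:
            raise ParameterError("stop_frac must exceed 1")
        if self.cv_start <= 0 or self.cv_stop <= 0:
            raise ParameterError("cv_start and cv_stop must be positive")
        if self.rate_low < 0 or self.rate_high <= self.rate_low:
            raise ParameterError("require rate_high > rate_low >= 0")
        for name in ("n_fi", "n_pi", "n_pin"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.criterion_T <= 0:
            raise ParameterError("criterion_T must be positive")
        if self.pi_trial_factor <= 1:
            raise ParameterError("pi_trial_factor must exceed 1")
        if self.noise_onset_d2 < 0 or self.noise_duration_d1 < 0:
            raise ParameterError(
                "noise_onset_d2 and noise_duration_d1 must be non-negative"
            )
        if (
            self.noise_onset_d2 + self.noise_duration_d1
            >= self.pi_trial_factor * self.criterion_T
        ):
            raise ParameterError(
                "noise_onset_d2 + noise_duration_d1 must be shorter than the trial"
            )
        if self.distracter_mode not in DISTRACTER_MODES:
            raise ParameterError(
                f"distracter_mode must be one of {DISTRACTER_MODES}"
            )
        if self.salience_lambda < 0:
            raise ParameterError("salience_lambda must be non-negative")
        if not 0 <= self.p_no_control <= 1:
            raise ParameterError("p_no_control must lie in [0, 1]")
        if self.iti_mean < 0 or self.iti_jitter < 0 or self.iti_jitter > self.iti_mean:
            raise ParameterError("require 0 <= iti_jitter <= iti_mean")
        if self.fi_grace <= 0:
            raise ParameterError("fi_grace must be positive")

    @property
    def pi_duration(self) -> float:
        return self.pi_trial_factor * self.criterion_T

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorParams":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(
                f"unknown generator parameter(s): {sorted(unknown)}"
            )
        return cls(**data)


@dataclass
class FreezingParams:
    """Parameters of the synthetic freezing-series generator.

    Freezing is scored in fixed-width bins.  Both groups freeze at a low
    baseline probability before the noise; FEAR animals jump to a high
    probability during the noise that decays exponentially back to
    baseline afterwards, emulating a long-lasting conditioned response.
    """

    bin_width: float = 2.5
    pre_duration: float = 60.0
    noise_duration: float = 5.0
    post_duration: float = 240.0
    p_base: float = 0.05
    p_high: float = 0.875
    tau_decay: float = 90.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ParameterError("bin_width must be positive")
        for name in ("pre_duration", "noise_duration", "post_duration"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.pre_duration + self.noise_duration + self.post_duration <= 0:
            raise ParameterError("series must contain at least one bin")
        for name in ("p_base", "p_high"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.tau_decay < 0:
            raise ParameterError("tau_decay must be non-negative")
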