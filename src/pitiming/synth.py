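"""Synthetic peak-interval sessions with known ground truth.

The generative model is the inverse of the analysis model: on each trial
with temporal control, responding is an inhomogeneous Poisson train that
is slow (``rate_low``) before a latent start time, fast (``rate_high``)
between start and stop, and slow again afterwards.  Latent start/stop
times are Normal with means at fixed fractions of the criterion and
standard deviations proportional to those means (scalar variability).  A
fraction ``p_no_control`` of trials lacks temporal control entirely and
presses uniformly at the low rate.

In PIN (distracter) trials the latent clock may ignore the noise
(``run``), pause for its duration (``stop``), restart from zero at its
offset (``reset``), or restart and stay diverted for an additional
exponential lag (``over_reset``), rigidly translating both latent times
by 0, d1, d1+d2, or d1+d2+Exp(salience_lambda) seconds respectively.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .params import DISTRACTER_MODES, FreezingParams, GeneratorParams, ParameterError
from .records import FreezingSeries, TrialRecord


def apply_distracter_mode(
    latent_start: float,
    latent_stop: float,
    mode: str,
    d1: float,
    d2: float,
    salience_lambda: float,
    rng: np.random.Generator,
    trial_duration: float | None = None,
) -> tuple[float, float, bool]:
    """Shift latent start/stop per the clock's response to the distracter.

    Returns ``(shifted_start, shifted_stop, truncated)`` where
    ``truncated`` flags a shifted stop clipped at ``trial_duration``.
    ``d1`` is the noise duration and ``d2`` the pre-distracter interval.
    """
    if mode not in DISTRACTER_MODES:
        raise ParameterError(f"distracter_mode must be one of {DISTRACTER_MODES}")
    if d1 < 0 or d2 < 0:
        raise ParameterError("d1 and d2 must be non-negative")
    if mode == "run":
        shift = 0.0
    elif mode == "stop":
        shift = d1
    elif mode == "reset":
        shift = d1 + d2
    else:  # over_reset
        extra = rng.exponential(salience_lambda) if salience_lambda > 0 else 0.0
        shift = d1 + d2 + extra
    s, e = latent_start + shift, latent_stop + shift
    truncated = False
    if trial_duration is not None and e > trial_duration:
        e = trial_duration
        truncated = True
    return s, e, truncated


def _poisson_train(
    rng: np.random.Generator, lo: float, hi: float, rate: float
) -> np.ndarray:
    """Homogeneous Poisson event times on [lo, hi)."""
    span = hi - lo
    if span <= 0 or rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * span)
    return np.sort(lo + rng.uniform(0.0, span, size=n))


def _sample_latents(
    params: GeneratorParams, rng: np.random.Generator, trial_duration: float
) -> tuple[float, float]:
    """Draw latent start/stop, resampling until 0 < s < e < duration."""
    T = params.criterion_T
    mu_s, mu_e = params.start_frac * T, params.stop_frac * T
    sd_s, sd_e = params.cv_start * mu_s, params.cv_stop * mu_e
    for _ in range(1000):
        s = rng.normal(mu_s, sd_s)
        e = rng.normal(mu_e, sd_e)
        if 0.0 < s < e < trial_duration:
            return s, e
    raise RuntimeError(
        "failed to sample latent start/stop inside the trial after 1000 tries"
    )


def generate_trial_presses(
    trial_spec: dict,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> TrialRecord:
    """Generate one trial's press train under the low-high-low model.

    ``trial_spec`` names at least ``trial_type``; optional keys
    ``subject_id``, ``session_id``, ``trial_index``, ``group``, ``drug``
    fill the design labels.
    """
    trial_type = trial_spec["trial_type"]
    if trial_type not in ("FI", "PI", "PIN"):
        raise ParameterError(f"unknown trial_type {trial_type!r}")

    T = params.criterion_T
    # FI trials can run to T + grace before timing out without reward.
    nominal = T + params.fi_grace if trial_type == "FI" else params.pi_duration

    no_control = rng.uniform() < params.p_no_control
    latent: tuple[float, float] | None = None
    truncated = False
    if not no_control:
        s, e = _sample_latents(params, rng, nominal)
        if trial_type == "PIN":
            s, e, truncated = apply_distracter_mode(
                s,
                e,
                params.distracter_mode,
                params.noise_duration_d1,
                params.noise_onset_d2,
                params.salience_lambda,
                rng,
                trial_duration=nominal,
            )
        latent = (s, e)

    if latent is None:
        presses = _poisson_train(rng, 0.0, nominal, params.rate_low)
    else:
        s, e = latent
        presses = np.concatenate(
            [
                _poisson_train(rng, 0.0, s, params.rate_low),
                _poisson_train(rng, s, e, params.rate_high),
                _poisson_train(rng, e, nominal, params.rate_low),
            ]
        )
        presses.sort()

    reward_time: float | None = None
    duration = nominal
    if trial_type == "FI":
        at_or_after = presses[presses >= T]
        if at_or_after.size:
            reward_time = float(at_or_after[0])
            duration = reward_time
            presses = presses[presses <= reward_time]

    return TrialRecord(
        subject_id=str(trial_spec.get("subject_id", "S0")),
        session_id=str(trial_spec.get("session_id", "sess0")),
        trial_index=int(trial_spec.get("trial_index", 0)),
        trial_type=trial_type,
        group=str(trial_spec.get("group", "CTRL")),
        drug=str(trial_spec.get("drug", "SAL")),
        trial_duration=float(duration),
        press_times=presses,
        noise_onset=params.noise_onset_d2 if trial_type == "PIN" else None,
        noise_duration=params.noise_duration_d1 if trial_type == "PIN" else None,
        latent_start=None if latent is None else float(latent[0]),
        latent_stop=None if latent is None else float(latent[1]),
        reward_time=reward_time,
        stop_truncated=truncated,
    )


def generate_session(
    params: GeneratorParams,
    subject_id: str = "S0",
    condition: dict | None = None,
    session_id: str = "sess0",
) -> list[TrialRecord]:
    """Generate one session: n_fi FI + n_pi PI + n_pin PIN trials in a
    uniformly random (seeded) order."""
    params.validate()
    condition = condition or {}
    group = condition.get("group", "CTRL")
    drug = condition.get("drug", "SAL")
    rng = np.random.default_rng(params.seed)

    types = ["FI"] * params.n_fi + ["PI"] * params.n_pi + ["PIN"] * params.n_pin
    order = rng.permutation(len(types))
    trials = []
    for idx, j in enumerate(order):
        spec = {
            "trial_type": types[j],
            "subject_id": subject_id,
            "session_id": session_id,
            "trial_index": idx,
            "group": group,
            "drug": drug,
        }
        trials.append(generate_trial_presses(spec, params, rng))
    return trials


def simulate_cohort(
    n_subjects: int,
    params: GeneratorParams,
    seed: int,
    group: str = "FEAR",
    drug: str = "SAL",
) -> list[TrialRecord]:
    """Generate one session per subject with independent child seeds."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_subjects) & 0x7FFFFFFF
    trials: list[TrialRecord] = []
    for i, child in enumerate(child_seeds):
        p = replace(params, seed=int(child))
        trials.extend(
            generate_session(
                p,
                subject_id=f"S{i:02d}",
                condition={"group": group, "drug": drug},
            )
        )
    return trials


def generate_freezing_series(
    group: str,
    params: FreezingParams,
    rng: np.random.Generator,
    series_id: str = "F0",
) -> FreezingSeries:
    """Generate a binary freezing series around one noise presentation.

    Both groups freeze with probability ``p_base`` before the noise.  FEAR
    animals freeze at ``p_high`` during the noise, decaying exponentially
    (time constant ``tau_decay``) back toward ``p_base`` afterwards; CTRL
    animals stay at baseline throughout.
    """
    if group not in ("FEAR", "CTRL"):
        raise ParameterError(f"group must be FEAR or CTRL, got {group!r}")
    bw = params.bin_width
    n_pre = int(round(params.pre_duration / bw))
    n_noise = int(round(params.noise_duration / bw))
    n_post = int(round(params.post_duration / bw))
    n = n_pre + n_noise + n_post
    centers = (np.arange(n) + 0.5) * bw
    onset = n_pre * bw
    offset = onset + n_noise * bw

    p = np.full(n, params.p_base)
    if group == "FEAR":
        during = (centers >= onset) & (centers < offset)
        p[during] = params.p_high
        post = centers >= offset
        if params.tau_decay > 0:
            decay = np.exp(-(centers[post] - offset) / params.tau_decay)
        else:
            decay = 0.0
        p[post] = params.p_base + (params.p_high - params.p_base) * decay
    frozen = rng.uniform(size=n) < p
    return FreezingSeries(
        bin_width=bw,
        bins=frozen,
        event_markers=(onset, offset),
        series_id=series_id,
        group=group,
    )
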