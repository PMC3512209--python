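"""Start/stop extraction: brute-force oracle equivalence, exclusion
criteria, recovery of latent transition times, and CV summaries."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pitiming import (
    ExclusionCriteria,
    GeneratorParams,
    StartStopEstimate,
    TrialRecord,
    exclude_no_temporal_control,
    extract_start_stop,
    summarize_start_stop,
)
from pitiming.single_trial import SingleTrialError, estimates_frame
from pitiming.synth import generate_trial_presses, simulate_cohort


def make_trial(presses, duration=120.0, trial_type="PI", group="CTRL"):
    kw = {}
    if trial_type == "PIN":
        kw = dict(noise_onset=5.0, noise_duration=5.0)
    return TrialRecord(
        subject_id="S0", session_id="x", trial_index=0, trial_type=trial_type,
        group=group, drug="SAL", trial_duration=duration,
        press_times=np.asarray(presses, dtype=float), **kw,
    )


def brute_force_index(presses, window):
    """Naive oracle: evaluate the low-high-low index at every ordered pair
    of candidates (press times + window edges), computing segment rates
    directly from first principles."""
    ws, we = window
    presses = np.asarray(presses, dtype=float)
    presses = presses[(presses >= ws) & (presses <= we)]
    span = we - ws
    r = presses.size / span
    cand = sorted(set([ws, we] + list(presses)))
    best = (-np.inf, None, None)
    for t1 in cand:
        for t2 in cand:
            if not t1 < t2:
                continue
            c1 = np.sum(presses < t1)
            c2 = np.sum((presses >= t1) & (presses <= t2))
            c3 = np.sum(presses > t2)
            r1 = c1 / (t1 - ws) if t1 > ws else 0.0
            r2 = c2 / (t2 - t1)
            r3 = c3 / (we - t2) if t2 < we else 0.0
            idx = (
                (t1 - ws) * (r - r1)
                + (t2 - t1) * (r2 - r)
                + (we - t2) * (r - r3)
            )
            if idx > best[0] + 1e-12:
                best = (idx, t1, t2)
    return best


class TestExtraction:
    def test_isolated_block_forces_exact_start_stop(self):
        presses = np.arange(30.0, 50.1, 2.0)
        est = extract_start_stop(make_trial(presses), (0.0, 100.0))
        assert est.start == 30.0
        assert est.stop == 50.0
        assert est.r1 == 0.0 and est.r3 == 0.0

    def test_uniform_pressing_has_weak_structure(self):
        presses = np.linspace(0.5, 99.5, 100)
        est = extract_start_stop(make_trial(presses), (0.0, 100.0))
        # 100 evenly spaced presses: any segmentation barely beats none
        assert est.index_value < 5.0
        est = exclude_no_temporal_control(est)
        assert not est.valid

    def test_no_presses_invalid(self):
        est = extract_start_stop(make_trial([]), (0.0, 100.0))
        assert not est.valid and est.exclusion_reason == "no presses"

    def test_window_outside_trial_rejected(self):
        with pytest.raises(SingleTrialError):
            extract_start_stop(make_trial([10.0], duration=50.0), (0.0, 100.0))

    def test_matches_brute_force_oracle_on_random_trials(self):
        """Exact agreement of index and (start, stop) with the O(n^2)
        oracle on 100 random synthetic trials."""
        rng = np.random.default_rng(2024)
        params = GeneratorParams()
        for i in range(100):
            tr = generate_trial_presses({"trial_type": "PI"}, params, rng)
            if tr.press_times[(tr.press_times >= 0) & (tr.press_times <= 100)].size == 0:
                continue
            est = extract_start_stop(tr, (0.0, 100.0))
            oracle_idx, t1, t2 = brute_force_index(tr.press_times, (0.0, 100.0))
            assert est.index_value == pytest.approx(oracle_idx, abs=1e-9)
            assert est.start == t1 and est.stop == t2


class TestExclusion:
    def flat_estimate(self, **kw):
        base = dict(start=30.0, stop=60.0, r1=0.0, r2=1.0, r3=0.0,
                    overall_rate=0.5, index_value=10.0)
        base.update(kw)
        return StartStopEstimate(**base)

    def test_no_high_state(self):
        est = self.flat_estimate(r1=1.0, r2=1.0, r3=1.0, overall_rate=1.0)
        assert not exclude_no_temporal_control(est).valid
        assert est.exclusion_reason == "no high state"

    def test_clean_trial_valid(self):
        est = self.flat_estimate(start=28.0, stop=56.0)
        assert exclude_no_temporal_control(est).valid

    def test_straddle_clause(self):
        est = self.flat_estimate(start=45.0, stop=60.0)
        assert not exclude_no_temporal_control(est).valid
        est = self.flat_estimate(start=10.0, stop=35.0)
        assert not exclude_no_temporal_control(est).valid

    def test_relax_start_skips_start_clauses(self):
        est = self.flat_estimate(start=45.0, stop=60.0, r1=0.9, relax_start=True)
        assert exclude_no_temporal_control(est).valid

    def test_exclusion_fraction_calibrated_to_mixture(self):
        """With p_no_control = 0.2, the excluded fraction over 2,000 PI
        trials matches the generator's mixing proportion within 0.03."""
        rng = np.random.default_rng(99)
        params = GeneratorParams()
        n = 2000
        excluded = 0
        for _ in range(n):
            tr = generate_trial_presses({"trial_type": "PI"}, params, rng)
            est = extract_start_stop(tr, (0.0, 100.0))
            est = exclude_no_temporal_control(est, criterion_T=params.criterion_T)
            excluded += not est.valid
        assert abs(excluded / n - 0.20) <= 0.03


class TestRecoveryAndSummary:
    def test_start_stop_recover_latents(self):
        """Mean |estimate - latent| < 2 s over valid synthetic trials."""
        rng = np.random.default_rng(7)
        params = GeneratorParams(p_no_control=0.0)
        errs_start, errs_stop = [], []
        n_valid = 0
        for _ in range(1000):
            tr = generate_trial_presses({"trial_type": "PI"}, params, rng)
            est = extract_start_stop(tr, (0.0, 100.0))
            est = exclude_no_temporal_control(est)
            if est.valid and tr.latent_stop < 100:
                n_valid += 1
                errs_start.append(abs(est.start - tr.latent_start))
                errs_stop.append(abs(est.stop - tr.latent_stop))
        assert n_valid > 500
        assert np.mean(errs_start) < 2.0
        assert np.mean(errs_stop) < 2.0

    def test_fear_pin_rigid_shift_recovered_with_relaxed_start(self):
        """Rigidly shifted FEAR PIN trials (reset: +10 s) yield start/stop
        means shifted by 10 +- 2 s in the (20, 120) window."""
        base = GeneratorParams(n_fi=0, n_pi=20, n_pin=20, p_no_control=0.0)
        run = simulate_cohort(6, base, seed=21, group="FEAR")
        shifted = simulate_cohort(
            6, replace(base, distracter_mode="reset"), seed=21, group="FEAR"
        )
        f_run = estimates_frame(run)
        f_shift = estimates_frame(shifted)
        for col in ("start", "stop"):
            a = f_run[(f_run.trial_type == "PIN") & f_run.valid][col].mean()
            b = f_shift[(f_shift.trial_type == "PIN") & f_shift.valid][col].mean()
            assert b - a == pytest.approx(10.0, abs=2.0)

    def test_cv_hand_value(self):
        frame = pd.DataFrame(
            {
                "subject": ["S0"] * 2, "drug": ["SAL"] * 2,
                "trial_type": ["PI"] * 2, "start": [30.0, 50.0],
                "stop": [60.0, 80.0], "valid": [True, True],
            }
        )
        out = summarize_start_stop(frame)
        assert out.loc[0, "mean_start"] == pytest.approx(40.0)
        assert out.loc[0, "cv_start"] == pytest.approx(np.sqrt(200) / 40, abs=1e-4)

    def test_cv_zero_for_identical_trials(self):
        frame = pd.DataFrame(
            {
                "subject": ["S0"] * 3, "drug": ["SAL"] * 3,
                "trial_type": ["PI"] * 3, "start": [30.0] * 3,
                "stop": [60.0] * 3, "valid": [True] * 3,
            }
        )
        out = summarize_start_stop(frame)
        assert out.loc[0, "cv_start"] == 0.0 and out.loc[0, "cv_stop"] == 0.0

    @given(k=st.floats(min_value=0.1, max_value=10.0))
    def test_cv_scale_invariance(self, k):
        starts = np.array([25.0, 30.0, 42.0])
        frame = pd.DataFrame(
            {
                "subject": ["S0"] * 3, "drug": ["SAL"] * 3,
                "trial_type": ["PI"] * 3, "start": starts, "stop": starts + 20,
                "valid": [True] * 3,
            }
        )
        scaled = frame.assign(start=starts * k, stop=(starts + 20) * k)
        cv0 = summarize_start_stop(frame).loc[0, "cv_start"]
        cv1 = summarize_start_stop(scaled).loc[0, "cv_start"]
        assert cv1 == pytest.approx(cv0, rel=1e-9)

    def test_single_valid_trial_reports_missing_cv(self):
        frame = pd.DataFrame(
            {
                "subject": ["S0"], "drug": ["SAL"], "trial_type": ["PI"],
                "start": [30.0], "stop": [60.0], "valid": [True],
            }
        )
        out = summarize_start_stop(frame)
        assert np.isnan(out.loc[0, "cv_start"])
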