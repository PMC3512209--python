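"""End-to-end orchestration: simulate -> bin -> fit -> delay -> stats.

`run_pipeline` emulates the full study design: FEAR and CTRL cohorts,
each subject tested under saline and nomifensine, with the distracter
mode set per group x drug (the FEAR group over-resets, more so under
saline; the CTRL group runs through the neutral noise).  Every stage's
output is written as plain CSV/JSON under an output directory, with a
manifest recording the seed and per-stage counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .curves import GaussLinFit, analysis_window, bin_presses, fit_gaussian_linear
from .distracter import benchmark_delays, classify_delay, compute_delay
from .freezing import mean_percent_freezing
from .params import FreezingParams, GeneratorParams, ParameterError
from .records import TrialRecord
from .single_trial import ExclusionCriteria, estimates_frame, summarize_start_stop
from .stats import mixed_anova
from .synth import generate_freezing_series, generate_session, simulate_cohort

log = logging.getLogger("pitiming")


@dataclass
class AnalysisConfig:
    bin_width: float = 4.0
    alpha: float = 0.05
    exclusion_f: float = 0.5
    tolerance: float = 2.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ParameterError("bin_width must be positive")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must lie in (0, 1)")


@dataclass
class CohortConfig:
    """Study design: subjects per group and distracter mode per condition."""

    n_fear: int = 11
    n_ctrl: int = 6
    drugs: tuple[str, ...] = ("SAL", "NOM")
    # (group, drug) -> distracter mode; FEAR over-resets (less under the
    # reuptake blocker), CTRL ignores the neutral noise.
    modes: dict = field(
        default_factory=lambda: {
            ("FEAR", "SAL"): "over_reset",
            ("FEAR", "NOM"): "over_reset",
            ("CTRL", "SAL"): "run",
            ("CTRL", "NOM"): "run",
        }
    )
    salience: dict = field(
        default_factory=lambda: {
            ("FEAR", "SAL"): 8.0,
            ("FEAR", "NOM"): 3.0,
            ("CTRL", "SAL"): 0.0,
            ("CTRL", "NOM"): 0.0,
        }
    )

    def n_subjects(self, group: str) -> int:
        return self.n_fear if group == "FEAR" else self.n_ctrl


@dataclass
class RunConfig:
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    freezing: FreezingParams = field(default_factory=FreezingParams)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0


def subject_fits(
    trials: list[TrialRecord], trial_type: str, bin_width: float = 4.0
) -> dict[str, GaussLinFit]:
    """Fit one Gaussian+linear curve per subject for one trial type."""
    window = analysis_window(trial_type)
    by_subject: dict[str, list[TrialRecord]] = {}
    for tr in trials:
        if tr.trial_type == trial_type:
            by_subject.setdefault(tr.subject_id, []).append(tr)
    return {
        subj: fit_gaussian_linear(bin_presses(ts, window, bin_width))
        for subj, ts in sorted(by_subject.items())
    }


def cohort_mean_delay(
    n_subjects: int,
    mode: str,
    seed: int,
    params: GeneratorParams | None = None,
    salience_lambda: float = 0.0,
    bin_width: float = 4.0,
) -> tuple[float, list[float]]:
    """Simulate a cohort under one distracter mode and recover the mean
    PIN-minus-PI peak-time delay through the binning/fitting pipeline."""
    base = params or GeneratorParams()
    base = replace(
        base, distracter_mode=mode, salience_lambda=salience_lambda, n_fi=0
    )
    trials = simulate_cohort(n_subjects, base, seed)
    fits_pi = subject_fits(trials, "PI", bin_width)
    fits_pin = subject_fits(trials, "PIN", bin_width)
    results, _ = compute_delay(
        fits_pin, fits_pi, base.noise_duration_d1, base.noise_onset_d2
    )
    delays = [r.delay for r in results]
    return float(np.mean(delays)), delays


def fits_table(trials: list[TrialRecord], bin_width: float = 4.0) -> pd.DataFrame:
    """Per subject x group x drug x trial_type fit parameters."""
    rows = []
    key = {}
    for tr in trials:
        key[(tr.subject_id, tr.group, tr.drug)] = True
    for (subj, group, drug) in sorted(key):
        sub = [t for t in trials if t.subject_id == subj and t.drug == drug]
        for ttype in ("PI", "PIN"):
            subset = [t for t in sub if t.trial_type == ttype]
            if not subset:
                continue
            fit = fit_gaussian_linear(
                bin_presses(subset, analysis_window(ttype), bin_width)
            )
            rows.append(
                {
                    "subject": subj,
                    "group": group,
                    "drug": drug,
                    "trial_type": ttype,
                    "t0": fit.t0,
                    "b": fit.b,
                    "fwhm": fit.fwhm,
                    "a": fit.a,
                    "c": fit.c,
                    "d0": fit.d0,
                    "peak_rate": fit.peak_rate,
                    "sse": fit.sse,
                    "r2": fit.r2,
                    "converged": fit.converged,
                    "peak_resolved": fit.peak_resolved,
                }
            )
    return pd.DataFrame(rows)


def delays_table(fits: pd.DataFrame, d1: float, d2: float) -> pd.DataFrame:
    """Per-subject delay table from a fits table (t0_PIN - t0_PI)."""
    rows = []
    for (subj, group, drug), cell in fits.groupby(["subject", "group", "drug"]):
        piv = cell.set_index("trial_type")
        if (
            {"PI", "PIN"} <= set(piv.index)
            and piv["converged"].all()
            and piv["peak_resolved"].all()
        ):
            rows.append(
                {
                    "subject": subj,
                    "group": group,
                    "drug": drug,
                    "delay": float(piv.loc["PIN", "t0"] - piv.loc["PI", "t0"]),
                }
            )
    return pd.DataFrame(rows)


def simulate_study(config: RunConfig) -> list[TrialRecord]:
    """One session per subject x drug under the configured study design."""
    trials: list[TrialRecord] = []
    ss = np.random.SeedSequence(config.seed)
    conditions = [
        (group, drug) for group in ("FEAR", "CTRL") for drug in config.cohort.drugs
    ]
    seeds = ss.generate_state(
        sum(config.cohort.n_subjects(g) for g, _ in conditions) + len(conditions)
    ) & 0x7FFFFFFF
    k = 0
    for group, drug in conditions:
        mode = config.cohort.modes.get((group, drug), "run")
        lam = config.cohort.salience.get((group, drug), 0.0)
        for i in range(config.cohort.n_subjects(group)):
            p = replace(
                config.generator,
                distracter_mode=mode,
                salience_lambda=lam,
                seed=int(seeds[k]),
            )
            k += 1
            trials.extend(
                generate_session(
                    p,
                    subject_id=f"{group[0]}{i:02d}",
                    condition={"group": group, "drug": drug},
                    session_id=f"{drug.lower()}",
                )
            )
    return trials


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage, write artifacts, return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def stage(name, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # simulate
    trials = stage("simulate", lambda: simulate_study(config))
    pio.write_session(trials, out)
    per_session = config.generator.n_fi + config.generator.n_pi + config.generator.n_pin
    manifest["stages"]["simulate"] = {
        "n_trials": len(trials),
        "trials_per_session": per_session,
    }

    # curves
    fits = stage("curves", lambda: fits_table(trials, config.analysis.bin_width))
    fits.to_csv(out / "fits.csv", index=False)
    manifest["stages"]["curves"] = {"n_fits": len(fits)}

    # single trials
    criteria = ExclusionCriteria(f=config.analysis.exclusion_f)
    est = stage(
        "trials",
        lambda: estimates_frame(trials, criteria, config.generator.criterion_T),
    )
    est.to_csv(out / "startstop.csv", index=False)
    summary = summarize_start_stop(est)
    summary.to_csv(out / "startstop_summary.csv", index=False)
    manifest["stages"]["trials"] = {
        "n_estimates": len(est),
        "n_excluded": int((~est["valid"]).sum()) if len(est) else 0,
    }

    # delays
    if config.generator.n_pin > 0 and not fits.empty:
        d1 = config.generator.noise_duration_d1
        d2 = config.generator.noise_onset_d2
        delays = stage("delay", lambda: delays_table(fits, d1, d2))
        delays.to_csv(out / "delays.csv", index=False)
        bench = benchmark_delays(d1, d2)
        summaries = {}
        for (group, drug), cell in delays.groupby(["group", "drug"]):
            cls = classify_delay(
                cell["delay"].to_numpy(),
                bench,
                config.analysis.alpha,
                config.analysis.tolerance,
            )
            summaries[f"{group}:{drug}"] = {
                "label": cls.label,
                "n": cls.n,
                "mean_delay": cls.mean_delay,
                "tests": cls.tests,
            }
        (out / "delay_summary.json").write_text(json.dumps(summaries, indent=2))
        manifest["stages"]["delay"] = {"n_subjects": delays["subject"].nunique()}
    else:
        delays = pd.DataFrame()
        log.info("delay stage skipped: no PIN trials")
        manifest["stages"]["delay"] = {"skipped": "no PIN trials"}

    # freezing
    def freeze_stage():
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF]).generate_state(1)[0])
        series = []
        for group in ("FEAR", "CTRL"):
            for i in range(config.cohort.n_subjects(group)):
                series.append(
                    generate_freezing_series(
                        group, config.freezing, rng, series_id=f"{group[0]}{i:02d}"
                    )
                )
        return series

    series = stage("freeze", freeze_stage)
    pio.write_freezing(series, out / "freezing.csv")
    freeze_summary = mean_percent_freezing(series)
    freeze_summary.to_csv(out / "freeze_summary.csv", index=False)
    manifest["stages"]["freeze"] = {"n_series": len(series)}

    # stats: subjects missing a drug cell (dropped fit) cannot enter the
    # split-plot design, so keep complete cases only
    n_drugs = len(config.cohort.drugs)
    if not delays.empty:
        complete = delays.groupby("subject")["drug"].transform("nunique") == n_drugs
        delays_cc = delays[complete]
    else:
        delays_cc = delays
    if (
        not delays_cc.empty
        and delays_cc.groupby("group")["subject"].nunique().min() >= 2
        and delays_cc["group"].nunique() == 2
    ):
        table = stage(
            "stats",
            lambda: mixed_anova(
                delays_cc, dv="delay", subject="subject", between="group",
                within=["drug"],
            ),
        )
        (out / "anova.json").write_text(
            json.dumps(
                {
                    "effects": table.effects,
                    "design": table.design,
                    "n_subjects": table.n_subjects,
                },
                indent=2,
            )
        )
        manifest["stages"]["stats"] = {"n_effects": len(table.effects)}
    else:
        manifest["stages"]["stats"] = {"skipped": "insufficient delay data"}

    manifest["versions"] = {"numpy": np.__version__, "pandas": pd.__version__}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
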