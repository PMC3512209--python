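"""Plain-text readers/writers for the pipeline's CSV schemas.

Schemas (all times in seconds, 0-based from signal onset):

- ``trials.csv``  — one row per trial: subject_id, session_id,
  trial_index, trial_type, group, drug, trial_duration, noise_onset,
  noise_duration, reward_time, stop_truncated.
- ``presses.csv`` — one row per press: subject_id, session_id,
  trial_index, press_time.
- ``truth.csv``   — synthetic ground truth (latent_start, latent_stop),
  written separately and never read by analysis stages.
- ``freezing.csv``— series_id, group, bin_width, noise_onset,
  noise_offset, bin_index, frozen.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import FreezingParams, GeneratorParams, ParameterError
from .records import FreezingSeries, TrialRecord

TRIAL_COLUMNS = [
    "subject_id",
    "session_id",
    "trial_index",
    "trial_type",
    "group",
    "drug",
    "trial_duration",
    "noise_onset",
    "noise_duration",
    "reward_time",
    "stop_truncated",
]
PRESS_COLUMNS = ["subject_id", "session_id", "trial_index", "press_time"]


class SchemaError(ValueError):
    pass


def _check_header(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def write_session(trials: list[TrialRecord], out_dir: str | Path) -> None:
    """Write trials.csv, presses.csv and truth.csv for a set of trials."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trows, prows, lrows = [], [], []
    for tr in trials:
        trows.append(
            {
                "subject_id": tr.subject_id,
                "session_id": tr.session_id,
                "trial_index": tr.trial_index,
                "trial_type": tr.trial_type,
                "group": tr.group,
                "drug": tr.drug,
                "trial_duration": tr.trial_duration,
                "noise_onset": tr.noise_onset,
                "noise_duration": tr.noise_duration,
                "reward_time": tr.reward_time,
                "stop_truncated": tr.stop_truncated,
            }
        )
        for t in tr.press_times:
            prows.append(
                {
                    "subject_id": tr.subject_id,
                    "session_id": tr.session_id,
                    "trial_index": tr.trial_index,
                    "press_time": repr(float(t)),
                }
            )
        lrows.append(
            {
                "subject_id": tr.subject_id,
                "session_id": tr.session_id,
                "trial_index": tr.trial_index,
                "latent_start": tr.latent_start,
                "latent_stop": tr.latent_stop,
            }
        )
    pd.DataFrame(trows, columns=TRIAL_COLUMNS).to_csv(out / "trials.csv", index=False)
    pd.DataFrame(prows, columns=PRESS_COLUMNS).to_csv(out / "presses.csv", index=False)
    pd.DataFrame(lrows).to_csv(out / "truth.csv", index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_header(df, TRIAL_COLUMNS, path)
    bad = df.index[df["trial_duration"] <= 0]
    if len(bad):
        raise SchemaError(f"{path}: non-positive trial_duration at line {bad[0] + 2}")
    return df


def read_presses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"press_time": float}, float_precision="round_trip")
    _check_header(df, PRESS_COLUMNS, path)
    bad = df.index[(df["press_time"] < 0) | df["press_time"].isna()]
    if len(bad):
        raise SchemaError(f"{path}: invalid press_time at line {bad[0] + 2}")
    return df


def load_trials(trials_path: str | Path, presses_path: str | Path) -> list[TrialRecord]:
    """Join trials.csv and presses.csv back into TrialRecords."""
    tdf = read_trials(trials_path)
    pdf = read_presses(presses_path)
    key = ["subject_id", "session_id", "trial_index"]
    known = set(map(tuple, tdf[key].itertuples(index=False, name=None)))
    for line, row in enumerate(pdf[key].itertuples(index=False, name=None), start=2):
        if row not in known:
            raise SchemaError(
                f"{presses_path}: press at line {line} references unknown trial {row}"
            )
    grouped = {k: g["press_time"].to_numpy() for k, g in pdf.groupby(key, sort=False)}
    records = []
    for _, row in tdf.iterrows():
        k = (row["subject_id"], row["session_id"], row["trial_index"])
        presses = np.sort(grouped.get(k, np.empty(0)))

        def opt(v):
            return None if pd.isna(v) else float(v)

        records.append(
            TrialRecord(
                subject_id=str(row["subject_id"]),
                session_id=str(row["session_id"]),
                trial_index=int(row["trial_index"]),
                trial_type=str(row["trial_type"]),
                group=str(row["group"]),
                drug=str(row["drug"]),
                trial_duration=float(row["trial_duration"]),
                press_times=presses,
                noise_onset=opt(row["noise_onset"]),
                noise_duration=opt(row["noise_duration"]),
                reward_time=opt(row["reward_time"]),
                stop_truncated=bool(row["stop_truncated"]),
            )
        )
    return records


def write_freezing(series_list: list[FreezingSeries], path: str | Path) -> None:
    rows = []
    for s in series_list:
        for i, frozen in enumerate(s.bins):
            rows.append(
                {
                    "series_id": s.series_id,
                    "group": s.group,
                    "bin_width": s.bin_width,
                    "noise_onset": s.event_markers[0],
                    "noise_offset": s.event_markers[1],
                    "bin_index": i,
                    "frozen": int(frozen),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_freezing(path: str | Path) -> list[FreezingSeries]:
    df = pd.read_csv(path)
    _check_header(
        df,
        ["series_id", "group", "bin_width", "noise_onset", "noise_offset", "bin_index", "frozen"],
        path,
    )
    out = []
    for sid, g in df.groupby("series_id", sort=False):
        g = g.sort_values("bin_index")
        out.append(
            FreezingSeries(
                bin_width=float(g["bin_width"].iloc[0]),
                bins=g["frozen"].to_numpy(dtype=bool),
                event_markers=(
                    float(g["noise_onset"].iloc[0]),
                    float(g["noise_offset"].iloc[0]),
                ),
                series_id=str(sid),
                group=str(g["group"].iloc[0]),
            )
        )
    return out


def load_config(path: str | Path) -> "RunConfig":
    """Load a YAML run configuration, rejecting unknown keys by name."""
    from .pipeline import AnalysisConfig, CohortConfig, RunConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"generator", "freezing", "cohort", "analysis", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown config section(s): {sorted(unknown)}")

    def build(cls, data, section):
        data = data or {}
        names = {f.name for f in cls.__dataclass_fields__.values()}
        bad = set(data) - names
        if bad:
            raise ParameterError(f"unknown key(s) in {section!r}: {sorted(bad)}")
        return cls(**data)

    cohort_raw = dict(raw.get("cohort") or {})
    for mapping in ("modes", "salience"):
        if mapping in cohort_raw:
            cohort_raw[mapping] = {
                tuple(k.split(":")): v for k, v in cohort_raw[mapping].items()
            }
    return RunConfig(
        generator=build(GeneratorParams, raw.get("generator"), "generator"),
        freezing=build(FreezingParams, raw.get("freezing"), "freezing"),
        cohort=build(CohortConfig, cohort_raw, "cohort"),
        analysis=build(AnalysisConfig, raw.get("analysis"), "analysis"),
        seed=int(raw.get("seed", 0)),
    )
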