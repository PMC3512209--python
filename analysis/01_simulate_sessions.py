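"""Simulate the full study design and write the raw session CSVs.

FEAR (n = 11) and CTRL (n = 6) cohorts, each subject tested under saline
and nomifensine, with 20 FI + 14 PI + 6 PIN trials per session.  The
FEAR group's clock over-resets after the distracter (more under saline
than under the reuptake blocker); the CTRL group runs straight through
the neutral noise.  Ground-truth latents go to truth.csv, which no later
stage reads.
"""

import argparse
from pathlib import Path

from pitiming import RunConfig
from pitiming.pipeline import simulate_study
from pitiming import io as pio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed)
    trials = simulate_study(cfg)
    pio.write_session(trials, args.out_dir)

    n_subjects = len({t.subject_id for t in trials})
    n_sessions = len({(t.subject_id, t.session_id) for t in trials})
    print(f"simulated {len(trials)} trials: {n_subjects} subjects, "
          f"{n_sessions} sessions ({len(trials)//n_sessions} trials each)")
    print(f"wrote trials/presses/truth CSVs to {args.out_dir}")


if __name__ == "__main__":
    main()
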