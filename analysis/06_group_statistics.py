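"""Group-level statistics on the recovered delays.

Mixed (split-plot) ANOVA of the peak-time delay with between-subject
factor group (FEAR, CTRL) and within-subject factor drug (SAL, NOM),
followed by a planned comparison of the drug effect within the FEAR
group — the design the timing experiments use.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from pitiming import mixed_anova, planned_comparison


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--delays", type=Path, default=Path("results/delays.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/anova.json"))
    args = ap.parse_args()

    delays = pd.read_csv(args.delays)
    complete = delays.groupby("subject")["drug"].transform("nunique") == 2
    delays = delays[complete]

    table = mixed_anova(
        delays, dv="delay", subject="subject", between="group", within=["drug"]
    )
    print(table.to_frame()[["name", "F", "df_num", "df_den", "p"]].to_string(index=False))

    contrast = planned_comparison(
        delays, "delay",
        {"group": "FEAR", "drug": "SAL"}, {"group": "FEAR", "drug": "NOM"},
        anova=table, error_term="group x drug",
    )
    print(f"planned comparison FEAR SAL vs NOM: F(1,{contrast['df_den']}) = "
          f"{contrast['F']:.2f}, p = {contrast['p']:.4f}")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(
        {"anova": table.effects, "planned_fear_sal_vs_nom": contrast}, indent=2
    ))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
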