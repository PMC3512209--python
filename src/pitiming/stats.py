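"""Group-level statistics: mixed (split-plot) ANOVA and planned tests.

The designs supported are those of the timing experiments: one
between-subject factor (group) crossed with one or two two-level
within-subject factors (drug, trial type), subjects as random blocks.
Sphericity corrections are unnecessary for two-level within factors, so
the module refuses factors with more than two within levels rather than
silently skipping the correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


class DesignError(ValueError):
    pass


@dataclass
class AnovaTable:
    effects: list[dict]
    design: dict
    n_subjects: int

    def effect(self, name: str) -> dict:
        for e in self.effects:
            if e["name"] == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.effects)


def _raw_ss(df: pd.DataFrame, dv: str, cols: tuple[str, ...]) -> float:
    """Sum over cells of (cell total)^2 / (cell size)."""
    if not cols:
        tot = df[dv].sum()
        return float(tot * tot / len(df))
    g = df.groupby(list(cols), observed=True)[dv].agg(["sum", "count"])
    return float((g["sum"] ** 2 / g["count"]).sum())


def mixed_anova(
    df: pd.DataFrame,
    dv: str,
    subject: str,
    between: str | None = None,
    within: list[str] | None = None,
) -> AnovaTable:
    """Classical sums-of-squares split-plot ANOVA.

    Requires a balanced design: every subject observed exactly once in
    every within-factor cell.  Between-group effects are tested against
    subjects-within-groups; each within effect (and its interaction with
    the group) against its own factor-by-subject error stratum.
    """
    within = list(within or [])
    if not within and between is None:
        raise DesignError("need at least one between or within factor")
    if len(within) > 2:
        raise DesignError("at most two within-subject factors are supported")
    for w in within:
        if df[w].nunique() > 2:
            raise DesignError(
                f"within factor {w!r} has more than two levels; sphericity "
                "corrections are not implemented"
            )

    subjects = df[subject].unique()
    n_subj = len(subjects)
    if within:
        # balance check: one observation per subject per within cell
        counts = df.groupby([subject] + within, observed=True).size()
        n_cells = int(np.prod([df[w].nunique() for w in within]))
        per_subj = counts.groupby(level=0).size()
        bad = sorted(
            set(per_subj[per_subj != n_cells].index)
            | set(counts[counts != 1].index.get_level_values(0))
        )
        if bad:
            raise DesignError(f"missing or duplicated within cells for subjects {bad}")
    if between is not None:
        g_of_subj = df.groupby(subject, observed=True)[between].nunique()
        if (g_of_subj != 1).any():
            raise DesignError("each subject must belong to exactly one group")
        group_sizes = df.drop_duplicates(subject).groupby(between, observed=True).size()
        if (group_sizes < 2).any():
            raise DesignError("need at least 2 subjects per group")
        n_groups = int(group_sizes.size)
    else:
        n_groups = 1

    levels = {w: df[w].nunique() for w in within}
    R0 = _raw_ss(df, dv, ())

    # effect definitions: (name, classification cols, df, stratum key)
    effs: list[tuple[str, tuple[str, ...], int, str]] = []
    if between is not None:
        effs.append((between, (between,), n_groups - 1, "between"))
    effs.append(("subjects", (subject,), n_subj - n_groups, "between_err"))
    for k in (1, 2):
        for combo in combinations(within, k):
            df_w = int(np.prod([levels[w] - 1 for w in combo]))
            name = " x ".join(combo)
            effs.append((name, combo, df_w, name))
            if between is not None:
                effs.append(
                    (
                        f"{between} x {name}",
                        (between, *combo),
                        (n_groups - 1) * df_w,
                        name,
                    )
                )
            effs.append(
                (
                    f"{name} x subjects",
                    (subject, *combo),
                    (n_subj - n_groups) * df_w,
                    f"{name}_err",
                )
            )

    # span: the classification each column set induces (subject implies group)
    def span(cols: tuple[str, ...]) -> frozenset:
        s = set(cols)
        if subject in s and between is not None:
            s.add(between)
        return frozenset(s)

    ss: dict[str, float] = {}
    spans: dict[str, frozenset] = {}
    for name, cols, dfree, _ in effs:
        contained = sum(ss[m] for m in ss if spans[m] <= span(cols))
        ss[name] = _raw_ss(df, dv, cols) - R0 - contained
        spans[name] = span(cols)

    # F tests: each stratum's effects over its error term
    err_ss = {}
    err_df = {}
    for name, _, dfree, stratum in effs:
        if stratum.endswith("_err") or stratum == "between_err":
            key = stratum.replace("_err", "")
            err_ss[key if key else "between"] = ss[name]
            err_df[key if key else "between"] = dfree

    rows = []
    for name, _, dfree, stratum in effs:
        if stratum.endswith("_err") or stratum == "between_err":
            continue
        key = "between" if stratum == "between" else stratum
        ms = ss[name] / dfree if dfree > 0 else np.nan
        mse = err_ss[key] / err_df[key] if err_df[key] > 0 else np.nan
        F = ms / mse if mse > 0 else (0.0 if ms == 0 else np.inf)
        p = float(sps.f.sf(F, dfree, err_df[key])) if np.isfinite(F) else 0.0
        rows.append(
            {
                "name": name,
                "ss": ss[name],
                "df_num": dfree,
                "df_den": err_df[key],
                "ms": ms,
                "ms_error": mse,
                "F": float(max(F, 0.0)),
                "p": p,
            }
        )
    return AnovaTable(
        effects=rows,
        design={"between": [between] if between else [], "within": within},
        n_subjects=n_subj,
    )


def one_sample_t(values, mu: float) -> dict:
    """Two-sided one-sample t-test of the mean against ``mu``."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DesignError("need n >= 2")
    if np.ptp(x) == 0:
        if x[0] == mu:
            return {"t": 0.0, "df": x.size - 1, "p": 1.0, "zero_variance": True}
        return {
            "t": float(np.inf if x[0] > mu else -np.inf),
            "df": x.size - 1,
            "p": float(np.finfo(float).eps),
            "zero_variance": True,
        }
    t, p = sps.ttest_1samp(x, mu)
    return {"t": float(t), "df": x.size - 1, "p": float(p), "zero_variance": False}


def paired_t(a, b) -> dict:
    """Two-sided paired t-test (inputs matched by subject order)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DesignError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0)


def planned_comparison(
    df: pd.DataFrame,
    dv: str,
    cell_a: dict,
    cell_b: dict,
    anova: AnovaTable | None = None,
    error_term: str | None = None,
    pooled: bool = True,
) -> dict:
    """F-test of a two-cell contrast.

    With ``pooled`` (default) the error mean square is taken from the
    fitted ANOVA (the named ``error_term`` stratum, or the finest one);
    otherwise a cell-wise error is computed from the two cells alone.
    """
    def select(cell):
        m = pd.Series(True, index=df.index)
        for k, v in cell.items():
            m &= df[k] == v
        return df.loc[m, dv].to_numpy(dtype=float)

    ya, yb = select(cell_a), select(cell_b)
    if ya.size == 0 or yb.size == 0:
        raise DesignError("empty cell in planned comparison")
    diff = ya.mean() - yb.mean()
    if pooled:
        if anova is None:
            raise DesignError("pooled comparison requires a fitted AnovaTable")
        if error_term is None:
            eff = anova.effects[-1]
        else:
            eff = anova.effect(error_term)
        mse, df_den = eff["ms_error"], eff["df_den"]
        F = diff**2 / (mse * (1.0 / ya.size + 1.0 / yb.size))
    else:
        se2 = ya.var(ddof=1) / ya.size + yb.var(ddof=1) / yb.size
        df_den = ya.size + yb.size - 2
        F = diff**2 / se2 if se2 > 0 else np.inf
    p = float(sps.f.sf(F, 1, df_den))
    return {"F": float(F), "df_num": 1, "df_den": int(df_den), "p": p, "diff": float(diff)}
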