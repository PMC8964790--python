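"""Factorial group statistics: two-way ANOVA and Tukey-Kramer post-hocs.

Connectivity strengths and network metrics are compared across the two
study factors, fatigue level (L1/L2/L3) and task (PVT/cognitive/driving),
with a fixed-effects two-way ANOVA (Type III sums of squares under
sum-to-zero coding, safe for unbalanced cells) and the partial eta squared
effect size SS_effect / (SS_effect + SS_error). Where the level main
effect is significant without a level x task interaction, pairwise
Tukey-Kramer comparisons (studentized-range test with the unequal-n
correction) locate which levels differ — the same reporting rule the
factorial-design literature prescribes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnovaResult",
    "EffectResult",
    "two_way_anova",
    "tukey_kramer",
    "band_metric_comparison",
]

ALPHA = 0.05


@dataclass(frozen=True)
class EffectResult:
    F: float
    p: float
    partial_eta_sq: float
    df: float
    ss: float


@dataclass
class AnovaResult:
    """Per-effect F, p, partial eta squared plus cell summaries."""

    effects: dict[str, EffectResult]  # keys: "level", "task", "interaction"
    df_error: float
    ss_error: float
    cell_means: pd.DataFrame

    def __getitem__(self, key: str) -> EffectResult:
        return self.effects[key]


def two_way_anova(values, level, task) -> AnovaResult:
    """Fixed-effects two-way ANOVA with interaction (Type III, sum coding)."""
    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "level": list(level), "task": list(task)}
    )
    for factor in ("level", "task"):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs at least 2 distinct values")
    if np.ptp(df["y"].to_numpy()) == 0.0:
        raise ValueError("zero residual variance: all values identical, ANOVA degenerate")
    counts = df.groupby(["level", "task"], sort=True).size()
    full = df["level"].nunique() * df["task"].nunique()
    if len(counts) < full:
        present = set(counts.index)
        missing = [
            (lv, tk)
            for lv in sorted(df["level"].unique())
            for tk in sorted(df["task"].unique())
            if (lv, tk) not in present
        ]
        raise ValueError(f"interaction inestimable: empty cells {missing}")
    model = smf.ols("y ~ C(level, Sum) * C(task, Sum)", data=df).fit()
    if model.df_resid < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    table = sm.stats.anova_lm(model, typ=3)
    ss_error = float(table.loc["Residual", "sum_sq"])
    if ss_error <= 0:
        raise ValueError("zero residual variance: ANOVA degenerate")
    key_map = {
        "level": "C(level, Sum)",
        "task": "C(task, Sum)",
        "interaction": "C(level, Sum):C(task, Sum)",
    }
    effects = {}
    for name, row in key_map.items():
        ss = float(table.loc[row, "sum_sq"])
        effects[name] = EffectResult(
            F=float(table.loc[row, "F"]),
            p=float(table.loc[row, "PR(>F)"]),
            partial_eta_sq=ss / (ss + ss_error),
            df=float(table.loc[row, "df"]),
            ss=ss,
        )
    cell_means = (
        df.groupby(["level", "task"], sort=True)["y"].agg(["mean", "count"]).reset_index()
    )
    return AnovaResult(
        effects=effects,
        df_error=float(model.df_resid),
        ss_error=ss_error,
        cell_means=cell_means,
    )


def tukey_kramer(values, group) -> pd.DataFrame:
    """All pairwise comparisons with the Tukey-Kramer studentized-range test.

    Returns a tidy frame: group_a, group_b, mean_diff (a - b), se, q, p.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    labels = sorted(np.unique(group).tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    by = {g: values[group == g] for g in labels}
    for g, v in by.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    n_total = values.size
    k = len(labels)
    df_error = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in by.values()) / df_error
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            va, vb = by[a], by[b]
            diff = va.mean() - vb.mean()
            se = np.sqrt(mse / 2.0 * (1.0 / va.size + 1.0 / vb.size))
            q = abs(diff) / se if se > 0 else np.inf
            p = float(sstats.studentized_range.sf(q, k, df_error))
            rows.append(
                {"group_a": a, "group_b": b, "mean_diff": diff, "se": se, "q": q, "p": p}
            )
    return pd.DataFrame(rows)


def band_metric_comparison(
    table: pd.DataFrame,
    targets: list[str],
    alpha: float = ALPHA,
    fdr_bh: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(band, target) two-way ANOVA with conditional Tukey post-hocs.

    ``table`` is tidy with columns band, level, task plus one column per
    target (a connectivity pair or network metric). Post-hoc rows are
    produced only where the level main effect is significant and the
    interaction is not — mirroring the usual factorial reporting rule.
    With ``fdr_bh`` a Benjamini-Hochberg adjusted p column (per band and
    effect, across targets) is added; no correction is applied by default.
    Returns (anova frame, post-hoc frame).
    """
    required = {"band", "level", "task"}
    if not required <= set(table.columns):
        raise ValueError(f"table must contain columns {sorted(required)}")
    anova_rows, posthoc_rows = [], []
    for band, sub in table.groupby("band", sort=False):
        for target in targets:
            res = two_way_anova(sub[target], sub["level"], sub["task"])
            for effect, er in res.effects.items():
                anova_rows.append(
                    {
                        "band": band,
                        "target": target,
                        "effect": effect,
                        "F": er.F,
                        "p": er.p,
                        "partial_eta_sq": er.partial_eta_sq,
                    }
                )
            if res["level"].p < alpha and res["interaction"].p >= alpha:
                ph = tukey_kramer(sub[target], sub["level"])
                ph.insert(0, "target", target)
                ph.insert(0, "band", band)
                posthoc_rows.append(ph)
    posthoc = (
        pd.concat(posthoc_rows, ignore_index=True)
        if posthoc_rows
        else pd.DataFrame(columns=["band", "target", "group_a", "group_b", "mean_diff", "se", "q", "p"])
    )
    anova = pd.DataFrame(anova_rows)
    if fdr_bh and len(anova):
        from statsmodels.stats.multitest import multipletests

        anova["p_adj"] = np.nan
        for (_, _), idx in anova.groupby(["band", "effect"]).groups.items():
            anova.loc[idx, "p_adj"] = multipletests(
                anova.loc[idx, "p"], method="fdr_bh"
            )[1]
    return anova, posthoc
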