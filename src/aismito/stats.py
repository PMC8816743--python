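"""Statistical comparisons for measurement tables (thin layer over standard tests).

This module only fixes the mapping from figure-legend test names to
procedures and the unit of analysis (cell-level values by default,
replicate means on request):

- ``welch_t``                 unpaired t-test with Welch's correction
- ``one_way_anova_dunnett``   ordinary one-way ANOVA, Dunnett vs control
- ``one_way_anova_tukey``     ordinary one-way ANOVA, Tukey HSD
- ``bf_welch_anova_dunnett``  Welch's ANOVA omnibus with Games-Howell
                              (unequal-variance) contrasts against control
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

DESIGNS = ("welch_t", "one_way_anova_dunnett", "one_way_anova_tukey", "bf_welch_anova_dunnett")


@dataclass
class GroupComparisonSpec:
    metric: str
    design: str
    group_col: str = "condition"
    value_col: str = "value"
    control: str | None = None
    alpha: float = 0.05
    replicate_level: bool = False  # test replicate means instead of cell values

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ValidationError(f"unknown design {self.design!r}; pick one of {DESIGNS}")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")


@dataclass
class GroupComparisonReport:
    design: str
    alpha: float
    group_stats: pd.DataFrame  # group, n, mean, sd
    normality: pd.DataFrame  # group, shapiro_w, shapiro_p (NaN when n < 3)
    omnibus: dict  # name, statistic, p
    contrasts: pd.DataFrame  # contrast, estimate, p_raw, p_adj, significant

    @property
    def any_significant(self) -> bool:
        return bool(self.contrasts["significant"].any())


def _groups(table: pd.DataFrame, spec: GroupComparisonSpec) -> dict[str, np.ndarray]:
    df = table
    if "metric_name" in df.columns and spec.metric:
        df = df[df["metric_name"] == spec.metric]
    if spec.replicate_level:
        if "replicate_id" not in df.columns:
            raise ValidationError("replicate_level=True needs a replicate_id column")
        df = (
            df.groupby([spec.group_col, "replicate_id"], as_index=False)[spec.value_col]
            .mean()
        )
    out = {}
    for g, sub in df.groupby(spec.group_col, sort=False):
        vals = np.asarray(sub[spec.value_col], dtype=float)
        if vals.size < 2:
            raise ValidationError(f"group {g!r} has n < 2")
        out[str(g)] = vals
    if len(out) < 2:
        raise ValidationError("need at least two groups")
    return out


def _zero_variance(groups: dict[str, np.ndarray]) -> bool:
    return all(np.ptp(v) == 0 for v in groups.values())


def compare_groups(table: pd.DataFrame, spec: GroupComparisonSpec) -> GroupComparisonReport:
    """Run the requested design on a tidy measurement table.

    Per-group Shapiro-Wilk normality is reported alongside the omnibus test
    and the adjusted per-contrast p-values; ``significant`` flags contrasts at
    ``spec.alpha``.
    """
    groups = _groups(table, spec)
    names = list(groups)
    control = spec.control or names[0]
    if control not in groups:
        raise ValidationError(f"control group {control!r} absent")
    gs = pd.DataFrame(
        {
            "group": names,
            "n": [groups[g].size for g in names],
            "mean": [groups[g].mean() for g in names],
            "sd": [groups[g].std(ddof=1) for g in names],
        }
    )
    norm_rows = []
    for g in names:
        v = groups[g]
        if v.size >= 3 and np.ptp(v) > 0:
            w, p = sps.shapiro(v)
        else:
            w, p = np.nan, np.nan
        norm_rows.append({"group": g, "shapiro_w": w, "shapiro_p": p})
    normality = pd.DataFrame(norm_rows)

    if spec.design == "welch_t":
        omnibus, contrasts = _welch_t(groups, names)
    elif spec.design == "one_way_anova_dunnett":
        omnibus, contrasts = _anova_dunnett(groups, names, control)
    elif spec.design == "one_way_anova_tukey":
        omnibus, contrasts = _anova_tukey(groups, names)
    else:
        omnibus, contrasts = _welch_anova_gameshowell(groups, names, control, spec)
    contrasts["significant"] = contrasts["p_adj"] < spec.alpha
    return GroupComparisonReport(spec.design, spec.alpha, gs, normality, omnibus, contrasts)


def _safe_p(p: float, groups_equal: bool) -> float:
    if np.isnan(p):
        return 1.0 if groups_equal else 0.0
    return float(p)


def _welch_t(groups, names):
    if len(names) != 2:
        raise ValidationError("welch_t needs exactly two groups")
    a, b = groups[names[0]], groups[names[1]]
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate zero-variance case: decided by the means alone
        p = 1.0 if a.mean() == b.mean() else 0.0
        stat = np.inf if p == 0.0 else 0.0
    else:
        stat, p = sps.ttest_ind(a, b, equal_var=False)
    omnibus = {"name": "welch_t", "statistic": float(stat), "p": float(p)}
    contrasts = pd.DataFrame(
        [
            {
                "contrast": f"{names[1]} vs {names[0]}",
                "estimate": float(b.mean() - a.mean()),
                "p_raw": float(p),
                "p_adj": float(p),
            }
        ]
    )
    return omnibus, contrasts


def _omnibus_anova(groups, names):
    if _zero_variance(groups):
        same = len({v[0] for v in groups.values()}) == 1
        return {"name": "one_way_anova", "statistic": 0.0 if same else np.inf,
                "p": 1.0 if same else 0.0}
    f, p = sps.f_oneway(*[groups[g] for g in names])
    return {"name": "one_way_anova", "statistic": float(f), "p": _safe_p(p, False)}


def _anova_dunnett(groups, names, control):
    omnibus = _omnibus_anova(groups, names)
    others = [g for g in names if g != control]
    rows = []
    if _zero_variance(groups):
        for g in others:
            same = groups[g].mean() == groups[control].mean()
            rows.append(
                {
                    "contrast": f"{g} vs {control}",
                    "estimate": float(groups[g].mean() - groups[control].mean()),
                    "p_raw": 1.0 if same else 0.0,
                    "p_adj": 1.0 if same else 0.0,
                }
            )
        return omnibus, pd.DataFrame(rows)
    res = sps.dunnett(*[groups[g] for g in others], control=groups[control])
    n_total = sum(v.size for v in groups.values())
    df = n_total - len(names)
    for i, g in enumerate(others):
        t = float(res.statistic[i])
        rows.append(
            {
                "contrast": f"{g} vs {control}",
                "estimate": float(groups[g].mean() - groups[control].mean()),
                "p_raw": float(2 * sps.t.sf(abs(t), df)),
                "p_adj": float(res.pvalue[i]),
            }
        )
    return omnibus, pd.DataFrame(rows)


def _anova_tukey(groups, names):
    omnibus = _omnibus_anova(groups, names)
    rows = []
    if _zero_variance(groups):
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                same = groups[a].mean() == groups[b].mean()
                rows.append(
                    {
                        "contrast": f"{b} vs {a}",
                        "estimate": float(groups[b].mean() - groups[a].mean()),
                        "p_raw": 1.0 if same else 0.0,
                        "p_adj": 1.0 if same else 0.0,
                    }
                )
        return omnibus, pd.DataFrame(rows)
    res = sps.tukey_hsd(*[groups[g] for g in names])
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            raw = sps.ttest_ind(groups[a], groups[b]).pvalue
            rows.append(
                {
                    "contrast": f"{b} vs {a}",
                    "estimate": float(groups[b].mean() - groups[a].mean()),
                    "p_raw": _safe_p(raw, np.array_equal(groups[a], groups[b])),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return omnibus, pd.DataFrame(rows)


def _welch_anova_gameshowell(groups, names, control, spec):
    import pingouin as pg

    long = pd.DataFrame(
        {
            spec.group_col: np.repeat(names, [groups[g].size for g in names]),
            "value": np.concatenate([groups[g] for g in names]),
        }
    )
    if _zero_variance(groups):
        same = len({v[0] for v in groups.values()}) == 1
        omnibus = {"name": "welch_anova", "statistic": 0.0 if same else np.inf,
                   "p": 1.0 if same else 0.0}
        rows = [
            {
                "contrast": f"{g} vs {control}",
                "estimate": float(groups[g].mean() - groups[control].mean()),
                "p_raw": 1.0 if groups[g].mean() == groups[control].mean() else 0.0,
                "p_adj": 1.0 if groups[g].mean() == groups[control].mean() else 0.0,
            }
            for g in names
            if g != control
        ]
        return omnibus, pd.DataFrame(rows)
    aov = pg.welch_anova(data=long, dv="value", between=spec.group_col)
    omnibus = {
        "name": "welch_anova",
        "statistic": float(aov["F"].iloc[0]),
        "p": float(aov["p_unc"].iloc[0]),
    }
    gh = pg.pairwise_gameshowell(data=long, dv="value", between=spec.group_col)
    rows = []
    for _, r in gh.iterrows():
        pair = {r["A"], r["B"]}
        if control not in pair:
            continue
        other = (pair - {control}).pop()
        raw = sps.ttest_ind(groups[other], groups[control], equal_var=False).pvalue
        rows.append(
            {
                "contrast": f"{other} vs {control}",
                "estimate": float(groups[other].mean() - groups[control].mean()),
                "p_raw": _safe_p(raw, np.array_equal(groups[other], groups[control])),
                "p_adj": float(r["pval"]),
            }
        )
    return omnibus, pd.DataFrame(rows)


def summarize_replicates(
    table: pd.DataFrame,
    group_by: str = "condition",
    value_col: str = "value",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate means plus condition-level summaries.

    Returns ``(replicate_table, condition_table)``: one row per
    (condition, replicate) with mean and n, and per condition the unweighted
    mean of replicate means with the SD across replicates (NaN for a single
    replicate).
    """
    if "replicate_id" not in table.columns:
        raise ValidationError("summarize_replicates needs a replicate_id column")
    rep = (
        table.groupby([group_by, "replicate_id"], as_index=False)
        .agg(mean=(value_col, "mean"), n=(value_col, "size"))
    )
    cond = (
        rep.groupby(group_by, as_index=False)
        .agg(
            mean=("mean", "mean"),
            sd=("mean", lambda v: v.std(ddof=1) if len(v) > 1 else np.nan),
            n_replicates=("mean", "size"),
        )
    )
    return rep, cond
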