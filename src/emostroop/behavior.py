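"""Reaction-time analysis: conflict adaptation and group comparisons.

Conflict adaptation is the reduction in RT on incongruent trials preceded
by incongruent trials (iI) relative to incongruent trials preceded by
congruent trials (cI): a typical performer shows iI < cI (negative
adaptation difference), reflecting up-regulated control after conflict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glm import StatResult
from .group import two_sample_t_from_samples
from .task_design import PAIR_TYPES

__all__ = ["AdaptationResult", "conflict_adaptation", "rt_group_comparisons", "mixed_anova_2x2"]

CONGRUENT_TYPES = ("cC", "iC")
INCONGRUENT_TYPES = ("cI", "iI")


@dataclass(frozen=True)
class AdaptationResult:
    group: str
    adaptation_ms: float  # mean RT(iI) - mean RT(cI)
    per_condition_means: dict[str, float]
    per_condition_ses: dict[str, float]
    n_subjects: int


def _check_table(rt: pd.DataFrame) -> None:
    required = {"subject_id", "group", "pair_type", "mean_rt_ms"}
    missing = required - set(rt.columns)
    if missing:
        raise ValueError(f"RT table missing columns {sorted(missing)}")
    for (g, s), sub in rt.groupby(["group", "subject_id"]):
        absent = set(PAIR_TYPES) - set(sub["pair_type"])
        if absent:
            raise ValueError(
                f"subject {s} ({g}) missing pair types {sorted(absent)}"
            )


def conflict_adaptation(rt: pd.DataFrame) -> dict[str, AdaptationResult]:
    """Per-group condition means/SEs and the iI - cI adaptation difference."""
    _check_table(rt)
    out = {}
    for g, sub in rt.groupby("group"):
        means, ses = {}, {}
        for p in PAIR_TYPES:
            vals = sub.loc[sub["pair_type"] == p, "mean_rt_ms"].to_numpy(dtype=float)
            means[p] = float(vals.mean())
            ses[p] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        out[g] = AdaptationResult(
            group=g,
            adaptation_ms=means["iI"] - means["cI"],
            per_condition_means=means,
            per_condition_ses=ses,
            n_subjects=sub["subject_id"].nunique(),
        )
    return out


def mixed_anova_2x2(rt: pd.DataFrame) -> pd.DataFrame:
    """2 (group, between) x 2 (congruency, within) mixed-design ANOVA.

    Computed on per-subject congruency means (congruent = cC/iC,
    incongruent = cI/iI).  Returns a table with sums of squares, df, F and
    p for the group main effect, the congruency main effect and their
    interaction, plus the two error strata — so the partition
    SS_total = SS_between-cells + SS_subject + SS_error is exact.
    """
    _check_table(rt)
    df = rt.copy()
    df["congruency"] = np.where(
        df["pair_type"].isin(INCONGRUENT_TYPES), "incongruent", "congruent"
    )
    cell = (
        df.groupby(["group", "subject_id", "congruency"])["mean_rt_ms"]
        .mean()
        .reset_index()
    )
    wide = cell.pivot_table(
        index=["group", "subject_id"], columns="congruency", values="mean_rt_ms"
    )
    groups = wide.index.get_level_values("group")
    y = wide.to_numpy()  # subjects x 2 conditions
    n_s, k = y.shape
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    cond_mean = y.mean(axis=0)
    group_labels = np.asarray(groups)
    ss_total = float(((y - grand) ** 2).sum())
    # between-subject stratum
    ss_group = float(
        sum(
            k * np.sum(group_labels == g) * (subj_mean[group_labels == g].mean() - grand) ** 2
            for g in np.unique(group_labels)
        )
    )
    ss_subj_within = float(k * ((subj_mean - np.array(
        [subj_mean[group_labels == g].mean() for g in group_labels]
    )) ** 2).sum())
    # within-subject stratum
    ss_cond = float(n_s * ((cond_mean - grand) ** 2).sum())
    gc_mean = np.vstack(
        [y[group_labels == g].mean(axis=0) for g in np.unique(group_labels)]
    )
    g_sizes = np.array([np.sum(group_labels == g) for g in np.unique(group_labels)])
    g_means = np.array([subj_mean[group_labels == g].mean() for g in np.unique(group_labels)])
    ss_inter = float(
        sum(
            g_sizes[i] * ((gc_mean[i] - g_means[i] - cond_mean + grand) ** 2).sum()
            for i in range(len(g_sizes))
        )
    )
    ss_err_within = ss_total - ss_group - ss_subj_within - ss_cond - ss_inter
    n_groups = len(np.unique(group_labels))
    df_group = n_groups - 1
    df_subj = n_s - n_groups
    df_cond = k - 1
    df_inter = df_group * df_cond
    df_err = df_subj * df_cond
    rows = []

    def add(name, ss, dfx, ss_err, df_err):
        ms = ss / dfx
        mse = ss_err / df_err
        F = ms / mse if mse > 0 else np.inf
        rows.append(
            {
                "effect": name,
                "SS": ss,
                "df": dfx,
                "F": F,
                "p": float(stats.f.sf(F, dfx, df_err)),
            }
        )

    add("group", ss_group, df_group, ss_subj_within, df_subj)
    add("congruency", ss_cond, df_cond, ss_err_within, df_err)
    add("group x congruency", ss_inter, df_inter, ss_err_within, df_err)
    rows.append({"effect": "subjects(group)", "SS": ss_subj_within, "df": df_subj,
                 "F": np.nan, "p": np.nan})
    rows.append({"effect": "error(within)", "SS": ss_err_within, "df": df_err,
                 "F": np.nan, "p": np.nan})
    rows.append({"effect": "total", "SS": ss_total, "df": n_s * k - 1,
                 "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("effect")


def rt_group_comparisons(rt: pd.DataFrame) -> dict:
    """Between-group RT comparisons and the mixed-design ANOVA.

    Returns per-pair-type pooled two-sample t-tests, the same for the
    congruent/incongruent aggregates, and the 2x2 mixed ANOVA table.
    """
    _check_table(rt)
    groups = sorted(rt["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    g1, g2 = groups
    per_condition: dict[str, StatResult] = {}
    degenerate: list[str] = []

    def group_vals(sub, g):
        return sub.loc[sub["group"] == g, "mean_rt_ms"].to_numpy(dtype=float)

    for p in PAIR_TYPES:
        sub = rt[rt["pair_type"] == p]
        a, b = group_vals(sub, g1), group_vals(sub, g2)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 subjects per group")
        scale = max(abs(a.mean()), abs(b.mean()), 1.0)
        if a.std(ddof=1) < 1e-9 * scale and b.std(ddof=1) < 1e-9 * scale:
            degenerate.append(p)
        per_condition[p] = two_sample_t_from_samples(a, b)
    aggregates: dict[str, StatResult] = {}
    df = rt.copy()
    df["congruency"] = np.where(
        df["pair_type"].isin(INCONGRUENT_TYPES), "incongruent", "congruent"
    )
    agg = (
        df.groupby(["group", "subject_id", "congruency"])["mean_rt_ms"]
        .mean()
        .reset_index()
    )
    for c in ("congruent", "incongruent"):
        sub = agg[agg["congruency"] == c]
        aggregates[c] = two_sample_t_from_samples(
            sub.loc[sub["group"] == g1, "mean_rt_ms"].to_numpy(dtype=float),
            sub.loc[sub["group"] == g2, "mean_rt_ms"].to_numpy(dtype=float),
        )
    return {
        "per_condition": per_condition,
        "aggregates": aggregates,
        "anova": mixed_anova_2x2(rt),
        "degenerate_conditions": degenerate,
        "groups": (g1, g2),
    }
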