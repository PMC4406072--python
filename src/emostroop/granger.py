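"""Granger causality indices (GCIs) between ROI time courses.

The GCI of a source for a target is the log ratio of residual sums of
squares of two autoregressive models of the target: a restricted model
using only the target's own past, and a full model that adds the source's
past.  Because the full model nests the restricted one, the GCI is
non-negative.  A mediated variant measures the influence of a source on a
target through a third region (here the thalamus): in the default joint
reading the full model adds the lags of BOTH the mediator and the source;
in the conditional reading the mediator's lags are present in both models,
so only the source's incremental contribution is measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .group import GroupSummary, StatResult, two_sample_t_from_samples

__all__ = [
    "GciEstimate",
    "gci",
    "mediated_gci",
    "select_order_bic",
    "subject_gci_table",
    "gci_group_stats",
]


@dataclass(frozen=True)
class GciEstimate:
    source: tuple[str, ...]
    target: str
    mediator: str | None
    order: int
    gci: float
    rss_restricted: float
    rss_full: float
    n_effective: int


def _lag_matrix(series: np.ndarray, order: int, n_eff: int) -> np.ndarray:
    """Columns are lags 1..order of ``series`` aligned to the last n_eff points."""
    n = len(series)
    return np.column_stack(
        [series[n - n_eff - lag : n - lag] for lag in range(1, order + 1)]
    )


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _validate(series_list, order: int):
    lengths = {len(s) for s in series_list}
    if len(lengths) != 1:
        raise ValueError(f"series lengths differ: {sorted(lengths)}")
    n = lengths.pop()
    if order < 1:
        raise ValueError("order must be >= 1")
    if n < 10 * order:
        raise ValueError(f"series too short: need >= {10 * order} points, got {n}")
    for s in series_list:
        if np.std(s) == 0:
            raise ValueError("constant series has zero variance")
    return n


def gci(
    source_series: np.ndarray,
    target_series: np.ndarray,
    order: int = 1,
    source_name: str = "source",
    target_name: str = "target",
) -> GciEstimate:
    """Granger causality index of ``source`` for ``target``.

    Restricted model: target on its own lags 1..order (+ intercept).
    Full model: adds the source's lags.  gci = ln(RSS_restricted / RSS_full).
    """
    x = np.asarray(source_series, dtype=float)
    y = np.asarray(target_series, dtype=float)
    n = _validate([x, y], order)
    n_eff = n - order
    yt = y[order:]
    ones = np.ones((n_eff, 1))
    Xr = np.hstack([ones, _lag_matrix(y, order, n_eff)])
    Xf = np.hstack([Xr, _lag_matrix(x, order, n_eff)])
    rss_r = _ols_rss(yt, Xr)
    rss_f = _ols_rss(yt, Xf)
    return GciEstimate(
        source=(source_name,),
        target=target_name,
        mediator=None,
        order=order,
        gci=float(np.log(rss_r / rss_f)),
        rss_restricted=rss_r,
        rss_full=rss_f,
        n_effective=n_eff,
    )


def mediated_gci(
    source_series: np.ndarray,
    mediator_series: np.ndarray,
    target_series: np.ndarray,
    order: int = 1,
    mode: str = "joint",
    source_name: str = "source",
    mediator_name: str = "mediator",
    target_name: str = "target",
) -> GciEstimate:
    """GCI of a source for a target through a mediator region.

    mode="joint" (default): restricted = target's own lags; full adds the
    lags of both mediator and source — the combined influence of the pair.
    mode="conditional": restricted also includes the mediator's lags; full
    adds the source's lags — the source's influence beyond the mediator.
    """
    x = np.asarray(source_series, dtype=float)
    z = np.asarray(mediator_series, dtype=float)
    y = np.asarray(target_series, dtype=float)
    n = _validate([x, z, y], order)
    n_eff = n - order
    yt = y[order:]
    ones = np.ones((n_eff, 1))
    own = _lag_matrix(y, order, n_eff)
    med = _lag_matrix(z, order, n_eff)
    src = _lag_matrix(x, order, n_eff)
    if mode == "joint":
        Xr = np.hstack([ones, own])
        Xf = np.hstack([ones, own, med, src])
    elif mode == "conditional":
        Xr = np.hstack([ones, own, med])
        Xf = np.hstack([ones, own, med, src])
    else:
        raise ValueError(f"mode must be 'joint' or 'conditional', got {mode!r}")
    rss_r = _ols_rss(yt, Xr)
    rss_f = _ols_rss(yt, Xf)
    return GciEstimate(
        source=(mediator_name, source_name) if mode == "joint" else (source_name,),
        target=target_name,
        mediator=mediator_name,
        order=order,
        gci=float(np.log(rss_r / rss_f)),
        rss_restricted=rss_r,
        rss_full=rss_f,
        n_effective=n_eff,
    )


def select_order_bic(
    source_series: np.ndarray,
    target_series: np.ndarray,
    max_order: int = 8,
) -> int:
    """Bivariate model order minimising BIC of the full model."""
    x = np.asarray(source_series, dtype=float)
    y = np.asarray(target_series, dtype=float)
    best, best_bic = 1, np.inf
    for order in range(1, max_order + 1):
        n = len(y)
        n_eff = n - max_order  # common sample for fair comparison
        yt = y[max_order:]
        ones = np.ones((n_eff, 1))
        own = _lag_matrix(y, order, n_eff)
        src = _lag_matrix(x, order, n_eff)
        Xf = np.hstack([ones, own, src])
        rss = _ols_rss(yt, Xf)
        k = Xf.shape[1]
        bic = n_eff * np.log(rss / n_eff) + k * np.log(n_eff)
        if bic < best_bic:
            best, best_bic = order, bic
    return best


@dataclass(frozen=True)
class Channel:
    """A requested causality channel: source(s) -> target, optional mediator."""

    source: str
    target: str
    mediator: str | None = None
    mode: str = "joint"

    @property
    def label(self) -> str:
        if self.mediator is None:
            return f"{self.source}->{self.target}"
        if self.mode == "joint":
            return f"{self.mediator} {self.source}->{self.target}"
        return f"{self.source}->{self.target}|{self.mediator}"


def subject_gci_table(
    dataset,
    channels: list[Channel],
    order: int = 1,
) -> pd.DataFrame:
    """Per-subject GCI for every requested channel.

    Returns a DataFrame indexed by subject_id with one column per channel
    label plus a ``group`` column.
    """
    roi_names = dataset.roi_names
    for ch in channels:
        for name in filter(None, (ch.source, ch.target, ch.mediator)):
            if name not in roi_names:
                raise ValueError(
                    f"unknown ROI {name!r}; available: {list(roi_names)}"
                )
    ids, groups, values = [], [], []
    for subj in dataset.subjects:
        ids.append(subj.subject_id)
        groups.append(subj.group)
        series = {name: subj.roi_series[roi_names.index(name)] for name in roi_names}
        row = []
        for ch in channels:
            if ch.mediator is None:
                est = gci(series[ch.source], series[ch.target], order=order,
                          source_name=ch.source, target_name=ch.target)
            else:
                est = mediated_gci(
                    series[ch.source], series[ch.mediator], series[ch.target],
                    order=order, mode=ch.mode, source_name=ch.source,
                    mediator_name=ch.mediator, target_name=ch.target,
                )
            row.append(est.gci)
        values.append(row)
    # duplicate channel labels are preserved as duplicate columns
    table = pd.DataFrame(values, columns=[ch.label for ch in channels],
                         index=pd.Index(ids, name="subject_id"))
    table.insert(0, "group", groups)
    return table


def gci_group_stats(table: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Per-channel group summaries, within-group tests and group comparison.

    For each channel column: per-group mean +/- sd with a two-sided
    one-sample t-test of the subject GCIs against zero, and a pooled
    two-sample t between the groups.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    g1, g2 = groups
    rows = []
    for col in table.columns:
        if col == group_col:
            continue
        a = table.loc[table[group_col] == g1, col].to_numpy(dtype=float)
        b = table.loc[table[group_col] == g2, col].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs n >= 2")
        row = {"channel": col}
        for label, vals in ((g1, a), (g2, b)):
            row[f"mean_{label}"] = vals.mean()
            row[f"sd_{label}"] = vals.std(ddof=1)
            if vals.std(ddof=1) == 0:
                row[f"p_vs_zero_{label}"] = np.nan
                row[f"degenerate_{label}"] = True
            else:
                t1, p1 = stats.ttest_1samp(vals, 0.0)
                row[f"p_vs_zero_{label}"] = float(p1)
                row[f"degenerate_{label}"] = False
        res: StatResult = two_sample_t_from_samples(a, b)
        row["t"] = res.t_value
        row["p"] = res.p_two_sided
        row["dof"] = res.dof
        rows.append(row)
    return pd.DataFrame(rows).set_index("channel")


def group_summary_from_table(
    table: pd.DataFrame, channel: str, group_col: str = "group"
) -> GroupSummary:
    groups = sorted(table[group_col].unique())
    g1, g2 = groups
    a = table.loc[table[group_col] == g1, channel].to_numpy(dtype=float)
    b = table.loc[table[group_col] == g2, channel].to_numpy(dtype=float)
    return GroupSummary(
        float(a.mean()), float(a.std(ddof=1)), len(a),
        float(b.mean()), float(b.std(ddof=1)), len(b),
    )
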