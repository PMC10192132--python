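"""Channel-level group statistics on HFD features.

The unit of analysis is the subject: each subject's HFD values are first
averaged over presentations (and windows) per channel, then compared
between groups — a double mean that avoids pseudo-replicating the 16
presentations as independent observations.  Per channel the contrast is

    delta_ch = mean_subjects(mean_presentations(HFD))_groupA
             - mean_subjects(mean_presentations(HFD))_groupB

with a two-sample Welch t-test (one-sided by default in the direction
novice > expert, the direction the task effect runs in frontal channels),
uncorrected p-values at alpha plus a Benjamini-Hochberg-adjusted column.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import EXPERT, NOVICE, TASK, REST, MontageSpec
from .hfd import HFDTable

__all__ = [
    "subject_channel_means",
    "delta_hfd",
    "channel_tests",
    "top_channels",
    "style_contrast",
    "export_topography",
]

CONTRAST_COLUMNS = ["channel", "delta", "t_stat", "p_value", "p_adj_bh", "significant", "rank"]


def subject_channel_means(
    features: HFDTable,
    condition: str = TASK,
    presentations: Sequence[str] | None = None,
    styles: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-subject, per-channel mean HFD (presentations and windows pooled).

    Returns a frame indexed by subject_id with a ``group`` column and one
    column per channel, channel order as first encountered in the table.
    """
    f = features.frame
    f = f[f["condition"] == condition]
    if presentations is not None:
        f = f[f["presentation_id"].isin(list(presentations))]
    if styles is not None:
        f = f[f["style"].isin(list(styles))]
    if f.empty:
        raise ValueError("no feature rows in scope")
    channel_order = list(pd.unique(f["channel"]))
    wide = (
        f.groupby(["subject_id", "group", "channel"], sort=False)["hfd"]
        .mean()
        .unstack("channel")
        .reindex(columns=channel_order)
    )
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"channels missing for some subjects: {missing}")
    wide = wide.reset_index("group")
    return wide


def delta_hfd(
    features: HFDTable,
    group_a: str = EXPERT,
    group_b: str = NOVICE,
    condition: str = TASK,
    presentations: Sequence[str] | None = None,
) -> pd.Series:
    """Signed per-channel contrast mean(group_a) - mean(group_b) of
    subject-level mean HFD."""
    means = subject_channel_means(features, condition=condition, presentations=presentations)
    for g in (group_a, group_b):
        if not (means["group"] == g).any():
            raise ValueError(f"group {g!r} absent from feature table")
    a = means[means["group"] == group_a].drop(columns="group").mean(axis=0)
    b = means[means["group"] == group_b].drop(columns="group").mean(axis=0)
    return a - b


def _assemble_contrasts(
    channels: Sequence[str],
    delta: np.ndarray,
    t_stat: np.ndarray,
    p_value: np.ndarray,
    alpha: float,
    rank_by: str,
) -> pd.DataFrame:
    p_adj = multipletests(p_value, method="fdr_bh")[1]
    frame = pd.DataFrame({
        "channel": list(channels),
        "delta": delta,
        "t_stat": t_stat,
        "p_value": p_value,
        "p_adj_bh": p_adj,
    })
    frame["significant"] = frame["p_value"] < alpha
    key = frame["delta"].abs() if rank_by == "abs" else frame["delta"]
    # ties broken by channel label for a deterministic ranking
    order = frame.assign(_key=-key).sort_values(["_key", "channel"]).index
    frame["rank"] = 0
    frame.loc[order, "rank"] = np.arange(1, len(frame) + 1)
    return frame[CONTRAST_COLUMNS]


def channel_tests(
    features: HFDTable,
    group_a: str = EXPERT,
    group_b: str = NOVICE,
    alpha: float = 0.05,
    alternative: str = "less",
    condition: str = TASK,
    presentations: Sequence[str] | None = None,
    rank_by: str = "abs",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-channel two-sample t-test of group_a vs group_b subject means.

    ``alternative`` follows scipy's convention for mean(group_a) -
    mean(group_b): the default ``"less"`` tests novice > expert when called
    with the default group order.  Welch's unequal-variance test is used
    unless ``equal_var``.  Channels with zero variance in both groups are
    flagged with NaN statistics rather than failing the whole contrast.
    """
    means = subject_channel_means(features, condition=condition, presentations=presentations)
    a = means[means["group"] == group_a].drop(columns="group")
    b = means[means["group"] == group_b].drop(columns="group")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 subjects per group for a t-test")
    delta = a.mean(axis=0).to_numpy() - b.mean(axis=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(
            a.to_numpy(), b.to_numpy(), axis=0, equal_var=equal_var, alternative=alternative
        )
    t, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} channel(s) had zero within-group variance; "
            "their test statistics are NaN",
            stacklevel=2,
        )
        p[degenerate] = np.nan
    return _assemble_contrasts(a.columns, delta, t, np.nan_to_num(p, nan=1.0), alpha, rank_by)


def top_channels(contrasts: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """The n channels with the largest contrast, by the ranking stored in
    the contrast table (absolute difference by default)."""
    if contrasts.empty:
        raise ValueError("empty contrast table")
    if n > len(contrasts):
        warnings.warn(
            f"requested top {n} of {len(contrasts)} channels; truncating", stacklevel=2
        )
        n = len(contrasts)
    return contrasts.sort_values("rank").head(n).reset_index(drop=True)


def style_contrast(
    features: HFDTable,
    group: str = EXPERT,
    style_a: str = "A",
    style_g: str = "G",
    alpha: float = 0.05,
    alternative: str = "two-sided",
    rank_by: str = "abs",
) -> pd.DataFrame:
    """Algebraic-minus-geometric contrast within one group, paired across
    subjects.

    Per subject and channel, mean HFD over algebraic presentations minus
    mean over geometric ones; the per-channel test is a paired t-test of
    those within-subject differences against zero.  Subjects missing one of
    the styles are excluded with a warning.
    """
    f = features.frame
    f = f[(f["condition"] == TASK) & (f["group"] == group)]
    if f.empty:
        raise ValueError(f"no task rows for group {group!r}")
    means_a = subject_channel_means(features, styles=[style_a])
    means_g = subject_channel_means(features, styles=[style_g])
    means_a = means_a[means_a["group"] == group].drop(columns="group")
    means_g = means_g[means_g["group"] == group].drop(columns="group")
    common = means_a.index.intersection(means_g.index)
    dropped = set(means_a.index).symmetric_difference(means_g.index)
    if dropped:
        warnings.warn(
            f"subjects missing one style excluded from style contrast: {sorted(dropped)}",
            stacklevel=2,
        )
    if len(common) < 2:
        raise ValueError("need at least 2 subjects with both styles")
    diffs = means_a.loc[common] - means_g.loc[common]
    delta = diffs.mean(axis=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_1samp(diffs.to_numpy(), 0.0, axis=0, alternative=alternative)
    t, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    p = np.where(np.isfinite(t), p, 1.0)
    return _assemble_contrasts(diffs.columns, delta, t, p, alpha, rank_by)


def export_topography(contrasts: pd.DataFrame, montage: MontageSpec) -> pd.DataFrame:
    """(channel, delta, p_value) table in montage order, ready for any
    topographic plotting tool; auxiliary channels never appear."""
    by_channel = contrasts.set_index("channel")
    rows = []
    for name in montage.eeg_names:
        if name not in by_channel.index:
            raise ValueError(f"montage channel {name!r} missing from contrasts")
        rows.append({
            "channel": name,
            "delta": float(by_channel.loc[name, "delta"]),
            "p_value": float(by_channel.loc[name, "p_value"]),
        })
    return pd.DataFrame(rows, columns=["channel", "delta", "p_value"])
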