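"""Visualisations for DAWOLS-type trial data.

Every figure has a tidy-table twin: each plotting function first builds a
plain DataFrame and then draws from it, so the numbers behind a figure are
always testable and exportable. Group colours default to the common
convention of control in red and intervention in blue; layouts are
deterministic (fixed orderings, no jitter).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
from matplotlib import cm, colors as mcolors

from .outcome import DataError, arms as arm_levels

ARM_COLORS = ("#c0392b", "#2e6da4", "#27ae60", "#8e44ad", "#d68910")


def _arm_color(i):
    return ARM_COLORS[i % len(ARM_COLORS)]


# ---------------------------------------------------------------------------
# Distribution panels (histograms + min/between/max summary)


def distribution_summary(tables: dict[str, pd.DataFrame], max_days: int) -> pd.DataFrame:
    """Per arm and death-handling variant: median, IQR and the percentages at
    the minimum value, strictly between, and at the maximum value."""
    rows = []
    for variant, df in tables.items():
        vmin = int(df["outcome"].min())
        for arm in arm_levels(df):
            y = np.asarray(df.loc[df["arm"] == arm, "outcome"], dtype=float)
            q1, med, q3 = np.percentile(y, [25, 50, 75])
            rows.append({
                "variant": variant, "arm": arm, "n": len(y),
                "median": med, "q1": q1, "q3": q3,
                "pct_min": 100.0 * (y == vmin).mean(),
                "pct_between": 100.0 * ((y > vmin) & (y < max_days)).mean(),
                "pct_max": 100.0 * (y == max_days).mean(),
            })
    return pd.DataFrame(rows)


def plot_distribution_panels(tables: dict[str, pd.DataFrame], max_days: int):
    """Histogram grid (arm x death-handling variant) with summary annotations.

    ``tables`` maps a variant label (e.g. ``"deaths as 0"``) to a trial table.
    Returns ``(fig, summary)`` where ``summary`` is
    :func:`distribution_summary`'s table.
    """
    summary = distribution_summary(tables, max_days)
    variants = list(tables)
    all_arms = arm_levels(tables[variants[0]])
    fig, axes = plt.subplots(
        len(all_arms), len(variants),
        figsize=(4.2 * len(variants), 2.8 * len(all_arms)),
        squeeze=False, sharex="col",
    )
    for j, variant in enumerate(variants):
        df = tables[variant]
        vmin = int(df["outcome"].min())
        bins = np.arange(vmin - 0.5, max_days + 1.5)
        for i, arm in enumerate(all_arms):
            ax = axes[i][j]
            y = df.loc[df["arm"] == arm, "outcome"]
            ax.hist(y, bins=bins, color=_arm_color(i), edgecolor="white", lw=0.3)
            s = summary[(summary["variant"] == variant) & (summary["arm"] == arm)].iloc[0]
            ax.set_title(
                f"{arm} — {variant}\nmedian {s['median']:.0f} "
                f"(IQR {s['q1']:.0f}–{s['q3']:.0f}); "
                f"min/between/max {s['pct_min']:.0f}/{s['pct_between']:.0f}/{s['pct_max']:.0f}%",
                fontsize=8,
            )
            ax.set_ylabel("patients")
    for ax in axes[-1]:
        ax.set_xlabel("days")
    fig.tight_layout()
    return fig, summary


# ---------------------------------------------------------------------------
# Cumulative percentage curves


def cumulative_pct_table(data: pd.DataFrame) -> pd.DataFrame:
    """Per arm: percentage of patients with an outcome <= each distinct value."""
    values = np.sort(data["outcome"].unique())
    rows = []
    for arm in arm_levels(data):
        y = np.asarray(data.loc[data["arm"] == arm, "outcome"], dtype=float)
        for v in values:
            rows.append({"arm": arm, "value": v,
                         "cum_pct": 100.0 * (y <= v).mean()})
    return pd.DataFrame(rows)


def plot_cumulative_pct(data: pd.DataFrame):
    """Step curves of the cumulative percentage of patients per value."""
    table = cumulative_pct_table(data)
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, arm in enumerate(arm_levels(data)):
        sub = table[table["arm"] == arm]
        ax.step(sub["value"], sub["cum_pct"], where="post",
                label=arm, color=_arm_color(i))
    ax.set_xlabel("days alive without life support")
    ax.set_ylabel("cumulative % of patients (Y ≤ value)")
    ax.set_ylim(0, 105)
    ax.legend()
    fig.tight_layout()
    return fig, table


# ---------------------------------------------------------------------------
# Value heat map (overturned stacked bar)


def value_heatmap_table(data: pd.DataFrame) -> pd.DataFrame:
    """Per arm: proportion of patients at each outcome value (ascending)."""
    if (data["outcome"] < 0).any():
        raise DataError("heat map expects deaths coded as 0 days")
    values = np.sort(data["outcome"].unique())
    rows = []
    for arm in arm_levels(data):
        y = np.asarray(data.loc[data["arm"] == arm, "outcome"])
        n = len(y)
        for v in values:
            rows.append({"arm": arm, "value": int(v),
                         "proportion": float((y == v).sum() / n)})
    return pd.DataFrame(rows)


def plot_value_heatmap(data: pd.DataFrame, max_days: int):
    """One horizontal stacked bar per arm; segment width = proportion at the
    value, red-to-blue gradient from worst (0) to best (max_days)."""
    table = value_heatmap_table(data)
    cmap = cm.get_cmap("RdYlBu") if hasattr(cm, "get_cmap") else plt.get_cmap("RdYlBu")
    norm = mcolors.Normalize(vmin=0, vmax=max_days)
    arms_ = arm_levels(data)
    fig, ax = plt.subplots(figsize=(7, 1.0 + 0.6 * len(arms_)))
    for i, arm in enumerate(arms_):
        sub = table[table["arm"] == arm].sort_values("value")
        left = 0.0
        for _, row in sub.iterrows():
            ax.barh(i, row["proportion"], left=left,
                    color=cmap(norm(row["value"])), edgecolor="none")
            left += row["proportion"]
    ax.set_yticks(range(len(arms_)), arms_)
    ax.set_xlabel("proportion of patients")
    ax.set_xlim(0, 1)
    sm = cm.ScalarMappable(norm=norm, cmap=cmap)
    fig.colorbar(sm, ax=ax, orientation="horizontal", label="days", pad=0.25)
    fig.tight_layout()
    return fig, table


# ---------------------------------------------------------------------------
# Daily state occupancy


def state_occupancy(daily: pd.DataFrame, arm_of: pd.Series | dict) -> pd.DataFrame:
    """Per arm and day: proportion of patients in each state (rows sum to 1).

    ``arm_of`` maps patient_id to arm (a Series indexed by patient_id, a
    dict, or a trial table with patient_id/arm columns).
    """
    from .outcome import STATES, validate_daily

    if isinstance(arm_of, pd.DataFrame):
        arm_of = arm_of.set_index("patient_id")["arm"]
    daily = validate_daily(daily)
    arm = daily["patient_id"].map(arm_of)
    if arm.isna().any():
        raise DataError("daily table contains patients with no arm assignment")
    counts = (
        pd.DataFrame({"arm": arm, "day": daily["day"], "state": daily["state"], "n": 1})
        .pivot_table(index=["arm", "day"], columns="state", values="n",
                     aggfunc="sum", fill_value=0, observed=True)
    )
    for st in STATES:
        if st not in counts.columns:
            counts[st] = 0
    counts = counts[list(STATES)]
    props = counts.div(counts.sum(axis=1), axis=0).reset_index()
    return props


def plot_state_occupancy(so: pd.DataFrame):
    """Stacked-area plot of daily state proportions, one panel per arm."""
    state_colors = {"home": "#2e6da4", "hospital": "#85c1e9",
                    "life_support": "#f1c40f", "dead": "#555555"}
    arms_ = list(pd.unique(so["arm"]))
    fig, axes = plt.subplots(1, len(arms_), figsize=(5 * len(arms_), 3.5),
                             squeeze=False, sharey=True)
    order = ["home", "hospital", "life_support", "dead"]
    for i, arm in enumerate(arms_):
        sub = so[so["arm"] == arm].sort_values("day")
        axes[0][i].stackplot(sub["day"], [sub[s] for s in order],
                             labels=order, colors=[state_colors[s] for s in order])
        axes[0][i].set_title(str(arm))
        axes[0][i].set_xlabel("day after randomisation")
        axes[0][i].set_ylim(0, 1)
    axes[0][0].set_ylabel("proportion of patients")
    axes[0][-1].legend(loc="center left", bbox_to_anchor=(1, 0.5), fontsize=8)
    fig.tight_layout()
    return fig


def save_figure(fig, path_stem) -> list[str]:
    """Export a figure as both PNG and SVG; returns the written paths."""
    paths = []
    for ext in ("png", "svg"):
        p = f"{path_stem}.{ext}"
        fig.savefig(p, dpi=150)
        paths.append(p)
    return paths
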