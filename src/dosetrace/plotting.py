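"""Static figure export: impact scatter, phospho-response scatter + pie,
and per-site fitted-curve panels.

Plotting is read-only — it never alters result tables.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

CATEGORY_COLORS = {
    "hyper": "#d62728",     # red
    "hypo": "#1f77b4",      # blue
    "biphasic": "#e8b339",  # yellow
    "NR": "#b0b0b0",        # grey
}


def plot_proteome_impact(impact: pd.DataFrame, path, hit_threshold: float = 0.5) -> Path:
    """Scatter of per-protein average slope at 37 °C vs 52 °C.

    Hits are annotated; kinases drawn in beige."""
    fig, ax = plt.subplots(figsize=(6, 6))
    if not impact.empty:
        base = impact[~impact["is_hit"].astype(bool)]
        hits = impact[impact["is_hit"].astype(bool)]
        ax.scatter(base["slope_37"], base["slope_52"], s=10, c="#c8c8c8", label="protein")
        if not hits.empty:
            kin = hits[hits["is_kinase"].astype(bool)]
            non = hits[~hits["is_kinase"].astype(bool)]
            ax.scatter(non["slope_37"], non["slope_52"], s=22, c="#2ca02c", label="hit")
            if not kin.empty:
                ax.scatter(kin["slope_37"], kin["slope_52"], s=26, c="#d9b382",
                           edgecolors="k", linewidths=0.4, label="kinase hit")
        ax.legend(loc="best", fontsize=8)
    for v in (hit_threshold, -hit_threshold):
        ax.axvline(v, ls="--", lw=0.6, c="grey")
        ax.axhline(v, ls="--", lw=0.6, c="grey")
    ax.set_xlabel("average slope, 37 °C (abundance)")
    ax.set_ylabel("average slope, 52 °C (thermal stability)")
    ax.set_title("Proteome impact")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_phospho_response(phospho: pd.DataFrame, path) -> Path:
    """Scatter of sites by upward intervals vs mean slope, colored by
    category, with a pie inset of the global category proportions."""
    fig, ax = plt.subplots(figsize=(7, 6))
    if not phospho.empty:
        for cat, color in CATEGORY_COLORS.items():
            sub = phospho[phospho["final_category"] == cat]
            if not sub.empty:
                ax.scatter(sub["upward_intervals"], sub["mean_slope"], s=12,
                           c=color, label=cat, alpha=0.8)
        counts = phospho["final_category"].value_counts()
        inset = fig.add_axes([0.72, 0.72, 0.24, 0.24])
        inset.pie(counts.values,
                  colors=[CATEGORY_COLORS.get(c, "#999999") for c in counts.index],
                  wedgeprops={"linewidth": 0.3, "edgecolor": "white"})
        inset.set_title("proportions", fontsize=7)
        ax.legend(loc="lower right", fontsize=8)
    ax.set_xlabel("number of continuous upward intervals")
    ax.set_ylabel("average slope, 37 °C")
    ax.set_title("Phospho response")
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_site_curves(site_calls, path, max_panels: int = 12) -> Path:
    """Per-site panels of observed points and the two replicate fits."""
    calls = list(site_calls)[:max_panels]
    n = max(len(calls), 1)
    ncols = min(4, n)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows),
                             squeeze=False)
    for ax in axes.flat:
        ax.set_axis_off()
    for ax, call in zip(axes.flat, calls):
        ax.set_axis_on()
        color = CATEGORY_COLORS.get(call.final_category.value, "#999999")
        for curve, line_color in zip(call.rep_curves, ("#2ca02c", "#8c564b")):
            ax.plot(curve.x, curve.y, "o", ms=3, c=line_color, alpha=0.5)
            ax.plot(curve.x, curve.y_hat, "-", c=line_color, lw=1.2)
        ax.set_title(f"{call.entity_id} ({call.final_category.value})",
                     fontsize=8, color=color)
        ax.set_xlabel("dose position", fontsize=7)
        ax.set_ylabel("fold change", fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
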