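"""Figure rendering. Figures are derived views: every figure is drawn from a
data frame the pipeline has already written to CSV."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _save(fig, path: str | Path) -> None:
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def plot_embedding(coords: pd.DataFrame, labels: pd.Series, path: str | Path, title: str) -> None:
    """Scatter of the 2-D projection colored by cluster label."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for c in sorted(labels.unique()):
        sel = coords.loc[labels.index[labels == c]]
        ax.scatter(sel["x"], sel["y"], s=8, alpha=0.6, label=f"{c}")
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title(title)
    ax.legend(title="cluster", fontsize=8)
    _save(fig, path)


def plot_factor_map(factor_map: pd.DataFrame, path: str | Path) -> None:
    """Arrows per variable with the inner (0.5) and outer (0.75) rings."""
    fig, ax = plt.subplots(figsize=(6, 6))
    for radius, style in ((0.5, ":"), (0.75, "--"), (1.0, "-")):
        ax.add_patch(plt.Circle((0, 0), radius, fill=False, linestyle=style, color="grey"))
    colors = {"outer": "tab:red", "middle": "tab:orange", "inner": "tab:blue"}
    for _, row in factor_map.iterrows():
        ax.annotate(
            "",
            xy=(row["r1"], row["r2"]),
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color=colors[row["ring"]], lw=0.8),
        )
    lim = max(1.05, factor_map["magnitude"].max() + 0.05)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.set_xlabel("correlation with dim 1")
    ax.set_ylabel("correlation with dim 2")
    ax.set_title("factor map")
    _save(fig, path)


def plot_core_hulls(hull_records: pd.DataFrame, path: str | Path) -> None:
    """Medoid positions and core-hull outlines at both timepoints.

    ``hull_records`` columns: phenotype, timepoint, x, y (polygon vertices in
    draw order) plus medoid_x/medoid_y repeated per row.
    """
    fig, ax = plt.subplots(figsize=(6, 5))
    cmap = plt.get_cmap("tab10")
    for (pheno, tp), grp in hull_records.groupby(["phenotype", "timepoint"]):
        color = cmap((int(pheno) - 1) % 10)
        style = "-" if tp == "t0" else "--"
        verts = grp[["x", "y"]].to_numpy()
        if len(verts) >= 2:
            closed = np.vstack([verts, verts[:1]])
            ax.plot(closed[:, 0], closed[:, 1], style, color=color,
                    label=f"PT{pheno} {tp}", lw=1.2)
        ax.scatter(
            grp["medoid_x"].iloc[0], grp["medoid_y"].iloc[0],
            marker="o" if tp == "t0" else "s", color=color, zorder=5,
        )
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title("medoids and core hulls")
    ax.legend(fontsize=7)
    _save(fig, path)


def plot_transitions(links: pd.DataFrame, sizes_t0: pd.Series, sizes_t1: pd.Series, path: str | Path) -> None:
    """Two-column flow diagram of phenotype transitions (links already filtered)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    clusters = sorted(set(sizes_t0.index) | set(sizes_t1.index))
    y0 = {c: -i for i, c in enumerate(clusters)}
    cmap = plt.get_cmap("tab10")
    for c in clusters:
        ax.text(0, y0[c], f"PT{c} ({int(sizes_t0.get(c, 0))})", ha="right", va="center")
        ax.text(1, y0[c], f"PT{c} ({int(sizes_t1.get(c, 0))})", ha="left", va="center")
    for _, row in links.iterrows():
        a, b = row["from"], row["to"]
        ax.plot(
            [0.02, 0.98],
            [y0[a], y0[b]],
            lw=max(0.5, 20 * row["share"]),
            alpha=0.5,
            color=cmap((int(a) - 1) % 10),
        )
    ax.set_xlim(-0.35, 1.35)
    ax.axis("off")
    ax.set_title("phenotype transitions t0 → t1")
    _save(fig, path)


def plot_radial_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """Per-phenotype polar bar chart of t0/t1 variable means."""
    phenos = sorted(summary["phenotype"].unique())
    fig, axes = plt.subplots(
        1, len(phenos), figsize=(4 * len(phenos), 4), subplot_kw={"projection": "polar"}
    )
    axes = np.atleast_1d(axes)
    for ax, pheno in zip(axes, phenos):
        grp = summary[summary["phenotype"] == pheno]
        theta = np.linspace(0, 2 * np.pi, len(grp), endpoint=False)
        width = 2 * np.pi / len(grp) * 0.4
        ax.bar(theta - width / 2, grp["mean_t0"], width=width, label="t0", alpha=0.7)
        ax.bar(theta + width / 2, grp["mean_t1"], width=width, label="t1", alpha=0.7)
        ax.set_xticks([])
        ax.set_title(f"PT{pheno}", fontsize=10)
    axes[0].legend(fontsize=7, loc="lower left")
    _save(fig, path)


def plot_pathway_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    """Line chart of within-pathway mean change per variable."""
    fig, ax = plt.subplots(figsize=(12, 4))
    for pathway, row in profiles.iterrows():
        ax.plot(range(len(row)), row.to_numpy(), marker=".", lw=0.8, label=f"PC{pathway}")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xticks(range(len(profiles.columns)))
    ax.set_xticklabels(profiles.columns, rotation=90, fontsize=5)
    ax.set_ylabel("mean Δ(t0,t1)")
    ax.legend(fontsize=7)
    _save(fig, path)


def plot_mosaic(counts: pd.DataFrame, pct: pd.DataFrame, path: str | Path) -> None:
    """Mosaic of phenotype x pathway patient counts."""
    fig, ax = plt.subplots(figsize=(7, 5))
    total = counts.to_numpy().sum()
    x = 0.0
    cmap = plt.get_cmap("tab10")
    for pheno in counts.index:
        width = counts.loc[pheno].sum() / total
        y = 0.0
        for j, pathway in enumerate(counts.columns):
            height = counts.at[pheno, pathway] / max(counts.loc[pheno].sum(), 1)
            ax.add_patch(
                plt.Rectangle((x, y), width * 0.97, height * 0.97, color=cmap(j % 10), alpha=0.8)
            )
            if height > 0.04:
                ax.text(
                    x + width / 2, y + height / 2, f"{pct.at[pheno, pathway]:.1f}%",
                    ha="center", va="center", fontsize=7,
                )
            y += height
        ax.text(x + width / 2, 1.02, f"PT{pheno}", ha="center", fontsize=9)
        x += width
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.06)
    ax.axis("off")
    ax.set_title("phenotype x pathway of change")
    _save(fig, path)
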