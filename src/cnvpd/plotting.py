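"""Minimal figure exports: per-pair V_ST Manhattan plots and the mean-V_ST
heatmap. Plots are deliberately plain; the TSV of plotted points is written
alongside each image so the figure is reproducible from text."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .models import Cnvr


def manhattan_points(vst_long: pd.DataFrame, cnvrs: list[Cnvr]) -> pd.DataFrame:
    """Per (pair, CNVR) plotting table; x is the CNVR midpoint."""
    mid = {r.cnvr_id: (r.chrom, (r.start + r.end) // 2) for r in cnvrs}
    df = vst_long.copy()
    df["chrom"] = df["cnvr_id"].map(lambda i: mid[i][0])
    df["midpoint"] = df["cnvr_id"].map(lambda i: mid[i][1])
    return df[["pop_a", "pop_b", "cnvr_id", "chrom", "midpoint", "vst"]]


def plot_manhattan(
    points: pd.DataFrame,
    out_prefix: str,
    thresholds: dict[float, float] | None = None,
) -> list[str]:
    """One Manhattan panel per population pair; returns written image paths."""
    written = []
    chrom_order = sorted(points["chrom"].unique())
    offsets = {}
    off = 0
    for c in chrom_order:
        offsets[c] = off
        off += int(points.loc[points["chrom"] == c, "midpoint"].max()) + 1
    for (a, b), grp in points.groupby(["pop_a", "pop_b"]):
        fig, ax = plt.subplots(figsize=(8, 2.5))
        x = grp["midpoint"] + grp["chrom"].map(offsets)
        colors = [("#4477aa" if i % 2 else "#66ccee") for i in grp["chrom"].map(
            {c: k for k, c in enumerate(chrom_order)}
        )]
        ax.scatter(x, grp["vst"], s=4, c=colors)
        if thresholds:
            for q, thr in thresholds.items():
                ax.axhline(thr, lw=0.8, color="green" if q < 0.995 else "red")
        ax.set_ylim(0, 1.05)
        ax.set_ylabel("V_ST")
        ax.set_title(f"{a} - {b}")
        path = f"{out_prefix}.{a}-{b}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written


def plot_mean_vst_heatmap(mean_matrix: pd.DataFrame, out_path: str) -> str:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mean_matrix.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(mean_matrix.columns)))
    ax.set_xticklabels(mean_matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(mean_matrix.index)))
    ax.set_yticklabels(mean_matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="mean V_ST")
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path
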