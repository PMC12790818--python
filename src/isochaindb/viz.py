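"""Figure rendering for query outputs.

Every renderer writes the figure plus a machine-readable TSV sidecar of
the plotted values (same path with a ``.tsv`` suffix appended), so tests
and users can check data rather than pixels. No query logic lives here.

Category order and palette are fixed for reproducible figures.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .io_formats import STRUCTURAL_CATEGORIES
from .queries import IntersectionSummary

CATEGORY_ORDER = list(STRUCTURAL_CATEGORIES)
CATEGORY_PALETTE = {
    "full-splice_match": "#6baed6",
    "incomplete-splice_match": "#fd8d3c",
    "novel_in_catalog": "#74c476",
    "novel_not_in_catalog": "#e377c2",
    "genic": "#9e9ac8",
    "antisense": "#a55194",
    "fusion": "#ce6dbd",
    "intergenic": "#969696",
    "genic_intron": "#8c6d31",
}


def _sidecar(path: Path, df: pd.DataFrame) -> Path:
    side = path.with_suffix(path.suffix + ".tsv")
    df.to_csv(side, sep="\t")
    return side


def render_category_bars(summary: pd.DataFrame, weight: str, path: str | Path) -> Path:
    """Stacked bar per experiment, one segment per structural category."""
    if summary.empty:
        raise ValueError("empty category summary; nothing to plot")
    path = Path(path)
    summary = summary.reindex(columns=CATEGORY_ORDER, fill_value=0.0)
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(summary), 4.5))
    bottom = pd.Series(0.0, index=summary.index)
    for cat in CATEGORY_ORDER:
        vals = summary[cat]
        if (vals > 0).any():
            ax.bar(summary.index, vals, bottom=bottom, label=cat,
                   color=CATEGORY_PALETTE[cat])
        bottom += vals
    ax.set_ylabel(f"proportion of {weight}")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    _sidecar(path, summary)
    return path


def render_upset(
    intersections: list[IntersectionSummary], path: str | Path
) -> Path:
    """UpSet-style plot: stacked intersection-size bars over a membership
    dot matrix, bars in the given order, stacks colored by category."""
    if not intersections:
        raise ValueError("no intersections to plot")
    path = Path(path)
    all_exps = sorted({e for s in intersections for e in s.member_set})
    n = len(intersections)
    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(1.5 + 0.6 * n, 5.5),
        height_ratios=[3, 1], sharex=True,
    )
    xs = range(n)
    bottom = [0.0] * n
    for cat in CATEGORY_ORDER:
        heights = [s.category_breakdown.get(cat, 0) for s in intersections]
        if any(heights):
            ax_bar.bar(xs, heights, bottom=bottom, label=cat,
                       color=CATEGORY_PALETTE[cat])
            bottom = [b + h for b, h in zip(bottom, heights)]
    ax_bar.set_ylabel("intersection size")
    ax_bar.legend(fontsize=6, bbox_to_anchor=(1.02, 1), loc="upper left")
    for x, s in enumerate(intersections):
        for y, e in enumerate(all_exps):
            inside = e in s.member_set
            ax_dot.plot(x, y, "o", color="black" if inside else "#dddddd",
                        markersize=6)
        ys = [all_exps.index(e) for e in s.member_set]
        if len(ys) > 1:
            ax_dot.plot([x, x], [min(ys), max(ys)], "-", color="black", lw=1.5)
    ax_dot.set_yticks(range(len(all_exps)), all_exps, fontsize=7)
    ax_dot.set_xticks([])
    ax_dot.set_ylim(-0.5, len(all_exps) - 0.5)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    rows = []
    for s in intersections:
        row = {"members": "&".join(sorted(s.member_set)), "size": s.size}
        row.update({c: s.category_breakdown.get(c, 0) for c in CATEGORY_ORDER})
        rows.append(row)
    _sidecar(path, pd.DataFrame(rows).set_index("members"))
    return path


def render_ends(
    starts: pd.DataFrame, ends: pd.DataFrame, path: str | Path
) -> Path:
    """Start/end coordinate read-support proportions, one series per sample."""
    if starts.empty and ends.empty:
        raise ValueError("no ends data to plot")
    path = Path(path)
    fig, (ax_s, ax_e) = plt.subplots(1, 2, figsize=(9, 3.8))
    for ax, table, label in ((ax_s, starts, "start"), (ax_e, ends, "end")):
        for exp in table.index:
            row = table.loc[exp]
            ax.plot(row.index, row.values, "o-", label=exp)
        ax.set_xlabel(f"{label} coordinate")
        ax.set_ylabel("proportion of reads")
        ax.set_ylim(0, 1.05)
    ax_s.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    combined = pd.concat({"start": starts, "end": ends}, names=["side"])
    _sidecar(path, combined)
    return path


def render_gene_prop(
    proportions: pd.DataFrame, totals: pd.Series, gene: str, path: str | Path
) -> Path:
    """Stacked per-group isoform read proportions; group totals annotated."""
    if proportions.empty:
        raise ValueError("no proportions to plot")
    path = Path(path)
    fig, ax = plt.subplots(figsize=(1.5 + 0.9 * len(proportions), 4.5))
    bottom = pd.Series(0.0, index=proportions.index)
    for label in proportions.columns:
        ax.bar(proportions.index, proportions[label], bottom=bottom, label=label)
        bottom += proportions[label]
    for i, grp in enumerate(proportions.index):
        ax.text(i, 1.02, str(int(totals.loc[grp])), ha="center", fontsize=8)
    ax.set_ylabel("proportion of reads")
    ax.set_title(gene)
    ax.set_ylim(0, 1.12)
    ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    side = proportions.copy()
    side["total_reads"] = totals
    _sidecar(path, side)
    return path
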