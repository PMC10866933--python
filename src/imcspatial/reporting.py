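"""Figures and the machine-readable run report.

Every figure has a CSV twin written beside it: figures are views, the CSVs
are the record. The run report is a versioned JSON snapshot of the
configuration, the per-stage seeds, the headline counts, and every artifact
the run emitted.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap

__all__ = [
    "render_cluster_heatmap",
    "render_pdr_heatmap",
    "render_feature_map",
    "render_zone_figure",
    "emit_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1

#: 0 = closest pair (yellow) .. 1 = furthest pair (black)
PDR_CMAP = LinearSegmentedColormap.from_list("pdr", [(1.0, 0.9, 0.1), (0.0, 0.0, 0.0)])


def render_cluster_heatmap(
    signatures: pd.DataFrame, out_path: str | Path | None = None
) -> plt.Figure:
    """Clusters × markers heatmap of scaled mean expression, diverging
    colormap centered at 0."""
    if signatures.size == 0:
        raise ValueError("empty signature matrix")
    vmax = max(float(np.abs(signatures.to_numpy()).max()), 1e-9)
    fig, ax = plt.subplots(
        figsize=(max(6, 0.3 * signatures.shape[1]), max(4, 0.3 * signatures.shape[0]))
    )
    im = ax.imshow(signatures.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(signatures.shape[1]), signatures.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(signatures.shape[0]), [str(i) for i in signatures.index], fontsize=7)
    ax.set_xlabel("marker")
    ax.set_ylabel("cluster")
    fig.colorbar(im, ax=ax, label="scaled mean expression")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig


def render_pdr_heatmap(
    pdr_matrix: pd.DataFrame, out_path: str | Path | None = None
) -> plt.Figure:
    """Symmetric PDR heatmap, yellow (0, closest pair) to black (1,
    furthest); missing entries hatched."""
    mat = pdr_matrix.to_numpy(float)
    n = len(pdr_matrix)
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * n + 2),) * 2)
    masked = np.ma.masked_invalid(mat)
    im = ax.imshow(masked, cmap=PDR_CMAP, vmin=0.0, vmax=1.0)
    # hatch the missing cells
    for i in range(n):
        for j in range(n):
            if np.isnan(mat[i, j]):
                ax.add_patch(
                    plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=True,
                                  facecolor="0.85", hatch="///", edgecolor="0.6",
                                  linewidth=0)
                )
    ax.set_xticks(range(n), pdr_matrix.columns, rotation=90, fontsize=8)
    ax.set_yticks(range(n), pdr_matrix.index, fontsize=8)
    cbar = fig.colorbar(im, ax=ax, ticks=[0, 1])
    cbar.ax.set_yticklabels(["0 (closest)", "1 (furthest)"])
    cbar.set_label("pairwise distance rank")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig


def render_feature_map(
    nodes: pd.DataFrame, edges: pd.DataFrame, out_path: str | Path | None = None
) -> plt.Figure:
    """PDR feature map: nodes at their embedding coordinates, size by
    frequency, color by row-mean PDR; edge opacity 1 - PDR."""
    fig, ax = plt.subplots(figsize=(6, 6))
    pos = {p: (nodes.loc[p, "x"], nodes.loc[p, "y"]) for p in nodes.index}
    for e in edges.itertuples(index=False):
        (x0, y0), (x1, y1) = pos[e.phenotype_a], pos[e.phenotype_b]
        ax.plot([x0, x1], [y0, y1], color="k", alpha=max(0.0, min(1.0, e.weight)),
                linewidth=1.5, zorder=1)
    sc = ax.scatter(
        nodes["x"], nodes["y"], s=3000 * nodes["size"].to_numpy() + 30,
        c=nodes["color"], cmap=PDR_CMAP, vmin=0, vmax=1, zorder=2,
        edgecolors="white",
    )
    for p in nodes.index:
        ax.annotate(str(p), pos[p], fontsize=8, ha="center", va="bottom",
                    xytext=(0, 6), textcoords="offset points")
    fig.colorbar(sc, ax=ax, label="row-mean PDR")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig


def render_zone_figure(
    table: pd.DataFrame,
    rgb: pd.DataFrame,
    roi: str,
    out_path: str | Path | None = None,
) -> plt.Figure:
    """Interaction-zone rendering of one ROI: each cell drawn at its
    centroid, colored by its RGB zone channels; white marks three-way
    co-proximity."""
    m = (table["roi_id"] == roi).to_numpy()
    sub = table[m]
    colors = rgb.loc[sub.index, ["R", "G", "B"]].to_numpy()
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.set_facecolor("black")
    # marker area roughly proportional to cell area
    ax.scatter(sub["x_um"], sub["y_um"], c=np.clip(colors, 0, 1),
               s=sub["area_um2"].to_numpy() * 0.2, linewidths=0)
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention: y down
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title(f"interaction zones — {roi}")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig


def emit_report(
    out_path: str | Path,
    config: dict,
    seeds: dict,
    counts: dict,
    artifacts: dict[str, str | Path],
    version: str = "0.1.0",
) -> dict:
    """Write the run report JSON. Every artifact path must exist; a missing
    one raises ``FileNotFoundError`` naming it."""
    missing = [name for name, p in artifacts.items() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing stage outputs: {', '.join(sorted(missing))}")
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software_version": version,
        "config": config,
        "seeds": seeds,
        "counts": counts,
        "artifacts": {k: str(v) for k, v in sorted(artifacts.items())},
    }
    Path(out_path).write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report
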