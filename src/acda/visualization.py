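"""Plotting: synergy-arc dendrogram and clustered prediction heatmap.

The dendrogram tool clusters drugs by monotherapy-derived distance (Ward on
cosine-similarity profiles, as in the distance pipeline), cuts the tree into
at most 10 groups, and draws the known synergy pairs as arcs connecting the
leaf positions.  Lighter arcs mean a smaller cophenetic distance between the
paired drugs; darker arcs a larger one.  This makes it easy to see whether
known synergistic pairs tend to sit far apart in sensitivity space.

The heatmap tool shows a (pairs x models) score table reordered by
hierarchical clustering on both margins.  Figures contain no randomness:
identical inputs give identical artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from matplotlib import colors as mcolors
from matplotlib.patches import Arc
from scipy.cluster import hierarchy

from .data_model import MonotherapyMatrix, ValidationError
from .drug_distance import drug_drug_distance

__all__ = ["DendrogramArcFigure", "plot_synergy_dendrogram", "plot_prediction_heatmap"]

logger = logging.getLogger(__name__)

MAX_CLUSTERS = 10


@dataclass
class ArcSpec:
    """One synergy arc: leaf positions, distance and its rendered color."""

    drug_a: str
    drug_b: str
    x_a: float
    x_b: float
    coph_dist: float
    color_value: float  # normalized distance in [0, 1]; larger = darker
    rgba: tuple[float, float, float, float]

    @property
    def luminance(self) -> float:
        """Perceptual lightness of the arc color (1 = white)."""
        r, g, b, _ = self.rgba
        return 0.2126 * r + 0.7152 * g + 0.0722 * b


@dataclass
class DendrogramArcFigure:
    """Inspectable figure model returned by :func:`plot_synergy_dendrogram`."""

    leaf_order: list[str]
    cluster_assignment: pd.Series
    arcs: list[ArcSpec]
    dropped_pairs: list[tuple[str, str]]
    figure: plt.Figure

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_assignment.nunique())


def plot_synergy_dendrogram(
    monotherapy: MonotherapyMatrix,
    synergy_pairs: list[tuple[str, str]],
    out_path: str | Path | None = None,
    cmap: str = "Greys",
) -> DendrogramArcFigure:
    """Drug dendrogram with known synergy pairs drawn as arcs.

    Pairs referencing drugs absent from the monotherapy matrix are dropped
    with a logged warning.  The tree is cut into ``min(10, n - 1)`` flat
    clusters; arc colors map the pair's cophenetic distance through a
    monotone light-to-dark scale.
    """
    coph, tree = drug_drug_distance(monotherapy, return_tree=True)
    n = tree.n_leaves
    n_clusters = min(MAX_CLUSTERS, n - 1)
    clusters = tree.cut(n_clusters)
    leaf_order = tree.leaf_order
    # scipy places leaf i at x = 5 + 10*i
    xpos = {drug: 5.0 + 10.0 * i for i, drug in enumerate(leaf_order)}

    known = set(monotherapy.drug_ids)
    kept, dropped = [], []
    for a, b in synergy_pairs:
        (kept if a in known and b in known else dropped).append((a, b))
    if dropped:
        logger.warning("dropping %d synergy pair(s) with unclustered drugs: %s",
                       len(dropped), dropped[:5])

    dists = [float(coph.at[a, b]) for a, b in kept]
    lo = min(dists) if dists else 0.0
    hi = max(dists) if dists else 1.0
    norm = mcolors.Normalize(vmin=lo, vmax=hi if hi > lo else lo + 1.0)
    colormap = plt.get_cmap(cmap)

    fig, (ax_arc, ax_den) = plt.subplots(
        2, 1, figsize=(max(6, 0.45 * n), 6), sharex=True,
        gridspec_kw={"height_ratios": [1, 2], "hspace": 0.05},
    )
    hierarchy.dendrogram(
        tree.linkage, labels=list(tree.ids), ax=ax_den,
        color_threshold=None, leaf_rotation=90,
    )
    ax_den.set_ylabel("Ward merge height")

    arcs: list[ArcSpec] = []
    span_max = 10.0 * max(n - 1, 1)
    for (a, b), dist in zip(kept, dists):
        value = float(norm(dist))
        # clip into the visible part of the ramp so "light" is never white
        rgba = colormap(0.15 + 0.8 * value)
        x1, x2 = sorted((xpos[a], xpos[b]))
        center, width = (x1 + x2) / 2.0, x2 - x1
        height = 0.9 * width / span_max  # vertical extent tracks leaf span
        ax_arc.add_patch(
            Arc((center, 0), width, 2 * height, theta1=0, theta2=180,
                color=rgba, lw=1.5)
        )
        arcs.append(ArcSpec(a, b, xpos[a], xpos[b], dist, value, tuple(rgba)))
    ax_arc.set_xlim(0, 10.0 * n)
    ax_arc.set_ylim(0, 1.05)
    ax_arc.set_yticks([])
    ax_arc.set_title(
        "Known synergy pairs (lighter arc = smaller cophenetic distance)"
    )

    result = DendrogramArcFigure(
        leaf_order=leaf_order,
        cluster_assignment=clusters,
        arcs=arcs,
        dropped_pairs=dropped,
        figure=fig,
    )
    if out_path is not None:
        fig.savefig(out_path, bbox_inches="tight", dpi=150)
        plt.close(fig)
    return result


def plot_prediction_heatmap(
    score_table: pd.DataFrame,
    out_path: str | Path | None = None,
    cmap: str = "vlag",
) -> sns.matrix.ClusterGrid:
    """Clustered heatmap of predicted synergy (pairs x models).

    Rows and columns are reordered by Ward clustering of Euclidean score
    profiles (matching the distance pipeline), with dendrograms attached on
    both margins.  Inputs are canonically sorted by label first, so the
    rendered ordering does not depend on the incoming row/column order.
    NaN cells are masked in the display and mean-imputed for clustering only.
    """
    if score_table.empty:
        raise ValidationError("score table is empty; nothing to plot")
    data = score_table.sort_index().sort_index(axis=1)
    mask = data.isna()
    filled = data.apply(lambda col: col.fillna(data.stack().mean()))
    grid = sns.clustermap(
        filled, mask=mask, method="ward", metric="euclidean", cmap=cmap,
        figsize=(max(6, 0.4 * data.shape[1]), max(6, 0.3 * data.shape[0])),
    )
    grid.ax_heatmap.set_xlabel("model")
    grid.ax_heatmap.set_ylabel("drug pair")
    if out_path is not None:
        grid.savefig(out_path, dpi=150)
        plt.close(grid.figure)
    return grid
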