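"""Compositional and stacked-bar visualization of ancestry fractions.

Geometry is computed by pure functions (polygon vertices, barycentric
point coordinates, bar segments) so it can be tested without rendering;
the ``*_plot`` wrappers draw with matplotlib and write image files.
"""

from __future__ import annotations

import os

import numpy as np

__all__ = [
    "polygon_vertices",
    "barycentric_coordinates",
    "barplot_segments",
    "compositional_plot",
    "ancestry_barplot",
    "pca_scatter_3d",
]


def polygon_vertices(K: int) -> np.ndarray:
    """K x 2 coordinates of a regular K-gon on the unit circle.

    Vertex 0 sits at the top and successive vertices proceed clockwise.
    """
    if K < 2:
        raise ValueError("need K >= 2 vertices")
    theta = np.pi / 2 - 2 * np.pi * np.arange(K) / K
    return np.column_stack([np.cos(theta), np.sin(theta)])


def barycentric_coordinates(alpha: np.ndarray, vertices: np.ndarray | None = None) -> np.ndarray:
    """Map simplex-valued rows to 2-D as alpha-weighted vertex combinations."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 2 or alpha.shape[1] < 2:
        raise ValueError("alpha must be N x K with K >= 2")
    if np.abs(alpha.sum(axis=1) - 1).max() > 1e-4 or alpha.min() < -1e-8:
        raise ValueError("alpha rows must be simplex-valued")
    if vertices is None:
        vertices = polygon_vertices(alpha.shape[1])
    return alpha @ vertices


def barplot_segments(
    alpha: np.ndarray, group_labels: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Stacked-bar geometry for an N x K fraction matrix.

    Individuals are ordered by group label (stable within groups, groups
    in first-appearance order).  Returns ``(order, bottoms, groups,
    boundaries)``: the permutation of individuals, the N x K matrix of
    stack baselines (cumulative fractions), the ordered group names and
    the cumulative group boundaries along the bar axis.
    """
    alpha = np.asarray(alpha, dtype=float)
    n = alpha.shape[0]
    if group_labels is None:
        group_labels = [""] * n
    if len(group_labels) != n:
        raise ValueError("group_labels length mismatch")
    groups = list(dict.fromkeys(group_labels))
    order = np.concatenate([[i for i in range(n) if group_labels[i] == g] for g in groups]).astype(int)
    stacked = alpha[order]
    bottoms = np.concatenate([np.zeros((n, 1)), np.cumsum(stacked, axis=1)[:, :-1]], axis=1)
    counts = np.array([sum(1 for lab in group_labels if lab == g) for g in groups])
    boundaries = np.cumsum(counts)
    return order, bottoms, groups, boundaries


def _colors(K: int):
    import matplotlib.pyplot as plt

    cmap = plt.get_cmap("tab10" if K <= 10 else "tab20")
    return [cmap(j % cmap.N) for j in range(K)]


def compositional_plot(
    alpha: np.ndarray,
    labels: list[str] | None = None,
    out: str | os.PathLike = "compositional.png",
    order_by_mass: bool = True,
) -> None:
    """Scatter individuals inside a regular K-gon of archetype vertices.

    Each individual is drawn at the barycentric combination of the
    vertices weighted by its ancestry row; a one-hot row lands exactly on
    a vertex.  Archetypes are ordered clockwise from the top by
    descending total ancestry mass (disable with ``order_by_mass``).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    alpha = np.asarray(alpha, dtype=float)
    k = alpha.shape[1]
    if k < 2:
        raise ValueError("compositional plot needs K >= 2")
    col_order = np.argsort(-alpha.sum(axis=0), kind="stable") if order_by_mass else np.arange(k)
    verts = polygon_vertices(k)
    pts = barycentric_coordinates(alpha[:, col_order], verts)
    fig, ax = plt.subplots(figsize=(6, 6))
    ring = np.vstack([verts, verts[:1]])
    ax.plot(ring[:, 0], ring[:, 1], color="0.6", lw=1, zorder=1)
    if labels is not None:
        for g in dict.fromkeys(labels):
            sel = [i for i, lab in enumerate(labels) if lab == g]
            ax.scatter(pts[sel, 0], pts[sel, 1], s=12, label=str(g), zorder=2)
        ax.legend(fontsize=7, loc="upper right")
    else:
        ax.scatter(pts[:, 0], pts[:, 1], s=12, zorder=2)
    for j, (x, y) in enumerate(verts):
        ax.annotate(f"A{j + 1}", (x * 1.08, y * 1.08), ha="center", va="center", fontsize=9)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)


def ancestry_barplot(
    alpha: np.ndarray,
    group_labels: list[str] | None = None,
    out: str | os.PathLike = "ancestry.png",
) -> None:
    """ADMIXTURE-style stacked bars, one narrow bar per individual, grouped by label."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    alpha = np.asarray(alpha, dtype=float)
    n, k = alpha.shape
    order, bottoms, groups, boundaries = barplot_segments(alpha, group_labels)
    stacked = alpha[order]
    colors = _colors(k)
    fig, ax = plt.subplots(figsize=(max(6, n / 25), 3))
    x = np.arange(n)
    for j in range(k):
        ax.bar(x, stacked[:, j], bottom=bottoms[:, j], width=1.0, color=colors[j], linewidth=0)
    for b in boundaries[:-1]:
        ax.axvline(b - 0.5, color="black", lw=0.8)
    if group_labels is not None:
        mids = np.concatenate([[0], boundaries[:-1]]) + np.diff(np.concatenate([[0], boundaries])) / 2
        ax.set_xticks(mids - 0.5)
        ax.set_xticklabels(groups, rotation=90, fontsize=7)
    ax.set_xlim(-0.5, n - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("ancestry fraction")
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)


def pca_scatter_3d(
    scores: np.ndarray,
    archetypes: np.ndarray | None = None,
    labels: list[str] | None = None,
    out: str | os.PathLike = "pca3d.png",
) -> None:
    """3-D scatter of the first three score columns with projected archetypes."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    scores = np.asarray(scores, dtype=float)
    if scores.shape[1] < 3:
        raise ValueError("need at least 3 score columns")
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    if labels is not None:
        for g in dict.fromkeys(labels):
            sel = [i for i, lab in enumerate(labels) if lab == g]
            ax.scatter(scores[sel, 0], scores[sel, 1], scores[sel, 2], s=8, label=str(g))
        ax.legend(fontsize=7)
    else:
        ax.scatter(scores[:, 0], scores[:, 1], scores[:, 2], s=8)
    if archetypes is not None:
        archetypes = np.asarray(archetypes, dtype=float)
        ax.scatter(
            archetypes[:, 0], archetypes[:, 1], archetypes[:, 2],
            s=120, marker="o", edgecolor="black", facecolor="none", linewidths=1.5,
        )
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_zlabel("PC3")
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
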