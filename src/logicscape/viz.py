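"""Visualisation: flattened hypercubes, landscape plots, basin compositions.

An N-gene landscape lives on the corners of an N-dimensional hypercube.
The flattened layout is recursive: the layout for N consists of two
copies of the layout for N-1 (an outer and an inner copy, corresponding
corners joined), bottoming out at a square for N=2.  Nodes are drawn as
pie glyphs with one sector per gene (filled = ON), colored by energy on
a diverging map symmetric about zero; edges are arrows toward lower
energy with width proportional to |dE|, or dashed lines for flat
segments.  Layouts beyond seven dimensions are refused: merge groups of
genes into shared dimensions or slice fixed hyperplanes instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Wedge

from .landscape import Attractor, EnergyLandscape
from .network import decode_state

__all__ = [
    "HypercubeLayout",
    "MergedLandscape",
    "hypercube_layout",
    "plot_landscape",
    "merge_genes",
    "slice_landscape",
    "plot_basin_strengths",
]

_MERGE_CAVEAT = (
    "Merged-gene landscape: reduced neighbors are not Hamming-1 neighbors "
    "of the full landscape, so apparent minima may differ from true attractors."
)

_ATTRACTOR_COLORS = ("tab:blue", "tab:red", "tab:green", "tab:orange", "tab:cyan", "tab:purple")


@dataclass(frozen=True)
class HypercubeLayout:
    n: int
    coords: np.ndarray  # (2^n, 2)
    edges: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class MergedLandscape:
    """A reduced landscape where gene groups share one dimension."""

    landscape: EnergyLandscape
    groups: tuple[tuple[str, ...], ...]
    full_state_of: tuple[int, ...]  # reduced index -> full state index
    caveat: str = _MERGE_CAVEAT


def hypercube_layout(n: int, scale: float = 2.2) -> HypercubeLayout:
    """Recursive two-copy flattening of the n-cube onto the plane.

    Node ``i`` (high bit 0) sits on the outer copy and node
    ``i + 2^(n-1)`` on the inner copy, scaled down by ``scale``.
    Deterministic for identical inputs.
    """
    if not 1 <= n <= 7:
        raise ValueError(
            "layouts support 1..7 dimensions; merge genes into shared "
            "dimensions (merge_genes) or fix a hyperplane (slice_landscape) "
            "for larger systems"
        )

    def build(m: int) -> np.ndarray:
        if m == 1:
            return np.array([[-1.0, 0.0], [1.0, 0.0]])
        if m == 2:
            return np.array([[-1.0, -1.0], [1.0, -1.0], [-1.0, 1.0], [1.0, 1.0]])
        prev = build(m - 1)
        return np.vstack([prev * scale, prev])

    coords = build(n)
    edges = tuple(
        (s, s ^ (1 << i))
        for s in range(1 << n)
        for i in range(n)
        if s < (s ^ (1 << i))
    )
    return HypercubeLayout(n, coords, edges)


def _pie_node(ax, xy, radius, bits, color, n_genes):
    """Draw one state glyph: a pie with one sector per gene, filled iff ON."""
    x, y = xy
    for i in range(n_genes):
        theta1 = 90 + 360 * i / n_genes
        theta2 = 90 + 360 * (i + 1) / n_genes
        face = color if bits[i] else "white"
        ax.add_patch(
            Wedge((x, y), radius, theta1, theta2, facecolor=face, edgecolor="black", lw=0.4)
        )


def plot_landscape(
    land: EnergyLandscape,
    layout: HypercubeLayout | None = None,
    attractors: Sequence[Attractor] | None = None,
    basin_map: Mapping[int, set[int]] | None = None,
    path=None,
    max_arrow_width: float = 3.0,
    title: str | None = None,
):
    """Render a full landscape plot; returns the matplotlib figure.

    Nodes are energy-colored pie glyphs; arrows point downhill with
    width proportional to |dE|; equal-energy neighbors are joined by
    dashed lines; attractor states and their incoming edges are
    color-coded and an optional ring around each node shows the basins
    it belongs to.  A labeled legend glyph identifies the sectors.
    """
    if layout is None:
        layout = hypercube_layout(land.n)
    if layout.n != land.n:
        raise ValueError(f"layout is {layout.n}-dimensional, landscape {land.n}")
    n = land.n
    E = land.energies
    coords = layout.coords
    span = np.abs(coords).max() or 1.0
    node_r = 0.055 * span

    vmax = max(abs(E.min()), abs(E.max()), 1)
    cmap = plt.get_cmap("RdBu_r")
    norm = plt.Normalize(-vmax, vmax)

    att_of_state: dict[int, int] = {}
    if attractors:
        for ai, att in enumerate(attractors):
            for s in att.states:
                att_of_state[s] = ai

    fig, ax = plt.subplots(figsize=(9, 8))
    dE_max = max(abs(E[a] - E[b]) for a, b in layout.edges) or 1.0
    for a, b in layout.edges:
        pa, pb = coords[a], coords[b]
        if E[a] == E[b]:
            ax.plot(*zip(pa, pb), ls="--", c="grey", lw=0.8, zorder=1)
            continue
        lo, hi = (a, b) if E[a] < E[b] else (b, a)
        width = max_arrow_width * abs(E[a] - E[b]) / dE_max
        color = "grey"
        if lo in att_of_state:
            color = _ATTRACTOR_COLORS[att_of_state[lo] % len(_ATTRACTOR_COLORS)]
        vec = coords[lo] - coords[hi]
        ax.annotate(
            "",
            xy=coords[hi] + 0.88 * vec,
            xytext=coords[hi] + 0.12 * vec,
            arrowprops=dict(arrowstyle="-|>", lw=width, color=color),
            zorder=2,
        )
    for s in range(1 << n):
        bits = decode_state(s, n)
        _pie_node(ax, coords[s], node_r, bits, cmap(norm(E[s])), n)
        if basin_map is not None and basin_map.get(s):
            ids = sorted(basin_map[s])
            arc = 360 / len(ids)
            for j, ai in enumerate(ids):
                ax.add_patch(
                    Wedge(
                        tuple(coords[s]),
                        node_r * 1.45,
                        90 + j * arc,
                        90 + (j + 1) * arc,
                        width=node_r * 0.28,
                        facecolor=_ATTRACTOR_COLORS[ai % len(_ATTRACTOR_COLORS)],
                        edgecolor="none",
                    )
                )
    # legend glyph naming the sectors
    lx, ly = span * 1.25, span * 1.05
    _pie_node(ax, (lx, ly), node_r * 1.6, [1] * n, "lightgrey", n)
    for i, g in enumerate(land.genes):
        ang = np.deg2rad(90 + 360 * (i + 0.5) / n)
        ax.text(
            lx + np.cos(ang) * node_r * 2.4,
            ly + np.sin(ang) * node_r * 2.4,
            g,
            ha="center",
            va="center",
            fontsize=8,
        )
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=norm)
    fig.colorbar(sm, ax=ax, label="energy", shrink=0.75)
    ax.set_aspect("equal")
    ax.set_xlim(-span * 1.15, span * 1.45)
    ax.set_ylim(-span * 1.15, span * 1.25)
    ax.axis("off")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def merge_genes(
    land: EnergyLandscape, groups: Sequence[Sequence[str]]
) -> MergedLandscape:
    """Collapse gene groups into shared dimensions.

    Keeps only the full states in which every group is internally
    uniform; each group then contributes a single reduced bit (genes not
    covered by any group keep their own dimension).  The reduced plot is
    *not* an exact representation of the landscape — see the caveat
    attached to the result.
    """
    seen: set[str] = set()
    for grp in groups:
        for g in grp:
            if g not in land.genes:
                raise ValueError(f"unknown gene {g!r}")
            if g in seen:
                raise ValueError(f"gene {g!r} in more than one group")
            seen.add(g)
    full_groups: list[tuple[str, ...]] = [tuple(g) for g in groups]
    for g in land.genes:
        if g not in seen:
            full_groups.append((g,))
    bit = {g: i for i, g in enumerate(land.genes)}
    m = len(full_groups)
    energies = np.empty(1 << m)
    full_of = []
    for r in range(1 << m):
        s = 0
        for j, grp in enumerate(full_groups):
            if (r >> j) & 1:
                for g in grp:
                    s |= 1 << bit[g]
        energies[r] = land.energies[s]
        full_of.append(s)
    reduced = EnergyLandscape(
        energies,
        tuple("+".join(grp) for grp in full_groups),
        land.L,
        land.H,
        provenance={"merged_from": land.genes},
    )
    return MergedLandscape(reduced, tuple(full_groups), tuple(full_of))


def slice_landscape(
    land: EnergyLandscape, fixed: Mapping[str, int]
) -> EnergyLandscape:
    """Restrict to the hyperplane where the ``fixed`` genes hold the
    given values; remaining genes are re-indexed in original order."""
    for g, v in fixed.items():
        if g not in land.genes:
            raise ValueError(f"unknown gene {g!r}")
        if v not in (0, 1):
            raise ValueError(f"fixed value for {g!r} must be 0/1")
    keep = [g for g in land.genes if g not in fixed]
    bit = {g: i for i, g in enumerate(land.genes)}
    base = sum(v << bit[g] for g, v in fixed.items())
    energies = np.empty(1 << len(keep))
    for r in range(1 << len(keep)):
        s = base
        for j, g in enumerate(keep):
            if (r >> j) & 1:
                s |= 1 << bit[g]
        energies[r] = land.energies[s]
    return EnergyLandscape(
        energies, tuple(keep), land.L, land.H, provenance={"sliced": dict(fixed)}
    )


def plot_basin_strengths(summary, path=None, title: str | None = None):
    """Stacked composition of attractor-reach probabilities.

    States run along an unlabeled continuous axis in the summary's
    order; one colored band per attractor ("Other" topmost, grey);
    vertical lines mark segment boundaries where the dominating
    attractor changes; shading shows the replicate standard deviation.
    """
    mean = summary.mean
    std = summary.std
    cols = list(summary.labels) + ["Other"]
    x = np.arange(len(summary.order))
    fig, ax = plt.subplots(figsize=(8, 4))
    bottom = np.zeros(len(x))
    for ci, col in enumerate(cols):
        vals = mean[col].to_numpy()
        color = "lightgrey" if col == "Other" else _ATTRACTOR_COLORS[ci % len(_ATTRACTOR_COLORS)]
        top = bottom + vals
        ax.fill_between(x, bottom, top, step="mid", color=color, label=col)
        sd = np.nan_to_num(std[col].to_numpy())
        ax.fill_between(x, top - sd, top + sd, step="mid", color=color, alpha=0.35, lw=0)
        bottom = top
    pos = 0
    for _, size in summary.segments[:-1]:
        pos += size
        ax.axvline(pos - 0.5, color="black", lw=0.8)
    ax.set_xlim(-0.5, len(x) - 0.5)
    ax.set_ylim(0, 1.02)
    ax.set_xticks([])
    ax.set_ylabel("probability of reaching attractor")
    ax.set_xlabel("initial states (ordered)")
    ax.legend(loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=8)
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
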