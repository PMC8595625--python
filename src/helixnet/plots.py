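"""Figure rendering: chord diagrams of group energies and structure-mapped networks.

Both renderers are thin: the quantitative layout (arc spans, ribbon widths,
edge lists) comes from pure functions so the numbers behind every figure are
testable and exportable without parsing image files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import PathPatch
from matplotlib.path import Path as MplPath

from .energetics import AveragedMatrix
from .errors import PlotError, ResidueLookupError
from .network import DiffNetwork, GroupMatrix, classify_change
from .structure import Structure

#: edge colors per change class (wildtype/mutant, attractive/repulsive)
CLASS_COLORS = {
    "attractive-lost": "tab:blue",
    "attractive-gained": "tab:green",
    "repulsive-gained": "tab:orange",
    "repulsive-lost": "magenta",
    "unchanged": "0.8",
}


@dataclass(frozen=True)
class ChordRibbon:
    group_a: str
    group_b: str
    energy: float
    width: float          # angular width (radians), ∝ |energy|
    start_a: float        # ribbon anchor angles (radians)
    start_b: float


def chord_layout(matrix: GroupMatrix, gap: float = 0.05,
                 min_width: float = 0.0) -> tuple[dict[str, tuple[float, float]],
                                                  list[ChordRibbon]]:
    """Angular arcs per group and one ribbon per nonzero off-diagonal entry.

    Each group's arc span is proportional to its summed |energy| with partners;
    ribbon widths are proportional to |pair energy|. Raises when there is
    nothing to draw.
    """
    groups = matrix.groups
    if not groups:
        raise PlotError("empty group matrix")
    absmat = np.abs(matrix.energy)
    weight = absmat.sum(axis=1)
    total = weight.sum()
    if total <= 0:
        raise PlotError("all group energies are zero: nothing to plot")
    n = len(groups)
    span = 2 * np.pi - n * gap
    arcs: dict[str, tuple[float, float]] = {}
    theta = 0.0
    for k, g in enumerate(groups):
        width = span * (weight[k] / total)
        arcs[g] = (theta, theta + width)
        theta += width + gap

    ribbons: list[ChordRibbon] = []
    cursor = {g: arcs[g][0] for g in groups}
    scale = span / total / 2.0  # each pair consumes width on both arcs
    for i in range(n):
        for j in range(i + 1, n):
            e = matrix.energy[i, j]
            if e == 0.0:
                continue
            w = max(abs(e) * scale, min_width)
            ribbons.append(ChordRibbon(groups[i], groups[j], float(e), w,
                                       cursor[groups[i]], cursor[groups[j]]))
            cursor[groups[i]] += w
            cursor[groups[j]] += w
    if not ribbons:
        raise PlotError("no off-diagonal group interactions: nothing to plot")
    return arcs, ribbons


def render_group_chord(matrix: GroupMatrix, out: str) -> str:
    """Chord-style diagram: group arcs with ribbon widths ∝ |group-pair energy|."""
    arcs, ribbons = chord_layout(matrix)
    fig, ax = plt.subplots(figsize=(6, 6), subplot_kw={"aspect": "equal"})
    radius = 1.0
    for g, (a0, a1) in arcs.items():
        t = np.linspace(a0, a1, 32)
        ax.plot(radius * 1.04 * np.cos(t), radius * 1.04 * np.sin(t), lw=6,
                solid_capstyle="butt")
        mid = 0.5 * (a0 + a1)
        ax.text(1.18 * np.cos(mid), 1.18 * np.sin(mid), g,
                ha="center", va="center", fontsize=8)
    for rb in ribbons:
        color = "tab:blue" if rb.energy < 0 else "tab:red"
        a0, a1 = rb.start_a, rb.start_a + rb.width
        b0, b1 = rb.start_b, rb.start_b + rb.width
        pts = []
        codes = []
        arc_a = np.linspace(a0, a1, 8)
        pts += [(radius * np.cos(t), radius * np.sin(t)) for t in arc_a]
        codes += [MplPath.MOVETO] + [MplPath.LINETO] * 7
        pts += [(0.0, 0.0), (radius * np.cos(b0), radius * np.sin(b0))]
        codes += [MplPath.CURVE3] * 2
        arc_b = np.linspace(b0, b1, 8)
        pts += [(radius * np.cos(t), radius * np.sin(t)) for t in arc_b]
        codes += [MplPath.LINETO] * 8
        pts += [(0.0, 0.0), (radius * np.cos(a0), radius * np.sin(a0))]
        codes += [MplPath.CURVE3] * 2
        ax.add_patch(PathPatch(MplPath(pts, codes), alpha=0.45,
                               facecolor=color, edgecolor="none"))
    ax.set_xlim(-1.35, 1.35)
    ax.set_ylim(-1.35, 1.35)
    ax.axis("off")
    fig.savefig(out, bbox_inches="tight")
    plt.close(fig)
    return out


# ---------------------------------------------------------------------------
# Structure-mapped residue networks
# ---------------------------------------------------------------------------

def network_edges(matrix: AveragedMatrix | DiffNetwork,
                  threshold: float = 0.0) -> list[tuple[tuple[str, int],
                                                        tuple[str, int],
                                                        float, str]]:
    """Unmasked residue pairs with |energy| ≥ threshold, with change class.

    For an averaged matrix the class encodes attraction/repulsion of the mean
    energy; for a difference network it is the wildtype-vs-mutant change class.
    """
    if isinstance(matrix, DiffNetwork):
        values = matrix.delta
        wt = matrix.wt_mean if matrix.wt_mean is not None else np.zeros_like(values)
        classes = lambda i, j: classify_change(wt[i, j], values[i, j])  # noqa: E731
    else:
        values = matrix.mean
        classes = lambda i, j: ("attractive-gained" if values[i, j] < 0  # noqa: E731
                                else "repulsive-gained")
    edges = []
    n = len(matrix.residues)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix.mask[i, j] or abs(values[i, j]) < threshold \
                    or values[i, j] == 0.0:
                continue
            edges.append((matrix.residues[i], matrix.residues[j],
                          float(values[i, j]), classes(i, j)))
    return edges


def render_structure_network(structure: Structure,
                             matrix: AveragedMatrix | DiffNetwork,
                             out: str, threshold: float = 0.0,
                             width_per_kcal: float = 1.0,
                             max_width: float = 8.0,
                             projection: tuple[int, int] = (0, 1)) -> str:
    """Project residue nodes at Cα positions; edge width ∝ |energy|, color by class."""
    ca: dict[tuple[str, int], np.ndarray] = {}
    for a in structure.atoms:
        if a.atom_name == "CA":
            ca[a.residue_id] = a.position
    edges = network_edges(matrix, threshold)
    px, py = projection
    fig, ax = plt.subplots(figsize=(7, 7), subplot_kw={"aspect": "equal"})
    for rid_a, rid_b, energy, cls in edges:
        if rid_a not in ca or rid_b not in ca:
            raise ResidueLookupError(f"no Cα for residue {rid_a} or {rid_b}")
        pa, pb = ca[rid_a], ca[rid_b]
        lw = min(abs(energy) * width_per_kcal, max_width)
        ax.plot([pa[px], pb[px]], [pa[py], pb[py]],
                color=CLASS_COLORS.get(cls, "0.5"), lw=lw, alpha=0.8, zorder=1)
    involved = {r for e in edges for r in e[:2]}
    pts = np.array([p for rid, p in ca.items()])
    ax.scatter(pts[:, px], pts[:, py], s=6, color="0.7", zorder=2)
    for rid in involved:
        p = ca[rid]
        ax.scatter([p[px]], [p[py]], s=24, color="k", zorder=3)
        ax.annotate(str(rid[1]), (p[px], p[py]), fontsize=7,
                    textcoords="offset points", xytext=(3, 3))
    ax.set_xlabel("x (Å)" if px == 0 else "yz"[px - 1] + " (Å)")
    ax.set_ylabel("y (Å)" if py == 1 else "xz"[py] + " (Å)")
    fig.savefig(out, bbox_inches="tight")
    plt.close(fig)
    return out
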