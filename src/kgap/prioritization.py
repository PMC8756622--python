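"""Hitlist prioritization for target illumination.

Post-ranking merges two annotation layers onto the scored gene list:

* **TDL** (target development level): Tclin / Tchem / Tbio / Tdark, a
  four-level druggability-illumination class; understudied (Tdark) genes
  near the top of the hitlist are the novel-target candidates.
* **Bibliometrics**: per-gene *novelty* (rarity of the gene in the
  literature) and *importance* (strength of disease–gene co-occurrence).
  Genes are ranked by successive non-dominated (Pareto) fronts maximizing
  both: ``nds_rank`` 1 is the set of genes no other gene beats strictly in
  both dimensions, rank 2 is the front after removing rank 1, and so on.

Novelty/importance values are consumed as inputs (the text mining that
produces them is upstream); log-scaled axes in plots are display-only and
never affect ranks, which are invariant to monotone transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import SchemaError, UsageError
from .graph_core import TDL_LEVELS
from .scoring import GeneScore


@dataclass(frozen=True)
class BiblioPoint:
    """A gene's position in the (novelty, importance) plane."""

    gene_id: str
    novelty: float
    importance: float
    nds_rank: int | None = None


@dataclass(frozen=True)
class AnnotatedScore:
    """A hitlist entry carrying its TDL class ('unknown' when unannotated)."""

    gene_id: str
    k: int
    score: float
    rank: int
    tdl: str = "unknown"


def nds_rank(points: Sequence[BiblioPoint]) -> list[BiblioPoint]:
    """Assign non-dominated-solution ranks by successive front peeling.

    A point dominates another only when it is *strictly* greater in both
    novelty and importance; equality in either coordinate does not
    dominate.  Rank 1 is the Pareto front of the full set, rank r the
    front of what remains after ranks < r are removed.  Input order is
    preserved in the returned list.
    """
    if not points:
        raise UsageError("no points to rank")
    for p in points:
        if (not math.isfinite(p.novelty) or not math.isfinite(p.importance)
                or p.novelty <= 0 or p.importance <= 0):
            raise UsageError(
                f"{p.gene_id}: novelty/importance must be finite and > 0")

    n = len(points)
    order = sorted(range(n), key=lambda i: (-points[i].novelty,
                                            -points[i].importance))
    ranks = [0] * n
    remaining = order
    current = 1
    while remaining:
        # one sweep in descending-novelty order: a point is on the front
        # iff no remaining point with strictly greater novelty also has
        # strictly greater importance
        front: list[int] = []
        rest: list[int] = []
        best_imp = -math.inf        # max importance over strictly-greater novelty
        group_imp = -math.inf
        group_nov = None
        for i in remaining:
            p = points[i]
            if group_nov is not None and p.novelty < group_nov:
                best_imp = max(best_imp, group_imp)
                group_imp = -math.inf
            group_nov = p.novelty
            if p.importance >= best_imp:  # dominance needs strictly greater imp
                front.append(i)
            else:
                rest.append(i)
            group_imp = max(group_imp, p.importance)
        for i in front:
            ranks[i] = current
        remaining = rest
        current += 1
    return [replace(p, nds_rank=r) for p, r in zip(points, ranks)]


def load_biblio_table(path) -> list[BiblioPoint]:
    """Read a TSV of (gene_id, novelty, importance)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "novelty", "importance"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return [BiblioPoint(r.gene_id, float(r.novelty), float(r.importance))
            for r in df.itertuples()]


def annotate_tdl(
    gene_scores: Iterable[GeneScore], tdl_table: Mapping[str, str]
) -> list[AnnotatedScore]:
    """Merge TDL classes onto a hitlist, preserving its order.

    Genes missing from the table are marked ``unknown``; a malformed TDL
    value in the table raises :class:`SchemaError`.
    """
    for g, t in tdl_table.items():
        if t not in TDL_LEVELS:
            raise SchemaError(f"invalid TDL {t!r} for gene {g!r}")
    return [AnnotatedScore(s.gene_id, s.k, s.score, s.rank,
                           tdl_table.get(s.gene_id, "unknown"))
            for s in gene_scores]


def load_tdl_table(path) -> dict[str, str]:
    """Read a TSV of (gene_id, tdl)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "tdl"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return dict(zip(df["gene_id"], df["tdl"]))


def top_dark(annotated: Sequence[AnnotatedScore], n: int) -> list[AnnotatedScore]:
    """The ``n`` highest-ranked understudied (Tdark) genes of the hitlist."""
    return [a for a in annotated if a.tdl == "Tdark"][:n]


def biblio_scatter(points: Sequence[BiblioPoint],
                   tdl_table: Mapping[str, str] | None = None,
                   out_path=None):
    """Novelty × importance scatter on log axes, colored by TDL.

    Display only — ranking never depends on the log scaling.  Returns the
    matplotlib figure; saves to ``out_path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tdl_table = tdl_table or {}
    colors = {"Tclin": "tab:green", "Tchem": "tab:blue",
              "Tbio": "tab:orange", "Tdark": "tab:red", "unknown": "gray"}
    fig, ax = plt.subplots(figsize=(6, 5))
    for tdl, color in colors.items():
        xs = [p.importance for p in points
              if tdl_table.get(p.gene_id, "unknown") == tdl]
        ys = [p.novelty for p in points
              if tdl_table.get(p.gene_id, "unknown") == tdl]
        if xs:
            ax.scatter(xs, ys, s=14, c=color, label=tdl, alpha=0.8)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("importance (disease–gene co-occurrence)")
    ax.set_ylabel("novelty (literature rarity)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig
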