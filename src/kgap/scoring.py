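"""Evidence-path enumeration and Stouffer aggregation (the KGAP score).

An *evidence path* is one Drug→Signature→Gene traversal whose
signature–gene differential-expression z-score survives the magnitude
threshold (default ``|z| > 3``, strict).  Per gene, the paths are combined
with Stouffer's z-score meta-analysis function,

    Z = Σᵢ wᵢ Zᵢ / sqrt(Σᵢ wᵢ²),

with all weights set to one.  Two scoring modes bracket how much the
expression magnitude matters:

* ``Z`` (z-weighted): Zᵢ is the path's |z| (or signed z), so the score is
  Σ|zᵢ| / √k for a gene with k paths;
* ``D`` (degree-weighted): every Zᵢ := 1, so the score is √k — rank order
  is exactly path-count order.

Confidence grows with confirmatory signatures in either mode; the
aggregate is a ranking score, not a test statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import UsageError
from .graph_core import KnowledgeGraph


@dataclass(frozen=True)
class EvidencePath:
    """One (drug, signature, gene) traversal with its z-score."""

    drug_id: str
    signature_id: str
    gene_id: str
    z: float


@dataclass(frozen=True)
class ScoreParams:
    """Scoring parameters.

    ``z_threshold`` is the strict magnitude cutoff applied during path
    enumeration; ``mode`` selects z-weighted (``Z``) or degree-weighted
    (``D``) aggregation; ``use_absolute_z`` feeds |z| rather than signed z
    into the aggregate (signed values can cancel across paths).
    """

    z_threshold: float = 3.0
    mode: str = "Z"
    use_absolute_z: bool = True

    def __post_init__(self):
        if self.z_threshold < 0:
            raise UsageError("z_threshold must be >= 0")
        if self.mode not in ("D", "Z"):
            raise UsageError(f"mode must be 'D' or 'Z', got {self.mode!r}")


@dataclass(frozen=True)
class GeneScore:
    """Per-gene aggregation result: path count k, Stouffer score, rank."""

    gene_id: str
    k: int
    score: float
    rank: int


def enumerate_paths(
    kg: KnowledgeGraph,
    drug_ids: Iterable[str],
    z_threshold: float = 3.0,
) -> list[EvidencePath]:
    """All Drug→Signature→Gene paths from ``drug_ids`` with |z| strictly
    above ``z_threshold``.

    Each distinct (drug, signature) pair contributes its own paths, even
    when drugs share signatures: every signature is an independent
    experiment.  Raises :class:`UsageError` on an empty drug set.
    """
    drug_ids = list(drug_ids)
    if not drug_ids:
        raise UsageError("drug set is empty")
    unknown = [d for d in drug_ids if d not in kg.drugs]
    if unknown:
        raise UsageError(f"unknown drug ids: {unknown[:5]}")

    paths: list[EvidencePath] = []
    for d in drug_ids:
        for s in kg.drug_to_signatures.get(d, ()):
            for g, z in kg.signature_to_genes.get(s, ()):
                if abs(z) > z_threshold:
                    paths.append(EvidencePath(d, s, g, z))
    return paths


def stouffer_aggregate(
    z_values: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Stouffer's weighted z-combination, Σ wᵢZᵢ / sqrt(Σ wᵢ²).

    Weights default to one, under which the aggregate is (ΣZᵢ)/√k.
    """
    if len(z_values) == 0:
        raise UsageError("z_values is empty")
    if weights is None:
        weights = [1.0] * len(z_values)
    if len(weights) != len(z_values):
        raise UsageError("z_values and weights differ in length")
    denom = math.fsum(w * w for w in weights)
    if denom <= 0:
        raise UsageError("sum of squared weights must be positive")
    return math.fsum(w * z for w, z in zip(weights, z_values)) / math.sqrt(denom)


def score_genes(
    paths: Iterable[EvidencePath], params: ScoreParams = ScoreParams()
) -> list[GeneScore]:
    """Aggregate evidence paths into a ranked per-gene hitlist.

    Sorted by score descending, ties broken by gene_id ascending; ranks are
    1..n.  An empty path list gives an empty hitlist.
    """
    by_gene: dict[str, list[float]] = {}
    for p in paths:
        by_gene.setdefault(p.gene_id, []).append(p.z)

    scored = []
    for gene_id, zs in by_gene.items():
        if params.mode == "D":
            contrib = [1.0] * len(zs)
        elif params.use_absolute_z:
            contrib = [abs(z) for z in zs]
        else:
            contrib = list(zs)
        scored.append((gene_id, len(zs), stouffer_aggregate(contrib)))

    scored.sort(key=lambda t: (-t[2], t[0]))
    return [GeneScore(g, k, s, rank=i + 1)
            for i, (g, k, s) in enumerate(scored)]


def hitlist_frame(kg: KnowledgeGraph, scores: Iterable[GeneScore]) -> pd.DataFrame:
    """Hitlist as a DataFrame (gene_id, symbol, k, score, rank, tdl) — the
    TSV interface consumed by validation and prioritization."""
    rows = []
    for s in scores:
        node = kg.genes.get(s.gene_id)
        rows.append({
            "gene_id": s.gene_id,
            "symbol": node.symbol if node else "",
            "k": s.k,
            "score": s.score,
            "rank": s.rank,
            "tdl": (node.tdl if node and node.tdl else "unknown"),
        })
    return pd.DataFrame(rows, columns=["gene_id", "symbol", "k", "score",
                                       "rank", "tdl"])
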