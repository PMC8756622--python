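"""ROC validation of gene rankings against known-target gene sets.

The gene hitlist is not a classifier; the ROC/AUC here measures
*enrichment* of known disease targets among highly scored genes.  The
default negative universe is every Gene node in the graph, with genes
absent from the hitlist scored 0; restricting the universe to scored genes
is available via ``universe``.  Ties contribute one half, so the
trapezoidal AUC over the tie-grouped ROC equals the Mann–Whitney U
statistic normalized by n_pos·n_neg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .exceptions import UsageError
from .graph_core import KnowledgeGraph
from .scoring import GeneScore, ScoreParams, enumerate_paths, score_genes


@dataclass(frozen=True)
class ValidationSet:
    """A named set of positive (known-target) gene ids."""

    name: str
    positives: frozenset[str]

    def __post_init__(self):
        if not self.positives:
            raise UsageError(f"validation set {self.name!r} has no positives")


@dataclass
class ValidationResult:
    """ROC result for one (scoring mode × validation set) cell."""

    mode: str
    set_name: str
    n_pos: int
    n_neg: int
    roc_points: list[tuple[float, float]] = field(repr=False)
    auc: float = 0.0


def label_scores(
    gene_scores: Iterable[GeneScore],
    vset: ValidationSet,
    universe: Iterable[str],
) -> list[tuple[str, float, int]]:
    """Attach a binary label to every gene in ``universe``.

    Genes absent from the hitlist get score 0; label is 1 iff the gene is
    in ``vset.positives``.  Raises :class:`UsageError` when no positive
    falls inside the universe.
    """
    universe = sorted(set(universe))
    score_of = {s.gene_id: s.score for s in gene_scores}
    labeled = [(g, score_of.get(g, 0.0), int(g in vset.positives))
               for g in universe]
    if not any(lab for _, _, lab in labeled):
        raise UsageError(
            f"no positives of {vset.name!r} are inside the gene universe")
    return labeled


def roc_auc(
    labeled: Sequence[tuple[str, float, int]],
    mode: str = "",
    set_name: str = "",
) -> ValidationResult:
    """ROC curve and AUC for a labeled score vector.

    The ROC is traced by descending score with tied scores grouped into a
    single vertex; AUC is the trapezoidal area, equal to the normalized
    Mann–Whitney U with ties counting one half.  Both classes must be
    present.
    """
    scores = np.asarray([s for _, s, _ in labeled], dtype=float)
    labels = np.asarray([lab for _, _, lab in labeled], dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UsageError("ROC needs both positive and negative examples")
    fpr, tpr, _ = _roc_curve(labels, scores, drop_intermediate=False)
    return ValidationResult(
        mode=mode, set_name=set_name, n_pos=n_pos, n_neg=n_neg,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        auc=float(_trapezoid_auc(fpr, tpr)),
    )


def run_validation(
    kg: KnowledgeGraph,
    drug_ids: Iterable[str],
    vsets: Iterable[ValidationSet],
    params_list: Iterable[ScoreParams] = (ScoreParams(mode="D"),
                                          ScoreParams(mode="Z")),
    universe: Iterable[str] | None = None,
) -> dict[tuple[str, str], ValidationResult]:
    """One ValidationResult per (scoring mode × validation set).

    Paths are enumerated once per distinct z-threshold; the default
    universe is all Gene nodes of the graph.
    """
    drug_ids = list(drug_ids)
    vsets = list(vsets)
    params_list = list(params_list)
    if universe is None:
        universe = list(kg.genes)
    else:
        universe = list(universe)

    path_cache: dict[float, list] = {}
    results: dict[tuple[str, str], ValidationResult] = {}
    for params in params_list:
        if params.z_threshold not in path_cache:
            path_cache[params.z_threshold] = enumerate_paths(
                kg, drug_ids, params.z_threshold)
        scores = score_genes(path_cache[params.z_threshold], params)
        for vset in vsets:
            labeled = label_scores(scores, vset, universe)
            results[(params.mode, vset.name)] = roc_auc(
                labeled, mode=params.mode, set_name=vset.name)
    return results


def load_gene_set(path, name: str) -> ValidationSet:
    """Read a one-column TSV of gene ids (header ``gene_id``)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns:
        raise UsageError(f"{path}: expected a 'gene_id' column")
    return ValidationSet(name=name, positives=frozenset(df["gene_id"]))
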