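"""Synthetic knowledge graphs with plantable drug→gene signal.

The generator emulates the shape of an expression-signature compendium at
desk scale: drugs each perturb several signatures across a handful of cell
lines, each signature carries z-scores for a random subset of genes, and a
disease Concept ties a designated query-drug subset together via
INDICATION edges.  Background z-scores are standard-normal (normalized
moderated z-scores have roughly unit spread, which makes the |z| > 3 path
filter meaningfully sparse); on edges linking a query drug's signatures to
a *true target* gene the z is drawn with magnitude centered at
``effect_mu`` and a random sign per edge, so magnitude-based scoring is
exercised against sign cancellation.  With ``effect_mu = 0`` true targets
are statistically indistinguishable from background.

Also provides the packaged desk-scale fixture reproducing the printed
Parkinson's-disease drug table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .disease_query import DiseaseQuery
from .exceptions import UsageError
from .graph_core import (
    CellNode,
    ConceptNode,
    DrugNode,
    DrugSignatureEdge,
    GeneNode,
    IndicationEdge,
    KnowledgeGraph,
    SignatureGeneEdge,
    SignatureNode,
)

_TDLS = ("Tclin", "Tchem", "Tbio", "Tdark")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters.

    Defaults are sized for sub-second generation: 20 drugs of which 5 are
    query drugs, 10 signatures per drug over 5 cell lines, 500 genes of
    which 10 are true targets, edge density 0.2.  ``effect_mu`` is the mean
    |z| on planted true-target edges; ``noise_sd`` the background spread.
    """

    n_drugs: int = 20
    n_query_drugs: int = 5
    n_signatures_per_drug: int = 10
    n_cells: int = 5
    n_genes: int = 500
    n_true_targets: int = 10
    effect_mu: float = 4.0
    noise_sd: float = 1.0
    edge_density: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_drugs, self.n_query_drugs, self.n_signatures_per_drug,
               self.n_cells, self.n_genes, self.n_true_targets) < 1:
            raise UsageError("all counts must be positive")
        if self.n_true_targets > self.n_genes:
            raise UsageError("n_true_targets must be <= n_genes")
        if self.n_query_drugs > self.n_drugs:
            raise UsageError("n_query_drugs must be <= n_drugs")
        if not (0 < self.edge_density <= 1):
            raise UsageError("edge_density must be in (0, 1]")
        if self.effect_mu < 0:
            raise UsageError("effect_mu must be >= 0")
        if self.noise_sd <= 0:
            raise UsageError("noise_sd must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated graph."""

    query_drug_ids: list[str]
    true_target_gene_ids: list[str]
    query_concept_id: str
    moa_target_gene_ids: list[str] = field(default_factory=list)


QUERY_CONCEPT_NAME = "Synthetic query disease"


def generate(spec: SyntheticSpec) -> tuple[KnowledgeGraph, SyntheticTruth]:
    """Generate a knowledge graph and its ground truth, deterministically
    for a given seed.

    Query drugs are the first ``n_query_drugs`` drugs; they carry
    nervous-system-style ATC codes and INDICATION edges to a single query
    Concept (non-query drugs point at distractor concepts).  True targets
    are sampled uniformly from the gene set.  Planting applies wherever the
    density draw created an edge between a query-drug signature and a true
    target, so edge counts carry no signal.
    """
    rng = np.random.default_rng(spec.seed)

    drug_ids = [f"D{i:04d}" for i in range(spec.n_drugs)]
    query_drugs = drug_ids[: spec.n_query_drugs]
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    true_targets = sorted(
        rng.choice(spec.n_genes, size=spec.n_true_targets, replace=False))
    true_target_ids = [gene_ids[i] for i in true_targets]
    cell_ids = [f"C{i:02d}" for i in range(spec.n_cells)]

    drugs = []
    for i, d in enumerate(drug_ids):
        if d in query_drugs:
            atc = frozenset({f"N04B{chr(ord('A') + i % 5)}{i:02d}"})
        else:
            letter = "ACDJR"[i % 5]
            atc = frozenset({f"{letter}01A{chr(ord('A') + i % 6)}{i:02d}"})
        drugs.append(DrugNode(d, name=f"compound-{i:04d}",
                              pubchem_cid=100000 + i, atc_codes=atc))

    tdl_draw = rng.choice(4, size=spec.n_genes, p=[0.15, 0.15, 0.35, 0.35])
    genes = [GeneNode(g, symbol=f"SYN{i:05d}", tdl=_TDLS[tdl_draw[i]])
             for i, g in enumerate(gene_ids)]
    cells = [CellNode(c, name=f"cell-line-{i}") for i, c in enumerate(cell_ids)]

    signatures, drug_sig = [], []
    sig_ids, sig_drug = [], []
    for d in drug_ids:
        for j in range(spec.n_signatures_per_drug):
            sid = f"S_{d}_{j:03d}"
            cell = cell_ids[int(rng.integers(spec.n_cells))]
            signatures.append(SignatureNode(sid, cell))
            drug_sig.append(DrugSignatureEdge(d, sid))
            sig_ids.append(sid)
            sig_drug.append(d)

    n_sigs = len(sig_ids)
    mask = rng.random((n_sigs, spec.n_genes)) < spec.edge_density
    z = rng.normal(0.0, spec.noise_sd, size=(n_sigs, spec.n_genes))

    # plant signal: query-drug signatures × true-target genes
    query_rows = np.array([sd in query_drugs for sd in sig_drug])
    target_cols = np.zeros(spec.n_genes, dtype=bool)
    target_cols[true_targets] = True
    plant_mask = mask & query_rows[:, None] & target_cols[None, :]
    n_plant = int(plant_mask.sum())
    if n_plant:
        signs = rng.choice([-1.0, 1.0], size=n_plant)
        z[plant_mask] = signs * rng.normal(spec.effect_mu, spec.noise_sd,
                                           size=n_plant)

    si, gi = np.nonzero(mask)
    sig_gene = [SignatureGeneEdge(sig_ids[s], gene_ids[g], float(z[s, g]))
                for s, g in zip(si, gi)]

    query_concept = ConceptNode("omop:9000000", QUERY_CONCEPT_NAME)
    distractors = [ConceptNode(f"omop:9000{i + 1:03d}",
                               f"Synthetic distractor condition {i + 1}")
                   for i in range(3)]
    indications = [IndicationEdge(d, query_concept.concept_id)
                   for d in query_drugs]
    for i, d in enumerate(drug_ids[spec.n_query_drugs:]):
        indications.append(
            IndicationEdge(d, distractors[i % len(distractors)].concept_id))

    kg = KnowledgeGraph(drugs, genes, signatures, cells,
                        [query_concept] + distractors,
                        sig_gene, drug_sig, indications)
    # a nested "known mechanism" subset of the truth, for two-set validation
    moa = true_target_ids[: max(1, len(true_target_ids) // 2)]
    truth = SyntheticTruth(query_drug_ids=list(query_drugs),
                           true_target_gene_ids=list(true_target_ids),
                           query_concept_id=query_concept.concept_id,
                           moa_target_gene_ids=moa)
    return kg, truth


# ----------------------------------------------------------------------
# Packaged Parkinson fixture

_FIXTURE_GENES = ["SLC6A3", "DRD2", "COMT", "MAOB", "SYNGR3"]
_FIXTURE_TDL = {"SLC6A3": "Tclin", "DRD2": "Tclin", "COMT": "Tclin",
                "MAOB": "Tclin", "SYNGR3": "Tdark"}


def table4_fixture() -> tuple[KnowledgeGraph, DiseaseQuery]:
    """Desk-scale fixture graph around the printed Parkinson's drug table.

    Contains the 25 printed drugs (names, PubChem CIDs, LINCS-membership
    flags as published), the five matched Parkinson concept terms, six
    distractor disease concepts, and nervous-system ATC codes on all 25
    drugs.  The 22 LINCS-member drugs get one stub signature each with a
    small deterministic set of signature–gene z-scores so that scoring can
    run end to end.  Everything beyond the printed table — concept ids,
    distractor concepts and drugs, the stub signatures and z values, and
    one extra Parkinson-indicated drug without a nervous-system ATC code
    (domperidone, exercising the ATC restriction) — is synthetic.
    """
    pkg = resources.files("kgap.data")
    drugs_df = pd.read_csv(pkg / "table4_drugs.tsv", sep="\t", dtype=str)
    concepts_df = pd.read_csv(pkg / "parkinson_concepts.tsv", sep="\t", dtype=str)

    drugs = []
    for _, r in drugs_df.iterrows():
        drugs.append(DrugNode(
            drug_id=f"dc{r['struct_id']}",
            name=r["name"],
            pubchem_cid=int(r["pubchem_cid"]),
            atc_codes=frozenset({"N04AA"}),
        ))
    # synthetic augmentation: Parkinson-indicated but not ATC class N
    drugs.append(DrugNode("dc940", "domperidone", pubchem_cid=3151,
                          atc_codes=frozenset({"A03FA03"})))
    # distractor drug on a distractor concept, ATC class N
    drugs.append(DrugNode("dc820", "diazepam", pubchem_cid=3016,
                          atc_codes=frozenset({"N05BA01"})))

    concepts = [ConceptNode(r["concept_id"], r["name"])
                for _, r in concepts_df.iterrows()]
    distractor_names = [
        "Alzheimer's disease", "Epilepsy", "Schizophrenia",
        "Essential hypertension", "Asthma", "Migraine",
    ]
    concepts += [ConceptNode(f"omop:5000{i:03d}", nm)
                 for i, nm in enumerate(distractor_names)]

    parkinson_concept = concepts[1].concept_id  # "Parkinson's disease"
    indications = [IndicationEdge(d.drug_id, parkinson_concept)
                   for d in drugs if d.drug_id not in ("dc820",)]
    indications.append(IndicationEdge("dc820", "omop:5000002"))

    cells = [CellNode("MCF7", "breast carcinoma"), CellNode("PC3", "prostate")]
    lincs_drugs = [f"dc{r['struct_id']}" for _, r in drugs_df.iterrows()
                   if r["in_lincs"].lower() == "true"]

    genes = [GeneNode(sym, symbol=sym, tdl=_FIXTURE_TDL[sym])
             for sym in _FIXTURE_GENES]

    rng = np.random.default_rng(20200601)  # fixed: fixture is deterministic
    signatures, drug_sig, sig_gene = [], [], []
    for i, d in enumerate(lincs_drugs):
        sid = f"sig_{d}"
        signatures.append(SignatureNode(sid, ["MCF7", "PC3"][i % 2]))
        drug_sig.append(DrugSignatureEdge(d, sid))
        for sym in _FIXTURE_GENES:
            z = float(np.round(rng.normal(0, 3), 4))
            sig_gene.append(SignatureGeneEdge(sid, sym, z))

    kg = KnowledgeGraph(drugs, genes, signatures, cells, concepts,
                        sig_gene, drug_sig, indications)
    return kg, DiseaseQuery(name_substring="Parkinson", atc_prefix="N")
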