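"""Disease query → drug set.

A disease is represented informatically by the set of approved drugs
indicated for it: concepts are matched by case-insensitive substring
search on the disease name, the drugs carrying an INDICATION edge to a
matched concept are collected, and an optional ATC class restriction (e.g.
level-1 prefix ``N``, nervous system) narrows the set to drugs whose
therapeutic class matches the disease etiology.  The resulting drug set is
the entry point for evidence-path scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import UsageError
from .graph_core import ConceptNode, KnowledgeGraph


@dataclass(frozen=True)
class DiseaseQuery:
    """Parameters of a disease query.

    ``name_substring`` is matched case-insensitively against concept names;
    ``atc_prefix``, when set, keeps only drugs with at least one ATC code
    starting with that prefix (drugs without ATC codes are dropped);
    ``require_in_lincs`` additionally drops drugs with no expression
    signatures.
    """

    name_substring: str
    atc_prefix: str | None = None
    require_in_lincs: bool = False

    def __post_init__(self):
        if not self.name_substring:
            raise UsageError("name_substring must be nonempty")


@dataclass
class DrugSet:
    """A disease-representing drug set: the matched disease concepts, the
    drugs indicated for them (ordered alphabetically by name), and the
    subset present in the expression-signature compendium."""

    matched_concepts: list[str] = field(default_factory=list)
    drugs: list[str] = field(default_factory=list)
    drugs_in_lincs: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.drugs)


def match_concepts(kg: KnowledgeGraph, name_substring: str) -> list[ConceptNode]:
    """Every Concept whose name contains ``name_substring``
    (case-insensitive), ordered by concept_id."""
    needle = name_substring.lower()
    hits = [c for c in kg.concepts.values() if needle in c.name.lower()]
    return sorted(hits, key=lambda c: c.concept_id)


def select_drug_set(kg: KnowledgeGraph, query: DiseaseQuery) -> DrugSet:
    """Resolve a disease query to its drug set.

    Drugs are those with an INDICATION edge to any matched concept, passing
    the ATC prefix restriction if one is set, ordered alphabetically by
    drug name (ties broken by drug_id for determinism).
    """
    concepts = match_concepts(kg, query.name_substring)
    concept_ids = [c.concept_id for c in concepts]

    drug_ids: set[str] = set()
    for cid in concept_ids:
        drug_ids.update(kg.concept_to_drugs.get(cid, ()))

    if query.atc_prefix is not None:
        drug_ids = {
            d for d in drug_ids
            if any(code.startswith(query.atc_prefix)
                   for code in kg.drugs[d].atc_codes)
        }
    if query.require_in_lincs:
        drug_ids = {d for d in drug_ids if kg.drugs[d].in_lincs}

    ordered = sorted(drug_ids, key=lambda d: (kg.drugs[d].name, d))
    in_lincs = [d for d in ordered if kg.drugs[d].in_lincs]
    return DrugSet(matched_concepts=concept_ids, drugs=ordered,
                   drugs_in_lincs=in_lincs)


def drug_set_frame(kg: KnowledgeGraph, ds: DrugSet) -> pd.DataFrame:
    """Tabulate a drug set as (name, drug_id, pubchem_cid, in_lincs)."""
    rows = []
    for d in ds.drugs:
        node = kg.drugs[d]
        rows.append({"name": node.name, "drug_id": d,
                     "pubchem_cid": node.pubchem_cid,
                     "in_lincs": node.in_lincs})
    return pd.DataFrame(rows, columns=["name", "drug_id", "pubchem_cid", "in_lincs"])
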