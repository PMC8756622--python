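"""Property-graph schema, TSV loading, indexing and export.

The knowledge graph has five node types — Drug, Signature, Gene, Cell,
Concept — and four relationship types:

* ``DRUG_SIGNATURE``: the drug (perturbagen) applied in an expression
  signature experiment;
* ``SIGNATURE_GENE``: carries the differential-expression z-score of a gene
  in one signature;
* ``CELL_SIGNATURE``: the cell line of a signature (stored as the
  ``cell_id`` foreign key on the Signature node);
* ``INDICATION``: a drug's approved clinical indication, pointing at a
  disease Concept.

Nodes and edges are loaded from UTF-8 tab-separated tables with a single
header row; column names are the field names below.  Unknown extra columns
are preserved as opaque string properties, mirroring schema-less property
graph loading, and survive an export/load round-trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import IntegrityError, SchemaError

NODE_TYPES = ("drug", "gene", "signature", "cell", "concept")
EDGE_TYPES = ("signature_gene", "drug_signature", "indication")

#: canonical file name for each collection, used by ``export_graph``/``load_dir``
CANONICAL_FILES = {
    "drug": "drugs.tsv",
    "gene": "genes.tsv",
    "signature": "signatures.tsv",
    "cell": "cells.tsv",
    "concept": "concepts.tsv",
    "signature_gene": "signature_gene.tsv",
    "drug_signature": "drug_signature.tsv",
    "indication": "indication.tsv",
}

TDL_LEVELS = ("Tclin", "Tchem", "Tbio", "Tdark")

_MAX_OFFENDERS = 10  # integrity errors list at most this many offending rows


@dataclass
class DrugNode:
    drug_id: str
    name: str
    pubchem_cid: int | None = None
    atc_codes: frozenset[str] = frozenset()
    in_lincs: bool = False
    props: dict[str, str] = field(default_factory=dict)


@dataclass
class GeneNode:
    gene_id: str
    symbol: str
    tdl: str | None = None
    family: str | None = None
    props: dict[str, str] = field(default_factory=dict)


@dataclass
class SignatureNode:
    signature_id: str
    cell_id: str
    props: dict[str, str] = field(default_factory=dict)


@dataclass
class CellNode:
    cell_id: str
    name: str | None = None
    props: dict[str, str] = field(default_factory=dict)


@dataclass
class ConceptNode:
    concept_id: str
    name: str = ""
    xrefs: dict[str, str] = field(default_factory=dict)
    props: dict[str, str] = field(default_factory=dict)


@dataclass
class SignatureGeneEdge:
    signature_id: str
    gene_id: str
    z: float
    props: dict[str, str] = field(default_factory=dict)


@dataclass
class DrugSignatureEdge:
    drug_id: str
    signature_id: str
    props: dict[str, str] = field(default_factory=dict)


@dataclass
class IndicationEdge:
    drug_id: str
    concept_id: str
    props: dict[str, str] = field(default_factory=dict)


class KnowledgeGraph:
    """Typed in-memory property graph with adjacency indexes.

    The in-memory analogue of the graph database: node collections keyed by
    id, edge collections per relationship type, and forward/reverse
    adjacency indexes for the Drug→Signature→Gene path pattern used by the
    scoring algorithm.  ``validate()`` asserts referential integrity and
    (re)builds the indexes; it runs automatically on construction.
    """

    def __init__(
        self,
        drugs: Iterable[DrugNode] = (),
        genes: Iterable[GeneNode] = (),
        signatures: Iterable[SignatureNode] = (),
        cells: Iterable[CellNode] = (),
        concepts: Iterable[ConceptNode] = (),
        signature_gene: Iterable[SignatureGeneEdge] = (),
        drug_signature: Iterable[DrugSignatureEdge] = (),
        indication: Iterable[IndicationEdge] = (),
        derive_in_lincs: bool = True,
    ):
        self.drugs = self._index_nodes(drugs, "drug_id", "drug")
        self.genes = self._index_nodes(genes, "gene_id", "gene")
        self.signatures = self._index_nodes(signatures, "signature_id", "signature")
        self.cells = self._index_nodes(cells, "cell_id", "cell")
        self.concepts = self._index_nodes(concepts, "concept_id", "concept")
        self.signature_gene = list(signature_gene)
        self.drug_signature = list(drug_signature)
        self.indication = list(indication)
        self.validate(derive_in_lincs=derive_in_lincs)

    @staticmethod
    def _index_nodes(nodes, key, type_name):
        out: dict = {}
        for n in nodes:
            k = getattr(n, key)
            if k in out:
                raise IntegrityError(f"duplicate {type_name} id {k!r}")
            out[k] = n
        return out

    # ------------------------------------------------------------------
    def validate(self, derive_in_lincs: bool = True) -> None:
        """Check all invariants and rebuild adjacency indexes.

        Raises :class:`IntegrityError` listing the first few offending
        edges on any dangling reference or duplicate edge.  When the
        ``in_lincs`` drug flag was supplied in input it must agree with the
        derivation "has at least one DRUG_SIGNATURE edge"; when it was not,
        it is derived here.
        """
        offenders: list[str] = []

        def check(cond: bool, msg: str) -> None:
            if not cond and len(offenders) < _MAX_OFFENDERS:
                offenders.append(msg)

        for s in self.signatures.values():
            check(s.cell_id in self.cells,
                  f"signature {s.signature_id!r} references unknown cell {s.cell_id!r}")

        seen_sg: set[tuple[str, str]] = set()
        for e in self.signature_gene:
            check(e.signature_id in self.signatures,
                  f"SIGNATURE_GENE references unknown signature {e.signature_id!r}")
            check(e.gene_id in self.genes,
                  f"SIGNATURE_GENE references unknown gene {e.gene_id!r}")
            check(math.isfinite(e.z),
                  f"SIGNATURE_GENE ({e.signature_id!r},{e.gene_id!r}) has non-finite z")
            key = (e.signature_id, e.gene_id)
            check(key not in seen_sg, f"duplicate SIGNATURE_GENE edge {key!r}")
            seen_sg.add(key)

        seen_ds: set[tuple[str, str]] = set()
        for e in self.drug_signature:
            check(e.drug_id in self.drugs,
                  f"DRUG_SIGNATURE references unknown drug {e.drug_id!r}")
            check(e.signature_id in self.signatures,
                  f"DRUG_SIGNATURE references unknown signature {e.signature_id!r}")
            key = (e.drug_id, e.signature_id)
            check(key not in seen_ds, f"duplicate DRUG_SIGNATURE edge {key!r}")
            seen_ds.add(key)

        seen_ind: set[tuple[str, str]] = set()
        for e in self.indication:
            check(e.drug_id in self.drugs,
                  f"INDICATION references unknown drug {e.drug_id!r}")
            check(e.concept_id in self.concepts,
                  f"INDICATION references unknown concept {e.concept_id!r}")
            key = (e.drug_id, e.concept_id)
            check(key not in seen_ind, f"duplicate INDICATION edge {key!r}")
            seen_ind.add(key)

        if offenders:
            raise IntegrityError(
                "graph integrity violated (first offenders):\n  "
                + "\n  ".join(offenders)
            )

        # adjacency indexes for path queries
        self.drug_to_signatures: dict[str, list[str]] = {}
        for e in self.drug_signature:
            self.drug_to_signatures.setdefault(e.drug_id, []).append(e.signature_id)
        self.signature_to_genes: dict[str, list[tuple[str, float]]] = {}
        for e in self.signature_gene:
            self.signature_to_genes.setdefault(e.signature_id, []).append(
                (e.gene_id, e.z))
        self.concept_to_drugs: dict[str, list[str]] = {}
        self.drug_to_concepts: dict[str, list[str]] = {}
        for e in self.indication:
            self.concept_to_drugs.setdefault(e.concept_id, []).append(e.drug_id)
            self.drug_to_concepts.setdefault(e.drug_id, []).append(e.concept_id)

        for d in self.drugs.values():
            derived = len(self.drug_to_signatures.get(d.drug_id, ())) > 0
            if d.props.pop("_in_lincs_given", None) is not None:
                if d.in_lincs != derived:
                    raise IntegrityError(
                        f"drug {d.drug_id!r}: in_lincs flag "
                        f"{d.in_lincs} disagrees with DRUG_SIGNATURE degree "
                        f"({'>0' if derived else '0'})")
            elif derive_in_lincs:
                d.in_lincs = derived

    # ------------------------------------------------------------------
    def node_counts(self) -> dict[str, int]:
        return {
            "Drug": len(self.drugs),
            "Gene": len(self.genes),
            "Signature": len(self.signatures),
            "Cell": len(self.cells),
            "Concept": len(self.concepts),
        }

    def edge_counts(self) -> dict[tuple[str, str, str], int]:
        return {
            ("Signature", "SIGNATURE_GENE", "Gene"): len(self.signature_gene),
            ("Cell", "CELL_SIGNATURE", "Signature"): len(self.signatures),
            ("Drug", "DRUG_SIGNATURE", "Signature"): len(self.drug_signature),
            ("Drug", "INDICATION", "Concept"): len(self.indication),
        }


@dataclass
class MetaGraph:
    """Schema report: node types with counts and (source, relationship,
    target) patterns with counts, restricted to nonempty collections."""

    nodes: list[tuple[str, int]]
    edges: list[tuple[str, str, str, int]]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"source": s, "relationship": r, "target": t, "count": c}
                for s, r, t, c in self.edges]
        return pd.DataFrame(rows)


def meta_graph(kg: KnowledgeGraph) -> MetaGraph:
    """Report the meta-graph: which node and relationship types are present
    and how many instances of each the graph holds."""
    nodes = [(t, c) for t, c in kg.node_counts().items() if c > 0]
    edges = [(s, r, t, c) for (s, r, t), c in kg.edge_counts().items() if c > 0]
    return MetaGraph(nodes=nodes, edges=edges)


# ----------------------------------------------------------------------
# TSV loading

_REQUIRED_COLS = {
    "drug": ["drug_id", "name"],
    "gene": ["gene_id", "symbol"],
    "signature": ["signature_id", "cell_id"],
    "cell": ["cell_id"],
    "concept": ["concept_id", "name"],
    "signature_gene": ["signature_id", "gene_id", "z"],
    "drug_signature": ["drug_id", "signature_id"],
    "indication": ["drug_id", "concept_id"],
}

_OPTIONAL_COLS = {
    "drug": ["pubchem_cid", "atc_codes", "in_lincs"],
    "gene": ["tdl", "family"],
    "cell": ["name"],
    "concept": ["xrefs"],
}


def _read_tsv(path, type_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLS[type_name] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing} for type {type_name!r}")
    return df

def _parse_bool(val: str, path, line: int) -> bool:
    v = val.strip().lower()
    if v in ("true", "1", "t", "yes"):
        return True
    if v in ("false", "0", "f", "no"):
        return False
    raise SchemaError(f"{path}:{line}: cannot parse boolean {val!r}")


def _props(row: pd.Series, known: set[str]) -> dict[str, str]:
    return {k: v for k, v in row.items() if k not in known and v != ""}


def load_graph(
    node_files: Mapping[str, Path | str],
    edge_files: Mapping[str, Path | str],
    dedup: bool = False,
) -> KnowledgeGraph:
    """Load a knowledge graph from TSV node and edge tables.

    Parameters
    ----------
    node_files
        Map from node type (``drug``, ``gene``, ``signature``, ``cell``,
        ``concept``) to file path.  Missing types yield empty collections.
    edge_files
        Map from edge type (``signature_gene``, ``drug_signature``,
        ``indication``) to file path.
    dedup
        Keep the first occurrence of a duplicate edge instead of failing.

    Raises
    ------
    SchemaError
        Missing required column, or an unparseable z / boolean value (the
        message names the file and line).
    IntegrityError
        An edge endpoint absent from the node tables, or a duplicate key.
    """
    for t in node_files:
        if t not in NODE_TYPES:
            raise SchemaError(f"unknown node type {t!r}")
    for t in edge_files:
        if t not in EDGE_TYPES:
            raise SchemaError(f"unknown edge type {t!r}")

    drugs: list[DrugNode] = []
    if "drug" in node_files:
        path = node_files["drug"]
        df = _read_tsv(path, "drug")
        known = set(_REQUIRED_COLS["drug"]) | set(_OPTIONAL_COLS["drug"])
        for i, row in df.iterrows():
            line = i + 2  # header is line 1
            cid_s = row.get("pubchem_cid", "")
            try:
                cid = int(cid_s) if cid_s != "" else None
            except ValueError:
                raise SchemaError(
                    f"{path}:{line}: cannot parse pubchem_cid {cid_s!r}") from None
            atc = frozenset(a for a in row.get("atc_codes", "").split("|") if a)
            props = _props(row, known)
            in_lincs_s = row.get("in_lincs", "")
            d = DrugNode(row["drug_id"], row["name"], cid, atc, props=props)
            if in_lincs_s != "":
                d.in_lincs = _parse_bool(in_lincs_s, path, line)
                d.props["_in_lincs_given"] = "1"
            drugs.append(d)

    genes: list[GeneNode] = []
    if "gene" in node_files:
        path = node_files["gene"]
        df = _read_tsv(path, "gene")
        known = set(_REQUIRED_COLS["gene"]) | set(_OPTIONAL_COLS["gene"])
        for i, row in df.iterrows():
            tdl = row.get("tdl", "") or None
            if tdl is not None and tdl not in TDL_LEVELS:
                raise SchemaError(
                    f"{path}:{i + 2}: tdl must be one of {TDL_LEVELS}, got {tdl!r}")
            genes.append(GeneNode(row["gene_id"], row["symbol"], tdl,
                                  row.get("family", "") or None,
                                  props=_props(row, known)))

    signatures: list[SignatureNode] = []
    if "signature" in node_files:
        df = _read_tsv(node_files["signature"], "signature")
        known = set(_REQUIRED_COLS["signature"])
        signatures = [SignatureNode(r["signature_id"], r["cell_id"],
                                    props=_props(r, known))
                      for _, r in df.iterrows()]

    cells: list[CellNode] = []
    if "cell" in node_files:
        df = _read_tsv(node_files["cell"], "cell")
        known = set(_REQUIRED_COLS["cell"]) | set(_OPTIONAL_COLS["cell"])
        cells = [CellNode(r["cell_id"], r.get("name", "") or None,
                          props=_props(r, known))
                 for _, r in df.iterrows()]

    concepts: list[ConceptNode] = []
    if "concept" in node_files:
        df = _read_tsv(node_files["concept"], "concept")
        known = set(_REQUIRED_COLS["concept"]) | set(_OPTIONAL_COLS["concept"])
        for _, r in df.iterrows():
            xrefs = {}
            for pair in r.get("xrefs", "").split("|"):
                if ":" in pair:
                    k, _, v = pair.partition(":")
                    xrefs[k] = v
            concepts.append(ConceptNode(r["concept_id"], r["name"], xrefs,
                                        props=_props(r, known)))

    sg: list[SignatureGeneEdge] = []
    if "signature_gene" in edge_files:
        path = edge_files["signature_gene"]
        df = _read_tsv(path, "signature_gene")
        known = set(_REQUIRED_COLS["signature_gene"])
        seen: set[tuple[str, str]] = set()
        for i, row in df.iterrows():
            try:
                z = float(row["z"])
            except ValueError:
                raise SchemaError(
                    f"{path}:{i + 2}: cannot parse z {row['z']!r}") from None
            key = (row["signature_id"], row["gene_id"])
            if key in seen:
                if dedup:
                    continue
                raise IntegrityError(
                    f"{path}:{i + 2}: duplicate SIGNATURE_GENE edge {key!r}")
            seen.add(key)
            sg.append(SignatureGeneEdge(key[0], key[1], z, props=_props(row, known)))

    ds: list[DrugSignatureEdge] = []
    if "drug_signature" in edge_files:
        path = edge_files["drug_signature"]
        df = _read_tsv(path, "drug_signature")
        known = set(_REQUIRED_COLS["drug_signature"])
        seen = set()
        for i, row in df.iterrows():
            key = (row["drug_id"], row["signature_id"])
            if key in seen:
                if dedup:
                    continue
                raise IntegrityError(
                    f"{path}:{i + 2}: duplicate DRUG_SIGNATURE edge {key!r}")
            seen.add(key)
            ds.append(DrugSignatureEdge(key[0], key[1], props=_props(row, known)))

    ind: list[IndicationEdge] = []
    if "indication" in edge_files:
        path = edge_files["indication"]
        df = _read_tsv(path, "indication")
        known = set(_REQUIRED_COLS["indication"])
        seen = set()
        for i, row in df.iterrows():
            key = (row["drug_id"], row["concept_id"])
            if key in seen:
                if dedup:
                    continue
                raise IntegrityError(
                    f"{path}:{i + 2}: duplicate INDICATION edge {key!r}")
            seen.add(key)
            ind.append(IndicationEdge(key[0], key[1], props=_props(row, known)))

    return KnowledgeGraph(drugs, genes, signatures, cells, concepts, sg, ds, ind)


def load_dir(directory: Path | str, dedup: bool = False) -> KnowledgeGraph:
    """Load a graph from a directory of canonically named TSVs (the layout
    written by :func:`export_graph`)."""
    directory = Path(directory)
    node_files = {t: directory / CANONICAL_FILES[t] for t in NODE_TYPES
                  if (directory / CANONICAL_FILES[t]).exists()}
    edge_files = {t: directory / CANONICAL_FILES[t] for t in EDGE_TYPES
                  if (directory / CANONICAL_FILES[t]).exists()}
    return load_graph(node_files, edge_files, dedup=dedup)


# ----------------------------------------------------------------------
# Export

def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)  # shortest round-trippable representation
    return str(v)


def _write_table(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def export_graph(kg: KnowledgeGraph, out_dir: Path | str) -> dict[str, Path]:
    """Write the graph as canonical TSVs round-trippable by ``load_graph``.

    Keys are sorted so exports are byte-deterministic; z-scores are written
    with full (shortest round-trippable) precision.  Returns the map of
    collection name to file path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def extra_keys(items) -> list[str]:
        keys: set[str] = set()
        for it in items:
            keys.update(k for k in it.props if not k.startswith("_"))
        return sorted(keys)

    ex = extra_keys(kg.drugs.values())
    rows = [[d.drug_id, d.name, d.pubchem_cid, "|".join(sorted(d.atc_codes)),
             d.in_lincs] + [d.props.get(k, "") for k in ex]
            for d in sorted(kg.drugs.values(), key=lambda d: d.drug_id)]
    paths["drug"] = out_dir / CANONICAL_FILES["drug"]
    _write_table(paths["drug"],
                 ["drug_id", "name", "pubchem_cid", "atc_codes", "in_lincs"] + ex,
                 rows)

    ex = extra_keys(kg.genes.values())
    rows = [[g.gene_id, g.symbol, g.tdl or "", g.family or ""]
            + [g.props.get(k, "") for k in ex]
            for g in sorted(kg.genes.values(), key=lambda g: g.gene_id)]
    paths["gene"] = out_dir / CANONICAL_FILES["gene"]
    _write_table(paths["gene"], ["gene_id", "symbol", "tdl", "family"] + ex, rows)

    ex = extra_keys(kg.signatures.values())
    rows = [[s.signature_id, s.cell_id] + [s.props.get(k, "") for k in ex]
            for s in sorted(kg.signatures.values(), key=lambda s: s.signature_id)]
    paths["signature"] = out_dir / CANONICAL_FILES["signature"]
    _write_table(paths["signature"], ["signature_id", "cell_id"] + ex, rows)

    ex = extra_keys(kg.cells.values())
    rows = [[c.cell_id, c.name or ""] + [c.props.get(k, "") for k in ex]
            for c in sorted(kg.cells.values(), key=lambda c: c.cell_id)]
    paths["cell"] = out_dir / CANONICAL_FILES["cell"]
    _write_table(paths["cell"], ["cell_id", "name"] + ex, rows)

    ex = extra_keys(kg.concepts.values())
    rows = [[c.concept_id, c.name,
             "|".join(f"{k}:{v}" for k, v in sorted(c.xrefs.items()))]
            + [c.props.get(k, "") for k in ex]
            for c in sorted(kg.concepts.values(), key=lambda c: c.concept_id)]
    paths["concept"] = out_dir / CANONICAL_FILES["concept"]
    _write_table(paths["concept"], ["concept_id", "name", "xrefs"] + ex, rows)

    ex = extra_keys(kg.signature_gene)
    rows = [[e.signature_id, e.gene_id, e.z] + [e.props.get(k, "") for k in ex]
            for e in sorted(kg.signature_gene,
                            key=lambda e: (e.signature_id, e.gene_id))]
    paths["signature_gene"] = out_dir / CANONICAL_FILES["signature_gene"]
    _write_table(paths["signature_gene"], ["signature_id", "gene_id", "z"] + ex, rows)

    ex = extra_keys(kg.drug_signature)
    rows = [[e.drug_id, e.signature_id] + [e.props.get(k, "") for k in ex]
            for e in sorted(kg.drug_signature,
                            key=lambda e: (e.drug_id, e.signature_id))]
    paths["drug_signature"] = out_dir / CANONICAL_FILES["drug_signature"]
    _write_table(paths["drug_signature"], ["drug_id", "signature_id"] + ex, rows)

    ex = extra_keys(kg.indication)
    rows = [[e.drug_id, e.concept_id] + [e.props.get(k, "") for k in ex]
            for e in sorted(kg.indication, key=lambda e: (e.drug_id, e.concept_id))]
    paths["indication"] = out_dir / CANONICAL_FILES["indication"]
    _write_table(paths["indication"], ["drug_id", "concept_id"] + ex, rows)

    return paths


def to_cypher(kg: KnowledgeGraph) -> str:
    """Generate a Cypher CREATE script for loading this graph into a Neo4j
    instance.  Generation only; no server interaction."""

    def esc(s: str) -> str:
        return s.replace("\\", "\\\\").replace("'", "\\'")

    lines = []
    for d in sorted(kg.drugs.values(), key=lambda d: d.drug_id):
        props = [f"drug_id:'{esc(d.drug_id)}'", f"name:'{esc(d.name)}'",
                 f"in_lincs:{'true' if d.in_lincs else 'false'}"]
        if d.pubchem_cid is not None:
            props.append(f"pubchem_cid:{d.pubchem_cid}")
        if d.atc_codes:
            codes = ",".join(f"'{esc(a)}'" for a in sorted(d.atc_codes))
            props.append(f"atc_codes:[{codes}]")
        lines.append(f"CREATE (:Drug {{{', '.join(props)}}});")
    for g in sorted(kg.genes.values(), key=lambda g: g.gene_id):
        props = [f"gene_id:'{esc(g.gene_id)}'", f"symbol:'{esc(g.symbol)}'"]
        if g.tdl:
            props.append(f"tdl:'{g.tdl}'")
        lines.append(f"CREATE (:Gene {{{', '.join(props)}}});")
    for c in sorted(kg.cells.values(), key=lambda c: c.cell_id):
        lines.append(f"CREATE (:Cell {{cell_id:'{esc(c.cell_id)}'}});")
    for s in sorted(kg.signatures.values(), key=lambda s: s.signature_id):
        lines.append(
            f"CREATE (:Signature {{signature_id:'{esc(s.signature_id)}'}});")
    for c in sorted(kg.concepts.values(), key=lambda c: c.concept_id):
        lines.append(f"CREATE (:Concept {{concept_id:'{esc(c.concept_id)}', "
                     f"name:'{esc(c.name)}'}});")
    for s in sorted(kg.signatures.values(), key=lambda s: s.signature_id):
        lines.append(
            f"MATCH (c:Cell {{cell_id:'{esc(s.cell_id)}'}}), "
            f"(s:Signature {{signature_id:'{esc(s.signature_id)}'}}) "
            f"CREATE (c)-[:CELL_SIGNATURE]->(s);")
    for e in sorted(kg.drug_signature, key=lambda e: (e.drug_id, e.signature_id)):
        lines.append(
            f"MATCH (d:Drug {{drug_id:'{esc(e.drug_id)}'}}), "
            f"(s:Signature {{signature_id:'{esc(e.signature_id)}'}}) "
            f"CREATE (d)-[:DRUG_SIGNATURE]->(s);")
    for e in sorted(kg.signature_gene, key=lambda e: (e.signature_id, e.gene_id)):
        lines.append(
            f"MATCH (s:Signature {{signature_id:'{esc(e.signature_id)}'}}), "
            f"(g:Gene {{gene_id:'{esc(e.gene_id)}'}}) "
            f"CREATE (s)-[:SIGNATURE_GENE {{z:{e.z!r}}}]->(g);")
    for e in sorted(kg.indication, key=lambda e: (e.drug_id, e.concept_id)):
        lines.append(
            f"MATCH (d:Drug {{drug_id:'{esc(e.drug_id)}'}}), "
            f"(c:Concept {{concept_id:'{esc(e.concept_id)}'}}) "
            f"CREATE (d)-[:INDICATION]->(c);")
    return "\n".join(lines) + "\n"
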