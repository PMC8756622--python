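"""Schema loading, referential integrity, meta-graph and round-trip export."""

import dataclasses

import pytest

from kgap.exceptions import IntegrityError, SchemaError
from kgap.graph_core import (
    export_graph,
    load_dir,
    load_graph,
    meta_graph,
    to_cypher,
)
from kgap.synthetic import SyntheticSpec, generate

from conftest import make_toy_graph


def write_tsv(path, header, rows):
    path.write_text("\n".join(["\t".join(header)]
                              + ["\t".join(map(str, r)) for r in rows]) + "\n")


@pytest.fixture
def toy_files(tmp_path):
    write_tsv(tmp_path / "drugs.tsv",
              ["drug_id", "name", "atc_codes"],
              [["d1", "alphadrug", "N04AA"], ["d2", "betadrug", "C01AB"]])
    write_tsv(tmp_path / "genes.tsv", ["gene_id", "symbol"],
              [[f"g{i}", f"GENE{i}"] for i in range(1, 5)])
    write_tsv(tmp_path / "signatures.tsv", ["signature_id", "cell_id"],
              [["s1", "c1"], ["s2", "c1"], ["s3", "c1"]])
    write_tsv(tmp_path / "cells.tsv", ["cell_id", "name"], [["c1", "toy"]])
    write_tsv(tmp_path / "concepts.tsv", ["concept_id", "name"],
              [["omop:1", "Toy syndrome"]])
    write_tsv(tmp_path / "signature_gene.tsv", ["signature_id", "gene_id", "z"],
              [["s1", "g1", 4.2], ["s1", "g2", -3.5], ["s2", "g3", 1.0],
               ["s3", "g4", -6.0]])
    write_tsv(tmp_path / "drug_signature.tsv", ["drug_id", "signature_id"],
              [["d1", "s1"], ["d1", "s2"], ["d2", "s3"]])
    write_tsv(tmp_path / "indication.tsv", ["drug_id", "concept_id"],
              [["d1", "omop:1"], ["d2", "omop:1"]])
    return tmp_path


def test_load_counts_match_input_rows(toy_files):
    kg = load_dir(toy_files)
    assert kg.node_counts() == {"Drug": 2, "Gene": 4, "Signature": 3,
                                "Cell": 1, "Concept": 1}
    assert kg.edge_counts()[("Signature", "SIGNATURE_GENE", "Gene")] == 4
    assert kg.edge_counts()[("Drug", "DRUG_SIGNATURE", "Signature")] == 3


def test_in_lincs_derived_from_drug_signature_degree(toy_files):
    kg = load_dir(toy_files)
    assert kg.drugs["d1"].in_lincs and kg.drugs["d2"].in_lincs


def test_supplied_in_lincs_flag_must_agree_with_degree(toy_files):
    write_tsv(toy_files / "drugs.tsv",
              ["drug_id", "name", "atc_codes", "in_lincs"],
              [["d1", "alphadrug", "N04AA", "false"],
               ["d2", "betadrug", "C01AB", "true"]])
    with pytest.raises(IntegrityError, match="in_lincs"):
        load_dir(toy_files)


def test_edge_to_unknown_signature_names_offender(toy_files):
    write_tsv(toy_files / "drug_signature.tsv", ["drug_id", "signature_id"],
              [["d1", "s1"], ["d1", "sMISSING"]])
    with pytest.raises(IntegrityError, match="sMISSING"):
        load_dir(toy_files)


def test_missing_required_column_is_schema_error(toy_files):
    write_tsv(toy_files / "signature_gene.tsv", ["signature_id", "gene_id"],
              [["s1", "g1"]])
    with pytest.raises(SchemaError, match="z"):
        load_dir(toy_files)


def test_non_numeric_z_reports_file_and_line(toy_files):
    write_tsv(toy_files / "signature_gene.tsv", ["signature_id", "gene_id", "z"],
              [["s1", "g1", "4.2"], ["s1", "g2", "high"]])
    with pytest.raises(SchemaError, match=r"signature_gene\.tsv:3"):
        load_dir(toy_files)


def test_duplicate_edge_fails_unless_dedup(toy_files):
    write_tsv(toy_files / "indication.tsv", ["drug_id", "concept_id"],
              [["d1", "omop:1"], ["d1", "omop:1"]])
    with pytest.raises(IntegrityError, match="duplicate"):
        load_dir(toy_files)
    kg = load_dir(toy_files, dedup=True)
    assert len(kg.indication) == 1


def test_unknown_extra_columns_preserved_through_round_trip(toy_files, tmp_path):
    write_tsv(toy_files / "cells.tsv", ["cell_id", "name", "tissue"],
              [["c1", "toy", "breast"]])
    kg = load_dir(toy_files)
    assert kg.cells["c1"].props["tissue"] == "breast"
    out = tmp_path / "rt"
    export_graph(kg, out)
    assert load_dir(out).cells["c1"].props["tissue"] == "breast"


def test_meta_graph_empty_and_toy(toy_graph):
    from kgap.graph_core import KnowledgeGraph

    empty = meta_graph(KnowledgeGraph())
    assert empty.nodes == [] and empty.edges == []

    mg = meta_graph(toy_graph)
    assert len(mg.nodes) == 5
    assert {(s, r, t) for s, r, t, _ in mg.edges} == {
        ("Signature", "SIGNATURE_GENE", "Gene"),
        ("Cell", "CELL_SIGNATURE", "Signature"),
        ("Drug", "DRUG_SIGNATURE", "Signature"),
        ("Drug", "INDICATION", "Concept"),
    }
    assert dict(mg.nodes)["Gene"] == 4


def test_meta_graph_synthetic_default_edge_patterns(planted):
    kg, _ = planted
    patterns = {(s, r, t) for s, r, t, _ in meta_graph(kg).edges}
    assert patterns == {
        ("Signature", "SIGNATURE_GENE", "Gene"),
        ("Cell", "CELL_SIGNATURE", "Signature"),
        ("Drug", "DRUG_SIGNATURE", "Signature"),
        ("Drug", "INDICATION", "Concept"),
    }


def deep_equal(a, b):
    """Element-wise comparison of two graphs: keys, fields and z values."""
    if a.node_counts() != b.node_counts() or a.edge_counts() != b.edge_counts():
        return False
    for coll in ("drugs", "genes", "signatures", "cells", "concepts"):
        da, db = getattr(a, coll), getattr(b, coll)
        if set(da) != set(db):
            return False
        for k in da:
            if dataclasses.asdict(da[k]) != dataclasses.asdict(db[k]):
                return False
    for coll in ("signature_gene", "drug_signature", "indication"):
        ea = sorted(map(dataclasses.asdict, getattr(a, coll)), key=str)
        eb = sorted(map(dataclasses.asdict, getattr(b, coll)), key=str)
        if ea != eb:
            return False
    return True


def test_round_trip_identity_toy(toy_graph, tmp_path):
    export_graph(toy_graph, tmp_path / "g")
    again = load_dir(tmp_path / "g")
    assert deep_equal(toy_graph, again)
    assert meta_graph(again).edges == meta_graph(toy_graph).edges


def test_round_trip_identity_synthetic_10k_edges(tmp_path):
    kg, _ = generate(SyntheticSpec(n_genes=250, edge_density=0.2, seed=3))
    assert len(kg.signature_gene) >= 5000
    export_graph(kg, tmp_path / "g")
    assert deep_equal(kg, load_dir(tmp_path / "g"))


def test_round_trip_preserves_z_to_full_precision(tmp_path):
    zs = {("s1", "g1"): 0.1 + 0.2, ("s1", "g2"): -3.5000000000000004,
          ("s2", "g3"): 1e-17, ("s3", "g4"): -6.0}
    kg = make_toy_graph(zs)
    export_graph(kg, tmp_path / "g")
    again = load_dir(tmp_path / "g")
    z_of = {(e.signature_id, e.gene_id): e.z for e in again.signature_gene}
    for key, z in zs.items():
        assert z_of[key] == z  # bit-exact


def test_cypher_export_mentions_all_entities(toy_graph):
    script = to_cypher(toy_graph)
    assert script.count("CREATE (:Drug") == 2
    assert script.count("SIGNATURE_GENE") == 5
    assert "INDICATION" in script and "CELL_SIGNATURE" in script
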