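"""Path enumeration and Stouffer aggregation."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kgap.exceptions import UsageError
from kgap.scoring import (
    EvidencePath,
    ScoreParams,
    enumerate_paths,
    score_genes,
    stouffer_aggregate,
)
from kgap.synthetic import SyntheticSpec, generate

from conftest import make_toy_graph


# ---------------------------------------------------------------- stouffer

def test_single_value_identity():
    for z in (-7.3, 0.0, 2.5):
        assert stouffer_aggregate([z], [1.0]) == z


def test_equal_values_give_sum_over_sqrt_k():
    assert stouffer_aggregate([3, 3, 3, 3]) == pytest.approx(6.0, abs=0)


def test_formula_oracle_1000_random_inputs():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        k = int(rng.integers(1, 20))
        z = rng.normal(0, 5, k)
        w = rng.uniform(0.1, 3.0, k)
        expected = float(np.sum(w * z) / np.sqrt(np.sum(w ** 2)))
        got = stouffer_aggregate(z.tolist(), w.tolist())
        assert got == pytest.approx(expected, rel=1e-12)


def test_empty_and_zero_weight_inputs_rejected():
    with pytest.raises(UsageError):
        stouffer_aggregate([])
    with pytest.raises(UsageError):
        stouffer_aggregate([1.0, 2.0], [0.0, 0.0])
    with pytest.raises(UsageError):
        stouffer_aggregate([1.0], [1.0, 2.0])


@given(st.lists(st.floats(-10, 10), min_size=1, max_size=12),
       st.floats(-4, 4))
@settings(deadline=None, derandomize=True)
def test_scale_equivariance(zs, c):
    base = stouffer_aggregate(zs)
    scaled = stouffer_aggregate([c * z for z in zs])
    assert scaled == pytest.approx(c * base, rel=1e-9, abs=1e-9)


# ---------------------------------------------------------------- paths

def test_threshold_is_strict_at_boundary():
    kg = make_toy_graph({("s1", "g1"): 3.0})
    assert enumerate_paths(kg, ["d1"], 3.0) == []


def test_toy_paths_above_magnitude_threshold(toy_graph):
    paths = enumerate_paths(kg := toy_graph, ["d1"], 3.0)
    assert {(p.signature_id, p.gene_id) for p in paths} == {
        ("s1", "g1"), ("s1", "g2")}
    both = enumerate_paths(kg, ["d1", "d2"], 3.0)
    assert {(p.gene_id, p.z) for p in both} == {
        ("g1", 4.2), ("g2", -3.5), ("g4", -6.0)}


def test_empty_drug_set_is_usage_error(toy_graph):
    with pytest.raises(UsageError):
        enumerate_paths(toy_graph, [], 3.0)


def brute_force_paths(kg, drug_ids, thr):
    """Independent oracle: exhaustive triple loop over (d, s, g)."""
    ds = {(e.drug_id, e.signature_id) for e in kg.drug_signature}
    sg = {(e.signature_id, e.gene_id): e.z for e in kg.signature_gene}
    out = set()
    for d in drug_ids:
        for s in kg.signatures:
            if (d, s) not in ds:
                continue
            for g in kg.genes:
                z = sg.get((s, g))
                if z is not None and abs(z) > thr:
                    out.add((d, s, g, z))
    return out


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_enumeration_matches_exhaustive_triple_loop(seed):
    spec = SyntheticSpec(n_drugs=6, n_query_drugs=3, n_signatures_per_drug=4,
                         n_cells=2, n_genes=40, n_true_targets=4,
                         edge_density=0.8, effect_mu=2.0, seed=seed)
    kg, truth = generate(spec)
    assert len(kg.signature_gene) <= 1000
    for thr in (0.5, 3.0):
        got = {(p.drug_id, p.signature_id, p.gene_id, p.z)
               for p in enumerate_paths(kg, truth.query_drug_ids, thr)}
        assert got == brute_force_paths(kg, truth.query_drug_ids, thr)
        assert len(got) == len(enumerate_paths(kg, truth.query_drug_ids, thr))


# ---------------------------------------------------------------- scoring

def paths_for(spec):
    return [EvidencePath(d, s, g, z) for d, s, g, z in spec]


def test_mode_z_many_weak_paths_vs_one_strong():
    paths = paths_for([("d", f"s{i}", "gA", 4.0) for i in range(4)]
                      + [("d", "s9", "gB", 9.0)])
    scores = {s.gene_id: s for s in score_genes(paths, ScoreParams(mode="Z"))}
    assert scores["gA"].score == pytest.approx(8.0)
    assert scores["gB"].score == pytest.approx(9.0)
    assert scores["gB"].rank == 1 and scores["gA"].rank == 2


def test_mode_d_is_sqrt_path_count():
    paths = paths_for([("d", f"s{i}", "gA", 4.0) for i in range(4)]
                      + [("d", "s9", "gB", 9.0)])
    scores = {s.gene_id: s for s in score_genes(paths, ScoreParams(mode="D"))}
    assert scores["gA"].score == pytest.approx(2.0)
    assert scores["gB"].score == pytest.approx(1.0)
    assert scores["gA"].rank == 1


def test_mode_d_rank_order_equals_path_count_order(planted):
    kg, truth = planted
    paths = enumerate_paths(kg, truth.query_drug_ids, 3.0)
    ranked = score_genes(paths, ScoreParams(mode="D"))
    counts = {}
    for p in paths:
        counts[p.gene_id] = counts.get(p.gene_id, 0) + 1
    oracle = sorted(counts, key=lambda g: (-counts[g], g))
    assert [s.gene_id for s in ranked] == oracle
    for s in ranked:
        assert s.k == counts[s.gene_id]
        assert s.score == pytest.approx(math.sqrt(s.k))


def test_score_genes_matches_groupby_formula_oracle(planted):
    kg, truth = planted
    paths = enumerate_paths(kg, truth.query_drug_ids, 3.0)
    got = {s.gene_id: s for s in score_genes(paths, ScoreParams(mode="Z"))}
    by_gene = {}
    for p in paths:
        by_gene.setdefault(p.gene_id, []).append(abs(p.z))
    assert set(got) == set(by_gene)
    for g, zs in by_gene.items():
        assert got[g].k == len(zs)
        assert got[g].score == pytest.approx(sum(zs) / math.sqrt(len(zs)),
                                             rel=1e-12)


def test_signed_z_mode_can_cancel():
    paths = paths_for([("d", "s1", "gA", 5.0), ("d", "s2", "gA", -5.0)])
    signed = score_genes(paths, ScoreParams(mode="Z", use_absolute_z=False))
    absolute = score_genes(paths, ScoreParams(mode="Z"))
    assert signed[0].score == pytest.approx(0.0)
    assert absolute[0].score == pytest.approx(10.0 / math.sqrt(2))


def test_appending_strong_path_increases_scores():
    base = paths_for([("d", "s1", "gA", 4.0), ("d", "s2", "gA", 5.0)])
    extra = base + paths_for([("d", "s3", "gA", 6.0)])  # above the mean |z|
    for mode in ("D", "Z"):
        s0 = score_genes(base, ScoreParams(mode=mode))[0].score
        s1 = score_genes(extra, ScoreParams(mode=mode))[0].score
        assert s1 > s0


def test_ranked_output_deterministic_under_path_shuffling(planted):
    kg, truth = planted
    paths = enumerate_paths(kg, truth.query_drug_ids, 3.0)
    baseline = score_genes(paths, ScoreParams(mode="Z"))
    rng = random.Random(1)
    for _ in range(3):
        shuffled = paths[:]
        rng.shuffle(shuffled)
        assert score_genes(shuffled, ScoreParams(mode="Z")) == baseline


def test_empty_path_list_gives_empty_hitlist():
    assert score_genes([], ScoreParams()) == []
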