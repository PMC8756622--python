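# kgap — knowledge-graph evidence-path aggregation for drug-target illumination

`kgap` identifies and ranks candidate drug-target genes for a disease by
aggregating *evidence paths* through a biomedical knowledge graph.  It is
aimed at computational drug-discovery researchers who want an
interpretable, training-free alternative to learned link-prediction
models: every unit of evidence is a concrete Drug→Signature→Gene
traversal that a domain scientist can inspect.

## The method

The graph has five node types — **Drug**, **Signature** (one
perturbation experiment's differential-expression profile), **Gene**,
**Cell** (the line the signature was measured in) and **Concept**
(disease/indication term) — and four relationships: `INDICATION`
(drug → disease concept), `DRUG_SIGNATURE`, `CELL_SIGNATURE`, and
`SIGNATURE_GENE`, which carries the per-gene differential-expression
z-score.

1. **Disease → drug set.** A case-insensitive substring search over
   Concept names, optionally restricted by ATC therapeutic class (e.g.
   level-1 prefix `N`, nervous system), selects the approved drugs that
   represent the disease.
2. **Evidence paths.** All Drug→Signature→Gene paths from those drugs
   with |z| > 3 (strict) are enumerated.
3. **Per-gene score.** The k paths of gene *g* are combined with
   Stouffer's z-score meta-analysis function,

   Z = Σᵢ wᵢZᵢ / √(Σᵢ wᵢ²),  all wᵢ = 1,

   in two modes: **Z-weighted** (Zᵢ = |zᵢ|, score = Σ|zᵢ|/√k) and
   **D-weighted** (Zᵢ = 1, score = √k, i.e. signature-degree only).
4. **Validation.** The ranked hitlist is scored by ROC/AUC against
   known-target gene sets — an *enrichment* measure, not a classifier
   metric; ties count ½ so the trapezoidal AUC equals the normalized
   Mann–Whitney U statistic.
5. **Prioritization.** Hits are annotated with target development level
   (Tclin/Tchem/Tbio/Tdark) and ranked by successive non-dominated
   (Pareto) fronts over bibliometric novelty × importance (`nds_rank`),
   surfacing understudied (Tdark) candidates.

A synthetic-graph generator with plantable drug→gene signal makes the
whole pipeline testable offline, and a packaged fixture reproduces the
published Parkinson's-disease drug-set query: the substring "Parkinson"
matches 5 disease concepts and, with the ATC-N restriction, returns 25
drugs of which 22 are LINCS members.

### Published full-scale results (documented, not reproduced here)

The original full-scale study ran on LINCS L1000 Level 5 signatures
joined with DrugCentral and TCRD — a graph with 45,623,637
SIGNATURE_GENE edges.  At that scale the Parkinson's query yields a
641-gene hitlist, validation AUCs range 0.64–0.74, and the top-ranked
Tdark gene is SYNGR3 (TIN-X nds_rank 6 of 103).  Those numbers are
properties of external database snapshots; this package reproduces the
*method* and its desk-scale contracts, not the snapshot-dependent
values.

## Worked example

Generate a synthetic graph (5 query drugs, 10 planted true-target genes,
planted |z| effect 4), resolve the disease query, score, and validate:

```
$ kgap simulate --out demo --seed 17
$ kgap query --graph demo --disease "Synthetic query" --out query_drugs.tsv
1 concepts matched; 5 drugs, 5 in LINCS
$ kgap score --graph demo --drug-set query_drugs.tsv --mode Z | head -6
gene_id	symbol	k	score	rank	tdl
G00276	SYN00276	9	13.981298161782783	1	Tbio
G00226	SYN00226	9	13.203657966980279	2	Tbio
G00079	SYN00079	10	13.197641577420734	3	Tchem
G00363	SYN00363	8	12.850011637334608	4	Tdark
G00017	SYN00017	8	12.38563654049639	5	Tchem
```

Each row is one gene: `k` evidence paths survived the |z| > 3 filter and
their magnitudes combine to the Stouffer score (e.g. G00276: nine paths,
Σ|z|/√9 ≈ 13.98).  All five top genes are planted true targets.
Validating both scoring modes against the planted truth and its "known
mechanism" subset gives the four-cell grid:

```
$ kgap validate --graph demo --drug-set query_drugs.tsv \
    --targets demo/truth_targets.tsv --targets-moa demo/truth_targets_moa.tsv
mode	set	n_pos	n_neg	auc
D	all-targets	10	490	1.0
D	moa-targets	5	495	0.992929292929293
Z	all-targets	10	490	1.0
Z	moa-targets	5	495	0.9931313131313132
```

AUC ≈ 1 means the planted targets sit at the top of the ranking; on a
null graph (`--effect-mu 0`) the same pipeline gives AUC ≈ 0.5.

The packaged Parkinson fixture works without any graph directory:

```
$ kgap query --disease Parkinson --atc N | head -4
5 concepts matched; 25 drugs, 22 in LINCS
name	drug_id	pubchem_cid	in_lincs
amantadine	dc144	2130	True
apomorphine	dc228	6005	True
```

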