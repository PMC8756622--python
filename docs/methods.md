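# Methods

## Model and assumptions

The package treats target discovery as evidence aggregation over a typed
property graph.  A disease is represented by its approved-drug set
(indications are high-confidence, regulator-vetted knowledge); each drug's
perturbation signatures connect it to genes through differential-expression
z-scores; and the amount of concordant, strong expression evidence linking
the drug set to a gene is the gene's score.  The method assumes:

* signatures are independent experiments — every (drug, signature) pair
  contributes its own evidence paths, with no deduplication of repeated
  signatures of a drug in the same cell line;
* a z-score magnitude |z| > 3 marks "strong" perturbation evidence; the
  inequality is strict, so z = 3 exactly is excluded;
* evidence accumulates as in z-score meta-analysis: per gene,
  Z = Σ wᵢZᵢ / √(Σ wᵢ²) with unit weights (Stouffer's function).  The
  aggregate is a ranking score, not a test statistic — no p-value is
  attached and no hypothesis test performed.

### The two scoring modes

The degree-weighted (**D**) mode sets every path contribution Zᵢ := 1, so
the score is √k for a gene with k paths and the ranking equals a raw
path-count ranking.  The z-weighted (**Z**) mode feeds path |z| values in,
score Σ|zᵢ|/√k.  The two modes bracket how much the expression magnitude
should matter beyond bare connectivity; how exactly degree and z-score are
blended is a genuinely open design point, and keeping both contributions
inside the same Stouffer framework makes the pair directly comparable.

Magnitudes |z| are the default because the path filter is itself two-sided
(up- and down-regulation are both evidence of target engagement) and signed
values from opposite-direction signatures would cancel; signed aggregation
remains available (`use_absolute_z=False`) for sensitivity analysis.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `z_threshold` | 3.0 | strict \|z\| cutoff for a path to count (unitless z-score) |
| `mode` | `Z` | path contribution: \|z\| (`Z`) or 1 (`D`) |
| `use_absolute_z` | true | magnitude vs signed aggregation in mode Z |
| ATC prefix | `N` for the packaged query | therapeutic-class restriction on the drug set |
| ROC universe | all Gene nodes | negatives; unscored genes enter with score 0 |

The all-genes ROC universe reflects that the score measures enrichment of
known targets over the whole gene space; restricting to scored genes only
(`universe="hitlist"`) asks a different, conditional question and is
exposed as an option.

## Synthetic data: what it emulates and what it does not

The generator emulates the *shape* of an expression-signature compendium:
drugs with several signatures each across a few cell lines, sparse
per-signature gene coverage (`edge_density`), standard-normal background
z-scores (Level-5-style moderated z-scores have roughly unit spread, which
makes the |z| > 3 filter pass ≈ 0.27 % of background edges), one disease
concept tied to a designated query-drug subset, and distractor concepts
for the rest.  Signal is planted by redrawing z on existing edges between
query-drug signatures and designated true-target genes with |mean| =
`effect_mu` and a random sign per edge — so magnitude-based scoring is
exercised against cancellation, and edge *counts* carry no signal at all.
Planting only where the density draw created an edge keeps degree
statistics identical between targets and background; with the defaults
(5 query drugs × 10 signatures, density 0.2) each true target still
receives ~10 planted edges.

Defaults (20 drugs / 5 query, 10 signatures per drug, 5 cells, 500 genes,
10 true targets, density 0.2, noise SD 1, effect 4) generate in well under
a second and give a ~20 000-edge graph.

Deliberately not emulated: real degree distributions (signature coverage
of genes is uniform here, not landmark-gene structured), cell-line panel
composition, correlated noise across signatures of the same drug, and any
realistic compound/indication ontology.  Passing the planted-recovery
tests therefore shows the pipeline recovers a known mean-shift signal
under idealized independence — it does not certify performance on real
compendia, where correlation and coverage bias can only reduce effective
sample size.

The packaged Parkinson fixture carries the published 25-drug table
(names, PubChem CIDs, LINCS flags) and the five matched concept names
verbatim; its concept identifiers, stub signatures/z-scores, distractor
concepts and the one extra non-ATC-N Parkinson-indicated drug
(domperidone, added so the ATC restriction is observable) are synthetic.

## Numerical and design choices

* **Stouffer in compensated arithmetic** (`math.fsum`); the oracle
  agreement tolerance is 1e-12 relative.
* **ROC/AUC via scikit-learn** (`roc_curve(drop_intermediate=False)` +
  trapezoid), which groups tied scores into single vertices; with ties-as-½
  this equals the normalized Mann–Whitney U, asserted against an O(n²)
  pairwise oracle in tests.
* **Ranking ties** break lexicographically by gene id, so output is
  byte-deterministic under input reordering.
* **Non-dominated ranking** uses strict dominance in both coordinates
  (equal in one coordinate never dominates — the conservative Pareto
  convention); fronts are peeled with a descending-novelty sweep,
  checked against brute-force peeling.  Ranks are invariant to monotone
  transforms of either axis, so log display scaling cannot change them.
* **TSV dialect**: UTF-8, single header, tab-separated, no quoting;
  ATC-code sets serialize `|`-joined; floats round-trip via shortest
  `repr`.  Duplicate edges fail loudly by default (`dedup=True` keeps the
  first).  Key comparison is case-sensitive; only disease-name matching is
  case-insensitive.
* **in_lincs** is derivable (DRUG_SIGNATURE degree > 0); a supplied flag
  that contradicts the derivation is an integrity error, not silently
  overridden.
* **Degenerate inputs**: empty drug set, empty z-vector, all-zero weights,
  single-class ROC input, and nonpositive/NaN bibliometric coordinates all
  raise `UsageError`; an empty path list is a valid empty hitlist.
* The graph store is a typed dict-backed container with explicit adjacency
  indexes rather than a generic graph library object: the loader's schema
  and integrity reporting (file/line of offenders) and the three fixed
  traversal patterns are the whole requirement, and a general-purpose
  multigraph adds indirection without new capability.  A Cypher CREATE
  script export is provided for loading the same graph into a Neo4j
  instance; no server interaction is attempted.

## Known limitations

* Scores grow with signature count, so heavily assayed drugs dominate; no
  per-drug normalization is applied (by design — confidence should grow
  with confirmatory data — but it entangles score with assay coverage).
* The D/Z pair brackets, rather than pins down, the degree-vs-magnitude
  weighting question.
* Bibliometric novelty/importance values are consumed as inputs; the text
  mining that produces them is upstream and out of scope, so `nds_rank`
  values depend entirely on the supplied table.
* Desk-scale fixtures cannot reproduce snapshot-dependent published
  numbers (hitlist sizes, AUC ranges); those are documented in the README
  and excluded from assertions.
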