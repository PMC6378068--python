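# Methods

`netpharm` implements the analysis pipeline used in systems pharmacology of
multi-herb formulas: starting from per-herb compound tables with predicted
ADME properties, it selects pharmacologically plausible compounds, maps them
to protein targets, keeps the targets shared with a disease gene list, tests
that overlap for gene-set over-representation, and summarizes the result as
two bipartite networks and a module-annotated integrated disease pathway.
This note records the model, its assumptions, the tunable parameters, and
the design decisions taken where the procedure was genuinely open.

## ADME screen

A compound is *active* when it satisfies all three inclusive criteria:

* **OB** — oral bioavailability, percent of unmodified drug reaching
  circulation; floor `ob_min = 30`.
* **DL** — drug-likeness index (below); floor `dl_min = 0.18`.
* **Caco-2** — modeled intestinal epithelial permeability, unitless and
  possibly negative; floor `caco2_min = 0`.

Thresholds are inclusive (`>=`) and configurable. Compounds failing the
screen can be *rescued* by a whitelist: an explicit mapping of molecule ids
to a free-text pharmacological rationale, kept in the run config so the
manual curation is declarative and versioned. Rescued compounds join the
active set but keep their per-criterion failure flags in the screening
report. OB and Caco-2 are consumed as input columns — this package does not
predict them from structure.

Input tables may print negative numbers in parentheses (`(2.22)` for
−2.22), a convention of some database exports; the readers parse it.

## Drug-likeness as a Tanimoto index

DL is the continuous Tanimoto similarity

    T(A, B) = A·B / (‖A‖² + ‖B‖² − A·B)

between a compound's molecular-property vector A and the mean property
vector B of a drug-like reference set. For non-negative vectors T ∈ [0, 1],
T = 1 iff A = B, and T is symmetric; both endpoints and symmetry are
property-tested. T(0, 0) is defined as 0 (no evidence of similarity).

Raw molecular descriptors live on incommensurable scales (molecular weight
in hundreds, ring counts in units), so both A and B are min–max scaled
against the reference set before the similarity is taken, and out-of-range
compounds are clamped to [0, 1]. A constant reference descriptor carries no
information and is scaled to 0 with a warning. Because scaling is affine,
the scaled mean of the reference equals the mean of the scaled reference,
so the reference centroid always scores DL = 1 against its own profile — a
useful self-consistency check.

Two consequences are documented rather than hidden: DL values depend on the
chosen reference set, and DL values imported from an external database are
accepted as-is (recomputation is opt-in) since their normalization is
unknown. The conventional 0.18 floor is the reference-average DL of a large
drug database; `reference_mean_dl` reproduces that calibration for any
reference table.

## Merging and target mapping

Per-herb lists are merged on molecule id; the same compound found in
several herbs becomes one record with the union of herb sources. Duplicates
must agree on ADME values to within 1e−9 — they originate from a single
database, so disagreement is treated as corrupted input, not noise.

Compound→target edges carry a provenance tag: `curated` edges (from
interaction databases) pass unconditionally; `predicted` edges must carry a
confidence and are kept only when it is **strictly** greater than
`confidence_min` (default 0.40). Duplicate (compound, gene) pairs collapse
to one edge keeping the maximum confidence; if any duplicate was curated
the merged edge is curated. Gene identity is the uppercased HGNC-style
symbol; identifier mapping to symbols is assumed done upstream.

The target universe is the set of genes touched by ≥ 1 active compound.
Intersecting it with the disease gene list yields the overlap genes;
active compounds with no edge into the overlap are discarded. The overlap
is computed first and drives the pruning (the two are only mutually
consistent in that order), and the operation is idempotent and monotone in
the disease list — both property-tested.

## Over-representation analysis

For query size n in a universe of N genes, a set with K universe members
and k query members is scored with the hypergeometric upper tail
P(X ≥ k) — the one-sided Fisher's exact test. The tail is summed exactly
in log space (log-binomials via `lgamma`, log-sum-exp accumulation), so
p-values far below double-precision underflow of a naive product are still
exact; the implementation is tested against a draw-enumeration oracle
(exact rationals over every C(N, n) draw, all N ≤ 12) and against an
independent library implementation at scale.

Multiplicity is controlled with Benjamini–Hochberg step-up q-values over
all tested sets (those with k ≥ 1); retention is strict, q < `fdr_max`
(default 0.01). Three deliberate conventions, chosen where web-tool
behaviour is not reproducible: the default universe is the union of all
genes in the loaded collection (overridable); the plain count k is used
rather than the EASE-style k − 1 deflation; and the BH procedure is used
where legacy tools offer several FDR variants. Query genes outside the
universe are dropped with a logged count.

## Networks and integration

The compound–target (C-T) network links final compounds to overlap genes;
the target–pathway (T-P) network links overlap genes to FDR-retained
pathways. Both are undirected bipartite graphs; isolated nodes are excluded
by construction, so node counts equal participating entities. Degree is
the only topological statistic: side means are edge count divided by side
size (edges per compound and per target for C-T), hubs are ranked by
degree with lexicographic tie-breaks. Exports (GraphML with `kind` and
`degree` attributes, SIF, TSV) use sorted node and edge order, so repeated
exports are byte-identical.

Pathway selection in the source workflows mixes statistics with manual
literature curation; here the manual step is formalized as a YAML
`ModuleConfig` mapping pathway ids to therapeutic-module labels (default
vocabulary: proliferation, apoptosis, inflammation). A bundled default maps
nine key gastric-precancerous-lesion pathways (hsa05200, hsa04151,
hsa04010, hsa04014, hsa04068, hsa04066, hsa04668, hsa04115, hsa04064) onto
the three modules. Retained pathways absent from the config are reported
as unassigned, not errors; each T-P target inherits the union of its
adjacent pathways' labels, so adding a pathway edge can never remove a
target label.

## Synthetic data

Real inputs for this analysis come from database snapshots (compound
databases, disease-gene portals, annotation services) that drift over
time, so the test bed is synthetic and fully deterministic.

**Pipeline fixture.** `generate_paper_shape_fixture` writes six per-herb
compound tables (87/25/55/202/81/37 compounds, 55 cross-herb duplicates →
432 unique), ADME values straddling the thresholds so exactly 88 pass
(20.37 %), a 5-compound whitelist of rescue analogs carrying published
ADME profiles of known rescued molecules (e.g. a danshensu analog at
DL 0.06, Caco-2 −0.27), an edge list realizing a heavy-tailed compound
degree plan (one degree-104 hub plus secondary hubs of degree 46/37/37/20)
over a 306-gene target universe, a 1261-gene disease list with a 146-gene
overlap, 11 actives whose targets all miss the overlap (93 → 82 final),
and GMT collections in which 21 pathway sets and 26 GO sets are planted
strongly enough to survive FDR < 0.01 while 40 null sets per collection do
not; the pathway sets cover exactly 97 of the 146 overlap genes, with the
largest covering 57. All counts are pinned by construction — partitioning
and wrap-around block assignment, never rejection sampling — and the
fixture is validated by running the real pipeline over the generated
files, not by generator bookkeeping. The seeded generator only controls
non-pinned jitter (exact ADME values, edge provenance, row order), so the
pinned counts hold for every seed and identical seeds give byte-identical
files.

What the fixture does *not* emulate: real descriptor correlations,
annotation-database topology (set overlap structure, GO term nesting), or
realistic gene-side degree distributions in the C-T network (gene degrees
are near-uniform by construction). Passing the fixture therefore
demonstrates that the pipeline machinery reproduces the documented counts
under the documented rules — it says nothing about any particular herbal
formula.

**Enrichment scenarios.** `generate_enrichment_scenario` builds collections
with known ground truth. At fold f, each planted set receives exactly
`round(f × n·K/N)` query genes (the chance expectation times f); the rest
of the query is uniform outside the planted sets. `fold = 1` is the null:
no planting, query uniform. The calibration tests use the null over 500
replicates (mean retained fraction at FDR < 0.01 must stay within
0.01 + 3 SE) and recovery at fold 5 with query 50, universe 5000, sets of
100 over 200 replicates (≥ 95 % of planted sets retained). At those
parameters each planted set holds exactly 5 query genes and its one-sided
p is ≈ 3.7e−3 deterministically, so the default collection is a compact
panel (10 sets, 4 planted) — the regime of a targeted pathway screen —
keeping the BH correction commensurate with the planted signal; with
collections much larger than ~10 tested sets a 5-gene overlap is simply
not significant at q < 0.01, which is the expected behaviour of BH, not a
defect.

**Reference descriptors.** `generate_reference_descriptor_set` draws a
non-negative log-normal descriptor table with per-descriptor scales as a
synthetic stand-in for a drug-database descriptor snapshot; it exists for
tests and for illustrating the threshold calibration, and mimics no real
chemistry.

## Numerical and degenerate-input conventions

* Threshold comparisons: screening floors inclusive (`>=`); prediction
  confidence and FDR retention strict (`>` / `<`), following the stated
  conventions of the original filters.
* `hypergeometric_tail` starts the tail sum at the true support lower
  bound, returns exactly 1.0 for k = 0, and caps at 1.0 after log-space
  accumulation.
* Empty inputs degrade gracefully: an empty gene list is valid (warned,
  not fatal), an empty query yields no enrichment results, an empty edge
  list yields zeroed networks and a complete run report; an empty
  enrichment universe is an error.
* All randomness flows through `numpy.random.default_rng(seed)`; pipeline
  outputs and exports are deterministic given config and inputs, and the
  run report carries a config hash covering every semantic field.

## Problem sizes

The bundled test bed runs the full pipeline on the 432-compound fixture
(sub-second), exhaustive tail enumeration for all universes N ≤ 12, 500
null-calibration and 200 recovery replicates (a few seconds each); the
whole suite completes in well under a minute on one core.

## Known limitations

* DL values are reference-relative; two reference sets give two DL scales.
* The enrichment universe convention (collection union) differs from
  genome-wide backgrounds; q-values are comparable only within a run.
* No GO graph propagation: terms are treated as flat sets.
* Degree is the only centrality; no layout or rendering is provided
  (exports are Cytoscape-compatible instead).
* The module map is curation, not inference: it encodes documented
  pathway–module relationships and should be edited per disease context.
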