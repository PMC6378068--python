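# netpharm

Systems-pharmacology analysis of multi-herb formulas: which of a formula's
hundreds of constituent compounds are plausibly active, which proteins do
they hit, and through which pathways could they act on a disease?

The package is aimed at computational pharmacologists working with
traditional-medicine formulas (or any multi-compound intervention) who
have per-herb compound tables with predicted ADME properties,
compound→target interaction lists, a disease gene list and gene-set
collections, and who want the standard network-pharmacology workflow as a
tested, deterministic pipeline instead of a chain of web tools.

## What it computes

1. **ADME screen** — compounds pass with OB ≥ 30 %, DL ≥ 0.18 and
   Caco-2 ≥ 0 (all configurable, all inclusive). Drug-likeness is the
   continuous Tanimoto index against the mean property vector **B** of a
   drug-like reference set,

   *T*(A, B) = A·B / (‖A‖² + ‖B‖² − A·B) ∈ [0, 1],

   with descriptors min–max scaled against the reference. Compounds
   failing the screen may be rescued via a documented whitelist.
2. **Target mapping** — predicted compound→target edges are kept only at
   confidence > 0.40 (curated edges always pass); the targets of active
   compounds are intersected with the disease gene list, and compounds
   with no disease-relevant target are discarded.
3. **Enrichment** — the overlap genes are tested against GO / pathway
   collections with the one-sided Fisher (hypergeometric upper tail,
   exact in log space) and Benjamini–Hochberg FDR; sets with q < 0.01 are
   retained.
4. **Networks** — bipartite compound–target and target–pathway graphs
   with degree statistics and hub ranking, exported as GraphML / SIF /
   TSV for Cytoscape.
5. **Integration** — retained pathways are assigned to therapeutic
   modules (proliferation / apoptosis / inflammation by default) through
   a declarative YAML map, and each target inherits its pathways' module
   labels.

A seeded synthetic-data module generates the entire input bundle: a
deterministic study-shaped fixture that reproduces the documented
pipeline counts end-to-end, and stochastic enrichment scenarios with
known ground truth for calibration tests. See `docs/methods.md` for the
model details and design decisions.

## Worked example

Generate the synthetic study-shaped inputs and run the full pipeline:

```bash
netpharm simulate --seed 0 --out fixtures/
netpharm run --config fixtures/config.yaml \
    --compounds HMM=fixtures/compounds_HMM.tsv --compounds PHP=fixtures/compounds_PHP.tsv \
    --compounds AMK=fixtures/compounds_AMK.tsv --compounds RMB=fixtures/compounds_RMB.tsv \
    --compounds CZR=fixtures/compounds_CZR.tsv --compounds HDW=fixtures/compounds_HDW.tsv \
    --edges fixtures/edges.tsv --disease fixtures/disease_genes.txt \
    --pathways fixtures/pathways.gmt --go fixtures/go_bp.gmt --out results/
```

which prints the run-report counts:

```json
{
 "herb_tables": 6,
 "compound_rows": 487,
 "unique_compounds": 432,
 "passed": 88,
 "rescued": 5,
 "rejected": 339,
 "active": 93,
 "pct_passed": 20.37,
 "edges_in": 893,
 "edges_confident": 868,
 "targets": 306,
 "disease_genes": 1261,
 "overlap_genes": 146,
 "final_compounds": 82,
 "dropped_compounds": 11,
 "pathways_tested": 61,
 "pathways_retained": 21,
 "go_tested": 66,
 "go_retained": 26,
 "ct_nodes": 228,
 "ct_edges": 677,
 "mean_edges_per_compound": 8.26,
 "mean_degree_per_target": 4.64,
 "tp_targets": 97,
 "tp_pathways": 21,
 "tp_edges": 321,
 "module_pathways": 9,
 "unassigned_pathways": 12,
 "annotated_targets": 97
}
```

Reading the numbers: the six herb tables hold 487 rows that merge to 432
unique compounds (55 appear in two herbs); 88 pass all three ADME
criteria (20.37 %) and 5 whitelisted compounds are rescued, giving 93
actives. Their confidence-filtered edges touch 306 targets, 146 of which
are shared with the 1261-gene disease list; 11 actives with no shared
target are discarded, leaving 82 final compounds. The compound–target
network has 228 nodes (82 + 146) and 677 edges — 8.26 edges per compound,
4.64 per target — and 21 pathway sets survive FDR < 0.01, mapping 97 of
the 146 targets into the target–pathway network. Nine of the retained
pathways carry therapeutic-module labels, annotating all 97 targets.
Intermediate artifacts (screening table, overlap gene list, enrichment
tables, GraphML networks, module annotations, `report.json`) are written
to `results/`.

The same stages are available as library functions:

```python
>>> from netpharm import compute_dl
>>> compute_dl([1, 2, 2], [2, 1, 0])   # A·B=4, |A|²=9, |B|²=5 → 4/(9+5−4)
0.4
```

## Layout

* `src/netpharm/data_io.py` — records, TSV/GMT/gene-list/YAML readers & writers
* `src/netpharm/screening.py` — Tanimoto DL, descriptor scaling, merge, ADME screen
* `src/netpharm/target_mapping.py` — confidence filter, target map, overlap, pruning
* `src/netpharm/enrichment.py` — hypergeometric tail, BH-FDR, `enrich`
* `src/netpharm/network_analysis.py` — bipartite builders, degree stats, exports
* `src/netpharm/pathway_integration.py` — module config, label inheritance
* `src/netpharm/synthetic_data.py` — fixture & scenario generators
* `src/netpharm/pipeline.py`, `src/netpharm/cli.py` — orchestration and CLI
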