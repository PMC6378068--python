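"""Synthetic study-shaped data generators.

Two kinds of inputs are produced:

* a deterministic **pipeline fixture** — six per-herb compound tables with
  cross-herb duplicates, an edge list with hub compounds, a disease gene
  list with controlled overlap and gene-set collections with planted
  enrichment — engineered so that running the *real* pipeline stages
  reproduces every headline count of the gastric-precancerous-lesion
  study shape (432 unique compounds, 88 screen passes, 93 actives after a
  5-compound whitelist rescue, 82 final compounds after discarding 11
  target-less candidates, a 306-gene target universe, a 1261-gene disease
  list with 146 overlapping genes, a 228-node / 677-edge compound–target
  network with a degree-104 hub, and 21 retained pathways covering 97
  targets).  Counts are pinned by construction (partitioning, never
  rejection sampling); only non-pinned values (ADME jitter, edge
  provenance, row order) are drawn from the seeded generator.

* **stochastic enrichment scenarios** with known ground truth, used for
  null calibration and planted-signal recovery tests.

Everything is seed-deterministic: the same spec and seed produce
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import (
    CompoundRecord,
    CompoundTargetEdge,
    DiseaseGeneList,
    EdgeSource,
    GeneSet,
    GeneSetCollection,
    HerbCompoundList,
    Namespace,
    PipelineConfig,
    ValidationError,
    write_compound_table,
    write_edge_list,
    write_gene_list,
    write_gmt,
)
from .pathway_integration import ModuleConfig

__all__ = [
    "FixtureSpec",
    "Scenario",
    "generate_paper_shape_fixture",
    "generate_enrichment_scenario",
    "generate_reference_descriptor_set",
]

#: Whitelist-rescued compounds: (name, OB %, DL, Caco-2).  These mirror
#: published ADME profiles of the five rescued molecules; each fails at
#: least one screening criterion.
_WHITELIST_ADME = (
    ("atractylenolide I analog", 37.37, 0.15, 1.30),
    ("oleanolic acid analog", 29.02, 0.76, 0.59),
    ("astragaloside IV analog", 17.74, 0.15, -2.22),
    ("curcumol analog", 103.55, 0.13, 1.12),
    ("danshensu analog", 36.91, 0.06, -0.27),
)

_HUB_ADME = ("quercetin analog", 46.43, 0.28, 0.05)

_SECONDARY_HUB_NAMES = (
    "luteolin analog",
    "kaempferol analog",
    "isorhamnetin analog",
    "acacetin analog",
)

#: Default pathway plan: (pathway id, number of mapped targets it covers).
_DEFAULT_PATHWAY_PLAN = (
    ("hsa05200", 57),
    ("hsa04151", 37),
    ("hsa04010", 24),
    ("hsa04014", 23),
    ("hsa04668", 19),
    ("hsa04115", 18),
    ("hsa04110", 18),
    ("hsa04210", 14),
    ("hsa04370", 12),
    ("hsa04064", 11),
    ("hsa04068", 8),
    ("hsa04066", 8),
    ("hsa90001", 8),
    ("hsa90002", 8),
    ("hsa90003", 8),
    ("hsa90004", 8),
    ("hsa90005", 8),
    ("hsa90006", 8),
    ("hsa90007", 8),
    ("hsa90008", 8),
    ("hsa90009", 8),
)


@dataclass
class FixtureSpec:
    """Pinned counts for the deterministic pipeline fixture.

    The defaults are the study shape; ``validate`` checks the internal
    identities (pass + whitelist − target-less == final count, the edge
    plan sums to the edge count, hub degrees fit in the overlap, ...).
    """

    herb_counts: dict = field(
        default_factory=lambda: {
            "HMM": 87, "PHP": 25, "AMK": 55, "RMB": 202, "CZR": 81, "HDW": 37,
        }
    )
    n_duplicates: int = 55
    n_pass: int = 88
    whitelist_size: int = 5
    n_targetless: int = 11
    n_targets: int = 306
    n_disease: int = 1261
    n_overlap: int = 146
    n_ct_edges: int = 677
    hub_degrees: tuple = (104, 46, 37, 37, 20)
    whitelist_degrees: tuple = (3, 2, 4, 2, 3)
    pathway_plan: tuple = _DEFAULT_PATHWAY_PLAN
    n_mapped_targets: int = 97
    n_go_sets: int = 26
    go_set_size: int = 10
    n_null_sets: int = 40
    seed: int = 0

    # -- derived quantities -------------------------------------------------
    @property
    def n_unique(self) -> int:
        return sum(self.herb_counts.values()) - self.n_duplicates

    @property
    def n_active(self) -> int:
        return self.n_pass + self.whitelist_size

    @property
    def n_final(self) -> int:
        return self.n_active - self.n_targetless

    def validate(self) -> None:
        problems = []
        if self.n_duplicates > sum(self.herb_counts.values()) // 2:
            problems.append("more duplicates than herb slots can host")
        if self.whitelist_size != len(_WHITELIST_ADME):
            problems.append(
                f"whitelist_size must be {len(_WHITELIST_ADME)} (one per rescued analog)"
            )
        if len(self.whitelist_degrees) != self.whitelist_size:
            problems.append("whitelist_degrees length != whitelist_size")
        if self.n_targetless > self.n_pass:
            problems.append("target-less candidates must come from the passing set")
        if self.n_final <= len(self.hub_degrees) + self.whitelist_size:
            problems.append("too few final compounds for the degree plan")
        if self.n_overlap > self.n_targets:
            problems.append("overlap larger than target universe")
        if self.n_overlap > self.n_disease:
            problems.append("overlap larger than disease list")
        fixed = sum(self.hub_degrees) + sum(self.whitelist_degrees)
        n_rest = self.n_final - len(self.hub_degrees) - self.whitelist_size
        rest = self.n_ct_edges - fixed
        if rest < n_rest:
            problems.append("edge plan leaves some final compounds with degree 0")
        if max(self.hub_degrees) > self.n_overlap:
            problems.append("hub degree exceeds overlap size")
        if self.n_ct_edges < self.n_overlap:
            problems.append("fewer edges than overlap genes: some genes would be isolated")
        if self.n_mapped_targets > self.n_overlap:
            problems.append("mapped targets exceed overlap genes")
        sizes = [s for _, s in self.pathway_plan]
        if any(s > self.n_mapped_targets for s in sizes):
            problems.append("a pathway covers more targets than are mapped")
        if sum(sizes) < self.n_mapped_targets:
            problems.append("pathway plan cannot cover all mapped targets")
        if self.n_go_sets * self.go_set_size < self.n_overlap:
            problems.append("GO plan cannot cover all overlap genes")
        if problems:
            raise ValidationError("inconsistent fixture spec: " + "; ".join(problems))

    def _degree_plan(self) -> list:
        """Per-final-compound degrees, aligned with the final-compound id
        order (hub, whitelist, secondary hubs, then the flat tail)."""
        n_rest = self.n_final - len(self.hub_degrees) - self.whitelist_size
        rest_total = self.n_ct_edges - sum(self.hub_degrees) - sum(self.whitelist_degrees)
        base = rest_total // n_rest
        extra = rest_total - base * n_rest
        tail = [base + 1] * extra + [base] * (n_rest - extra)
        return (
            [self.hub_degrees[0]]
            + list(self.whitelist_degrees)
            + list(self.hub_degrees[1:])
            + tail
        )


@dataclass
class Scenario:
    """A generated scenario plus the ground truth that exactly describes it.

    For pipeline fixtures ``files`` holds the paths of everything written;
    enrichment scenarios are in-memory (``collection``, ``query``,
    ``universe``) with optional files.
    """

    ground_truth: dict
    files: dict = field(default_factory=dict)
    collection: GeneSetCollection | None = None
    query: frozenset | None = None
    universe: tuple | None = None


# ---------------------------------------------------------------------------
# Pipeline fixture
# ---------------------------------------------------------------------------


def _assign_herbs(spec: FixtureSpec) -> list:
    """Greedy capacity-balanced herb assignment: the first ``n_duplicates``
    compounds go to the two herbs with the most remaining slots, the rest
    to the single fullest herb.  Exactly exhausts every herb's count."""
    herbs = list(spec.herb_counts)
    remaining = dict(spec.herb_counts)
    assignment = []
    for _ in range(spec.n_duplicates):
        top2 = sorted(herbs, key=lambda h: (-remaining[h], herbs.index(h)))[:2]
        for h in top2:
            remaining[h] -= 1
        assignment.append(frozenset(top2))
    for _ in range(spec.n_unique - spec.n_duplicates):
        top = max(herbs, key=lambda h: (remaining[h], -herbs.index(h)))
        remaining[top] -= 1
        assignment.append(frozenset({top}))
    assert all(v == 0 for v in remaining.values())
    return assignment


def _adme_values(spec: FixtureSpec, rng: np.random.Generator) -> list:
    """Per-compound (name, ob, dl, caco2) honouring the pass/fail plan.

    Compound order: hub, 5 whitelisted, remaining passers, then failers.
    Non-pinned values straddle the thresholds uniformly.
    """
    rows = [_HUB_ADME] + list(_WHITELIST_ADME)
    for j in range(spec.n_pass - 1):
        name = (
            _SECONDARY_HUB_NAMES[j]
            if j < len(_SECONDARY_HUB_NAMES)
            else f"compound-{j + 7:04d}"
        )
        rows.append(
            (
                name,
                round(rng.uniform(30.5, 110.0), 2),
                round(rng.uniform(0.19, 0.80), 2),
                round(rng.uniform(0.01, 1.50), 2),
            )
        )
    patterns = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    n_fail = spec.n_unique - spec.n_pass - spec.whitelist_size
    for j in range(n_fail):
        fail_ob, fail_dl, fail_c2 = patterns[j % len(patterns)]
        ob = rng.uniform(5.0, 29.5) if fail_ob else rng.uniform(30.5, 110.0)
        dl = rng.uniform(0.01, 0.17) if fail_dl else rng.uniform(0.19, 0.80)
        c2 = rng.uniform(-2.0, -0.01) if fail_c2 else rng.uniform(0.01, 1.50)
        rows.append(
            (f"compound-{spec.n_pass + spec.whitelist_size + j + 1:04d}",
             round(ob, 2), round(dl, 2), round(c2, 2))
        )
    return rows


def _block_assign(items: Sequence[str], sizes: Sequence[int]):
    """Yield consecutive wrap-around blocks of ``items``; with a total of
    at least ``len(items)`` slots every item is covered at least once, and
    no block repeats an item (block size <= len(items))."""
    ptr = 0
    n = len(items)
    for size in sizes:
        yield [items[(ptr + j) % n] for j in range(size)]
        ptr = (ptr + size) % n


def _edge(rng, mol_id, gene):
    if rng.random() < 0.6:
        return CompoundTargetEdge(mol_id, gene, EdgeSource.CURATED, None)
    return CompoundTargetEdge(
        mol_id, gene, EdgeSource.PREDICTED, round(float(rng.uniform(0.45, 0.99)), 3)
    )


def generate_paper_shape_fixture(spec: FixtureSpec | None = None, out_dir=None) -> Scenario:
    """Write the deterministic fixture files and return the scenario.

    Files: one compound TSV per herb, ``edges.tsv``, ``disease_genes.txt``,
    ``pathways.gmt``, ``go_bp.gmt``, ``config.yaml`` and
    ``ground_truth.json``.
    """
    spec = spec or FixtureSpec()
    spec.validate()
    if out_dir is None:
        raise ValidationError("out_dir is required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    mol_ids = [f"MOLX{i + 1:04d}" for i in range(spec.n_unique)]
    herb_sets = _assign_herbs(spec)
    adme = _adme_values(spec, rng)
    records = [
        CompoundRecord(
            mol_id=mid, name=name, herb_sources=herbs, ob=ob, dl=dl, caco2=c2
        )
        for mid, herbs, (name, ob, dl, c2) in zip(mol_ids, herb_sets, adme)
    ]

    whitelist_ids = mol_ids[1 : 1 + spec.whitelist_size]
    active_ids = mol_ids[: spec.n_active]
    final_ids = mol_ids[: spec.n_final]
    dropped_ids = mol_ids[spec.n_final : spec.n_active]

    # Gene inventories.
    overlap_genes = [f"GPL{i + 1:03d}" for i in range(spec.n_overlap)]
    other_targets = [f"TGT{i + 1:03d}" for i in range(spec.n_targets - spec.n_overlap)]
    disease_only = [f"DIS{i + 1:04d}" for i in range(spec.n_disease - spec.n_overlap)]

    # C-T edges per the degree plan; wrap-around blocks guarantee every
    # overlap gene is touched (n_ct_edges >= n_overlap).
    edges = []
    for mol_id, block in zip(
        final_ids, _block_assign(overlap_genes, spec._degree_plan())
    ):
        for gene in block:
            edges.append(_edge(rng, mol_id, gene))
    # Target-less actives: edges only to non-overlap targets, enough slots
    # to cover all of them.
    per_dropped = -(-len(other_targets) // spec.n_targetless) + 1
    for mol_id, block in zip(
        dropped_ids, _block_assign(other_targets, [per_dropped] * spec.n_targetless)
    ):
        for gene in block:
            edges.append(_edge(rng, mol_id, gene))
    # Decoys that the pipeline must remove: low-confidence predictions from
    # active compounds and edges from compounds that fail the screen.
    for j in range(25):
        mol_id = active_ids[int(rng.integers(0, len(active_ids)))]
        edges.append(
            CompoundTargetEdge(
                mol_id, f"XTG{j + 1:04d}", EdgeSource.PREDICTED,
                round(float(rng.uniform(0.05, 0.39)), 3),
            )
        )
    inactive_ids = mol_ids[spec.n_active :]
    for j in range(15):
        mol_id = inactive_ids[int(rng.integers(0, len(inactive_ids)))]
        edges.append(
            CompoundTargetEdge(mol_id, overlap_genes[j % len(overlap_genes)],
                               EdgeSource.CURATED, None)
        )
    edges = [edges[i] for i in rng.permutation(len(edges))]

    # Gene-set collections with planted enrichment.
    mapped = overlap_genes[: spec.n_mapped_targets]
    pathway_sets = []
    bg_pool = [f"PBG{i + 1:04d}" for i in range(6000)]
    for (set_id, size), block in zip(
        spec.pathway_plan, _block_assign(mapped, [s for _, s in spec.pathway_plan])
    ):
        filler = [bg_pool[i] for i in rng.choice(len(bg_pool), size=size, replace=False)]
        pathway_sets.append(
            GeneSet(set_id=set_id, set_name=f"synthetic pathway {set_id}",
                    genes=frozenset(block) | frozenset(filler))
        )
    for j in range(spec.n_null_sets):
        filler = [bg_pool[i] for i in rng.choice(len(bg_pool), size=99, replace=False)]
        pathway_sets.append(
            GeneSet(set_id=f"hsa8{j + 1:04d}", set_name="synthetic null pathway",
                    genes=frozenset([mapped[j % len(mapped)]]) | frozenset(filler))
        )
    pathway_collection = GeneSetCollection(namespace=Namespace.KEGG, sets=pathway_sets)

    go_sets = []
    go_pool = [f"GBG{i + 1:04d}" for i in range(4000)]
    go_sizes = [spec.go_set_size] * spec.n_go_sets
    for j, block in enumerate(_block_assign(overlap_genes, go_sizes)):
        filler = [go_pool[i] for i in rng.choice(len(go_pool), size=spec.go_set_size,
                                                 replace=False)]
        go_sets.append(
            GeneSet(set_id=f"GO:09{j + 1:05d}", set_name=f"synthetic process {j + 1}",
                    genes=frozenset(block) | frozenset(filler))
        )
    for j in range(spec.n_null_sets):
        filler = [go_pool[i] for i in rng.choice(len(go_pool), size=99, replace=False)]
        go_sets.append(
            GeneSet(set_id=f"GO:08{j + 1:05d}", set_name="synthetic null process",
                    genes=frozenset([overlap_genes[j % len(overlap_genes)]]) | frozenset(filler))
        )
    go_collection = GeneSetCollection(namespace=Namespace.GO_BP, sets=go_sets)

    # Disease list: overlap genes plus disease-only genes, shuffled.
    disease_genes = overlap_genes + disease_only
    disease_genes = [disease_genes[i] for i in rng.permutation(len(disease_genes))]

    # ---- write everything -------------------------------------------------
    files = {}
    for herb in spec.herb_counts:
        herb_records = [r for r in records if herb in r.herb_sources]
        path = out_dir / f"compounds_{herb}.tsv"
        write_compound_table(herb_records, path)
        files[f"compounds_{herb}"] = path
    files["edges"] = out_dir / "edges.tsv"
    write_edge_list(edges, files["edges"])
    files["disease"] = out_dir / "disease_genes.txt"
    with open(files["disease"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# synthetic disease gene list\n")
        for gene in disease_genes:
            fh.write(gene + "\n")
    files["pathways"] = out_dir / "pathways.gmt"
    write_gmt(pathway_collection, files["pathways"])
    files["go_bp"] = out_dir / "go_bp.gmt"
    write_gmt(go_collection, files["go_bp"])

    config = PipelineConfig(
        whitelist={
            mid: f"documented pharmacological activity ({name})"
            for mid, (name, *_rest) in zip(whitelist_ids, _WHITELIST_ADME)
        },
        modules={k: list(v) for k, v in ModuleConfig.default().assignments.items()},
        seed=spec.seed,
    )
    files["config"] = out_dir / "config.yaml"
    config.to_yaml(files["config"])

    ground_truth = {
        "n_unique": spec.n_unique,
        "n_pass": spec.n_pass,
        "pct_pass": round(100.0 * spec.n_pass / spec.n_unique, 2),
        "n_active": spec.n_active,
        "n_final": spec.n_final,
        "n_dropped": spec.n_targetless,
        "n_targets": spec.n_targets,
        "n_disease": spec.n_disease,
        "n_overlap": spec.n_overlap,
        "ct_nodes": spec.n_final + spec.n_overlap,
        "ct_edges": spec.n_ct_edges,
        "mean_edges_per_compound": round(spec.n_ct_edges / spec.n_final, 2),
        "mean_degree_per_target": round(spec.n_ct_edges / spec.n_overlap, 2),
        "tp_targets": spec.n_mapped_targets,
        "tp_pathways": len(spec.pathway_plan),
        "retained_go": spec.n_go_sets,
        "hub": {"mol_id": mol_ids[0], "degree": spec.hub_degrees[0]},
        "whitelist_ids": whitelist_ids,
        "dropped_ids": dropped_ids,
        "planted_pathways": [sid for sid, _ in spec.pathway_plan],
        "seed": spec.seed,
    }
    files["ground_truth"] = out_dir / "ground_truth.json"
    with open(files["ground_truth"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(ground_truth, fh, indent=1, sort_keys=False)
        fh.write("\n")

    return Scenario(ground_truth=ground_truth, files={k: Path(v) for k, v in files.items()})


# ---------------------------------------------------------------------------
# Stochastic enrichment scenarios
# ---------------------------------------------------------------------------


def generate_enrichment_scenario(
    n_sets: int = 10,
    set_size: int = 100,
    universe_size: int = 5000,
    n_planted: int = 4,
    fold_enrichment: float = 5.0,
    query_size: int = 50,
    seed: int = 0,
) -> Scenario:
    """Gene-set collection with planted over-representation.

    Each planted set receives exactly ``round(fold_enrichment × expected)``
    query genes, where expected = query_size × set_size / universe_size is
    the chance overlap; the rest of the query is drawn uniformly outside
    the planted sets.  ``fold_enrichment == 1`` is the null scenario: no
    planting, query uniform over the whole universe.
    """
    if fold_enrichment < 1:
        raise ValidationError("fold_enrichment must be >= 1")
    if n_planted > n_sets:
        raise ValidationError("n_planted must not exceed n_sets")
    if n_planted * set_size > universe_size:
        raise ValidationError("planted sets do not fit in the universe")
    expected = query_size * set_size / universe_size
    planted_count = int(round(fold_enrichment * expected))
    if planted_count > set_size:
        raise ValidationError(
            f"infeasible fold: {planted_count} planted genes exceed set size {set_size}"
        )
    null = fold_enrichment == 1
    if not null and planted_count * n_planted > query_size:
        raise ValidationError("planted genes exceed the query size")

    rng = np.random.default_rng(seed)
    universe = [f"U{i:05d}" for i in range(universe_size)]
    shuffled = [universe[i] for i in rng.permutation(universe_size)]

    sets = []
    planted_ids = []
    if null:
        for j in range(n_sets):
            members = rng.choice(universe_size, size=set_size, replace=False)
            sets.append(GeneSet(set_id=f"SET{j:03d}", set_name="null set",
                                genes=frozenset(universe[i] for i in members)))
        query = frozenset(
            universe[i] for i in rng.choice(universe_size, size=query_size, replace=False)
        )
    else:
        ptr = 0
        query_genes = []
        for j in range(n_planted):
            block = shuffled[ptr : ptr + set_size]
            ptr += set_size
            planted_id = f"SET{j:03d}"
            planted_ids.append(planted_id)
            sets.append(GeneSet(set_id=planted_id, set_name="planted set",
                                genes=frozenset(block)))
            chosen = rng.choice(set_size, size=planted_count, replace=False)
            query_genes.extend(block[i] for i in chosen)
        background = shuffled[ptr:]
        for j in range(n_planted, n_sets):
            members = rng.choice(universe_size, size=set_size, replace=False)
            sets.append(GeneSet(set_id=f"SET{j:03d}", set_name="null set",
                                genes=frozenset(universe[i] for i in members)))
        n_extra = query_size - len(query_genes)
        extra = rng.choice(len(background), size=n_extra, replace=False)
        query_genes.extend(background[i] for i in extra)
        query = frozenset(query_genes)

    return Scenario(
        ground_truth={
            "planted": planted_ids,
            "planted_count": 0 if null else planted_count,
            "fold_enrichment": fold_enrichment,
            "seed": seed,
        },
        collection=GeneSetCollection(namespace=Namespace.OTHER, sets=sets),
        query=query,
        universe=tuple(universe),
    )


_DESCRIPTOR_NAMES = ("mw", "alogp", "hdon", "hacc", "rbn", "tpsa", "nring", "narom")


def generate_reference_descriptor_set(
    n_molecules: int = 500, n_descriptors: int = 8, seed: int = 0
) -> pd.DataFrame:
    """Synthetic drug-like reference descriptor table (non-negative,
    log-normal per descriptor with distinct scales), reproducible by seed.

    This is a synthetic stand-in for a real drug-database descriptor
    snapshot, intended for tests and for illustrating the calibration of
    the drug-likeness threshold as the reference-average index.
    """
    if n_molecules < 2:
        raise ValidationError("need at least 2 reference molecules")
    rng = np.random.default_rng(seed)
    names = [
        _DESCRIPTOR_NAMES[i] if i < len(_DESCRIPTOR_NAMES) else f"d{i + 1}"
        for i in range(n_descriptors)
    ]
    means = rng.uniform(0.5, 5.0, size=n_descriptors)
    sigmas = rng.uniform(0.2, 0.8, size=n_descriptors)
    data = {
        name: rng.lognormal(mean=mu, sigma=sg, size=n_molecules)
        for name, mu, sg in zip(names, means, sigmas)
    }
    return pd.DataFrame(data)
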