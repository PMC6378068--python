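"""Compound→target assembly, disease-gene intersection and pruning.

Predicted interactions are kept only when their prediction confidence is
strictly greater than the configured floor (default 0.40); curated
database edges carry no confidence and always pass.  The target universe
of the active compounds is then intersected with the disease gene list,
and active compounds with no edge into the overlap are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .data_io import CompoundTargetEdge, DiseaseGeneList, EdgeSource, ValidationError
from .screening import ScreeningResult

log = logging.getLogger("netpharm")

__all__ = [
    "TargetMap",
    "OverlapResult",
    "filter_predicted_edges",
    "build_target_map",
    "intersect_disease_genes",
    "prune_compounds",
]


@dataclass
class TargetMap:
    """Deduplicated edges restricted to active compounds, plus the set of
    gene symbols touched by at least one active compound."""

    edges: list
    target_universe: frozenset
    active_compounds: frozenset


@dataclass
class OverlapResult:
    """Intersection of the target universe with the disease gene list and
    the induced partition of active compounds."""

    overlap_genes: frozenset
    retained_compounds: frozenset
    dropped_compounds: frozenset
    edges: list  # edges into the overlap, for network construction


def filter_predicted_edges(
    edges: Iterable[CompoundTargetEdge], confidence_min: float = 0.40
) -> list:
    """Keep predicted edges with confidence strictly above the floor;
    curated edges pass unconditionally."""
    if not (0.0 <= confidence_min <= 1.0):
        raise ValidationError(f"confidence_min must be in [0, 1], got {confidence_min}")
    kept = []
    for e in edges:
        if e.source is EdgeSource.CURATED or (
            e.confidence is not None and e.confidence > confidence_min
        ):
            kept.append(e)
    return kept


def build_target_map(active: Iterable[str], edges: Iterable[CompoundTargetEdge]) -> TargetMap:
    """Restrict (already confidence-filtered) edges to active compounds and
    deduplicate by (mol_id, gene_symbol)."""
    active = frozenset(active)
    seen = set()
    kept = []
    for e in edges:
        if e.mol_id not in active:
            continue
        key = (e.mol_id, e.gene_symbol)
        if key in seen:
            continue
        seen.add(key)
        kept.append(e)
    universe = frozenset(e.gene_symbol for e in kept)
    return TargetMap(edges=kept, target_universe=universe, active_compounds=active)


def intersect_disease_genes(target_map: TargetMap, disease: DiseaseGeneList) -> OverlapResult:
    """Intersect the target universe with the disease genes and partition
    active compounds by whether they keep at least one overlap edge."""
    if not disease.genes:
        log.warning("disease gene list %r is empty; overlap will be empty", disease.disease_label)
    overlap = target_map.target_universe & disease.genes
    overlap_edges = [e for e in target_map.edges if e.gene_symbol in overlap]
    retained = frozenset(e.mol_id for e in overlap_edges)
    dropped = target_map.active_compounds - retained
    return OverlapResult(
        overlap_genes=frozenset(overlap),
        retained_compounds=retained,
        dropped_compounds=frozenset(dropped),
        edges=overlap_edges,
    )


def prune_compounds(overlap: OverlapResult, active: ScreeningResult | Iterable[str] | None = None):
    """Final compound set: active compounds with ≥ 1 disease-overlap edge.

    Returns (retained_ids, dropped_ids) as sorted lists; the counts satisfy
    |retained| + |dropped| == |active|.
    """
    retained = sorted(overlap.retained_compounds)
    dropped = sorted(overlap.dropped_compounds)
    if dropped:
        log.info("discarded %d compounds with no relevant targets: %s", len(dropped), dropped)
    return retained, dropped
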