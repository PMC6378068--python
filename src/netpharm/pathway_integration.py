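"""Integrated disease-pathway assembly.

The enrichment step leaves a set of statistically retained pathways; the
biological step of keeping only pathways with a direct disease connection
is formalized here as a declarative, versioned module configuration:
each key pathway is assigned to one or more therapeutic modules (by
default cell proliferation, cell apoptosis and inflammation).  Targets in
the target–pathway network then inherit the union of their adjacent
pathways' module labels, yielding an export-ready annotated view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd
import yaml

from .data_io import ValidationError
from .network_analysis import BipartiteNetwork

log = logging.getLogger("netpharm")

__all__ = ["DEFAULT_MODULE_VOCABULARY", "ModuleConfig", "IntegratedPathway",
           "assign_modules", "build_integrated_pathway"]

DEFAULT_MODULE_VOCABULARY = frozenset({"proliferation", "apoptosis", "inflammation"})


@dataclass
class ModuleConfig:
    """Mapping pathway_id → module labels, checked against a vocabulary."""

    assignments: dict
    vocabulary: frozenset = DEFAULT_MODULE_VOCABULARY

    def __post_init__(self):
        self.vocabulary = frozenset(self.vocabulary)
        clean = {}
        for pathway_id, labels in self.assignments.items():
            labels = tuple(labels)
            if not labels:
                raise ValidationError(f"pathway {pathway_id!r} has an empty label list")
            unknown = [l for l in labels if l not in self.vocabulary]
            if unknown:
                raise ValidationError(
                    f"pathway {pathway_id!r} uses labels outside the vocabulary: {unknown}"
                )
            clean[pathway_id] = labels
        self.assignments = clean

    @classmethod
    def from_yaml(cls, path) -> "ModuleConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            assignments=raw.get("assignments", {}),
            vocabulary=frozenset(raw.get("vocabulary", DEFAULT_MODULE_VOCABULARY)),
        )

    @classmethod
    def default(cls) -> "ModuleConfig":
        """Bundled map of the nine key gastric-precancerous-lesion pathways
        onto the three therapeutic modules."""
        ref = resources.files("netpharm.data") / "gpl_modules.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


@dataclass
class IntegratedPathway:
    """Selected pathways with module labels plus per-target label sets.

    ``pathways`` maps pathway_id → label tuple; ``unassigned`` lists
    retained pathways absent from the module config; ``target_labels``
    (filled by :func:`build_integrated_pathway`) maps each target to the
    union of its adjacent pathways' labels.
    """

    pathways: dict
    unassigned: tuple
    target_labels: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_annotation_table(self) -> pd.DataFrame:
        rows = [
            {"target": t, "modules": ",".join(sorted(labels))}
            for t, labels in sorted(self.target_labels.items())
        ]
        return pd.DataFrame(rows, columns=["target", "modules"])


def assign_modules(retained: Iterable, config: ModuleConfig) -> IntegratedPathway:
    """Keep retained pathways present in the module config with their
    labels; retained pathways absent from the config are reported as
    unassigned (not errors)."""
    retained_ids = [r.set_id for r in retained if getattr(r, "retained", True)]
    pathways = {pid: config.assignments[pid] for pid in retained_ids if pid in config.assignments}
    unassigned = tuple(pid for pid in retained_ids if pid not in config.assignments)
    if unassigned:
        log.info("%d retained pathways have no module assignment: %s",
                 len(unassigned), list(unassigned))
    return IntegratedPathway(pathways=pathways, unassigned=unassigned)


def build_integrated_pathway(
    tp_net: BipartiteNetwork, skeleton: IntegratedPathway
) -> IntegratedPathway:
    """Annotate each target in the T-P network with the union of the
    module labels of its adjacent, module-assigned pathways.  Targets
    adjacent only to unassigned pathways carry an empty label set."""
    target_labels: dict = {}
    for target in sorted(tp_net.side_a):
        labels: set = set()
        for pathway in tp_net.graph.neighbors(target):
            labels.update(skeleton.pathways.get(pathway, ()))
        target_labels[target] = frozenset(labels)
    return IntegratedPathway(
        pathways=dict(skeleton.pathways),
        unassigned=skeleton.unassigned,
        target_labels=target_labels,
        provenance=dict(skeleton.provenance),
    )
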