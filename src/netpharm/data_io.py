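"""Readers, writers and validated domain records for every file format the
pipeline touches.

The canonical table dialect is tab-separated UTF-8 with a header row, so
free-text compound names containing commas are safe.  Gene identity is the
uppercased, whitespace-stripped HGNC-style symbol; all readers normalize
symbols on the way in, so downstream code may assume
``symbol == symbol.strip().upper()``.

Database exports sometimes print negative numbers in parentheses
(e.g. a Caco-2 permeability of ``(2.22)`` meaning −2.22); numeric cells are
parsed accordingly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

log = logging.getLogger("netpharm")

__all__ = [
    "FormatError",
    "ValidationError",
    "normalize_symbol",
    "parse_numeric",
    "CompoundRecord",
    "HerbCompoundList",
    "EdgeSource",
    "CompoundTargetEdge",
    "GeneSet",
    "GeneSetCollection",
    "DiseaseGeneList",
    "PipelineConfig",
    "read_compound_table",
    "write_compound_table",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
]


class FormatError(ValueError):
    """A file does not conform to its expected dialect (missing column,
    malformed line, non-numeric cell)."""


class ValidationError(ValueError):
    """Content is well-formed but violates a domain invariant (duplicate
    identifier, confidence out of range, ...)."""


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol."""
    return str(symbol).strip().upper()


_PAREN_RE = re.compile(r"^\((.+)\)$")


def parse_numeric(cell, *, column: str | None = None, row: int | None = None) -> float:
    """Parse a numeric table cell; ``(x)`` denotes a negative number.

    ``row`` is the 1-based file line number used in error messages.
    """
    text = str(cell).strip()
    match = _PAREN_RE.match(text)
    negate = False
    if match:
        text = match.group(1).strip()
        negate = True
    try:
        value = float(text)
    except ValueError:
        where = ""
        if column is not None:
            where += f" in column {column!r}"
        if row is not None:
            where += f" at line {row}"
        raise FormatError(f"non-numeric value {cell!r}{where}") from None
    return -value if negate else value


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass
class CompoundRecord:
    """One herbal molecule with its ADME profile and herb provenance.

    ``ob`` is oral bioavailability in percent (≥ 0), ``dl`` the unitless
    drug-likeness index, ``caco2`` the Caco-2 permeability score (may be
    negative). ``descriptors`` optionally carries a named molecular-property
    vector used when drug-likeness is recomputed in-package.
    """

    mol_id: str
    name: str
    herb_sources: frozenset
    ob: float
    dl: float
    caco2: float
    descriptors: dict | None = None
    whitelisted: bool = False

    def __post_init__(self):
        self.herb_sources = frozenset(self.herb_sources)
        if not self.herb_sources:
            raise ValidationError(f"{self.mol_id}: herb_sources must be non-empty")
        if self.ob < 0:
            raise ValidationError(f"{self.mol_id}: ob must be >= 0, got {self.ob}")
        if not (0.0 <= self.dl <= 1.0):
            # Input DL values come from external databases and are accepted
            # as-is, but anything outside the Tanimoto range is suspicious.
            log.warning("%s: dl=%s outside [0, 1]", self.mol_id, self.dl)


@dataclass
class HerbCompoundList:
    """Ordered compound list for one herb, duplicate-free by mol_id."""

    herb_code: str
    compounds: list

    def __post_init__(self):
        seen = set()
        for rec in self.compounds:
            if rec.mol_id in seen:
                raise ValidationError(
                    f"duplicate mol_id {rec.mol_id!r} in herb {self.herb_code!r}"
                )
            seen.add(rec.mol_id)

    def __len__(self):
        return len(self.compounds)


class EdgeSource(str, Enum):
    CURATED = "curated"
    PREDICTED = "predicted"


@dataclass(frozen=True)
class CompoundTargetEdge:
    """A compound→gene interaction; predicted edges carry a confidence."""

    mol_id: str
    gene_symbol: str
    source: EdgeSource
    confidence: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "gene_symbol", normalize_symbol(self.gene_symbol))
        object.__setattr__(self, "source", EdgeSource(self.source))
        if self.source is EdgeSource.PREDICTED and self.confidence is None:
            raise ValidationError(
                f"predicted edge ({self.mol_id}, {self.gene_symbol}) lacks a confidence"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"edge ({self.mol_id}, {self.gene_symbol}): confidence "
                f"{self.confidence} outside [0, 1]"
            )


@dataclass
class GeneSet:
    set_id: str
    set_name: str
    genes: frozenset

    def __post_init__(self):
        self.genes = frozenset(normalize_symbol(g) for g in self.genes)
        if not self.genes:
            raise ValidationError(f"gene set {self.set_id!r} is empty")


class Namespace(str, Enum):
    GO_BP = "GO_BP"
    KEGG = "KEGG"
    OTHER = "other"


@dataclass
class GeneSetCollection:
    """Named gene sets (GO terms / pathways); their union is the default
    enrichment universe."""

    namespace: Namespace
    sets: list

    def __post_init__(self):
        self.namespace = Namespace(self.namespace)
        seen = set()
        for gs in self.sets:
            if gs.set_id in seen:
                raise ValidationError(f"duplicate set_id {gs.set_id!r} in collection")
            seen.add(gs.set_id)

    def all_genes(self) -> frozenset:
        out = set()
        for gs in self.sets:
            out |= gs.genes
        return frozenset(out)

    def __len__(self):
        return len(self.sets)


@dataclass
class DiseaseGeneList:
    disease_label: str
    genes: frozenset

    def __post_init__(self):
        self.genes = frozenset(normalize_symbol(g) for g in self.genes)


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters.

    Defaults are the screening thresholds OB ≥ 30 %, DL ≥ 0.18,
    Caco-2 ≥ 0, a strict 40 % prediction-confidence floor and a strict
    FDR < 0.01 enrichment cut.  ``whitelist`` maps rescued mol_ids to a
    free-text pharmacological rationale; ``modules`` maps pathway ids to
    therapeutic-module labels for the integrated disease pathway.
    """

    ob_min: float = 30.0
    dl_min: float = 0.18
    caco2_min: float = 0.0
    whitelist: dict = field(default_factory=dict)
    confidence_min: float = 0.40
    fdr_max: float = 0.01
    universe: str = "collection"
    modules: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        import math

        for name in ("ob_min", "dl_min", "caco2_min", "confidence_min"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if not (0.0 < self.fdr_max <= 1.0):
            raise ValidationError(f"fdr_max must be in (0, 1], got {self.fdr_max}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Stable digest over every semantic field."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_MANDATORY_COMPOUND_COLUMNS = ("mol_id", "name", "ob", "dl", "caco2")


def read_compound_table(path, herb_code: str) -> HerbCompoundList:
    """Read a TSV compound table into one herb's compound list.

    Mandatory columns: mol_id, name, ob, dl, caco2.  Columns prefixed
    ``desc_`` are collected into the descriptor vector.  An optional
    ``herbs`` column (comma-separated codes) overrides ``herb_code`` for
    multi-herb exports.  Row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _MANDATORY_COMPOUND_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    desc_cols = [c for c in df.columns if c.startswith("desc_")]
    records = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        row = row._asdict()
        mol_id = str(row["mol_id"]).strip()
        if mol_id in seen:
            raise ValidationError(f"{path}: duplicate mol_id {mol_id!r} at line {line_no}")
        seen.add(mol_id)
        adme = {
            c: parse_numeric(row[c], column=c, row=line_no) for c in ("ob", "dl", "caco2")
        }
        herbs = (
            frozenset(h.strip() for h in str(row["herbs"]).split(",") if h.strip())
            if "herbs" in row and str(row["herbs"]).strip()
            else frozenset({herb_code})
        )
        descriptors = (
            {c[len("desc_"):]: parse_numeric(row[c], column=c, row=line_no) for c in desc_cols}
            if desc_cols
            else None
        )
        records.append(
            CompoundRecord(
                mol_id=mol_id,
                name=str(row["name"]).strip(),
                herb_sources=herbs,
                descriptors=descriptors,
                **adme,
            )
        )
    return HerbCompoundList(herb_code=herb_code, compounds=records)


def write_compound_table(records: Iterable[CompoundRecord], path) -> None:
    """Write compound records as canonical TSV (round-trips with the reader)."""
    records = list(records)
    desc_names: list = []
    for rec in records:
        if rec.descriptors:
            for name in rec.descriptors:
                if name not in desc_names:
                    desc_names.append(name)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        header = ["mol_id", "name", "ob", "dl", "caco2", "herbs"]
        header += [f"desc_{n}" for n in desc_names]
        fh.write("\t".join(header) + "\n")
        for rec in records:
            cells = [
                rec.mol_id,
                rec.name,
                repr(rec.ob),
                repr(rec.dl),
                repr(rec.caco2),
                ",".join(sorted(rec.herb_sources)),
            ]
            for name in desc_names:
                value = (rec.descriptors or {}).get(name)
                cells.append("" if value is None else repr(value))
            fh.write("\t".join(cells) + "\n")


def read_edge_list(path) -> list:
    """Read a compound→target TSV edge list.

    Columns: mol_id, gene_symbol, source ∈ {curated, predicted}, optional
    confidence.  Symbols are uppercased; duplicate (mol_id, gene_symbol)
    rows are collapsed keeping the maximum confidence (a curated duplicate
    makes the merged edge curated).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("mol_id", "gene_symbol", "source"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    has_conf = "confidence" in df.columns
    merged: dict = {}
    order: list = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2
        row = row._asdict()
        mol_id = str(row["mol_id"]).strip()
        gene = normalize_symbol(row["gene_symbol"])
        source_txt = str(row["source"]).strip().lower()
        try:
            source = EdgeSource(source_txt)
        except ValueError:
            raise FormatError(
                f"{path}: unknown source {row['source']!r} at line {line_no}"
            ) from None
        conf_cell = str(row.get("confidence", "")).strip() if has_conf else ""
        confidence = parse_numeric(conf_cell, column="confidence", row=line_no) if conf_cell else None
        edge = CompoundTargetEdge(mol_id, gene, source, confidence)
        key = (mol_id, gene)
        if key not in merged:
            merged[key] = edge
            order.append(key)
        else:
            prev = merged[key]
            confidences = [c for c in (prev.confidence, edge.confidence) if c is not None]
            best = max(confidences) if confidences else None
            src = (
                EdgeSource.CURATED
                if EdgeSource.CURATED in (prev.source, edge.source)
                else EdgeSource.PREDICTED
            )
            merged[key] = CompoundTargetEdge(mol_id, gene, src, best)
    return [merged[k] for k in order]


def write_edge_list(edges: Iterable[CompoundTargetEdge], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("mol_id\tgene_symbol\tsource\tconfidence\n")
        for e in edges:
            conf = "" if e.confidence is None else repr(e.confidence)
            fh.write(f"{e.mol_id}\t{e.gene_symbol}\t{e.source.value}\t{conf}\n")


def read_gmt(path, namespace: Namespace | str = Namespace.OTHER) -> GeneSetCollection:
    """Read a GMT gene-set file (set_id TAB description TAB gene TAB gene…)."""
    sets = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {line_no} has {len(fields)} fields, expected >= 3"
                )
            set_id, set_name, *genes = fields
            sets.append(
                GeneSet(
                    set_id=set_id.strip(),
                    set_name=set_name.strip(),
                    genes=frozenset(normalize_symbol(g) for g in genes if g.strip()),
                )
            )
    return GeneSetCollection(namespace=Namespace(namespace), sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in collection.sets:
            fh.write("\t".join([gs.set_id, gs.set_name] + sorted(gs.genes)) + "\n")


def read_gene_list(path, label: str) -> DiseaseGeneList:
    """Read a plain-text gene list (one symbol per line; blanks and ``#``
    comments ignored).  An empty result is valid but logged."""
    genes = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            genes.add(normalize_symbol(text))
    if not genes:
        log.warning("%s: gene list %r is empty", path, label)
    return DiseaseGeneList(disease_label=label, genes=frozenset(genes))


def write_gene_list(gene_list: DiseaseGeneList, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene in sorted(gene_list.genes):
            fh.write(gene + "\n")
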