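"""Drug-likeness computation and the three-criterion ADME screen.

Drug-likeness (DL) is the Tanimoto similarity

    T(A, B) = A·B / (‖A‖² + ‖B‖² − A·B)

between a compound's molecular-property vector A and the mean property
vector B of a drug-like reference set.  Because raw molecular descriptors
live on wildly different scales, both A and B are min–max scaled against
the reference set before the similarity is taken; DL values therefore
depend on the reference, which is an explicit input.  For non-negative
vectors T lies in [0, 1] and equals 1 iff A == B.

The integrative screen keeps compounds with OB ≥ 30 %, DL ≥ 0.18 and
Caco-2 ≥ 0 (all thresholds inclusive and configurable); compounds that
fail but appear on a documented whitelist are rescued into the active set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_io import CompoundRecord, HerbCompoundList, ValidationError

log = logging.getLogger("netpharm")

__all__ = [
    "ReferenceProfile",
    "ScreeningCriteria",
    "ScreeningResult",
    "scale_descriptors",
    "compute_reference_profile",
    "compute_dl",
    "reference_mean_dl",
    "merge_herb_lists",
    "screen_compounds",
]

#: ADME conflict tolerance when merging duplicate mol_ids across herbs.
ADME_MERGE_TOL = 1e-9

#: Failure-flag labels, in fixed report order.
CRITERIA = ("OB", "DL", "Caco-2")


@dataclass
class ReferenceProfile:
    """Scaled mean descriptor vector of a drug-like reference set.

    ``b_vector`` holds the component-wise mean of the min–max scaled
    reference vectors; ``scaling_params`` keeps the per-descriptor
    (min, max) of the raw reference set so new compounds can be mapped
    onto the same [0, 1] scale.
    """

    descriptor_names: tuple
    b_vector: np.ndarray
    scaling_params: dict  # name -> (min, max)

    def __post_init__(self):
        self.descriptor_names = tuple(self.descriptor_names)
        self.b_vector = np.asarray(self.b_vector, dtype=float)
        if self.b_vector.shape != (len(self.descriptor_names),):
            raise ValidationError("b_vector dimension must match descriptor_names")
        if np.any(self.b_vector < 0) or np.any(self.b_vector > 1):
            raise ValidationError("scaled b_vector components must lie in [0, 1]")


def _as_vector(raw, names: Sequence[str]) -> np.ndarray:
    if isinstance(raw, Mapping):
        missing = [n for n in names if n not in raw]
        unknown = [n for n in raw if n not in names]
        if missing or unknown:
            raise ValidationError(
                f"descriptor names mismatch: missing {missing}, unknown {unknown}"
            )
        return np.array([float(raw[n]) for n in names])
    vec = np.asarray(raw, dtype=float)
    if vec.shape != (len(names),):
        raise ValidationError(
            f"descriptor vector has shape {vec.shape}, expected ({len(names)},)"
        )
    return vec


def scale_descriptors(raw, profile: ReferenceProfile) -> np.ndarray:
    """Min–max scale a raw descriptor vector using the reference ranges.

    Each component maps through (x − min)/(max − min) and is clamped to
    [0, 1]; a degenerate reference descriptor (min == max) maps to 0.
    """
    vec = _as_vector(raw, profile.descriptor_names)
    out = np.empty_like(vec)
    for i, name in enumerate(profile.descriptor_names):
        lo, hi = profile.scaling_params[name]
        if hi == lo:
            out[i] = 0.0
        else:
            out[i] = min(1.0, max(0.0, (vec[i] - lo) / (hi - lo)))
    return out


def compute_reference_profile(reference_table) -> ReferenceProfile:
    """Build a :class:`ReferenceProfile` from raw reference descriptors.

    ``reference_table`` is a pandas DataFrame (columns = descriptors) or a
    sequence of equally-keyed mappings with ≥ 2 rows.
    """
    import pandas as pd

    df = (
        reference_table
        if isinstance(reference_table, pd.DataFrame)
        else pd.DataFrame(list(reference_table))
    )
    if len(df) < 2:
        raise ValidationError("reference set needs at least 2 molecules")
    names = tuple(df.columns)
    raw = df.to_numpy(dtype=float)
    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    degenerate = hi == lo
    if degenerate.any():
        log.warning(
            "constant reference descriptors scaled to 0: %s",
            [n for n, d in zip(names, degenerate) if d],
        )
    span = np.where(degenerate, 1.0, hi - lo)
    scaled = np.clip((raw - lo) / span, 0.0, 1.0)
    scaled[:, degenerate] = 0.0
    return ReferenceProfile(
        descriptor_names=names,
        b_vector=scaled.mean(axis=0),
        scaling_params={n: (float(l), float(h)) for n, l, h in zip(names, lo, hi)},
    )


def compute_dl(a, profile_or_b) -> float:
    """Tanimoto drug-likeness of a scaled descriptor vector.

    ``a`` must already be on the reference [0, 1] scale (see
    :func:`scale_descriptors`); negative components are rejected.  Returns
    0 when both vectors are all-zero.
    """
    if isinstance(profile_or_b, ReferenceProfile):
        b = profile_or_b.b_vector
        a = _as_vector(a, profile_or_b.descriptor_names)
    else:
        b = np.asarray(profile_or_b, dtype=float)
        a = np.asarray(a, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if np.any(a < 0) or np.any(b < 0):
        raise ValidationError("Tanimoto index requires non-negative components")
    dot = float(a @ b)
    denom = float(a @ a) + float(b @ b) - dot
    if denom == 0.0:
        return 0.0
    return dot / denom


def reference_mean_dl(reference_table, profile: ReferenceProfile | None = None) -> float:
    """Mean DL of the reference molecules against their own profile.

    This is the calibration that motivates using the reference-average DL
    as a screening threshold.
    """
    import pandas as pd

    df = (
        reference_table
        if isinstance(reference_table, pd.DataFrame)
        else pd.DataFrame(list(reference_table))
    )
    if profile is None:
        profile = compute_reference_profile(df)
    values = [
        compute_dl(scale_descriptors(row, profile), profile)
        for row in df.to_dict("records")
    ]
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Merging and screening
# ---------------------------------------------------------------------------


def merge_herb_lists(lists: Iterable[HerbCompoundList]) -> list:
    """Merge per-herb compound lists into one duplicate-free table.

    Compounds sharing a mol_id across herbs are collapsed into a single
    record whose herb_sources is the union; their ADME values must agree
    within ``ADME_MERGE_TOL`` (duplicates originate from one database, so
    disagreement indicates corrupted input).  First-seen order is kept.
    """
    merged: dict = {}
    order: list = []
    conflicts: list = []
    for herb_list in lists:
        for rec in herb_list.compounds:
            if rec.mol_id not in merged:
                merged[rec.mol_id] = CompoundRecord(
                    mol_id=rec.mol_id,
                    name=rec.name,
                    herb_sources=rec.herb_sources,
                    ob=rec.ob,
                    dl=rec.dl,
                    caco2=rec.caco2,
                    descriptors=dict(rec.descriptors) if rec.descriptors else None,
                    whitelisted=rec.whitelisted,
                )
                order.append(rec.mol_id)
            else:
                prev = merged[rec.mol_id]
                if (
                    abs(prev.ob - rec.ob) > ADME_MERGE_TOL
                    or abs(prev.dl - rec.dl) > ADME_MERGE_TOL
                    or abs(prev.caco2 - rec.caco2) > ADME_MERGE_TOL
                ):
                    conflicts.append(rec.mol_id)
                    continue
                prev.herb_sources = prev.herb_sources | rec.herb_sources
    if conflicts:
        raise ValidationError(
            f"conflicting ADME values for duplicate mol_ids: {sorted(set(conflicts))}"
        )
    return [merged[m] for m in order]


@dataclass
class ScreeningCriteria:
    """Inclusive screening floors for the three ADME criteria."""

    ob_min: float = 30.0
    dl_min: float = 0.18
    caco2_min: float = 0.0

    def failed(self, rec: CompoundRecord) -> tuple:
        flags = []
        if rec.ob < self.ob_min:
            flags.append("OB")
        if rec.dl < self.dl_min:
            flags.append("DL")
        if rec.caco2 < self.caco2_min:
            flags.append("Caco-2")
        return tuple(flags)


@dataclass
class ScreeningResult:
    """Partition of the input table into passed / rescued / rejected.

    ``failures`` maps every failing mol_id (rescued or rejected) to the
    tuple of criteria it failed.  ``active`` is passed ∪ rescued.
    """

    passed: list
    rescued: list
    rejected: list
    failures: dict

    @property
    def active(self) -> list:
        return self.passed + self.rescued

    def status(self, mol_id: str) -> str:
        if mol_id in set(self.passed):
            return "passed"
        if mol_id in set(self.rescued):
            return "rescued"
        return "rejected"


def screen_compounds(
    table: Iterable[CompoundRecord],
    criteria: ScreeningCriteria | None = None,
    whitelist: Iterable[str] = (),
) -> ScreeningResult:
    """Apply the three-criterion integrative screen with whitelist rescue.

    A record passes iff it satisfies all three inclusive thresholds; a
    failing record on the whitelist is rescued (it joins the active set but
    keeps its failure flags); everything else is rejected.  The three lists
    partition the input.
    """
    criteria = criteria or ScreeningCriteria()
    whitelist = set(whitelist)
    table = list(table)
    present = {rec.mol_id for rec in table}
    absent = whitelist - present
    if absent:
        log.warning("whitelist ids absent from table: %s", sorted(absent))
    passed, rescued, rejected = [], [], []
    failures = {}
    for rec in table:
        flags = criteria.failed(rec)
        if not flags:
            passed.append(rec.mol_id)
        elif rec.mol_id in whitelist:
            rescued.append(rec.mol_id)
            failures[rec.mol_id] = flags
        else:
            rejected.append(rec.mol_id)
            failures[rec.mol_id] = flags
    return ScreeningResult(passed=passed, rescued=rescued, rejected=rejected, failures=failures)
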