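"""High-confidence filtering, replicate pooling, and final potency resolution.

The curation model: raw activity records pass dialect-specific confidence
filters; potencies are converted to the negative decadic log scale
(pPot = 9 - log10(value in nM), so 10 uM corresponds to pPot 5); replicates
of the same endpoint for one compound-target pair are pooled and averaged
only if mutually consistent; equilibrium endpoints (Ki/Kd) take precedence
over IC50; the highest surviving averaged value becomes the final
annotation; and a minimal potency threshold (default pPot >= 5) is applied.

Consistency rules
-----------------
Kinase-side pairs use the *span* rule: replicate pPot values are averaged
only if max - min < 1.0 (all values within the same order of magnitude);
a span of exactly one full log unit is discarded.  Non-kinase pairs use the
*SD* rule: averages with population standard deviation strictly greater
than 1 are discarded, so SD exactly 1.0 is retained.  Both boundaries are
config-overridable.
"""

from __future__ import annotations

import math
import statistics
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .records import (
    EQUILIBRIUM_ENDPOINTS,
    ActivityRecord,
    CuratedInteraction,
    MeasurementGroup,
    ResolvedRecord,
    TargetEntry,
)
from .standardize import StructureError, standardize_structure


class CurationError(ValueError):
    pass


def to_ppot(value: float, units: str = "nM") -> float:
    """Convert a potency in nM to its negative decadic log (pPot).

    10000 nM (10 uM) maps to 5.0; 1 nM maps to 9.0.
    """
    if units != "nM":
        raise CurationError(f"unit_mismatch: {units!r}")
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise CurationError(f"bad_value: {value!r}")
    return 9.0 - math.log10(value)


@dataclass(frozen=True)
class CurationRuleset:
    """Dialect-specific acceptance rules; defaults mirror the study settings."""

    chembl_target_type: str = "SINGLE PROTEIN"
    organism: str = "Homo sapiens"
    chembl_relationship: str = "D"  # direct binding assay
    chembl_confidence: int = 9  # highest single-protein confidence
    relation: str = "="
    units: str = "nM"
    contradiction_vocabulary: frozenset[str] = frozenset(
        {"inactive", "inconclusive", "not active"}
    )
    span_cutoff: float = 1.0  # discard when span >= cutoff
    sd_cutoff: float = 1.0  # discard when population SD > cutoff
    ppot_min: float = 5.0
    # None = pick per target (span for PKs, sd for non-PKs); "span"/"sd" force one
    consistency_rule: Optional[str] = None


DEFAULT_RULESET = CurationRuleset()


def filter_high_confidence(
    records: Iterable[ActivityRecord],
    ruleset: CurationRuleset = DEFAULT_RULESET,
) -> tuple[list[ActivityRecord], list[tuple[ActivityRecord, str]]]:
    """Keep only records meeting the high-confidence criteria.

    ChEMBL-dialect records must be single-protein, human, direct-binding
    (relationship D) at confidence 9 with relation "=" and nM units.
    BindingDB-dialect records must be human single-protein chains with
    relation "=" and nM units (the dialect has no confidence columns).
    Each rejection carries the name of the first failed rule.
    """
    accepted: list[ActivityRecord] = []
    rejected: list[tuple[ActivityRecord, str]] = []
    for rec in records:
        reason = _first_failed_rule(rec, ruleset)
        if reason is None:
            accepted.append(rec)
        else:
            rejected.append((rec, reason))
    return accepted, rejected


def _first_failed_rule(rec: ActivityRecord, rs: CurationRuleset) -> Optional[str]:
    if rec.source == "chembl":
        if rec.target_type != rs.chembl_target_type:
            return "target_type"
        if rec.organism != rs.organism:
            return "organism"
        if rec.assay_relationship != rs.chembl_relationship:
            return "relationship"
        if rec.confidence_score != rs.chembl_confidence:
            return "confidence"
    else:
        # BindingDB rows are single-protein chains by construction; the
        # dialect carries no target_type/confidence columns, so only rows
        # explicitly marked otherwise fail here.
        if rec.target_type is not None and rec.target_type != rs.chembl_target_type:
            return "target_type"
        if rec.organism != rs.organism:
            return "organism"
    if rec.relation != rs.relation:
        return "relation"
    if rec.units != rs.units:
        return "units"
    return None


def resolve_records(
    records: Iterable[ActivityRecord],
    targets: Mapping[str, TargetEntry],
    salt_set: Optional[frozenset[str]] = None,
) -> tuple[list[ResolvedRecord], list[tuple[ActivityRecord, str]]]:
    """Attach compound keys and canonical target IDs to accepted records.

    Targets are aggregated on UniProt accessions: a record whose ``uniprot``
    matches a catalog entry maps to that entry; otherwise its ``target_ref``
    is looked up directly.  Unmappable targets and unstandardizable
    structures are rejected with reasons.
    """
    by_uniprot = {t.uniprot: t for t in targets.values() if t.uniprot}
    resolved: list[ResolvedRecord] = []
    rejected: list[tuple[ActivityRecord, str]] = []
    for rec in records:
        entry = None
        if rec.uniprot is not None:
            entry = by_uniprot.get(rec.uniprot)
        if entry is None:
            entry = targets.get(rec.target_ref)
        if entry is None:
            rejected.append((rec, "unknown_target"))
            continue
        try:
            key = standardize_structure(rec.smiles_raw, salt_set)
        except StructureError as exc:
            rejected.append((rec, exc.reason))
            continue
        try:
            ppot = to_ppot(rec.value, rec.units)
        except CurationError:
            rejected.append((rec, "bad_value"))
            continue
        resolved.append(
            ResolvedRecord(
                compound_key=key,
                target_id=entry.target_id,
                is_pk=entry.is_pk,
                measurement_type=rec.measurement_type,
                ppot=ppot,
                source=rec.source,
                compound_ref=rec.compound_ref,
                activity_comment=rec.activity_comment,
            )
        )
    return resolved, rejected


def drop_contradicted_pairs(
    records: Sequence[ResolvedRecord],
    vocabulary: Optional[frozenset[str]] = None,
) -> tuple[list[ResolvedRecord], list[tuple[str, str]]]:
    """Remove every record of a pair that carries a contradictory comment.

    A (compound_key, target_id) pair with at least one record whose
    activity_comment matches the contradiction vocabulary (case-insensitive)
    loses ALL its records for that target.
    """
    if vocabulary is None:
        vocabulary = DEFAULT_RULESET.contradiction_vocabulary
    vocab = {v.lower() for v in vocabulary}
    contradicted: set[tuple[str, str]] = set()
    for rec in records:
        if rec.activity_comment and rec.activity_comment.strip().lower() in vocab:
            contradicted.add((rec.compound_key, rec.target_id))
    kept = [r for r in records if (r.compound_key, r.target_id) not in contradicted]
    return kept, sorted(contradicted)


def group_measurements(
    records: Iterable[ResolvedRecord],
) -> dict[tuple[str, str, str], MeasurementGroup]:
    """Pool replicates per (compound_key, target_id, endpoint) across sources."""
    groups: dict[tuple[str, str, str], MeasurementGroup] = {}
    for rec in records:
        gkey = (rec.compound_key, rec.target_id, rec.measurement_type)
        grp = groups.get(gkey)
        if grp is None:
            grp = groups[gkey] = MeasurementGroup(
                compound_key=rec.compound_key,
                target_id=rec.target_id,
                measurement_type=rec.measurement_type,
            )
        grp.ppot_values.append(rec.ppot)
        grp.sources.append(rec.source)
    return groups


def pool_and_average(
    group: MeasurementGroup,
    consistency_rule: str,
    cutoff: float = 1.0,
) -> tuple[Optional[float], Optional[str]]:
    """Average a replicate group if consistent; otherwise discard.

    span rule: mean iff max - min < cutoff, else ``(None, "inconsistent_span")``.
    sd rule: mean iff population SD <= cutoff, else ``(None, "inconsistent_sd")``.
    """
    values = group.ppot_values
    if not values:
        raise CurationError("empty measurement group")
    if len(values) == 1:
        return values[0], None
    if consistency_rule == "span":
        if max(values) - min(values) < cutoff:
            return statistics.fmean(values), None
        return None, "inconsistent_span"
    if consistency_rule == "sd":
        if statistics.pstdev(values) <= cutoff:
            return statistics.fmean(values), None
        return None, "inconsistent_sd"
    raise CurationError(f"unknown consistency rule: {consistency_rule!r}")


def resolve_final_annotation(
    averaged: Mapping[str, Optional[float]],
) -> Optional[tuple[float, str]]:
    """Pick the final annotation from averaged per-endpoint values.

    Equilibrium endpoints (Ki, Kd) are prioritized over IC50; among
    surviving equilibrium averages the highest value wins.  Returns
    ``(ppot_final, basis)`` or None when nothing survives.
    """
    eq = [
        v
        for e, v in averaged.items()
        if e in EQUILIBRIUM_ENDPOINTS and v is not None
    ]
    if eq:
        return max(eq), "equilibrium"
    ic50 = averaged.get("IC50")
    if ic50 is not None:
        return ic50, "ic50"
    return None


def apply_activity_threshold(
    interactions: Iterable[CuratedInteraction], ppot_min: float = 5.0
) -> list[CuratedInteraction]:
    """Retain exactly the interactions with ppot_final >= ppot_min."""
    return [i for i in interactions if i.ppot_final >= ppot_min]


@dataclass
class CurationLedger:
    """Audit trail of everything curation removed, with reasons."""

    filtered: list[tuple[ActivityRecord, str]] = field(default_factory=list)
    unresolved: list[tuple[ActivityRecord, str]] = field(default_factory=list)
    contradicted_pairs: list[tuple[str, str]] = field(default_factory=list)
    inconsistent_groups: list[tuple[str, str, str, str]] = field(default_factory=list)
    below_threshold: list[CuratedInteraction] = field(default_factory=list)


def curate_interactions(
    records: Sequence[ActivityRecord],
    targets: Mapping[str, TargetEntry],
    ruleset: CurationRuleset = DEFAULT_RULESET,
    salt_set: Optional[frozenset[str]] = None,
) -> tuple[list[CuratedInteraction], CurationLedger]:
    """Run the full curation cascade on raw records.

    Stages: high-confidence filter -> structure standardization and target
    mapping -> contradicted-pair removal -> per-endpoint pooling and
    consistency averaging -> equilibrium-over-IC50 prioritization with max
    -> activity threshold.  The ledger records every removal.
    """
    ledger = CurationLedger()
    accepted, ledger.filtered = filter_high_confidence(records, ruleset)
    resolved, ledger.unresolved = resolve_records(accepted, targets, salt_set)
    resolved, ledger.contradicted_pairs = drop_contradicted_pairs(
        resolved, ruleset.contradiction_vocabulary
    )

    groups = group_measurements(resolved)
    per_pair: dict[tuple[str, str], dict[str, Optional[float]]] = defaultdict(dict)
    pair_n: dict[tuple[str, str], int] = defaultdict(int)
    for (ck, tid, endpoint), grp in groups.items():
        rule = ruleset.consistency_rule
        if rule is None:
            rule = "span" if targets[tid].is_pk else "sd"
        cutoff = ruleset.span_cutoff if rule == "span" else ruleset.sd_cutoff
        mean, discard = pool_and_average(grp, rule, cutoff)
        if discard is not None:
            ledger.inconsistent_groups.append((ck, tid, endpoint, discard))
            continue
        per_pair[(ck, tid)][endpoint] = mean
        pair_n[(ck, tid)] += len(grp.ppot_values)

    interactions: list[CuratedInteraction] = []
    for (ck, tid) in sorted(per_pair):
        final = resolve_final_annotation(per_pair[(ck, tid)])
        if final is None:
            continue
        ppot_final, basis = final
        interactions.append(
            CuratedInteraction(
                compound_key=ck,
                target_id=tid,
                ppot_final=ppot_final,
                basis=basis,
                n_measurements=pair_n[(ck, tid)],
            )
        )
    retained = apply_activity_threshold(interactions, ruleset.ppot_min)
    ledger.below_threshold = [
        i for i in interactions if i.ppot_final < ruleset.ppot_min
    ]
    return retained, ledger
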