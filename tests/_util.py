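"""Shared test helpers: record builders and independent brute-force oracles.

The oracles here re-derive pipeline results with deliberately plain
single-pass dict-and-loop code so they stay independent of the staged
implementations they check.
"""

from __future__ import annotations

import math
import statistics as st
from itertools import combinations

from pkitargets.records import ActivityRecord, CuratedInteraction, TargetEntry
from pkitargets.standardize import StructureError, standardize_structure


def record(**kw) -> ActivityRecord:
    """An ActivityRecord that passes every high-confidence rule by default."""
    base = dict(
        source="chembl",
        compound_ref="C1",
        smiles_raw="CCO",
        target_ref="T1",
        uniprot="P1",
        organism="Homo sapiens",
        target_type="SINGLE PROTEIN",
        assay_relationship="D",
        confidence_score=9,
        measurement_type="IC50",
        relation="=",
        value=100.0,
        units="nM",
        activity_comment=None,
    )
    base.update(kw)
    return ActivityRecord(**base)


def target(tid, is_pk=False, is_antitarget=False, **kw) -> TargetEntry:
    base = dict(
        target_id=tid,
        uniprot=kw.pop("uniprot", f"UP_{tid}"),
        name=tid,
        is_pk=is_pk,
        kinase_group="TK" if is_pk else None,
        class_l1="enzyme" if not is_pk else "enzyme",
        class_l2=None,
        is_antitarget=is_antitarget,
    )
    base.update(kw)
    return TargetEntry(**base)


def targets_from_frame(df) -> dict[str, TargetEntry]:
    out = {}
    for row in df.to_dict("records"):
        is_pk = str(row["is_pk"]).lower() == "true"
        out[row["target_id"]] = TargetEntry(
            target_id=row["target_id"],
            uniprot=row["uniprot"],
            name=row["name"],
            is_pk=is_pk,
            kinase_group=(row["kinase_group"] or None) if is_pk else None,
            class_l1=row["class_l1"] or None,
            class_l2=row["class_l2"] or None,
            is_antitarget=str(row["is_antitarget"]).lower() == "true",
        )
    return out


def interactions_from_manifest(manifest) -> list[CuratedInteraction]:
    """The curated interactions the manifest predicts (anti-targets included)."""
    out = []
    for c in manifest.compounds:
        for i in c.interactions:
            if i.expected_retained:
                out.append(
                    CuratedInteraction(
                        compound_key=c.compound_key,
                        target_id=i.target_id,
                        ppot_final=i.expected_final,
                        basis=i.expected_basis,
                        n_measurements=sum(
                            len(v) for v in i.pooled_values.values()
                        ),
                    )
                )
    return out


def naive_curation(records, targets, ppot_min=5.0):
    """Single-pass brute-force curation: filter -> key -> contradiction ->
    group -> average -> prioritize -> max -> threshold.

    Returns {(compound_key, target_id): (ppot_final, basis)}.
    """
    by_uniprot = {t.uniprot: t for t in targets.values() if t.uniprot}
    rows = []
    for r in records:
        if r.source == "chembl":
            if r.target_type != "SINGLE PROTEIN":
                continue
            if r.organism != "Homo sapiens":
                continue
            if r.assay_relationship != "D":
                continue
            if r.confidence_score != 9:
                continue
        else:
            if r.target_type not in (None, "SINGLE PROTEIN"):
                continue
            if r.organism != "Homo sapiens":
                continue
        if r.relation != "=" or r.units != "nM":
            continue
        t = None
        if r.uniprot is not None:
            t = by_uniprot.get(r.uniprot)
        if t is None:
            t = targets.get(r.target_ref)
        if t is None:
            continue
        try:
            key = standardize_structure(r.smiles_raw)
        except StructureError:
            continue
        comment = (r.activity_comment or "").strip().lower()
        rows.append(
            (key, t.target_id, t.is_pk, r.measurement_type,
             9.0 - math.log10(r.value), comment)
        )
    bad = {
        (k, tid)
        for k, tid, _, _, _, c in rows
        if c in ("inactive", "inconclusive", "not active")
    }
    groups: dict = {}
    for k, tid, is_pk, m, p, _ in rows:
        if (k, tid) in bad:
            continue
        groups.setdefault((k, tid, m, is_pk), []).append(p)
    per_pair: dict = {}
    for (k, tid, m, is_pk), vals in groups.items():
        if len(vals) > 1:
            if is_pk and max(vals) - min(vals) >= 1.0:
                continue
            if not is_pk and st.pstdev(vals) > 1.0:
                continue
        per_pair.setdefault((k, tid), {})[m] = st.fmean(vals)
    out = {}
    for (k, tid), means in per_pair.items():
        eq = [means[m] for m in ("Ki", "Kd") if m in means]
        if eq:
            final, basis = max(eq), "equilibrium"
        elif "IC50" in means:
            final, basis = means["IC50"], "ic50"
        else:
            continue
        if final >= ppot_min:
            out[(k, tid)] = (final, basis)
    return out


def brute_force_edges(profiles, min_shared=2):
    """O(T^2 * C) pairwise-intersection recount of the target network."""
    all_targets = sorted(
        set().union(*((p.pk_targets | p.nonpk_targets) for p in profiles))
        if profiles
        else set()
    )
    edges = {}
    for t1, t2 in combinations(all_targets, 2):
        n = sum(
            1
            for p in profiles
            if t1 in (p.pk_targets | p.nonpk_targets)
            and t2 in (p.pk_targets | p.nonpk_targets)
        )
        if n >= min_shared:
            edges[(t1, t2)] = n
    return edges
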