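"""Promiscuity degrees, their distributions, ranking reports, and the
potency-level scan.

A compound enters the analysis set when it has at least one retained kinase
(PK) interaction and at least one retained non-kinase (non-PK) interaction.
Its PK promiscuity degree (PK_PD) is the number of distinct PK targets;
Non-PK_PD counts distinct non-PK targets.  Anti-targets never count toward
either degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .records import CuratedInteraction, PromiscuityProfile, TargetEntry

#: Degree bins used for the distribution report: single target, two to
#: four, five to nine, and ten or more.  ``None`` marks an open upper end.
DEFAULT_BINS: tuple[tuple[int, Optional[int]], ...] = (
    (1, 1),
    (2, 4),
    (5, 9),
    (10, None),
)


class AnalysisError(ValueError):
    pass


def build_profiles(
    interactions: Iterable[CuratedInteraction],
    targets: Mapping[str, TargetEntry],
) -> list[PromiscuityProfile]:
    """Build the analysis set: compounds with >= 1 PK and >= 1 non-PK target.

    An interaction naming a target absent from the metadata is fatal (the
    error names the ID).  Anti-target interactions are ignored here; the
    anti-target screen removes such compounds earlier in the pipeline.
    """
    pk: dict[str, set[str]] = {}
    nonpk: dict[str, set[str]] = {}
    for inter in interactions:
        entry = targets.get(inter.target_id)
        if entry is None:
            raise AnalysisError(f"target not in metadata: {inter.target_id}")
        if entry.is_antitarget:
            continue
        bucket = pk if entry.is_pk else nonpk
        bucket.setdefault(inter.compound_key, set()).add(inter.target_id)
    profiles = [
        PromiscuityProfile(
            compound_key=ck,
            pk_targets=frozenset(pk[ck]),
            nonpk_targets=frozenset(nonpk[ck]),
        )
        for ck in sorted(set(pk) & set(nonpk))
    ]
    return profiles


def _round_half_up_1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _validate_bins(bins: Sequence[tuple[int, Optional[int]]]) -> None:
    expect_lo = 1
    for i, (lo, hi) in enumerate(bins):
        if lo != expect_lo:
            raise AnalysisError(f"bins do not partition degrees >= 1 at {lo}")
        if hi is None:
            if i != len(bins) - 1:
                raise AnalysisError("open bin must be last")
            return
        if hi < lo:
            raise AnalysisError(f"empty bin ({lo}, {hi})")
        expect_lo = hi + 1
    raise AnalysisError("last bin must be open-ended")


def bin_degree_counts(
    degrees: Iterable[int],
    bins: Sequence[tuple[int, Optional[int]]] = DEFAULT_BINS,
) -> dict[tuple[int, Optional[int]], tuple[int, float]]:
    """Bin a sequence of promiscuity degrees into (count, percentage) cells.

    Percentages are 100 * count / total, rounded half-up to one decimal.
    """
    _validate_bins(bins)
    degrees = list(degrees)
    total = len(degrees)
    out = {}
    for lo, hi in bins:
        n = sum(1 for d in degrees if d >= lo and (hi is None or d <= hi))
        pct = _round_half_up_1(100.0 * n / total) if total else 0.0
        out[(lo, hi)] = (n, pct)
    if sum(c for c, _ in out.values()) != total:
        raise AnalysisError("degrees below 1 are not binnable")
    return out


def bin_distribution(
    profiles: Sequence[PromiscuityProfile],
    which: str,
    bins: Sequence[tuple[int, Optional[int]]] = DEFAULT_BINS,
) -> dict[tuple[int, Optional[int]], tuple[int, float]]:
    """Distribution of PK_PD (``which="pk"``) or Non-PK_PD (``"nonpk"``)."""
    if which not in ("pk", "nonpk"):
        raise AnalysisError(f"which must be 'pk' or 'nonpk', got {which!r}")
    degrees = [p.pk_pd if which == "pk" else p.nonpk_pd for p in profiles]
    return bin_degree_counts(degrees, bins)


@dataclass(frozen=True)
class TargetRankRow:
    """One row of a shared-inhibitor ranking report."""

    target_id: str
    n_shared_pkis: int
    n_counterpart_targets: int


def rank_targets_by_shared_inhibitors(
    profiles: Sequence[PromiscuityProfile],
    domain: str,
    k: int = 10,
) -> list[TargetRankRow]:
    """Rank targets of one domain by how many analysis-set compounds hit them.

    For ``domain="pk"`` each row reports a PK target, the number of
    analysis-set compounds active against it, and the size of the union of
    those compounds' non-PK targets (and symmetrically for ``"nonpk"``).
    Ties are broken by target_id.
    """
    if domain not in ("pk", "nonpk"):
        raise AnalysisError(f"domain must be 'pk' or 'nonpk', got {domain!r}")
    hits: dict[str, list[PromiscuityProfile]] = {}
    for p in profiles:
        own = p.pk_targets if domain == "pk" else p.nonpk_targets
        for t in own:
            hits.setdefault(t, []).append(p)
    rows = []
    for t, plist in hits.items():
        counterpart: set[str] = set()
        for p in plist:
            counterpart |= p.nonpk_targets if domain == "pk" else p.pk_targets
        rows.append(TargetRankRow(t, len(plist), len(counterpart)))
    rows.sort(key=lambda r: (-r.n_shared_pkis, r.target_id))
    return rows[:k]


def rank_compounds_by_nonpk_targets(
    profiles: Sequence[PromiscuityProfile], k: int = 10
) -> list[PromiscuityProfile]:
    """Top-k compounds by Non-PK_PD (ties: PK_PD desc, then compound key)."""
    ranked = sorted(
        profiles, key=lambda p: (-p.nonpk_pd, -p.pk_pd, p.compound_key)
    )
    return ranked[:k]


@dataclass(frozen=True)
class PotencyScanRow:
    """Unique target counts at one potency threshold."""

    ppot_threshold: float
    unique_pk_targets: int
    unique_nonpk_targets: int


def potency_scan(
    interactions: Sequence[CuratedInteraction],
    targets: Mapping[str, TargetEntry],
    thresholds: Sequence[float] = (5.0, 6.0, 7.0, 8.0),
) -> list[PotencyScanRow]:
    """Count unique PK / non-PK targets at increasing potency thresholds.

    The compound set is fixed to the analysis set defined at the base
    (first) threshold; only the interactions are re-thresholded, so both
    count columns are non-increasing in the threshold.
    """
    base = min(thresholds)
    base_profiles = build_profiles(
        [i for i in interactions if i.ppot_final >= base], targets
    )
    analysis_set = {p.compound_key for p in base_profiles}
    rows = []
    for t in thresholds:
        pk_t: set[str] = set()
        nonpk_t: set[str] = set()
        for inter in interactions:
            if inter.compound_key not in analysis_set or inter.ppot_final < t:
                continue
            entry = targets[inter.target_id]
            if entry.is_antitarget:
                continue
            (pk_t if entry.is_pk else nonpk_t).add(inter.target_id)
        rows.append(PotencyScanRow(t, len(pk_t), len(nonpk_t)))
    return rows


def count_inverted_primary(
    interactions: Sequence[CuratedInteraction],
    targets: Mapping[str, TargetEntry],
    nonpk_min: float = 7.0,
    pk_band: tuple[float, float] = (5.0, 6.0),
) -> tuple[int, list[str]]:
    """Count compounds whose primary target is a non-kinase.

    Selects analysis-set compounds with nanomolar potency against their
    best non-PK target (max non-PK pPot >= ``nonpk_min``) but only
    micromolar potency against kinases (max PK pPot within ``pk_band``,
    upper bound exclusive).
    """
    profiles = build_profiles(interactions, targets)
    analysis_set = {p.compound_key for p in profiles}
    best_pk: dict[str, float] = {}
    best_nonpk: dict[str, float] = {}
    for inter in interactions:
        if inter.compound_key not in analysis_set:
            continue
        entry = targets[inter.target_id]
        if entry.is_antitarget:
            continue
        bucket = best_pk if entry.is_pk else best_nonpk
        prev = bucket.get(inter.compound_key)
        if prev is None or inter.ppot_final > prev:
            bucket[inter.compound_key] = inter.ppot_final
    lo, hi = pk_band
    selected = [
        ck
        for ck in sorted(analysis_set)
        if best_nonpk.get(ck, float("-inf")) >= nonpk_min
        and lo <= best_pk.get(ck, float("-inf")) < hi
    ]
    return len(selected), selected


ANNOTATION_COLUMNS = (
    "compound_key",
    "pk_pd",
    "nonpk_pd",
    "pk_target_ids",
    "nonpk_target_ids",
)


def profiles_to_table(profiles: Sequence[PromiscuityProfile]) -> pd.DataFrame:
    """Serialize profiles in the deposited-annotation-file schema."""
    rows = [
        {
            "compound_key": p.compound_key,
            "pk_pd": p.pk_pd,
            "nonpk_pd": p.nonpk_pd,
            "pk_target_ids": ";".join(sorted(p.pk_targets)),
            "nonpk_target_ids": ";".join(sorted(p.nonpk_targets)),
        }
        for p in sorted(profiles, key=lambda p: p.compound_key)
    ]
    return pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))


def profiles_from_annotation_table(path_or_df) -> list[PromiscuityProfile]:
    """Load profiles from an annotation table (compound line notation,
    PK_PD, Non-PK_PD, semicolon-separated target ID lists)."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        sep = "\t" if "\t" in open(path_or_df, encoding="utf-8").readline() else ","
        df = pd.read_csv(path_or_df, sep=sep, dtype=str, keep_default_na=False)
    profiles = []
    for row in df.to_dict("records"):
        pk = frozenset(t for t in str(row["pk_target_ids"]).split(";") if t)
        nonpk = frozenset(t for t in str(row["nonpk_target_ids"]).split(";") if t)
        p = PromiscuityProfile(str(row["compound_key"]), pk, nonpk)
        declared = (int(row["pk_pd"]), int(row["nonpk_pd"]))
        if declared != (p.pk_pd, p.nonpk_pd):
            raise AnalysisError(
                f"degree mismatch for {p.compound_key}: {declared} vs sets"
            )
        profiles.append(p)
    return profiles
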