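"""Domain record model shared by all pipeline stages.

The pipeline moves bioactivity measurements through four representations:
raw :class:`ActivityRecord` rows as exported from a source database, records
resolved to a standardized compound key and canonical target
(:class:`ResolvedRecord`), replicate pools (:class:`MeasurementGroup`), and
the final per-pair :class:`CuratedInteraction` annotation.  Target metadata
lives in :class:`TargetEntry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: The three potency endpoints admitted into curation.  Single-point
#: readouts ("% inhibition" and friends) are rejected at parse time.
ENDPOINTS = ("IC50", "Ki", "Kd")

#: Equilibrium (assay-independent) endpoints, prioritized over IC50 when
#: resolving the final annotation for a compound-target pair.
EQUILIBRIUM_ENDPOINTS = ("Ki", "Kd")

#: Major phylogenetic branches of the human kinome tree.  Real exports
#: occasionally carry other labels (e.g. "AUR"); ingest is lenient.
KINASE_GROUPS = ("TK", "TKL", "AGC", "CAMK", "CMGC", "CK1", "STE", "Other/Atypical")

#: Level-1 protein classes of the ChEMBL-style classification scheme.
CLASS_L1 = (
    "enzyme",
    "membrane receptor",
    "epigenetic regulator",
    "ion channel",
    "transcription factor",
    "transporter",
    "secreted protein",
    "cytosolic other protein",
    "other",
    "unclassified",
)


@dataclass(frozen=True)
class ActivityRecord:
    """One raw measurement row from either source dialect, pre-curation.

    Fields absent from a dialect's export (e.g. confidence_score for
    BindingDB rows) are ``None``, never defaulted, so curation rules can
    treat the dialects differently.
    """

    source: str  # "chembl" | "bindingdb"
    compound_ref: str
    smiles_raw: str
    target_ref: str
    uniprot: Optional[str]
    organism: str
    target_type: Optional[str]
    assay_relationship: Optional[str]
    confidence_score: Optional[int]
    measurement_type: str  # one of ENDPOINTS
    relation: str
    value: float  # potency in the units given; must be finite and > 0
    units: str
    activity_comment: Optional[str] = None


@dataclass(frozen=True)
class TargetEntry:
    """Target metadata: identity, kinase flag and group, protein class."""

    target_id: str
    uniprot: str
    name: str
    is_pk: bool
    kinase_group: Optional[str]  # required when is_pk
    class_l1: Optional[str]
    class_l2: Optional[str]
    is_antitarget: bool = False


@dataclass(frozen=True)
class ResolvedRecord:
    """An accepted record after compound standardization and target mapping."""

    compound_key: str
    target_id: str
    is_pk: bool
    measurement_type: str
    ppot: float
    source: str
    compound_ref: str
    activity_comment: Optional[str] = None


@dataclass
class MeasurementGroup:
    """All replicate measurements of one endpoint for one compound-target pair.

    ``ppot_values`` are on the negative decadic log scale (9 - log10(nM)).
    """

    compound_key: str
    target_id: str
    measurement_type: str
    ppot_values: list[float] = field(default_factory=list)
    sources: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CuratedInteraction:
    """Final potency annotation for one (compound_key, target_id) pair."""

    compound_key: str
    target_id: str
    ppot_final: float
    basis: str  # "equilibrium" (from Ki/Kd) | "ic50"
    n_measurements: int


@dataclass(frozen=True)
class StandardizedCompound:
    """A canonical compound key and the source references that mapped to it."""

    compound_key: str
    member_refs: frozenset[str]
    smiles_raw_examples: tuple[str, ...]  # up to 3 originals, for audit


@dataclass(frozen=True)
class PromiscuityProfile:
    """Per-compound promiscuity degrees with the underlying target sets."""

    compound_key: str
    pk_targets: frozenset[str]
    nonpk_targets: frozenset[str]

    @property
    def pk_pd(self) -> int:
        return len(self.pk_targets)

    @property
    def nonpk_pd(self) -> int:
        return len(self.nonpk_targets)


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of one compound-level quality screen."""

    compound_key: str
    passed: bool
    matched_rules: tuple[str, ...]
    stage: str  # "interference" | "chemistry_rules" | "antitarget"
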