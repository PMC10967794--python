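"""Compound structure standardization and the aggregation key.

Measurements are pooled per compound under a canonical, non-stereo SMILES
key obtained by salt stripping, charge neutralization, and removal of
stereochemistry and isotope labels.  Salt and stereo variants of one parent
therefore share one key.

Salt elimination rule: the structure is split into covalently connected
components; components matching the configured salt/solvent list, plus any
component without a carbon atom, are dropped; the largest remaining
component is kept (tie on heavy-atom count broken by lexicographically
smallest canonical SMILES).  Neutralization is limited to protonation-state
changes that preserve valence, so permanently charged groups (quaternary
nitrogen) stay charged.  Tautomers are NOT merged.
"""

from __future__ import annotations

import functools
from importlib import resources
from typing import Iterable, Optional

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .records import ActivityRecord, StandardizedCompound

RDLogger.DisableLog("rdApp.error")

TOOLKIT = "rdkit"
TOOLKIT_VERSION = __import__("rdkit").__version__


class StructureError(ValueError):
    """Raised for structures that cannot yield a compound key."""

    def __init__(self, reason: str, smiles: str):
        super().__init__(f"{reason}: {smiles!r}")
        self.reason = reason
        self.smiles = smiles


def _canonical(smiles: str) -> Optional[str]:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


@functools.lru_cache(maxsize=1)
def default_salt_set() -> frozenset[str]:
    """Canonical SMILES of the shipped salt/solvent component list."""
    text = (resources.files("pkitargets.data") / "salts.smi").read_text()
    out = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        can = _canonical(line)
        if can is None:
            raise StructureError("bad_salt_pattern", line)
        out.add(can)
    return frozenset(out)


def load_salt_set(path) -> frozenset[str]:
    """Load a user salt list (one SMILES per line, '#' comments)."""
    out = set()
    for line in open(path, encoding="utf-8"):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        can = _canonical(line)
        if can is None:
            raise StructureError("bad_salt_pattern", line)
        out.add(can)
    return frozenset(out)


def standardize_structure(
    smiles_raw: str, salt_set: Optional[frozenset[str]] = None
) -> str:
    """Return the canonical non-stereo compound key for a raw SMILES.

    Raises
    ------
    StructureError
        With ``reason`` ``"bad_structure"`` for unparseable input, or
        ``"no_organic_component"`` when salt stripping leaves nothing.
    """
    if salt_set is None:
        salt_set = default_salt_set()
    return _standardize_cached(smiles_raw, salt_set)


@functools.lru_cache(maxsize=200_000)
def _standardize_cached(smiles_raw: str, salt_set: frozenset[str]) -> str:
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise StructureError("bad_structure", smiles_raw)

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    kept = []
    organic = []
    for frag in frags:
        can = Chem.MolToSmiles(frag)
        has_carbon = any(a.GetAtomicNum() == 6 for a in frag.GetAtoms())
        if not has_carbon:
            continue
        organic.append((frag.GetNumHeavyAtoms(), can, frag))
        if can in salt_set:
            continue
        kept.append((frag.GetNumHeavyAtoms(), can, frag))
    if not kept:
        # salt stripping must never empty a structure that has an organic
        # component (the compound may itself be a listed counterion, e.g.
        # sodium acetate as the substance of interest)
        kept = organic
    if not kept:
        raise StructureError("no_organic_component", smiles_raw)
    # largest component; ties broken by smallest canonical SMILES
    kept.sort(key=lambda t: (-t[0], t[1]))
    parent = kept[0][2]

    parent = rdMolStandardize.Uncharger().uncharge(parent)
    Chem.RemoveStereochemistry(parent)
    for atom in parent.GetAtoms():
        atom.SetIsotope(0)
    # re-canonicalize through a fresh parse so the key is self-stable
    key = Chem.MolToSmiles(parent)
    reparsed = Chem.MolFromSmiles(key)
    if reparsed is None:  # pragma: no cover - defensive
        raise StructureError("bad_structure", smiles_raw)
    return Chem.MolToSmiles(reparsed)


def aggregate_compounds(
    records: Iterable[ActivityRecord],
    salt_set: Optional[frozenset[str]] = None,
) -> tuple[dict[str, StandardizedCompound], list[tuple[str, str, str]]]:
    """Group records by compound key.

    Returns ``(by_key, rejected)`` where ``rejected`` lists
    ``(compound_ref, smiles_raw, reason)`` for records whose structure could
    not be standardized.  Every accepted compound_ref appears in exactly one
    StandardizedCompound's member_refs.
    """
    members: dict[str, set[str]] = {}
    examples: dict[str, list[str]] = {}
    rejected: list[tuple[str, str, str]] = []
    for rec in records:
        try:
            key = standardize_structure(rec.smiles_raw, salt_set)
        except StructureError as exc:
            rejected.append((rec.compound_ref, rec.smiles_raw, exc.reason))
            continue
        members.setdefault(key, set()).add(rec.compound_ref)
        ex = examples.setdefault(key, [])
        if rec.smiles_raw not in ex and len(ex) < 3:
            ex.append(rec.smiles_raw)
    by_key = {
        key: StandardizedCompound(
            compound_key=key,
            member_refs=frozenset(refs),
            smiles_raw_examples=tuple(examples[key]),
        )
        for key, refs in members.items()
    }
    return by_key, rejected
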