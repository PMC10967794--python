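"""Compound-level quality screens.

Three independent predicates decide whether a compound stays in the
analysis: absence of pan-assay interference (PAINS) substructures, absence
of reactive/assay-hostile chemistry alerts, and absence of reported
activity against anti-targets (hERG-like liabilities, CYP isoforms,
albumin).  Each screen is a pure compound-level predicate, so the final
compound set is independent of the order in which screens run.
"""

from __future__ import annotations

import functools
from importlib import resources
from typing import Iterable, Mapping, Optional

from rdkit import Chem

from .records import CuratedInteraction, FilterVerdict, TargetEntry


class CatalogError(ValueError):
    """Raised when a substructure catalog cannot be loaded."""


class SubstructureCatalog:
    """A named set of SMARTS substructure queries loaded from a file.

    File format: one ``name<TAB>SMARTS`` pair per line; ``#`` comments.
    A malformed pattern is fatal at load time and the error names it.
    """

    def __init__(self, patterns: dict[str, "Chem.Mol"], name: str = "catalog"):
        self.patterns = patterns
        self.name = name

    @classmethod
    def from_text(cls, text: str, name: str = "catalog") -> "SubstructureCatalog":
        patterns: dict[str, Chem.Mol] = {}
        for line in text.splitlines():
            line = line.rstrip()
            if not line or line.lstrip().startswith("#"):
                continue
            try:
                rule_name, smarts = line.split("\t", 1)
            except ValueError as exc:
                raise CatalogError(f"{name}: malformed line {line!r}") from exc
            query = Chem.MolFromSmarts(smarts.strip())
            if query is None:
                raise CatalogError(f"{name}: malformed pattern {rule_name!r}")
            patterns[rule_name.strip()] = query
        return cls(patterns, name)

    @classmethod
    def from_file(cls, path) -> "SubstructureCatalog":
        return cls.from_text(open(path, encoding="utf-8").read(), name=str(path))

    def __len__(self) -> int:
        return len(self.patterns)

    def matches(self, mol: "Chem.Mol") -> list[str]:
        return [n for n, q in self.patterns.items() if mol.HasSubstructMatch(q)]


@functools.lru_cache(maxsize=1)
def default_interference_catalog() -> SubstructureCatalog:
    text = (resources.files("pkitargets.data") / "pains_subset.smarts").read_text()
    return SubstructureCatalog.from_text(text, name="pains_subset")


@functools.lru_cache(maxsize=1)
def default_chemistry_catalog() -> SubstructureCatalog:
    text = (resources.files("pkitargets.data") / "chemistry_alerts.smarts").read_text()
    return SubstructureCatalog.from_text(text, name="chemistry_alerts")


def screen_substructures(
    compound_key: str,
    catalog: SubstructureCatalog,
    stage: str = "interference",
) -> FilterVerdict:
    """Test one compound against a pattern catalog.

    The verdict lists every matched pattern name; ``passed`` is true iff
    none matched.  Deterministic for a fixed catalog.
    """
    mol = Chem.MolFromSmiles(compound_key)
    if mol is None:
        raise CatalogError(f"unparseable compound key: {compound_key!r}")
    matched = tuple(sorted(catalog.matches(mol)))
    return FilterVerdict(
        compound_key=compound_key,
        passed=not matched,
        matched_rules=matched,
        stage=stage,
    )


def screen_compound_set(
    compound_keys: Iterable[str],
    interference: Optional[SubstructureCatalog] = None,
    chemistry: Optional[SubstructureCatalog] = None,
) -> tuple[set[str], list[FilterVerdict]]:
    """Run both substructure screens; return surviving keys and all verdicts."""
    if interference is None:
        interference = default_interference_catalog()
    if chemistry is None:
        chemistry = default_chemistry_catalog()
    verdicts: list[FilterVerdict] = []
    clean: set[str] = set()
    for key in sorted(set(compound_keys)):
        v1 = screen_substructures(key, interference, stage="interference")
        v2 = screen_substructures(key, chemistry, stage="chemistry_rules")
        verdicts.extend([v1, v2])
        if v1.passed and v2.passed:
            clean.add(key)
    return clean, verdicts


def screen_antitargets(
    interactions: Iterable[CuratedInteraction],
    targets: Mapping[str, TargetEntry],
    ppot_min: Optional[float] = None,
) -> tuple[set[str], dict[str, list[str]]]:
    """Remove compounds with retained activity against anti-targets.

    A compound with at least one retained interaction against a target
    flagged ``is_antitarget`` is removed entirely, regardless of potency by
    default; pass ``ppot_min`` to restrict the trigger to interactions at or
    above that pPot.

    Returns ``(clean_compound_keys, removed)`` where ``removed`` maps each
    removed compound to the triggering anti-target IDs.
    """
    removed: dict[str, list[str]] = {}
    seen: set[str] = set()
    for inter in interactions:
        seen.add(inter.compound_key)
        entry = targets.get(inter.target_id)
        if entry is None or not entry.is_antitarget:
            continue
        if ppot_min is not None and inter.ppot_final < ppot_min:
            continue
        removed.setdefault(inter.compound_key, []).append(inter.target_id)
    for key in removed:
        removed[key] = sorted(set(removed[key]))
    return seen - set(removed), removed
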