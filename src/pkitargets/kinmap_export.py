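"""Kinome-tree annotation export.

For every kinase in the analysis set, emit the number of distinct
non-kinase targets reached through shared inhibitors.  The output is the
two-attribute annotation CSV consumed by external kinome-tree viewers
(kinase name plus a numeric value driving both node size and color ramp).
The UniProt-to-tree-name mapping is an editable fixture because tree
naming schemes drift between viewer versions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .records import PromiscuityProfile, TargetEntry


@dataclass(frozen=True)
class KinomeAnnotation:
    kinase_name: str
    group: Optional[str]
    size_value: int  # number of non-PK targets of shared inhibitors
    color_value: int  # same value, feeding the color ramp


def load_name_map(path=None) -> dict[str, str]:
    """Read a ``uniprot<TAB>kinase_name`` mapping (default: shipped fixture)."""
    if path is None:
        text = (resources.files("pkitargets.data") / "kinmap_name_map.tsv").read_text()
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    out = {}
    for ln in lines[1:]:  # header row skipped
        uniprot, name = ln.split("\t")[:2]
        out[uniprot.strip()] = name.strip()
    return out


def annotate_kinome(
    profiles: Sequence[PromiscuityProfile],
    targets: Mapping[str, TargetEntry],
    name_map: Mapping[str, str],
) -> tuple[list[KinomeAnnotation], list[str]]:
    """Per analysis-set kinase, count non-PK targets of its shared inhibitors.

    ``size_value`` for a kinase equals the size of the union of non-PK
    target sets over all analysis-set compounds active against it (the same
    counterpart count the shared-inhibitor ranking reports).  Kinases whose
    UniProt accession is missing from ``name_map`` are reported in the
    second return value, not dropped silently and not fatal.
    """
    nonpk_union: dict[str, set[str]] = {}
    for p in profiles:
        for t in p.pk_targets:
            nonpk_union.setdefault(t, set()).update(p.nonpk_targets)

    annotations: list[KinomeAnnotation] = []
    unmapped: list[str] = []
    for tid in sorted(nonpk_union):
        entry = targets[tid]
        name = name_map.get(entry.uniprot)
        if name is None:
            unmapped.append(tid)
            continue
        n = len(nonpk_union[tid])
        annotations.append(
            KinomeAnnotation(
                kinase_name=name,
                group=entry.kinase_group,
                size_value=n,
                color_value=n,
            )
        )
    annotations.sort(key=lambda a: a.kinase_name)
    return annotations, unmapped


#: Column layout of the annotation CSV; template-driven so a viewer schema
#: change is a config edit, not a code change.
DEFAULT_TEMPLATE = ("xName", "size", "color")


def write_kinmap_annotation(
    annotations: Sequence[KinomeAnnotation],
    path,
    unmapped: Sequence[str] = (),
    template: Sequence[str] = DEFAULT_TEMPLATE,
) -> None:
    """Write the viewer annotation CSV (plus a sidecar of unmapped IDs)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(template)
        for a in annotations:
            writer.writerow([a.kinase_name, a.size_value, a.color_value])
    if unmapped:
        sidecar = path.with_suffix(path.suffix + ".unmapped.txt")
        sidecar.write_text("\n".join(unmapped) + "\n", encoding="utf-8")
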