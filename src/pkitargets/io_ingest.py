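"""Reading and writing the pipeline's tabular formats.

Two activity-table dialects are supported: ChEMBL-style flat exports (which
carry target type, assay relationship and confidence columns) and
BindingDB-style exports (which do not).  Both are parsed into the unified
:class:`~pkitargets.records.ActivityRecord` model; fields a dialect lacks
stay ``None``.  Rows that cannot be parsed are returned in a rejection list
with machine-readable reasons, never silently dropped.

All outputs are UTF-8 tab-separated tables with a header and deterministic
column and row order.
"""

from __future__ import annotations

import math
from dataclasses import asdict, fields, is_dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .records import ENDPOINTS, ActivityRecord, TargetEntry

# Default column names per dialect, patterned on the flat exports of the
# respective databases.  A user-supplied column_map (ours -> theirs) remaps
# any of them.
CHEMBL_COLUMNS = {
    "compound_ref": "molecule_chembl_id",
    "smiles_raw": "canonical_smiles",
    "target_ref": "target_chembl_id",
    "uniprot": "accession",
    "organism": "organism",
    "target_type": "target_type",
    "assay_relationship": "relationship_type",
    "confidence_score": "confidence_score",
    "measurement_type": "standard_type",
    "relation": "standard_relation",
    "value": "standard_value",
    "units": "standard_units",
    "activity_comment": "activity_comment",
}

BINDINGDB_COLUMNS = {
    "compound_ref": "monomer_id",
    "smiles_raw": "ligand_smiles",
    "target_ref": "target_chain_id",
    "uniprot": "uniprot_id",
    "organism": "organism",
    "measurement_type": "measurement_type",
    "relation": "relation",
    "value": "value_nm",
    "units": "units",
}

# Fields a row must provide to yield a record at all.
_MANDATORY = {
    "chembl": (
        "compound_ref",
        "smiles_raw",
        "target_ref",
        "organism",
        "measurement_type",
        "relation",
        "value",
        "units",
    ),
    "bindingdb": (
        "compound_ref",
        "smiles_raw",
        "target_ref",
        "organism",
        "measurement_type",
        "relation",
        "value",
        "units",
    ),
}

# Endpoint spelling normalization; anything else is "unsupported_endpoint".
_ENDPOINT_ALIASES = {e.lower(): e for e in ENDPOINTS}


class IngestError(Exception):
    """Fatal ingest failure (unreadable file, duplicate target ID, ...)."""


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _cell(row: Mapping, column: Optional[str]) -> Optional[str]:
    if column is None or column not in row:
        return None
    v = row[column]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip()
    return s or None


def read_activity_table(
    path: str | Path,
    dialect: str,
    column_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[ActivityRecord], list[tuple[int, str]]]:
    """Parse an activity table into records plus per-row rejections.

    Parameters
    ----------
    path
        Delimited text file; tab vs comma is auto-detected from the header.
    dialect
        ``"chembl"`` or ``"bindingdb"``.
    column_map
        Optional remapping ``{canonical_field: actual_column_name}`` applied
        on top of the dialect defaults.

    Returns
    -------
    (records, rejected)
        ``rejected`` holds ``(row_index, reason)`` pairs; row indices are
        0-based over the data rows.  Rows in = records out + rejections out.
    """
    if dialect not in ("chembl", "bindingdb"):
        raise IngestError(f"unknown dialect: {dialect!r}")
    path = Path(path)
    if not path.is_file():
        raise IngestError(f"cannot read activity table: {path}")
    colmap = dict(CHEMBL_COLUMNS if dialect == "chembl" else BINDINGDB_COLUMNS)
    if column_map:
        colmap.update(column_map)

    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    df = df.replace("", None)

    missing = [
        colmap[f] for f in _MANDATORY[dialect] if colmap[f] not in df.columns
    ]
    if missing:
        raise IngestError(
            f"{dialect} table {path} lacks mandatory column(s): {', '.join(missing)}"
        )

    records: list[ActivityRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records")):
        rec_or_reason = _parse_row(row, dialect, colmap)
        if isinstance(rec_or_reason, str):
            rejected.append((i, rec_or_reason))
        else:
            records.append(rec_or_reason)
    return records, rejected


def _parse_row(row: Mapping, dialect: str, colmap: Mapping[str, str]):
    for f in _MANDATORY[dialect]:
        if _cell(row, colmap.get(f)) is None:
            return f"missing_field:{f}"

    mtype = _cell(row, colmap["measurement_type"])
    canonical = _ENDPOINT_ALIASES.get(mtype.lower())
    if canonical is None:
        return "unsupported_endpoint"

    raw_value = _cell(row, colmap["value"])
    try:
        value = float(raw_value)
    except ValueError:
        return "bad_value"
    if not math.isfinite(value) or value <= 0:
        return "bad_value"

    confidence: Optional[int] = None
    conf_cell = _cell(row, colmap.get("confidence_score"))
    if conf_cell is not None:
        try:
            confidence = int(float(conf_cell))
        except ValueError:
            return "bad_confidence_score"

    return ActivityRecord(
        source=dialect,
        compound_ref=_cell(row, colmap["compound_ref"]),
        smiles_raw=_cell(row, colmap["smiles_raw"]),
        target_ref=_cell(row, colmap["target_ref"]),
        uniprot=_cell(row, colmap.get("uniprot")),
        organism=_cell(row, colmap["organism"]),
        target_type=_cell(row, colmap.get("target_type")),
        assay_relationship=_cell(row, colmap.get("assay_relationship")),
        confidence_score=confidence,
        measurement_type=canonical,
        relation=_cell(row, colmap["relation"]),
        value=value,
        units=_cell(row, colmap["units"]),
        activity_comment=_cell(row, colmap.get("activity_comment")),
    )


TARGET_TABLE_COLUMNS = (
    "target_id",
    "uniprot",
    "name",
    "is_pk",
    "kinase_group",
    "class_l1",
    "class_l2",
    "is_antitarget",
)


def _parse_bool(s: Optional[str]) -> bool:
    return str(s).strip().lower() in ("true", "1", "yes")


def read_target_table(
    path: str | Path,
) -> tuple[dict[str, TargetEntry], list[tuple[int, str]]]:
    """Read the target-metadata table into ``{target_id: TargetEntry}``.

    A duplicated target_id is fatal (the error names the ID).  Rows claiming
    a protein kinase without a kinase group, or flagging a kinase as an
    anti-target, are rejected with a reason rather than ingested.
    """
    path = Path(path)
    if not path.is_file():
        raise IngestError(f"cannot read target table: {path}")
    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    df = df.replace("", None)
    for col in ("target_id", "uniprot", "name", "is_pk"):
        if col not in df.columns:
            raise IngestError(f"target table {path} lacks column {col}")

    targets: dict[str, TargetEntry] = {}
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records")):
        tid = _cell(row, "target_id")
        if tid is None:
            rejected.append((i, "missing_field:target_id"))
            continue
        if tid in targets:
            raise IngestError(f"duplicate target_id in target table: {tid}")
        is_pk = _parse_bool(row.get("is_pk"))
        is_anti = _parse_bool(row.get("is_antitarget"))
        group = _cell(row, "kinase_group")
        if is_pk and group is None:
            rejected.append((i, "pk_missing_kinase_group"))
            continue
        if is_pk and is_anti:
            rejected.append((i, "pk_marked_antitarget"))
            continue
        targets[tid] = TargetEntry(
            target_id=tid,
            uniprot=_cell(row, "uniprot") or "",
            name=_cell(row, "name") or "",
            is_pk=is_pk,
            kinase_group=group if is_pk else None,
            class_l1=_cell(row, "class_l1"),
            class_l2=_cell(row, "class_l2"),
            is_antitarget=is_anti,
        )
    return targets, rejected


def write_table(
    records,
    path: str | Path,
    columns: Optional[Sequence[str]] = None,
    sort_by: Optional[Sequence[str]] = None,
) -> None:
    """Write any tabular pipeline artifact as a deterministic TSV.

    Accepts a DataFrame, a sequence of dataclasses, or a sequence of dicts.
    Rows are sorted by ``sort_by`` (default: the first column), columns keep
    the declared order; output is UTF-8 with a header.
    """
    if records is None:
        raise ValueError("records must not be None")
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = list(records)
        if rows and is_dataclass(rows[0]):
            if columns is None:
                columns = [f.name for f in fields(rows[0])]
            df = pd.DataFrame([asdict(r) for r in rows])
        else:
            df = pd.DataFrame(rows)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    if len(df):
        keys = list(sort_by) if sort_by else [df.columns[0]]
        df = df.sort_values(keys, kind="mergesort")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def activity_records_to_table(
    records: Iterable[ActivityRecord], dialect: str
) -> pd.DataFrame:
    """Serialize records back into a dialect-shaped DataFrame (round-trip aid)."""
    colmap = CHEMBL_COLUMNS if dialect == "chembl" else BINDINGDB_COLUMNS
    out = []
    for r in records:
        row = {}
        for field_name, col in colmap.items():
            v = getattr(r, field_name)
            if field_name == "value":
                v = format(v, ".10g")
            row[col] = "" if v is None else v
        out.append(row)
    return pd.DataFrame(out, columns=list(colmap.values()))


def target_entries_to_table(targets: Mapping[str, TargetEntry]) -> pd.DataFrame:
    rows = []
    for tid in sorted(targets):
        t = targets[tid]
        rows.append(
            {
                "target_id": t.target_id,
                "uniprot": t.uniprot,
                "name": t.name,
                "is_pk": str(t.is_pk).lower(),
                "kinase_group": t.kinase_group or "",
                "class_l1": t.class_l1 or "",
                "class_l2": t.class_l2 or "",
                "is_antitarget": str(t.is_antitarget).lower(),
            }
        )
    return pd.DataFrame(rows, columns=list(TARGET_TABLE_COLUMNS))
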