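"""End-to-end pipeline: ingest -> curate -> quality screens -> analysis.

``run_pipeline`` ties all stages together, writes every artifact as a
deterministic TSV (plus GraphML/SIF network exports and the kinome
annotation CSV) into a run directory, and records the effective
configuration, toolkit versions, and per-stage counts in a plain-text run
log.  Two runs on identical inputs and configuration produce byte-identical
tabular outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import classify_network, curate, io_ingest, kinmap_export, promiscuity
from .quality_filters import (
    SubstructureCatalog,
    default_chemistry_catalog,
    default_interference_catalog,
    screen_antitargets,
    screen_compound_set,
)
from .standardize import TOOLKIT, TOOLKIT_VERSION, load_salt_set


class PipelineError(RuntimeError):
    """Fatal pipeline failure; carries the name of the failing stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Effective settings of one pipeline run; defaults are the study's."""

    chembl_path: Optional[str] = None
    bindingdb_path: Optional[str] = None
    target_path: Optional[str] = None
    out_dir: str = "run"
    ppot_min: float = 5.0
    consistency_rule: Optional[str] = None  # None = span for PKs, sd otherwise
    span_cutoff: float = 1.0
    sd_cutoff: float = 1.0
    contradiction_vocabulary: tuple[str, ...] = (
        "inactive",
        "inconclusive",
        "not active",
    )
    interference_catalog: Optional[str] = None  # path; None = shipped subset
    chemistry_catalog: Optional[str] = None
    salt_list: Optional[str] = None
    antitarget_ppot_min: Optional[float] = None  # None = any reported activity
    min_shared: int = 2
    scan_thresholds: tuple[float, ...] = (5.0, 6.0, 7.0, 8.0)
    bins: tuple[tuple[int, Optional[int]], ...] = promiscuity.DEFAULT_BINS
    top_k: int = 10
    name_map: Optional[str] = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls(**raw)
        cfg.bins = tuple(tuple(b) for b in cfg.bins)
        cfg.scan_thresholds = tuple(cfg.scan_thresholds)
        cfg.contradiction_vocabulary = tuple(cfg.contradiction_vocabulary)
        return cfg


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the populated run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"toolkit: {TOOLKIT} {TOOLKIT_VERSION}",
        "config:",
    ]
    log += [f"  {k}: {v}" for k, v in sorted(asdict(config).items())]

    # --- ingest ----------------------------------------------------------
    stage = "io_ingest"
    try:
        records = []
        rejected_rows = []
        for path, dialect in (
            (config.chembl_path, "chembl"),
            (config.bindingdb_path, "bindingdb"),
        ):
            if path is None:
                continue
            recs, rej = io_ingest.read_activity_table(path, dialect)
            records.extend(recs)
            rejected_rows.extend((dialect, i, r) for i, r in rej)
        if config.target_path is None:
            raise io_ingest.IngestError("no target table configured")
        targets, target_rejects = io_ingest.read_target_table(config.target_path)
    except io_ingest.IngestError as exc:
        raise PipelineError(stage, str(exc)) from exc
    log.append(f"ingest: {len(records)} records, {len(rejected_rows)} rejected rows")
    io_ingest.write_table(
        pd.DataFrame(rejected_rows, columns=["dialect", "row", "reason"]),
        out / "ingest_rejections.tsv",
    )

    # --- curate ----------------------------------------------------------
    stage = "curate"
    salt_set = load_salt_set(config.salt_list) if config.salt_list else None
    ruleset = curate.CurationRuleset(
        contradiction_vocabulary=frozenset(config.contradiction_vocabulary),
        span_cutoff=config.span_cutoff,
        sd_cutoff=config.sd_cutoff,
        ppot_min=config.ppot_min,
        consistency_rule=config.consistency_rule,
    )
    interactions, ledger = curate.curate_interactions(
        records, targets, ruleset, salt_set
    )
    log.append(
        "curate: "
        f"{len(interactions)} retained interactions; "
        f"{len(ledger.filtered)} filtered records, "
        f"{len(ledger.unresolved)} unresolved, "
        f"{len(ledger.contradicted_pairs)} contradicted pairs, "
        f"{len(ledger.inconsistent_groups)} inconsistent groups, "
        f"{len(ledger.below_threshold)} below threshold"
    )
    _write_discards(ledger, out / "discard_ledger.tsv")

    # --- quality filters --------------------------------------------------
    stage = "quality_filters"
    interference = (
        SubstructureCatalog.from_file(config.interference_catalog)
        if config.interference_catalog
        else default_interference_catalog()
    )
    chemistry = (
        SubstructureCatalog.from_file(config.chemistry_catalog)
        if config.chemistry_catalog
        else default_chemistry_catalog()
    )
    keys = {i.compound_key for i in interactions}
    clean_struct, verdicts = screen_compound_set(keys, interference, chemistry)
    clean_anti, removed_anti = screen_antitargets(
        interactions, targets, config.antitarget_ppot_min
    )
    clean = clean_struct & clean_anti
    interactions = [i for i in interactions if i.compound_key in clean]
    log.append(
        f"quality_filters: {len(keys) - len(clean_struct)} flagged by "
        f"substructure screens, {len(removed_anti)} anti-target actives, "
        f"{len(clean)} compounds retained"
    )
    io_ingest.write_table(
        verdicts, out / "filter_verdicts.tsv",
        sort_by=["compound_key", "stage"],
    )
    io_ingest.write_table(
        pd.DataFrame(
            [(k, ";".join(v)) for k, v in sorted(removed_anti.items())],
            columns=["compound_key", "antitargets"],
        ),
        out / "antitarget_removals.tsv",
    )
    io_ingest.write_table(
        interactions, out / "curated_interactions.tsv",
        sort_by=["compound_key", "target_id"],
    )

    # --- promiscuity analysis --------------------------------------------
    stage = "promiscuity"
    try:
        profiles = promiscuity.build_profiles(interactions, targets)
    except promiscuity.AnalysisError as exc:
        raise PipelineError(stage, str(exc)) from exc
    log.append(f"promiscuity: {len(profiles)} compounds in the analysis set")
    io_ingest.write_table(
        promiscuity.profiles_to_table(profiles), out / "profiles.tsv"
    )
    for which in ("pk", "nonpk"):
        dist = promiscuity.bin_distribution(profiles, which, config.bins)
        io_ingest.write_table(
            pd.DataFrame(
                [
                    {
                        "bin_lo": lo,
                        "bin": f"{lo}" if hi == lo else f"{lo}-{hi or 'inf'}",
                        "count": c,
                        "percentage": p,
                    }
                    for (lo, hi), (c, p) in dist.items()
                ]
            ),
            out / f"distribution_{which}.tsv",
            sort_by=["bin_lo"],
        )
        io_ingest.write_table(
            promiscuity.rank_targets_by_shared_inhibitors(
                profiles, which, config.top_k
            ),
            out / f"top_targets_{which}.tsv",
            sort_by=["target_id"],
        )
    top_compounds = promiscuity.rank_compounds_by_nonpk_targets(
        profiles, config.top_k
    )
    io_ingest.write_table(
        pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "compound_key": p.compound_key,
                    "nonpk_pd": p.nonpk_pd,
                    "pk_pd": p.pk_pd,
                }
                for i, p in enumerate(top_compounds)
            ],
            columns=["rank", "compound_key", "nonpk_pd", "pk_pd"],
        ),
        out / "top_compounds_nonpk.tsv",
        sort_by=["rank"],
    )
    scan = promiscuity.potency_scan(interactions, targets, config.scan_thresholds)
    io_ingest.write_table(scan, out / "potency_scan.tsv")
    n_inverted, inverted = promiscuity.count_inverted_primary(interactions, targets)
    log.append(f"promiscuity: {n_inverted} inverted-primary compounds")
    io_ingest.write_table(
        pd.DataFrame({"compound_key": inverted}), out / "inverted_primary.tsv"
    )

    # --- classification and network --------------------------------------
    stage = "classify_network"
    nonpk_in_analysis = sorted(set().union(*(p.nonpk_targets for p in profiles)) if profiles else set())
    try:
        dist1 = classify_network.class_distribution(nonpk_in_analysis, targets, 1)
    except classify_network.NetworkError as exc:
        raise PipelineError(stage, str(exc)) from exc
    io_ingest.write_table(
        pd.DataFrame(
            [{"class": c, "count": n, "percentage": p} for c, (n, p) in dist1.items()]
        ),
        out / "class_distribution_l1.tsv",
    )
    net = classify_network.build_network(profiles, config.min_shared)
    n_pk, n_nonpk, n_edges, top_table = classify_network.network_summary(net)
    log.append(
        f"network: {n_pk} PK nodes, {n_nonpk} non-PK nodes, {n_edges} edges"
    )
    io_ingest.write_table(top_table, out / "network_top_degree.tsv")
    for fmt, name in (
        ("graphml", "network.graphml"),
        ("sif", "network.sif"),
        ("edgelist", "network.edgelist"),
    ):
        classify_network.export_network(net, fmt, out / name)

    # --- kinome annotation ------------------------------------------------
    stage = "kinmap_export"
    name_map = kinmap_export.load_name_map(config.name_map)
    # synthetic catalogs name kinases by accession; fall back to identity
    # for accessions absent from the fixture so the export stays complete
    for t in targets.values():
        if t.is_pk:
            name_map.setdefault(t.uniprot, t.uniprot)
    annotations, unmapped = kinmap_export.annotate_kinome(profiles, targets, name_map)
    kinmap_export.write_kinmap_annotation(
        annotations, out / "kinome_annotation.csv", unmapped
    )
    log.append(
        f"kinmap: {len(annotations)} kinases annotated, {len(unmapped)} unmapped"
    )

    (out / "run_log.txt").write_text("\n".join(log) + "\n", encoding="utf-8")
    return out


def _write_discards(ledger: curate.CurationLedger, path) -> None:
    rows = []
    for rec, reason in ledger.filtered:
        rows.append(("high_confidence", rec.source, rec.compound_ref, rec.target_ref, reason))
    for rec, reason in ledger.unresolved:
        rows.append(("resolve", rec.source, rec.compound_ref, rec.target_ref, reason))
    for ck, tid in ledger.contradicted_pairs:
        rows.append(("contradiction", "", ck, tid, "contradicted_pair"))
    for ck, tid, endpoint, reason in ledger.inconsistent_groups:
        rows.append(("consistency", endpoint, ck, tid, reason))
    for inter in ledger.below_threshold:
        rows.append(("threshold", "", inter.compound_key, inter.target_id, "below_ppot_min"))
    io_ingest.write_table(
        pd.DataFrame(
            rows, columns=["stage", "context", "compound", "target", "reason"]
        ),
        path,
        sort_by=["stage", "compound", "target"],
    )
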