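"""Synthetic bioactivity tables with planted ground truth.

The generator emulates the raw inputs of the curation pipeline: ChEMBL-style
and BindingDB-style activity tables plus a target catalog, with a manifest
that fully determines the expected output of every pipeline stage under the
default configuration.  Planted features:

* compounds appearing as salt and stereo variants of a parent structure;
* replicate measurements of the same endpoint with Gaussian noise on the
  pPot scale (log-normal assay error), truncated so planted-consistent
  groups obey the span/SD consistency rules;
* contradictory "inactive" comments that void a compound-target pair;
* rows violating the high-confidence rules (relation ">", wrong organism);
* interference decoys embedding a quinone motif from the shipped catalog;
* actives against anti-targets; and
* per-compound true pPot values against kinase and non-kinase targets,
  drawn uniformly from a configurable range so the potency scan has signal.

Structures are assembled from a fixture set of parseable scaffolds with
enumerated substituents; no chemical realism beyond validity is attempted.
"""

from __future__ import annotations

import json
import math
import statistics
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_ingest import BINDINGDB_COLUMNS, CHEMBL_COLUMNS
from .records import CLASS_L1, KINASE_GROUPS
from .standardize import standardize_structure

# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class GeneratorParams:
    """Stated world of the synthetic benchmark.

    The promiscuity-degree bin weights default to the published shape of
    the analysis set (single-target compounds dominant, a long tail of
    highly promiscuous ones); noise defaults to SD 0.2 log units, clipped
    at +/-0.45 so replicate groups stay within one order of magnitude.
    """

    n_compounds: int = 200
    n_pk_targets: int = 40
    n_nonpk_targets: int = 20
    n_antitargets: int = 3
    pk_pd_distribution: tuple[float, ...] = (0.573, 0.221, 0.036, 0.170)
    nonpk_pd_distribution: tuple[float, ...] = (0.783, 0.192, 0.018, 0.007)
    replicate_noise_sd: float = 0.2
    consistent_halfspan: Optional[float] = 0.45  # None = unclipped noise
    fraction_contradicted: float = 0.05
    fraction_interference: float = 0.05
    fraction_antitarget: float = 0.05
    fraction_variants: float = 0.2
    fraction_relation_violation: float = 0.05
    fraction_wrong_organism: float = 0.05
    fraction_inconsistent: float = 0.0
    dialect_overlap: float = 0.3
    ppot_range: tuple[float, float] = (5.2, 9.5)
    ppot_min: float = 5.0
    seed: int = 0
    scenario: Optional[str] = None  # internal: perturbation scenarios


# ---------------------------------------------------------------------------
# manifest

@dataclass
class PlantedInteraction:
    target_id: str
    is_pk: bool
    is_antitarget: bool
    true_ppot: float
    # endpoint -> pPot values the pipeline will pool (dialect copies included)
    pooled_values: dict[str, list[float]] = field(default_factory=dict)
    contradicted: bool = False
    inconsistent: bool = False
    expected_final: Optional[float] = None
    expected_basis: Optional[str] = None
    expected_retained: bool = False
    discarded_endpoints: list[str] = field(default_factory=list)


@dataclass
class CompoundTruth:
    compound_id: str
    parent_smiles: str
    compound_key: str
    variants: list[tuple[str, str, str]] = field(default_factory=list)  # (ref, smiles, kind)
    interference: bool = False
    antitarget_active: bool = False
    interactions: list[PlantedInteraction] = field(default_factory=list)
    expected_pk_targets: list[str] = field(default_factory=list)
    expected_nonpk_targets: list[str] = field(default_factory=list)
    expected_in_analysis_set: bool = False


@dataclass
class GroundTruthManifest:
    seed: int
    params: GeneratorParams
    compounds: list[CompoundTruth]
    planted_violations: list[tuple[str, str, str]]  # (kind, compound_id, target_id)
    contradicted_pairs: list[tuple[str, str]]  # (compound_key, target_id)

    def expected_profiles(self) -> dict[str, tuple[set[str], set[str]]]:
        """compound_key -> (pk target set, non-pk target set) for the
        compounds expected to survive into the analysis set."""
        return {
            c.compound_key: (
                set(c.expected_pk_targets),
                set(c.expected_nonpk_targets),
            )
            for c in self.compounds
            if c.expected_in_analysis_set
        }

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "params": asdict(self.params),
            "compounds": [asdict(c) for c in self.compounds],
            "planted_violations": self.planted_violations,
            "contradicted_pairs": self.contradicted_pairs,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        params = GeneratorParams(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in payload["params"].items()
            }
        )
        compounds = []
        for c in payload["compounds"]:
            inters = [PlantedInteraction(**i) for i in c.pop("interactions")]
            variants = [tuple(v) for v in c.pop("variants")]
            compounds.append(
                CompoundTruth(**c, interactions=inters, variants=variants)
            )
        return cls(
            seed=payload["seed"],
            params=params,
            compounds=compounds,
            planted_violations=[tuple(v) for v in payload["planted_violations"]],
            contradicted_pairs=[tuple(v) for v in payload["contradicted_pairs"]],
        )


# ---------------------------------------------------------------------------
# structure fixtures

_SCAFFOLD_PREFIXES = (
    "c1ccc(cc1)",
    "c1ccc(nc1)",
    "C1CCN(CC1)",
    "c1csc(c1)",
    "C1CCC(CC1)",
)
_CHAIN_UNITS = ("C", "CC", "CO", "CN", "CCO", "CCN", "C(C)")
_TAIL = "CC(C)O"
_STEREO_TAIL = "C[C@@H](C)O"
_QUINONE_CORE = "O=C1C=CC(=O)C({chain})=C1"


def _chain_for_index(idx: int) -> str:
    units = []
    n = idx
    while True:
        units.append(_CHAIN_UNITS[n % len(_CHAIN_UNITS)])
        n //= len(_CHAIN_UNITS)
        if n == 0:
            break
    return "".join(units)


def _parent_smiles(idx: int, decoy: bool, taken: set[str]) -> tuple[str, str]:
    """Deterministic unique (parent_smiles, compound_key) for compound idx."""
    chain = _chain_for_index(idx)
    suffix = ""
    while True:
        if decoy:
            smi = _QUINONE_CORE.format(chain=chain + suffix + _TAIL)
        else:
            prefix = _SCAFFOLD_PREFIXES[idx % len(_SCAFFOLD_PREFIXES)]
            smi = prefix + chain + suffix + _TAIL
        key = standardize_structure(smi)
        if key not in taken:
            taken.add(key)
            return smi, key
        suffix += "C"


# ---------------------------------------------------------------------------
# target catalog

_NONPK_CLASS_CYCLE = (
    ("enzyme", "reductase"),
    ("enzyme", "hydrolase"),
    ("enzyme", "protease"),
    ("enzyme", "transferase"),
    ("membrane receptor", "7tm1"),
    ("membrane receptor", "7tm1"),
    ("unclassified", None),
    ("epigenetic regulator", None),
    ("ion channel", None),
    ("transcription factor", None),
    ("transporter", None),
    ("secreted protein", None),
    ("cytosolic other protein", None),
    ("other", None),
)

_ANTITARGETS = (
    ("AT001", "ATP001", "hERG channel", "ion channel"),
    ("AT002", "ATP002", "Cytochrome P450 3A4", "enzyme"),
    ("AT003", "ATP003", "Serum albumin", "secreted protein"),
)


def _make_target_table(params: GeneratorParams) -> pd.DataFrame:
    rows = []
    for i in range(params.n_pk_targets):
        rows.append(
            {
                "target_id": f"PK{i + 1:03d}",
                "uniprot": f"KIN{i + 1:03d}",
                "name": f"Synthetic kinase {i + 1}",
                "is_pk": "true",
                "kinase_group": KINASE_GROUPS[i % len(KINASE_GROUPS)],
                "class_l1": "enzyme",
                "class_l2": "kinase",
                "is_antitarget": "false",
            }
        )
    for i in range(params.n_nonpk_targets):
        l1, l2 = _NONPK_CLASS_CYCLE[i % len(_NONPK_CLASS_CYCLE)]
        rows.append(
            {
                "target_id": f"NPK{i + 1:03d}",
                "uniprot": f"NPT{i + 1:03d}",
                "name": f"Synthetic non-kinase target {i + 1}",
                "is_pk": "false",
                "kinase_group": "",
                "class_l1": l1,
                "class_l2": l2 or "",
                "is_antitarget": "false",
            }
        )
    for tid, acc, name, l1 in _ANTITARGETS[: params.n_antitargets]:
        rows.append(
            {
                "target_id": tid,
                "uniprot": acc,
                "name": name,
                "is_pk": "false",
                "kinase_group": "",
                "class_l1": l1,
                "class_l2": "",
                "is_antitarget": "true",
            }
        )
    assert CLASS_L1  # classes above are drawn from the canonical ten
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generation

_BIN_RANGES = ((1, 1), (2, 4), (5, 9), (10, 15))
_ENDPOINT_CYCLE = ("Ki", "IC50", "Kd")


def _draw_degree(rng, weights, n_available: int) -> int:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    b = int(rng.choice(len(_BIN_RANGES), p=w))
    lo, hi = _BIN_RANGES[b]
    hi = min(hi, n_available)
    lo = min(lo, hi)
    return int(rng.integers(lo, hi + 1))


def _fmt(value_nm: float) -> str:
    return format(value_nm, ".10g")


def _emitted_ppot(ppot: float) -> float:
    """pPot after the nM round trip through the serialized table."""
    return 9.0 - math.log10(float(_fmt(10.0 ** (9.0 - ppot))))


def generate_catalog(**overrides) -> tuple[
    pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruthManifest
]:
    """Generate (chembl_table, bindingdb_table, target_table, manifest).

    Keyword arguments override :class:`GeneratorParams` fields.  The same
    seed reproduces byte-identical tables.
    """
    params = GeneratorParams(**overrides)
    combined = (
        params.fraction_contradicted
        + params.fraction_interference
        + params.fraction_antitarget
    )
    if combined > 1.0:
        raise ValueError(
            f"planted fractions sum to {combined:.2f} > 1; infeasible"
        )
    for w in (params.pk_pd_distribution, params.nonpk_pd_distribution):
        if len(w) != 4 or min(w) < 0 or sum(w) <= 0:
            raise ValueError(f"bad degree distribution: {w}")
    if min(params.n_compounds, params.n_pk_targets, params.n_nonpk_targets) < 1:
        raise ValueError("n_compounds and target counts must be >= 1")

    rng_struct = np.random.default_rng([params.seed, 1])
    rng_noise = np.random.default_rng([params.seed, 2])
    rng_emit = np.random.default_rng([params.seed, 3])

    n = params.n_compounds
    order = rng_struct.permutation(n)
    n_contra = round(params.fraction_contradicted * n)
    n_interf = round(params.fraction_interference * n)
    n_anti = round(params.fraction_antitarget * n)
    contra_ids = set(order[:n_contra])
    interf_ids = set(order[n_contra : n_contra + n_interf])
    anti_ids = set(order[n_contra + n_interf : n_contra + n_interf + n_anti])
    variant_ids = {
        i for i in range(n) if rng_struct.random() < params.fraction_variants
    }
    inconsistent_ids = {
        i for i in range(n) if rng_struct.random() < params.fraction_inconsistent
    }

    pk_ids = [f"PK{i + 1:03d}" for i in range(params.n_pk_targets)]
    nonpk_ids = [f"NPK{i + 1:03d}" for i in range(params.n_nonpk_targets)]
    uniprot_of = {t: f"KIN{t[2:]}" for t in pk_ids}
    uniprot_of.update({t: f"NPT{t[3:]}" for t in nonpk_ids})
    for tid, acc, _, _ in _ANTITARGETS[: params.n_antitargets]:
        uniprot_of[tid] = acc

    taken_keys: set[str] = set()
    chembl_rows: list[dict] = []
    bdb_rows: list[dict] = []
    compounds: list[CompoundTruth] = []
    violations: list[tuple[str, str, str]] = []
    contradicted_pairs: list[tuple[str, str]] = []

    lo_p, hi_p = params.ppot_range
    edge_cycle = (4.99, 5.00, 5.01)
    edge_counter = 0

    for idx in range(n):
        cid = f"C{idx + 1:04d}"
        decoy = idx in interf_ids
        parent, key = _parent_smiles(idx, decoy, taken_keys)
        truth = CompoundTruth(
            compound_id=cid,
            parent_smiles=parent,
            compound_key=key,
            interference=decoy,
            antitarget_active=idx in anti_ids,
        )

        # variant forms sharing the parent's key
        refs = [cid]
        if idx in variant_ids:
            kind = "salt" if rng_struct.random() < 0.5 else "stereo"
            if kind == "stereo" and not parent.endswith(_TAIL):
                kind = "salt"  # quinone decoys embed the tail mid-string
            if kind == "salt":
                vsmi = parent + ".Cl"
            else:
                vsmi = parent[: -len(_TAIL)] + _STEREO_TAIL
            vref = f"{cid}_V1"
            truth.variants.append((vref, vsmi, kind))
            refs.append(vref)

        pk_deg = _draw_degree(rng_struct, params.pk_pd_distribution, len(pk_ids))
        nonpk_deg = _draw_degree(
            rng_struct, params.nonpk_pd_distribution, len(nonpk_ids)
        )
        picked_pk = [pk_ids[j] for j in sorted(
            rng_struct.choice(len(pk_ids), size=pk_deg, replace=False))]
        picked_nonpk = [nonpk_ids[j] for j in sorted(
            rng_struct.choice(len(nonpk_ids), size=nonpk_deg, replace=False))]

        planted = [(t, True, False) for t in picked_pk]
        planted += [(t, False, False) for t in picked_nonpk]
        if truth.antitarget_active:
            anti = _ANTITARGETS[idx % params.n_antitargets][0]
            planted.append((anti, False, True))

        contradict_target = None
        if idx in contra_ids:
            # void one non-kinase pair via an "inactive" comment
            contradict_target = picked_nonpk[
                int(rng_struct.integers(len(picked_nonpk)))
            ]

        for tid, is_pk, is_anti in planted:
            if params.scenario == "threshold_edge" and not is_anti:
                true_ppot = edge_cycle[edge_counter % len(edge_cycle)]
                edge_counter += 1
            elif is_anti:
                true_ppot = 6.5
            else:
                true_ppot = float(rng_struct.uniform(lo_p, hi_p))
            inter = PlantedInteraction(
                target_id=tid,
                is_pk=is_pk,
                is_antitarget=is_anti,
                true_ppot=true_ppot,
                contradicted=(tid == contradict_target),
                inconsistent=(idx in inconsistent_ids and not is_anti),
            )

            if params.scenario == "threshold_edge":
                endpoints = {_ENDPOINT_CYCLE[0]: 1}
            else:
                e0 = _ENDPOINT_CYCLE[int(rng_emit.integers(3))]
                endpoints = {e0: int(rng_emit.integers(1, 4))}
                if rng_emit.random() < 0.3:
                    e1 = _ENDPOINT_CYCLE[int(rng_emit.integers(3))]
                    if e1 != e0:
                        endpoints[e1] = int(rng_emit.integers(1, 4))

            for endpoint, n_rep in endpoints.items():
                offsets = _replicate_offsets(
                    rng_noise, n_rep, params, inter.inconsistent
                )
                pooled: list[float] = []
                for off in offsets:
                    ppot_rep = true_ppot + off
                    value = _fmt(10.0 ** (9.0 - ppot_rep))
                    ref = refs[int(rng_emit.integers(len(refs)))]
                    smi = parent
                    for vref, vsmi, _ in truth.variants:
                        if vref == ref:
                            smi = vsmi
                    u = rng_emit.random()
                    emit_ch = u < params.dialect_overlap or u >= 0.5 + (
                        params.dialect_overlap / 2
                    )
                    emit_bd = u < 0.5 + params.dialect_overlap / 2
                    if emit_ch:
                        chembl_rows.append(
                            _chembl_row(ref, smi, tid, uniprot_of[tid], endpoint, value)
                        )
                        pooled.append(_emitted_ppot(ppot_rep))
                    if emit_bd:
                        bdb_rows.append(
                            _bdb_row(ref, smi, tid, uniprot_of[tid], endpoint, value)
                        )
                        pooled.append(_emitted_ppot(ppot_rep))
                inter.pooled_values.setdefault(endpoint, []).extend(pooled)

            if inter.contradicted:
                row = _chembl_row(
                    cid, parent, tid, uniprot_of[tid], "IC50", _fmt(10.0 ** 4)
                )
                row["activity_comment"] = "inactive"
                chembl_rows.append(row)
                contradicted_pairs.append((key, tid))

            truth.interactions.append(inter)

        # rows that the high-confidence filter must reject
        if rng_struct.random() < params.fraction_relation_violation:
            tid = planted[0][0]
            row = _chembl_row(
                cid, parent, tid, uniprot_of[tid], "IC50", _fmt(500.0)
            )
            row["standard_relation"] = ">"
            chembl_rows.append(row)
            violations.append(("relation_violation", cid, tid))
        if rng_struct.random() < params.fraction_wrong_organism:
            tid = planted[-1][0]
            row = _chembl_row(
                cid, parent, tid, uniprot_of[tid], "Ki", _fmt(500.0)
            )
            row["organism"] = "Rattus norvegicus"
            chembl_rows.append(row)
            violations.append(("wrong_organism", cid, tid))

        _fill_expectations(truth, params)
        compounds.append(truth)

    manifest = GroundTruthManifest(
        seed=params.seed,
        params=params,
        compounds=compounds,
        planted_violations=violations,
        contradicted_pairs=sorted(contradicted_pairs),
    )
    chembl_df = pd.DataFrame(chembl_rows, columns=list(CHEMBL_COLUMNS.values()))
    bdb_df = pd.DataFrame(bdb_rows, columns=list(BINDINGDB_COLUMNS.values()))
    target_df = _make_target_table(params)
    return chembl_df, bdb_df, target_df, manifest


def _replicate_offsets(
    rng, n_rep: int, params: GeneratorParams, inconsistent: bool
) -> list[float]:
    if inconsistent:
        # guaranteed to violate both the span (<1) and SD (<=1) rules
        base = [1.1, -1.1]
        extra = [float(rng.normal(0.0, 0.1)) for _ in range(max(0, n_rep - 2))]
        return base + extra
    offsets = []
    for _ in range(n_rep):
        off = float(rng.normal(0.0, params.replicate_noise_sd))
        if params.consistent_halfspan is not None:
            off = max(-params.consistent_halfspan, min(params.consistent_halfspan, off))
        offsets.append(off)
    return offsets


def _chembl_row(ref, smiles, tid, uniprot, endpoint, value) -> dict:
    return {
        "molecule_chembl_id": ref,
        "canonical_smiles": smiles,
        "target_chembl_id": f"CH_{tid}",
        "accession": uniprot,
        "organism": "Homo sapiens",
        "target_type": "SINGLE PROTEIN",
        "relationship_type": "D",
        "confidence_score": "9",
        "standard_type": endpoint,
        "standard_relation": "=",
        "standard_value": value,
        "standard_units": "nM",
        "activity_comment": "",
    }


def _bdb_row(ref, smiles, tid, uniprot, endpoint, value) -> dict:
    return {
        "monomer_id": f"BDB_{ref}",
        "ligand_smiles": smiles,
        "target_chain_id": f"BD_{tid}",
        "uniprot_id": uniprot,
        "organism": "Homo sapiens",
        "measurement_type": endpoint,
        "relation": "=",
        "value_nm": value,
        "units": "nM",
    }


def _fill_expectations(truth: CompoundTruth, params: GeneratorParams) -> None:
    """Compute the expected curated outcome by direct arithmetic."""
    for inter in truth.interactions:
        if inter.contradicted:
            inter.expected_retained = False
            continue
        means: dict[str, float] = {}
        for endpoint, values in inter.pooled_values.items():
            if not values:
                continue
            if len(values) > 1:
                if inter.is_pk:
                    if max(values) - min(values) >= 1.0:
                        inter.discarded_endpoints.append(endpoint)
                        continue
                elif statistics.pstdev(values) > 1.0:
                    inter.discarded_endpoints.append(endpoint)
                    continue
            # fmean's exact summation makes the expectation independent of
            # the order in which the pipeline happens to pool replicates
            means[endpoint] = statistics.fmean(values)
        eq = [means[e] for e in ("Ki", "Kd") if e in means]
        if eq:
            inter.expected_final, inter.expected_basis = max(eq), "equilibrium"
        elif "IC50" in means:
            inter.expected_final, inter.expected_basis = means["IC50"], "ic50"
        else:
            inter.expected_retained = False
            continue
        inter.expected_retained = inter.expected_final >= params.ppot_min

    truth.expected_pk_targets = sorted(
        i.target_id
        for i in truth.interactions
        if i.expected_retained and i.is_pk
    )
    truth.expected_nonpk_targets = sorted(
        i.target_id
        for i in truth.interactions
        if i.expected_retained and not i.is_pk and not i.is_antitarget
    )
    truth.expected_in_analysis_set = bool(
        not truth.interference
        and not truth.antitarget_active
        and truth.expected_pk_targets
        and truth.expected_nonpk_targets
    )


SCENARIOS = ("all_consistent", "heavy_noise", "threshold_edge")


def perturb_manifest(
    manifest: GroundTruthManifest, scenario: str
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruthManifest]:
    """Regenerate the tables under a stress scenario.

    ``all_consistent``: zero noise, no contradictions or inconsistencies —
    the curation discard ledger must come out empty.
    ``heavy_noise``: unclipped noise at SD 1.5, so a sizable fraction of
    replicate groups violates the consistency rules.
    ``threshold_edge``: single exact measurements cycling through pPot
    4.99 / 5.00 / 5.01 to probe the inclusive activity threshold.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario: {scenario!r}")
    p = manifest.params
    if scenario == "all_consistent":
        p = replace(
            p,
            replicate_noise_sd=0.0,
            fraction_contradicted=0.0,
            fraction_inconsistent=0.0,
            scenario="all_consistent",
        )
    elif scenario == "heavy_noise":
        p = replace(
            p,
            replicate_noise_sd=1.5,
            consistent_halfspan=None,
            scenario="heavy_noise",
        )
    else:
        p = replace(
            p,
            replicate_noise_sd=0.0,
            fraction_contradicted=0.0,
            fraction_inconsistent=0.0,
            scenario="threshold_edge",
        )
    return generate_catalog(**asdict(p))
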