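"""Curation cascade: pPot conversion, confidence filters, replicate pooling,
endpoint prioritization, and the activity threshold."""

import random

import pytest

from pkitargets.curate import (
    CurationError,
    CurationRuleset,
    apply_activity_threshold,
    curate_interactions,
    drop_contradicted_pairs,
    filter_high_confidence,
    pool_and_average,
    resolve_final_annotation,
    resolve_records,
    to_ppot,
)
from pkitargets.records import CuratedInteraction, MeasurementGroup

from _util import record, target


class TestToPpot:
    @pytest.mark.parametrize(
        "value,expected",
        [(10_000.0, 5.0), (1.0, 9.0), (50.0, 7.30103)],
    )
    def test_conversion(self, value, expected):
        assert to_ppot(value) == pytest.approx(expected, abs=1e-5)

    def test_unit_mismatch(self):
        with pytest.raises(CurationError, match="unit_mismatch"):
            to_ppot(5.0, units="uM")

    def test_bad_value(self):
        with pytest.raises(CurationError, match="bad_value"):
            to_ppot(-1.0)


class TestHighConfidenceFilter:
    @pytest.mark.parametrize(
        "override,reason",
        [
            (dict(relation=">"), "relation"),
            (dict(confidence_score=8), "confidence"),
            (dict(assay_relationship="H"), "relationship"),
            (dict(organism="Rattus norvegicus"), "organism"),
            (dict(target_type="PROTEIN COMPLEX"), "target_type"),
            (dict(units="ug.mL-1"), "units"),
        ],
    )
    def test_chembl_rule_violations(self, override, reason):
        accepted, rejected = filter_high_confidence([record(**override)])
        assert accepted == []
        assert rejected[0][1] == reason

    def test_bindingdb_has_no_confidence_columns(self):
        """A BindingDB row without relationship/confidence must still pass."""
        rec = record(
            source="bindingdb",
            target_type=None,
            assay_relationship=None,
            confidence_score=None,
        )
        accepted, rejected = filter_high_confidence([rec])
        assert len(accepted) == 1 and not rejected

    def test_clean_chembl_record_passes(self):
        accepted, rejected = filter_high_confidence([record()])
        assert len(accepted) == 1 and not rejected


class TestContradictions:
    def test_pair_with_inactive_comment_is_voided(self):
        targets = {"T1": target("T1")}
        recs = [
            record(value=630.0),  # pPot ~6.2
            record(activity_comment="inactive"),
        ]
        resolved, _ = resolve_records(recs, targets)
        kept, dropped = drop_contradicted_pairs(resolved)
        assert kept == []
        assert len(dropped) == 1

    def test_numeric_only_pair_untouched(self):
        targets = {"T1": target("T1")}
        resolved, _ = resolve_records([record(), record(value=90.0)], targets)
        kept, dropped = drop_contradicted_pairs(resolved)
        assert len(kept) == 2 and dropped == []


class TestPooling:
    def _group(self, values):
        return MeasurementGroup("c", "t", "Ki", list(values))

    @pytest.mark.parametrize("rule", ["span", "sd"])
    def test_single_value_is_identity(self, rule):
        assert pool_and_average(self._group([6.5]), rule) == (6.5, None)

    def test_span_rule_mean(self):
        mean, discard = pool_and_average(self._group([6.1, 6.3, 6.2]), "span")
        assert mean == pytest.approx(6.2) and discard is None

    def test_span_boundary_discarded(self):
        """A full order of magnitude is not 'the same order'."""
        mean, discard = pool_and_average(self._group([5.0, 6.0]), "span")
        assert mean is None and discard == "inconsistent_span"

    def test_sd_boundary_retained(self):
        """Population SD exactly 1.0 survives the strictly-greater cutoff."""
        mean, discard = pool_and_average(self._group([4.0, 6.0]), "sd")
        assert mean == pytest.approx(5.0) and discard is None

    def test_sd_above_cutoff_discarded(self):
        mean, discard = pool_and_average(self._group([4.0, 6.5]), "sd")
        assert mean is None and discard == "inconsistent_sd"


class TestFinalAnnotation:
    def test_equilibrium_beats_stronger_ic50(self):
        assert resolve_final_annotation({"Ki": 7.0, "IC50": 8.5}) == (
            7.0,
            "equilibrium",
        )

    def test_highest_equilibrium_value_wins(self):
        assert resolve_final_annotation({"Ki": 6.0, "Kd": 7.0}) == (
            7.0,
            "equilibrium",
        )

    def test_ic50_fallback(self):
        assert resolve_final_annotation({"IC50": 6.5}) == (6.5, "ic50")

    def test_nothing_survives(self):
        assert resolve_final_annotation({}) is None


def _ci(ppot):
    return CuratedInteraction("c", "t", ppot, "ic50", 1)


def test_threshold_boundary_inclusive():
    kept = apply_activity_threshold([_ci(5.0), _ci(4.9)])
    assert [i.ppot_final for i in kept] == [5.0]


def _toy_records():
    targets = {
        "PK1": target("PK1", is_pk=True, uniprot="UPK1"),
        "N1": target("N1", uniprot="UN1"),
    }
    recs = []
    for i, (tid, up, mtype, value) in enumerate(
        [
            ("PK1", "UPK1", "Ki", 100.0),
            ("PK1", "UPK1", "Ki", 120.0),
            ("PK1", "UPK1", "IC50", 10.0),
            ("N1", "UN1", "IC50", 5000.0),
            ("N1", "UN1", "Kd", 800.0),
        ]
    ):
        recs.append(
            record(compound_ref=f"C{i}", target_ref=tid, uniprot=up,
                   measurement_type=mtype, value=value)
        )
    return recs, targets


def test_curation_is_permutation_invariant():
    """Averaging within groups and max across groups commute with order."""
    recs, targets = _toy_records()
    base, _ = curate_interactions(recs, targets)
    for seed in range(5):
        shuffled = recs[:]
        random.Random(seed).shuffle(shuffled)
        got, _ = curate_interactions(shuffled, targets)
        assert got == base


def test_threshold_monotonicity(catalog_small, tmp_path):
    """Raising ppot_min never increases the retained-interaction count."""
    from pkitargets.io_ingest import read_activity_table, read_target_table

    chembl_df, bdb_df, target_df, _ = catalog_small
    for name, df in (("c.tsv", chembl_df), ("b.tsv", bdb_df), ("t.tsv", target_df)):
        df.to_csv(tmp_path / name, sep="\t", index=False)
    recs, _ = read_activity_table(tmp_path / "c.tsv", "chembl")
    recs += read_activity_table(tmp_path / "b.tsv", "bindingdb")[0]
    targets, _ = read_target_table(tmp_path / "t.tsv")
    counts = []
    for ppot_min in (5.0, 6.0, 7.0, 8.0):
        rs = CurationRuleset(ppot_min=ppot_min)
        inters, _ = curate_interactions(recs, targets, rs)
        counts.append(len(inters))
    assert counts == sorted(counts, reverse=True)
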