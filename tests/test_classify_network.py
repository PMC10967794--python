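"""Target-class distributions and the shared-inhibitor network."""

import networkx as nx
import pytest

from pkitargets.classify_network import (
    NetworkError,
    build_network,
    class_distribution,
    export_network,
    network_summary,
)
from pkitargets.promiscuity import build_profiles, profiles_to_table, profiles_from_annotation_table
from pkitargets.records import PromiscuityProfile

from _util import brute_force_edges, interactions_from_manifest, target, targets_from_frame


def _p(ck, pk, nonpk):
    return PromiscuityProfile(ck, frozenset(pk), frozenset(nonpk))


class TestClassDistribution:
    def _metadata(self):
        meta = {}
        for i in range(4):
            meta[f"E{i}"] = target(f"E{i}", class_l1="enzyme", class_l2="protease")
        for i in range(3):
            meta[f"R{i}"] = target(f"R{i}", class_l1="membrane receptor", class_l2="7tm1")
        for i in range(3):
            meta[f"U{i}"] = target(f"U{i}", class_l1="unclassified")
        return meta

    def test_level1_percentages(self):
        dist = class_distribution(self._metadata().keys(), self._metadata(), 1)
        assert dist["enzyme"] == (4, 40.0)
        assert dist["membrane receptor"] == (3, 30.0)

    def test_all_one_class(self):
        meta = {f"E{i}": target(f"E{i}", class_l1="enzyme") for i in range(5)}
        assert class_distribution(meta.keys(), meta, 1) == {"enzyme": (5, 100.0)}

    def test_level2_subtypes(self):
        dist = class_distribution(self._metadata().keys(), self._metadata(), 2)
        assert dist["protease"] == (4, 40.0) and dist["7tm1"] == (3, 30.0)

    def test_unknown_class_fatal(self):
        meta = {"T1": target("T1", class_l1="Adhesion")}
        with pytest.raises(NetworkError, match="Adhesion"):
            class_distribution(["T1"], meta, 1)

    def test_synthetic_class_mix_recovered(self, catalog_small):
        _, _, target_df, _ = catalog_small
        targets = targets_from_frame(target_df)
        nonpk = [t for t in targets if targets[t].class_l1 and not targets[t].is_pk
                 and not targets[t].is_antitarget]
        dist = class_distribution(nonpk, targets, 1)
        expected = {}
        for t in nonpk:
            expected[targets[t].class_l1] = expected.get(targets[t].class_l1, 0) + 1
        assert {c: n for c, (n, _) in dist.items()} == expected


TOY = [
    _p("c1", {"T1"}, {"T2", "T3"}),
    _p("c2", {"T1"}, {"T2"}),
]


class TestBuildNetwork:
    def test_edge_threshold(self):
        """T1,T2 share two compounds; T1,T3 only one -> single edge, T3 absent."""
        net = build_network(TOY, min_shared=2)
        assert set(net.edges) == {("T1", "T2")}
        assert net.edges["T1", "T2"]["n_shared"] == 2
        assert "T3" not in net.nodes

    def test_min_shared_one(self):
        net = build_network(TOY, min_shared=1)
        assert net.number_of_edges() == 3  # all pairs sharing >= 1 compound
        assert "T3" in net.nodes

    def test_min_shared_zero_fatal(self):
        with pytest.raises(NetworkError):
            build_network(TOY, min_shared=0)

    def test_handshake_lemma(self, catalog_small):
        _, _, target_df, manifest = catalog_small
        targets = targets_from_frame(target_df)
        profiles = build_profiles(interactions_from_manifest(manifest), targets)
        net = build_network(profiles)
        assert sum(d for _, d in net.degree) == 2 * net.number_of_edges()
        assert all(d["degree"] >= 1 for _, d in net.nodes(data=True))

    def test_monotone_in_min_shared(self, catalog_small):
        _, _, target_df, manifest = catalog_small
        targets = targets_from_frame(target_df)
        profiles = build_profiles(interactions_from_manifest(manifest), targets)
        prev_edges = None
        for ms in (1, 2, 3, 5):
            net = build_network(profiles, min_shared=ms)
            edges = {tuple(sorted(e)) for e in net.edges}
            if prev_edges is not None:
                assert edges <= prev_edges
            prev_edges = edges

    def test_brute_force_equivalence(self, catalog_small):
        _, _, target_df, manifest = catalog_small
        targets = targets_from_frame(target_df)
        profiles = build_profiles(interactions_from_manifest(manifest), targets)
        net = build_network(profiles, min_shared=2)
        expected = brute_force_edges(profiles, min_shared=2)
        got = {tuple(sorted(e)): net.edges[e]["n_shared"] for e in net.edges}
        assert got == expected


class TestSummaryAndExport:
    def test_toy_summary(self):
        net = build_network(TOY, min_shared=2)
        n_pk, n_nonpk, n_edges, table = network_summary(net)
        assert (n_pk, n_nonpk, n_edges) == (1, 1, 1)
        assert list(table["target_id"]) == ["T1", "T2"]

    def test_empty_profiles(self):
        net = build_network([_p("c1", set(), set())])
        n_pk, n_nonpk, n_edges, table = network_summary(net)
        assert (n_pk, n_nonpk, n_edges) == (0, 0, 0) and table.empty

    def test_graphml_round_trip(self, tmp_path):
        net = build_network(TOY, min_shared=1)
        path = tmp_path / "net.graphml"
        export_network(net, "graphml", path)
        back = nx.read_graphml(path)
        assert nx.is_isomorphic(
            net,
            back,
            node_match=lambda a, b: bool(a["is_pk"]) == bool(b["is_pk"]),
            edge_match=lambda a, b: int(a["n_shared"]) == int(b["n_shared"]),
        )

    def test_edgelist_content(self, tmp_path):
        net = build_network(TOY, min_shared=2)
        path = tmp_path / "net.edgelist"
        export_network(net, "edgelist", path)
        assert path.read_text().strip() == "T1 T2 2"

    def test_sif_label(self, tmp_path):
        net = build_network(TOY, min_shared=2)
        path = tmp_path / "net.sif"
        export_network(net, "sif", path)
        assert path.read_text().strip() == "T1\tshares_PKIs\tT2"

    def test_empty_graphml_is_valid(self, tmp_path):
        net = build_network([_p("c", set(), set())])
        path = tmp_path / "empty.graphml"
        export_network(net, "graphml", path)
        assert nx.read_graphml(path).number_of_nodes() == 0

    def test_unknown_format_fatal(self, tmp_path):
        with pytest.raises(NetworkError):
            export_network(nx.Graph(), "gexf", tmp_path / "x")


def test_annotation_table_round_trip(catalog_small):
    """Profiles survive the deposited-annotation-file schema round trip."""
    _, _, target_df, manifest = catalog_small
    targets = targets_from_frame(target_df)
    profiles = build_profiles(interactions_from_manifest(manifest), targets)
    back = profiles_from_annotation_table(profiles_to_table(profiles))
    assert sorted(back, key=lambda p: p.compound_key) == sorted(
        profiles, key=lambda p: p.compound_key
    )
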