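"""Target-class distributions and the shared-inhibitor target network.

The network connects two targets (kinase or not) by an edge when at least
``min_shared`` analysis-set compounds are active against both.  Isolated
targets (those on no qualifying edge) are excluded from the node set by
default; nodes carry ``is_pk`` and ``degree`` attributes and edges carry
the shared-compound count ``n_shared``.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .promiscuity import _round_half_up_1
from .records import CLASS_L1, PromiscuityProfile, TargetEntry


class NetworkError(ValueError):
    pass


def class_distribution(
    target_ids: Iterable[str],
    metadata: Mapping[str, TargetEntry],
    level: int = 1,
    allowed_classes: Optional[Sequence[str]] = None,
) -> dict[str, tuple[int, float]]:
    """Class membership counts over unique targets, with percentages.

    ``level=1`` tabulates the ten top-level protein classes; ``level=2``
    tabulates sub-types and is meaningful for enzyme and membrane-receptor
    targets (others typically lack a level-2 label and fall under
    ``"(none)"``).  An unknown level-1 class string is fatal.
    """
    if level not in (1, 2):
        raise NetworkError(f"level must be 1 or 2, got {level!r}")
    if allowed_classes is None:
        allowed_classes = CLASS_L1
    ids = sorted(set(target_ids))
    counts: dict[str, int] = {}
    for tid in ids:
        entry = metadata.get(tid)
        if entry is None:
            raise NetworkError(f"target not in metadata: {tid}")
        if level == 1:
            cls = entry.class_l1 or "unclassified"
            if cls not in allowed_classes:
                raise NetworkError(f"unknown level-1 class: {cls!r}")
        else:
            cls = entry.class_l2 or "(none)"
        counts[cls] = counts.get(cls, 0) + 1
    total = len(ids)
    return {
        cls: (n, _round_half_up_1(100.0 * n / total) if total else 0.0)
        for cls, n in sorted(counts.items())
    }


def build_network(
    profiles: Sequence[PromiscuityProfile],
    min_shared: int = 2,
    include_isolates: bool = False,
    bipartite_only: bool = False,
) -> nx.Graph:
    """Build the shared-inhibitor target network from analysis-set profiles.

    Edge (t1, t2) exists iff at least ``min_shared`` compounds are active
    against both targets.  ``bipartite_only`` restricts edges to PK/non-PK
    pairs.  ``include_isolates`` adds targets that end up on no edge.
    """
    if min_shared < 1:
        raise NetworkError("min_shared must be >= 1")
    shared: dict[tuple[str, str], int] = {}
    is_pk: dict[str, bool] = {}
    for p in profiles:
        for t in p.pk_targets:
            is_pk[t] = True
        for t in p.nonpk_targets:
            is_pk[t] = False
        for t1, t2 in combinations(sorted(p.pk_targets | p.nonpk_targets), 2):
            shared[(t1, t2)] = shared.get((t1, t2), 0) + 1

    g = nx.Graph()
    if include_isolates:
        for t in sorted(is_pk):
            g.add_node(t, is_pk=is_pk[t])
    for (t1, t2), n in sorted(shared.items()):
        if n < min_shared:
            continue
        if bipartite_only and is_pk[t1] == is_pk[t2]:
            continue
        g.add_node(t1, is_pk=is_pk[t1])
        g.add_node(t2, is_pk=is_pk[t2])
        g.add_edge(t1, t2, n_shared=n)
    for t in g.nodes:
        g.nodes[t]["degree"] = g.degree[t]
    return g


def network_summary(
    net: nx.Graph, top: int = 10
) -> tuple[int, int, int, pd.DataFrame]:
    """(n_pk_nodes, n_nonpk_nodes, n_edges, top-degree node table)."""
    n_pk = sum(1 for _, d in net.nodes(data=True) if d.get("is_pk"))
    n_nonpk = net.number_of_nodes() - n_pk
    rows = sorted(
        (
            {
                "target_id": t,
                "is_pk": bool(d.get("is_pk")),
                "degree": d.get("degree", net.degree[t]),
            }
            for t, d in net.nodes(data=True)
        ),
        key=lambda r: (-r["degree"], r["target_id"]),
    )[:top]
    table = pd.DataFrame(rows, columns=["target_id", "is_pk", "degree"])
    return n_pk, n_nonpk, net.number_of_edges(), table


def export_network(net: nx.Graph, fmt: str, path) -> None:
    """Write the network as GraphML, SIF, or a whitespace edge list.

    Element order is deterministic (nodes and edges sorted by target ID).
    """
    ordered = nx.Graph()
    for t in sorted(net.nodes):
        ordered.add_node(t, **net.nodes[t])
    for t1, t2 in sorted(tuple(sorted(e)) for e in net.edges):
        ordered.add_edge(t1, t2, **net.edges[t1, t2])
    if fmt == "graphml":
        nx.write_graphml(ordered, path)
    elif fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for t1, t2 in ordered.edges:
                fh.write(f"{t1}\tshares_PKIs\t{t2}\n")
    elif fmt == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            for t1, t2, d in ordered.edges(data=True):
                fh.write(f"{t1} {t2} {d['n_shared']}\n")
    else:
        raise NetworkError(f"unknown network format: {fmt!r}")
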