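"""Homology-network construction, components, paralog classes, sweeps.

Networks are built at four levels:

* ``intra`` — in-paralog edges of one named replicon;
* ``plasmidome`` — all edges among plasmid-role replicons;
* ``plasmid_vs_chromosome`` — only edges joining a plasmid protein to a
  chromosome protein;
* ``genome`` — every edge (intra- + inter-plasmid + chromosome links); this
  is the scope used for the headline connectivity table.

Isolated nodes are kept in the graphs (unconnected proteins are first-class
citizens) but are never components: a protein is *connected* iff it has at
least one retained edge at the active level and threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .seq_io import RepliconSet
from .similarity import HomologyEdge

__all__ = [
    "LEVELS",
    "SweepConfig",
    "ComponentSummary",
    "classify_edges",
    "edge_class_of",
    "build_network",
    "connected_components",
    "largest_component",
    "connectivity_rows",
    "connectivity_table",
    "threshold_sweep",
    "identity_histogram",
    "paralog_class_counts",
]

LEVELS = ("intra", "plasmidome", "plasmid_vs_chromosome", "genome")

IN_PARALOG = "in_paralog"
OUT_PARALOG = "out_paralog"
PLASMID_CHROMOSOME = "plasmid_chromosome"


@dataclass(frozen=True)
class SweepConfig:
    """Identity thresholds for network re-construction and histogram bins.

    ``thresholds`` are lower bounds (>= t, with the top threshold keeping
    only identity == 100 since identity cannot exceed 100).  ``bins`` are
    upper-inclusive integer intervals on the rounded identity; the default
    decade bins place a boundary value such as 50 in the 40-50 bin.
    """

    thresholds: tuple[float, ...] = (40, 50, 60, 70, 80, 90, 100)
    bins: tuple[tuple[int, int], ...] = (
        (40, 50), (51, 60), (61, 70), (71, 80), (81, 90), (91, 99), (100, 100),
    )

    def __post_init__(self) -> None:
        if any(b >= a for b, a in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        for (lo1, hi1), (lo2, _) in zip(self.bins, self.bins[1:]):
            if lo1 > hi1 or lo2 != hi1 + 1:
                raise ValueError("bins must be disjoint, ordered, and contiguous")

    def bin_labels(self) -> list[str]:
        return [f"{lo}" if lo == hi else f"{lo}-{hi}" for lo, hi in self.bins]


@dataclass(frozen=True)
class ComponentSummary:
    """One connected component of a homology network.

    ``per_replicon`` counts members by replicon; ``class_mix`` counts the
    component's internal edges by paralogy class.
    """

    members: frozenset[str]
    per_replicon: Mapping[str, int]
    class_mix: Mapping[str, int]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def min_member(self) -> str:
        return min(self.members)

    def __post_init__(self) -> None:
        if sum(self.per_replicon.values()) != len(self.members):
            raise ValueError("per_replicon counts do not sum to component size")


def edge_class_of(edge: HomologyEdge, replicons: RepliconSet) -> str:
    """Classify an edge as in_paralog / out_paralog / plasmid_chromosome."""
    ru, rv = replicons.replicon_of(edge.u), replicons.replicon_of(edge.v)
    if ru == rv:
        return IN_PARALOG
    chroms = set(replicons.chromosome_ids())
    if (ru in chroms) != (rv in chroms):
        return PLASMID_CHROMOSOME
    return OUT_PARALOG


def classify_edges(
    edges: Iterable[HomologyEdge], replicons: RepliconSet
) -> list[HomologyEdge]:
    """Return edges with ``edge_class`` filled from replicon assignments."""
    return [
        HomologyEdge(e.u, e.v, e.identity, e.e_value, edge_class_of(e, replicons))
        for e in edges
    ]


def _eligible_proteins(replicons: RepliconSet, level: str, replicon_id: str | None):
    if level == "intra":
        if replicon_id is None:
            raise ValueError("intra level requires a named replicon")
        return replicons.proteins_of(replicon_id)
    if level == "plasmidome":
        plasmids = set(replicons.plasmid_ids())
        return [p for p in replicons.proteins if p.replicon_id in plasmids]
    if level in ("plasmid_vs_chromosome", "genome"):
        return list(replicons.proteins)
    raise ValueError(f"unknown network level {level!r} (expected one of {LEVELS})")


def _edge_passes_level(
    e: HomologyEdge, level: str, replicon_id: str | None, replicons: RepliconSet
) -> bool:
    cls = e.edge_class or edge_class_of(e, replicons)
    if level == "intra":
        return cls == IN_PARALOG and replicons.replicon_of(e.u) == replicon_id
    if level == "plasmidome":
        plasmids = set(replicons.plasmid_ids())
        return replicons.replicon_of(e.u) in plasmids and replicons.replicon_of(e.v) in plasmids
    if level == "plasmid_vs_chromosome":
        return cls == PLASMID_CHROMOSOME
    return True  # genome scope keeps everything


def build_network(
    edges: Iterable[HomologyEdge],
    replicons: RepliconSet,
    level: str,
    min_identity: float = 40.0,
    replicon_id: str | None = None,
) -> nx.Graph:
    """Build the homology graph at one level and identity threshold.

    Nodes are *all* proteins eligible at the level, including isolated
    ones; edges are those matching the level's class filter with
    identity >= ``min_identity``.
    """
    g = nx.Graph()
    g.graph["level"] = level
    g.graph["min_identity"] = min_identity
    for p in _eligible_proteins(replicons, level, replicon_id):
        g.add_node(p.protein_id, replicon=p.replicon_id)
    for e in edges:
        if e.identity < min_identity:
            continue
        if not _edge_passes_level(e, level, replicon_id, replicons):
            continue
        cls = e.edge_class or edge_class_of(e, replicons)
        g.add_edge(e.u, e.v, identity=e.identity, e_value=e.e_value, edge_class=cls)
    return g


def connected_components(graph: nx.Graph) -> list[ComponentSummary]:
    """Maximal connected subgraphs of the non-isolated nodes.

    Singletons are not components — they form the unconnected set.  The
    result is sorted by size descending, ties broken by the
    lexicographically smallest member id, so output order is deterministic.
    """
    out: list[ComponentSummary] = []
    for nodes in nx.connected_components(graph):
        if len(nodes) < 2:
            continue
        per_rep: dict[str, int] = {}
        for n in nodes:
            rep = graph.nodes[n].get("replicon", "?")
            per_rep[rep] = per_rep.get(rep, 0) + 1
        mix: dict[str, int] = {}
        for u, v, data in graph.subgraph(nodes).edges(data=True):
            cls = data.get("edge_class", "?")
            mix[cls] = mix.get(cls, 0) + 1
        out.append(ComponentSummary(frozenset(nodes), per_rep, mix))
    out.sort(key=lambda c: (-c.size, c.min_member))
    return out


def largest_component(components: Sequence[ComponentSummary]) -> ComponentSummary:
    """First component under the deterministic sort order."""
    if not components:
        raise ValueError("no components: the network has no connected proteins")
    return components[0]


def _percent_half_up(connected: int, total: int, precision: int) -> float:
    q = Decimal(1).scaleb(-precision)
    return float(
        (Decimal(100 * connected) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )


def connectivity_rows(
    totals: Mapping[str, int],
    connected_counts: Mapping[str, int],
    precision: int = 2,
) -> pd.DataFrame:
    """Connectivity-table formatter: totals + connected counts -> table.

    percent_connected = 100 * connected / total, rounded half-up to
    ``precision`` decimals.  Row order follows ``totals``.
    """
    rows = []
    for rid, total in totals.items():
        conn = connected_counts.get(rid, 0)
        if conn > total:
            raise ValueError(f"replicon {rid!r}: connected {conn} exceeds total {total}")
        rows.append(
            {
                "replicon_id": rid,
                "total": total,
                "unconnected": total - conn,
                "connected": conn,
                "percent_connected": _percent_half_up(conn, total, precision),
            }
        )
    return pd.DataFrame(rows)


def connectivity_table(
    components: Sequence[ComponentSummary],
    replicons: RepliconSet,
    scope: str = "genome",
    precision: int = 2,
) -> pd.DataFrame:
    """Per-replicon connected/unconnected tallies at a scope.

    A protein is connected iff it appears in any component computed at that
    scope.  The table covers the replicons eligible at the scope (all for
    ``genome``/``plasmid_vs_chromosome``, plasmid-role only for
    ``plasmidome``), in registry order.
    """
    if scope == "plasmidome":
        rep_ids = replicons.plasmid_ids()
    elif scope in ("genome", "plasmid_vs_chromosome"):
        rep_ids = [r.replicon_id for r in replicons.replicons]
    elif scope == "intra":
        rep_ids = [r.replicon_id for r in replicons.replicons]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    connected_ids: set[str] = set()
    for c in components:
        connected_ids |= c.members
    totals = {rid: replicons.replicon(rid).protein_count for rid in rep_ids}
    conn = {
        rid: sum(
            1 for p in replicons.proteins_of(rid) if p.protein_id in connected_ids
        )
        for rid in rep_ids
    }
    df = connectivity_rows(totals, conn, precision)
    df.attrs["scope"] = scope
    return df


def threshold_sweep(
    edges: Sequence[HomologyEdge],
    replicons: RepliconSet,
    level: str,
    config: SweepConfig | None = None,
    replicon_id: str | None = None,
) -> pd.DataFrame:
    """Rebuild the network at each identity threshold.

    Returns one row per threshold with the retained edge count and the
    number of connected (non-isolated) nodes; both are non-increasing in
    the threshold.
    """
    config = config or SweepConfig()
    rows = []
    for t in config.thresholds:
        g = build_network(edges, replicons, level, min_identity=t, replicon_id=replicon_id)
        connected_nodes = sum(1 for n in g.nodes if g.degree(n) > 0)
        rows.append({"threshold": t, "edges": g.number_of_edges(),
                     "connected_nodes": connected_nodes})
    return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    return int(Decimal(str(x)).quantize(Decimal(1), rounding=ROUND_HALF_UP))


def identity_histogram(
    edges: Iterable[HomologyEdge], config: SweepConfig | None = None
) -> pd.DataFrame:
    """Assign each edge to exactly one identity bin.

    The edge's identity is rounded half-up to the nearest integer and
    matched against the upper-inclusive bins; identities outside the binned
    range are an error (they should have been filtered upstream).
    """
    config = config or SweepConfig()
    counts = {label: 0 for label in config.bin_labels()}
    lo_bound = config.bins[0][0]
    hi_bound = config.bins[-1][1]
    for e in edges:
        ident = _round_half_up(e.identity)
        if ident < lo_bound or ident > hi_bound:
            raise ValueError(
                f"edge {e.u}-{e.v}: identity {e.identity} outside "
                f"[{lo_bound}, {hi_bound}]"
            )
        for (lo, hi), label in zip(config.bins, config.bin_labels()):
            if lo <= ident <= hi:
                counts[label] += 1
                break
    return pd.DataFrame(
        {"bin": list(counts.keys()), "edges": list(counts.values())}
    )


def paralog_class_counts(
    edges: Iterable[HomologyEdge], replicons: RepliconSet
) -> dict[str, int]:
    """Counts of in-paralog, out-paralog and plasmid-chromosome edges."""
    counts = {IN_PARALOG: 0, OUT_PARALOG: 0, PLASMID_CHROMOSOME: 0}
    for e in edges:
        counts[e.edge_class or edge_class_of(e, replicons)] += 1
    return counts
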