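"""GC-deviation tracks and export of networks/tracks for external renderers.

Exports are plain-text files for Cytoscape (TSV edge list, GraphML) and
Circos (karyotype, highlight, tile, histogram dialects).  Nothing is drawn
here.  Internal coordinates are 0-based half-open; Circos files are written
1-based inclusive, with an explicit bijective conversion at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .pos import PosRecord
from .seq_io import RepliconSet, gc_content

__all__ = [
    "TrackConfig",
    "GcTrack",
    "gc_deviation_track",
    "to_circos_interval",
    "from_circos_interval",
    "export_edge_list",
    "export_graphml",
    "export_circos_tracks",
]


@dataclass(frozen=True)
class TrackConfig:
    """Sliding-window parameters for GC tracks.

    Defaults (10 kb windows, 5 kb step) give a few hundred windows on a
    typical plasmid — enough resolution to see compositionally atypical
    islands without dominating noise.
    """

    window_size: int = 10_000
    step: int = 5_000
    precision: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window_size:
            raise ValueError("require 0 < step <= window_size")


@dataclass(frozen=True)
class GcTrack:
    """Windowed GC deviation from a reference mean, in percentage points."""

    replicon_id: str
    windows: tuple[tuple[int, int, float], ...]  # (start, end, deviation)


def gc_deviation_track(
    seq: str,
    mean_gc: float,
    config: TrackConfig | None = None,
    replicon_id: str = "",
) -> GcTrack:
    """Per-window GC percentage minus ``mean_gc``.

    Windows start every ``step`` bases; a final partial window is emitted
    if it is at least ``step`` long.  Regions deviating strongly from the
    replicon mean flag compositionally atypical (possibly horizontally
    acquired) segments.
    """
    config = config or TrackConfig()
    if len(seq) < config.window_size:
        raise ValueError(
            f"sequence ({len(seq)} bp) shorter than window ({config.window_size} bp)"
        )
    windows: list[tuple[int, int, float]] = []
    start = 0
    while start < len(seq):
        end = min(start + config.window_size, len(seq))
        if end - start < config.step and start > 0:
            break
        windows.append((start, end, gc_content(seq[start:end]) - mean_gc))
        if end == len(seq):
            break
        start += config.step
    return GcTrack(replicon_id=replicon_id, windows=tuple(windows))


def to_circos_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> Circos 1-based inclusive."""
    if end <= start:
        raise ValueError(f"empty interval [{start}, {end})")
    return start + 1, end


def from_circos_interval(start1: int, end1: int) -> tuple[int, int]:
    """Circos 1-based inclusive -> 0-based half-open (inverse bijection)."""
    return start1 - 1, end1


def export_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """TSV edge list: source, target, identity, e_value, edge_class.

    One line per edge, ordered lexicographically by the (sorted) pair, so
    re-export of the same graph is byte-identical.
    """
    rows = []
    for u, v, data in graph.edges(data=True):
        a, b = (u, v) if str(u) <= str(v) else (v, u)
        rows.append((a, b, data.get("identity", ""), data.get("e_value", ""),
                     data.get("edge_class", "")))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("source_id\ttarget_id\tidentity\te_value\tedge_class\n")
        for a, b, ident, ev, cls in rows:
            ident_s = f"{ident:.2f}" if isinstance(ident, float) else str(ident)
            ev_s = f"{ev:.3g}" if isinstance(ev, float) else str(ev)
            fh.write(f"{a}\t{b}\t{ident_s}\t{ev_s}\t{cls}\n")


def export_graphml(
    graph: nx.Graph,
    path: str | Path,
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
) -> None:
    """Write GraphML with typed node/edge attributes.

    ``node_attrs`` maps attribute name -> {node -> value} (e.g. replicon,
    connected flag, POS organism, COG letters).  Attribute names that would
    overwrite an existing node attribute with a different meaning are
    rejected.  Nodes are written in sorted order for determinism.
    """
    node_attrs = node_attrs or {}
    g = nx.Graph()
    g.add_nodes_from(sorted(graph.nodes(data=True), key=lambda x: str(x[0])))
    g.add_edges_from(
        sorted(
            ((u, v, d) if str(u) <= str(v) else (v, u, d)
             for u, v, d in graph.edges(data=True)),
            key=lambda x: (str(x[0]), str(x[1])),
        )
    )
    existing = {k for _, d in g.nodes(data=True) for k in d}
    for name, mapping in node_attrs.items():
        if name in existing:
            raise ValueError(f"node attribute name collision: {name!r}")
        for node in g.nodes:
            if node in mapping:
                g.nodes[node][name] = mapping[node]
    nx.write_graphml(g, str(path))


# fixed, order-stable palette for categorical Circos tiles
_TILE_COLORS = (
    "red", "blue", "green", "orange", "purple", "yellow",
    "dgrey", "lblue", "lgreen", "lred",
)


def export_circos_tracks(
    replicons: RepliconSet,
    connected_set: set[str],
    pos_records: Sequence[PosRecord],
    gc_tracks: Sequence[GcTrack],
    out_dir: str | Path,
    gene_coords: Mapping[str, tuple[str, int, int]] | None = None,
) -> dict[str, Path]:
    """Write the Circos track bundle.

    Files: ``karyotype.txt`` (one band per replicon), ``connected.txt``
    (two-color highlight: connected red, unconnected blue — outer circle),
    ``pos_tiles.txt`` (categorical tiles per POS organism — inner circle)
    and ``gc_deviation.txt`` (histogram).  When no gene-coordinate table is
    supplied, genes are laid out proportionally by index along their
    replicon — a visualization fallback; real coordinates come from the
    genome annotation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {name: out_dir / f"{name}.txt"
             for name in ("karyotype", "connected", "pos_tiles", "gc_deviation")}

    lengths: dict[str, int] = {}
    for r in replicons.replicons:
        if r.nt_length is None:
            raise ValueError(
                f"replicon {r.replicon_id!r} has no nucleotide sequence; "
                "tracks need nt_length"
            )
        lengths[r.replicon_id] = r.nt_length

    with open(paths["karyotype"], "w") as fh:
        for i, r in enumerate(replicons.replicons):
            s1, e1 = to_circos_interval(0, lengths[r.replicon_id])
            # karyotype uses chr - id label start end color
            fh.write(f"chr - {r.replicon_id} {r.replicon_id} {s1 - 1} {e1} "
                     f"chr{(i % 22) + 1}\n")

    def interval_of(protein_id: str, rid: str, idx: int, n: int) -> tuple[int, int]:
        if gene_coords and protein_id in gene_coords:
            _, s, e = gene_coords[protein_id]
            return s, e
        # proportional fallback layout
        length = lengths[rid]
        return (idx * length) // n, max(((idx + 1) * length) // n, (idx * length) // n + 1)

    with open(paths["connected"], "w") as fh:
        for r in replicons.replicons:
            prots = replicons.proteins_of(r.replicon_id)
            for idx, p in enumerate(prots):
                s, e = interval_of(p.protein_id, r.replicon_id, idx, len(prots))
                s1, e1 = to_circos_interval(s, e)
                color = "red" if p.protein_id in connected_set else "blue"
                fh.write(f"{r.replicon_id} {s1} {e1} fill_color={color}\n")

    organisms = sorted({rec.pos_organism for rec in pos_records if rec.pos_organism})
    color_of = {org: _TILE_COLORS[i % len(_TILE_COLORS)]
                for i, org in enumerate(organisms)}
    pos_by_protein = {rec.protein_id: rec for rec in pos_records}
    with open(paths["pos_tiles"], "w") as fh:
        for r in replicons.replicons:
            prots = replicons.proteins_of(r.replicon_id)
            for idx, p in enumerate(prots):
                rec = pos_by_protein.get(p.protein_id)
                if rec is None or rec.pos_organism is None:
                    continue
                s, e = interval_of(p.protein_id, r.replicon_id, idx, len(prots))
                s1, e1 = to_circos_interval(s, e)
                fh.write(f"{r.replicon_id} {s1} {e1} "
                         f"color={color_of[rec.pos_organism]}\n")

    with open(paths["gc_deviation"], "w") as fh:
        for track in gc_tracks:
            for s, e, dev in track.windows:
                s1, e1 = to_circos_interval(s, e)
                fh.write(f"{track.replicon_id} {s1} {e1} {dev:.2f}\n")

    return paths
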