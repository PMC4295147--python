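"""End-to-end pipeline: manifest -> hits -> filter -> networks -> tables.

``run_pipeline`` chains every stage deterministically and writes plain-text
tables plus Circos/GraphML exports into one output directory, together with
a run-metadata file recording every parameter and input digest.  Repeated
runs with the same inputs and configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation, network, pos, similarity, tracks
from .seq_io import RepliconSet, load_replicon_set
from .similarity import AlignerParams, FilterCriteria
from .tracks import TrackConfig

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    ``backend`` is either ``"internal"`` (built-in aligner) or
    ``"tabular"`` with ``hits_path`` pointing at a 12-column blast-tabular
    file from an external search engine.
    """

    manifest: str | Path
    out_dir: str | Path
    backend: str = "internal"
    hits_path: str | Path | None = None
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    sweep: network.SweepConfig = field(default_factory=network.SweepConfig)
    annotation: annotation.AnnotationCriteria = field(
        default_factory=annotation.AnnotationCriteria
    )
    track: TrackConfig = field(default_factory=TrackConfig)
    aligner: AlignerParams = field(default_factory=AlignerParams)
    cog_table: str | Path | None = None
    pos_table: str | Path | None = None
    self_strain: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("internal", "tabular"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.backend == "tabular" and self.hits_path is None:
            raise ValueError("tabular backend requires hits_path")


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path, header_note: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header_note}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    crit = config.criteria
    note = (
        f"min_identity={crit.min_identity} max_evalue={crit.max_evalue} "
        f"min_query_coverage={crit.min_query_coverage}"
    )
    digests: dict[str, str] = {}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrap

    # -- load ----------------------------------------------------------
    rset: RepliconSet = stage("load")(load_replicon_set, config.manifest)
    digests["manifest"] = _sha256(Path(config.manifest))
    lengths = rset.lengths()

    # -- hits ----------------------------------------------------------
    if config.backend == "tabular":
        hits = stage("hits")(similarity.parse_tabular_hits, config.hits_path)
        digests["hits"] = _sha256(Path(config.hits_path))
    else:
        hits = stage("hits")(similarity.all_vs_all, rset.proteins, config.aligner)

    # -- filter --------------------------------------------------------
    retained, rejected = stage("filter")(
        similarity.filter_hits_detailed, hits, crit, lengths
    )
    similarity.write_hits_tsv(retained, out / "filtered_hits.tsv")
    similarity.write_rejected_tsv(rejected, out / "rejected_hits.tsv")

    # -- network -------------------------------------------------------
    edges = stage("network")(similarity.symmetrize, retained)
    edges = network.classify_edges(edges, rset)
    genome_graph = network.build_network(
        edges, rset, "genome", min_identity=crit.min_identity
    )
    tracks.export_edge_list(genome_graph, out / "edge_list.tsv")

    components = network.connected_components(genome_graph)
    comp_rows = [
        {
            "component": i,
            "size": c.size,
            "per_replicon": ";".join(f"{k}:{v}" for k, v in sorted(c.per_replicon.items())),
            "members": ";".join(sorted(c.members)),
        }
        for i, c in enumerate(components)
    ]
    _write_table(pd.DataFrame(comp_rows, columns=["component", "size", "per_replicon", "members"]),
                 out / "components_genome.tsv", note)

    conn_table = network.connectivity_table(components, rset, scope="genome")
    _write_table(conn_table, out / "connectivity.tsv", f"scope=genome {note}")

    if components:
        big = network.largest_component(components)
        big_rows = [
            {"replicon_id": rset.replicon_of(pid), "protein_id": pid}
            for pid in sorted(big.members, key=lambda p: (rset.replicon_of(p), p))
        ]
        _write_table(pd.DataFrame(big_rows), out / "largest_component.tsv", note)

    # per-level sweeps and histogram
    for level in ("genome", "plasmidome", "plasmid_vs_chromosome"):
        sweep_df = stage("sweep")(
            network.threshold_sweep, edges, rset, level, config.sweep
        )
        _write_table(sweep_df, out / f"sweep_{level}.tsv", f"level={level} {note}")
    hist = stage("sweep")(network.identity_histogram, edges, config.sweep)
    _write_table(hist, out / "identity_histogram.tsv", note)

    class_counts = network.paralog_class_counts(edges, rset)
    _write_table(pd.DataFrame([class_counts]), out / "paralog_classes.tsv", note)

    connected_ids: set[str] = set()
    for c in components:
        connected_ids |= c.members

    # -- annotation ----------------------------------------------------
    if config.cog_table is not None:
        cog_hits = stage("annotate")(annotation.read_cog_table, config.cog_table)
        digests["cog_table"] = _sha256(Path(config.cog_table))
        assignments = [
            annotation.assign_cog(pid, cog_hits.get(pid, []), config.annotation)
            for pid in sorted(p.protein_id for p in rset.proteins)
        ]
        profile = stage("annotate")(
            annotation.functional_profile, assignments,
            connected_ids & {a.protein_id for a in assignments},
        )
        _write_table(profile, out / "cog_profile.tsv",
                     f"max_evalue={config.annotation.max_evalue} {note}")

    # -- pos -----------------------------------------------------------
    pos_records: list = []
    if config.pos_table is not None:
        ext_hits = stage("pos")(pos.read_external_hits, config.pos_table)
        digests["pos_table"] = _sha256(Path(config.pos_table))
        pos_records = [
            pos.assign_pos(pid, ext_hits.get(pid, []), config.self_strain)
            for pid in sorted(p.protein_id for p in rset.proteins)
        ]
        pos.write_pos_table(pos_records, connected_ids, out / "pos_table.tsv")
        _write_table(pos.pos_summary(pos_records, rset), out / "pos_summary.tsv", note)

    # -- exports -------------------------------------------------------
    node_attrs: dict[str, dict] = {
        "connected": {p.protein_id: p.protein_id in connected_ids for p in rset.proteins}
    }
    if pos_records:
        node_attrs["pos_organism"] = {
            r.protein_id: r.pos_organism for r in pos_records if r.pos_organism
        }
    stage("export")(tracks.export_graphml, genome_graph, out / "network.graphml",
                    node_attrs)

    if all(r.nt_sequence is not None for r in rset.replicons):
        gc_tracks = []
        for r in rset.replicons:
            if r.nt_length >= config.track.window_size:
                gc_tracks.append(
                    tracks.gc_deviation_track(
                        r.nt_sequence, r.gc_percent, config.track, r.replicon_id
                    )
                )
        stage("export")(tracks.export_circos_tracks, rset, connected_ids,
                        pos_records, gc_tracks, out / "circos")

    # -- metadata ------------------------------------------------------
    meta = {
        "seed": config.seed,
        "backend": config.backend,
        "criteria": {
            "min_identity": crit.min_identity,
            "max_evalue": crit.max_evalue,
            "min_query_coverage": crit.min_query_coverage,
        },
        "aligner": {
            "substitution_matrix": config.aligner.substitution_matrix,
            "gap_open": config.aligner.gap_open,
            "gap_extend": config.aligner.gap_extend,
            "karlin_lambda": config.aligner.karlin_lambda,
            "karlin_k": config.aligner.karlin_k,
            "evalue_model": "karlin-altschul fixed-parameter approximation",
        },
        "sweep_thresholds": list(config.sweep.thresholds),
        "annotation_max_evalue": config.annotation.max_evalue,
        "track": {"window_size": config.track.window_size, "step": config.track.step},
        "self_strain": config.self_strain,
        "input_digests": digests,
        "replicons": {
            r.replicon_id: {"role": r.role, "proteins": r.protein_count}
            for r in rset.replicons
        },
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return out
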