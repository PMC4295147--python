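# plasnet

Similarity-network analysis of bacterial **plasmidomes** — the complete set
of plasmids carried by one strain, treated as a single analyzable gene pool.

Bacterial plasmids evolve by gene duplication and by exchanging genes with
each other, with the chromosome, and with other organisms.  `plasnet` maps
those relationships for one sequenced strain (the motivating system is
*Azospirillum brasilense* Sp245: one chromosome and six plasmids,
AZOBR1–AZOBR6) by:

1. comparing every encoded protein against every other (built-in
   Smith–Waterman aligner, or ingested blast-tabular output from an external
   search engine);
2. keeping a pair as *homologous* only when the hit simultaneously passes
   three inclusive thresholds — identity ≥ 40.0 %, E-value ≤ 0.05, and the
   alignment covering ≥ 70 % of the query sequence — with self-hits removed;
3. building undirected homology networks at the intra-plasmid, plasmidome,
   plasmid-vs-chromosome and whole-genome levels, re-built across an
   identity-threshold sweep (≥40 % … 100 %) to stratify links by inferred
   recency of duplication or transfer;
4. extracting paralog families as connected components (a protein is
   *connected* iff it has at least one retained edge; isolated proteins are
   the unconnected set), classifying edges as in-paralog (same replicon),
   out-paralog (different plasmids) or plasmid–chromosome links;
5. profiling connected vs unconnected proteins by COG functional category,
   assigning each protein its **POS** (Preferential Organismal Sharing: the
   organism contributing the best-ranked external homolog from a strain
   other than the query's own), and computing windowed GC-deviation tracks
   that flag compositionally atypical, possibly horizontally acquired
   regions;
6. exporting everything as plain text: TSV tables, Cytoscape-ready edge
   lists, GraphML, and Circos karyotype/highlight/tile/histogram tracks.

A synthetic-plasmidome generator (`plasnet.synthio`) plants paralog
families at exact, controlled identities together with matching POS/COG
tables, so the entire pipeline is testable against known ground truth
without downloading anything.

## Worked example

Simulate a small three-replicon plasmidome (two plasmids + chromosome, two
planted families, 100 background genes) and run the full pipeline:

```bash
plasnet simulate --seed 7 --out demo/sim
plasnet run --manifest demo/sim/manifest.yaml --out-dir demo/out \
    --cog demo/sim/cog_hits.tsv --pos demo/sim/pos_hits.tsv \
    --self-strain "Azospirillum brasilense Sp245"
cat demo/out/connectivity.tsv
```

```
# scope=genome min_identity=40.0 max_evalue=0.05 min_query_coverage=0.7
replicon_id	total	unconnected	connected	percent_connected
pA	34	30	4	11.76
pB	32	30	2	6.25
chr	41	40	1	2.44
```

Of plasmid pA's 34 proteins, 4 have at least one filtered homology edge
anywhere in the genome (11.76 %); none of the random background genes is
connected.  The recovered components coincide with the planted families:

```
$ head -3 demo/out/components_genome.tsv
# min_identity=40.0 max_evalue=0.05 min_query_coverage=0.7
component	size	per_replicon	members
0	4	pA:2;pB:2	fam1_pA_m00;fam1_pA_m01;fam1_pB_m02;fam1_pB_m03
```

— component 0 is the 0.80-identity family spanning both plasmids (its two
pA members are in-paralogs, the cross-plasmid links out-paralogs).  The
threshold sweep shows the expected monotone decay of links, with only the
0.95-identity family surviving past 90 %:

```
$ cat demo/out/sweep_genome.tsv
# level=genome min_identity=40.0 max_evalue=0.05 min_query_coverage=0.7
threshold	edges	connected_nodes
40	9	7
50	9	7
60	9	7
70	6	7
80	6	7
90	3	3
100	0	0
```

The output directory also contains the filtered/rejected hit tables (each
rejection labelled `self_hit` / `identity` / `evalue` / `coverage`), the
largest-component membership, identity histograms, COG profiles split by
connectivity, the per-protein POS table, `network.graphml`, and a
`circos/` bundle (karyotype, connected/unconnected highlights, POS tiles,
GC-deviation histogram).  `run_metadata.json` records every parameter and
input digest; reruns are byte-identical.

The same stages are available as library functions
(`plasnet.similarity.all_vs_all`, `filter_hits`, `symmetrize`;
`plasnet.network.build_network`, `connected_components`,
`connectivity_table`, `threshold_sweep`; `plasnet.annotation.assign_cog`;
`plasnet.pos.assign_pos`; `plasnet.tracks.gc_deviation_track`, …).

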