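# Methods

## Homology model

Two proteins of the same cell are treated as homologous — linked in the
network — when a pairwise local alignment between them passes three
criteria *simultaneously*, every boundary inclusive:

* percent identity ≥ 40.0 (identical aligned residue pairs / alignment
  columns, gap columns counted in the denominator — the blast-tabular
  `pident` convention, so ingested and internally computed hits are
  comparable);
* E-value ≤ 0.05;
* alignment length ≥ 70 % of the **query** length.

Self-hits are always removed.  Directed hits A→B and B→A can disagree on
coverage (different query lengths), so symmetrization keeps an undirected
edge whenever at least one direction passed, with edge identity = max over
directions and edge E-value = min (best evidence).  The working assumption
throughout is the usual molecular-clock-style reading of identity: higher
identity ⇒ more recent duplication or transfer.  The toolkit only computes
the networks; it makes no horizontal-transfer claims itself.

## Internal aligner and E-values

The built-in backend is Smith–Waterman with affine gaps (BLOSUM62, gap
open 11, extend 1), executed by `Bio.Align.PairwiseAligner`; its scores are
cross-checked in the test suite against an independent hand-written Gotoh
dynamic program.  E-values use the Karlin–Altschul form
`E = K·m·n·exp(−λS)` with fixed gapped-BLOSUM62 constants λ = 0.267,
K = 0.041, m = query length and n = total residues in the dataset.  This is
an explicit approximation — no composition-based statistics, no
finite-size edge correction — recorded in the run metadata.  When fidelity
to a specific external search engine matters, run that engine and ingest
its 12-column tabular output (`backend: tabular`); the filter and all
downstream stages are identical for both backends.

## Network levels and connectivity

Edges are classified by replicon assignment: `in_paralog` (both endpoints
on the same replicon), `out_paralog` (different plasmids),
`plasmid_chromosome` (exactly one endpoint on a chromosome).  Four graph
levels reuse the same edge set: `intra` (one named replicon),
`plasmidome` (edges among plasmid-role replicons), `plasmid_vs_chromosome`,
and `genome` (everything — the scope used for the headline connectivity
table).  Graphs retain isolated nodes, but components are defined on the
non-isolated nodes only: singletons are the *unconnected* set, and
`percent_connected = 100 × connected / total`, rounded **half-up** to the
requested precision (the published two-decimal percentages are only
reproduced under half-up rounding, e.g. 244/1748 → 13.96).

Components are sorted by size descending, ties broken by lexicographically
smallest member id, purely to make outputs deterministic.  Identity
histograms round each edge identity half-up to the nearest integer and use
upper-inclusive decade bins 40–50, 51–60, …, 91–99, 100 (so a boundary
value of exactly 50 falls in 40–50); the threshold sweep re-builds the
graph at lower bounds 40, 50, …, 100.

## Annotation and POS

COG assignment takes the categories of the single best precomputed hit if
its E-value ≤ 1e-20 (inclusive); later hits never matter, and a
multi-letter assignment (e.g. "EK") contributes to each letter in the
functional profiles — a documented convention, since connected/unconnected
category plots rarely state it.  The enrichment ratio
(connected fraction / unconnected fraction) is descriptive only; no
significance testing is attached.

POS follows the first-hit-from-another-*strain* rule: organisms are
compared as case-folded, whitespace-collapsed "genus species strain"
strings, so other strains of the same species are eligible donors.  No
identity or E-value floor is applied beyond what the ranked table already
encodes.

## GC-deviation tracks

`deviation(w) = GC(w) − mean_gc` per window, with N bases excluded from
both numerator and denominator of GC (assembly gaps should not read as
AT-richness).  Window/step defaults are 10 kb / 5 kb — a few hundred
windows on a megabase-scale plasmid; any reasonable window reproduces the
tracks qualitatively.  A final partial window is emitted only if it is at
least one step long.  Over an exact non-overlapping tiling whose reference
mean comes from the same sequence, the length-weighted mean deviation is 0
to floating-point precision (asserted at 1e-9).  Circos files are written
1-based inclusive from 0-based half-open internal coordinates via an
explicit bijection.  When no gene-coordinate table is available, gene
intervals for the highlight/tile circles are laid out proportionally by
index — a visualization fallback only.

## Synthetic plasmidome

The generator emulates the study conditions: a few replicons carrying
*background* genes (independent uniform-random 20-letter sequences, length
120–240 by default) plus *planted families*.  Background genes essentially
never pass the triple filter — a 70 %-coverage, 40 %-identity local
alignment between independent random proteins of this length is
vanishingly improbable — so every retained edge is attributable to a
planted family.

Each family grows from one random ancestor.  The ancestor itself is
emitted as the family's first member (a hub); every other member is an
exact-count mutated copy: exactly `round((1−t)·L)` positions, chosen
uniformly without replacement, substituted with a different residue — no
indels, so the ungapped hub-to-member identity is exactly the target `t`
and boundary behaviour (≥ 40.0 inclusive) is exercisable precisely.  The
hub is what makes recovery well-defined: had every member been mutated
independently, member-to-member identity would concentrate near `t²`
(≈ 36 % at t = 0.6, below the filter), whereas the star topology
guarantees one component per family at any threshold ≤ 100·t, while
member–member identities (≈ `t²`, worst case `2t−1`) supply additional
in-component edges without changing the partition.  Per-family and
per-replicon random streams are derived by stable sub-seeding from one
global seed, so adding a family does not perturb existing sequences.

Nucleotide backbones allocate one fixed-width block per gene (900 bp
default) at a global GC target, with family-gene blocks shifted by +8
percentage points, planting detectable GC islands for track testing.
POS and COG tables are synthesized with one planted donor organism and one
planted category per family; half of the background genes get an external
donor, half a self-strain-only hit list (POS = none), and half are
COG-assignable — all recorded in the ground-truth JSON.

What the generator does **not** emulate: phylogenetically realistic
substitution (no rate matrices, no site heterogeneity), indels (an aligner
would then mediate realized identity), shared domains between unrelated
proteins, transposases and repeat families, operonic gene order, or
database-bias effects on POS.  Passing tests therefore demonstrate the
pipeline's bookkeeping and threshold logic under clean conditions, not
recovery performance on real proteomes, where domain-level homology and
low-complexity sequence make connectivity noisier.

## Problem sizes and determinism

The planted-recovery study uses 3 plasmids × ~75 genes (224 proteins,
~25 000 alignments, well under a minute on one CPU); families sit at hub
identities 0.60/0.70/0.80/0.85/0.95 so a ≥ 90 % threshold isolates exactly
the most recent family.  Recovery is scored as the adjusted Rand index
between recovered components and planted families, with every unclustered
protein a singleton in both partitions — ARI 1.0 means exact recovery and
zero background contamination.  All outputs (tables, edge lists, GraphML,
Circos files) are sorted deterministically and byte-identical across
reruns with the same inputs and seed.

## Known limitations

* E-values from the internal aligner are approximate; do not compare them
  numerically with an external engine's output, only through the filter.
* `percent_identity` is gap-inclusive; tools reporting identity over
  matched columns only will disagree near thresholds.
* Whether published per-replicon protein totals included pseudogene
  fragments is unknowable from the tables alone; the toolkit counts every
  FASTA entry.
* Exact-string organism matching for POS treats differently formatted
  names of the same strain as different organisms; normalize upstream if
  needed.
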