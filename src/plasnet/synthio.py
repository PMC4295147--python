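"""Synthetic plasmidomes with planted paralog families and known answers.

The generator emulates the object of study: a handful of replicons whose
proteins are either *background* genes (independent uniform-random amino
acid sequences, which share no detectable homology at the default filter)
or members of *planted families*.  Each family grows from one random
ancestor: the ancestor itself is emitted as the family's first member (a
hub), and every other member is an exact-count mutated copy at the family's
target identity.  The hub guarantees that a family simulated at identity t
forms a single network component at any threshold <= 100*t, while
member-member identities fall near t^2 — mimicking the star-like divergence
of a duplicated gene's descendants.

Matching POS and COG tables are synthesized with one planted organism and
one planted category per family, so every pipeline stage can be verified
against ground truth without any download.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from sklearn.metrics import adjusted_rand_score

from .network import ComponentSummary
from .pos import ExternalHit
from .seq_io import ProteinRecord, Replicon, RepliconSet, write_protein_fasta

__all__ = [
    "RepliconSpec",
    "FamilySpec",
    "SimConfig",
    "PlantedTruth",
    "SimulatedPlasmidome",
    "SELF_STRAIN",
    "mutate_to_identity",
    "simulate_plasmidome",
    "write_simulation",
    "recovery_ari",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

SELF_STRAIN = "Azospirillum brasilense Sp245"

# plausible donor organisms for planted POS answers
ORGANISM_POOL = (
    "Azospirillum lipoferum 4B",
    "Azospirillum sp. B510",
    "Rhodospirillum centenum SW",
    "Magnetospirillum magneticum AMB-1",
    "Bradyrhizobium japonicum USDA 110",
    "Rhizobium leguminosarum bv. viciae 3841",
)

COG_POOL = "EKLTCGPINM"


@dataclass(frozen=True)
class RepliconSpec:
    replicon_id: str
    role: str = "plasmid"
    n_background_genes: int = 50
    protein_length_range: tuple[int, int] = (120, 240)


@dataclass(frozen=True)
class FamilySpec:
    """A planted paralog family.

    ``placements`` lists (replicon_id, member count); ``target_identity``
    is the exact hub-to-member identity fraction.
    """

    family_id: str
    placements: tuple[tuple[str, int], ...]
    target_identity: float = 0.8
    ancestral_length: int = 200

    def __post_init__(self) -> None:
        if not 0.25 < self.target_identity <= 1.0:
            raise ValueError("target_identity must be in (0.25, 1]")
        if self.ancestral_length < 30:
            raise ValueError("ancestral_length must be >= 30")
        if any(c < 1 for _, c in self.placements):
            raise ValueError("placement counts must be >= 1")

    @property
    def n_members(self) -> int:
        return sum(c for _, c in self.placements)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    replicons: tuple[RepliconSpec, ...] = ()
    families: tuple[FamilySpec, ...] = ()
    nt_per_gene: int = 900
    gc_target: float = 60.0
    gc_family_delta: float = 8.0  # GC shift of family-gene windows, pct points


@dataclass
class PlantedTruth:
    """Ground truth of a simulated plasmidome."""

    family_members: dict[str, set[str]]
    expected_identity: dict[str, float]  # hub-to-member, per family
    background: set[str]
    pos_by_protein: dict[str, str | None]
    cog_by_protein: dict[str, str | None]

    def partition_labels(self, protein_ids: Sequence[str]) -> list[str]:
        """Family label per protein; background genes are singletons."""
        by_protein = {
            pid: fid for fid, members in self.family_members.items() for pid in members
        }
        return [by_protein.get(pid, f"singleton:{pid}") for pid in protein_ids]


@dataclass
class SimulatedPlasmidome:
    replicon_set: RepliconSet
    truth: PlantedTruth
    pos_hits: dict[str, list[ExternalHit]]
    cog_hits: dict[str, list[tuple[str, float]]]
    self_strain: str = SELF_STRAIN


def _rng(seed: int, *tags: str) -> np.random.Generator:
    """Stable sub-seeded generator: adding a family never perturbs others."""
    return np.random.default_rng(
        [seed] + [zlib.crc32(str(t).encode()) for t in tags]
    )


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def mutate_to_identity(seq: str, target_identity: float, rng_seed) -> str:
    """Substitute an exact number of positions to hit a target identity.

    Exactly ``round((1 - target) * len(seq))`` positions, chosen uniformly
    without replacement, are replaced by a residue different from the
    original; length is preserved and no indels are introduced, so the
    ungapped identity to the input is exactly the target (up to the
    rounding of the count).  ``rng_seed`` may be an int or a seed sequence.
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0, 1]")
    if target_identity < 1.0 / len(seq):
        raise ValueError(
            f"target identity {target_identity} below 1/len feasibility "
            f"for length {len(seq)}"
        )
    n_mut = round((1.0 - target_identity) * len(seq))
    if n_mut == 0:
        return seq
    rng = np.random.default_rng(rng_seed)
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [a for a in AA_ALPHABET if a != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _synth_nt(rng: np.random.Generator, length: int, gc_percent: float) -> str:
    gc = np.clip(gc_percent, 0.0, 100.0) / 100.0
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ATGC"), size=length, p=[p[0], p[3], p[1], p[2]]))


def simulate_plasmidome(config: SimConfig) -> SimulatedPlasmidome:
    """Generate a full synthetic plasmidome with planted ground truth.

    Deterministic given ``config.seed``; per-replicon and per-family random
    streams are derived by stable sub-seeding.
    """
    if not config.replicons:
        raise ValueError("config must declare at least one replicon")
    known = {r.replicon_id for r in config.replicons}
    for fam in config.families:
        bad = [rid for rid, _ in fam.placements if rid not in known]
        if bad:
            raise ValueError(f"family {fam.family_id!r}: unknown replicons {bad}")

    proteins_by_rep: dict[str, list[ProteinRecord]] = {
        r.replicon_id: [] for r in config.replicons
    }
    truth = PlantedTruth({}, {}, set(), {}, {})
    pos_hits: dict[str, list[ExternalHit]] = {}
    cog_hits: dict[str, list[tuple[str, float]]] = {}

    # background genes: uniform random sequences, no planted homology
    for rspec in config.replicons:
        rng = _rng(config.seed, "bg", rspec.replicon_id)
        lo, hi = rspec.protein_length_range
        for i in range(rspec.n_background_genes):
            pid = f"bg_{rspec.replicon_id}_{i:04d}"
            seq = _random_protein(rng, int(rng.integers(lo, hi + 1)))
            proteins_by_rep[rspec.replicon_id].append(
                ProteinRecord(pid, rspec.replicon_id, seq, pid)
            )
            truth.background.add(pid)
            if rng.random() < 0.5:  # half the background has an external donor
                org = ORGANISM_POOL[int(rng.integers(len(ORGANISM_POOL)))]
                ident = float(np.round(40 + 40 * rng.random(), 1))
                pos_hits[pid] = [ExternalHit(1, org, ident, 1e-30)]
                truth.pos_by_protein[pid] = org
            else:  # self-strain hit only -> POS must be none
                pos_hits[pid] = [ExternalHit(1, SELF_STRAIN, 100.0, 0.0)]
                truth.pos_by_protein[pid] = None
            if rng.random() < 0.5:  # half the background is COG-assignable
                cat = COG_POOL[int(rng.integers(len(COG_POOL)))]
                cog_hits[pid] = [(cat, 1e-25)]
                truth.cog_by_protein[pid] = cat
            else:  # best hit too weak for the 1e-20 threshold
                cog_hits[pid] = [(COG_POOL[0], 1e-10)]
                truth.cog_by_protein[pid] = None

    # planted families: hub ancestor + exact-identity mutated copies
    for fi, fam in enumerate(config.families):
        rng = _rng(config.seed, "fam", fam.family_id)
        ancestor = _random_protein(rng, fam.ancestral_length)
        org = ORGANISM_POOL[fi % len(ORGANISM_POOL)]
        cat = COG_POOL[fi % len(COG_POOL)]
        members: list[tuple[str, str, str]] = []  # (pid, replicon, seq)
        k = 0
        for rid, count in fam.placements:
            for _ in range(count):
                pid = f"{fam.family_id}_{rid}_m{k:02d}"
                if k == 0:
                    seq = ancestor  # the hub member
                else:
                    sub = _rng(config.seed, "fam", fam.family_id, f"member{k}")
                    seq = mutate_to_identity(ancestor, fam.target_identity, sub)
                members.append((pid, rid, seq))
                k += 1
        truth.family_members[fam.family_id] = {pid for pid, _, _ in members}
        truth.expected_identity[fam.family_id] = fam.target_identity
        for pid, rid, seq in members:
            proteins_by_rep[rid].append(ProteinRecord(pid, rid, seq, pid))
            pos_hits[pid] = [
                ExternalHit(1, SELF_STRAIN, 100.0, 0.0),
                ExternalHit(2, org, round(100 * fam.target_identity, 1), 1e-50),
            ]
            truth.pos_by_protein[pid] = org
            cog_hits[pid] = [(cat, 1e-30)]
            truth.cog_by_protein[pid] = cat

    # nucleotide backbones: one fixed-width block per gene; family-gene
    # blocks shifted in GC so tracks show planted compositional islands
    replicons: list[Replicon] = []
    proteins: list[ProteinRecord] = []
    for rspec in config.replicons:
        prots = proteins_by_rep[rspec.replicon_id]
        rng = _rng(config.seed, "nt", rspec.replicon_id)
        blocks = []
        for p in prots:
            gc = config.gc_target
            if p.protein_id not in truth.background:
                gc += config.gc_family_delta
            blocks.append(_synth_nt(rng, config.nt_per_gene, gc))
        replicons.append(
            Replicon(rspec.replicon_id, rspec.role, nt_sequence="".join(blocks))
        )
        proteins.extend(prots)

    rset = RepliconSet(replicons=replicons, proteins=proteins)
    return SimulatedPlasmidome(rset, truth, pos_hits, cog_hits)


def write_simulation(sim: SimulatedPlasmidome, out_dir: str | Path) -> dict[str, Path]:
    """Write the simulation in the formats the pipeline reads.

    Per-replicon protein FASTA and nucleotide FASTA, a YAML manifest, the
    ranked POS and COG hit TSVs, and the ground truth as JSON.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for r in sim.replicon_set.replicons:
        faa = out_dir / f"{r.replicon_id}.faa"
        write_protein_fasta(sim.replicon_set.proteins_of(r.replicon_id), faa)
        entry = {"role": r.role, "proteins": faa.name}
        if r.nt_sequence is not None:
            fna = out_dir / f"{r.replicon_id}.fna"
            with open(fna, "w") as fh:
                fh.write(f">{r.replicon_id}\n")
                for i in range(0, len(r.nt_sequence), 70):
                    fh.write(r.nt_sequence[i : i + 70] + "\n")
            entry["nucleotide"] = fna.name
        manifest[r.replicon_id] = entry
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    with open(out_dir / "pos_hits.tsv", "w") as fh:
        fh.write("protein_id\trank\tsubject_organism\tpercent_identity\te_value\n")
        for pid in sorted(sim.pos_hits):
            for h in sim.pos_hits[pid]:
                fh.write(f"{pid}\t{h.rank}\t{h.subject_organism}\t"
                         f"{h.percent_identity}\t{h.e_value}\n")
    with open(out_dir / "cog_hits.tsv", "w") as fh:
        fh.write("protein_id\tcategories\te_value\n")
        for pid in sorted(sim.cog_hits):
            for cats, ev in sim.cog_hits[pid]:
                fh.write(f"{pid}\t{cats}\t{ev}\n")
    truth_json = {
        "family_members": {k: sorted(v) for k, v in sim.truth.family_members.items()},
        "expected_identity": sim.truth.expected_identity,
        "background": sorted(sim.truth.background),
        "pos_by_protein": sim.truth.pos_by_protein,
        "cog_by_protein": sim.truth.cog_by_protein,
        "self_strain": sim.self_strain,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
    return {
        "manifest": out_dir / "manifest.yaml",
        "pos": out_dir / "pos_hits.tsv",
        "cog": out_dir / "cog_hits.tsv",
        "truth": out_dir / "truth.json",
    }


def recovery_ari(
    truth: PlantedTruth,
    components: Sequence[ComponentSummary],
    protein_ids: Sequence[str],
) -> float:
    """Adjusted Rand index between planted families and recovered components.

    Both partitions place every unclustered protein in its own singleton,
    so an ARI of 1.0 means the components reproduce the planted families
    exactly and no background gene joined any component.
    """
    true_labels = truth.partition_labels(protein_ids)
    comp_of = {
        pid: f"comp{idx}" for idx, c in enumerate(components) for pid in c.members
    }
    pred_labels = [comp_of.get(pid, f"single:{pid}") for pid in protein_ids]
    return float(adjusted_rand_score(true_labels, pred_labels))
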