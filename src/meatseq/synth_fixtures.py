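"""Deterministic synthetic worlds: mitogenome-like references, categories,
implanted primer cassettes, conserved cross-category blocks, and mixed
error-bearing reads.

Every module of the pipeline is testable against these fixtures with no
external data: genomes diverge by substitution only (matching the ungapped
mapper), primer sites are implanted exactly, and conserved blocks reproduce
the near-identical cross-category marker segments that force read discards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp, write_fasta, write_fastq
from .insilico_pcr import PRESETS, Primer
from .read_classifier import SeqRead
from .reference_db import CategoryMap, GenomeRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {c: i for i, c in enumerate("ACGT")}


@dataclass(frozen=True)
class CategorySpec:
    """One synthetic meat category.

    ``between_divergence`` is the category root's substitution load relative
    to the shared ancestor (half the expected pairwise distance between two
    categories); ``within_divergence`` plays the same role among species of
    the category.
    """

    name: str
    n_species: int = 2
    between_divergence: float = 0.15
    within_divergence: float = 0.02


@dataclass(frozen=True)
class ConservedBlock:
    """A segment copied verbatim into every genome of the named categories."""

    length: int
    categories: frozenset[str]
    in_amplicon: bool = False

    def __post_init__(self):
        object.__setattr__(self, "categories", frozenset(self.categories))


@dataclass
class SynthWorld:
    seed: int
    categories: Sequence[CategorySpec]
    genome_length: int = 16_000
    conserved_blocks: Sequence[ConservedBlock] = ()
    primer_cassette: tuple[Primer, int, Primer] = (PRESETS["cytb"][0], 300, PRESETS["cytb"][1])

    def __post_init__(self):
        if not self.categories:
            raise ValueError("at least one category required")
        names = [c.name for c in self.categories]
        if len(set(names)) != len(names):
            raise ValueError("category names must be unique")
        for c in self.categories:
            for d in (c.between_divergence, c.within_divergence):
                if not 0 <= d < 0.75:
                    raise ValueError(f"divergence {d} outside [0, 0.75)")
        fwd, spacer, rev = self.primer_cassette
        if spacer < 0:
            raise ValueError("negative spacer length")
        cass_len = len(fwd) + spacer + len(rev)
        amp_payload = sum(b.length for b in self.conserved_blocks if b.in_amplicon)
        if amp_payload > spacer:
            raise ValueError("in-amplicon conserved blocks exceed the spacer")
        flank_payload = sum(b.length + 50 for b in self.conserved_blocks if not b.in_amplicon)
        if self.genome_length // 4 + cass_len + 100 + flank_payload > self.genome_length:
            raise ValueError("cassette and conserved blocks do not fit in the genome")
        unknown = {
            c for b in self.conserved_blocks for c in b.categories
        } - set(names)
        if unknown:
            raise ValueError(f"conserved blocks reference unknown categories {sorted(unknown)}")

    @property
    def cassette_length(self) -> int:
        fwd, spacer, rev = self.primer_cassette
        return len(fwd) + spacer + len(rev)


@dataclass
class WorldData:
    """Realised world: genome records, category map, and per-genome truth."""

    world: SynthWorld
    records: list[GenomeRecord]
    cmap: CategoryMap
    #: accession -> {category, species, amplicon_start, amplicon_end}
    truth: dict[str, dict]

    def amplicon(self, accession: str) -> str:
        info = self.truth[accession]
        rec = next(r for r in self.records if r.accession == accession)
        return rec.sequence[info["amplicon_start"] : info["amplicon_end"]]

    def accessions_of(self, category: str) -> list[str]:
        return [a for a, info in self.truth.items() if info["category"] == category]

    def write(self, fasta_path, cfg_path) -> None:
        with open(fasta_path, "w") as fh:
            write_fasta(
                ((f"{r.accession} {r.species_name} {' '.join(r.taxon_names)}", r.sequence)
                 for r in self.records),
                fh,
            )
        self.cmap.to_file(cfg_path)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability *rate*, always to a different base."""
    out = codes.copy()
    if rate <= 0:
        return out
    mask = rng.random(len(codes)) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _encode4(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.uint8)


def make_world(world: SynthWorld) -> WorldData:
    """Generate genomes, category map, and truth record from a world spec.

    Layout per genome: a shared ancestor is mutated into category roots
    (between-divergence / 2 each) and then into species genomes
    (within-divergence / 2).  The primer cassette is implanted at a fixed
    locus (L/4) in every genome *after* mutation, so primer sites are always
    exact; conserved blocks are copied verbatim into their categories, inside
    the cassette spacer when ``in_amplicon`` else downstream of it.
    """
    rng = np.random.default_rng(world.seed)
    L = world.genome_length
    fwd, spacer, rev = world.primer_cassette
    fwd_codes = _encode4(fwd.sequence)
    rev_rc_codes = _encode4(revcomp(rev.sequence))
    cass_start = L // 4
    amp_len = world.cassette_length

    ancestor = rng.integers(0, 4, size=L, dtype=np.uint8)

    # block sequences are drawn once so every member genome shares them verbatim
    block_seqs = [rng.integers(0, 4, size=b.length, dtype=np.uint8) for b in world.conserved_blocks]
    amp_pos = cass_start + len(fwd.sequence)  # next free position inside the spacer
    flank_pos = cass_start + amp_len + 100
    block_loci: list[tuple[ConservedBlock, int]] = []
    for b in world.conserved_blocks:
        if b.in_amplicon:
            block_loci.append((b, amp_pos))
            amp_pos += b.length
        else:
            block_loci.append((b, flank_pos))
            flank_pos += b.length + 50

    records: list[GenomeRecord] = []
    truth: dict[str, dict] = {}
    cmap_entries: list[tuple[str, list[str]]] = []
    for ci, cat in enumerate(world.categories):
        root = _mutate(ancestor, cat.between_divergence / 2.0, rng)
        taxon = f"{cat.name}_genus"
        cmap_entries.append((cat.name, [taxon]))
        for si in range(cat.n_species):
            genome = _mutate(root, cat.within_divergence / 2.0, rng)
            for (block, pos), seq in zip(block_loci, block_seqs):
                if cat.name in block.categories:
                    genome[pos : pos + block.length] = seq
            genome[cass_start : cass_start + len(fwd_codes)] = fwd_codes
            rs = cass_start + len(fwd_codes) + spacer
            genome[rs : rs + len(rev_rc_codes)] = rev_rc_codes
            acc = f"SYN{ci:02d}S{si:02d}"
            species = f"{cat.name}_sp{si}"
            records.append(
                GenomeRecord(
                    accession=acc,
                    species_name=species,
                    taxon_names=(taxon,),
                    sequence=_decode(genome),
                )
            )
            truth[acc] = {
                "category": cat.name,
                "species": species,
                "amplicon_start": cass_start,
                "amplicon_end": cass_start + amp_len,
            }
    return WorldData(world, records, CategoryMap(cmap_entries), truth)


@dataclass
class ReadSimSpec:
    mixture: Mapping[str, float]  # category -> mass fraction, sums to 1
    n_reads: int
    read_length: int = 301
    substitution_error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        self.mixture = dict(self.mixture)
        if any(v < 0 for v in self.mixture.values()):
            raise ValueError("mixture fractions must be >= 0")
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ValueError("mixture fractions must sum to 1")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


def simulate_reads(
    data: WorldData,
    spec: ReadSimSpec,
    mode: Literal["amplicon", "shotgun"] = "amplicon",
) -> tuple[list[SeqRead], pd.DataFrame]:
    """Draw reads from the world per the mixture, with i.i.d. substitution errors.

    Amplicon mode fragments the implanted-cassette product; shotgun mode draws
    uniformly from the whole genome.  Returns the reads and a truth table
    (read_id, category, accession, start position on source, strand).
    """
    for cat in spec.mixture:
        if cat not in {c.name for c in data.world.categories}:
            raise ValueError(f"mixture references unknown category {cat!r}")
    rng = np.random.default_rng(spec.seed)
    cats = sorted(c for c, f in spec.mixture.items() if f > 0)
    probs = np.array([spec.mixture[c] for c in cats])
    probs = probs / probs.sum()
    genomes = {c: data.accessions_of(c) for c in cats}
    templates: dict[str, str] = {}
    for c in cats:
        for acc in genomes[c]:
            rec = next(r for r in data.records if r.accession == acc)
            templates[acc] = (
                data.amplicon(acc) if mode == "amplicon" else rec.sequence
            )
            if len(templates[acc]) < spec.read_length:
                raise ValueError(
                    f"read_length {spec.read_length} exceeds {mode} template "
                    f"of {acc} ({len(templates[acc])} bp)"
                )
    reads: list[SeqRead] = []
    rows = []
    if spec.n_reads:
        cat_draws = rng.choice(len(cats), size=spec.n_reads, p=probs)
        for i in range(spec.n_reads):
            cat = cats[int(cat_draws[i])]
            acc = genomes[cat][int(rng.integers(len(genomes[cat])))]
            tpl = templates[acc]
            start = int(rng.integers(0, len(tpl) - spec.read_length + 1))
            frag = tpl[start : start + spec.read_length]
            codes = _encode4(frag)
            codes = _mutate(codes, spec.substitution_error_rate, rng)
            bases = _decode(codes)
            strand = "+"
            if rng.random() < 0.5:
                bases, strand = revcomp(bases), "-"
            rid = f"r{i:07d}"
            reads.append(SeqRead(rid, bases, "I" * spec.read_length))
            rows.append({"read_id": rid, "category": cat, "accession": acc,
                         "start": start, "strand": strand})
    truth = pd.DataFrame(rows, columns=["read_id", "category", "accession", "start", "strand"])
    return reads, truth


#: six-component mixture mirroring the evaluation sample's target composition (%)
H1_TARGET_PCT = (40.38, 22.70, 22.40, 10.83, 2.54, 1.08)

#: recommended sequencing throughput (reads) used for the H1-like simulation
H1_DEFAULT_READS = 30_000


def simulate_h1_like(
    data: WorldData,
    seed: int,
    n_reads: int = H1_DEFAULT_READS,
    read_length: int = 301,
    substitution_error_rate: float = 0.005,
) -> tuple[list[SeqRead], pd.DataFrame]:
    """Six-category mixture at the evaluation-sample target proportions.

    The first six categories of the world (in spec order) receive the target
    fractions, normalised to sum to 1.
    """
    names = [c.name for c in data.world.categories]
    if len(names) < 6:
        raise ValueError("h1-like simulation needs a world with >= 6 categories")
    weights = np.array(H1_TARGET_PCT)
    mixture = dict(zip(names[:6], weights / weights.sum()))
    spec = ReadSimSpec(
        mixture=mixture,
        n_reads=n_reads,
        read_length=read_length,
        substitution_error_rate=substitution_error_rate,
        seed=seed,
    )
    return simulate_reads(data, spec, mode="amplicon")


def write_reads_fastq(reads: Sequence[SeqRead], path) -> int:
    with open(path, "w") as fh:
        return write_fastq(((r.read_id, r.bases, r.qualities or "I" * len(r.bases)) for r in reads), fh)
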