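"""Read mapping and single-category assignment by the unique-read rule.

Each read is aligned against every genome sharing a k-mer seed with it
(seed-and-extend, ungapped).  A read whose hits all fall in one meat category
is counted for that category; hits spanning two or more categories discard the
read; no hit leaves it unmapped.  The same decision is applied to externally
produced SAM alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pysam

from ._seq import FastqFormatError, encode, iter_fastq, open_text, revcomp
from .reference_db import ReferenceDB

logger = logging.getLogger(__name__)

DISCARDED = "DISCARDED"
UNMAPPED = "UNMAPPED"


@dataclass(frozen=True)
class SeqRead:
    read_id: str
    bases: str
    qualities: str | None = None  # carried through but never used for classification

    def __post_init__(self):
        if not self.bases:
            raise ValueError(f"read {self.read_id}: empty bases")


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    accession: str
    position: int  # 0-based start of the aligned block on the genome plus strand
    strand: str
    aligned_length: int
    identity: float
    score: int  # number of matching bases

    def __post_init__(self):
        assert 0 <= self.identity <= 1.0


@dataclass
class MapParams:
    """Internal mapper tuning.

    ``seed_step`` samples every n-th read k-mer as a seed; 1 (default) checks
    every k-mer, guaranteeing that any genome sharing a single exact k-mer
    with the read is examined.  Larger steps trade that guarantee for speed.
    """

    min_identity: float = 0.90
    min_cov: float = 0.80
    seed_step: int = 1
    min_read_length: int = 50


@dataclass
class CategoryCounts:
    counts: dict[str, int] = field(default_factory=dict)
    discarded: int = 0
    unmapped: int = 0
    total_reads: int = 0
    short_reads: int = 0  # subset of unmapped: skipped by the length filter

    def add(self, label: str) -> None:
        self.total_reads += 1
        if label == UNMAPPED:
            self.unmapped += 1
        elif label == DISCARDED:
            self.discarded += 1
        else:
            self.counts[label] = self.counts.get(label, 0) + 1

    def check_conservation(self) -> None:
        assert sum(self.counts.values()) + self.discarded + self.unmapped == self.total_reads


def map_read(read: SeqRead, db: ReferenceDB, params: MapParams | None = None) -> list[AlignmentHit]:
    """Best ungapped alignment per genome reachable from an exact k-mer seed.

    Seeds anchor a diagonal; the whole read is compared against the genome on
    that diagonal (clipped at genome ends).  Hits must reach ``min_identity``
    over at least ``min_cov`` of the read length.  At most one hit — the
    highest-identity, then leftmost — is reported per genome, so repeats within
    a genome cannot mimic multi-genome evidence.
    """
    params = params or MapParams()
    k = db.k
    rl = len(read.bases)
    if rl < k:
        raise ValueError(f"read {read.read_id}: length {rl} < k={k}")
    best: dict[str, AlignmentHit] = {}
    for strand, bases in (("+", read.bases.upper()), ("-", revcomp(read.bases.upper()))):
        n_kmers = rl - k + 1
        positions = list(range(0, n_kmers, params.seed_step))
        if positions[-1] != n_kmers - 1:
            positions.append(n_kmers - 1)
        diagonals: set[tuple[str, int]] = set()
        for i in positions:
            for acc, pos, s in db.seed_hits(bases[i : i + k]):
                if s == "+":
                    diagonals.add((acc, pos - i))
        if not diagonals:
            continue
        rcodes = encode(bases)
        for acc, diag in sorted(diagonals):
            g = db.encoded(acc)
            gstart = max(0, diag)
            gend = min(len(g), diag + rl)
            aligned = gend - gstart
            if aligned < params.min_cov * rl or aligned < k:
                continue
            rstart = gstart - diag
            matches = int(np.count_nonzero(g[gstart:gend] == rcodes[rstart : rstart + aligned]))
            identity = matches / aligned
            if identity < params.min_identity:
                continue
            hit = AlignmentHit(read.read_id, acc, gstart, strand, aligned, identity, matches)
            prev = best.get(acc)
            if prev is None or (hit.identity, -hit.position) > (prev.identity, -prev.position):
                best[acc] = hit
    return sorted(best.values(), key=lambda h: h.accession)


def classify_hits(hits: list[AlignmentHit], db: ReferenceDB) -> str:
    """Single category name, or DISCARDED (multi-category) / UNMAPPED (no hits)."""
    if not hits:
        return UNMAPPED
    cats = set()
    for h in hits:
        if h.accession not in db.category_of:
            raise KeyError(f"hit references accession {h.accession!r} not in database")
        cats.add(db.category_of[h.accession])
    return cats.pop() if len(cats) == 1 else DISCARDED


def classify_reads(
    reads: Iterable[SeqRead], db: ReferenceDB, params: MapParams | None = None
) -> CategoryCounts:
    """Map and classify an iterable of reads into CategoryCounts."""
    params = params or MapParams()
    out = CategoryCounts()
    for n, read in enumerate(reads, 1):
        if len(read.bases) < max(params.min_read_length, db.k):
            out.add(UNMAPPED)
            out.short_reads += 1
        else:
            out.add(classify_hits(map_read(read, db, params), db))
        if n % 100_000 == 0:
            logger.info("classified %d reads", n)
    out.check_conservation()
    return out


def iter_fastq_reads(path) -> Iterator[SeqRead]:
    with open_text(path) as fh:
        for rid, bases, quals in iter_fastq(fh):
            yield SeqRead(rid, bases, quals)


def classify_fastq(
    paths, db: ReferenceDB, params: MapParams | None = None
) -> CategoryCounts:
    """Classify one FASTQ file (or several, e.g. unmerged mates) into counts.

    Mates are classified independently and tallied together; quality strings
    are ignored.  Accepts plain or gzip-compressed input.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]

    def reads() -> Iterator[SeqRead]:
        for p in paths:
            yield from iter_fastq_reads(p)

    return classify_reads(reads(), db, params)


def ingest_sam(path, db: ReferenceDB) -> CategoryCounts:
    """Tally externally produced alignments by the same unique-read rule.

    All alignment records of a read — primary, secondary, supplementary —
    contribute hit genomes equally; mapping quality is ignored.  A read whose
    every record carries the unmapped flag is unmapped.
    """
    read_cats: dict[str, set[str]] = {}
    unknown: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            name = rec.query_name
            cats = read_cats.setdefault(name, set())
            if rec.is_unmapped:
                continue
            ref = rec.reference_name
            if ref not in db.category_of:
                unknown.add(ref)
                continue
            cats.add(db.category_of[ref])
    if unknown:
        raise KeyError(
            "SAM reference names not present in the database: " + ", ".join(sorted(unknown))
        )
    out = CategoryCounts()
    for name, cats in read_cats.items():
        if not cats:
            out.add(UNMAPPED)
        elif len(cats) == 1:
            out.add(next(iter(cats)))
        else:
            out.add(DISCARDED)
    out.check_conservation()
    return out
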