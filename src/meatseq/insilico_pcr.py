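"""In-silico PCR: locate universal-primer binding sites and slice amplicons.

Matching is ungapped (primers rarely tolerate indels).  IUPAC codes in a
primer match their expansion set; an ambiguous base in the *template* matches
nothing and counts as a mismatch.  Mitochondrial templates are treated as
circular by default, so products spanning the origin are found.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seq import DNA_BASES, IUPAC_EXPAND, encode, revcomp, validate_dna
from .reference_db import GenomeRecord, ReferenceDB


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str  # 5'->3'

    def __post_init__(self):
        object.__setattr__(self, "sequence", validate_dna(self.sequence, context=f"primer {self.name}"))
        if not self.sequence:
            raise ValueError(f"primer {self.name}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


#: primer presets, exactly as printed in the assay's primer table
PRESETS: dict[str, tuple[Primer, Primer]] = {
    "cytb": (
        Primer("CB1-5", "CCATCCAACATCTCAGCATGATGAAA"),
        Primer("CB3A", "CCCTCAGAATGATATTTGTCCTCA"),
    ),
    "coi": (
        Primer("COIF", "AATTGGGGGGTTTGGAAATTG"),
        Primer("COIR", "GCTCGTGTATCAACGTCTATTCC"),
    ),
    "dloop": (
        Primer("CE CVZV 1", "GATCACGAGCTTGATCACCA"),
        Primer("CE CVZV 2", "AGGAGTGGGCGATTTTAGGT"),
    ),
}

#: product length bounds: generic default and the CYTB marker preset
DEFAULT_LENGTH_BOUNDS = (100, 1000)
CYTB_LENGTH_BOUNDS = (250, 500)


@dataclass(frozen=True)
class PrimerSite:
    template_accession: str
    start: int  # 0-based, on the plus strand of the template
    end: int  # half-open
    strand: str  # '+': primer sequence matches template as-is; '-': matches revcomp
    mismatches: int


@dataclass(frozen=True)
class AmpliconHit:
    template_accession: str
    start: int
    end: int  # half-open, primer-inclusive; may exceed template length if the product wraps
    fwd_site: PrimerSite
    rev_site: PrimerSite
    sequence: str  # 5'->3' starting with the forward primer
    spans_origin: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def _allowed_table(primer_seq: str) -> np.ndarray:
    """Boolean (len(primer), 256) table: row j marks template ASCII codes that
    satisfy primer base j.  Ambiguous template bases are never allowed."""
    table = np.zeros((len(primer_seq), 256), dtype=bool)
    for j, p in enumerate(primer_seq):
        for b in IUPAC_EXPAND[p] & set(DNA_BASES):
            table[j, ord(b)] = True
    return table


def _scan(template_codes: np.ndarray, primer_seq: str, max_mismatch: int,
          lock: int) -> list[tuple[int, int]]:
    """All ungapped placements of *primer_seq* with <= max_mismatch mismatches.

    *lock* forces the final `lock` 3'-end bases of the primer to match exactly.
    Returns (start, mismatches) pairs, ascending by start.
    """
    m = len(primer_seq)
    n = len(template_codes) - m + 1
    if n <= 0:
        return []
    table = _allowed_table(primer_seq)
    mism = np.zeros(n, dtype=np.int32)
    for j in range(m):
        mism += ~table[j][template_codes[j : j + n]]
    ok = mism <= max_mismatch
    if lock > 0:
        for j in range(max(0, m - lock), m):
            ok &= table[j][template_codes[j : j + n]]
    return [(int(i), int(mism[i])) for i in np.flatnonzero(ok)]


def find_primer_sites(
    template: str,
    primer: Primer,
    max_mismatch: int = 3,
    *,
    accession: str = "",
    three_prime_lock: int = 0,
) -> list[PrimerSite]:
    """All ungapped binding sites of *primer* on either strand of *template*.

    A '+' site means the primer sequence aligns to the template as written; a
    '-' site means it aligns to the reverse complement (coordinates are always
    reported on the plus strand).  Sorted by start position.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    template = validate_dna(template, context="template")
    codes = encode(template)
    m = len(primer)
    sites = [
        PrimerSite(accession, s, s + m, "+", mm)
        for s, mm in _scan(codes, primer.sequence, max_mismatch, three_prime_lock)
    ]
    # primer on the minus strand <=> revcomp(primer) on the plus strand; the
    # primer's 3' end then sits at the *left* edge, handled by scanning the
    # reverse-complemented template and mirroring coordinates.
    rc_codes = encode(revcomp(template))
    L = len(template)
    for s, mm in _scan(rc_codes, primer.sequence, max_mismatch, three_prime_lock):
        sites.append(PrimerSite(accession, L - s - m, L - s, "-", mm))
    sites.sort(key=lambda x: (x.start, x.strand))
    return sites


def extract_amplicons(
    template: GenomeRecord | str,
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = 3,
    min_len: int = DEFAULT_LENGTH_BOUNDS[0],
    max_len: int = DEFAULT_LENGTH_BOUNDS[1],
    *,
    circular: bool = True,
    three_prime_lock: int = 2,
) -> list[AmpliconHit]:
    """Every productive fwd/rev primer pairing with an in-bounds product.

    Productive means the two primers point toward each other: forward on '+'
    upstream of the reverse primer's '-' site, or the mirror arrangement.
    Product sequences are reported 5'->3' starting with the forward primer.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if isinstance(template, GenomeRecord):
        accession, seq = template.accession, template.sequence
    else:
        accession, seq = "", validate_dna(template, context="template")
    L = len(seq)
    work = seq
    wraps = circular and L > max_len
    if wraps:
        work = seq + seq[: max_len - 1]

    fsites = find_primer_sites(work, fwd, max_mismatch, accession=accession,
                               three_prime_lock=three_prime_lock)
    rsites = find_primer_sites(work, rev, max_mismatch, accession=accession,
                               three_prime_lock=three_prime_lock)

    hits: list[AmpliconHit] = []
    seen: set[tuple[int, int, str]] = set()

    def emit(start: int, end: int, sequence: str, f: PrimerSite, r: PrimerSite, orient: str):
        key = (start % L if wraps else start, end - start, orient)
        if key in seen:
            return
        seen.add(key)
        spans = wraps and end > L
        if wraps:
            start, end = start % L, start % L + (end - start)
        hits.append(AmpliconHit(accession, start, end, f, r, sequence, spans_origin=spans))

    for f in fsites:
        for r in rsites:
            if f.strand == "+" and r.strand == "-" and r.start >= f.end:
                length = r.end - f.start
                if min_len <= length <= max_len:
                    emit(f.start, r.end, work[f.start : r.end], f, r, "+")
            elif f.strand == "-" and r.strand == "+" and f.start >= r.end:
                length = f.end - r.start
                if min_len <= length <= max_len:
                    emit(r.start, f.end, revcomp(work[r.start : f.end]), f, r, "-")

    # on a circularised template every non-wrapping product is found twice;
    # `seen` keys on (start mod L, length, orientation) to deduplicate, but
    # sites found only in the extension with start >= L are pure duplicates
    hits = [h for h in hits if h.start < L]
    hits.sort(key=lambda h: (h.start, h.length))
    return hits


def slice_marker_panel(
    db: ReferenceDB,
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = 3,
    min_len: int = DEFAULT_LENGTH_BOUNDS[0],
    max_len: int = DEFAULT_LENGTH_BOUNDS[1],
    *,
    circular: bool = True,
    three_prime_lock: int = 2,
) -> tuple[list[tuple[str, str]], list[str]]:
    """One marker amplicon per genome (longest in-bounds product).

    Returns ``(panel, skips)`` where panel entries are
    ``("accession|species|category", sequence)`` and skips lists accessions
    with no productive primer pair.  Ties on length break to smallest start.
    """
    if len(db) == 0:
        raise ValueError("database is empty")
    panel: list[tuple[str, str]] = []
    skips: list[str] = []
    for rec in db.records:
        products = extract_amplicons(
            rec, fwd, rev, max_mismatch, min_len, max_len,
            circular=circular, three_prime_lock=three_prime_lock,
        )
        if not products:
            skips.append(rec.accession)
            continue
        best = max(products, key=lambda h: (h.length, -h.start))
        category = db.category_of.get(rec.accession, "")
        label = f"{rec.accession}|{rec.species_name}|{category}"
        panel.append((label, best.sequence))
    return panel, skips
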