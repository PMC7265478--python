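"""Category-curated mitochondrial genome database: records, filtering, k-mer index, persistence.

The database groups reference mitogenomes into user-defined meat categories
(e.g. "Pork" spanning *Sus*) via a plain-text category map, and indexes every
genome k-mer on both strands so reads can be seeded against it without an
external aligner.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from ._seq import encode, revcomp, validate_dna, write_fasta

DB_FORMAT_VERSION = 1

#: plausible size range for a complete vertebrate mitogenome (bp)
MITOGENOME_LENGTH_GATE = (12_000, 20_500)


class CategoryMapError(ValueError):
    pass


@dataclass(frozen=True)
class GenomeRecord:
    """One reference mitochondrial genome with taxon labels for category matching."""

    accession: str
    species_name: str
    taxon_names: tuple[str, ...]
    sequence: str

    def __post_init__(self):
        if not self.accession:
            raise ValueError("accession must be non-empty")
        object.__setattr__(self, "sequence", validate_dna(self.sequence, context=f"{self.accession} sequence"))
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        object.__setattr__(self, "taxon_names", tuple(self.taxon_names))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def match_tokens(self) -> frozenset[str]:
        """Lower-cased whole tokens usable for category matching."""
        tokens = set(t.lower() for t in self.taxon_names)
        tokens.update(w.lower() for w in self.species_name.split())
        tokens.discard("")
        return frozenset(tokens)


class CategoryMap:
    """Ordered mapping from meat-category name to the taxon tokens it spans.

    Each taxon token may belong to at most one category; membership tests are
    case-insensitive whole-token matches (no fuzzy matching).
    """

    def __init__(self, categories: dict[str, Sequence[str]] | Iterable[tuple[str, Sequence[str]]]):
        items = categories.items() if isinstance(categories, dict) else categories
        self._categories: dict[str, tuple[str, ...]] = {}
        owner: dict[str, str] = {}
        for name, taxa in items:
            if name in self._categories:
                raise CategoryMapError(f"duplicate category {name!r}")
            taxa = tuple(t.strip() for t in taxa if t.strip())
            if not taxa:
                raise CategoryMapError(f"category {name!r} has no taxon names")
            for t in taxa:
                key = t.lower()
                if key in owner:
                    raise CategoryMapError(
                        f"taxon {t!r} listed under both {owner[key]!r} and {name!r}"
                    )
                owner[key] = name
            self._categories[name] = taxa
        if not self._categories:
            raise CategoryMapError("category map is empty")
        self._owner = owner

    @property
    def categories(self) -> dict[str, tuple[str, ...]]:
        return dict(self._categories)

    def names(self) -> list[str]:
        return list(self._categories)

    def __len__(self) -> int:
        return len(self._categories)

    def __contains__(self, name: str) -> bool:
        return name in self._categories

    def category_for(self, record: GenomeRecord) -> str | None:
        """Category whose taxon list intersects the record's tokens, or None."""
        cats = {self._owner[t] for t in record.match_tokens() if t in self._owner}
        if len(cats) > 1:  # unreachable if the one-owner invariant holds
            raise CategoryMapError(
                f"record {record.accession} matches multiple categories: {sorted(cats)}"
            )
        return cats.pop() if cats else None

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name, taxa in self._categories.items():
                fh.write(f"{name}: {', '.join(taxa)}\n")


def load_category_map(path) -> CategoryMap:
    """Parse a ``category: taxon1, taxon2`` config file (one category per line).

    Blank lines and ``#`` comments are ignored; load order is preserved.
    """
    entries: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise CategoryMapError(f"{path}:{lineno}: expected 'category: taxa', got {line!r}")
            name, _, rest = line.partition(":")
            entries.append((name.strip(), [t.strip() for t in rest.split(",")]))
    if not entries:
        raise CategoryMapError(f"{path}: no category entries found")
    return CategoryMap(entries)


def filter_records(
    records: Sequence[GenomeRecord], cmap: CategoryMap
) -> list[tuple[GenomeRecord, str]]:
    """Keep records whose taxa fall in some category, paired with that category.

    Order follows the input; records matching no category are dropped.
    """
    out = []
    for rec in records:
        cat = cmap.category_for(rec)
        if cat is not None:
            out.append((rec, cat))
    return out


class ReferenceDB:
    """Filtered genome set plus an exhaustive both-strand k-mer index.

    The index maps every length-k genome substring to ``(accession, plus-strand
    position, strand)`` tuples.  A minus-strand entry at position *p* means the
    reverse complement of ``genome[p:p+k]`` equals the key.  IUPAC ambiguity
    codes are indexed literally and therefore never collide with A/C/G/T
    queries.
    """

    def __init__(self, records: Sequence[GenomeRecord], category_of: dict[str, str], k: int):
        if k < 11:
            raise ValueError(f"k must be >= 11, got {k}")
        self.records = list(records)
        self.category_of = dict(category_of)
        self.k = k
        for acc in self.category_of:
            if acc not in {r.accession for r in self.records}:
                raise ValueError(f"category_of references unknown accession {acc!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)
        self._by_accession = {r.accession: r for r in self.records}
        self._encoded = {r.accession: encode(r.sequence) for r in self.records}
        self._index: dict[str, list[tuple[str, int, str]]] = {}
        self._build()

    def _build(self) -> None:
        k = self.k
        index = self._index
        for rec in self.records:
            if rec.length < k:
                raise ValueError(
                    f"k={k} exceeds length of genome {rec.accession} ({rec.length} bp)"
                )
            seq = rec.sequence
            acc = rec.accession
            for p in range(rec.length - k + 1):
                kmer = seq[p : p + k]
                index.setdefault(kmer, []).append((acc, p, "+"))
                index.setdefault(revcomp(kmer), []).append((acc, p, "-"))

    # -- queries -------------------------------------------------------------

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All (accession, position, strand) locations of *kmer* in the database."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k={self.k}")
        return list(self._index.get(kmer.upper(), ()))

    def seed_hits(self, kmer: str) -> tuple[tuple[str, int, str], ...]:
        """Internal fast-path lookup without copying (mapper hot loop)."""
        return tuple(self._index.get(kmer, ()))

    def record(self, accession: str) -> GenomeRecord:
        return self._by_accession[accession]

    def encoded(self, accession: str) -> np.ndarray:
        return self._encoded[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def __len__(self) -> int:
        return len(self.records)

    def categories(self) -> list[str]:
        seen = dict.fromkeys(self.category_of.values())
        return list(seen)


def build_index(records: Sequence[GenomeRecord], k: int, category_of: dict[str, str] | None = None) -> ReferenceDB:
    """Index *records* with k-mer size *k* (categories optional)."""
    if category_of is None:
        category_of = {}
    return ReferenceDB(records, category_of, k)


def build_reference_db(
    records: Sequence[GenomeRecord],
    cmap: CategoryMap,
    k: int = 21,
    length_gate: tuple[int, int] | None = MITOGENOME_LENGTH_GATE,
) -> ReferenceDB:
    """Filter records against the category map and index the survivors.

    Records outside *length_gate* are kept but trigger a warning — the gate
    flags inputs that are unlikely to be complete mitogenomes.  Pass
    ``length_gate=None`` to silence (e.g. for synthetic data).
    """
    kept = filter_records(records, cmap)
    if length_gate is not None:
        lo, hi = length_gate
        for rec, _ in kept:
            if not lo <= rec.length <= hi:
                warnings.warn(
                    f"{rec.accession}: length {rec.length} bp outside the expected "
                    f"complete-mitogenome range [{lo}, {hi}]",
                    stacklevel=2,
                )
    return ReferenceDB([r for r, _ in kept], {r.accession: c for r, c in kept}, k)


def read_genome_fasta(path) -> list[GenomeRecord]:
    """Load reference genomes from a multi-FASTA file.

    Header convention: ``>accession species words...``; every description word
    doubles as a taxon token for category matching.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        words = rec.description.split()
        species = " ".join(words[1:]) if len(words) > 1 else rec.id
        out.append(
            GenomeRecord(
                accession=rec.id,
                species_name=species,
                taxon_names=tuple(words[1:]),
                sequence=str(rec.seq),
            )
        )
    return out


# -- persistence -------------------------------------------------------------


def save_db(db: ReferenceDB, path) -> None:
    """Persist the database as a directory of plain-text files.

    Layout: ``genomes.fasta`` (sequences), ``manifest.csv`` (accession,
    species, taxa, category, length) and ``meta.json`` (k, format version).
    The k-mer index is rebuilt on load — it is a pure function of the inputs.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "genomes.fasta", "w") as fh:
        write_fasta(((r.accession, r.sequence) for r in db.records), fh)
    with open(path / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["accession", "species", "taxa", "category", "length"])
        for r in db.records:
            w.writerow(
                [r.accession, r.species_name, ";".join(r.taxon_names),
                 db.category_of.get(r.accession, ""), r.length]
            )
    with open(path / "meta.json", "w") as fh:
        json.dump({"format_version": DB_FORMAT_VERSION, "k": db.k}, fh)


def load_db(path) -> ReferenceDB:
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"{path}: not a meatseq database (missing meta.json)")
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta.get("format_version") != DB_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported database format version {meta.get('format_version')!r}"
        )
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path / "genomes.fasta"), "fasta")}
    records = []
    category_of = {}
    with open(path / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            acc = row["accession"]
            if acc not in seqs:
                raise ValueError(f"{path}: manifest lists {acc!r} but genomes.fasta lacks it")
            rec = GenomeRecord(
                accession=acc,
                species_name=row["species"],
                taxon_names=tuple(t for t in row["taxa"].split(";") if t),
                sequence=seqs[acc],
            )
            if int(row["length"]) != rec.length:
                raise ValueError(f"{path}: corrupted entry for {acc!r} (length mismatch)")
            records.append(rec)
            if row["category"]:
                category_of[acc] = row["category"]
    return ReferenceDB(records, category_of, int(meta["k"]))
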