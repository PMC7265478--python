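"""Low-level DNA sequence helpers shared across modules.

Conventions: sequences are uppercase strings over the IUPAC DNA alphabet;
coordinates are 0-based, half-open.  Hot paths encode sequences as
``numpy.uint8`` arrays of ASCII codes.
"""

from __future__ import annotations

import gzip
from typing import Iterable, Iterator, TextIO

import numpy as np

DNA_BASES = "ACGT"

# IUPAC code -> set of concrete bases it stands for
IUPAC_EXPAND: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_CODES = frozenset(IUPAC_EXPAND)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase *seq* and reject characters outside the IUPAC DNA alphabet."""
    seq = seq.upper()
    bad = set(seq) - IUPAC_CODES
    if bad:
        raise ValueError(f"{context} contains non-IUPAC characters: {sorted(bad)!r}")
    return seq


def encode(seq: str) -> np.ndarray:
    """ASCII-encode a sequence for vectorised comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def open_text(path, mode: str = "rt") -> TextIO:
    """Open a possibly gzip-compressed text file (sniffed by magic bytes)."""
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
        return open(path, mode)
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


class FastqFormatError(ValueError):
    """Raised for structurally invalid FASTQ records; carries the record number."""

    def __init__(self, record_number: int, message: str):
        self.record_number = record_number
        super().__init__(f"FASTQ record {record_number}: {message}")


def iter_fastq(handle: TextIO | Iterable[str]) -> Iterator[tuple[str, str, str]]:
    """Yield ``(read_id, bases, qualities)`` from a 4-line FASTQ stream.

    Strict: every record must be exactly four lines with matching
    sequence/quality lengths.  Errors report the 1-based record number.
    """
    it = iter(handle)
    n = 0
    while True:
        header = next(it, None)
        if header is None:
            return
        header = header.rstrip("\n")
        if not header:  # tolerate trailing blank lines
            for extra in it:
                if extra.strip():
                    raise FastqFormatError(n + 1, "blank line inside file")
            return
        n += 1
        if not header.startswith("@"):
            raise FastqFormatError(n, f"header does not start with '@': {header[:30]!r}")
        try:
            bases = next(it).rstrip("\n")
            plus = next(it).rstrip("\n")
            quals = next(it).rstrip("\n")
        except StopIteration:
            raise FastqFormatError(n, "truncated record") from None
        if not plus.startswith("+"):
            raise FastqFormatError(n, "missing '+' separator line")
        if len(bases) != len(quals):
            raise FastqFormatError(n, "sequence and quality lengths differ")
        if not bases:
            raise FastqFormatError(n, "empty sequence")
        yield header[1:].split()[0], bases.upper(), quals


def write_fastq(records: Iterable[tuple[str, str, str]], handle: TextIO) -> int:
    """Write ``(read_id, bases, qualities)`` records; returns the count."""
    n = 0
    for rid, bases, quals in records:
        handle.write(f"@{rid}\n{bases}\n+\n{quals}\n")
        n += 1
    return n


def write_fasta(records: Iterable[tuple[str, str]], handle: TextIO, width: int = 70) -> int:
    n = 0
    for name, seq in records:
        handle.write(f">{name}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i : i + width] + "\n")
        n += 1
    return n


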