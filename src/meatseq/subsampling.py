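"""Seeded FASTQ subsampling and the throughput/precision (RSD) study.

Default sampling mode is exact-count: exactly ``floor(N * ratio)`` reads drawn
without replacement, original order preserved.  A Bernoulli mode (each read
kept independently with probability *ratio*) is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ._seq import iter_fastq, open_text, write_fastq
from .read_classifier import MapParams, SeqRead, classify_reads
from .mixture_report import compute_proportions
from .reference_db import ReferenceDB


@dataclass
class SubsampleSpec:
    ratios: Sequence[float]
    replicates: int
    seed: int

    def __post_init__(self):
        self.ratios = tuple(self.ratios)
        if not self.ratios:
            raise ValueError("at least one ratio required")
        if any(not 0 < r <= 1 for r in self.ratios):
            raise ValueError("ratios must lie in (0, 1]")
        if list(self.ratios) != sorted(self.ratios):
            raise ValueError("ratios must be sorted ascending")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _count_records(path) -> int:
    n = 0
    with open_text(path) as fh:
        for _ in iter_fastq(fh):
            n += 1
    return n


def _selection(n_records: int, ratio: float, seed, mode: str) -> np.ndarray:
    """Boolean keep-mask over record indices, order-preserving."""
    rng = np.random.default_rng(seed)
    mask = np.zeros(n_records, dtype=bool)
    if mode == "exact":
        m = math.floor(n_records * ratio)
        mask[rng.choice(n_records, size=m, replace=False)] = True
    elif mode == "bernoulli":
        mask = rng.random(n_records) < ratio
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return mask


def subsample_fastq(path, ratio: float, seed: int, out_path, *, mode: str = "exact") -> int:
    """Randomly extract reads from a FASTQ file into *out_path*; returns the count kept.

    Two passes: count records, draw the selection, then stream records through
    in order.  Identical seed and input give identical output.
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must lie in (0, 1]")
    n = _count_records(path)
    mask = _selection(n, ratio, seed, mode)
    with open_text(path) as fh, open_text(out_path, "wt") as out:
        kept = write_fastq(
            (rec for i, rec in enumerate(iter_fastq(fh)) if mask[i]), out
        )
    return kept


def iter_subsample(path, ratio: float, seed, *, mode: str = "exact") -> Iterator[SeqRead]:
    """Stream the subsampled reads without writing an intermediate file."""
    n = _count_records(path)
    mask = _selection(n, ratio, seed, mode)
    with open_text(path) as fh:
        for i, (rid, bases, quals) in enumerate(iter_fastq(fh)):
            if mask[i]:
                yield SeqRead(rid, bases, quals)


def replicate_seed(base_seed: int, ratio: float, replicate: int) -> np.random.SeedSequence:
    """Deterministic per-(ratio, replicate) seed, disjoint across the grid."""
    return np.random.SeedSequence([int(base_seed), int(round(ratio * 10**9)), int(replicate)])


def rsd_study(
    path,
    db: ReferenceDB,
    spec: SubsampleSpec,
    params: MapParams | None = None,
    *,
    mode: str = "exact",
) -> pd.DataFrame:
    """Subsample-classify-aggregate study of throughput vs precision.

    For each ratio x replicate: draw a subsample (seed derived from
    ``spec.seed``), classify it, and record per-category percentages.  The
    result has one row per (ratio, category) with columns ``mean_pct``,
    ``sd_pct`` (sample SD, n-1), ``rsd_pct`` (= sd/mean*100, NaN when the mean
    is 0) and ``n_reads_mean``.
    """
    rows = []
    for ratio in spec.ratios:
        results = []
        for rep in range(spec.replicates):
            reads = iter_subsample(path, ratio, replicate_seed(spec.seed, ratio, rep), mode=mode)
            counts = classify_reads(reads, db, params)
            results.append((counts, compute_proportions(counts)))
        cats = sorted({c for _, res in results for c in res.categories()})
        for cat in cats:
            pcts = np.array([res.exact_proportion(cat) for _, res in results])
            nreads = np.array([counts.counts.get(cat, 0) for counts, _ in results])
            mean = float(pcts.mean())
            sd = float(pcts.std(ddof=1)) if len(pcts) > 1 else 0.0
            rows.append(
                {
                    "ratio": ratio,
                    "category": cat,
                    "mean_pct": mean,
                    "sd_pct": sd,
                    "rsd_pct": sd / mean * 100.0 if mean > 0 else float("nan"),
                    "n_reads_mean": float(nreads.mean()),
                }
            )
    return pd.DataFrame(rows, columns=["ratio", "category", "mean_pct", "sd_pct", "rsd_pct", "n_reads_mean"])
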