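"""Reporting: proportions, target comparisons, presence calls, concordance, depth.

Percentages are rounded half-up to two decimals at presentation, mirroring how
such results are conventionally printed; all internal arithmetic is unrounded
except where a derived quantity (difference, relative difference) is defined
on the printed values themselves.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .read_classifier import CategoryCounts

#: default qualitative call threshold, % of mapped unique reads
DEFAULT_PRESENCE_THRESHOLD = 0.5


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (unlike Python's banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ResultRow:
    category: str
    reads_mapped: int
    proportion_pct: float  # rounded to 2 decimals


@dataclass
class IdentificationResult:
    """Per-category unique-read tallies with percentage of mapped reads.

    The denominator is the sum of per-category counts; discarded and unmapped
    reads are excluded.  Rows are sorted by reads_mapped descending (ties by
    name) and carry presentation-rounded percentages; ``exact_proportion``
    exposes the unrounded value.
    """

    rows: list[ResultRow]
    denominator: int

    def exact_proportion(self, category: str) -> float:
        for row in self.rows:
            if row.category == category:
                return row.reads_mapped / self.denominator * 100.0
        return 0.0

    def proportion(self, category: str) -> float:
        for row in self.rows:
            if row.category == category:
                return row.proportion_pct
        return 0.0

    def categories(self) -> list[str]:
        return [r.category for r in self.rows]


@dataclass(frozen=True)
class ComparisonRow:
    category: str
    target_pct: float
    measured_pct: float
    diff_abs_pct: float
    diff_rel_pct: float | None  # None when target is 0 (undefined)


@dataclass(frozen=True)
class PresenceCall:
    sample_id: str
    category: str
    call: str  # '+' or '-'
    threshold_pct: float


@dataclass(frozen=True)
class ConcordanceResult:
    tp: int
    fp: int
    fn: int
    tn: int
    tpr: float | None  # % ; None when tp+fn == 0
    fpr: float | None  # % ; None when fp+tn == 0
    fnr: float | None


def compute_proportions(counts: CategoryCounts) -> IdentificationResult:
    """Percentage of mapped unique reads per category (discarded/unmapped excluded)."""
    denom = sum(counts.counts.values())
    ordered = sorted(counts.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = [
        ResultRow(cat, n, round_half_up(n / denom * 100.0))
        for cat, n in ordered
    ] if denom > 0 else []
    return IdentificationResult(rows, denom)


def target_from_concentrations(conc: Mapping[str, float]) -> dict[str, float]:
    """Convert per-category DNA concentrations (ng/uL) to percentages."""
    if any(v < 0 for v in conc.values()):
        raise ValueError("concentrations must be >= 0")
    total = sum(conc.values())
    if total <= 0:
        raise ValueError("concentrations sum to zero")
    return {cat: round_half_up(v / total * 100.0) for cat, v in conc.items()}


def compare_to_target(
    result: IdentificationResult, target: Mapping[str, float]
) -> list[ComparisonRow]:
    """Absolute and relative differences between measured and target percentages.

    Differences are taken on the presentation-rounded values, matching how
    such tables are printed; a category missing on either side counts as 0 and
    the relative difference is undefined (None) for a zero target.
    """
    cats = list(result.categories())
    cats.extend(c for c in target if c not in cats)
    out = []
    for cat in cats:
        t = round_half_up(float(target.get(cat, 0.0)))
        m = result.proportion(cat)
        diff_abs = round_half_up(abs(t - m))
        diff_rel = round_half_up(diff_abs / t * 100.0) if t > 0 else None
        out.append(ComparisonRow(cat, t, m, diff_abs, diff_rel))
    return out


def call_presence(
    result: IdentificationResult,
    threshold_pct: float = DEFAULT_PRESENCE_THRESHOLD,
    *,
    sample_id: str = "sample",
    categories: Sequence[str] | None = None,
) -> list[PresenceCall]:
    """Qualitative +/- call per category: + iff proportion >= threshold.

    *categories* extends the call universe (absent categories are called -);
    by default only categories present in the result are called.
    """
    if not 0 <= threshold_pct <= 100:
        raise ValueError("threshold must be in [0, 100]")
    cats = list(result.categories())
    if categories is not None:
        cats.extend(c for c in categories if c not in cats)
    return [
        PresenceCall(sample_id, cat, "+" if result.proportion(cat) >= threshold_pct else "-",
                     threshold_pct)
        for cat in cats
    ]


def compute_concordance(
    test_calls: Sequence[PresenceCall], ref_calls: Sequence[PresenceCall]
) -> ConcordanceResult:
    """TP/FP/FN/TN of test vs reference calls over a shared (sample, category) universe.

    Rates: TPR = TP/(TP+FN), FPR = FP/(FP+TN), FNR = FN/(TP+FN), as
    percentages rounded to 2 decimals; a rate with a zero denominator is
    reported as None (undefined) rather than 0.
    """
    tmap = {(c.sample_id, c.category): c.call for c in test_calls}
    rmap = {(c.sample_id, c.category): c.call for c in ref_calls}
    if set(tmap) != set(rmap):
        missing = set(tmap) ^ set(rmap)
        raise ValueError(f"call universes differ on {sorted(missing)}")
    tp = fp = fn = tn = 0
    for key, t in tmap.items():
        r = rmap[key]
        if t == "+" and r == "+":
            tp += 1
        elif t == "+" and r == "-":
            fp += 1
        elif t == "-" and r == "+":
            fn += 1
        else:
            tn += 1

    def rate(num: int, den: int) -> float | None:
        return round_half_up(num / den * 100.0) if den > 0 else None

    return ConcordanceResult(tp, fp, fn, tn, rate(tp, tp + fn), rate(fp, fp + tn), rate(fn, tp + fn))


def mean_depth(total_aligned_bases: int, region_length: int) -> float:
    """Fold coverage: aligned bases divided by region length."""
    if region_length <= 0:
        raise ValueError("region_length must be > 0")
    return total_aligned_bases / region_length


# -- CSV output --------------------------------------------------------------


def _fmt_pct(x: float | None) -> str:
    return "" if x is None else f"{x:.2f}"


def write_result_csv(obj, path) -> None:
    """Write a result/comparison/call list/concordance object as RFC-4180 CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        if isinstance(obj, IdentificationResult):
            w.writerow(["category", "reads_mapped", "proportion_pct"])
            for r in obj.rows:
                w.writerow([r.category, r.reads_mapped, _fmt_pct(r.proportion_pct)])
        elif isinstance(obj, ConcordanceResult):
            w.writerow(["tp", "fp", "fn", "tn", "tpr_pct", "fpr_pct", "fnr_pct"])
            w.writerow([obj.tp, obj.fp, obj.fn, obj.tn,
                        _fmt_pct(obj.tpr), _fmt_pct(obj.fpr), _fmt_pct(obj.fnr)])
        elif obj and isinstance(obj[0], ComparisonRow):
            w.writerow(["category", "target_pct", "measured_pct", "diff_abs_pct", "diff_rel_pct"])
            for r in obj:
                w.writerow([r.category, _fmt_pct(r.target_pct), _fmt_pct(r.measured_pct),
                            _fmt_pct(r.diff_abs_pct), _fmt_pct(r.diff_rel_pct)])
        elif obj and isinstance(obj[0], PresenceCall):
            w.writerow(["sample_id", "category", "call", "threshold_pct"])
            for r in obj:
                w.writerow([r.sample_id, r.category, r.call, _fmt_pct(r.threshold_pct)])
        elif isinstance(obj, (list, tuple)) and not obj:
            w.writerow(["category", "reads_mapped", "proportion_pct"])
        else:
            raise TypeError(f"cannot serialise {type(obj).__name__} to CSV")
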