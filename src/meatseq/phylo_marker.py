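"""Marker-resolution assessment: distances, neighbor-joining, category coherence.

Distances are p-distance (optionally Jukes-Cantor transformed) over a
center-star end-gap alignment — adequate for near-equal-length homologous
amplicons.  The tree is built by canonical Saitou-Nei neighbor joining with a
deterministic tie-break, written and re-read as Newick.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._seq import DNA_BASES

logger = logging.getLogger(__name__)

_ACGT = frozenset(DNA_BASES)


def p_distance(a: str, b: str, *, model: str = "p") -> float:
    """Proportion of differing sites between two equal-length sequences.

    Sites where either sequence holds a non-A/C/G/T character (gap, N, other
    ambiguity) are excluded.  ``model="jc"`` applies the Jukes-Cantor
    correction ``-(3/4) * ln(1 - 4p/3)``.
    """
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length ({len(a)} vs {len(b)})")
    a, b = a.upper(), b.upper()
    compared = mismatches = 0
    for x, y in zip(a, b):
        if x in _ACGT and y in _ACGT:
            compared += 1
            if x != y:
                mismatches += 1
    if compared == 0:
        raise ValueError("no comparable (A/C/G/T vs A/C/G/T) sites")
    p = mismatches / compared
    if model == "p":
        return p
    if model == "jc":
        if p >= 0.75:
            raise ValueError(f"p-distance {p:.3f} >= 0.75: Jukes-Cantor undefined")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    raise ValueError(f"unknown model {model!r}")


def align_amplicons(seqs: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """End-gap-only center-star alignment of near-equal-length amplicons.

    The longest sequence is the center; every other sequence is slid along it
    ungapped, placed at the offset minimising mismatches, and padded with end
    gaps.  Sufficient for homologous products of one primer pair; not a
    general MSA.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return list(seqs)
    center_i = max(range(len(seqs)), key=lambda i: len(seqs[i][1]))
    center = seqs[center_i][1].upper()
    ccodes = np.frombuffer(center.encode(), dtype=np.uint8)
    out: list[tuple[str, str]] = []
    for name, seq in seqs:
        seq = seq.upper()
        if len(seq) == len(center):
            out.append((name, seq))
            continue
        scodes = np.frombuffer(seq.encode(), dtype=np.uint8)
        best_off, best_mm = 0, len(seq) + 1
        for off in range(len(center) - len(seq) + 1):
            mm = int(np.count_nonzero(ccodes[off : off + len(seq)] != scodes))
            if mm < best_mm:
                best_off, best_mm = off, mm
        out.append((name, "-" * best_off + seq + "-" * (len(center) - len(seq) - best_off)))
    return out


def drop_gappy_columns(rows: Sequence[tuple[str, str]], max_gap_frac: float = 0.5) -> list[tuple[str, str]]:
    """Remove alignment columns where more than *max_gap_frac* of rows are gaps."""
    if not rows:
        return []
    ncol = len(rows[0][1])
    keep = []
    for j in range(ncol):
        gaps = sum(1 for _, s in rows if s[j] == "-")
        if gaps / len(rows) <= max_gap_frac:
            keep.append(j)
    return [(name, "".join(s[j] for j in keep)) for name, s in rows]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not fit {n} labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")

    @classmethod
    def from_alignment(cls, rows: Sequence[tuple[str, str]], *, model: str = "p") -> "DistanceMatrix":
        labels = [name for name, _ in rows]
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = p_distance(rows[i][1], rows[j][1], model=model)
        return cls(labels, d)


# -- tree structure ----------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Unrooted tree (stored with a trifurcating root) with Newick I/O."""

    def __init__(self, root: TreeNode, n_clamped: int = 0):
        self.root = root
        self.n_clamped = n_clamped  # negative NJ branch estimates clamped to 0

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf():
                out.append(node.name or "")
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def bipartitions(self) -> list[frozenset[str]]:
        """Leaf set on the child side of every internal edge."""
        parts: list[frozenset[str]] = []

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.name or ""])
            below = frozenset()
            for child, _ in node.children:
                sub = walk(child)
                parts.append(sub)
                below |= sub
            return below

        walk(self.root)
        return parts

    # Newick ------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return _quote_label(node.name or "")
            inner = ",".join(f"{fmt(c)}:{bl:.6f}" for c, bl in node.children)
            return f"({inner})"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        text = text.strip()
        if not text.endswith(";"):
            raise ValueError("Newick string must end with ';'")
        pos = 0
        s = text[:-1]

        def parse_node() -> TreeNode:
            nonlocal pos
            node = TreeNode()
            if pos < len(s) and s[pos] == "(":
                pos += 1
                while True:
                    child = parse_node()
                    bl = 0.0
                    if pos < len(s) and s[pos] == ":":
                        pos += 1
                        start = pos
                        while pos < len(s) and s[pos] not in ",()[]:;":
                            pos += 1
                        bl = float(s[start:pos])
                    node.children.append((child, bl))
                    if pos < len(s) and s[pos] == ",":
                        pos += 1
                        continue
                    if pos < len(s) and s[pos] == ")":
                        pos += 1
                        break
                    raise ValueError(f"malformed Newick near offset {pos}")
            # optional label (internal or leaf)
            if pos < len(s) and s[pos] == "'":
                pos += 1
                start = pos
                label = []
                while pos < len(s):
                    if s[pos] == "'" and pos + 1 < len(s) and s[pos + 1] == "'":
                        label.append("'")
                        pos += 2
                        continue
                    if s[pos] == "'":
                        break
                    label.append(s[pos])
                    pos += 1
                pos += 1
                node.name = "".join(label)
            else:
                start = pos
                while pos < len(s) and s[pos] not in ",()[]:;":
                    pos += 1
                if pos > start:
                    node.name = s[start:pos]
            return node

        root = parse_node()
        if pos != len(s):
            raise ValueError(f"trailing characters in Newick at offset {pos}")
        return cls(root)


def _quote_label(label: str) -> str:
    if any(c in label for c in " ,():;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# -- neighbor joining --------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining.

    Repeatedly joins the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j;
    ties break to the lexicographically smallest pair of representative labels
    (smallest leaf label in each cluster).  Negative branch-length estimates
    are clamped to zero and counted on the returned tree.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    active: list[int] = list(range(n))
    nodes: dict[int, TreeNode] = {i: TreeNode(name=dm.labels[i]) for i in range(n)}
    reprs: dict[int, str] = {i: dm.labels[i] for i in range(n)}
    D: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(dm.d[i, j])
    next_id = n
    n_clamped = 0

    def dist(i: int, j: int) -> float:
        return D[(i, j) if i < j else (j, i)]

    def clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0:
            n_clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, j) for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                tie = tuple(sorted((reprs[i], reprs[j])))
                key = (q, tie)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = dist(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        u = next_id
        next_id += 1
        nodes[u] = TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        reprs[u] = min(reprs[i], reprs[j])
        for k in active:
            if k in (i, j):
                continue
            D[(min(u, k), max(u, k))] = 0.5 * (dist(i, k) + dist(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    dij, dik, djk = dist(i, j), dist(i, k), dist(j, k)
    li = 0.5 * (dij + dik - djk)
    lj = 0.5 * (dij + djk - dik)
    lk = 0.5 * (dik + djk - dij)
    order = sorted([(reprs[i], i, li), (reprs[j], j, lj), (reprs[k], k, lk)])
    root = TreeNode(children=[(nodes[idx], clamp(bl)) for _, idx, bl in order])
    tree = PhyloTree(root, n_clamped=n_clamped)
    if n_clamped:
        logger.info("clamped %d negative branch length estimate(s) to 0", n_clamped)
    return tree


# -- category coherence ------------------------------------------------------


def leaf_category(label: str) -> str:
    """Category component of an ``accession|species|category`` leaf label."""
    parts = label.split("|")
    return parts[-1] if len(parts) >= 3 else label


def category_coherence(tree: PhyloTree) -> tuple[float, dict[str, bool]]:
    """Fraction of categories forming a clade under some edge bipartition.

    Treats the tree as unrooted: a category with leaf set S is coherent when
    some edge splits the leaves into exactly (S, rest).  Single-leaf
    categories are coherent by convention.
    """
    leaves = tree.leaves()
    all_leaves = frozenset(leaves)
    by_cat: dict[str, set[str]] = {}
    for leaf in leaves:
        by_cat.setdefault(leaf_category(leaf), set()).add(leaf)
    if not by_cat:
        raise ValueError("tree has no leaves")
    splits = set()
    for part in tree.bipartitions():
        splits.add(part)
        splits.add(all_leaves - part)
    verdicts = {}
    for cat, members in by_cat.items():
        verdicts[cat] = len(members) == 1 or frozenset(members) in splits
    frac = sum(verdicts.values()) / len(verdicts)
    return frac, verdicts


def build_marker_tree(
    seqs: Sequence[tuple[str, str]], *, model: str = "p"
) -> tuple[PhyloTree, DistanceMatrix]:
    """Align amplicons, compute distances, and return the NJ tree."""
    aligned = drop_gappy_columns(align_amplicons(seqs))
    dm = DistanceMatrix.from_alignment(aligned, model=model)
    return nj_tree(dm), dm
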