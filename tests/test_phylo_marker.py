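import itertools
import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, strategies as st

from meatseq.insilico_pcr import PRESETS
from meatseq.phylo_marker import (
    DistanceMatrix,
    PhyloTree,
    align_amplicons,
    build_marker_tree,
    category_coherence,
    drop_gappy_columns,
    nj_tree,
    p_distance,
)
from meatseq.reference_db import build_reference_db
from meatseq.insilico_pcr import slice_marker_panel
from meatseq.synth_fixtures import CategorySpec, SynthWorld, make_world

from conftest import random_dna


# -- p_distance --------------------------------------------------------------


def test_identical_sequences_zero():
    assert p_distance("ACGTACGT", "ACGTACGT") == 0.0


def test_one_mismatch_in_four():
    assert p_distance("ACGT", "ACGA") == 0.25


def test_matches_per_site_oracle(rng):
    a = random_dna(rng, 300)
    b = "".join(
        c if rng.random() > 0.1 else "ACGT"[int(rng.integers(4))] for c in a
    )
    naive = sum(x != y for x, y in zip(a, b)) / 300
    assert p_distance(a, b) == naive


def test_non_acgt_sites_excluded():
    assert p_distance("ACG-T", "ACGAT") == 0.0  # gap column dropped, 4 compared
    assert p_distance("ANGT", "AAGT") == 0.0


def test_no_comparable_sites_raises():
    with pytest.raises(ValueError):
        p_distance("NNNN", "ACGT")


def test_length_mismatch_raises():
    with pytest.raises(ValueError):
        p_distance("ACGT", "ACG")


def test_jukes_cantor_transform():
    p = 0.25
    expected = -0.75 * math.log(1 - 4 * p / 3)
    assert math.isclose(p_distance("AAAA", "AAAC", model="jc"), expected)


def test_jukes_cantor_saturation_raises():
    with pytest.raises(ValueError):
        p_distance("AAAA", "CCCC", model="jc")


@given(st.integers(0, 2**32 - 1))
def test_p_distance_metric_spot_checks(seed):
    r = np.random.default_rng(seed)
    seqs = ["".join("ACGT"[i] for i in r.integers(0, 4, 30)) for _ in range(3)]
    a, b, c = seqs
    assert p_distance(a, b) == p_distance(b, a)
    assert p_distance(a, a) == 0.0
    assert p_distance(a, c) <= p_distance(a, b) + p_distance(b, c) + 1e-12


# -- alignment ---------------------------------------------------------------


def test_equal_length_identical_unchanged():
    seqs = [("a", "ACGTACGT"), ("b", "ACGTACGT")]
    assert align_amplicons(seqs) == seqs


def test_terminal_base_gets_end_gap():
    rows = dict(align_amplicons([("a", "ACGTACGTA"), ("b", "CGTACGTA")]))
    assert rows["a"] == "ACGTACGTA"
    assert rows["b"] == "-CGTACGTA"


def test_alignment_rows_equal_length(rng):
    seqs = [(f"s{i}", random_dna(rng, 280 + int(rng.integers(0, 40)))) for i in range(5)]
    rows = align_amplicons(seqs)
    assert len({len(s) for _, s in rows}) == 1


def test_empty_input_raises():
    with pytest.raises(ValueError):
        align_amplicons([])


def test_drop_gappy_columns():
    rows = [("a", "A-CG"), ("b", "A-CG"), ("c", "AACG")]
    trimmed = drop_gappy_columns(rows, 0.5)
    assert [s for _, s in trimmed] == ["ACG", "ACG", "ACG"]


def test_simulated_amplicon_distances_near_truth(rng):
    # mutate a root at known per-site rates; center-star alignment (no indels)
    # must recover pairwise distances within 0.02
    root = random_dna(rng, 350)

    def mutate(seq, rate):
        return "".join(
            "ACGT"[("ACGT".index(c) + 1 + int(rng.integers(3))) % 4] if rng.random() < rate else c
            for c in seq
        )

    leaves = [(f"l{i}", mutate(root, 0.05)) for i in range(5)]
    aligned = align_amplicons(leaves)
    for (n1, s1), (n2, s2) in itertools.combinations(aligned, 2):
        true_frac = sum(
            x != y for x, y in zip(dict(leaves)[n1], dict(leaves)[n2])
        ) / 350
        assert abs(p_distance(s1, s2) - true_frac) < 0.02


# -- DistanceMatrix ----------------------------------------------------------


def test_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[1.0, 0.0], [0.0, 0.0]]))  # nonzero diag


# -- neighbor joining --------------------------------------------------------


def tree_splits(tree: PhyloTree) -> set[frozenset]:
    """Non-trivial bipartitions (each as the smaller-side frozenset pair)."""
    leaves = frozenset(tree.leaves())
    out = set()
    for part in tree.bipartitions():
        if 1 < len(part) < len(leaves) - 1:
            out.add(frozenset((part, leaves - part)))
    return out


def make_additive(rng, labels):
    """Random additive tree: returns (splits, DistanceMatrix) built by
    simulating a random binary tree and summing path lengths."""
    # cluster-merge construction: each cluster tracks leaf -> distance to its root
    forest = [({name: 0.0}, frozenset([name])) for name in labels]
    dist = {}
    splits = set()
    while len(forest) > 1:
        idx = sorted(rng.choice(len(forest), size=2, replace=False))
        (da, sa), (db, sb) = forest[idx[0]], forest[idx[1]]
        bla, blb = float(rng.uniform(0.5, 3.0)), float(rng.uniform(0.5, 3.0))
        for x, dx in da.items():
            for y, dy in db.items():
                dist[frozenset((x, y))] = dx + bla + dy + blb
        merged = {k: v + bla for k, v in da.items()}
        merged.update({k: v + blb for k, v in db.items()})
        forest = [forest[i] for i in range(len(forest)) if i not in idx]
        forest.append((merged, sa | sb))
        if len(forest) > 1:
            splits.add(sa | sb)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dist[frozenset((labels[i], labels[j]))]
    all_leaves = frozenset(labels)
    canon = {
        frozenset((s, all_leaves - s))
        for s in splits
        if 1 < len(s) < n - 1
    }
    return canon, DistanceMatrix(list(labels), d)


def test_three_taxon_closed_form():
    d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    tree = nj_tree(DistanceMatrix(["A", "B", "C"], d))
    bl = {c.name: l for c, l in tree.root.children}
    # three-point equations: a = (dAB+dAC-dBC)/2 etc.
    assert math.isclose(bl["A"], 1.0)
    assert math.isclose(bl["B"], 2.0)
    assert math.isclose(bl["C"], 3.0)


def fit_topology_residual(dm, split):
    """Least-squares check used as an independent oracle for 4 taxa: an
    additive matrix satisfies the four-point condition for the true split."""
    (a, b), (c, d) = split
    i = {l: k for k, l in enumerate(dm.labels)}
    s1 = dm.d[i[a], i[b]] + dm.d[i[c], i[d]]
    s2 = dm.d[i[a], i[c]] + dm.d[i[b], i[d]]
    s3 = dm.d[i[a], i[d]] + dm.d[i[b], i[c]]
    return s1, s2, s3


def test_four_taxon_additive_recovers_ab_cd():
    # tree ((A:1,B:2):1,(C:3,D:4)) -> path-length matrix
    d = np.array(
        [
            [0.0, 3.0, 5.0, 6.0],
            [3.0, 0.0, 6.0, 7.0],
            [5.0, 6.0, 0.0, 7.0],
            [6.0, 7.0, 7.0, 0.0],
        ]
    )
    dm = DistanceMatrix(["A", "B", "C", "D"], d)
    # four-point oracle over the 3 possible splits: AB|CD minimises the sum
    sums = {
        "AB|CD": d[0, 1] + d[2, 3],
        "AC|BD": d[0, 2] + d[1, 3],
        "AD|BC": d[0, 3] + d[1, 2],
    }
    assert min(sums, key=sums.get) == "AB|CD"
    tree = nj_tree(dm)
    split = tree_splits(tree)
    assert split == {frozenset((frozenset("AB"), frozenset("CD")))}


@pytest.mark.parametrize("n_leaves", [4, 5, 6, 8, 10])
def test_nj_recovers_random_additive_trees(n_leaves, rng):
    labels = [f"L{i}" for i in range(n_leaves)]
    for _ in range(5):
        true_splits, dm = make_additive(rng, labels)
        tree = nj_tree(dm)
        assert tree_splits(tree) == true_splits
        assert sorted(tree.leaves()) == sorted(labels)


@pytest.mark.parametrize("n_leaves", [4, 5])
def test_nj_matches_exhaustive_topology_search(n_leaves, rng):
    # enumerate all unrooted topologies; the generating one is the only one
    # whose quartets all satisfy the four-point condition
    labels = [f"L{i}" for i in range(n_leaves)]
    true_splits, dm = make_additive(rng, labels)
    i = {l: k for k, l in enumerate(labels)}

    def quartet_ok(split):
        (side_a, side_b) = split
        for a, b in itertools.combinations(sorted(side_a), 2):
            for c, d in itertools.combinations(sorted(side_b), 2):
                s_ab = dm.d[i[a], i[b]] + dm.d[i[c], i[d]]
                s_ac = dm.d[i[a], i[c]] + dm.d[i[b], i[d]]
                s_ad = dm.d[i[a], i[d]] + dm.d[i[b], i[c]]
                if not (s_ab <= s_ac + 1e-9 and s_ab <= s_ad + 1e-9):
                    return False
        return True

    all_leaves = frozenset(labels)
    candidate_splits = [
        frozenset((frozenset(s), all_leaves - frozenset(s)))
        for r in range(2, n_leaves - 1)
        for s in itertools.combinations(labels, r)
    ]
    consistent = {s for s in set(candidate_splits) if quartet_ok(tuple(s))}
    assert consistent == true_splits  # oracle isolates the generating topology
    assert tree_splits(nj_tree(dm)) == consistent


def test_degenerate_equal_distances_deterministic():
    labels = ["A", "B", "C", "D", "E"]
    d = np.ones((5, 5)) - np.eye(5)
    dm = DistanceMatrix(labels, d)
    t1, t2 = nj_tree(dm), nj_tree(dm)
    assert t1.to_newick() == t2.to_newick()
    assert sorted(t1.leaves()) == labels


def test_negative_branch_clamped():
    # a matrix engineered to give a negative NJ branch estimate
    d = np.array(
        [
            [0.0, 1.0, 5.0, 5.0],
            [1.0, 0.0, 5.0, 5.0],
            [5.0, 5.0, 0.0, 0.5],
            [5.0, 5.0, 0.5, 0.0],
        ]
    )
    tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))

    def min_bl(node):
        if not node.children:
            return float("inf")
        return min(min(bl for _, bl in node.children), min(min_bl(c) for c, _ in node.children))

    assert min_bl(tree.root) >= 0.0


# -- Newick ------------------------------------------------------------------


def test_newick_roundtrip_preserves_topology_and_lengths():
    d = np.array(
        [
            [0.0, 3.0, 5.0, 6.0],
            [3.0, 0.0, 6.0, 7.0],
            [5.0, 6.0, 0.0, 7.0],
            [6.0, 7.0, 7.0, 0.0],
        ]
    )
    tree = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
    text = tree.to_newick()
    back = PhyloTree.from_newick(text)
    assert back.to_newick() == text
    assert tree_splits(back) == tree_splits(tree)


def test_newick_readable_by_dendropy(small_world, small_db):
    fwd, rev = PRESETS["cytb"]
    panel, _ = slice_marker_panel(small_db, fwd, rev)
    tree, _ = build_marker_tree(panel)
    dtree = dendropy.Tree.get(data=tree.to_newick(), schema="newick", preserve_underscores=True)
    assert sorted(t.label for t in dtree.taxon_namespace) == sorted(tree.leaves())


def test_quoted_labels_roundtrip():
    tree = PhyloTree.from_newick("('a b':1.0,'c,d':2.0,e:0.5);")
    assert sorted(tree.leaves()) == ["a b", "c,d", "e"]
    assert PhyloTree.from_newick(tree.to_newick()).leaves() == tree.leaves()


def test_nj_too_few_labels():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]])))


# -- category coherence ------------------------------------------------------


def leaf(acc, cat):
    return f"{acc}|{acc}_sp|{cat}"


def test_divergent_categories_fully_coherent(small_world, small_db):
    fwd, rev = PRESETS["cytb"]
    panel, _ = slice_marker_panel(small_db, fwd, rev)
    tree, _ = build_marker_tree(panel)
    frac, verdicts = category_coherence(tree)
    assert frac == 1.0
    assert set(verdicts) == {"Pork", "Beef", "Mutton"}


def test_single_leaf_categories_coherent():
    nwk = f"(({leaf('a', 'X')}:1,{leaf('b', 'Y')}:1):1,{leaf('c', 'Z')}:1,{leaf('d', 'X')}:1);"
    tree = PhyloTree.from_newick(nwk)
    frac, verdicts = category_coherence(tree)
    assert verdicts["Y"] and verdicts["Z"]
    assert not verdicts["X"]  # a,d separated by b


def test_randomized_labels_match_bipartition_oracle(rng):
    # random tree over 12 leaves with random category labels; compare against
    # an exhaustive check over dendropy-extracted bipartitions
    labels = [leaf(f"t{i}", f"C{int(rng.integers(3))}") for i in range(12)]
    canon, dm = make_additive(rng, labels)
    tree = nj_tree(dm)
    frac, verdicts = category_coherence(tree)

    dtree = dendropy.Tree.get(data=tree.to_newick(), schema="newick", preserve_underscores=True)
    dtree.encode_bipartitions()
    sides = set()
    taxa = frozenset(t.label for t in dtree.taxon_namespace)
    for edge in dtree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        side = frozenset(t.label for t in dtree.taxon_namespace
                         if edge.bipartition.leafset_bitmask & dtree.taxon_namespace.taxon_bitmask(t))
        sides.add(side)
        sides.add(taxa - side)
    by_cat = {}
    for l in labels:
        by_cat.setdefault(l.split("|")[2], set()).add(l)
    for cat, members in by_cat.items():
        expected = len(members) == 1 or frozenset(members) in sides
        assert verdicts[cat] == expected
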