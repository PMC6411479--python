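"""Distances, neighbor joining, bootstrap supports, midpoint rooting."""

import math

import numpy as np
import pytest

from conftest import make_alignment
from egt_screen.phylo import (
    DistanceMatrix,
    bootstrap_supports,
    midpoint_root,
    neighbor_joining,
    pairwise_distances,
)
from egt_screen.trees import Node, PhyloTree


def random_tree(rng, n, blen=(0.1, 1.0)):
    nodes = [Node(name=f"L{i}") for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False), reverse=True)
        p = Node()
        a, b = nodes.pop(int(i)), nodes.pop(int(j))
        a.length = float(rng.uniform(*blen))
        b.length = float(rng.uniform(*blen))
        p.add(a)
        p.add(b)
        nodes.append(p)
    root = Node()
    for x in nodes:
        x.length = float(rng.uniform(*blen))
        root.add(x)
    return PhyloTree(root, rooted=False)


def path_distance_matrix(tree):
    from egt_screen.phylo import _adjacency, _farthest

    adj, _ = _adjacency(tree)
    leaves = tree.leaves()
    ids = [lf.name for lf in leaves]
    mat = np.zeros((len(ids), len(ids)))
    for i, lf in enumerate(leaves):
        d, _ = _farthest(adj, id(lf))
        for j, lf2 in enumerate(leaves):
            mat[i, j] = d[id(lf2)]
    return DistanceMatrix(ids, mat)


# -- distances --------------------------------------------------------------


def test_identical_rows_zero_distance():
    aln = make_alignment("f", [("a", "MKLV"), ("b", "MKLV"), ("c", "MKLV")])
    dm = pairwise_distances(aln)
    assert np.allclose(dm.matrix, 0)


def test_poisson_and_kimura_closed_forms():
    aln = make_alignment("f", [("a", "AAAA"), ("b", "AAAV")])
    p = 0.25
    dm = pairwise_distances(aln, correction="p_distance")
    assert dm.matrix[0, 1] == pytest.approx(p)
    dm = pairwise_distances(aln, correction="poisson")
    assert dm.matrix[0, 1] == pytest.approx(-math.log(0.75))
    dm = pairwise_distances(aln, correction="kimura_protein")
    assert dm.matrix[0, 1] == pytest.approx(-math.log(1 - p - p * p / 5))


def test_saturated_pair_capped_with_warning():
    aln = make_alignment("f", [("a", "AAAAAAAAAA"), ("b", "VVVVVVVVVC")])
    with pytest.warns(UserWarning, match="capped"):
        dm = pairwise_distances(aln)
    assert dm.matrix[0, 1] == 10.0


def test_pairwise_deletion_and_incomparable_pair():
    aln = make_alignment("f", [("a", "MK--"), ("b", "M-K-"), ("c", "MKKK")])
    with pytest.raises(ValueError, match="comparable"):
        # a vs b share only column 0? column 0 M/M comparable -> fine;
        # make them fully disjoint instead
        pairwise_distances(
            make_alignment("g", [("a", "MK--"), ("b", "--KV"), ("c", "MKKV")])
        )
    dm = pairwise_distances(aln)
    assert dm.matrix[0, 1] == 0.0  # only the M column is comparable


# -- neighbor joining -------------------------------------------------------


def test_nj_recovers_additive_topologies():
    rng = np.random.default_rng(11)
    for _ in range(20):
        t = random_tree(rng, int(rng.integers(5, 9)))
        nj = neighbor_joining(path_distance_matrix(t))
        assert nj.bipartitions() == t.bipartitions()


def test_nj_three_leaves_closed_form():
    ids = ["a", "b", "c"]
    mat = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
    tree = neighbor_joining(DistanceMatrix(ids, mat))
    depth = {lf.name: lf.length for lf in tree.leaves()}
    assert depth["a"] == pytest.approx(1.0)  # (3+4-5)/2
    assert depth["b"] == pytest.approx(2.0)
    assert depth["c"] == pytest.approx(3.0)


def test_nj_leaf_order_invariance():
    rng = np.random.default_rng(13)
    t = random_tree(rng, 7)
    dm = path_distance_matrix(t)
    perm = rng.permutation(len(dm.ids))
    dm2 = DistanceMatrix(
        [dm.ids[i] for i in perm], dm.matrix[np.ix_(perm, perm)]
    )
    assert neighbor_joining(dm).bipartitions() == \
        neighbor_joining(dm2).bipartitions()


def test_nj_needs_three_leaves():
    with pytest.raises(ValueError, match="3 leaves"):
        neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


# -- bootstrap --------------------------------------------------------------


@pytest.fixture(scope="module")
def two_clade_alignment():
    rng = np.random.default_rng(17)
    from egt_screen.profile_hmm import BACKGROUND
    from egt_screen.seqio import AMINO_ACIDS

    a = rng.choice(20, size=300, p=BACKGROUND)
    b = a.copy()
    flip = rng.random(300) < 0.5
    b[flip] = rng.choice(20, size=int(flip.sum()))

    def variant(base, d):
        out = base.copy()
        flip = rng.random(300) < d
        out[flip] = rng.choice(20, size=int(flip.sum()))
        return "".join(AMINO_ACIDS[i] for i in out)

    rows = [(f"a{i}", variant(a, 0.08)) for i in range(4)]
    rows += [(f"b{i}", variant(b, 0.08)) for i in range(4)]
    return make_alignment("two_clades", rows)


def test_bootstrap_separating_edge_strongly_supported(two_clade_alignment):
    n_high = 0
    for seed in range(10):
        tree = bootstrap_supports(two_clade_alignment, n_reps=100, seed=seed)
        split = frozenset({"a0", "a1", "a2", "a3"})
        for node in tree.postorder():
            if node.is_leaf() or node.parent is None:
                continue
            clade = tree.clade_leafset(node)
            if clade == split or clade == frozenset(
                {"b0", "b1", "b2", "b3"}
            ):
                n_high += node.support >= 95
                break
    assert n_high >= 9


def test_bootstrap_single_replicate_supports_binary(two_clade_alignment):
    tree = bootstrap_supports(two_clade_alignment, n_reps=1, seed=0)
    sups = [n.support for n in tree.postorder()
            if not n.is_leaf() and n.parent is not None and n.support is not None]
    assert sups and all(s in (0, 100) for s in sups)


def test_bootstrap_deterministic_given_seed(two_clade_alignment):
    t1 = bootstrap_supports(two_clade_alignment, n_reps=50, seed=4)
    t2 = bootstrap_supports(two_clade_alignment, n_reps=50, seed=4)
    s1 = {frozenset(t1.clade_leafset(n)): n.support
          for n in t1.postorder() if not n.is_leaf()}
    s2 = {frozenset(t2.clade_leafset(n)): n.support
          for n in t2.postorder() if not n.is_leaf()}
    assert s1 == s2


def test_bootstrap_few_rows_warns():
    aln = make_alignment("f", [("a", "MKLV"), ("b", "MKLA"), ("c", "MALA")])
    with pytest.warns(UserWarning, match="undefined"):
        bootstrap_supports(aln, n_reps=5, seed=0)


# -- midpoint rooting -------------------------------------------------------


def test_midpoint_symmetric_quartet():
    root = Node()
    left, right = Node(length=1.0), Node(length=1.0)
    for nm, side in (("a", left), ("b", left), ("c", right), ("d", right)):
        side.add(Node(name=nm, length=2.0))
    root.add(left)
    root.add(right)
    rooted = midpoint_root(PhyloTree(root, rooted=False))
    depths = {}

    def walk(n, d):
        if n.is_leaf():
            depths[n.name] = d
        for c in n.children:
            walk(c, d + c.length)

    walk(rooted.root, 0.0)
    assert all(d == pytest.approx(3.0) for d in depths.values())


def test_midpoint_asymmetric_pendant_arithmetic():
    # leaf-to-leaf path a--b of length 10, a's pendant edge 9
    root = Node()
    root.add(Node(name="a", length=9.0))
    root.add(Node(name="b", length=1.0))
    root.add(Node(name="c", length=0.1))
    rooted = midpoint_root(PhyloTree(root, rooted=False))
    depths = {}

    def walk(n, d):
        if n.is_leaf():
            depths[n.name] = d
        for c in n.children:
            walk(c, d + c.length)

    walk(rooted.root, 0.0)
    assert depths["a"] == pytest.approx(5.0)
    assert depths["b"] == pytest.approx(5.0)


def test_midpoint_properties_on_random_trees():
    rng = np.random.default_rng(23)
    for _ in range(20):
        t = random_tree(rng, int(rng.integers(4, 10)))
        rooted = midpoint_root(t)
        # bipartitions and total length preserved
        assert rooted.bipartitions() == t.bipartitions()
        assert rooted.total_length() == pytest.approx(t.total_length(), abs=1e-9)
        # the two farthest leaves are equidistant from the root
        dm = path_distance_matrix(t)
        i, j = np.unravel_index(np.argmax(dm.matrix), dm.matrix.shape)
        depths = {}

        def walk(n, d):
            if n.is_leaf():
                depths[n.name] = d
            for c in n.children:
                walk(c, d + c.length)

        walk(rooted.root, 0.0)
        assert abs(depths[dm.ids[i]] - depths[dm.ids[j]]) < 1e-9


def test_midpoint_preserves_supports_by_bipartition(two_clade_alignment):
    tree = bootstrap_supports(two_clade_alignment, n_reps=50, seed=1)
    before = {}
    all_leaves = frozenset(tree.leaf_names())
    for n in tree.postorder():
        if not n.is_leaf() and n.parent is not None and n.support is not None:
            s = tree.clade_leafset(n)
            key = min(s, all_leaves - s, key=lambda x: (len(x), sorted(x)))
            before[key] = n.support
    rooted = midpoint_root(tree)
    for n in rooted.postorder():
        if n.is_leaf() or n.parent is None or n.support is None:
            continue
        s = rooted.clade_leafset(n)
        if 1 < len(s) < len(all_leaves) - 1:
            key = min(s, all_leaves - s, key=lambda x: (len(x), sorted(x)))
            assert before.get(key) == n.support


def test_midpoint_rejects_zero_length_tree():
    root = Node()
    for nm in "abc":
        root.add(Node(name=nm, length=0.0))
    with pytest.raises(ValueError, match="zero"):
        midpoint_root(PhyloTree(root, rooted=False))
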