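"""Distance-based tree inference with bootstrap supports.

Trees are inferred by neighbor joining on corrected pairwise protein
distances, with edge confidence from a nonparametric bootstrap over alignment
columns.  The downstream provenance classifier consumes only topology and
supports, so externally computed trees (e.g., maximum likelihood) can be
substituted through the Newick import path in :mod:`egt_screen.seqio`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .seqio import AMINO_ACIDS, Alignment
from .trees import Node, PhyloTree

__all__ = [
    "DistanceMatrix",
    "pairwise_distances",
    "neighbor_joining",
    "bootstrap_supports",
    "midpoint_root",
    "encode_alignment",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_CORRECTIONS = {"p_distance": 0, "poisson": 1, "kimura_protein": 2}


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.matrix < 0):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)


def encode_alignment(alignment: Alignment) -> np.ndarray:
    """(rows, columns) int8 matrix: residues 0..19, X = 20, gap = -1."""
    enc = np.empty((alignment.n_rows, alignment.n_columns), dtype=np.int8)
    for i, (_, gapped) in enumerate(alignment.rows):
        for c, ch in enumerate(gapped):
            enc[i, c] = -1 if ch == "-" else _AA_INDEX.get(ch, 20)
    return enc


def pairwise_distances(
    alignment: Alignment,
    correction: str = "kimura_protein",
    cap: float = 0.85,
    max_distance: float = 10.0,
) -> DistanceMatrix:
    """Corrected pairwise distances with pairwise deletion of gap/X columns.

    p is the mismatch fraction on comparable columns; Poisson d = -ln(1-p);
    Kimura protein d = -ln(1 - p - p^2/5).  Pairs at or beyond ``cap`` are
    assigned ``max_distance`` with a warning (saturation).
    """
    if alignment.n_rows < 2:
        raise ValueError("need at least two rows for distances")
    if correction not in _CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    enc = encode_alignment(alignment)
    D = _kernels.pdist_kernel(enc, cap, max_distance, _CORRECTIONS[correction])
    ids = alignment.ids()
    bad = np.argwhere(D < 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"rows {ids[i]!r} and {ids[j]!r} share no comparable columns"
        )
    if np.any(D >= max_distance):
        warnings.warn(
            f"{int((np.triu(D) >= max_distance).sum())} saturated pair(s) "
            f"capped at distance {max_distance}",
            stacklevel=2,
        )
    return DistanceMatrix(ids, D)


# --------------------------------------------------------------------------
# neighbor joining


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # negative branch length: clamp to zero, move the deficit to the sibling
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classic NJ (Saitou & Nei Q criterion).  Deterministic: Q ties are
    broken by the lowest working-index pair.  Returns an unrooted tree with a
    trifurcating placeholder root."""
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 leaves")
    nodes: dict[int, Node] = {i: Node(name=dm.ids[i]) for i in range(n)}
    merges, lengths, act, D = _kernels.nj_kernel(dm.matrix)
    for step in range(merges.shape[0]):
        i, j = int(merges[step, 0]), int(merges[step, 1])
        li, lj = _clamp_pair(float(lengths[step, 0]), float(lengths[step, 1]))
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes.pop(i))
        parent.add(nodes.pop(j))
        nodes[n + step] = parent
    a, b, c = (int(x) for x in act)
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = Node()
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(ln, 0.0)
        root.add(nodes.pop(idx))
    return PhyloTree(root, rooted=False)


def _bipartition_masks(merges, act, n: int) -> set[int]:
    """Canonical bitmasks of the non-trivial bipartitions implied by an NJ
    merge sequence over n leaves."""
    full = (1 << n) - 1
    mask: dict[int, int] = {i: 1 << i for i in range(n)}
    out: set[int] = set()
    for step in range(merges.shape[0]):
        i, j = int(merges[step, 0]), int(merges[step, 1])
        m = mask.pop(i) | mask.pop(j)
        mask[n + step] = m
        size = bin(m).count("1")
        if 1 < size < n - 1:
            other = full ^ m
            out.add(min(m, other))
    return out


def bootstrap_supports(
    alignment: Alignment,
    n_reps: int = 100,
    seed: int = 0,
    correction: str = "kimura_protein",
    cap: float = 0.85,
    max_distance: float = 10.0,
) -> PhyloTree:
    """NJ point-estimate tree with column-bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each internal edge of the point tree is the percentage of replicate trees
    containing the same bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = neighbor_joining(pairwise_distances(alignment, correction, cap, max_distance))
    n = alignment.n_rows
    if n < 4:
        warnings.warn("fewer than 4 rows: bootstrap supports are undefined",
                      stacklevel=2)
        return tree
    enc = encode_alignment(alignment)
    ids = alignment.ids()
    leaf_index = {name: i for i, name in enumerate(ids)}
    mode = _CORRECTIONS[correction]
    rng = np.random.default_rng(seed)
    counts: dict[int, int] = {}
    ncol = enc.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        D = _kernels.pdist_kernel(np.ascontiguousarray(enc[:, cols]), cap,
                                  max_distance, mode)
        D[D < 0] = max_distance  # incomparable pair under this resample
        merges, _, act, _ = _kernels.nj_kernel(D)
        for m in _bipartition_masks(merges, act, n):
            counts[m] = counts.get(m, 0) + 1

    full = (1 << n) - 1
    below: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_leaf():
            below[id(node)] = 1 << leaf_index[node.name]
        else:
            m = 0
            for ch in node.children:
                m |= below[id(ch)]
            below[id(node)] = m
            size = bin(m).count("1")
            if node.parent is not None and 1 < size < n - 1:
                key = min(m, full ^ m)
                node.support = round(100.0 * counts.get(key, 0) / n_reps)
    return tree


# --------------------------------------------------------------------------
# midpoint rooting


def _adjacency(tree: PhyloTree):
    """Undirected edge list view: node -> list of (neighbor, length, support).
    Edge support is the support stored on the child node of the edge."""
    adj: dict[int, list] = {}
    obj: dict[int, Node] = {}

    def reg(n):
        obj[id(n)] = n
        adj.setdefault(id(n), [])

    for node in tree.postorder():
        reg(node)
        for ch in node.children:
            reg(ch)
            adj[id(node)].append((id(ch), ch.length, ch.support))
            adj[id(ch)].append((id(node), ch.length, ch.support))
    return adj, obj


def _farthest(adj, start):
    dist = {start: 0.0}
    prev = {start: None}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, ln, _ in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + ln
                prev[v] = u
                stack.append(v)
    return dist, prev


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root the tree halfway along its longest leaf-to-leaf path.  Supports
    stay attached to their bipartitions."""
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least two leaves")
    if tree.total_length() <= 0:
        raise ValueError(
            "all branch lengths are zero; midpoint is undefined "
            "(root arbitrarily instead)"
        )
    adj, obj = _adjacency(tree)
    leaf_ids = [id(lf) for lf in leaves]
    d0, _ = _farthest(adj, leaf_ids[0])
    f1 = max(leaf_ids, key=lambda x: d0[x])
    d1, prev1 = _farthest(adj, f1)
    f2 = max(leaf_ids, key=lambda x: d1[x])
    diameter = d1[f2]
    # walk back from f2 toward f1 to find the midpoint edge
    path = [f2]
    while path[-1] != f1:
        path.append(prev1[path[-1]])
    path.reverse()  # f1 ... f2
    half = diameter / 2.0
    acc = 0.0
    root_at_node = None
    split_edge = None
    for a, b in zip(path, path[1:]):
        ln = next(l for (v, l, _) in adj[a] if v == b)
        if abs(acc - half) < 1e-12:
            root_at_node = a
            break
        if acc + ln > half:
            split_edge = (a, b, half - acc, ln)
            break
        acc += ln
    else:
        root_at_node = path[-1]

    # orient the adjacency graph from the new root
    def build(u, parent_id, length, support):
        src = obj[u]
        node = Node(
            name=src.name, length=length, support=support,
            taxon=src.taxon, role=src.role,
        )
        for v, ln, sup in adj[u]:
            if v != parent_id:
                node.add(build(v, u, ln, sup))
        return node

    if root_at_node is not None:
        root = build(root_at_node, None, 0.0, None)
        root.support = None
    else:
        a, b, from_a, ln = split_edge
        sup = next(s for (v, l, s) in adj[a] if v == b)
        root = Node()
        left = build(a, b, from_a, sup)
        right = build(b, a, ln - from_a, sup)
        root.add(left)
        root.add(right)
    rooted = PhyloTree(root, rooted=True)
    # a support describes the bipartition of its edge; with the edge now split
    # in two, keeping it on both halves would double-count -- drop it from the
    # side whose bipartition no longer matches the original set
    _reconcile_supports(tree, rooted)
    return rooted


def _reconcile_supports(original: PhyloTree, rooted: PhyloTree) -> None:
    orig = {}
    all_leaves = frozenset(original.leaf_names())
    below: dict[int, frozenset] = {}
    for node in original.postorder():
        if node.is_leaf():
            below[id(node)] = frozenset([node.name])
        else:
            s = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = s
            if node.parent is not None and node.support is not None:
                orig[min(s, all_leaves - s, key=lambda x: (len(x), sorted(x)))] = (
                    node.support
                )
    for node in rooted.postorder():
        if node.is_leaf() or node.parent is None:
            continue
        s = rooted.clade_leafset(node)
        if 1 < len(s) < len(all_leaves):
            key = min(s, all_leaves - s, key=lambda x: (len(x), sorted(x)))
            node.support = orig.get(key)
        else:
            node.support = None
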