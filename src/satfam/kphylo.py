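"""Alignment-free k-mer distance phylogeny with minimum-evolution search.

Monomer consensus sequences are compared by their sets of distinct k-mers
(default k = 9; presence/absence, since a 9-mer rarely repeats inside a
short monomer). Similarity is the fractional common k-mer count
F = |P1 n P2| / min(|P1|, |P2|), converted to a distance either as 1 - F
(default) or -ln F. Monomers are canonicalised for strand and rotation and
profiled circularly, so satellite phase cannot affect the tree. The tree is
built by neighbor joining, then improved by nearest-neighbour-interchange
hill climbing on the minimum-evolution criterion (total OLS branch length),
and finally rooted on the ancestral-monomer leaf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import TreeNode, nj

from .seqio import canonical_rotation, revcomp, write_newick


@dataclass
class KPhyloParams:
    k: int = 9
    distance_form: str = "one_minus_F"  # or neg_log_F
    circular: bool = True

    def validate(self) -> None:
        if not 4 <= self.k <= 15:
            raise ValueError("k must be in [4, 15]")
        if self.distance_form not in ("one_minus_F", "neg_log_F"):
            raise ValueError(f"unknown distance form {self.distance_form!r}")


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray

    def validate(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix/label shape mismatch")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")


def kmer_profile(seq: str, params: KPhyloParams | None = None) -> frozenset:
    """Distinct k-mers of the canonicalised (strand/rotation) sequence.

    With circular=True the sequence is wrapped by k-1 bases so every
    rotation yields the same profile.
    """
    params = params or KPhyloParams()
    params.validate()
    if len(seq) < params.k:
        raise ValueError(f"sequence shorter than k={params.k}")
    if params.circular:
        s = canonical_rotation(seq)
        s = s + s[: params.k - 1]
    else:
        s = min(seq, revcomp(seq))
    k = params.k
    return frozenset(s[i : i + k] for i in range(len(s) - k + 1))


def fractional_common_distance(
    p1: frozenset, p2: frozenset, params: KPhyloParams | None = None
) -> float:
    """Distance from the fractional common k-mer count F = |∩| / min(|·|,|·|)."""
    params = params or KPhyloParams()
    if not p1 or not p2:
        raise ValueError("profiles must be non-empty")
    f = len(p1 & p2) / min(len(p1), len(p2))
    if params.distance_form == "one_minus_F":
        return 1.0 - f
    eps = 1.0 / (len(p1) + len(p2) + 1)
    return -float(np.log(max(f, eps)))


def distance_matrix(seqs: dict, params: KPhyloParams | None = None) -> DistanceMatrix:
    params = params or KPhyloParams()
    labels = sorted(seqs)
    profiles = {l: kmer_profile(seqs[l], params) for l in labels}
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = fractional_common_distance(profiles[labels[i]], profiles[labels[j]], params)
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=labels, matrix=m)


# --- minimum evolution ---------------------------------------------------


class _METree:
    """Unrooted binary tree over leaf ids 0..n-1; adjacency over node ids."""

    def __init__(self, adj: dict, n_leaves: int):
        self.adj = adj  # node -> set(node)
        self.n = n_leaves

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (min(u, v), max(u, v)) for u in self.adj for v in self.adj[u]
        )

    def internal_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v)
            for u, v in set(self.edges())
            if len(self.adj[u]) > 1 and len(self.adj[v]) > 1
        ]

    def leaf_paths(self) -> dict:
        """Edge-index path between every leaf pair (edge order = edges())."""
        eidx = {e: i for i, e in enumerate(self.edges())}
        paths = {}
        for leaf in range(self.n):
            # BFS recording parent
            parent = {leaf: None}
            stack = [leaf]
            while stack:
                u = stack.pop()
                for v in self.adj[u]:
                    if v not in parent:
                        parent[v] = u
                        stack.append(v)
            for other in range(leaf + 1, self.n):
                path = []
                x = other
                while parent[x] is not None:
                    path.append(eidx[(min(x, parent[x]), max(x, parent[x]))])
                    x = parent[x]
                paths[(leaf, other)] = path
        return paths


def _ols_lengths(tree: _METree, dm: np.ndarray) -> tuple[np.ndarray, float]:
    edges = tree.edges()
    paths = tree.leaf_paths()
    pairs = sorted(paths)
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        A[r, paths[(i, j)]] = 1.0
        y[r] = dm[i, j]
    lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
    return lengths, float(lengths.sum())


def _nj_start(dm: DistanceMatrix) -> _METree:
    labels = dm.labels
    n = len(labels)
    if n == 3:
        adj = {0: {3}, 1: {3}, 2: {3}, 3: {0, 1, 2}}
        return _METree(adj, 3)
    sk = nj(SkbioDM(dm.matrix, ids=labels))
    idx = {l: i for i, l in enumerate(labels)}
    adj: dict[int, set] = {}
    next_id = [n]

    def add_edge(a, b):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    def walk(node) -> int:
        if node.is_tip():
            return idx[node.name]
        my = next_id[0]
        next_id[0] += 1
        adj.setdefault(my, set())
        for ch in node.children:
            add_edge(my, walk(ch))
        return my

    root_id = walk(sk)
    # suppress degree-2 root left by skbio's rooted representation
    while root_id in adj and len(adj[root_id]) == 2:
        a, b = sorted(adj[root_id])
        adj[a].discard(root_id)
        adj[b].discard(root_id)
        del adj[root_id]
        add_edge(a, b)
    return _METree(adj, n)


def _nni_neighbors(tree: _METree):
    for u, v in sorted(tree.internal_edges()):
        a = sorted(tree.adj[u] - {v})
        b = sorted(tree.adj[v] - {u})
        if len(a) < 2 or len(b) < 2:
            continue
        for swap_b in b:
            # swap a[1] <-> swap_b across edge (u, v)
            adj = {k: set(vs) for k, vs in tree.adj.items()}
            adj[u].discard(a[1])
            adj[a[1]].discard(u)
            adj[v].discard(swap_b)
            adj[swap_b].discard(v)
            adj[u].add(swap_b)
            adj[swap_b].add(u)
            adj[v].add(a[1])
            adj[a[1]].add(v)
            yield _METree(adj, tree.n)


def me_tree(dm: DistanceMatrix) -> TreeNode:
    """NJ start, OLS branch lengths, NNI search minimising total length;
    negative lengths clamped to 0 afterwards; rooted on the 'ancestral' leaf
    when present (else on the first label)."""
    dm.validate()
    if len(dm.labels) < 3:
        raise ValueError("need >= 3 labels")
    tree = _nj_start(dm)
    lengths, score = _ols_lengths(tree, dm.matrix)
    improved = True
    while improved:
        improved = False
        best = (score, tree, lengths)
        for cand in _nni_neighbors(tree):
            cl, cs = _ols_lengths(cand, dm.matrix)
            if cs < best[0] - 1e-12:
                best = (cs, cand, cl)
                improved = True
        score, tree, lengths = best
    lengths = np.maximum(lengths, 0.0)
    edge_len = {e: float(l) for e, l in zip(tree.edges(), lengths)}

    root_label = "ancestral" if "ancestral" in dm.labels else dm.labels[0]
    root_leaf = dm.labels.index(root_label)

    def build(node: int, parent: int) -> TreeNode:
        length = edge_len[(min(node, parent), max(node, parent))]
        if node < tree.n:
            return TreeNode(name=dm.labels[node], length=length)
        children = [build(c, node) for c in sorted(tree.adj[node] - {parent})]
        return TreeNode(length=length, children=children)

    attach = next(iter(tree.adj[root_leaf]))
    kids = [build(root_leaf, attach)] + [
        build(c, attach) for c in sorted(tree.adj[attach] - {root_leaf})
    ]
    return TreeNode(name="root", length=None, children=kids)


def monomer_tree_pipeline(seqs: dict, params: KPhyloParams | None = None) -> str:
    """Canonicalise -> k-mer profiles -> distances -> ME tree -> Newick."""
    params = params or KPhyloParams()
    dm = distance_matrix(seqs, params)
    tree = me_tree(dm)
    return write_newick(tree)
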