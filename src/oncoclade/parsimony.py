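"""Maximum-parsimony cladogram inference for binary aberration characters.

Specimens are leaves; characters are 0/1 aberration presence columns.
Wagner parsimony (free 0<->1 reversals, Fitch counting) is the default
character model; Camin-Sokal (irreversible 0->1, appropriate when an
aberration is assumed never to revert) is available as an option.  Three
searches are provided:

* ``exhaustive_search`` enumerates every unrooted binary topology (<= 9
  taxa) and returns all optimal trees;
* ``branch_and_bound_search`` is exact for mid-sized cohorts, pruning on
  the partial Fitch length plus a count of characters that still must
  change;
* ``heuristic_search`` does stepwise addition with random addition order
  followed by NNI hill-climbing, deterministic under a seed.

Optimal trees are rooted by attaching a hypothetical all-zero ancestor
(the normal genome: every aberration scored absent/ancestral) at its best
insertion edge, and each node is annotated with the characters that define
it, both strictly (characters whose 1-state leaves are exactly the node's
leaf set) and under a Fitch final-pass reconstruction (characters gained
on the node's stem).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import BinaryCharacterMatrix

MAX_EXHAUSTIVE_TAXA = 9
DEFAULT_TREE_CAP = 1000


# ---------------------------------------------------------------------------
# Tree representations
#
# Internally an unrooted binary tree over taxon indices 0..n-1 is a pair
# (t0, rtree): leaf t0 attached to the root edge of a nested-tuple binary
# tree over the remaining indices.  Every edge of the unrooted tree
# corresponds to exactly one node (subtree) of rtree.


def _rtree_leaves(rt) -> frozenset[int]:
    if isinstance(rt, (int, np.integer)):
        return frozenset([int(rt)])
    return _rtree_leaves(rt[0]) | _rtree_leaves(rt[1])


def _insert_everywhere(rt, x):
    """Yield every rtree obtained by attaching leaf x on one edge."""
    yield (rt, x)
    if isinstance(rt, tuple):
        a, b = rt
        for na in _insert_everywhere(a, x):
            yield (na, b)
        for nb in _insert_everywhere(b, x):
            yield (a, nb)


def _splits(structure) -> frozenset[frozenset[int]]:
    """Nontrivial bipartitions (identified by the side not containing t0)."""
    t0, rt = structure
    out: set[frozenset[int]] = set()

    def rec(t) -> frozenset[int]:
        if isinstance(t, (int, np.integer)):
            return frozenset([int(t)])
        ls = rec(t[0]) | rec(t[1])
        out.add(ls)
        return ls

    full = rec(rt)
    out.discard(full)
    return frozenset(s for s in out if len(s) > 1)


@dataclass(frozen=True)
class UnrootedTree:
    """An unrooted binary tree over named taxa."""

    taxa: tuple[str, ...]
    structure: tuple  # (t0 index, nested-tuple rtree over the other indices)

    def splits(self) -> frozenset[frozenset[int]]:
        return _splits(self.structure)

    def newick(self) -> str:
        t0, rt = self.structure

        def rec(t) -> str:
            if isinstance(t, (int, np.integer)):
                return self.taxa[int(t)]
            return f"({rec(t[0])},{rec(t[1])})"

        if isinstance(rt, (int, np.integer)):
            return f"({self.taxa[t0]},{self.taxa[int(rt)]});"
        return f"({self.taxa[t0]},{rec(rt[0])},{rec(rt[1])});"

    def same_topology(self, other: "UnrootedTree") -> bool:
        return set(self.taxa) == set(other.taxa) and self._canonical() == other._canonical()

    def _canonical(self) -> frozenset:
        return frozenset(
            frozenset(self.taxa[i] for i in s) for s in self.splits()
        )


# ---------------------------------------------------------------------------
# Scoring

def _leaf_masks(matrix: BinaryCharacterMatrix):
    n, m = matrix.shape
    mask = (1 << m) - 1
    h1, h0 = [], []
    for i in range(n):
        ones = 0
        for j in range(m):
            if matrix.entries[i, j]:
                ones |= 1 << j
        h1.append(ones)
        h0.append(~ones & mask)
    return h0, h1, mask


def _wagner_pair(t0: int, rt, h0, h1, mask) -> int:
    def rec(t):
        if isinstance(t, (int, np.integer)):
            return h0[int(t)], h1[int(t)], 0
        a0, a1, sa = rec(t[0])
        b0, b1, sb = rec(t[1])
        i0, i1 = a0 & b0, a1 & b1
        empty = mask & ~(i0 | i1)
        return i0 | ((a0 | b0) & empty), i1 | ((a1 | b1) & empty), sa + sb + empty.bit_count()

    s0, s1, steps = rec(rt)
    empty = mask & ~((s0 & h0[t0]) | (s1 & h1[t0]))
    return steps + empty.bit_count()


def _to_adjacency(structure, next_id: int):
    """(t0, rtree) -> adjacency dict; leaves keep their indices, internal
    nodes get ids starting at next_id."""
    t0, rt = structure
    adj: dict[int, list[int]] = {}
    counter = [next_id]

    def add_edge(u, v):
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def build(t) -> int:
        if isinstance(t, (int, np.integer)):
            adj.setdefault(int(t), [])
            return int(t)
        node = counter[0]
        counter[0] += 1
        a, b = build(t[0]), build(t[1])
        add_edge(node, a)
        add_edge(node, b)
        return node

    r = build(rt)
    add_edge(t0, r)
    return adj


def _adjacency_to_pair(adj, t0: int):
    def build(v, parent):
        nb = [w for w in adj[v] if w != parent]
        if not nb:
            return v
        if len(nb) != 2:
            raise ValueError("tree is not binary")
        return (build(nb[0], v), build(nb[1], v))

    (r,) = adj[t0]
    return (t0, build(r, t0))


def _caminsokal_pair(t0: int, rt, entries: np.ndarray) -> int:
    """Camin-Sokal length of an unrooted tree = min over root placements of
    the number of irreversible 0->1 transitions needed, per character."""
    n = entries.shape[0]
    adj = _to_adjacency((t0, rt), n)
    memo: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def side(v: int, parent: int):
        key = (v, parent)
        if key in memo:
            return memo[key]
        if v < n:  # leaf
            col = entries[v]
            res = (col == 1, col.astype(np.int64))
        else:
            parts = [side(w, v) for w in adj[v] if w != parent]
            allones = np.logical_and.reduce([p[0] for p in parts])
            gains = np.where(allones, 1, sum(p[1] for p in parts))
            res = (allones, gains)
        memo[key] = res
        return res

    best = None
    for u in adj:
        for v in adj[u]:
            if u < v:
                total = int((side(u, v)[1] + side(v, u)[1]).sum())
                if best is None or total < best:
                    best = total
    return best


def _make_scorer(matrix: BinaryCharacterMatrix, model: str):
    if model == "wagner":
        h0, h1, mask = _leaf_masks(matrix)
        return lambda t0, rt: _wagner_pair(t0, rt, h0, h1, mask)
    if model == "caminsokal":
        entries = matrix.entries.astype(np.int64)
        return lambda t0, rt: _caminsokal_pair(t0, rt, entries)
    raise ValueError(f"unknown character model {model!r}")


def fitch_length(tree, matrix: BinaryCharacterMatrix, model: str = "wagner") -> int:
    """Minimum number of character-state changes of ``matrix`` on ``tree``
    (sum over characters).  ``tree`` is an UnrootedTree or a binary
    Cladogram over exactly the matrix's taxa."""
    if isinstance(tree, Cladogram):
        tree = tree.unrooted()
    if set(tree.taxa) != set(matrix.taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    if tuple(tree.taxa) != tuple(matrix.taxa):
        relabel = {name: matrix.taxa.index(name) for name in tree.taxa}

        def rec(t):
            if isinstance(t, (int, np.integer)):
                return relabel[tree.taxa[int(t)]]
            return (rec(t[0]), rec(t[1]))

        t0, rt = tree.structure
        tree = UnrootedTree(tuple(matrix.taxa), (relabel[tree.taxa[t0]], rec(rt)))
    scorer = _make_scorer(matrix, model)
    t0, rt = tree.structure
    return scorer(t0, rt)


# ---------------------------------------------------------------------------
# Searches

@dataclass
class SearchResult:
    best_length: int
    trees: list[UnrootedTree]
    method: str
    seed: int | None = None
    n_examined: int = 0
    tree_cap_hit: bool = False

    def exemplar(self) -> UnrootedTree:
        """Deterministic single representative (first optimal tree found)."""
        return self.trees[0]


def _enumerate_rtrees(leaves: Sequence[int]):
    """All distinct rtrees over the given leaves (each unrooted topology of
    {t0} + leaves appears exactly once)."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    if len(leaves) == 2:
        yield (leaves[0], leaves[1])
        return

    def rec(k: int):
        if k == 2:
            yield (leaves[0], leaves[1])
            return
        for sub in rec(k - 1):
            yield from _insert_everywhere(sub, leaves[k - 1])

    yield from rec(len(leaves))


def exhaustive_search(
    matrix: BinaryCharacterMatrix,
    model: str = "wagner",
    max_trees: int = DEFAULT_TREE_CAP,
) -> SearchResult:
    """Score every unrooted binary topology; exact but limited to <= 9 taxa
    (135 135 topologies)."""
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if n > MAX_EXHAUSTIVE_TAXA:
        raise ValueError(
            f"{n} taxa is too many for exhaustive search "
            f"(max {MAX_EXHAUSTIVE_TAXA}); use branch_and_bound_search or heuristic_search"
        )
    scorer = _make_scorer(matrix, model)
    best = None
    trees: list[tuple] = []
    examined = 0
    cap_hit = False
    for rt in _enumerate_rtrees(list(range(1, n))):
        examined += 1
        s = scorer(0, rt)
        if best is None or s < best:
            best, trees, cap_hit = s, [(0, rt)], False
        elif s == best:
            if len(trees) < max_trees:
                trees.append((0, rt))
            else:
                cap_hit = True
    taxa = tuple(matrix.taxa)
    return SearchResult(
        best_length=int(best),
        trees=[UnrootedTree(taxa, t) for t in trees],
        method="exhaustive",
        n_examined=examined,
        tree_cap_hit=cap_hit,
    )


def _extra_steps_bound(matrix: BinaryCharacterMatrix, model: str) -> list[int]:
    """extra[k]: characters that contribute nothing to the score of the
    partial tree on taxa[0:k] but must change at least once on any full
    tree.  Valid lower-bound complement for both models."""
    entries = matrix.entries
    n, m = entries.shape
    nonconstant = (entries.sum(axis=0) > 0) & (entries.sum(axis=0) < n)
    extra = [0] * (n + 1)
    for k in range(3, n + 1):
        prefix = entries[:k]
        if model == "wagner":
            silent = (prefix.sum(axis=0) == 0) | (prefix.sum(axis=0) == k)
        else:  # caminsokal: an all-one prefix already pays its single gain
            silent = prefix.sum(axis=0) == 0
        extra[k] = int((nonconstant & silent).sum())
    return extra


def branch_and_bound_search(
    matrix: BinaryCharacterMatrix,
    model: str = "wagner",
    max_trees: int = DEFAULT_TREE_CAP,
    node_budget: int | None = 5_000_000,
) -> SearchResult:
    """Exact search by depth-first taxon insertion with pruning.

    A partial tree is pruned when its length plus the number of characters
    still guaranteed to change exceeds the best complete length found.
    Scores never decrease as taxa are added, so the optimum equals the
    exhaustive optimum.
    """
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    scorer = _make_scorer(matrix, model)
    extra = _extra_steps_bound(matrix, model)

    best: int | None = None
    trees: list[tuple] = []
    cap_hit = False
    if n >= 4:  # initial bound from a quick hill-climb
        warm = heuristic_search(matrix, seed=0, n_starts=2, model=model, max_trees=1)
        best = warm.best_length
    examined = 0

    stack: list[tuple[tuple, int]] = [((1, 2), 3)]
    while stack:
        rt, k = stack.pop()
        examined += 1
        if node_budget is not None and examined > node_budget:
            raise RuntimeError(f"branch-and-bound node budget of {node_budget} exhausted")
        s = scorer(0, rt)
        if k == n:
            if best is None or s < best:
                best, trees, cap_hit = s, [(0, rt)], False
            elif s == best:
                if len(trees) < max_trees:
                    trees.append((0, rt))
                else:
                    cap_hit = True
            continue
        if best is not None and s + extra[k] > best:
            continue
        for child in _insert_everywhere(rt, k):
            stack.append((child, k + 1))

    if not trees:
        # the warm-start bound was already optimal but its topology was not
        # re-found before pruning; rerun keeping ties at the known optimum
        stack = [((1, 2), 3)]
        while stack:
            rt, k = stack.pop()
            s = scorer(0, rt)
            if k == n:
                if s == best and len(trees) < max_trees:
                    trees.append((0, rt))
                continue
            if s + extra[k] > best:
                continue
            for child in _insert_everywhere(rt, k):
                stack.append((child, k + 1))

    taxa = tuple(matrix.taxa)
    return SearchResult(
        best_length=int(best),
        trees=[UnrootedTree(taxa, t) for t in trees],
        method="branch_and_bound",
        n_examined=examined,
        tree_cap_hit=cap_hit,
    )


def _greedy_addition(order: Sequence[int], scorer) -> tuple[tuple, int]:
    """Stepwise addition: attach each taxon at its best edge (first tie)."""
    t0 = order[0]
    rt: tuple = (order[1], order[2])
    s = scorer(t0, rt)
    for x in order[3:]:
        best_rt, best_s = None, None
        for cand in _insert_everywhere(rt, x):
            cs = scorer(t0, cand)
            if best_s is None or cs < best_s:
                best_rt, best_s = cand, cs
        rt, s = best_rt, best_s
    return (t0, rt), s


def _nni_neighbors(structure, n: int):
    """Yield the 2 NNI rearrangements per internal edge, as (t0=0, rtree)."""
    adj = _to_adjacency(structure, n)
    internal = [v for v in adj if v >= n]
    for u in internal:
        for v in adj[u]:
            if v < u or v < n:
                continue  # visit each internal edge once
            a, b = [w for w in adj[u] if w != v]
            c, d = [w for w in adj[v] if w != u]
            for x, y in ((b, c), (b, d)):
                new = {k: list(ws) for k, ws in adj.items()}
                new[u].remove(x); new[v].remove(y)
                new[u].append(y); new[v].append(x)
                new[x].remove(u); new[y].remove(v)
                new[x].append(v); new[y].append(u)
                yield _adjacency_to_pair(new, 0)


def heuristic_search(
    matrix: BinaryCharacterMatrix,
    seed: int = 0,
    n_starts: int = 10,
    model: str = "wagner",
    max_trees: int = DEFAULT_TREE_CAP,
) -> SearchResult:
    """Random-addition-order stepwise addition + NNI hill climbing.

    Never reports a length better than the exact optimum (every reported
    tree is scored by the same Fitch counting); deterministic given seed.
    """
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    scorer = _make_scorer(matrix, model)
    taxa = tuple(matrix.taxa)
    if n == 3:
        t = (0, (1, 2))
        return SearchResult(scorer(0, (1, 2)), [UnrootedTree(taxa, t)],
                            "heuristic", seed=seed, n_examined=1)
    rng = np.random.default_rng(seed)
    best: int | None = None
    found: list[tuple] = []
    seen_splits: set[frozenset] = set()
    cap_hit = False
    examined = 0
    for _ in range(n_starts):
        order = [int(i) for i in rng.permutation(n)]
        structure, s = _greedy_addition(order, scorer)
        # normalize so leaf 0 is the outer leaf, as NNI rebuilding expects
        structure = _adjacency_to_pair(_to_adjacency(structure, n), 0)
        improved = True
        while improved:
            improved = False
            best_nb, best_nb_s = None, s
            for nb in _nni_neighbors(structure, n):
                examined += 1
                ns = scorer(*nb)
                if ns < best_nb_s:
                    best_nb, best_nb_s = nb, ns
            if best_nb is not None:
                structure, s = best_nb, best_nb_s
                improved = True
        if best is None or s < best:
            best = s
            found = [structure]
            seen_splits = {_splits(structure)}
            cap_hit = False
        elif s == best:
            sp = _splits(structure)
            if sp not in seen_splits:
                if len(found) < max_trees:
                    found.append(structure)
                    seen_splits.add(sp)
                else:
                    cap_hit = True
    return SearchResult(
        best_length=int(best),
        trees=[UnrootedTree(taxa, t) for t in found],
        method="heuristic",
        seed=seed,
        n_examined=examined,
        tree_cap_hit=cap_hit,
    )


def search(matrix: BinaryCharacterMatrix, method: str = "auto",
           model: str = "wagner", seed: int = 0, n_starts: int = 10,
           max_trees: int = DEFAULT_TREE_CAP) -> SearchResult:
    """Dispatch: exhaustive (<=9 taxa), branch and bound (<=20), else
    heuristic."""
    n = len(matrix.taxa)
    if method == "auto":
        method = "exhaustive" if n <= MAX_EXHAUSTIVE_TAXA else (
            "bb" if n <= 20 else "heuristic")
    if method == "exhaustive":
        return exhaustive_search(matrix, model=model, max_trees=max_trees)
    if method in ("bb", "branch_and_bound"):
        return branch_and_bound_search(matrix, model=model, max_trees=max_trees)
    if method == "heuristic":
        return heuristic_search(matrix, seed=seed, n_starts=n_starts,
                                model=model, max_trees=max_trees)
    raise ValueError(f"unknown search method {method!r}")


# ---------------------------------------------------------------------------
# Rooted cladograms

class CladeNode:
    __slots__ = ("id", "name", "children", "leaf_indices",
                 "strict_synapomorphies", "reconstructed_gains")

    def __init__(self, name: str | None = None):
        self.id: int | None = None
        self.name = name
        self.children: list[CladeNode] = []
        self.leaf_indices: frozenset[int] = frozenset()
        self.strict_synapomorphies: list[int] = []
        self.reconstructed_gains: list[int] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Cladogram:
    """Rooted tree over specimens whose root is the hypothetical all-zero
    (aberration-free) ancestor, with per-node defining-character lists."""

    root: CladeNode
    taxa: tuple[str, ...]
    model: str = "wagner"
    note: str = ""

    def nodes(self) -> list[CladeNode]:
        out: list[CladeNode] = []

        def rec(v: CladeNode):
            out.append(v)
            for c in v.children:
                rec(c)

        rec(self.root)
        return out

    def internal_clades(self) -> set[frozenset[str]]:
        return {
            frozenset(self.taxa[i] for i in v.leaf_indices)
            for v in self.nodes() if not v.is_leaf
        }

    def newick(self, internal_labels: bool = True) -> str:
        def rec(v: CladeNode) -> str:
            if v.is_leaf:
                return v.name
            inner = ",".join(rec(c) for c in v.children)
            label = f"Nd{v.id}" if internal_labels and v.id is not None else ""
            return f"({inner}){label}"

        return rec(self.root) + ";"

    def node_table(self, matrix: BinaryCharacterMatrix | None = None) -> pd.DataFrame:
        def charname(j: int) -> str:
            return str(matrix.characters[j]) if matrix is not None else f"char{j}"

        rows = []
        for v in self.nodes():
            rows.append(
                {"node": (f"Nd{v.id}" if not v.is_leaf else v.name),
                 "n_leaves": len(v.leaf_indices),
                 "leaves": ",".join(sorted(self.taxa[i] for i in v.leaf_indices)),
                 "strict_synapomorphies": ";".join(charname(j) for j in v.strict_synapomorphies),
                 "reconstructed_gains": ";".join(charname(j) for j in v.reconstructed_gains)}
            )
        return pd.DataFrame(rows)

    def unrooted(self) -> UnrootedTree:
        """Collapse the root (binary trees only) back to an unrooted tree."""

        def rec(v: CladeNode):
            if v.is_leaf:
                return self.taxa.index(v.name)
            if len(v.children) != 2:
                raise ValueError("cladogram contains a polytomy; not convertible")
            return (rec(v.children[0]), rec(v.children[1]))

        return _unroot_merged(rec(self.root), self.taxa)


def _unroot_merged(merged, taxa: tuple[str, ...]) -> UnrootedTree:
    a, b = merged
    if isinstance(a, (int, np.integer)):
        return UnrootedTree(taxa, (int(a), b))
    if isinstance(b, (int, np.integer)):
        return UnrootedTree(taxa, (int(b), a))
    # both sides internal: re-root at leaf 0 via adjacency
    n = len(taxa)
    adj: dict[int, list[int]] = {}
    counter = [n]

    def add_edge(u, v):
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def build(t) -> int:
        if isinstance(t, (int, np.integer)):
            adj.setdefault(int(t), [])
            return int(t)
        node = counter[0]
        counter[0] += 1
        add_edge(node, build(t[0]))
        add_edge(node, build(t[1]))
        return node

    ra, rb = build(a), build(b)
    add_edge(ra, rb)
    return UnrootedTree(taxa, _adjacency_to_pair(adj, 0))


def root_and_annotate(
    tree: UnrootedTree, matrix: BinaryCharacterMatrix, model: str = "wagner"
) -> Cladogram:
    """Root an optimal unrooted tree at the all-zero hypothetical ancestor
    and annotate every node with its defining characters.

    The ancestor (a taxon scoring 0 for every character) is attached at the
    edge minimizing total length (first edge on ties, in deterministic
    enumeration order), the tree is rooted there and the ancestor removed.
    Internal nodes are numbered in preorder from the root.  Per node two
    lists are produced: strict synapomorphies (characters present in
    exactly the node's leaves) and characters reconstructed as gained on
    the node's stem under a Fitch final pass with the ancestral state
    forced to 0.
    """
    if set(tree.taxa) != set(matrix.taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    n, m = matrix.shape
    order = [matrix.taxa.index(name) for name in tree.taxa]

    # relabel structure into matrix taxon indices
    def relabel(t):
        if isinstance(t, (int, np.integer)):
            return order[int(t)]
        return (relabel(t[0]), relabel(t[1]))

    t0, rt = tree.structure
    t0, rt = order[t0], relabel(rt)

    # score each attachment of an all-zero pseudo-taxon (index n)
    h0, h1, mask = _leaf_masks(matrix)
    h0 = h0 + [mask]
    h1 = h1 + [0]
    z = n
    best_rt, best_s = None, None
    for cand in _insert_everywhere(rt, z):
        s = _wagner_pair(t0, cand, h0, h1, mask)
        if best_s is None or s < best_s:
            best_rt, best_s = cand, s

    adj = _to_adjacency((t0, best_rt), n + 1)
    (anchor,) = [w for w in adj[z]]

    def build(v: int, parent: int) -> CladeNode:
        if v < n:
            node = CladeNode(name=matrix.taxa[v])
            node.leaf_indices = frozenset([v])
            return node
        node = CladeNode()
        for w in adj[v]:
            if w in (parent, z):
                continue
            child = build(w, v)
            node.children.append(child)
        node.leaf_indices = frozenset().union(*(c.leaf_indices for c in node.children))
        return node

    root = build(anchor, z)
    clad = Cladogram(root=root, taxa=tuple(matrix.taxa), model=model)

    # preorder ids for internal nodes
    next_id = [1]
    for v in clad.nodes():
        if not v.is_leaf:
            v.id = next_id[0]
            next_id[0] += 1

    # Fitch downpass (state sets as 2-bit codes) and final pass with root
    # ancestral state forced to 0
    codes: dict[int, np.ndarray] = {}

    def down(v: CladeNode) -> np.ndarray:
        if v.is_leaf:
            (i,) = v.leaf_indices
            code = np.where(matrix.entries[i] == 1, 2, 1).astype(np.uint8)
        else:
            parts = [down(c) for c in v.children]
            code = parts[0]
            for p in parts[1:]:
                inter = code & p
                code = np.where(inter != 0, inter, code | p).astype(np.uint8)
        codes[id(v)] = code
        return code

    down(root)
    ones_per_char = [frozenset(np.flatnonzero(matrix.entries[:, j] == 1).tolist())
                     for j in range(m)]

    def final(v: CladeNode, parent_state: np.ndarray):
        code = codes[id(v)]
        state = np.where(code == 2, 1, np.where(code == 1, 0, parent_state)).astype(np.int8)
        gained = np.flatnonzero((state == 1) & (parent_state == 0))
        v.reconstructed_gains = [int(j) for j in gained]
        v.strict_synapomorphies = [
            j for j in range(m) if ones_per_char[j] == v.leaf_indices
        ]
        for c in v.children:
            final(c, state)

    final(root, np.zeros(m, dtype=np.int8))
    return clad


# ---------------------------------------------------------------------------
# Strict consensus

def _tree_from_clades(clades: set[frozenset[int]], taxa: tuple[str, ...]) -> Cladogram:
    full = frozenset(range(len(taxa)))
    work = {c for c in clades if 1 < len(c) < len(taxa)}
    nodes: dict[frozenset[int], CladeNode] = {}
    root = CladeNode()
    root.leaf_indices = full
    nodes[full] = root
    for c in sorted(work, key=len, reverse=True):
        node = CladeNode()
        node.leaf_indices = c
        parents = [p for p in nodes if c < p]
        parent = min(parents, key=len)
        nodes[parent].children.append(node)
        nodes[c] = node
    for i, name in enumerate(taxa):
        leaf = CladeNode(name=name)
        leaf.leaf_indices = frozenset([i])
        parents = [p for p in nodes if i in p]
        nodes[min(parents, key=len)].children.append(leaf)
    clad = Cladogram(root=root, taxa=taxa)
    next_id = [1]
    for v in clad.nodes():
        if not v.is_leaf:
            v.id = next_id[0]
            next_id[0] += 1
    return clad


def strict_consensus(trees: Sequence) -> Cladogram:
    """Tree containing exactly the clades present in every input tree.

    Accepts rooted Cladograms (clade-set intersection) or UnrootedTrees
    (bipartition intersection; the result is then returned rooted at the
    first taxon's stem purely for representation, flagged in ``note``).
    """
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one tree")
    if isinstance(trees[0], Cladogram):
        taxa = trees[0].taxa
        if any(set(t.taxa) != set(taxa) for t in trees):
            raise ValueError("trees have different leaf sets")
        common = set.intersection(*(set(t.internal_clades()) for t in trees))
        idx = {name: i for i, name in enumerate(taxa)}
        clades = {frozenset(idx[x] for x in c) for c in common}
        return _tree_from_clades(clades, taxa)
    taxa = trees[0].taxa
    if any(set(t.taxa) != set(taxa) for t in trees):
        raise ValueError("trees have different leaf sets")

    def named(t: UnrootedTree) -> set[frozenset[str]]:
        return {frozenset(t.taxa[i] for i in s) for s in t.splits()}

    common = set.intersection(*(named(t) for t in trees))
    idx = {name: i for i, name in enumerate(taxa)}
    clades = {frozenset(idx[x] for x in c) for c in common}
    out = _tree_from_clades(clades, tuple(taxa))
    out.note = "rooted at the first taxon's stem for representation only"
    return out


def annotate_strict(clad: Cladogram, matrix: BinaryCharacterMatrix) -> Cladogram:
    """Fill strict synapomorphy lists of an (e.g. consensus) cladogram."""
    m = matrix.shape[1]
    idx = {name: i for i, name in enumerate(matrix.taxa)}
    ones = [frozenset(np.flatnonzero(matrix.entries[:, j] == 1).tolist())
            for j in range(m)]
    for v in clad.nodes():
        leafset = frozenset(idx[clad.taxa[i]] for i in v.leaf_indices)
        v.strict_synapomorphies = [j for j in range(m) if ones[j] == leafset]
    return clad
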