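"""Exact signed reversal distance and rearrangement-based branch lengths.

The minimum number of reversals transforming one signed gene order into
another is computed exactly from the breakpoint graph: with n genes, c
alternating cycles, h hurdles and a fortress indicator f, the distance is
d = n + 1 - c + h + f (Hannenhalli-Pevzner).  Circular gene orders are
reduced to a canonical linear representative by anchoring one gene, the
standard circular-to-linear reduction.  A breadth-first-search oracle over
the full reversal graph validates the implementation for small n.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
import scipy.optimize

from .characters import ensure_node_labels
from .gene_order import SignedGeneOrder


@dataclass
class BreakpointGraphStats:
    n: int
    breakpoints: int
    cycles: int
    hurdles: int
    fortress: int
    distance: int


# --- breakpoint graph --------------------------------------------------------


def hp_stats(perm: tuple[int, ...]) -> BreakpointGraphStats:
    """Breakpoint-graph statistics of a signed permutation vs the identity.

    ``perm`` is a signed permutation of 1..n (linear).  Elements are doubled
    (+x -> 2x-1,2x; -x -> 2x,2x-1) and capped with 0 and 2n+1; black edges
    join consecutive positions, gray edges join consecutive values.
    """
    n = len(perm)
    if sorted(abs(x) for x in perm) != list(range(1, n + 1)):
        raise ValueError("not a signed permutation of 1..n")
    seq = [0]
    for x in perm:
        v = abs(x)
        seq.extend((2 * v - 1, 2 * v) if x > 0 else (2 * v, 2 * v - 1))
    seq.append(2 * n + 1)
    m = len(seq)  # 2n + 2
    pos = [0] * m
    for i, v in enumerate(seq):
        pos[v] = i

    def gray_mate(p: int) -> int:
        v = seq[p]
        return pos[v + 1] if v % 2 == 0 else pos[v - 1]

    def black_mate(p: int) -> int:
        return p + 1 if p % 2 == 0 else p - 1

    # cycle decomposition
    cycle_id = [-1] * m
    n_cycles = 0
    cycle_sizes: list[int] = []
    for start in range(m):
        if cycle_id[start] != -1:
            continue
        size = 0
        p = start
        while cycle_id[p] == -1:
            cycle_id[p] = n_cycles
            q = black_mate(p)
            cycle_id[q] = n_cycles
            size += 1
            p = gray_mate(q)
        n_cycles += 1
        cycle_sizes.append(size)

    adjacencies = sum(1 for s in cycle_sizes if s == 1)
    breakpoints = (n + 1) - adjacencies

    # gray edges with orientation; a gray edge spanning positions (p, q) is
    # oriented iff p + q is even (acting on its black edges flips a sign)
    gray_edges = []
    for i in range(n + 1):
        p, q = sorted((pos[2 * i], pos[2 * i + 1]))
        gray_edges.append((p, q, cycle_id[p], (p + q) % 2 == 0))

    nontrivial = {cid for cid, s in enumerate(cycle_sizes) if s > 1}
    # interleaving components via union-find over crossing gray edges
    parent = {cid: cid for cid in nontrivial}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    edges = [e for e in gray_edges if e[2] in nontrivial]
    for (p1, q1, c1, _), (p2, q2, c2, _) in combinations(edges, 2):
        if c1 != c2 and (p1 < p2 < q1 < q2 or p2 < p1 < q2 < q1):
            union(c1, c2)

    comp_span: dict[int, list[int]] = {}
    comp_oriented: dict[int, bool] = {}
    for p, q, cid, oriented in edges:
        root = find(cid)
        span = comp_span.setdefault(root, [p, q])
        span[0] = min(span[0], p)
        span[1] = max(span[1], q)
        comp_oriented[root] = comp_oriented.get(root, False) or oriented

    unoriented = [tuple(comp_span[r]) for r in comp_span if not comp_oriented[r]]
    hurdles = _hurdles(unoriented)
    fortress = int(
        len(hurdles) % 2 == 1
        and len(hurdles) >= 3
        and all(_is_superhurdle(span, unoriented) for span in hurdles)
    )
    distance = n + 1 - n_cycles + len(hurdles) + fortress
    return BreakpointGraphStats(
        n=n, breakpoints=breakpoints, cycles=n_cycles,
        hurdles=len(hurdles), fortress=fortress, distance=distance,
    )


def _contains(outer: tuple[int, int], inner: tuple[int, int]) -> bool:
    return outer[0] < inner[0] and inner[1] < outer[1]


def _hurdles(unoriented: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Unoriented components that do not separate other unoriented components.

    Component spans are pairwise nested or disjoint; a component is a hurdle
    iff the other unoriented components lie entirely inside it or entirely
    outside it.
    """
    out = []
    for span in unoriented:
        others = [s for s in unoriented if s != span]
        inside = sum(_contains(span, s) for s in others)
        if inside == 0 or inside == len(others):
            out.append(span)
    return out


def _is_superhurdle(span: tuple[int, int],
                    unoriented: list[tuple[int, int]]) -> bool:
    """A hurdle whose removal turns another unoriented component into a hurdle."""
    rest = [s for s in unoriented if s != span]
    before = set(_hurdles(unoriented))
    after = set(_hurdles(rest))
    return bool(after - before)


# --- order reduction ---------------------------------------------------------


def _relabel(a: SignedGeneOrder, b: SignedGeneOrder) -> tuple[int, ...]:
    """Express order a as a signed permutation in the coordinates of b."""
    if len(a) != len(b):
        raise ValueError("orders must have equal length")
    sa, sb = a.symbols(), b.symbols()
    if set(sa) != set(sb):
        diff = set(sa).symmetric_difference(sb)
        raise ValueError(f"gene sets differ: {sorted(diff)}")
    if len(set(sa)) != len(sa):
        raise ValueError("orders must contain one copy per gene")
    code = {name: i + 1 for i, (name, sign) in enumerate(b.signed_symbols())}
    flip = {name: sign for name, sign in b.signed_symbols()}
    return tuple(code[name] * sign * flip[name]
                 for name, sign in a.signed_symbols())


def _canonical_linear(perm: tuple[int, ...]) -> tuple[int, ...]:
    """Reduce a circular signed permutation to its linear representative.

    Rotate (and if needed reflect) so that element 1 sits first with sign +,
    then drop it and renumber the remainder 1..n-1: sorting a circular order
    of n genes is equivalent to sorting this linear order of n-1.
    """
    n = len(perm)
    idx = next(i for i, x in enumerate(perm) if abs(x) == 1)
    rotated = perm[idx:] + perm[:idx]
    if rotated[0] < 0:
        rotated = tuple(-x for x in reversed(rotated))
        rotated = rotated[-1:] + rotated[:-1]
    return tuple((abs(x) - 1) * (1 if x > 0 else -1) for x in rotated[1:])


def reversal_distance(a: SignedGeneOrder, b: SignedGeneOrder
                      ) -> BreakpointGraphStats:
    """Exact minimum number of signed reversals between two gene orders.

    Both orders must cover the same gene set with one copy per gene (reduce
    duplicated genes first, e.g. with ``extract_signed_order(...,
    dedup='one-ir-copy')``).  Circular orders are compared via the canonical
    linear reduction.
    """
    perm = _relabel(a, b)
    circular = a.topology == "circular" and b.topology == "circular"
    if circular:
        perm = _canonical_linear(perm)
    return hp_stats(perm)


# --- BFS oracle --------------------------------------------------------------


@lru_cache(maxsize=None)
def _bfs_table(n: int) -> dict[tuple[int, ...], int]:
    """Distance from the identity to every signed permutation of size n."""
    identity = tuple(range(1, n + 1))
    dist = {identity: 0}
    frontier = [identity]
    while frontier:
        nxt = []
        for p in frontier:
            d = dist[p]
            for i in range(n):
                for j in range(i, n):
                    q = (p[:i]
                         + tuple(-x for x in reversed(p[i:j + 1]))
                         + p[j + 1:])
                    if q not in dist:
                        dist[q] = d + 1
                        nxt.append(q)
        frontier = nxt
    return dist


def brute_force_distance(a: SignedGeneOrder | tuple[int, ...],
                         b: SignedGeneOrder | tuple[int, ...] | None = None,
                         n_max: int = 7) -> int:
    """Reversal distance by exhaustive breadth-first search (n <= n_max).

    Accepts two gene orders, or a single signed permutation (distance to the
    identity).  Entirely independent of the breakpoint-graph computation.
    """
    if isinstance(a, SignedGeneOrder):
        perm = _relabel(a, b)
        if a.topology == "circular" and b.topology == "circular":
            perm = _canonical_linear(perm)
    else:
        perm = tuple(a)
    n = len(perm)
    if n > n_max:
        raise ValueError(f"brute force limited to n <= {n_max} (got {n})")
    if n == 0:
        return 0
    return _bfs_table(n)[perm]


# --- distance matrices and branch lengths ------------------------------------


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray
    stats: dict[tuple[str, str], BreakpointGraphStats]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="taxon")

    def value(self, a: str, b: str) -> int:
        return int(self.matrix[self.taxa.index(a), self.taxa.index(b)])


def distance_matrix(orders: list[SignedGeneOrder],
                    gene_set: set[str] | None = None) -> DistanceMatrix:
    """All pairwise reversal distances over a shared gene set."""
    if len(orders) < 2:
        raise ValueError("need at least two gene orders")
    if gene_set is None:
        gene_set = set(orders[0].symbols())
        for o in orders[1:]:
            gene_set &= set(o.symbols())
    reduced = []
    for o in orders:
        seen = set()
        genes = []
        for name, copy, sign in o.genes:
            if name in gene_set and name not in seen:
                genes.append((name, copy, sign))
                seen.add(name)
        reduced.append(SignedGeneOrder(o.taxon_id, genes, o.topology))
    taxa = [o.taxon_id for o in reduced]
    k = len(taxa)
    mat = np.zeros((k, k), dtype=int)
    stats = {}
    for i in range(k):
        for j in range(i + 1, k):
            s = reversal_distance(reduced[i], reduced[j])
            mat[i, j] = mat[j, i] = s.distance
            stats[(taxa[i], taxa[j])] = s
    return DistanceMatrix(taxa=taxa, matrix=mat, stats=stats)


def fit_branch_lengths(dm: DistanceMatrix, tree: dendropy.Tree
                       ) -> tuple[dict[str, float], float]:
    """Nonnegative least-squares additive branch lengths for a fixed topology.

    Approximates rearrangement branch lengths by fitting the pairwise
    reversal distances to the tree's path structure; returns per-branch
    lengths keyed by child-node label, plus the sum-of-squares residual.
    Exact ancestral-gene-order (median-genome) reconstruction is out of
    scope, so the result is labeled approximate.
    """
    ensure_node_labels(tree)
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    missing = set(dm.taxa) - set(leaves)
    if missing:
        raise ValueError(f"distance-matrix taxa not in tree: {sorted(missing)}")
    nodes = [n for n in tree.preorder_node_iter() if n is not tree.seed_node]
    col = {n: i for i, n in enumerate(nodes)}
    rows, y = [], []
    for a, b in combinations(dm.taxa, 2):
        na, nb = leaves[a], leaves[b]
        anc_a = set()
        cur = na
        while cur is not None:
            anc_a.add(cur)
            cur = cur.parent_node
        path = []
        cur = nb
        while cur not in anc_a:
            path.append(cur)
            cur = cur.parent_node
        meet = cur
        cur = na
        while cur is not meet:
            path.append(cur)
            cur = cur.parent_node
        row = np.zeros(len(nodes))
        for node in path:
            row[col[node]] = 1.0
        rows.append(row)
        y.append(dm.value(a, b))
    A = np.vstack(rows)
    x, rnorm = scipy.optimize.nnls(A, np.asarray(y, dtype=float))
    lengths = {n.label: float(v) for n, v in zip(nodes, x)}
    return lengths, float(rnorm ** 2)


def annotate_tree_lengths(tree: dendropy.Tree,
                          lengths: dict[str, float]) -> str:
    """Write the fitted lengths onto the tree; return the newick string."""
    for node in tree.preorder_node_iter():
        if node.label in lengths:
            node.edge.length = lengths[node.label]
    return tree.as_string(schema="newick").strip()
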