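import random

import numpy as np
import pytest

from plastcomp.characters import load_tree
from plastcomp.gene_order import SignedGeneOrder
from plastcomp.rearrangement import (brute_force_distance, distance_matrix,
                                     fit_branch_lengths, hp_stats,
                                     reversal_distance)


def _order(taxon, signed, topology="linear"):
    return SignedGeneOrder(
        taxon, [(f"g{abs(x)}", 1, 1 if x > 0 else -1) for x in signed],
        topology)


def _apply_reversal(genes, i, j):
    return (genes[:i]
            + [(n, c, -s) for n, c, s in reversed(genes[i:j])]
            + genes[j:])


def test_identical_orders_have_zero_distance():
    a = _order("a", [1, -2, 3], "circular")
    b = _order("b", [1, -2, 3], "circular")
    s = reversal_distance(a, b)
    assert s.distance == 0 and s.breakpoints == 0


def test_single_reversal_distance_one():
    base = [(f"g{i}", 1, 1) for i in range(8)]
    a = SignedGeneOrder("a", base, "linear")
    b = SignedGeneOrder("b", _apply_reversal(base, 2, 6), "linear")
    assert reversal_distance(a, b).distance == 1


def test_unsigned_transposition_needs_three_reversals():
    # the classic hurdle case: swapping two positive genes costs 3
    a = _order("a", [2, 1])
    b = _order("b", [1, 2])
    s = reversal_distance(a, b)
    assert s.distance == 3
    assert s.hurdles == 1
    assert s.distance > s.n + 1 - s.cycles


@pytest.mark.parametrize("seed", [0, 1])
def test_matches_bfs_oracle_on_random_pairs(seed):
    rng = random.Random(seed)
    for _ in range(60):
        n = rng.randint(1, 6)
        perm = list(range(1, n + 1))
        rng.shuffle(perm)
        perm = tuple(x * rng.choice([1, -1]) for x in perm)
        assert hp_stats(perm).distance == brute_force_distance(perm)


def test_distance_invariant_under_rotation_and_reflection():
    rng = random.Random(4)
    base = [(f"g{i}", 1, rng.choice([1, -1])) for i in range(9)]
    shuffled = list(base)
    rng.shuffle(shuffled)
    a = SignedGeneOrder("a", shuffled, "circular")
    b = SignedGeneOrder("b", base, "circular")
    d0 = reversal_distance(a, b).distance
    for k in (1, 4, 7):
        assert reversal_distance(a.rotate(k), b).distance == d0
        assert reversal_distance(a, b.rotate(k)).distance == d0
    assert reversal_distance(a.reverse_complement(), b).distance == d0
    assert reversal_distance(a, b.reverse_complement()).distance == d0


def test_distance_invariant_under_relabeling():
    rng = random.Random(5)
    base = [(f"g{i}", 1, rng.choice([1, -1])) for i in range(7)]
    shuffled = list(base)
    rng.shuffle(shuffled)
    a = SignedGeneOrder("a", shuffled, "linear")
    b = SignedGeneOrder("b", base, "linear")
    d0 = reversal_distance(a, b).distance
    rename = {f"g{i}": f"x{9 - i}" for i in range(7)}
    a2 = SignedGeneOrder("a", [(rename[n], c, s) for n, c, s in a.genes],
                         "linear")
    b2 = SignedGeneOrder("b", [(rename[n], c, s) for n, c, s in b.genes],
                         "linear")
    assert reversal_distance(a2, b2).distance == d0


def test_unequal_gene_sets_rejected_with_difference():
    a = _order("a", [1, 2, 3])
    b = SignedGeneOrder("b", [("g1", 1, 1), ("g2", 1, 1), ("g9", 1, 1)],
                        "linear")
    with pytest.raises(ValueError, match="g9"):
        reversal_distance(a, b)


def test_distance_lower_bound_half_breakpoints():
    rng = random.Random(6)
    for _ in range(40):
        n = rng.randint(2, 7)
        perm = list(range(1, n + 1))
        rng.shuffle(perm)
        perm = tuple(x * rng.choice([1, -1]) for x in perm)
        s = hp_stats(perm)
        assert s.distance >= s.breakpoints / 2
        assert s.distance >= 0


def test_distance_matrix_properties(sim_bundle):
    orders = [sim_bundle["leaves"][k].signed_order() for k in "ABCDEF"]
    dm = distance_matrix(orders)
    assert np.all(np.diag(dm.matrix) == 0)
    assert np.array_equal(dm.matrix, dm.matrix.T)
    # triangle inequality
    k = len(dm.taxa)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                assert dm.matrix[i, j] <= dm.matrix[i, l] + dm.matrix[l, j]


def test_identical_orders_zero_matrix():
    base = [(f"g{i}", 1, 1) for i in range(10)]
    orders = [SignedGeneOrder(t, list(base), "circular") for t in "xyz"]
    dm = distance_matrix(orders)
    assert dm.matrix.sum() == 0


def test_branch_lengths_recover_additive_metric():
    tree = load_tree("((A:2,B:3):1,(C:4,D:1):2);")
    import itertools
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    taxa = sorted(leaves)
    mat = np.zeros((4, 4))
    for a, b in itertools.combinations(taxa, 2):
        pdist = {("A", "B"): 5, ("A", "C"): 9, ("A", "D"): 6,
                 ("B", "C"): 10, ("B", "D"): 7, ("C", "D"): 5}[(a, b)]
        i, j = taxa.index(a), taxa.index(b)
        mat[i, j] = mat[j, i] = pdist
    from plastcomp.rearrangement import DistanceMatrix
    dm = DistanceMatrix(taxa=taxa, matrix=mat, stats={})
    lengths, residual = fit_branch_lengths(dm, tree)
    assert residual == pytest.approx(0.0, abs=1e-12)
    assert lengths["A"] == pytest.approx(2.0, abs=1e-9)
    assert lengths["C"] == pytest.approx(4.0, abs=1e-9)


def test_branch_lengths_star_symmetry():
    tree = load_tree("(A:1,B:1,C:1);")
    from plastcomp.rearrangement import DistanceMatrix
    mat = np.full((3, 3), 6.0)
    np.fill_diagonal(mat, 0.0)
    dm = DistanceMatrix(taxa=["A", "B", "C"], matrix=mat, stats={})
    lengths, residual = fit_branch_lengths(dm, tree)
    assert residual == pytest.approx(0.0, abs=1e-12)
    assert all(lengths[t] == pytest.approx(3.0, abs=1e-9) for t in "ABC")


def test_planted_reversals_bound_matrix(sim_bundle):
    # distances can never exceed the number of planted reversals on the path
    truth = sim_bundle["truth"]
    leaves = sim_bundle["leaves"]
    tree = sim_bundle["tree"]
    counts = {label: sum(1 for e in evs if e["kind"] == "reversal")
              for label, evs in truth.events.items()}
    # path A..B passes through branches A and B only
    k = counts["A"] + counts["B"]
    a, b = leaves["A"].signed_order(), leaves["B"].signed_order()
    common = set(a.symbols()) & set(b.symbols())
    a.genes = [g for g in a.genes if g[0] in common]
    b.genes = [g for g in b.genes if g[0] in common]
    assert reversal_distance(a, b).distance <= k


# --- property tests ----------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@st.composite
def signed_permutations(draw, max_n=6):
    n = draw(st.integers(min_value=1, max_value=max_n))
    perm = draw(st.permutations(list(range(1, n + 1))))
    signs = draw(st.lists(st.sampled_from([1, -1]), min_size=n, max_size=n))
    return tuple(p * s for p, s in zip(perm, signs))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(signed_permutations())
def test_distance_symmetric_under_inversion(perm):
    """Sorting a permutation costs the same as sorting its inverse: the
    reversal distance between two orders does not depend on which one is
    taken as the reference frame."""
    n = len(perm)
    inverse = [0] * n
    for i, x in enumerate(perm):
        inverse[abs(x) - 1] = (i + 1) * (1 if x > 0 else -1)
    assert hp_stats(perm).distance == hp_stats(tuple(inverse)).distance


@settings(max_examples=60, deadline=None, derandomize=True)
@given(signed_permutations())
def test_distance_zero_iff_identity(perm):
    s = hp_stats(perm)
    is_identity = perm == tuple(range(1, len(perm) + 1))
    assert (s.distance == 0) == is_identity
    assert s.breakpoints <= 2 * s.distance or is_identity
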