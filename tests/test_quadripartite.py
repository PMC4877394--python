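import itertools
import random

import pytest

from plastcomp.model import AnnotatedGenome, GeneFeature, revcomp
from plastcomp.quadripartite import (classify_partitioning,
                                     detect_inverted_repeat,
                                     min_removals_to_segregate,
                                     partition_genes)


def _rotate_genome(genome, k):
    L = genome.length
    seq = genome.sequence[k:] + genome.sequence[:k]
    feats = []
    for f in genome.features:
        exons = []
        for s, e in f.exons:
            span = e - s
            s2 = (s - k) % L
            exons.append((s2, s2 + span))
        feats.append(GeneFeature(name=f.name, category=f.category,
                                 exons=exons, strand=f.strand,
                                 copy_index=f.copy_index))
    return AnnotatedGenome(taxon_id=genome.taxon_id, sequence=seq,
                           topology="circular", features=feats)


def test_planted_ir_recovered_exactly(sim_bundle, ancestor_genome):
    truth = sim_bundle["ancestor"].ir_coordinates()
    q = detect_inverted_repeat(ancestor_genome)
    assert q.has_ir
    assert (q.ir_a, q.ir_b) == (truth["ir_a"], truth["ir_b"])
    assert q.ir_length == truth["ir_length"]
    assert q.identity == 1.0


def test_region_tiling_invariant(ancestor_genome):
    q = detect_inverted_repeat(ancestor_genome)
    total = sum(iv[1] - iv[0] for iv in (q.ir_a, q.ir_b, q.ssc, q.lsc))
    assert total == ancestor_genome.length
    assert (q.ssc[1] - q.ssc[0]) <= (q.lsc[1] - q.lsc[0])


def test_no_repeat_sequence_has_no_ir():
    rng = random.Random(3)
    seq = "".join(rng.choice("ACGT") for _ in range(8000))
    g = AnnotatedGenome(taxon_id="r", sequence=seq, topology="circular")
    assert not detect_inverted_repeat(g, min_len=1000).has_ir


def test_short_genome_warns_and_reports_no_ir():
    g = AnnotatedGenome(taxon_id="s", sequence="ACGT" * 100,
                        topology="circular")
    with pytest.warns(UserWarning):
        q = detect_inverted_repeat(g, min_len=1000)
    assert not q.has_ir


def test_detection_is_rotation_invariant(ancestor_genome):
    q0 = detect_inverted_repeat(ancestor_genome)
    for k in (1234, ancestor_genome.length // 2):
        q = detect_inverted_repeat(_rotate_genome(ancestor_genome, k))
        assert q.has_ir
        assert q.ir_length == q0.ir_length
        assert {q.ssc[1] - q.ssc[0], q.lsc[1] - q.lsc[0]} == \
            {q0.ssc[1] - q0.ssc[0], q0.lsc[1] - q0.lsc[0]}


def test_detection_survives_reverse_complement(ancestor_genome):
    q0 = detect_inverted_repeat(ancestor_genome)
    rc = AnnotatedGenome(taxon_id="rc", sequence=revcomp(
        ancestor_genome.sequence), topology="circular")
    q = detect_inverted_repeat(rc)
    assert q.has_ir and q.ir_length == q0.ir_length
    assert {q.ssc[1] - q.ssc[0], q.lsc[1] - q.lsc[0]} == \
        {q0.ssc[1] - q0.ssc[0], q0.lsc[1] - q0.lsc[0]}


def test_rdna_operon_genes_labeled_ir(sim_bundle, ancestor_genome):
    q = detect_inverted_repeat(ancestor_genome)
    pattern = partition_genes(ancestor_genome, q)
    for gene in ("rrs", "rrl", "rrf", "trnI(gau)", "trnA(ugc)"):
        regions = {r for (n, c), r in pattern.region_of.items() if n == gene}
        assert regions == {"IR"}, gene


def test_straddling_gene_majority_rule():
    # 10 kb circle with an exact 2 kb IR at [2000,4000) and [6000,8000)
    rng = random.Random(7)
    core = "".join(rng.choice("ACGT") for _ in range(2000))
    sc1 = "".join(rng.choice("ACGT") for _ in range(2000))
    sc2 = "".join(rng.choice("ACGT") for _ in range(2000))
    seq = sc1 + core + sc2 + revcomp(core) + sc1[::-1]
    feats = [
        # 60% inside the single-copy gap [4000,6000), 40% in the IR
        GeneFeature("straddler", "protein", [(5700, 6200)], 1),
        GeneFeature("inside", "protein", [(2100, 2400)], 1),
    ]
    g = AnnotatedGenome(taxon_id="t", sequence=seq, topology="circular",
                        features=feats)
    q = detect_inverted_repeat(g, min_len=500)
    assert q.has_ir
    pattern = partition_genes(g, q)
    assert pattern.region_of[("inside", 1)] == "IR"
    assert pattern.region_of[("straddler", 1)] in ("SSC", "LSC")
    assert ("straddler", 1) in pattern.straddlers


def test_irless_genome_single_region(sim_bundle):
    from plastcomp.simulate import apply_event
    sim = sim_bundle["ancestor"].clone("noir")
    apply_event(sim, {"kind": "ir_loss"})
    g = sim.render()
    q = detect_inverted_repeat(g)
    pattern = partition_genes(g, q)
    assert set(pattern.region_of.values()) == {"SC"}


# --- segregation scoring -----------------------------------------------------


def _brute_min_removals(labels):
    """Oracle: smallest subset whose removal leaves each side contiguous."""
    m = len(labels)

    def contiguous(kept):
        for side in ("ssc-side", "lsc-side"):
            idx = [i for i, k in enumerate(kept) if k == side]
            if not idx:
                continue
            n = len(kept)
            # circular contiguity: one maximal gap between occurrences
            gaps = sum(1 for i in range(n)
                       if kept[i] == side and kept[(i + 1) % n] != side)
            if gaps > 1:
                return False
        return True

    for k in range(m + 1):
        for drop in itertools.combinations(range(m), k):
            kept = [lab for i, lab in enumerate(labels) if i not in drop]
            if contiguous(kept):
                return k
    return m


@pytest.mark.parametrize("seed", range(8))
def test_segregation_matches_bruteforce(seed):
    rng = random.Random(seed)
    labels = [rng.choice(["ssc-side", "lsc-side"])
              for _ in range(rng.randint(4, 12))]
    assert min_removals_to_segregate(labels) == _brute_min_removals(labels)


def test_identical_partitioning_zero_violations(ancestor_genome):
    q = detect_inverted_repeat(ancestor_genome)
    pattern = partition_genes(ancestor_genome, q)
    report = classify_partitioning(pattern, pattern)
    assert report.violations == 0


def test_single_translocation_is_one_violation(ancestor_genome):
    q = detect_inverted_repeat(ancestor_genome)
    ref = partition_genes(ancestor_genome, q)
    target = partition_genes(ancestor_genome, q)
    # move one SSC gene deep into the LSC arc of the circular order
    ssc_genes = [i for i, (n, r) in enumerate(target.order) if r == "SSC"]
    lsc_genes = [i for i, (n, r) in enumerate(target.order) if r == "LSC"]
    moved = target.order.pop(ssc_genes[len(ssc_genes) // 2])
    target.order.insert(lsc_genes[len(lsc_genes) // 2], moved)
    report = classify_partitioning(target, ref)
    assert report.violations == 1


def test_heavy_shuffling_produces_violations(sim_bundle):
    from plastcomp.simulate import SimulationConfig, apply_event, \
        simulate_ancestor
    import numpy as np
    sim = sim_bundle["ancestor"].clone("shuffled")
    apply_event(sim, {"kind": "ir_loss"})
    rng = np.random.default_rng(5)
    for _ in range(50):
        elems = sim.regions()["all"]
        i, j = sorted(rng.integers(0, len(elems), size=2))
        apply_event(sim, {"kind": "reversal", "region": "all",
                          "i": int(i), "j": int(j) + 1})
    g = sim.render()
    q = detect_inverted_repeat(g)
    ref_g = sim_bundle["ancestor"].render()
    ref = partition_genes(ref_g, detect_inverted_repeat(ref_g))
    target = partition_genes(g, q)
    report = classify_partitioning(target, ref)
    assert report.violations > 0
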