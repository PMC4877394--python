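import random

import numpy as np
import pytest

from plastcomp.model import AnnotatedGenome, GeneFeature, revcomp
from plastcomp.seqstats import (codon_decoding_audit, colinear_divergence,
                                find_repeats, gc_by_codon_position,
                                gc_content, repeat_summary)


def _rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


# --- composition -------------------------------------------------------------


@pytest.mark.parametrize("seq,expected", [
    ("GGCC", 1.0),
    ("AATT", 0.0),
    ("GANC", 2 / 3),  # N excluded from the denominator
])
def test_gc_content_values(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


def test_gc_content_complement_symmetric():
    rng = random.Random(0)
    seq = _rand_seq(rng, 500)
    assert gc_content(seq) == pytest.approx(gc_content(revcomp(seq)))


def test_gc_content_empty_rejected():
    with pytest.raises(ValueError):
        gc_content("NNN")


def test_gc_by_codon_position_construction():
    assert gc_by_codon_position(["GATGAT"]) == pytest.approx((1.0, 0.0, 0.0))


def test_gc_by_codon_position_weighted_mean_property():
    import warnings as _warnings
    rng = random.Random(1)
    genes = [_rand_seq(rng, 3 * rng.randint(20, 60)) for _ in range(5)]
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # random genes contain stop codons
        combined = gc_by_codon_position(genes)
        per_gene = [gc_by_codon_position([g]) for g in genes]
    weights = [len(g) // 3 for g in genes]
    for p in range(3):
        mean = sum(w * v[p] for w, v in zip(weights, per_gene)) / sum(weights)
        assert combined[p] == pytest.approx(mean)


def test_gc_by_codon_position_warns_on_internal_stops():
    with pytest.warns(UserWarning):
        gc_by_codon_position(["ATGTAACCC"])


def test_gc_by_codon_position_empty_rejected():
    with pytest.raises(ValueError):
        gc_by_codon_position([])


# --- repeats -----------------------------------------------------------------


def _oracle_repeats(seq, min_len):
    """All maximal repeated pairs by per-offset numpy run scanning."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    L = len(seq)
    out = set()

    def runs(eq):
        idx = np.flatnonzero(eq)
        if idx.size == 0:
            return []
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]

    for d in range(1, L):
        eq = arr[:-d] == arr[d:]
        for s, e in runs(eq):
            if e - s >= min_len:
                out.add(("direct", (s, e), (s + d, e + d)))
    rc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    for d in range(-(L - 1), L):
        if d >= 0:
            eq = arr[d:] == rc[:L - d]
            base_a, base_r = d, 0
        else:
            eq = arr[:L + d] == rc[-d:]
            base_a, base_r = 0, -d
        for s, e in runs(eq):
            if e - s >= min_len:
                a = (base_a + s, base_a + e)
                p = base_r + s
                b = (L - p - (e - s), L - p)
                if a == b:
                    continue
                out.add(("inverted",) + tuple(sorted((a, b))))
    return out


@pytest.mark.parametrize("seed,length", [(2, 1500), (3, 3000)])
def test_find_repeats_matches_quadratic_oracle(seed, length):
    rng = random.Random(seed)
    seq = _rand_seq(rng, length)
    # plant a direct pair and an inverted pair
    motif = _rand_seq(rng, 45)
    seq = seq[:200] + motif + seq[200:900] + motif + seq[900:]
    seq = seq[:1300] + revcomp(motif) + seq[1300:]
    cat = find_repeats(seq, min_len=30)
    got = {(r.kind, r.copy1, r.copy2) for r in cat.records}
    assert got == _oracle_repeats(seq, 30)


def test_random_sequence_has_negligible_repeat_content():
    rng = random.Random(8)
    seq = _rand_seq(rng, 100_000)
    cat = find_repeats(seq, min_len=30)
    assert cat.masked_fraction < 0.001


def test_three_planted_copies_found_pairwise():
    rng = random.Random(9)
    motif = _rand_seq(rng, 40)
    back = _rand_seq(rng, 3000)
    # pairwise-distinct flanking bases prevent chance extension of any pair
    seq = back[:500] + "C" + motif + "C" + back[500:1500] + "G" + motif \
        + "G" + back[1500:2500] + "T" + motif + "T" + back[2500:]
    cat = find_repeats(seq, min_len=30, kinds=("direct",))
    assert len(cat.records) == 3  # three pairwise maximal matches
    masked = sum(e - s for s, e in cat.masked_intervals)
    assert masked == 120


def test_planted_palindrome_reported_as_inverted():
    rng = random.Random(10)
    half = _rand_seq(rng, 35)
    back = _rand_seq(rng, 2000)
    seq = back[:600] + half + back[600:1400] + revcomp(half) + back[1400:]
    cat = find_repeats(seq, min_len=30, kinds=("inverted",))
    assert any(r.kind == "inverted" and r.length >= 35 for r in cat.records)


def test_gc_rich_repeats_stand_out_from_at_background():
    rng = random.Random(11)
    back = "".join(rng.choice("AATT" + "GC") for _ in range(4000))
    motif = "".join(rng.choice("GGCC" + "AT") for _ in range(60))
    seq = back[:1000] + motif + back[1000:2500] + motif + back[2500:]
    cat = find_repeats(seq, min_len=30, kinds=("direct",))
    summary = repeat_summary(seq, cat)
    assert summary.gc_repeat > summary.gc_unique


# --- colinear divergence -----------------------------------------------------


def test_identical_sequences_diverge_nowhere():
    rng = random.Random(12)
    seq = _rand_seq(rng, 20_000)
    rep = colinear_divergence(seq, seq)
    assert rep.total_sites == 0
    assert rep.aligned_fraction == pytest.approx(1.0)
    assert rep.colinear


def test_planted_mutations_recovered_exactly():
    rng = random.Random(13)
    a = _rand_seq(rng, 100_000)
    b = list(a)
    sub_pos = rng.sample(range(1000, 99_000), 10)
    for p in sub_pos:
        b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
    b = "".join(b)
    # two deletions, lengths 2 and 4, far from the substitutions
    b = b[:30_500] + b[30_502:]
    b = b[:60_500] + b[60_504:]
    rep = colinear_divergence(a, b)
    assert rep.substitution_sites == 10
    assert rep.indel_events == 2
    assert sorted(rep.indel_lengths) == [2, 4]
    assert rep.total_sites == 12


def test_substitution_count_symmetric():
    rng = random.Random(14)
    a = _rand_seq(rng, 30_000)
    b = list(a)
    for p in rng.sample(range(500, 29_500), 25):
        b[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b[p]]
    b = "".join(b)
    assert colinear_divergence(a, b).substitution_sites \
        == colinear_divergence(b, a).substitution_sites


def test_rearranged_sequences_flagged_non_colinear():
    rng = random.Random(15)
    a = _rand_seq(rng, 20_000)
    b = a[13_000:] + revcomp(a[:13_000])
    rep = colinear_divergence(a, b)
    assert not rep.colinear


# --- codon decoding ----------------------------------------------------------


def _genome_with_trnas(trna_names, cds="ATGACTACCACAACGTAA"):
    feats = [GeneFeature("geneX", "protein", [(0, len(cds))], 1)]
    pos = len(cds) + 10
    for name in trna_names:
        feats.append(GeneFeature(name, "tRNA", [(pos, pos + 72)], 1))
        pos += 80
    seq = cds + "A" * (pos + 100 - len(cds))
    return AnnotatedGenome("t", seq, "circular", feats)


def test_full_ancestral_trna_set_decodes_everything():
    from plastcomp import catalog
    trnas = [g for g in catalog.ANCESTRAL_GENES if g.startswith("trn")]
    # a CDS using one codon from every sense family
    import itertools
    codons = [c for c in ("".join(t) for t in itertools.product("ACGT",
                                                                repeat=3))
              if c not in ("TAA", "TAG", "TGA")]
    cds = "ATG" + "".join(codons) + "TAA"
    audit = codon_decoding_audit(_genome_with_trnas(trnas, cds))
    assert audit.undecodable_superwobble == []


def test_missing_threonine_trnas_leave_acn_unreadable():
    from plastcomp import catalog
    trnas = [g for g in catalog.ANCESTRAL_GENES
             if g.startswith("trn") and not g.startswith("trnT")]
    audit = codon_decoding_audit(
        _genome_with_trnas(trnas, cds="ATGACTACCACAACGTAA"))
    assert set(audit.undecodable_superwobble) == {"ACT", "ACC", "ACA", "ACG"}
    assert set(audit.undecodable) >= {"ACT", "ACC", "ACA", "ACG"}


def test_empty_cds_set_gives_empty_audit():
    g = AnnotatedGenome("t", "ACGT" * 100, "circular",
                        [GeneFeature("trnF(gaa)", "tRNA", [(0, 72)], 1)])
    audit = codon_decoding_audit(g)
    assert audit.codon_usage == {}
    assert audit.undecodable == []
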