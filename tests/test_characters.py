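import itertools
import random

import dendropy
import pytest

from plastcomp.characters import (MISSING, CharacterMatrix, build_gene_matrix,
                                  build_intron_matrix, build_ir_matrix,
                                  classify_events, dollo_map,
                                  fitch_wagner_map, load_tree,
                                  reconstruct_leaf_states)


def _random_tree(rng, n_leaves):
    taxa = [f"t{i}" for i in range(n_leaves)]
    ns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_leaves,
        taxon_namespace=ns, rng=rng)
    tree.is_rooted = True
    return tree, taxa


def _matrix(taxa, states, kind="gene"):
    return CharacterMatrix(taxa=taxa, labels=["c1"], kind=kind,
                           states=[[s] for s in states])


def _dollo_oracle(tree, obs, root_presence):
    """Minimal loss count by exhaustive search over loss-branch subsets."""
    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    ones = [t for t, v in obs.items() if v == 1]
    if not ones and not root_presence:
        return 0
    if root_presence:
        gain = tree.seed_node
    elif len(ones) == 1:
        gain = leaves[ones[0]]
    else:
        gain = tree.mrca(taxa=[tree.taxon_namespace.get_taxon(t)
                               for t in ones])
    candidates = [n for n in gain.preorder_iter() if n is not gain]
    below_gain = {l.taxon.label for l in gain.leaf_iter()}

    def consistent(subset):
        lost = set()
        for n in subset:
            lost |= {l.taxon.label for l in n.leaf_iter()}
        for t, v in obs.items():
            implied = 1 if (t in below_gain and t not in lost) else 0
            if v != MISSING and v != implied:
                return False
        return True

    for k in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, k):
            if consistent(subset):
                return k
    raise AssertionError("no consistent loss set found")


def test_all_present_character_needs_no_losses():
    tree = load_tree("((a,b),(c,d));")
    m = _matrix(["a", "b", "c", "d"], [1, 1, 1, 1])
    scn = dollo_map(m, tree, assume_root_presence=True)
    assert scn.total_losses == 0


def test_single_clade_loss_is_one_event():
    tree = load_tree("((a,b),(c,d));")
    m = _matrix(["a", "b", "c", "d"], [0, 0, 1, 1])
    scn = dollo_map(m, tree, assume_root_presence=True)
    ev = scn.characters["c1"]
    assert ev.n_losses == 1
    assert ev.gain_branch == "root"


def test_never_observed_character_warns():
    tree = load_tree("((a,b),(c,d));")
    m = _matrix(["a", "b", "c", "d"], [0, 0, 0, 0], kind="intron")
    with pytest.warns(UserWarning):
        scn = dollo_map(m, tree, assume_root_presence=False)
    assert scn.characters["c1"].n_events == 0


@pytest.mark.parametrize("root_presence", [True, False])
def test_dollo_equals_exhaustive_oracle(root_presence):
    rng = random.Random(17 if root_presence else 23)
    for _ in range(60):
        n = rng.randint(3, 8)
        tree, taxa = _random_tree(rng, n)
        states = [rng.choice([0, 1, 1, MISSING]) for _ in taxa]
        if not root_presence and 1 not in states:
            states[0] = 1
        m = _matrix(taxa, states)
        scn = dollo_map(m, tree, assume_root_presence=root_presence)
        expected = _dollo_oracle(tree, dict(zip(taxa, states)), root_presence)
        assert scn.characters["c1"].n_losses == expected


def test_dollo_reconstruction_reproduces_observed_states():
    rng = random.Random(31)
    for _ in range(40):
        n = rng.randint(3, 8)
        tree, taxa = _random_tree(rng, n)
        states = [rng.choice([0, 1, 1, MISSING]) for _ in taxa]
        m = _matrix(taxa, states)
        scn = dollo_map(m, tree, assume_root_presence=True)
        implied = reconstruct_leaf_states(scn, tree, "c1")
        for t, v in zip(taxa, states):
            if v != MISSING:
                assert implied[t] == v


def test_flipping_absence_to_missing_never_costs_more():
    rng = random.Random(47)
    for _ in range(30):
        n = rng.randint(4, 8)
        tree, taxa = _random_tree(rng, n)
        states = [rng.choice([0, 0, 1, 1]) for _ in taxa]
        m = _matrix(taxa, states)
        base = dollo_map(m, tree,
                         assume_root_presence=True).characters["c1"].n_losses
        zeros = [i for i, s in enumerate(states) if s == 0]
        if not zeros:
            continue
        relaxed_states = list(states)
        relaxed_states[rng.choice(zeros)] = MISSING
        relaxed = dollo_map(_matrix(taxa, relaxed_states), tree,
                            assume_root_presence=True)
        assert relaxed.characters["c1"].n_losses <= base


def test_fitch_single_leaf_presence_is_one_gain():
    tree = load_tree("((a,b),(c,d));")
    m = _matrix(["a", "b", "c", "d"], [1, 0, 0, 0])
    scn = fitch_wagner_map(m, tree)
    ev = scn.characters["c1"]
    assert ev.gain_branch == "a"
    assert ev.n_losses == 0


def test_fitch_total_not_above_dollo_for_two_distant_clades():
    tree = load_tree("(((a,b),(c,d)),((e,f),(g,h)));")
    taxa = list("abcdefgh")
    # present in two distant clades: Dollo forces one gain + many losses,
    # Fitch allows two gains
    states = [1, 1, 0, 0, 0, 0, 1, 1]
    m = _matrix(taxa, states, kind="intron")
    dollo = dollo_map(m, tree, assume_root_presence=False)
    fitch = fitch_wagner_map(m, tree)
    ev_f = fitch.characters["c1"]
    fitch_total = ev_f.n_events + len(getattr(ev_f, "extra_gains", []))
    dollo_total = dollo.characters["c1"].n_events
    assert fitch_total <= dollo_total


def test_multifurcating_tree_counts_each_child_loss_once():
    tree = load_tree("(a,b,c,(d,e));")
    m = _matrix(list("abcde"), [0, 1, 1, 1, 1])
    scn = dollo_map(m, tree, assume_root_presence=True)
    assert scn.characters["c1"].n_losses == 1
    assert scn.characters["c1"].loss_branches == ["a"]


def test_classify_events_split():
    tree = load_tree("((a,b),(c,d));")
    m = CharacterMatrix(
        taxa=list("abcd"), labels=["once", "four"], kind="gene",
        states=[[0, 0], [1, 0], [1, 0], [1, 0]])
    scn = dollo_map(m, tree, assume_root_presence=True)
    summary = classify_events(scn)
    assert "once" in summary.synapomorphic
    # 'four' lost in every leaf -> single loss at root-adjacent branches is
    # impossible, so it is homoplasic with >1 events
    assert summary.homoplasic.get("four", 0) >= 2


def test_gene_matrix_flags_planted_loss(sim_bundle):
    from plastcomp import catalog
    genomes = [sim_bundle["leaves"][k].render() for k in "ABCDEF"]
    m = build_gene_matrix(genomes, catalog.ANCESTRAL_GENES)
    lost = {}
    for label, events in sim_bundle["truth"].events.items():
        for ev in events:
            if ev["kind"] == "gene_loss":
                lost.setdefault(ev["gene"], []).append(label)
    leaf_losses = {g: br for g, br in lost.items()
                   if all(b in "ABCDEF" for b in br)}
    for gene, branches in list(leaf_losses.items())[:5]:
        for leaf in branches:
            assert m.state(leaf, gene) == 0


def test_intron_matrix_masks_lost_host_genes():
    from plastcomp.model import AnnotatedGenome, GeneFeature, IntronSite
    site = IntronSite("trnV(uac)", "trnV(uac)_37")
    f1 = GeneFeature("trnV(uac)", "tRNA", [(0, 72)], 1, intron_sites=[site])
    g_with = AnnotatedGenome("has", "A" * 500, "circular", [f1])
    g_without = AnnotatedGenome(
        "lacks", "A" * 500, "circular",
        [GeneFeature("rbcL", "protein", [(0, 90)], 1)])
    m = build_intron_matrix([g_with, g_without])
    assert m.state("has", "trnV(uac)_37") == 1
    assert m.state("lacks", "trnV(uac)_37") == MISSING


def test_matrix_tsv_and_nexus_round_trips(tmp_path):
    m = CharacterMatrix(taxa=["a", "b"], labels=["x", "y", "z"], kind="gene",
                        states=[[1, 0, MISSING], [0, 1, 1]])
    m.to_tsv(tmp_path / "m.tsv")
    back = CharacterMatrix.from_tsv(tmp_path / "m.tsv")
    assert back.states == m.states and back.labels == m.labels
    m.to_nexus(tmp_path / "m.nex")
    nex = CharacterMatrix.from_nexus(tmp_path / "m.nex")
    assert nex.states == m.states


def test_ir_matrix_and_empty_catalog():
    m = build_ir_matrix({"a": 1, "b": 0, "c": None})
    assert m.state("a", "IR") == 1
    assert m.state("c", "IR") == MISSING
    empty = build_gene_matrix([], [])
    assert empty.n_characters == 0
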