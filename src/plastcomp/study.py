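"""Published comparison panel: taxa, tree topology and IR presence states.

The 28-taxon streptophyte phylogeny (18 green algae plus ten land plants,
rooted on the Mesostigma + Chlorokybus clade) and the large-inverted-repeat
presence/absence states of the compared chloroplast genomes, for use as a
worked example and as inputs to the character-evolution stage.  IR presence
follows the reported genome features: taxa without a delimited IR are coded
absent.
"""

from __future__ import annotations

import dendropy

from .characters import (CharacterMatrix, EventScenario, build_ir_matrix,
                         dollo_map, ensure_node_labels, load_tree)

ALGAE: tuple[str, ...] = (
    "Mesostigma_viride", "Chlorokybus_atmophyticus",
    "Klebsormidium_sp_SAG_51_86", "Klebsormidium_flaccidum",
    "Entransia_fimbriata", "Chara_vulgaris", "Chaetosphaeridium_globosum",
    "Coleochaete_scutata", "Mesotaenium_endlicherianum",
    "Zygnema_circumcarinatum", "Cylindrocystis_brebissonii",
    "Spirogyra_maxima", "Netrium_digitus", "Roya_anglica", "Roya_obtusa",
    "Closterium_baillyanum", "Cosmarium_botrytis", "Staurastrum_punctulatum",
)

LAND_PLANTS: tuple[str, ...] = (
    "Marchantia_polymorpha", "Physcomitrella_patens", "Syntrichia_ruralis",
    "Anthoceros_formosae", "Huperzia_lucidula", "Pinus_thunbergii",
    "Oryza_sativa", "Acorus_calamus", "Arabidopsis_thaliana",
    "Nicotiana_tabacum",
)

ZYGNEMATOPHYCEAE: tuple[str, ...] = (
    "Mesotaenium_endlicherianum", "Zygnema_circumcarinatum",
    "Cylindrocystis_brebissonii", "Spirogyra_maxima", "Netrium_digitus",
    "Roya_anglica", "Roya_obtusa", "Closterium_baillyanum",
    "Cosmarium_botrytis", "Staurastrum_punctulatum",
)

_ZYGNEMA_CLADE = (
    "(Mesotaenium_endlicherianum,((Zygnema_circumcarinatum,"
    "Cylindrocystis_brebissonii),(Spirogyra_maxima,(Netrium_digitus,"
    "((Roya_anglica,Roya_obtusa),(Closterium_baillyanum,"
    "(Cosmarium_botrytis,Staurastrum_punctulatum)))))))"
)

_LAND_PLANT_CLADE = (
    "(Marchantia_polymorpha,((Physcomitrella_patens,Syntrichia_ruralis),"
    "(Anthoceros_formosae,(Huperzia_lucidula,(Pinus_thunbergii,"
    "((Oryza_sativa,Acorus_calamus),(Arabidopsis_thaliana,"
    "Nicotiana_tabacum)))))))"
)

#: rooted streptophyte topology; Mesostigma and Chlorokybus are the outgroup
STREPTOPHYTE_TREE_NEWICK: str = (
    "((Mesostigma_viride,Chlorokybus_atmophyticus),"
    "(((Klebsormidium_sp_SAG_51_86,Klebsormidium_flaccidum),"
    "Entransia_fimbriata),(Chara_vulgaris,((Chaetosphaeridium_globosum,"
    "Coleochaete_scutata),(" + _ZYGNEMA_CLADE + "," + _LAND_PLANT_CLADE
    + ")))));"
)

#: large-IR presence per taxon: 1 where an IR was delimited, 0 otherwise
#: (the partially sequenced Klebsormidium sp. genome has no delimited IR and
#: the Coleochaete and six zygnematophycean genomes lack one; land plant
#: chloroplast genomes in the panel all retain the IR)
IR_PRESENCE: dict[str, int] = {
    "Mesostigma_viride": 1,
    "Chlorokybus_atmophyticus": 1,
    "Klebsormidium_sp_SAG_51_86": 0,
    "Klebsormidium_flaccidum": 1,
    "Entransia_fimbriata": 1,
    "Chara_vulgaris": 1,
    "Chaetosphaeridium_globosum": 1,
    "Coleochaete_scutata": 0,
    "Mesotaenium_endlicherianum": 0,
    "Zygnema_circumcarinatum": 0,
    "Cylindrocystis_brebissonii": 0,
    "Spirogyra_maxima": 0,
    "Netrium_digitus": 0,
    "Roya_anglica": 1,
    "Roya_obtusa": 1,
    "Closterium_baillyanum": 1,
    "Cosmarium_botrytis": 1,
    "Staurastrum_punctulatum": 0,
    **{t: 1 for t in LAND_PLANTS},
}


def streptophyte_tree() -> dendropy.Tree:
    tree = load_tree(STREPTOPHYTE_TREE_NEWICK)
    ensure_node_labels(tree)
    return tree


def ir_matrix() -> CharacterMatrix:
    return build_ir_matrix(dict(IR_PRESENCE))


def ir_loss_scenario() -> tuple[EventScenario, dendropy.Tree, int]:
    """Dollo mapping of IR presence; returns the losses inside the
    Zygnematophyceae alongside the scenario and the labeled tree."""
    tree = streptophyte_tree()
    scenario = dollo_map(ir_matrix(), tree, assume_root_presence=True)
    mrca = tree.mrca(taxa=[tree.taxon_namespace.get_taxon(t)
                           for t in ZYGNEMATOPHYCEAE])
    inside = {d.label for d in mrca.preorder_iter()}
    losses = sum(
        sum(1 for b in c.loss_branches if b in inside)
        for c in scenario.characters.values()
    )
    return scenario, tree, losses
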