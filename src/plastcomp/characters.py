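"""Binary character matrices and parsimony mapping on a fixed rooted tree.

Characters (gene presence, intron sites, gene pairs, IR presence) take
states present (1), absent (0) or missing (?).  Under Dollo parsimony a
character is gained once — at the root for characters assumed ancestral, or
at the most recent common ancestor of the taxa carrying it — and the minimal
set of loss branches explaining the observed absences is reconstructed
exactly by dynamic programming over the tree; missing states impose no
constraint.  Fitch/Wagner small parsimony (equivalent for binary states) is
available as a variant that permits repeated gains.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

MISSING = -1
_STATE_CHARS = {1: "1", 0: "0", MISSING: "?"}
_CHAR_STATES = {"1": 1, "0": 0, "?": MISSING, "-": MISSING}


@dataclass
class CharacterMatrix:
    """Taxa x binary characters with states {1, 0, ?}."""

    taxa: list[str]
    labels: list[str]
    kind: str = "gene"  # gene | intron | gene_pair | ir
    states: list[list[int]] = field(default_factory=list)  # [taxon][character]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("character labels must be unique")
        if len(self.states) != len(self.taxa):
            raise ValueError("one state row per taxon required")
        for row in self.states:
            if len(row) != len(self.labels):
                raise ValueError("ragged state matrix")
            for v in row:
                if v not in (0, 1, MISSING):
                    raise ValueError(f"invalid state {v!r}")

    @property
    def n_characters(self) -> int:
        return len(self.labels)

    def state(self, taxon: str, label: str) -> int:
        return self.states[self.taxa.index(taxon)][self.labels.index(label)]

    def column(self, label: str) -> dict[str, int]:
        j = self.labels.index(label)
        return {t: self.states[i][j] for i, t in enumerate(self.taxa)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[_STATE_CHARS[v] for v in row] for row in self.states],
            index=self.taxa, columns=self.labels,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "gene") -> "CharacterMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(
            taxa=[str(t) for t in df.index],
            labels=[str(c) for c in df.columns],
            kind=kind,
            states=[[_CHAR_STATES[str(v)] for v in row]
                    for row in df.itertuples(index=False)],
        )

    def to_nexus(self, path: str | Path) -> None:
        dm = self._dendropy_matrix()
        dm.write(path=str(path), schema="nexus")

    def _dendropy_matrix(self):
        rows = "\n".join(
            f"{t} {''.join(_STATE_CHARS[v] for v in row)}"
            for t, row in zip(self.taxa, self.states)
        )
        nexus = (
            "#NEXUS\nBEGIN DATA;\n"
            f"DIMENSIONS NTAX={len(self.taxa)} NCHAR={self.n_characters};\n"
            'FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\nMATRIX\n'
            f"{rows}\n;\nEND;\n"
        )
        return dendropy.StandardCharacterMatrix.get(
            file=_io.StringIO(nexus), schema="nexus")

    @classmethod
    def from_nexus(cls, path: str | Path, kind: str = "gene") -> "CharacterMatrix":
        dm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
        taxa = [t.label for t in dm.taxon_namespace]
        states = []
        for t in dm.taxon_namespace:
            row = []
            for cell in dm[t]:
                sym = str(cell.symbol)
                row.append(_CHAR_STATES.get(sym, MISSING))
            states.append(row)
        labels = [f"char{i + 1}" for i in range(len(states[0]))]
        return cls(taxa=taxa, labels=labels, kind=kind, states=states)


# --- trees -------------------------------------------------------------------


def load_tree(source: str | Path, taxa: list[str] | None = None) -> dendropy.Tree:
    """Load a rooted newick tree; label internal nodes deterministically."""
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        if "(" not in text and ";" not in text:
            text = Path(text).read_text()
        else:
            try:
                if len(text) < 255 and Path(text).exists():
                    text = Path(text).read_text()
            except OSError:
                pass
    tree = dendropy.Tree.get(data=text, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    tree.is_rooted = True
    ensure_node_labels(tree)
    if taxa is not None:
        leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        missing = set(taxa) - leaf_labels
        if missing:
            raise ValueError(f"matrix taxa missing from tree: {sorted(missing)}")
    return tree


def ensure_node_labels(tree: dendropy.Tree) -> None:
    """Give every node a stable label (leaves keep their taxon labels)."""
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label if node.taxon else node.label
        elif not node.label:
            counter += 1
            node.label = f"node{counter}"


def branch_label(node: dendropy.Node) -> str:
    """A branch is named by its child node's label."""
    return node.label


# --- Dollo parsimony ---------------------------------------------------------


@dataclass
class CharacterEvents:
    label: str
    gain_branch: str | None          # child-node label, "root", or None
    loss_branches: list[str]
    n_alternative_placements: int = 1

    @property
    def n_events(self) -> int:
        return (1 if self.gain_branch not in (None, "root") else 0) + len(
            self.loss_branches)

    @property
    def n_losses(self) -> int:
        return len(self.loss_branches)


@dataclass
class EventScenario:
    method: str
    characters: dict[str, CharacterEvents]

    @property
    def total_losses(self) -> int:
        return sum(c.n_losses for c in self.characters.values())

    @property
    def total_gains(self) -> int:
        return sum(1 for c in self.characters.values()
                   if c.gain_branch not in (None, "root"))

    def losses_within(self, tree: dendropy.Tree, clade_root_label: str) -> int:
        """Losses on branches inside the clade rooted at the given node."""
        node = next(n for n in tree.preorder_node_iter()
                    if n.label == clade_root_label)
        inside = {d.label for d in node.preorder_iter()}
        return sum(
            sum(1 for b in c.loss_branches if b in inside)
            for c in self.characters.values()
        )

    def per_branch_table(self) -> pd.DataFrame:
        rows = []
        for c in self.characters.values():
            if c.gain_branch not in (None, "root"):
                rows.append({"branch": c.gain_branch, "character": c.label,
                             "event": "gain"})
            for b in c.loss_branches:
                rows.append({"branch": b, "character": c.label, "event": "loss"})
        return pd.DataFrame(rows, columns=["branch", "character", "event"])


def _mrca(tree: dendropy.Tree, leaves: list[str]) -> dendropy.Node:
    taxa = [tree.taxon_namespace.get_taxon(x) for x in leaves]
    if len(taxa) == 1:
        return tree.find_node_for_taxon(taxa[0])
    return tree.mrca(taxa=taxa)


def _observed(node, obs: dict[str, int]):
    """(any 1-leaf, any 0-leaf) below (and including) this node."""
    has1 = has0 = False
    for leaf in node.leaf_iter():
        v = obs.get(leaf.taxon.label, MISSING)
        if v == 1:
            has1 = True
        elif v == 0:
            has0 = True
    return has1, has0


def _min_losses(node, obs) -> tuple[int, list, int]:
    """Minimal losses below a present node: (count, loss nodes, #placements).

    Tie-break pushes each loss as deep as possible (latest loss); the number
    of alternative minimal placements is counted exactly.
    """
    has1, has0 = _observed(node, obs)
    if not has0:
        return 0, [], 1
    if not has1:
        # entire subtree can be explained by one loss on this branch; it may
        # equivalently be placed deeper while exactly one child carries the
        # observed absences
        ways = 1
        deepest = node
        cursor = node
        while True:
            informative = [c for c in cursor.child_nodes()
                           if any(v != MISSING for v in (
                               obs.get(l.taxon.label, MISSING)
                               for l in c.leaf_iter()))]
            if len(informative) == 1 and not informative[0].is_leaf():
                ways += 1
                cursor = informative[0]
                deepest = cursor
            elif len(informative) == 1 and informative[0].is_leaf():
                ways += 1
                deepest = informative[0]
                break
            else:
                break
        return 1, [deepest], ways
    count, losses, ways = 0, [], 1
    for child in node.child_nodes():
        c, l, w = _min_losses(child, obs)
        count += c
        losses += l
        ways *= w
    return count, losses, ways


DEFAULT_ROOT_PRESENCE = {"gene": True, "intron": False, "gene_pair": False,
                         "ir": False}


def dollo_map(matrix: CharacterMatrix, tree: dendropy.Tree,
              assume_root_presence: bool | dict[str, bool] | None = None
              ) -> EventScenario:
    """Map characters on a rooted tree under Dollo parsimony.

    Each character is gained once — at the root when assumed ancestrally
    present (the default for gene characters), else at the MRCA of the taxa
    carrying it — and lost on the exact minimal set of branches consistent
    with the observed states.  Missing (?) leaves impose no constraint.
    """
    ensure_node_labels(tree)
    if assume_root_presence is None:
        root_presence = DEFAULT_ROOT_PRESENCE.get(matrix.kind, False)
    elif isinstance(assume_root_presence, dict):
        root_presence = assume_root_presence.get(matrix.kind, False)
    else:
        root_presence = bool(assume_root_presence)
    events: dict[str, CharacterEvents] = {}
    for label in matrix.labels:
        obs = matrix.column(label)
        ones = [t for t, v in obs.items() if v == 1]
        if not ones and not root_presence:
            warnings.warn(f"character {label}: never observed present; "
                          "no events inferred")
            events[label] = CharacterEvents(label, None, [])
            continue
        if root_presence:
            gain_node = tree.seed_node
            gain_branch = "root"
        else:
            gain_node = _mrca(tree, ones)
            gain_branch = ("root" if gain_node is tree.seed_node
                           else branch_label(gain_node))
        has1, has0 = _observed(gain_node, obs)
        if has0 and not has1 and gain_branch == "root":
            # the root has no branch of its own: absences must be explained
            # by losses on (or below) its child branches
            loss_nodes, ways = [], 1
            for child in gain_node.child_nodes():
                _, l, w = _min_losses(child, obs)
                loss_nodes += l
                ways *= w
        else:
            _, loss_nodes, ways = _min_losses(gain_node, obs)
        events[label] = CharacterEvents(
            label=label,
            gain_branch=gain_branch,
            loss_branches=[branch_label(n) for n in loss_nodes],
            n_alternative_placements=ways,
        )
    return EventScenario(method="dollo", characters=events)


def reconstruct_leaf_states(scenario: EventScenario, tree: dendropy.Tree,
                            label: str) -> dict[str, int]:
    """Leaf states implied by a Dollo scenario (for invariant checking)."""
    ev = scenario.characters[label]
    if ev.gain_branch is None:
        return {l.taxon.label: 0 for l in tree.leaf_node_iter()}
    if ev.gain_branch == "root":
        gain = tree.seed_node
    else:
        gain = next(n for n in tree.preorder_node_iter()
                    if n.label == ev.gain_branch)
    lost_roots = [n for n in tree.preorder_node_iter()
                  if n.label in set(ev.loss_branches)]
    below_gain = {l.taxon.label for l in gain.leaf_iter()}
    lost = set()
    for n in lost_roots:
        lost |= {l.taxon.label for l in n.leaf_iter()}
    return {
        l.taxon.label: (1 if l.taxon.label in below_gain - lost else 0)
        for l in tree.leaf_node_iter()
    }


# --- Fitch / Wagner ----------------------------------------------------------


def fitch_wagner_map(matrix: CharacterMatrix, tree: dendropy.Tree
                     ) -> EventScenario:
    """Minimal-change binary reconstruction allowing repeated gains.

    Unit-cost Sankoff dynamic programming; for binary characters Fitch
    (unordered) and Wagner (ordered) parsimony coincide.  Events are labeled
    gain/loss by the parent-to-child state change.
    """
    ensure_node_labels(tree)
    INF = 10 ** 9
    events: dict[str, CharacterEvents] = {}
    for label in matrix.labels:
        obs = matrix.column(label)
        cost: dict = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                v = obs.get(node.taxon.label, MISSING)
                cost[node] = {
                    0: 0 if v in (0, MISSING) else INF,
                    1: 0 if v in (1, MISSING) else INF,
                }
            else:
                c0 = c1 = 0
                for child in node.child_nodes():
                    c0 += min(cost[child][0], cost[child][1] + 1)
                    c1 += min(cost[child][1], cost[child][0] + 1)
                cost[node] = {0: c0, 1: c1}
        root = tree.seed_node
        state = {root: 0 if cost[root][0] <= cost[root][1] else 1}
        gains, losses = [], []
        for node in tree.preorder_node_iter():
            if node is root:
                continue
            p = state[node.parent_node]
            keep = cost[node][p]
            flip = cost[node][1 - p] + 1
            s = p if keep <= flip else 1 - p
            state[node] = s
            if s != p:
                (gains if s == 1 else losses).append(branch_label(node))
        gain_branch: str | None
        if state[root] == 1:
            gain_branch = "root"
        elif gains:
            gain_branch = gains[0]
        else:
            gain_branch = None
        events[label] = CharacterEvents(
            label=label,
            gain_branch=gain_branch,
            loss_branches=losses,
        )
        # extra gains beyond the first are still events; keep them countable
        events[label].extra_gains = gains[1:] if gain_branch != "root" else gains  # type: ignore[attr-defined]
    return EventScenario(method="fitch", characters=events)


# --- summaries ---------------------------------------------------------------


@dataclass
class EventSummary:
    synapomorphic: list[str]
    homoplasic: dict[str, int]
    loss_histogram: dict[int, int]
    per_branch: pd.DataFrame


def classify_events(scenario: EventScenario) -> EventSummary:
    """Split characters into unique-event (synapomorphic) vs homoplasic."""
    synapomorphic, homoplasic = [], {}
    hist: dict[int, int] = {}
    for label, ev in scenario.characters.items():
        n = ev.n_events + len(getattr(ev, "extra_gains", []))
        hist[ev.n_losses] = hist.get(ev.n_losses, 0) + 1
        if n == 1:
            synapomorphic.append(label)
        elif n > 1:
            homoplasic[label] = n
    return EventSummary(
        synapomorphic=synapomorphic,
        homoplasic=homoplasic,
        loss_histogram=dict(sorted(hist.items())),
        per_branch=scenario.per_branch_table(),
    )


# --- matrix builders ---------------------------------------------------------


def build_gene_matrix(genomes, catalog_genes,
                      partial_taxa: tuple[str, ...] = ()) -> CharacterMatrix:
    """Presence/absence matrix over a gene catalog (ORFs excluded).

    For taxa listed in ``partial_taxa`` (incompletely sequenced genomes)
    unobserved genes are coded missing rather than absent.
    """
    taxa, states = [], []
    for g in genomes:
        present = {f.name for f in g.features if f.category != "ORF"}
        if not (present & set(catalog_genes)) and catalog_genes:
            raise ValueError(
                f"{g.taxon_id}: no catalog genes found (mis-parsed input?)")
        absent_state = MISSING if g.taxon_id in partial_taxa else 0
        taxa.append(g.taxon_id)
        states.append([1 if name in present else absent_state
                       for name in catalog_genes])
    return CharacterMatrix(taxa=taxa, labels=list(catalog_genes), kind="gene",
                           states=states)


def build_intron_matrix(genomes, site_catalog=None) -> CharacterMatrix:
    """Presence/absence matrix over intron sites.

    A site is coded missing (?) in a taxon lacking the host gene, so host
    gene losses are not double-counted as intron losses.
    """
    site_host: dict[str, str] = {}
    observed: dict[str, set[str]] = {}
    for g in genomes:
        sites = set()
        for f in g.features:
            for s in f.intron_sites:
                sites.add(s.site_label)
                site_host[s.site_label] = s.host_gene
        observed[g.taxon_id] = sites
    if site_catalog is None:
        labels = sorted(site_host)
    else:
        labels = list(site_catalog)
        for lab in labels:
            if lab not in site_host:
                host = lab.rsplit("_", 1)[0]
                site_host[lab] = host
    taxa, states = [], []
    for g in genomes:
        genes_present = {f.name for f in g.features}
        row = []
        for lab in labels:
            if lab in observed[g.taxon_id]:
                row.append(1)
            elif site_host.get(lab) not in genes_present:
                row.append(MISSING)
            else:
                row.append(0)
        taxa.append(g.taxon_id)
        states.append(row)
    return CharacterMatrix(taxa=taxa, labels=labels, kind="intron",
                           states=states)


def build_ir_matrix(ir_states: dict[str, int | None]) -> CharacterMatrix:
    """One-character matrix of large-inverted-repeat presence per taxon."""
    taxa = list(ir_states)
    states = [[MISSING if ir_states[t] is None else int(ir_states[t])]
              for t in taxa]
    return CharacterMatrix(taxa=taxa, labels=["IR"], kind="ir", states=states)
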