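"""Signed gene orders, signed adjacencies (gene pairs) and synteny blocks.

A genome is reduced to the ordered list of its gene symbols, each signed by
coding strand.  Gene pairs are canonicalized so that a pair and its reverse
complement are the same object, which makes adjacency sets invariant under
genome rotation and full reverse complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .characters import CharacterMatrix
from .model import AnnotatedGenome

log = logging.getLogger(__name__)

SignedGene = tuple[str, int, int]  # (symbol, copy_index, sign)
GenePair = tuple[tuple[str, int], tuple[str, int]]

DEFAULT_CATEGORIES = ("protein", "tRNA", "rRNA", "tmRNA")


@dataclass
class SignedGeneOrder:
    taxon_id: str
    genes: list[SignedGene]
    topology: str = "circular"

    def __len__(self) -> int:
        return len(self.genes)

    def symbols(self) -> list[str]:
        return [g[0] for g in self.genes]

    def signed_symbols(self) -> list[tuple[str, int]]:
        return [(g[0], g[2]) for g in self.genes]

    def reverse_complement(self) -> "SignedGeneOrder":
        return SignedGeneOrder(
            self.taxon_id,
            [(n, c, -s) for (n, c, s) in reversed(self.genes)],
            self.topology,
        )

    def rotate(self, k: int) -> "SignedGeneOrder":
        if self.topology != "circular":
            raise ValueError("cannot rotate a linear gene order")
        k %= len(self.genes)
        return SignedGeneOrder(self.taxon_id, self.genes[k:] + self.genes[:k],
                               self.topology)


def extract_signed_order(genome: AnnotatedGenome,
                         categories: tuple[str, ...] = DEFAULT_CATEGORIES,
                         gene_catalog: set[str] | None = None,
                         dedup: str = "keep-all",
                         qmap=None,
                         trans_downstream: bool = True) -> SignedGeneOrder:
    """Extract the orientation-signed gene order of a genome.

    ``dedup='one-ir-copy'`` keeps a single copy of each duplicated gene: the
    copy outside the second inverted-repeat arm when a quadripartite map is
    supplied, otherwise the lowest-coordinate copy.  Trans-spliced genes are
    placed at their downstream exon block by default.
    """
    length = genome.length
    feats = [f for f in genome.features if f.category in categories]
    if gene_catalog is not None:
        feats = [f for f in feats if f.name in gene_catalog]

    def position(f):
        if trans_downstream and len(f.exons) > 1 and any(
                s.cis_or_trans == "trans" for s in f.intron_sites):
            return f.exons[1][0] % length
        return f.genomic_start

    feats.sort(key=lambda f: (position(f), f.name, f.copy_index))
    if dedup == "one-ir-copy":
        chosen = []
        seen: dict[str, int] = {}
        in_irb = set()
        if qmap is not None and getattr(qmap, "has_ir", False):
            b0, b1 = qmap.ir_b
            for f in feats:
                mid = (position(f) + f.coding_length // 2) % length
                if b0 <= mid < b1 or (b1 > length and mid < b1 - length):
                    in_irb.add(f.key())
        for f in feats:
            if f.name in seen:
                continue
            copies = [g for g in feats if g.name == f.name]
            if len(copies) > 1:
                outside = [g for g in copies if g.key() not in in_irb]
                pick = (outside or copies)[0]
                if len(outside) > 1 and qmap is not None:
                    log.info("%s: duplicate gene %s outside IR; keeping copy %d",
                             genome.taxon_id, f.name, pick.copy_index)
            else:
                pick = f
            seen[f.name] = 1
            chosen.append(pick)
        chosen.sort(key=lambda f: (position(f), f.name))
        feats = chosen
    elif dedup != "keep-all":
        raise ValueError(f"unknown dedup mode {dedup!r}")
    return SignedGeneOrder(
        taxon_id=genome.taxon_id,
        genes=[(f.name, f.copy_index, f.strand) for f in feats],
        topology=genome.topology,
    )


def canonical_pair(a: tuple[str, int], b: tuple[str, int]) -> GenePair:
    """Canonical form of a signed adjacency: (a,b) == (-b,-a)."""
    fwd = (a, b)
    rev = ((b[0], -b[1]), (a[0], -a[1]))
    return min(fwd, rev)


def signed_adjacencies(order: SignedGeneOrder) -> set[GenePair]:
    """Canonical signed gene pairs of an order (n pairs circular, n-1 linear)."""
    if not order.genes:
        raise ValueError("empty gene order")
    items = order.signed_symbols()
    pairs = set()
    last = len(items) if order.topology == "circular" else len(items) - 1
    for i in range(last):
        a = items[i]
        b = items[(i + 1) % len(items)]
        pairs.add(canonical_pair(a, b))
    return pairs


def pair_label(pair: GenePair) -> str:
    (na, sa), (nb, sb) = pair
    return f"{'+' if sa > 0 else '-'}{na}|{'+' if sb > 0 else '-'}{nb}"


def shared_pair_matrix(orders: list[SignedGeneOrder], min_taxa: int = 3,
                       loss_mask: CharacterMatrix | None = None) -> CharacterMatrix:
    """Binary taxa x gene-pair matrix over pairs conserved in >= min_taxa taxa.

    In a taxon where either member gene is absent (per ``loss_mask``, or per
    the taxon's own gene complement when no mask is given) the pair state is
    missing (?) rather than absent, so gene losses are not misread as
    rearrangements.
    """
    taxa = [o.taxon_id for o in orders]
    per_taxon_pairs = {o.taxon_id: signed_adjacencies(o) for o in orders}
    if loss_mask is not None:
        present = {
            t: {g for g in loss_mask.labels
                if loss_mask.state(t, g) == 1}
            for t in taxa
        }
    else:
        present = {o.taxon_id: set(o.symbols()) for o in orders}
    universe = sorted(set().union(*per_taxon_pairs.values()))
    kept, rows = [], {t: [] for t in taxa}
    for pair in universe:
        (na, _), (nb, _) = pair
        states = {}
        for t in taxa:
            if pair in per_taxon_pairs[t]:
                states[t] = 1
            elif na not in present[t] or nb not in present[t]:
                states[t] = -1  # missing
            else:
                states[t] = 0
        if sum(1 for v in states.values() if v == 1) >= min_taxa:
            kept.append(pair)
            for t in taxa:
                rows[t].append(states[t])
    return CharacterMatrix(
        taxa=taxa,
        labels=[pair_label(p) for p in kept],
        kind="gene_pair",
        states=[rows[t] for t in taxa],
    )


def order_to_frame(order: SignedGeneOrder) -> "pd.DataFrame":
    import pandas as pd
    return pd.DataFrame(
        [{"taxon": order.taxon_id, "rank": i, "gene": n, "copy": c, "sign": s,
          "topology": order.topology}
         for i, (n, c, s) in enumerate(order.genes)]
    )


def order_from_frame(df) -> SignedGeneOrder:
    df = df.sort_values("rank")
    return SignedGeneOrder(
        taxon_id=str(df["taxon"].iloc[0]),
        genes=[(str(r.gene), int(getattr(r, "copy", 1)), int(r.sign))
               for r in df.itertuples(index=False)],
        topology=str(df["topology"].iloc[0]) if "topology" in df else "circular",
    )


def read_order_tsv(path) -> list[SignedGeneOrder]:
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    return [order_from_frame(sub) for _, sub in df.groupby("taxon", sort=False)]


def write_order_tsv(orders: list[SignedGeneOrder], path) -> None:
    import pandas as pd
    pd.concat([order_to_frame(o) for o in orders]).to_csv(
        path, sep="\t", index=False)


# --- synteny -----------------------------------------------------------------


@dataclass
class SyntenyBlock:
    block_id: int
    genes: list[str]               # in A order
    a_span: tuple[int, int]        # index range in reduced A (inclusive)
    b_span: tuple[int, int]        # index range in reduced B (inclusive)
    orientation: str               # same | inverted


@dataclass
class MissingGeneRecord:
    gene: str
    donor: str
    classification: str            # internal_excision | breakpoint_associated


@dataclass
class SyntenyBlockSet:
    taxon_a: str
    taxon_b: str
    blocks: list[SyntenyBlock]
    n_common: int
    block_of: dict[str, int] = field(default_factory=dict)
    missing: list[MissingGeneRecord] = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def _reduce_to_common(order: SignedGeneOrder, common: set[str],
                      choice: dict[str, int] | None = None) -> list[tuple[str, int]]:
    """Common-set order with one copy per gene as (symbol, sign).

    ``choice`` maps gene -> wanted copy_index; without it (or when the wanted
    copy is absent) the lowest-coordinate copy is used.
    """
    pick = choice or {}
    best: dict[str, tuple[int, int]] = {}
    for i, (name, copy, sign) in enumerate(order.genes):
        if name not in common:
            continue
        if name not in best or pick.get(name) == copy:
            best[name] = (i, sign)
    return [(name, sign)
            for name, (i, sign) in sorted(best.items(), key=lambda kv: kv[1][0])]


def _count_breaks(a_red, b_red, circular: bool) -> int:
    nb = len(b_red)
    pos = {name: i for i, (name, _) in enumerate(b_red)}
    sgn = {name: s for name, s in b_red}
    na = len(a_red)
    if na <= 1:
        return 0
    breaks = 0
    last = na if circular else na - 1
    for i in range(last):
        (n1, s1) = a_red[i]
        (n2, s2) = a_red[(i + 1) % na]
        r1, r2 = s1 * sgn[n1], s2 * sgn[n2]
        p1, p2 = pos[n1], pos[n2]
        ok = False
        if r1 == 1 and r2 == 1:
            ok = p2 == (p1 + 1) % nb if circular else p2 == p1 + 1
        elif r1 == -1 and r2 == -1:
            ok = p2 == (p1 - 1) % nb if circular else p2 == p1 - 1
        if not ok:
            breaks += 1
    return breaks


def _resolve_duplicates(a: SignedGeneOrder, b: SignedGeneOrder,
                        common: set[str], circular: bool):
    """Pick copies of duplicated shared genes minimizing breakpoints."""
    def copies(order, name):
        return [c for (n, c, _) in order.genes if n == name]

    choice_a: dict[str, int] = {}
    choice_b: dict[str, int] = {}
    dup = [g for g in sorted(common)
           if len(copies(a, g)) > 1 or len(copies(b, g)) > 1]
    for g in dup:
        best = None
        for ca in copies(a, g):
            for cb in copies(b, g):
                trial_a = dict(choice_a, **{g: ca})
                trial_b = dict(choice_b, **{g: cb})
                ar = _reduce_to_common(a, common, trial_a)
                br = _reduce_to_common(b, common, trial_b)
                score = _count_breaks(ar, br, circular)
                key = (score, ca, cb)
                if best is None or key < best:
                    best = key
        if best is not None:
            choice_a[g], choice_b[g] = best[1], best[2]
    return choice_a, choice_b


def synteny_blocks(a: SignedGeneOrder, b: SignedGeneOrder,
                   min_block_genes: int = 1) -> SyntenyBlockSet:
    """Maximal runs of genes consecutive and co-oriented in both genomes.

    Blocks are defined on the common gene set (one copy per gene); a block
    matched in inverted orientation has all signs flipped and order reversed.
    Every common gene belongs to exactly one block; singletons are allowed.
    """
    common = set(a.symbols()) & set(b.symbols())
    result = SyntenyBlockSet(a.taxon_id, b.taxon_id, [], len(common))
    if not common:
        return result
    circular = a.topology == "circular" and b.topology == "circular"
    ch_a, ch_b = _resolve_duplicates(a, b, common, circular)
    a_red = _reduce_to_common(a, common, ch_a)
    b_red = _reduce_to_common(b, common, ch_b)
    if circular:
        # deterministic anchor: lexicographically smallest shared gene first,
        # reflected so that it carries + orientation
        anchor = min(common)
        ai = next(i for i, (n, _) in enumerate(a_red) if n == anchor)
        a_red = a_red[ai:] + a_red[:ai]
        if a_red[0][1] < 0:
            a_red = [(n, -s) for (n, s) in reversed(a_red)]
            a_red = a_red[-1:] + a_red[:-1]
    nb = len(b_red)
    pos = {name: i for i, (name, _) in enumerate(b_red)}
    sgn = {name: s for name, s in b_red}
    na = len(a_red)

    def joined(i, j):
        (n1, s1), (n2, s2) = a_red[i], a_red[j]
        r1, r2 = s1 * sgn[n1], s2 * sgn[n2]
        p1, p2 = pos[n1], pos[n2]
        if r1 == 1 and r2 == 1:
            return p2 == (p1 + 1) % nb if circular else p2 == p1 + 1
        if r1 == -1 and r2 == -1:
            return p2 == (p1 - 1) % nb if circular else p2 == p1 - 1
        return False

    # segment the (possibly circular) A order at break positions
    if na == 1:
        runs = [[0]]
    else:
        last = na if circular else na - 1
        breaks = sorted(i for i in range(last) if not joined(i, (i + 1) % na))
        if circular and not breaks:
            runs = [list(range(na))]
        elif circular:
            runs = []
            for k, br in enumerate(breaks):
                start = (br + 1) % na
                end = breaks[(k + 1) % len(breaks)]
                run, i = [], start
                while True:
                    run.append(i)
                    if i == end:
                        break
                    i = (i + 1) % na
                runs.append(run)
        else:
            runs = []
            start = 0
            for i in breaks:
                runs.append(list(range(start, i + 1)))
                start = i + 1
            runs.append(list(range(start, na)))
    if min_block_genes > 1:
        runs = [piece for r in runs
                for piece in ([r] if len(r) >= min_block_genes
                              else [[i] for i in r])]
    blocks = []
    for bid, run in enumerate(sorted(runs, key=lambda r: r[0])):
        names = [a_red[i][0] for i in run]
        bpos = [pos[n] for n in names]
        rel = a_red[run[0]][1] * sgn[names[0]]
        blocks.append(SyntenyBlock(
            block_id=bid,
            genes=names,
            a_span=(run[0], run[-1]),
            b_span=(min(bpos), max(bpos)),
            orientation="same" if rel == 1 else "inverted",
        ))
        for n in names:
            result.block_of[n] = bid
    result.blocks = blocks
    return result


def classify_missing_genes(a_full: SignedGeneOrder, b_full: SignedGeneOrder,
                           blocks: SyntenyBlockSet) -> list[MissingGeneRecord]:
    """Classify genes present in exactly one genome.

    A gene is an internal excision when its two flanking shared genes in the
    donor genome are adjacent within a single synteny block of the other
    genome; otherwise it is breakpoint-associated.
    """
    set_a, set_b = set(a_full.symbols()), set(b_full.symbols())
    common = set_a & set_b
    records = []
    for donor, other in ((a_full, b_full), (b_full, a_full)):
        donor_only = (set(donor.symbols()) - common)
        other_syms = [n for n, *_ in _reduce_to_common(other, common)]
        opos = {n: i for i, n in enumerate(other_syms)}
        n_other = len(other_syms)
        donor_syms = [g[0] for g in donor.genes]
        nd = len(donor_syms)
        for gene in sorted(donor_only):
            idx = donor_syms.index(gene)
            left = right = None
            for step in range(1, nd):
                cand = donor_syms[(idx - step) % nd]
                if cand in common:
                    left = cand
                    break
            for step in range(1, nd):
                cand = donor_syms[(idx + step) % nd]
                if cand in common:
                    right = cand
                    break
            cls = "breakpoint_associated"
            if left is not None and right is not None and left != right:
                p1, p2 = opos[left], opos[right]
                adjacent = abs(p1 - p2) == 1 or (
                    other.topology == "circular" and abs(p1 - p2) == n_other - 1)
                same_block = blocks.block_of.get(left) == blocks.block_of.get(right)
                if adjacent and same_block:
                    cls = "internal_excision"
            records.append(MissingGeneRecord(gene=gene, donor=donor.taxon_id,
                                             classification=cls))
    blocks.missing = records
    return records
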