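"""Chloroplast genome evolution simulator with logged ground truth.

An ancestral quadripartite genome (two identical inverted-repeat arms
carrying the five-gene rDNA operon, SSC and LSC single-copy regions) is
evolved along a rooted tree by branch-wise events: reversals with
intergenic breakpoints, clean gene and intron losses, intron gains, loss of
one IR copy, IR boundary shifts (whole genes moving between the IR and the
single-copy regions), nucleotide substitutions and short intergenic indels.
While the IR exists, every change touching one arm is mirrored into the
other, emulating concerted evolution.  Every event is logged with explicit
parameters so the history replays deterministically.
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from . import catalog, io
from .characters import ensure_node_labels
from .gene_order import SignedGeneOrder
from .model import AnnotatedGenome, GeneFeature, IntronSite, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_NONSTOP = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA")]

#: intron sites planted by default: real plastid site labels covering group I
#: and group II, cis and trans configurations
DEFAULT_INTRON_SITES: tuple[tuple[str, str, str, str], ...] = (
    ("trnL(uaa)", "trnL(uaa)_35", "I", "cis"),
    ("rps12", "rps12_114", "II", "trans"),
    ("rpl16", "rpl16_9", "II", "cis"),
    ("trnG(ucc)", "trnG(ucc)_23", "II", "cis"),
    ("atpF", "atpF_17", "II", "cis"),
    ("trnV(uac)", "trnV(uac)_37", "II", "cis"),
    ("trnI(gau)", "trnI(gau)_39", "II", "cis"),
    ("trnK(uuu)", "trnK(uuu)_37", "II", "cis"),
    ("ndhA", "ndhA_55", "II", "cis"),
    ("clpP", "clpP_21", "II", "cis"),
)


@dataclass
class SimulationConfig:
    """Parameters of one simulated history.

    Per-branch event means are Poisson expectations (scaled by branch length
    when the tree has branch lengths); substitution and indel rates are per
    base pair per branch.
    """

    seed: int = 0
    genes: tuple[str, ...] = catalog.ANCESTRAL_GENES
    ir_extra_genes: tuple[str, ...] = ("trnR(acg)",)
    n_ssc_genes: int = 12
    gc: float = 0.32
    spacer_range: tuple[int, int] = (80, 250)
    protein_codon_range: tuple[int, int] = (100, 500)
    intron_sites: tuple[tuple[str, str, str, str], ...] = DEFAULT_INTRON_SITES
    intron_len_range: tuple[int, int] = (400, 900)
    # per-branch event means
    reversal_rate: float = 1.0
    gene_loss_rate: float = 0.5
    intron_gain_rate: float = 0.2
    intron_loss_rate: float = 0.5
    ir_loss_rate: float = 0.05
    ir_boundary_shift_rate: float = 0.2
    substitution_rate: float = 2e-3   # per bp per branch
    indel_rate: float = 5e-5          # per bp per branch (intergenic)
    indel_mean_len: float = 2.0       # geometric mean length
    unique_losses: bool = False       # homoplasy-free gene/intron losses
    protected_genes: tuple[str, ...] = catalog.RDNA_OPERON
    # planted small dispersed repeat family (G+C-rich, as real desmid repeats)
    repeat_family_copies: int = 6
    repeat_family_len: int = 40

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d


# --- structured genome -------------------------------------------------------


@dataclass
class SimGene:
    name: str
    category: str
    strand: int
    # alternating payload: ("exon", None, seq) / ("intron", site_label, seq)
    parts: list[tuple[str, str | None, str]]
    intron_meta: dict[str, tuple[str, str]] = field(default_factory=dict)

    def transcript_parts(self) -> list[tuple[str, str | None, str]]:
        return self.parts

    def length(self) -> int:
        return sum(len(p[2]) for p in self.parts)

    def rendered(self) -> str:
        s = "".join(p[2] for p in self.parts)
        return s if self.strand > 0 else revcomp(s)

    def intron_labels(self) -> list[str]:
        return [p[1] for p in self.parts if p[0] == "intron"]


@dataclass
class SimElement:
    kind: str                      # gene | spacer
    gene: SimGene | None = None
    seq: str = ""

    def length(self) -> int:
        return self.gene.length() if self.kind == "gene" else len(self.seq)

    def rendered(self) -> str:
        return self.gene.rendered() if self.kind == "gene" else self.seq


@dataclass
class SimGenome:
    taxon_id: str
    has_ir: bool
    lsc: list[SimElement] = field(default_factory=list)
    ir: list[SimElement] = field(default_factory=list)
    ssc: list[SimElement] = field(default_factory=list)
    elements: list[SimElement] = field(default_factory=list)  # when IR-less
    planted_repeat: dict | None = None

    def clone(self, taxon_id: str | None = None) -> "SimGenome":
        g = _copy.deepcopy(self)
        if taxon_id:
            g.taxon_id = taxon_id
        return g

    def regions(self) -> dict[str, list[SimElement]]:
        if self.has_ir:
            return {"lsc": self.lsc, "ir": self.ir, "ssc": self.ssc}
        return {"all": self.elements}

    def all_gene_elements(self) -> list[tuple[str, int, SimElement]]:
        out = []
        for region, elems in self.regions().items():
            for i, el in enumerate(elems):
                if el.kind == "gene":
                    out.append((region, i, el))
        return out

    def gene_names(self) -> set[str]:
        return {el.gene.name for _, _, el in self.all_gene_elements()}

    def intron_inventory(self) -> list[tuple[str, str]]:
        out = []
        for _, _, el in self.all_gene_elements():
            for lab in el.gene.intron_labels():
                out.append((el.gene.name, lab))
        return out

    # -- rendering ------------------------------------------------------------

    def _layout(self) -> list[tuple[SimElement, int, bool]]:
        """Elements in genomic order as (element, strand_multiplier, is_ir_b)."""
        if not self.has_ir:
            return [(el, 1, False) for el in self.elements]
        out = [(el, 1, False) for el in self.lsc]
        out += [(el, 1, False) for el in self.ir]
        out += [(el, 1, False) for el in self.ssc]
        out += [(el, -1, True) for el in reversed(self.ir)]
        return out

    def sequence(self) -> str:
        chunks = []
        for el, mult, _ in self._layout():
            s = el.rendered()
            chunks.append(s if mult > 0 else revcomp(s))
        return "".join(chunks)

    def render(self) -> AnnotatedGenome:
        """Materialize as an AnnotatedGenome with exon-level features."""
        features = []
        offset = 0
        for el, mult, _is_b in self._layout():
            size = el.length()
            if el.kind == "gene":
                g = el.gene
                strand = g.strand * mult
                # exon offsets within the element, on the + strand of the
                # genome; the element payload is transcript-oriented
                bounds = []
                pos = 0
                for kind, _lab, seq in g.parts:
                    bounds.append((kind, pos, pos + len(seq)))
                    pos += len(seq)
                exons_t = [(s, e) for kind, s, e in bounds if kind == "exon"]
                if strand > 0:
                    ordered = [(offset + s, offset + e) for s, e in exons_t]
                else:
                    # transcript order maps to descending genomic coordinates
                    ordered = [(offset + size - e, offset + size - s)
                               for s, e in exons_t]
                sites = [
                    IntronSite(host_gene=g.name, site_label=lab,
                               intron_class=g.intron_meta.get(
                                   lab, ("II", "cis"))[0],
                               cis_or_trans=g.intron_meta.get(
                                   lab, ("II", "cis"))[1])
                    for lab in g.intron_labels()
                ]
                features.append(GeneFeature(
                    name=g.name, category=g.category, exons=ordered,
                    strand=strand, intron_sites=sites,
                ))
            offset += size
        genome = AnnotatedGenome(
            taxon_id=self.taxon_id, sequence=self.sequence(),
            topology="circular", features=features,
            source="plastcomp-simulation",
        )
        genome.assign_copy_indices()
        genome.validate()
        return genome

    def signed_order(self, one_ir_copy: bool = True) -> SignedGeneOrder:
        """Signed gene order without sequence rendering (fast path)."""
        genes = []
        counts: dict[str, int] = {}
        for el, mult, is_b in self._layout():
            if el.kind != "gene":
                continue
            if is_b and one_ir_copy:
                continue
            name = el.gene.name
            counts[name] = counts.get(name, 0) + 1
            genes.append((name, counts[name], el.gene.strand * mult))
        return SignedGeneOrder(self.taxon_id, genes, "circular")

    def ir_coordinates(self) -> dict | None:
        if not self.has_ir:
            return None
        lsc_len = sum(el.length() for el in self.lsc)
        ir_len = sum(el.length() for el in self.ir)
        ssc_len = sum(el.length() for el in self.ssc)
        return {
            "ir_a": (lsc_len, lsc_len + ir_len),
            "ir_b": (lsc_len + ir_len + ssc_len,
                     lsc_len + 2 * ir_len + ssc_len),
            "ssc": (lsc_len + ir_len, lsc_len + ir_len + ssc_len),
            "lsc": (lsc_len + 2 * ir_len + ssc_len,
                    2 * lsc_len + 2 * ir_len + ssc_len),
            "ir_length": ir_len,
        }


# --- ancestor construction ---------------------------------------------------


def _random_seq(rng, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _random_cds(rng, n_codons: int, gc: float) -> str:
    # per-base composition at the target G+C, stop codons rejected
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    weights = np.array([
        np.prod([p["ACGT".index(c)] for c in codon]) for codon in _NONSTOP
    ])
    weights /= weights.sum()
    body = rng.choice(_NONSTOP, size=n_codons - 2, p=weights)
    stop = rng.choice(["TAA", "TAG", "TGA"])
    return "ATG" + "".join(body) + stop


def _gene_length(rng, name: str, cfg: SimulationConfig) -> tuple[str, str]:
    cat = catalog.gene_category(name)
    if cat == "tRNA":
        return cat, _random_seq(rng, 72, cfg.gc + 0.1)
    if cat == "rRNA":
        size = {"rrs": 1480, "rrl": 2890, "rrf": 120}[name]
        return cat, _random_seq(rng, size, cfg.gc + 0.1)
    if cat == "tmRNA":
        return cat, _random_seq(rng, 350, cfg.gc)
    n = int(rng.integers(cfg.protein_codon_range[0],
                         cfg.protein_codon_range[1] + 1))
    return cat, _random_cds(rng, n, cfg.gc)


def simulate_ancestor(cfg: SimulationConfig) -> SimGenome:
    """Build the ancestral quadripartite genome.

    The IR carries the rDNA operon (rrs, trnI(gau), trnA(ugc), rrl, rrf, in
    transcription order) plus any configured extra genes; a configured
    number of genes goes to the SSC and the remainder to the LSC, separated
    by random intergenic spacers.  Output is deterministic in the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    site_by_gene: dict[str, list[tuple[str, str, str]]] = {}
    for gene, label, cls, cistrans in cfg.intron_sites:
        site_by_gene.setdefault(gene, []).append((label, cls, cistrans))

    def build_gene(name: str, strand: int) -> SimGene:
        cat, seq = _gene_length(rng, name, cfg)
        parts: list[tuple[str, str | None, str]] = [("exon", None, seq)]
        meta = {}
        for label, cls, cistrans in site_by_gene.get(name, []):
            # split the last exon at an interior position
            kind, _, exon_seq = parts[-1]
            if len(exon_seq) < 20:
                continue
            cut = int(rng.integers(5, len(exon_seq) - 5))
            intron_seq = _random_seq(
                rng, int(rng.integers(*cfg.intron_len_range)), cfg.gc)
            parts[-1] = ("exon", None, exon_seq[:cut])
            parts.append(("intron", label, intron_seq))
            parts.append(("exon", None, exon_seq[cut:]))
            meta[label] = (cls, cistrans)
        return SimGene(name=name, category=cat, strand=strand, parts=parts,
                       intron_meta=meta)

    def spacer() -> SimElement:
        n = int(rng.integers(*cfg.spacer_range))
        return SimElement(kind="spacer", seq=_random_seq(rng, n, cfg.gc - 0.05))

    operon = list(catalog.RDNA_OPERON)
    ir_genes = operon + [g for g in cfg.ir_extra_genes
                         if g in cfg.genes and g not in operon]
    rest = [g for g in cfg.genes if g not in ir_genes]
    order = list(rng.permutation(rest))
    ssc_genes = order[:cfg.n_ssc_genes]
    lsc_genes = order[cfg.n_ssc_genes:]

    def region(genes: list[str], operon_block: bool = False) -> list[SimElement]:
        out = [spacer()]
        for name in genes:
            strand = 1 if (operon_block and name in operon) else int(
                rng.choice([1, -1]))
            out.append(SimElement(kind="gene", gene=build_gene(name, strand)))
            out.append(spacer())
        return out

    genome = SimGenome(
        taxon_id="ancestor", has_ir=True,
        lsc=region(lsc_genes),
        ir=region(ir_genes, operon_block=True),
        ssc=region(ssc_genes),
    )
    if cfg.repeat_family_copies > 1 and cfg.repeat_family_len > 0:
        motif = _random_seq(rng, cfg.repeat_family_len, min(cfg.gc + 0.25, 0.8))
        spacer_idx = [i for i, el in enumerate(genome.lsc)
                      if el.kind == "spacer"]
        n = min(cfg.repeat_family_copies, len(spacer_idx))
        for k in rng.choice(spacer_idx, size=n, replace=False):
            ins = motif if rng.random() < 0.7 else revcomp(motif)
            el = genome.lsc[int(k)]
            off = int(rng.integers(len(el.seq) + 1))
            el.seq = el.seq[:off] + ins + el.seq[off:]
        genome.planted_repeat = {"motif": motif, "copies": n}
    _seal_ir_junctions(genome)
    return genome


def _seal_ir_junctions(genome: SimGenome) -> None:
    """Adjust spacer bases at the four junctions so the planted IR is maximal.

    Detection extends repeats outward; the bases flanking the arms must not
    be reverse-complementary or the detected IR would overshoot the planted
    coordinates.
    """
    if not genome.has_ir:
        return

    def set_base(elems: list[SimElement], which: str, base: str) -> None:
        el = elems[0] if which == "first" else elems[-1]
        if el.kind != "spacer" or not el.seq:
            return
        if which == "first":
            el.seq = base + el.seq[1:]
        else:
            el.seq = el.seq[:-1] + base

    # layout: LSC | IR-A | SSC | IR-B | (wrap to LSC)
    # junction 1: last base of LSC vs first base of LSC (after IR-B):
    # extension pairs sequence[lsc_end-1] with complement of sequence[ir_b_end]
    set_base(genome.lsc, "last", "A")
    set_base(genome.lsc, "first", "A")   # comp would need T at lsc end
    # junction 2: IR-A end vs SSC: pairs sequence[ir_a_end] with ssc end
    set_base(genome.ssc, "first", "C")
    set_base(genome.ssc, "last", "C")
    # the pairings above are (lsc.last, lsc.first) and (ssc.first, ssc.last):
    # A pairs with T and C with G, so A/A and C/C never extend.


# --- events ------------------------------------------------------------------


class EventSkipped(Exception):
    pass


def apply_event(genome: SimGenome, event: dict) -> None:
    """Apply one logged event in place; raise EventSkipped if impossible."""
    kind = event["kind"]
    if kind == "reversal":
        elems = _region_list(genome, event["region"])
        i, j = event["i"], event["j"]
        if j > len(elems):
            raise EventSkipped("reversal span outside region")
        segment = elems[i:j]
        for el in reversed(segment):
            if el.kind == "gene":
                el.gene.strand *= -1
            else:
                el.seq = revcomp(el.seq)
        elems[i:j] = list(reversed(segment))
    elif kind == "gene_loss":
        found = [
            (region, idx) for region, idx, el in genome.all_gene_elements()
            if el.gene.name == event["gene"]
        ]
        if not found:
            raise EventSkipped(f"gene {event['gene']} absent")
        region, idx = found[0]
        _region_list(genome, region).pop(idx)
    elif kind == "intron_loss":
        for _, _, el in genome.all_gene_elements():
            g = el.gene
            if g.name != event["gene"]:
                continue
            for pi, (pk, lab, _seq) in enumerate(g.parts):
                if pk == "intron" and lab == event["site_label"]:
                    # merge flanking exons
                    left = g.parts[pi - 1]
                    right = g.parts[pi + 1]
                    merged = ("exon", None, left[2] + right[2])
                    g.parts[pi - 1:pi + 2] = [merged]
                    g.intron_meta.pop(lab, None)
                    return
        raise EventSkipped(
            f"intron {event['site_label']} absent from {event['gene']}")
    elif kind == "intron_gain":
        for _, _, el in genome.all_gene_elements():
            g = el.gene
            if g.name != event["gene"]:
                continue
            if event["site_label"] in g.intron_labels():
                raise EventSkipped("intron already present")
            pk, _, exon_seq = g.parts[0]
            if len(exon_seq) < 20:
                raise EventSkipped("exon too short to split")
            cut = event["cut"] % max(len(exon_seq) - 10, 1) + 5
            g.parts[0:1] = [
                ("exon", None, exon_seq[:cut]),
                ("intron", event["site_label"], event["seq"]),
                ("exon", None, exon_seq[cut:]),
            ]
            g.intron_meta[event["site_label"]] = (
                event.get("intron_class", "II"), event.get("cis_or_trans", "cis"))
            return
        raise EventSkipped(f"host gene {event['gene']} absent")
    elif kind == "ir_loss":
        if not genome.has_ir:
            raise EventSkipped("no IR to lose")
        genome.elements = genome.lsc + genome.ir + genome.ssc
        genome.lsc, genome.ir, genome.ssc = [], [], []
        genome.has_ir = False
    elif kind == "ir_boundary_shift":
        if not genome.has_ir:
            raise EventSkipped("no IR for boundary shift")
        side, direction = event["side"], event["direction"]
        if direction == "into":
            src = genome.lsc if side == "lsc" else genome.ssc
            movable = [k for k, el in enumerate(src) if el.kind == "gene"]
            if not movable:
                raise EventSkipped("no gene to move into IR")
            k = movable[-1] if side == "lsc" else movable[0]
            el = src.pop(k)
            if side == "lsc":
                genome.ir.insert(0, el)
            else:
                genome.ir.append(el)
        else:
            movable = [k for k, el in enumerate(genome.ir)
                       if el.kind == "gene"
                       and el.gene.name not in catalog.RDNA_OPERON]
            if not movable:
                raise EventSkipped("no movable gene in IR")
            k = movable[0] if side == "lsc" else movable[-1]
            el = genome.ir.pop(k)
            if side == "lsc":
                genome.lsc.append(el)
            else:
                genome.ssc.insert(0, el)
    elif kind == "substitution":
        el = _region_list(genome, event["region"])[event["index"]]
        off, base = event["offset"], event["base"]
        if el.kind == "spacer":
            if off >= len(el.seq):
                raise EventSkipped("offset outside spacer")
            el.seq = el.seq[:off] + base + el.seq[off + 1:]
        else:
            pos = off
            for pi, (pk, lab, seq) in enumerate(el.gene.parts):
                if pos < len(seq):
                    el.gene.parts[pi] = (pk, lab,
                                         seq[:pos] + base + seq[pos + 1:])
                    return
                pos -= len(seq)
            raise EventSkipped("offset outside gene")
    elif kind == "indel":
        el = _region_list(genome, event["region"])[event["index"]]
        if el.kind != "spacer":
            raise EventSkipped("indels restricted to intergenic spacers")
        off = event["offset"]
        if event["op"] == "del":
            n = event["length"]
            if off + n > len(el.seq):
                raise EventSkipped("deletion outside spacer")
            el.seq = el.seq[:off] + el.seq[off + n:]
        else:
            el.seq = el.seq[:off] + event["seq"] + el.seq[off:]
    else:
        raise ValueError(f"unknown event kind {kind!r}")


def _region_list(genome: SimGenome, region: str) -> list[SimElement]:
    return genome.regions()[region]


# --- evolution along a tree --------------------------------------------------


@dataclass
class SimulationTruth:
    config: dict
    tree_newick: str
    events: dict[str, list[dict]]            # branch (child label) -> events
    leaf_ir: dict[str, dict | None] = field(default_factory=dict)
    leaf_genes: dict[str, list[str]] = field(default_factory=dict)
    leaf_introns: dict[str, list[list[str]]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1,
                                         default=list))


def _draw_events(genome: SimGenome, rng, cfg: SimulationConfig, scale: float,
                 lost_genes: set[str], lost_introns: set[str]) -> list[dict]:
    """Sample a branch's events against the current genome state."""
    events: list[dict] = []

    def poisson(rate):
        return int(rng.poisson(rate * scale))

    for _ in range(poisson(cfg.ir_loss_rate)):
        if genome.has_ir and not (cfg.unique_losses
                                  and "__IR__" in lost_genes):
            events.append({"kind": "ir_loss"})
            apply_event(genome, events[-1])
            lost_genes.add("__IR__")
    for _ in range(poisson(cfg.ir_boundary_shift_rate)):
        if not genome.has_ir:
            continue
        ev = {"kind": "ir_boundary_shift",
              "side": str(rng.choice(["lsc", "ssc"])),
              "direction": str(rng.choice(["into", "out"]))}
        try:
            apply_event(genome, ev)
            events.append(ev)
        except EventSkipped:
            pass
    for _ in range(poisson(cfg.gene_loss_rate)):
        candidates = sorted(
            g for g in genome.gene_names()
            if g not in cfg.protected_genes
            and not (cfg.unique_losses and g in lost_genes))
        if not candidates:
            continue
        gene = str(rng.choice(candidates))
        ev = {"kind": "gene_loss", "gene": gene}
        try:
            apply_event(genome, ev)
            events.append(ev)
            lost_genes.add(gene)
        except EventSkipped:
            pass
    for _ in range(poisson(cfg.intron_loss_rate)):
        inventory = sorted(
            (g, lab) for g, lab in genome.intron_inventory()
            if not (cfg.unique_losses and lab in lost_introns))
        if not inventory:
            continue
        g, lab = inventory[int(rng.integers(len(inventory)))]
        ev = {"kind": "intron_loss", "gene": g, "site_label": lab}
        try:
            apply_event(genome, ev)
            events.append(ev)
            lost_introns.add(lab)
        except EventSkipped:
            pass
    for _ in range(poisson(cfg.intron_gain_rate)):
        present = {lab for _, lab in genome.intron_inventory()}
        genes_present = genome.gene_names()
        open_sites = [
            (g, lab, cls, ct) for g, lab, cls, ct in cfg.intron_sites
            if lab not in present and g in genes_present]
        if not open_sites:
            continue
        g, lab, cls, ct = open_sites[int(rng.integers(len(open_sites)))]
        ev = {"kind": "intron_gain", "gene": g, "site_label": lab,
              "intron_class": cls, "cis_or_trans": ct,
              "cut": int(rng.integers(0, 10 ** 6)),
              "seq": _random_seq(rng, int(rng.integers(*cfg.intron_len_range)),
                                 cfg.gc)}
        try:
            apply_event(genome, ev)
            events.append(ev)
        except EventSkipped:
            pass
    for _ in range(poisson(cfg.reversal_rate)):
        regions = [(name, elems) for name, elems in genome.regions().items()
                   if name != "ir" and len(elems) >= 2]
        if not regions:
            continue
        weights = np.array([len(e) for _, e in regions], dtype=float)
        weights /= weights.sum()
        name, elems = regions[int(rng.choice(len(regions), p=weights))]
        ev = None
        for _try in range(20):
            i = int(rng.integers(0, len(elems)))
            j = int(rng.integers(0, len(elems)))
            i, j = min(i, j), max(i, j) + 1
            if any(el.kind == "gene" for el in elems[i:j]):
                ev = {"kind": "reversal", "region": name, "i": i, "j": j}
                break
        if ev is None:
            continue
        apply_event(genome, ev)
        events.append(ev)
    # sequence-level noise last
    total = sum(el.length() for _, elems in genome.regions().items()
                for el in elems)
    for _ in range(poisson(cfg.substitution_rate * total)):
        region, elems = _pick_region(genome, rng)
        idx = int(rng.integers(len(elems)))
        el = elems[idx]
        if el.length() == 0:
            continue
        off = int(rng.integers(el.length()))
        base = str(rng.choice(list("ACGT")))
        ev = {"kind": "substitution", "region": region, "index": idx,
              "offset": off, "base": base}
        try:
            apply_event(genome, ev)
            events.append(ev)
        except EventSkipped:
            pass
    for _ in range(poisson(cfg.indel_rate * total)):
        region, elems = _pick_region(genome, rng)
        spacers = [k for k, el in enumerate(elems)
                   if el.kind == "spacer" and len(el.seq) > 10]
        if not spacers:
            continue
        idx = spacers[int(rng.integers(len(spacers)))]
        el = elems[idx]
        length = int(rng.geometric(1.0 / cfg.indel_mean_len))
        if rng.random() < 0.5 and len(el.seq) > length + 2:
            off = int(rng.integers(len(el.seq) - length))
            ev = {"kind": "indel", "op": "del", "region": region,
                  "index": idx, "offset": off, "length": length}
        else:
            off = int(rng.integers(len(el.seq)))
            ev = {"kind": "indel", "op": "ins", "region": region,
                  "index": idx, "offset": off,
                  "seq": _random_seq(rng, length, cfg.gc)}
        try:
            apply_event(genome, ev)
            events.append(ev)
        except EventSkipped:
            pass
    return events


def _pick_region(genome: SimGenome, rng):
    regions = list(genome.regions().items())
    weights = np.array([max(sum(el.length() for el in elems), 1)
                        for _, elems in regions], dtype=float)
    weights /= weights.sum()
    k = int(rng.choice(len(regions), p=weights))
    return regions[k]


def evolve_on_tree(ancestor: SimGenome, tree: dendropy.Tree,
                   cfg: SimulationConfig
                   ) -> tuple[dict[str, SimGenome], SimulationTruth]:
    """Evolve the ancestor along a rooted tree, logging every event."""
    ensure_node_labels(tree)
    rng = np.random.default_rng(cfg.seed + 1)
    truth = SimulationTruth(
        config=cfg.to_dict(),
        tree_newick=tree.as_string(schema="newick").strip(),
        events={},
    )
    lost_genes: set[str] = set()
    lost_introns: set[str] = set()
    state: dict = {tree.seed_node: ancestor}
    leaves: dict[str, SimGenome] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_genome = state[node.parent_node]
        genome = parent_genome.clone(taxon_id=node.label)
        scale = node.edge.length if node.edge.length else 1.0
        truth.events[node.label] = _draw_events(
            genome, rng, cfg, scale, lost_genes, lost_introns)
        state[node] = genome
        if node.is_leaf():
            leaves[node.label] = genome
            truth.leaf_ir[node.label] = genome.ir_coordinates()
            order = genome.signed_order(one_ir_copy=False)
            truth.leaf_genes[node.label] = [
                f"{'+' if s > 0 else '-'}{n}" for n, _c, s in order.genes]
            truth.leaf_introns[node.label] = [
                [g, lab] for g, lab in sorted(genome.intron_inventory())]
    return leaves, truth


def replay(ancestor: SimGenome, tree: dendropy.Tree,
           truth: SimulationTruth) -> dict[str, SimGenome]:
    """Re-apply the logged events; must reproduce every leaf exactly."""
    ensure_node_labels(tree)
    state: dict = {tree.seed_node: ancestor}
    leaves: dict[str, SimGenome] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        genome = state[node.parent_node].clone(taxon_id=node.label)
        for ev in truth.events.get(node.label, []):
            try:
                apply_event(genome, ev)
            except EventSkipped:
                pass
        state[node] = genome
        if node.is_leaf():
            leaves[node.label] = genome
    return leaves


def emit_fixtures(leaves: dict[str, SimGenome], truth: SimulationTruth,
                  out_dir: str | Path) -> list[Path]:
    """Write GenBank + GFF3/FASTA per leaf, the tree, and the truth log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for label, sim in sorted(leaves.items()):
        genome = sim.render()
        gb = out / f"{label}.gb"
        gff = out / f"{label}.gff3"
        fasta = out / f"{label}.fasta"
        io.write_genbank(genome, gb)
        io.write_gff_fasta(genome, gff, fasta)
        written += [gb, gff, fasta]
    tree_path = out / "tree.nwk"
    tree_path.write_text(truth.tree_newick + "\n")
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    written += [tree_path, truth_path]
    return written
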