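"""Nucleotide composition, small-repeat content, colinear divergence and
tRNA decoding audits.

Small dispersed repeats are all maximal exact repeated segment pairs above a
length threshold, in direct and inverted orientation; their merged footprint
gives the masked fraction of the genome and the composition split between
repeated and unique sequence.  Colinear divergence counts substitution sites
and indel events between two genomes that share gene order over their whole
length, using unique shared k-mer anchors and global alignment of the
inter-anchor gaps.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import edlib

from . import catalog
from .model import AnnotatedGenome, Interval, revcomp
from .quadripartite import maximal_matches


def gc_content(regions: str | list[str]) -> float:
    """(G+C)/(A+C+G+T) over one or several sequences; N excluded."""
    if isinstance(regions, str):
        regions = [regions]
    gc = acgt = 0
    for seq in regions:
        c = Counter(seq.upper())
        gc += c["G"] + c["C"]
        acgt += c["A"] + c["C"] + c["G"] + c["T"]
    if acgt == 0:
        raise ValueError("no A/C/G/T positions in input")
    return gc / acgt


STOP_CODONS = {"TAA", "TAG", "TGA"}


def gc_by_codon_position(genes: list[str]) -> tuple[float, float, float]:
    """Positionwise G+C over concatenated codons of protein-coding genes.

    Incomplete terminal codons are trimmed; internal stop codons trigger a
    warning with their count.
    """
    if not genes:
        raise ValueError("empty gene set")
    counts = [[0, 0] for _ in range(3)]  # per position: [gc, acgt]
    internal_stops = 0
    for seq in genes:
        seq = seq.upper()
        seq = seq[:len(seq) - len(seq) % 3]
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        for ci, codon in enumerate(codons):
            if codon in STOP_CODONS and ci < len(codons) - 1:
                internal_stops += 1
            for p, base in enumerate(codon):
                if base in "ACGT":
                    counts[p][1] += 1
                    if base in "GC":
                        counts[p][0] += 1
    if internal_stops:
        warnings.warn(f"{internal_stops} internal stop codons in input genes")
    return tuple(gc / n if n else 0.0 for gc, n in counts)  # type: ignore[return-value]


# --- repeats -----------------------------------------------------------------


@dataclass
class RepeatRecord:
    kind: str          # direct | inverted
    copy1: Interval
    copy2: Interval
    length: int


@dataclass
class RepeatCatalog:
    taxon_id: str
    min_len: int
    records: list[RepeatRecord]
    masked_intervals: list[Interval] = field(default_factory=list)
    masked_fraction: float = 0.0
    gc_repeat: float = 0.0
    gc_unique: float = 0.0


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def find_repeats(genome: AnnotatedGenome | str, min_len: int = 30,
                 kinds: tuple[str, ...] = ("direct", "inverted"),
                 exclude: list[Interval] | None = None) -> RepeatCatalog:
    """All maximal exact repeated pairs >= min_len, direct and inverted.

    The sequence is handled linearly (as deposited).  ``exclude`` masks
    intervals — typically the arms of the large inverted repeat — before
    searching, so the catalog reflects small dispersed repeats only.
    """
    if isinstance(genome, AnnotatedGenome):
        seq, taxon = genome.sequence, genome.taxon_id
    else:
        seq, taxon = genome.upper(), "sequence"
    if exclude:
        chars = list(seq)
        for s, e in exclude:
            for i in range(s, min(e, len(chars))):
                chars[i] = "N"
            if e > len(seq):  # wrapping interval
                for i in range(0, e - len(seq)):
                    chars[i] = "N"
        seq = "".join(chars)
    records: list[RepeatRecord] = []
    if "direct" in kinds:
        seen = set()
        for i, j, length in maximal_matches(seq, seq, min_len,
                                            exclude_self_diagonal=True):
            a, b = sorted(((i, i + length), (j, j + length)))
            if (a, b) in seen:
                continue
            seen.add((a, b))
            records.append(RepeatRecord("direct", a, b, length))
    if "inverted" in kinds:
        L = len(seq)
        seen = set()
        for i, p, length in maximal_matches(seq, revcomp(seq), min_len):
            arm1 = (i, i + length)
            arm2 = (L - p - length, L - p)
            if arm1 == arm2:
                continue
            a, b = sorted((arm1, arm2))
            if (a, b) in seen:
                continue
            seen.add((a, b))
            records.append(RepeatRecord("inverted", a, b, length))
    records.sort(key=lambda r: (r.copy1, r.copy2, r.kind))
    cat = RepeatCatalog(taxon_id=taxon, min_len=min_len, records=records)
    _summarize(seq, cat)
    return cat


def _summarize(seq: str, cat: RepeatCatalog) -> None:
    arms = [r.copy1 for r in cat.records] + [r.copy2 for r in cat.records]
    cat.masked_intervals = merge_intervals(arms)
    masked_bp = sum(e - s for s, e in cat.masked_intervals)
    n_valid = sum(1 for c in seq if c in "ACGT")
    cat.masked_fraction = masked_bp / len(seq) if seq else 0.0
    masked_seq = "".join(seq[s:e] for s, e in cat.masked_intervals)
    unique_seq = _complement_regions(seq, cat.masked_intervals)
    cat.gc_repeat = gc_content(masked_seq) if any(
        c in "ACGT" for c in masked_seq) else 0.0
    cat.gc_unique = gc_content(unique_seq) if any(
        c in "ACGT" for c in unique_seq) else 0.0
    del n_valid


def _complement_regions(seq: str, intervals: list[Interval]) -> str:
    out, prev = [], 0
    for s, e in intervals:
        out.append(seq[prev:s])
        prev = e
    out.append(seq[prev:])
    return "".join(out)


@dataclass
class RepeatSummary:
    masked_fraction: float
    gc_repeat: float   # percent
    gc_unique: float   # percent


def repeat_summary(genome: AnnotatedGenome | str,
                   cat: RepeatCatalog) -> RepeatSummary:
    """Masked fraction plus G+C of repeated vs unique sequence (percent)."""
    return RepeatSummary(
        masked_fraction=cat.masked_fraction,
        gc_repeat=100.0 * cat.gc_repeat,
        gc_unique=100.0 * cat.gc_unique,
    )


def soft_mask(seq: str, intervals: list[Interval]) -> str:
    """Lowercase the masked intervals (RepeatMasker -xsmall style)."""
    chars = list(seq.upper())
    for s, e in intervals:
        for i in range(s, min(e, len(chars))):
            chars[i] = chars[i].lower()
    return "".join(chars)


# --- colinear divergence -----------------------------------------------------


@dataclass
class DivergenceReport:
    aligned_fraction: float
    substitution_sites: int
    indel_events: int
    indel_lengths: list[int]
    colinear: bool = True

    @property
    def total_sites(self) -> int:
        """Divergent sites: substitutions plus one site per indel event."""
        return self.substitution_sites + self.indel_events


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    counts: Counter = Counter(seq[i:i + k] for i in range(len(seq) - k + 1))
    return {seq[i:i + k]: i for i in range(len(seq) - k + 1)
            if counts[seq[i:i + k]] == 1}


def _lis_chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain increasing in both coordinates (anchors sorted by a)."""
    import bisect
    tails: list[int] = []
    tails_idx: list[int] = []
    back = [-1] * len(anchors)
    for i, (_, b) in enumerate(anchors):
        j = bisect.bisect_left(tails, b)
        if j == len(tails):
            tails.append(b)
            tails_idx.append(i)
        else:
            tails[j] = b
            tails_idx[j] = i
        back[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1] if tails_idx else -1
    while i != -1:
        chain.append(anchors[i])
        i = back[i]
    return chain[::-1]


def _align_gap(ga: str, gb: str) -> tuple[int, list[int]]:
    """Substitution count and indel-run lengths from a global alignment."""
    if not ga and not gb:
        return 0, []
    if not ga or not gb:
        return 0, [abs(len(ga) - len(gb))]
    res = edlib.align(ga, gb, mode="NW", task="path")
    subs = 0
    indels: list[int] = []
    import re
    for length, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        length = int(length)
        if op == "X":
            subs += length
        elif op in "ID":
            indels.append(length)
    return subs, indels


def colinear_divergence(a: str, b: str, anchor_k: int = 31) -> DivergenceReport:
    """Count substitution sites and indel events between colinear genomes.

    Unique shared k-mers are chained colinearly; the gaps between successive
    anchors (and the flanks) are globally aligned.  Each maximal gap run
    counts as one indel event.  If the anchor chain covers less than half of
    the shorter genome the pair is declared non-colinear and a partial
    report is returned.
    """
    a, b = a.upper(), b.upper()
    ka = _unique_kmers(a, anchor_k)
    kb = _unique_kmers(b, anchor_k)
    shared = sorted((ka[s], kb[s]) for s in ka.keys() & kb.keys())
    chain = _lis_chain(shared) if shared else []
    # merge overlapping/abutting anchors into exact colinear segments
    segments: list[list[int]] = []  # [a_start, a_end, b_start, b_end]
    for pa, pb in chain:
        if not segments:
            segments.append([pa, pa + anchor_k, pb, pb + anchor_k])
            continue
        s = segments[-1]
        if pa - s[1] == pb - s[3] and pa <= s[1]:
            s[1] = pa + anchor_k
            s[3] = pb + anchor_k
            continue
        # anchor on a shifted diagonal: trim any overlap with the previous
        # segment so the diagonal shift surfaces as an alignable gap
        trim = max(s[1] - pa, s[3] - pb, 0)
        if trim >= anchor_k:
            continue
        segments.append([pa + trim, pa + anchor_k, pb + trim,
                         pb + anchor_k])
    if not segments:
        return DivergenceReport(0.0, 0, 0, [], colinear=False)
    anchored = sum(s[1] - s[0] for s in segments)
    subs = 0
    indel_lengths: list[int] = []
    aligned = anchored
    prev = [0, 0]
    for seg in segments + [[len(a), len(a), len(b), len(b)]]:
        ga = a[prev[0]:seg[0]]
        gb = b[prev[1]:seg[2]]
        s, ind = _align_gap(ga, gb)
        subs += s
        indel_lengths.extend(ind)
        aligned += min(len(ga), len(gb))
        prev = [seg[1], seg[3]]
    aligned_fraction = min(aligned / min(len(a), len(b)), 1.0)
    colinear = anchored >= 0.5 * min(len(a), len(b))
    return DivergenceReport(
        aligned_fraction=aligned_fraction,
        substitution_sites=subs,
        indel_events=len(indel_lengths),
        indel_lengths=sorted(indel_lengths),
        colinear=colinear,
    )


# --- codon decoding audit ----------------------------------------------------


@dataclass
class CodonAudit:
    codon_usage: dict[str, int]
    anticodon_trnas: list[str]
    undecodable: list[str]              # strict wobble rules
    undecodable_superwobble: list[str]  # U34 superwobble in family boxes


def codon_decoding_audit(genome: AnnotatedGenome) -> CodonAudit:
    """List sense codons used by the CDS set that no encoded tRNA can read.

    Both decoding models are reported: strict organellar wobble rules, and
    the superwobble variant in which an unmodified U34 reads the whole
    four-codon family box.
    """
    usage: Counter = Counter()
    for f in genome.features:
        if f.category != "protein":
            continue
        seq = f.extract(genome.sequence)
        seq = seq[:len(seq) - len(seq) % 3]
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            if codon not in STOP_CODONS and set(codon) <= set("ACGT"):
                usage[codon] += 1
    trnas = sorted({f.name for f in genome.features if f.category == "tRNA"})
    readable_strict: set[str] = set()
    readable_super: set[str] = set()
    for t in trnas:
        readable_strict |= catalog.codons_read(t, superwobble=False)
        readable_super |= catalog.codons_read(t, superwobble=True)
    used = set(usage)
    return CodonAudit(
        codon_usage=dict(sorted(usage.items())),
        anticodon_trnas=trnas,
        undecodable=sorted(used - readable_strict),
        undecodable_superwobble=sorted(used - readable_super),
    )
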