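"""Large inverted repeat detection and quadripartite architecture analysis.

Chloroplast genomes typically carry two identical, oppositely oriented
copies of a large inverted repeat (IR) containing the rRNA operon, which
split the circle into small and large single-copy regions (SSC, LSC).  This
module finds the IR by exact (optionally mismatch-tolerant) self-comparison,
delimits the four regions, assigns genes to them, and scores how well an
IR-less genome preserves the ancestral partitioning of genes between the
SSC- and LSC-sides of the rRNA operon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import catalog
from .model import AnnotatedGenome, Interval, revcomp, warn


@dataclass
class QuadripartiteMap:
    taxon_id: str
    has_ir: bool
    ir_a: Interval | None = None
    ir_b: Interval | None = None
    ssc: Interval | None = None
    lsc: Interval | None = None
    ir_length: int = 0
    identity: float = 1.0

    def regions(self) -> dict[str, Interval]:
        if not self.has_ir:
            return {}
        return {"IRa": self.ir_a, "IRb": self.ir_b,
                "SSC": self.ssc, "LSC": self.lsc}


# --- repeat match machinery (shared with seq_stats) --------------------------


def maximal_matches(seq_a: str, seq_b: str, min_len: int,
                    seed: int | None = None,
                    exclude_self_diagonal: bool = False
                    ) -> list[tuple[int, int, int]]:
    """Maximal exact matches >= min_len between two strings.

    Returns (start_a, start_b, length) triples.  Seed-and-merge on k-mer
    diagonals: any match of length >= min_len contains seeds at every
    offset, so merged seed runs are exactly the maximal matches.
    """
    k = seed or min(min_len, 32)
    if min_len < k:
        k = min_len
    if k <= 0 or len(seq_a) < k or len(seq_b) < k:
        return []
    index: dict[str, list[int]] = {}
    for j in range(len(seq_b) - k + 1):
        kmer = seq_b[j:j + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)
    diagonals: dict[int, list[int]] = {}
    for i in range(len(seq_a) - k + 1):
        for j in index.get(seq_a[i:i + k], ()):
            if exclude_self_diagonal and i == j:
                continue
            diagonals.setdefault(i - j, []).append(i)
    out = []
    for d, starts in diagonals.items():
        starts.sort()
        run_start = prev = starts[0]
        for i in starts[1:] + [None]:
            if i is not None and i == prev + 1:
                prev = i
                continue
            length = prev - run_start + k
            if length >= min_len:
                out.append((run_start, run_start - d, length))
            if i is not None:
                run_start = prev = i
    return out


def _inverted_pairs(sequence: str, min_len: int, circular: bool
                    ) -> list[tuple[Interval, Interval]]:
    """Disjoint reverse-complementary segment pairs >= min_len (canonical)."""
    L = len(sequence)
    S = sequence + sequence if circular else sequence
    R = revcomp(S)
    pairs = set()
    for i, p, length in maximal_matches(S, R, min_len):
        length = min(length, L)
        arm1 = (i % L, length)
        arm2 = ((len(S) - p - length) % L, length)
        a, b = sorted((arm1, arm2))
        if a == b:
            continue
        pairs.add((a, b))
    out = []
    for (s1, l1), (s2, l2) in pairs:
        iv1 = (s1, s1 + l1)
        iv2 = (s2, s2 + l2)
        if _intervals_overlap(iv1, iv2, L, circular):
            continue
        out.append((iv1, iv2))
    return out


def _intervals_overlap(a: Interval, b: Interval, length: int,
                       circular: bool) -> bool:
    def cover(iv):
        s, e = iv
        if not circular or e <= length:
            return {(s, min(e, length))}
        return {(s, length), (0, e - length)}

    for s1, e1 in cover(a):
        for s2, e2 in cover(b):
            if s1 < e2 and s2 < e1:
                return True
    return False


def detect_inverted_repeat(genome: AnnotatedGenome, min_len: int = 1000,
                           max_mismatch_frac: float = 0.0
                           ) -> QuadripartiteMap:
    """Locate the large inverted repeat and delimit the quadripartite map.

    The longest pair of disjoint reverse-complementary segments passing the
    thresholds is returned, maximally extended at both junctions.  Ties go
    to the pair whose copies contain an rRNA gene (the IR is defined by the
    rRNA operon it carries), then to the smallest start coordinate.  The
    shorter single-copy region is named SSC.
    """
    L = genome.length
    if L < 2 * min_len:
        warn(f"{genome.taxon_id}: genome shorter than twice min_len; no IR")
        return QuadripartiteMap(genome.taxon_id, has_ir=False)
    circular = genome.topology == "circular"
    pairs = _inverted_pairs(genome.sequence, min_len, circular)
    if max_mismatch_frac > 0:
        pairs = _extend_with_mismatches(genome.sequence, pairs,
                                        max_mismatch_frac, circular)
    if not pairs:
        return QuadripartiteMap(genome.taxon_id, has_ir=False)

    rrna_positions = [
        f.genomic_start for f in genome.features if f.category == "rRNA"
    ]

    def contains_rrna(pair):
        for (s, e) in pair:
            for p in rrna_positions:
                q = p if p >= s else p + L
                if s <= q < e:
                    return True
        return False

    def score(pair):
        (s1, e1), (s2, e2) = pair
        return (-(e1 - s1), 0 if contains_rrna(pair) else 1, s1, s2)

    ir_a, ir_b = min(pairs, key=score)
    arm_len = ir_a[1] - ir_a[0]
    identity = _arm_identity(genome.sequence, ir_a, ir_b)

    # single-copy gaps between the two arms, walking the circle
    gap1 = (ir_a[1] % L, ir_b[0] if ir_b[0] >= ir_a[1] % L else ir_b[0] + L)
    gap2 = (ir_b[1] % L, ir_a[0] if ir_a[0] >= ir_b[1] % L else ir_a[0] + L)
    g1, g2 = gap1[1] - gap1[0], gap2[1] - gap2[0]
    ssc, lsc = (gap1, gap2) if g1 <= g2 else (gap2, gap1)
    return QuadripartiteMap(
        taxon_id=genome.taxon_id, has_ir=True,
        ir_a=ir_a, ir_b=ir_b, ssc=ssc, lsc=lsc,
        ir_length=arm_len, identity=identity,
    )


def _arm_identity(sequence: str, arm_a: Interval, arm_b: Interval) -> float:
    L = len(sequence)
    doubled = sequence + sequence
    sa = doubled[arm_a[0]:arm_a[0] + (arm_a[1] - arm_a[0])]
    sb = doubled[arm_b[0]:arm_b[0] + (arm_b[1] - arm_b[0])]
    sb = revcomp(sb)
    if not sa or len(sa) != len(sb):
        return 0.0
    return sum(x == y for x, y in zip(sa, sb)) / len(sa)


def _extend_with_mismatches(sequence: str, pairs, max_frac: float,
                            circular: bool):
    """Greedily extend exact arms outward, tolerating sparse mismatches."""
    L = len(sequence)
    doubled = sequence + sequence if circular else sequence

    def base(i):
        return doubled[i % len(doubled)]

    out = []
    for (s1, e1), (s2, e2) in pairs:
        # left of arm1 pairs with right of arm2
        mism = 0
        length = e1 - s1
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        while s1 > 0 and e2 < 2 * L:
            if (length + 1) and (mism + (base(s1 - 1) != comp[base(e2)])) / (
                    length + 1) > max_frac:
                break
            mism += base(s1 - 1) != comp[base(e2)]
            s1 -= 1
            e2 += 1
            length += 1
        out.append(((s1, e1), (s2, e2)))
    return out


# --- gene partitioning -------------------------------------------------------


@dataclass
class PartitionPattern:
    taxon_id: str
    region_of: dict[tuple[str, int], str]       # (gene, copy) -> IR|SSC|LSC|SC
    order: list[tuple[str, str]]                # (gene, region) by coordinate
    straddlers: set[tuple[str, int]] = field(default_factory=set)
    ancestral_side: dict[str, str] = field(default_factory=dict)
    segregation_violations: int | None = None


def _overlap_on_circle(exon: Interval, region: Interval, L: int) -> int:
    es, ee = exon[0] % L, exon[0] % L + (exon[1] - exon[0])
    rs, re = region[0] % L, region[0] % L + (region[1] - region[0])
    total = 0
    for off_e in (0, L):
        for off_r in (0, L):
            lo = max(es + off_e, rs + off_r)
            hi = min(ee + off_e, re + off_r)
            if hi > lo:
                total += hi - lo
    return min(total, ee - es)


def partition_genes(genome: AnnotatedGenome, qmap: QuadripartiteMap
                    ) -> PartitionPattern:
    """Label each gene by the region holding the majority of its coding length.

    Genes straddling a junction are labeled by majority and flagged.  In an
    IR-less genome every gene is labeled 'SC' (single region by convention).
    """
    L = genome.length
    pattern = PartitionPattern(genome.taxon_id, {}, [])
    feats = genome.sorted_features()
    if not qmap.has_ir:
        for f in feats:
            pattern.region_of[f.key()] = "SC"
        pattern.order = [(f.name, "SC") for f in feats]
        return pattern
    regions = {"IR": [qmap.ir_a, qmap.ir_b], "SSC": [qmap.ssc],
               "LSC": [qmap.lsc]}
    for f in feats:
        per_region = {}
        for name, ivs in regions.items():
            per_region[name] = sum(
                _overlap_on_circle(e, iv, L) for e in f.exons for iv in ivs)
        best = max(per_region, key=lambda r: (per_region[r], r))
        pattern.region_of[f.key()] = best
        if sum(1 for v in per_region.values() if v > 0) > 1:
            pattern.straddlers.add(f.key())
    pattern.order = [(f.name, pattern.region_of[f.key()]) for f in feats]
    return pattern


@dataclass
class SegregationReport:
    taxon_id: str
    reference_id: str
    n_shared: int
    violations: int
    sides: dict[str, str]


def _assign_sides(reference: PartitionPattern) -> dict[str, str]:
    sides: dict[str, str] = {}
    for (name, copy), region in reference.region_of.items():
        if name in catalog.RDNA_OPERON:
            sides[name] = "rdna"
        elif region == "SSC":
            sides[name] = "ssc-side"
        elif region == "LSC":
            sides[name] = "lsc-side"
        elif region == "IR":
            sides.setdefault(name, "unclassified")
        else:
            sides[name] = "unclassified"
    return sides


def min_removals_to_segregate(labels: list[str]) -> int:
    """Minimum deletions making the two side labels contiguous circular arcs.

    ``labels`` is the circular sequence of 'ssc-side'/'lsc-side' labels.
    Exact O(m^2) scan over candidate arcs: choose the arc that will hold all
    ssc-side genes; remove lsc-side genes inside it and ssc-side genes
    outside it.
    """
    m = len(labels)
    if m == 0:
        return 0
    is_s = [1 if lab == "ssc-side" else 0 for lab in labels]
    total_s = sum(is_s)
    doubled = is_s + is_s
    pref = [0]
    for v in doubled:
        pref.append(pref[-1] + v)
    best = min(total_s, m - total_s)  # empty arc / full arc
    for start in range(m):
        for length in range(1, m + 1):
            s_in = pref[start + length] - pref[start]
            cost = (length - s_in) + (total_s - s_in)
            if cost < best:
                best = cost
    return best


def classify_partitioning(target: PartitionPattern,
                          reference: PartitionPattern) -> SegregationReport:
    """Score retention of the ancestral SSC/LSC gene partitioning.

    Each shared gene inherits its side (relative to the rRNA operon) from
    the reference genome; the report counts the minimum number of genes
    whose removal leaves the ssc-side and lsc-side genes of the target in
    two contiguous arcs of its circular gene order.
    """
    sides = _assign_sides(reference)
    target_genes = {name for name, _ in target.order}
    shared = target_genes & set(sides)
    if target_genes and len(shared) < 0.5 * len(target_genes):
        warn(f"{target.taxon_id}: fewer than half of the genes are shared "
             f"with reference {reference.taxon_id}")
    target.ancestral_side = {
        name: sides.get(name, "unclassified") for name in target_genes}
    labels = [sides[name] for name, _ in target.order
              if sides.get(name) in ("ssc-side", "lsc-side")]
    violations = min_removals_to_segregate(labels)
    target.segregation_violations = violations
    return SegregationReport(
        taxon_id=target.taxon_id, reference_id=reference.taxon_id,
        n_shared=len(shared), violations=violations,
        sides=dict(target.ancestral_side),
    )
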