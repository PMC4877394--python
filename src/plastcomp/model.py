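"""Core domain model for annotated chloroplast genomes.

Coordinates are 0-based, half-open throughout the package.  On circular
genomes a feature may wrap the origin; such intervals are stored with
``end > genome length`` so that ``end - start`` is always the interval
length and positions are interpreted modulo the genome length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def interval_len(iv: Interval) -> int:
    return iv[1] - iv[0]


def normalize_interval(iv: Interval, length: int) -> Interval:
    """Bring a (possibly wrapping) interval to a start in [0, length)."""
    start, end = iv
    span = end - start
    start %= length
    return (start, start + span)


@dataclass
class IntronSite:
    """A named intron insertion site carried by a gene.

    ``site_label`` follows the host-gene + position convention used for
    plastid introns, e.g. ``rps12_114`` or ``trnL(uaa)_35``.
    """

    host_gene: str
    site_label: str
    intron_class: str = "II"  # "I" or "II"
    cis_or_trans: str = "cis"
    has_orf: bool = False


@dataclass
class GeneFeature:
    """A (possibly multi-exon) gene on an annotated genome.

    ``exons`` are ordered along the transcription direction, so for a
    minus-strand gene the first exon has the largest genomic coordinate.
    ``copy_index`` distinguishes duplicate copies of the same gene symbol
    (e.g. the two inverted-repeat copies of ``rrs``).
    """

    name: str
    category: str  # protein | tRNA | rRNA | tmRNA | ORF
    exons: list[Interval]
    strand: int  # +1 or -1
    copy_index: int = 1
    intron_sites: list[IntronSite] = field(default_factory=list)

    @property
    def genomic_start(self) -> int:
        return min(e[0] for e in self.exons)

    @property
    def genomic_end(self) -> int:
        return max(e[1] for e in self.exons)

    @property
    def coding_length(self) -> int:
        return sum(e[1] - e[0] for e in self.exons)

    def key(self) -> tuple[str, int]:
        return (self.name, self.copy_index)

    def extract(self, sequence: str) -> str:
        """Spliced sequence of the gene in transcription direction."""
        length = len(sequence)
        doubled = sequence + sequence
        parts = []
        for start, end in self.exons:
            span = end - start
            start %= length
            chunk = doubled[start:start + span]
            parts.append(chunk if self.strand > 0 else revcomp(chunk))
        return "".join(parts)


@dataclass
class AnnotatedGenome:
    """A chloroplast genome sequence plus its gene annotations."""

    taxon_id: str
    sequence: str
    topology: str = "circular"  # circular | linear
    features: list[GeneFeature] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def sorted_features(self) -> list[GeneFeature]:
        return sorted(self.features, key=lambda f: (f.genomic_start, f.name))

    def sort(self) -> None:
        self.features = self.sorted_features()

    def feature_map(self) -> dict[tuple[str, int], GeneFeature]:
        return {f.key(): f for f in self.features}

    def gene_names(self) -> set[str]:
        return {f.name for f in self.features}

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if self.length == 0:
            raise ValueError(f"{self.taxon_id}: empty sequence")
        for f in self.features:
            if f.strand not in (+1, -1):
                raise ValueError(f"{self.taxon_id}/{f.name}: bad strand {f.strand}")
            for start, end in f.exons:
                if not (0 <= start < self.length):
                    raise ValueError(
                        f"{self.taxon_id}/{f.name}: exon start {start} outside [0, {self.length})"
                    )
                if end <= start:
                    raise ValueError(f"{self.taxon_id}/{f.name}: empty exon {start}..{end}")
                if end > self.length and self.topology != "circular":
                    raise ValueError(
                        f"{self.taxon_id}/{f.name}: wrapping exon on linear genome"
                    )
        seen: set[tuple[str, int]] = set()
        for f in self.features:
            if f.key() in seen:
                raise ValueError(f"{self.taxon_id}: duplicate (name, copy_index) {f.key()}")
            seen.add(f.key())

    def assign_copy_indices(self) -> None:
        """Number duplicate gene copies 1, 2, ... in coordinate order."""
        counts: dict[str, int] = {}
        for f in self.sorted_features():
            counts[f.name] = counts.get(f.name, 0) + 1
            f.copy_index = counts[f.name]
        self.sort()

    def copy(self) -> "AnnotatedGenome":
        return AnnotatedGenome(
            taxon_id=self.taxon_id,
            sequence=self.sequence,
            topology=self.topology,
            features=[
                replace(
                    f,
                    exons=list(f.exons),
                    intron_sites=[replace(s) for s in f.intron_sites],
                )
                for f in self.features
            ],
            source=self.source,
        )

    def gene_sequence(self, name: str, copy_index: int = 1) -> str:
        feat = self.feature_map()[(name, copy_index)]
        return feat.extract(self.sequence)


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
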