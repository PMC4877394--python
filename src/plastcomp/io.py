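"""Reading and writing annotated genomes.

Supported formats: GenBank flat files and GFF3 + FASTA pairs, converted at
the boundary to the internal 0-based half-open coordinate convention
(GenBank and GFF3 are 1-based inclusive).  A simple two-column TSV maps
source gene spellings to canonical symbols.
"""

from __future__ import annotations

import logging
import urllib.parse
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from . import catalog
from .model import AnnotatedGenome, GeneFeature, IntronSite, warn

log = logging.getLogger(__name__)

_GB_TYPES = {"CDS": "protein", "tRNA": "tRNA", "rRNA": "rRNA", "tmRNA": "tmRNA"}


class ParseError(ValueError):
    pass


class ConfigError(ValueError):
    pass


def _feature_name(feat) -> str | None:
    for key in ("gene", "locus_tag", "product", "Name", "ID"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return None


def _merge_wrapped_parts(parts: list[tuple[int, int]], length: int,
                         circular: bool) -> list[tuple[int, int]]:
    """Join consecutive exon parts that continue across the origin."""
    if not circular or len(parts) < 2:
        return parts
    # a wrapping feature is encoded as (s..length) + (0..e): re-join it
    first, last = parts[0], parts[-1]
    if last[1] == length and first[0] == 0 and len(parts) >= 2:
        parts = parts[1:-1] + [(last[0], length + first[1])]
    return parts


def read_genbank(path: str | Path, intron_table: pd.DataFrame | None = None,
                 taxon_id: str | None = None) -> AnnotatedGenome:
    """Read an annotated genome from a GenBank flat file.

    Compound (join) locations become multi-exon genes; on circular records a
    feature spanning the origin is stored as a single wrapping exon.  If an
    intron-site table is supplied (columns: gene, ordinal, site_label,
    intron_class, cis_or_trans), intron sites are attached to multi-exon
    genes.
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: malformed GenBank record: {exc}") from exc
    topology = record.annotations.get("topology", "linear")
    length = len(record.seq)
    features: list[GeneFeature] = []
    typed_names: set[str] = set()
    for feat in record.features:
        if feat.type not in _GB_TYPES:
            continue
        name = _feature_name(feat)
        if name is None:
            continue
        features.append(_convert_location(feat, name, _GB_TYPES[feat.type],
                                          length, topology == "circular"))
        typed_names.add(name)
    # fall back to bare `gene` features only when no typed feature exists
    for feat in record.features:
        if feat.type != "gene":
            continue
        name = _feature_name(feat)
        if name is None or name in typed_names:
            continue
        cat = catalog.gene_category(catalog.canonical_name(name) or name)
        features.append(_convert_location(feat, name, cat, length,
                                          topology == "circular"))
        typed_names.add(name)
    if not features:
        warn(f"{path}: no gene features found")
    genome = AnnotatedGenome(
        taxon_id=taxon_id or record.id or path.stem,
        sequence=str(record.seq),
        topology=topology,
        features=features,
        source=f"genbank:{path.name}",
    )
    genome.assign_copy_indices()
    if intron_table is not None:
        attach_intron_sites(genome, intron_table)
    genome.validate()
    return genome


def _convert_location(feat, name: str, category: str, length: int,
                      circular: bool) -> GeneFeature:
    strand = 1 if (feat.location.strand or 1) >= 0 else -1
    parts = [(int(p.start), int(p.end)) for p in feat.location.parts]
    if strand < 0:
        # Biopython lists parts in genomic order; transcription order for a
        # minus-strand gene runs from the highest-coordinate part down.
        genomic = _merge_wrapped_parts(sorted(parts), length, circular)
        exons = list(reversed(genomic))
    else:
        exons = _merge_wrapped_parts(sorted(parts), length, circular)
    if category == "protein" and catalog.gene_category(name) == "ORF":
        category = "ORF"
    return GeneFeature(name=name, category=category, exons=exons, strand=strand)


def attach_intron_sites(genome: AnnotatedGenome, table: pd.DataFrame) -> None:
    """Attach intron-site records to multi-exon genes from a site table."""
    lookup: dict[tuple[str, int], dict] = {}
    for _, row in table.iterrows():
        lookup[(str(row["gene"]), int(row["ordinal"]))] = row.to_dict()
    for feat in genome.features:
        feat.intron_sites = []
        for ordinal in range(1, len(feat.exons)):
            row = lookup.get((feat.name, ordinal))
            if row is None:
                continue
            feat.intron_sites.append(IntronSite(
                host_gene=feat.name,
                site_label=str(row["site_label"]),
                intron_class=str(row.get("intron_class", "II")),
                cis_or_trans=str(row.get("cis_or_trans", "cis")),
                has_orf=bool(row.get("has_orf", False)),
            ))


_GFF_TYPES = {"gene", "exon"}


def read_gff_fasta(gff: str | Path, fasta: str | Path,
                   taxon_id: str | None = None) -> AnnotatedGenome:
    """Read an annotated genome from a GFF3 file plus a FASTA sequence.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Exon rows are grouped under their parent gene; gene rows may carry
    ``category``, ``copy_index``, ``circular`` and intron-site attributes.
    """
    gff, fasta = Path(gff), Path(fasta)
    rec = SeqIO.read(str(fasta), "fasta")
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    skipped = 0
    topology = "linear"
    seqids: set[str] = set()
    for lineno, line in enumerate(gff.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            if line.startswith("##sequence-region") and "circular" in line:
                topology = "circular"
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ParseError(f"{gff}:{lineno}: expected 9 columns")
        seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
        seqids.add(seqid)
        if ftype not in _GFF_TYPES:
            skipped += 1
            continue
        attr = dict(
            (k, urllib.parse.unquote(v))
            for k, _, v in (a.partition("=") for a in attrs.split(";") if a)
        )
        iv = (int(start) - 1, int(end))
        if ftype == "gene":
            gid = attr.get("ID", attr.get("Name", f"gene{lineno}"))
            genes[gid] = {
                "name": attr.get("Name", gid),
                "category": attr.get("category", "protein"),
                "strand": 1 if strand != "-" else -1,
                "copy_index": int(attr.get("copy_index", 1)),
                "introns": attr.get("intron_sites", ""),
                "circular": attr.get("circular", "") == "true",
                "iv": iv,
            }
        else:
            parent = attr.get("Parent")
            if parent is None:
                raise ParseError(f"{gff}:{lineno}: exon without Parent")
            exons.setdefault(parent, []).append(iv)
    if skipped:
        log.info("%s: skipped %d rows of unhandled feature types", gff, skipped)
    if seqids and rec.id not in seqids:
        raise ParseError(
            f"sequence ID mismatch: FASTA has {rec.id!r}, GFF has {sorted(seqids)}"
        )
    length = len(rec.seq)
    features = []
    for gid, info in genes.items():
        parts = sorted(exons.get(gid, [info["iv"]]))
        if info["circular"] and len(parts) > 1 and parts[-1][1] == length and parts[0][0] == 0:
            # wrap-around exon split at the origin by the GFF writer
            first = parts.pop(0)
            parts[-1] = (parts[-1][0], length + first[1])
        ordered = parts if info["strand"] > 0 else list(reversed(parts))
        sites = []
        if info["introns"]:
            for token in info["introns"].split(","):
                label, _, meta = token.partition("|")
                cls, _, cistrans = meta.partition("|")
                sites.append(IntronSite(
                    host_gene=info["name"], site_label=label,
                    intron_class=cls or "II",
                    cis_or_trans=cistrans or "cis",
                ))
        features.append(GeneFeature(
            name=info["name"], category=info["category"], exons=ordered,
            strand=info["strand"], copy_index=info["copy_index"],
            intron_sites=sites,
        ))
    genome = AnnotatedGenome(
        taxon_id=taxon_id or rec.id,
        sequence=str(rec.seq),
        topology="circular" if topology == "circular" else "linear",
        features=features,
        source=f"gff:{gff.name}",
    )
    genome.sort()
    genome.validate()
    return genome


def write_gff_fasta(genome: AnnotatedGenome, gff: str | Path,
                    fasta: str | Path) -> None:
    """Write a genome as GFF3 + FASTA (lossless round trip with read_gff_fasta)."""
    gff, fasta = Path(gff), Path(fasta)
    length = genome.length
    lines = ["##gff-version 3"]
    region = f"##sequence-region {genome.taxon_id} 1 {length}"
    if genome.topology == "circular":
        region += " circular"
    lines.append(region)
    for feat in genome.sorted_features():
        gid = f"{feat.name}.{feat.copy_index}"
        strand = "+" if feat.strand > 0 else "-"
        span = (feat.genomic_start,
                max(e[1] for e in feat.exons))
        intron_attr = ",".join(
            f"{s.site_label}|{s.intron_class}|{s.cis_or_trans}"
            for s in feat.intron_sites
        )
        wraps = any(e[1] > length for e in feat.exons)
        attrs = [f"ID={urllib.parse.quote(gid)}",
                 f"Name={urllib.parse.quote(feat.name)}",
                 f"category={feat.category}",
                 f"copy_index={feat.copy_index}"]
        if intron_attr:
            attrs.append(f"intron_sites={intron_attr}")
        if wraps:
            attrs.append("circular=true")
        gene_end = min(span[1], length) if wraps else span[1]
        lines.append("\t".join([
            genome.taxon_id, "plastcomp", "gene",
            str(span[0] + 1), str(gene_end), ".", strand, ".",
            ";".join(attrs),
        ]))
        for start, end in sorted((e[0] % length, e[1]) for e in feat.exons):
            pieces = [(start, min(end, length))]
            if end > length:
                pieces.append((0, end - length))
            for ps, pe in pieces:
                lines.append("\t".join([
                    genome.taxon_id, "plastcomp", "exon",
                    str(ps + 1), str(pe), ".", strand, ".",
                    f"Parent={urllib.parse.quote(gid)}",
                ]))
    gff.write_text("\n".join(lines) + "\n")
    SeqIO.write(
        SeqRecord(Seq(genome.sequence), id=genome.taxon_id, description=""),
        str(fasta), "fasta",
    )


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write a genome as a GenBank flat file."""
    record = SeqRecord(Seq(genome.sequence), id=genome.taxon_id[:16],
                       name=genome.taxon_id[:16],
                       description=genome.source or genome.taxon_id)
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = genome.topology
    length = genome.length
    gb_type = {"protein": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
               "tmRNA": "tmRNA", "ORF": "CDS"}
    for feat in genome.sorted_features():
        locs = []
        for start, end in sorted((e[0] % length, e[1]) for e in feat.exons):
            if end > length:
                locs.append(SimpleLocation(start, length, strand=feat.strand))
                locs.append(SimpleLocation(0, end - length, strand=feat.strand))
            else:
                locs.append(SimpleLocation(start, end, strand=feat.strand))
        if feat.strand < 0:
            locs = list(reversed(locs))
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        record.features.append(SeqFeature(
            location=location, type=gb_type[feat.category],
            qualifiers={"gene": [feat.name]},
        ))
    SeqIO.write(record, str(path), "genbank")


def read_synonyms(path: str | Path) -> dict[str, str]:
    """Load a two-column (source_name, canonical_name) TSV synonym table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["source", "canonical"], dtype=str)
    table: dict[str, str] = {}
    for _, row in df.iterrows():
        src, dst = row["source"].strip(), row["canonical"].strip()
        if src in table and table[src] != dst:
            raise ConfigError(
                f"synonym table maps {src!r} to both {table[src]!r} and {dst!r}"
            )
        table[src] = dst
    return table


def normalize_gene_names(genome: AnnotatedGenome,
                         synonyms: dict[str, str] | None = None) -> AnnotatedGenome:
    """Return a copy of the genome with gene names drawn from the catalog.

    Unmapped names are preserved and logged; duplicate copies are renumbered
    in coordinate order after renaming.
    """
    out = genome.copy()
    unmapped = []
    for feat in out.features:
        canon = catalog.canonical_name(feat.name, synonyms)
        if canon is None:
            unmapped.append(feat.name)
        else:
            feat.name = canon
            for site in feat.intron_sites:
                site.host_gene = canon
    if unmapped:
        log.info("%s: %d gene names left unmapped: %s", genome.taxon_id,
                 len(unmapped), sorted(set(unmapped))[:10])
    out.assign_copy_indices()
    return out


def gene_table(genome: AnnotatedGenome) -> pd.DataFrame:
    """Flat per-gene table (taxon, gene, copy, start, end, strand, category)."""
    rows = [
        {
            "taxon": genome.taxon_id, "gene": f.name, "copy": f.copy_index,
            "start": f.genomic_start, "end": max(e[1] for e in f.exons),
            "strand": f.strand, "category": f.category,
        }
        for f in genome.sorted_features()
    ]
    return pd.DataFrame(rows, columns=["taxon", "gene", "copy", "start",
                                       "end", "strand", "category"])
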