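"""Canonical gene nomenclature for streptophyte chloroplast genomes.

The catalog distinguishes the set of genes inferred to have been present in
the chloroplast of the common ancestor of streptophytes (144 standard genes)
from the subset universally retained across the compared streptophyte algae
and land plants (90 genes).  tRNA genes use the anticodon-in-parentheses
convention, e.g. ``trnK(uuu)``.
"""

from __future__ import annotations

import re

# Genes retained in every compared streptophyte chloroplast genome:
# 3 rRNAs, 24 tRNAs and 63 protein-coding genes.
RETAINED_GENES: tuple[str, ...] = (
    # ATP synthase
    "atpA", "atpB", "atpE", "atpF", "atpH", "atpI",
    # envelope / chlorophyll biosynthesis / protease
    "cemA", "chlB", "chlL", "chlN", "clpP", "ftsH",
    # NADH dehydrogenase
    "ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF", "ndhG", "ndhH",
    "ndhI", "ndhJ",
    # cytochrome b6/f
    "petA", "petB", "petD", "petG", "petL",
    # photosystem I
    "psaA", "psaB", "psaC", "psaI", "psaJ",
    # photosystem II
    "psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH", "psbI",
    "psbJ", "psbK", "psbL", "psbM", "psbN", "psbT", "psbZ",
    # Rubisco
    "rbcL",
    # ribosomal proteins (large subunit)
    "rpl2", "rpl20", "rpl33", "rpl36",
    # RNA polymerase
    "rpoB", "rpoC1", "rpoC2",
    # ribosomal proteins (small subunit)
    "rps2", "rps8", "rps11", "rps18", "rps19",
    # rRNAs
    "rrf", "rrl", "rrs",
    # conserved hypothetical chloroplast ORFs
    "ycf1", "ycf4", "ycf12",
    # tRNAs (24)
    "trnA(ugc)", "trnC(gca)", "trnD(guc)", "trnE(uuc)", "trnF(gaa)",
    "trnG(gcc)", "trnH(gug)", "trnI(cau)", "trnI(gau)", "trnK(uuu)",
    "trnL(uaa)", "trnL(uag)", "trnMe(cau)", "trnMf(cau)", "trnN(guu)",
    "trnP(ugg)", "trnQ(uug)", "trnR(acg)", "trnR(ucu)", "trnS(gcu)",
    "trnS(gga)", "trnS(uga)", "trnW(cca)", "trnY(gua)",
)

# Ancestral genes that experienced at least one loss among the compared
# streptophyte algae: 42 protein-coding genes, 11 tRNA genes and the ssrA
# tmRNA gene.
LOST_GENES: tuple[str, ...] = (
    # protein-coding (42)
    "accD", "ccsA", "ccs1", "chlI", "cysA", "cysT", "infA", "minD",
    "ndhK", "odpB", "petN", "psaM", "rpl12", "rpl14", "rpl16", "rpl19",
    "rpl21", "rpl22", "rpl23", "rpl32", "rpoA", "rps3", "rps4", "rps7",
    "rps9", "rps12", "rps14", "rps15", "rps16", "tilS", "tufA", "ycf3",
    "ycf20", "ycf26", "ycf35", "ycf37", "ycf39", "ycf47", "ycf53",
    "ycf62", "ycf65", "ycf66",
    # tRNAs (11)
    "trnG(ucc)", "trnL(caa)", "trnL(gag)", "trnP(ggg)", "trnR(ccg)",
    "trnR(ccu)", "trnS(cga)", "trnT(ggu)", "trnT(ugu)", "trnV(gac)",
    "trnV(uac)",
    # tmRNA
    "ssrA",
)

ANCESTRAL_GENES: tuple[str, ...] = tuple(sorted(RETAINED_GENES + LOST_GENES))

# The rRNA (rDNA) operon as transcribed: three rRNAs plus two tRNAs.
RDNA_OPERON: tuple[str, ...] = ("rrs", "trnI(gau)", "trnA(ugc)", "rrl", "rrf")


def shared_gene_set(exclude: tuple[str, ...] = ()) -> tuple[str, ...]:
    """Universally retained genes, optionally excluding some symbols.

    Rearrangement analyses restricted to genes shared by every genome may
    use either all 90 retained genes or an 89-gene subset; pass the symbol(s)
    to drop via ``exclude``.
    """
    return tuple(g for g in RETAINED_GENES if g not in exclude)


def gene_category(name: str) -> str:
    """Infer the feature category from a canonical gene symbol."""
    if name.startswith("trn"):
        return "tRNA"
    if name in ("rrs", "rrl", "rrf"):
        return "rRNA"
    if name == "ssrA":
        return "tmRNA"
    if re.match(r"^orf\d+", name, re.IGNORECASE):
        return "ORF"
    return "protein"


_TRN_RE = re.compile(
    r"^trn(?P<aa>[A-Za-z]{1,2})\s*[-_(]\s*(?P<ac>[ACGTUacgtu]{3})\)?$"
)
_RRNA_WORDS = {
    "16s": "rrs", "23s": "rrl", "5s": "rrf", "4.5s": "rrl",
}


def canonical_name(raw: str, synonyms: dict[str, str] | None = None) -> str | None:
    """Map a source gene spelling to the canonical symbol.

    Returns None when the name cannot be interpreted; callers should then
    keep the original spelling.  Explicit ``synonyms`` entries take priority
    over the built-in rules (tRNA anticodon notation, rRNA spellings).
    """
    name = raw.strip()
    if synonyms and name in synonyms:
        return synonyms[name]
    m = _TRN_RE.match(name)
    if m:
        aa = m.group("aa")
        aa = aa[0].upper() + aa[1:].lower()
        ac = m.group("ac").lower().replace("t", "u")
        return f"trn{aa}({ac})"
    low = name.lower()
    for word, symbol in _RRNA_WORDS.items():
        if low.startswith(word) and ("rrna" in low or "ribosomal" in low):
            return symbol
    if name in ANCESTRAL_GENES:
        return name
    return None


# --- tRNA decoding -----------------------------------------------------------

#: codon third-position bases read by each anticodon wobble (34) base under
#: standard organellar decoding rules.  A34 is treated as inosine.
WOBBLE_READS: dict[str, str] = {
    "G": "CT",
    "C": "G",
    "U": "AG",
    "T": "AG",
    "A": "TCA",
}

#: gene-specific overrides: tRNAs whose modified anticodon restricts or
#: redirects decoding regardless of the generic wobble rules.
DECODING_OVERRIDES: dict[str, tuple[str, ...]] = {
    "trnI(cau)": ("ATA",),            # lysidine-modified C34 reads AUA as Ile
    "trnMe(cau)": ("ATG",),
    "trnMf(cau)": ("ATG",),
}


def anticodon_of(trn_name: str) -> str | None:
    m = re.match(r"^trn[A-Za-z]{1,2}\((?P<ac>[acgu]{3})\)$", trn_name)
    if not m:
        return None
    return m.group("ac").upper().replace("U", "T")


FOURFOLD_BOX_PREFIXES: tuple[str, ...] = (
    "CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG",
)


def codons_read(trn_name: str, superwobble: bool = False) -> set[str]:
    """Sense codons (DNA alphabet) decodable by one tRNA gene.

    With ``superwobble`` enabled, an unmodified U at anticodon position 34
    reads all four codons of an unsplit family box, the mechanism plastids
    use to cover four-codon boxes with a single tRNA species.
    """
    if trn_name in DECODING_OVERRIDES:
        return set(DECODING_OVERRIDES[trn_name])
    ac = anticodon_of(trn_name)
    if ac is None:
        return set()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    codon_12 = comp[ac[2]] + comp[ac[1]]
    wobble = ac[0]
    thirds = WOBBLE_READS.get(wobble, "")
    if superwobble and wobble in ("U", "T") and codon_12 in FOURFOLD_BOX_PREFIXES:
        thirds = "ACGT"
    return {codon_12 + t for t in thirds}
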