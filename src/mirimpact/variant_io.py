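"""Variant reading/normalisation and strand-aware transcript contexts.

Variants are normalised to zero-based half-open genomic coordinates with
genome-strand alleles. A transcript context is the hairpin plus chosen
flanks, extracted in gene orientation as RNA; for minus-strand genes the
sequence is the reverse complement and input alleles are complemented
internally when the variant is introduced.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

from . import seqtools
from .mirna_db import MiRNAGene

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicVariant",
    "TranscriptContext",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_vcf",
    "extract_context",
    "apply_variant",
]

VARIANT_COLUMNS = ["chromosome", "begin", "end", "type", "ref", "alt"]


@dataclass(frozen=True)
class GenomicVariant:
    """A normalised sequence change: snp, ins or del.

    Alleles are genome-strand. Insertions have ``begin == end`` and an
    empty ref; deletions an empty alt. The ref allele is verified
    against the genome at analysis time, not on construction.
    """

    chrom: str
    begin: int
    end: int
    type: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.begin < 0 or self.end < self.begin:
            raise ValueError(f"invalid interval [{self.begin},{self.end})")
        t = self.type
        if t == "snp":
            if not (self.end - self.begin == len(self.ref) == len(self.alt) == 1):
                raise ValueError(f"snp must be a 1-base substitution: {self}")
        elif t == "ins":
            if self.end != self.begin or self.ref != "" or not self.alt:
                raise ValueError(f"ins must have begin==end, empty ref: {self}")
        elif t == "del":
            if len(self.ref) != self.end - self.begin or self.alt != "" or self.end == self.begin:
                raise ValueError(f"del must delete [begin,end) with empty alt: {self}")
        else:
            raise ValueError(f"unknown variant type {t!r}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.begin, self.end, self.type, self.ref, self.alt)


def read_variants_tsv(path) -> list[GenomicVariant]:
    """Read the tab-delimited variant format (header + 6 columns)."""
    variants = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:6]] != VARIANT_COLUMNS:
            raise ValueError(f"{path}: expected header {VARIANT_COLUMNS}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0]):
                continue
            if len(row) < 4:
                raise ValueError(f"{path}:{lineno}: too few fields")
            row = row + [""] * (6 - len(row))  # allow trailing empty allele cells
            try:
                variants.append(GenomicVariant(
                    row[0], int(row[1]), int(row[2]), row[3],
                    row[4].upper(), row[5].upper(),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return variants


def write_variants_tsv(variants, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(VARIANT_COLUMNS)
        for v in variants:
            w.writerow([v.chrom, v.begin, v.end, v.type, v.ref, v.alt])


def _normalize_alleles(pos0: int, ref: str, alt: str) -> tuple[str, str, int]:
    """Trim shared trailing then leading bases of a VCF allele pair."""
    ref, alt = ref.upper(), alt.upper()
    # trim shared trailing, then shared leading bases
    while ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    return ref, alt, pos0


def read_vcf(path, chrom=None) -> list[GenomicVariant]:
    """Read VCF 4.x; multi-allelic records are split per ALT.

    Symbolic ALTs (<DEL>, breakends) and complex substitutions that do
    not reduce to snp/ins/del by trimming are skipped with a warning.
    """
    from cyvcf2 import VCF

    variants = []
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            if not alt or alt[0] in "<[]." or "[" in alt or "]" in alt:
                logger.warning("%s:%s symbolic ALT %r skipped", rec.CHROM, rec.POS, alt)
                continue
            ref, a, pos0 = _normalize_alleles(rec.POS - 1, rec.REF, alt)
            if len(ref) == 1 and len(a) == 1:
                v = GenomicVariant(rec.CHROM, pos0, pos0 + 1, "snp", ref, a)
            elif not ref and a:
                v = GenomicVariant(rec.CHROM, pos0, pos0, "ins", "", a)
            elif ref and not a:
                v = GenomicVariant(rec.CHROM, pos0, pos0 + len(ref), "del", ref, "")
            else:
                logger.warning("%s:%s complex allele %s>%s skipped",
                               rec.CHROM, rec.POS, rec.REF, alt)
                continue
            variants.append(v)
    return variants


@dataclass(frozen=True)
class TranscriptContext:
    """Hairpin +/- flanks in gene orientation, as RNA.

    ``start``/``stop`` are the genomic bounds of the extracted window;
    flank5p applies to the gene's 5' side, i.e. the genomic right for
    minus-strand genes. Clipping at chromosome ends shrinks the
    effective flanks (with a warning at extraction time).
    """

    gene: MiRNAGene
    flank5p: int
    flank3p: int
    start: int   # genomic begin of the window
    stop: int    # genomic end of the window
    sequence: str

    @property
    def length(self) -> int:
        return self.stop - self.start

    def genomic_to_transcript(self, begin: int, end: int) -> tuple[int, int]:
        """Genomic [begin, end) -> transcript [begin, end), clipped."""
        if self.gene.strand == "+":
            tb, te = begin - self.start, end - self.start
        else:
            tb, te = self.stop - end, self.stop - begin
        return max(tb, 0), min(te, self.length)

    def genomic_point_to_transcript(self, pos: int) -> int:
        if self.gene.strand == "+":
            t = pos - self.start
        else:
            t = self.stop - pos
        return min(max(t, 0), self.length)

    def transcript_to_gene_relative(self, pos: int) -> int:
        return pos - self.flank5p


def extract_context(genome, gene: MiRNAGene, flank5p: int, flank3p: int) -> TranscriptContext:
    """Extract the hairpin plus flanks from the genome, gene-oriented."""
    if flank5p < 0 or flank3p < 0:
        raise ValueError("flanks must be >= 0")
    if gene.strand == "+":
        start, stop = gene.begin - flank5p, gene.end + flank3p
    else:
        start, stop = gene.begin - flank3p, gene.end + flank5p
    clen = seqtools.chrom_length(genome, gene.chrom)
    cstart, cstop = max(start, 0), min(stop, clen)
    if (cstart, cstop) != (start, stop):
        logger.warning("%s: flanks clipped to chromosome bounds [%d,%d)",
                       gene.name, cstart, cstop)
    dna = seqtools.fetch(genome, gene.chrom, cstart, cstop)
    if gene.strand == "-":
        dna = seqtools.revcomp(dna)
    eff5 = (gene.begin - cstart) if gene.strand == "+" else (cstop - gene.end)
    eff3 = (cstop - gene.end) if gene.strand == "+" else (gene.begin - cstart)
    return TranscriptContext(gene, eff5, eff3, cstart, cstop, seqtools.dna_to_rna(dna))


def apply_variant(context: TranscriptContext, variant: GenomicVariant):
    """Introduce a variant into the transcript sequence.

    Returns ``(variant_sequence, position_map)`` where position_map[i]
    is the variant-sequence index of reference transcript position i, or
    None for deleted bases. Alleles are complemented to the gene strand
    internally. The ref allele is verified against the context sequence;
    a mismatch signals a stale genome or wrong build. Deletions
    overlapping the context boundary are clipped with a warning.
    """
    seq = context.sequence
    n = context.length
    strand = context.gene.strand

    if variant.type == "ins":
        p = context.genomic_point_to_transcript(variant.begin)
        alt = seqtools.dna_to_rna(variant.alt if strand == "+" else seqtools.revcomp(variant.alt))
        var_seq = seq[:p] + alt + seq[p:]
        k = len(alt)
        position_map = tuple(i if i < p else i + k for i in range(n))
        return var_seq, position_map

    gb, ge = max(variant.begin, context.start), min(variant.end, context.stop)
    if (gb, ge) != (variant.begin, variant.end):
        logger.warning("variant %s clipped to context", variant.key)
    tb, te = context.genomic_to_transcript(gb, ge)
    if te <= tb:
        raise ValueError("variant does not overlap the transcript context")

    ref_dna = variant.ref[gb - variant.begin : ge - variant.begin]
    expect = seqtools.dna_to_rna(ref_dna if strand == "+" else seqtools.revcomp(ref_dna))
    observed = seq[tb:te]
    if variant.ref and observed != expect:
        raise ValueError(
            f"reference allele mismatch at {variant.chrom}:[{gb},{ge}): "
            f"observed {observed!r}, expected {expect!r} "
            "(signals stale genome or wrong build)"
        )

    if variant.type == "snp":
        alt = seqtools.dna_to_rna(variant.alt if strand == "+" else seqtools.complement(variant.alt))
        var_seq = seq[:tb] + alt + seq[te:]
        return var_seq, tuple(range(n))
    if variant.type == "del":
        var_seq = seq[:tb] + seq[te:]
        d = te - tb
        position_map = tuple(
            i if i < tb else (None if i < te else i - d) for i in range(n)
        )
        return var_seq, position_map
    raise ValueError(f"unsupported variant type {variant.type!r}")  # pragma: no cover
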