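"""Self-contained synthetic fixtures: designed hairpins with known truth.

Designed hairpins have GC-rich perfectly complementary stems and a
low-structure loop, so any sane thermodynamic model recovers the
designed stem; flanks are drawn from an A/C-biased alphabet chosen to
avoid complementarity with the stems, keeping the designed fold stable.
Fixtures embed hairpins on both strands in artificial chromosomes and
emit variants at every functional region class together with
by-construction expected location annotations, computed here by plain
offset arithmetic, independently of the annotation module.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import seqtools
from .mirna_db import Mature, MiRNADatabase, MiRNAGene, write_db_tsv
from .variant_io import GenomicVariant, write_variants_tsv

__all__ = ["HairpinDesign", "make_hairpin", "make_fixture", "FixturePaths"]

#: Region classes cycled through when placing variants, with the
#: gene-relative anchor used (offsets are relative to designed regions).
VARIANT_CLASSES = (
    "flank5p", "arm5p", "mature5p_seed", "loop", "mature3p",
    "upstream", "arm3p", "flank3p", "mature5p", "downstream", "faraway",
)

PAD = 2500  # chromosome padding on each side of the hairpin


@dataclass(frozen=True)
class HairpinDesign:
    """Parameters of a designed perfect hairpin."""

    stem_length: int = 30
    loop_length: int = 8
    mature5p: tuple[int, int] = (4, 26)   # gene-relative within the hairpin
    mature3p: tuple[int, int] = (42, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        hlen = 2 * self.stem_length + self.loop_length
        lb, le = self.stem_length, self.stem_length + self.loop_length
        for b, e in (self.mature5p, self.mature3p):
            if not (0 <= b < e <= hlen):
                raise ValueError("mature outside hairpin")
            if b < le and lb < e:
                raise ValueError("mature overlaps loop")
        if not self.mature5p[1] <= lb or not self.mature3p[0] >= le:
            raise ValueError("matures must flank the loop")

    @property
    def hairpin_length(self) -> int:
        return 2 * self.stem_length + self.loop_length

    @property
    def loop(self) -> tuple[int, int]:
        return self.stem_length, self.stem_length + self.loop_length


def make_hairpin(design: HairpinDesign) -> tuple[str, str]:
    """(RNA sequence, designed dot-bracket) of a perfect hairpin.

    sequence = arm + loop + revcomp(arm); reproducible from the seed.
    """
    rng = np.random.default_rng(design.seed)
    arm = "".join(rng.choice(["G", "C"], size=design.stem_length,
                             p=[0.6, 0.4]))
    loop = "".join(rng.choice(["A", "C"], size=design.loop_length,
                              p=[0.8, 0.2]))
    seq_dna = arm + loop + seqtools.revcomp(arm)
    structure = "(" * design.stem_length + "." * design.loop_length + \
                ")" * design.stem_length
    return seqtools.dna_to_rna(seq_dna), structure


def _flank_seq(rng, n: int) -> str:
    return "".join(rng.choice(["A", "C"], size=n, p=[0.7, 0.3]))


def _expected_for_class(cls: str, design: HairpinDesign) -> tuple[int, str]:
    """(gene-relative snp position, expected location annotation)."""
    hlen = design.hairpin_length
    m5b, m5e = design.mature5p
    m3b, m3e = design.mature3p
    lb, le = design.loop
    if cls == "flank5p":
        return -50, "flank5p(a-50)"
    if cls == "arm5p":  # lower 5p arm, counted upstream from the mature
        pos = m5b // 2
        return pos, f"arm5p(m-{m5b - pos})"
    if cls == "mature5p_seed":
        return m5b + 2, "mature5p(a+3)seed"
    if cls == "mature5p":
        pos = m5b + 9
        return pos, f"mature5p(a+{pos - m5b + 1})"
    if cls == "loop":
        pos = lb + design.loop_length // 2
        return pos, f"loop(a+{pos - lb + 1})"
    if cls == "mature3p":
        pos = m3b + 9
        return pos, f"mature3p(a+{pos - m3b + 1})"
    if cls == "arm3p":  # upper 3p arm, second base after the loop
        pos = le + 1
        if pos - le <= m3b - (pos + 1):  # nearest boundary is the loop
            return pos, f"arm3p(l+{pos - le + 1})"
        return pos, f"arm3p(m-{m3b - pos})"
    if cls == "flank3p":
        pos = hlen + 49
        return pos, f"flank3p(a+{pos - hlen + 1})"
    if cls == "upstream":
        return -150, "upstream(a-150)"
    if cls == "downstream":
        return hlen + 149, f"downstream(a+{hlen + 149 - hlen + 1})"
    if cls == "faraway":
        return -2100, ""  # outside the 2000 nt window: expected absence
    raise ValueError(cls)


@dataclass(frozen=True)
class FixturePaths:
    fasta: Path
    db_tsv: Path
    variants_tsv: Path
    expected_tsv: Path


def make_fixture(out_dir, n_genes: int = 2, variants_per_gene: int = len(VARIANT_CLASSES),
                 seed: int = 0, design: HairpinDesign | None = None):
    """Write genome FASTA, db TSV, variant TSV and expected annotations.

    Genes alternate strands (+, -, +, ...), one artificial chromosome
    per gene. Variants are snps placed per region class; expected
    location annotations are derived from the design arithmetic. Returns
    (FixturePaths, genome dict, MiRNADatabase, variants, expected) where
    expected is a list of (variant, gene name, annotation-or-"").
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    design = design or HairpinDesign(seed=seed)
    hlen = design.hairpin_length
    classes = [VARIANT_CLASSES[i % len(VARIANT_CLASSES)]
               for i in range(variants_per_gene)]

    genome: dict[str, str] = {}
    genes: list[MiRNAGene] = []
    variants: list[GenomicVariant] = []
    expected: list[tuple[GenomicVariant, str, str]] = []

    for g in range(n_genes):
        strand = "+" if g % 2 == 0 else "-"
        chrom = f"chr_syn{g + 1}"
        hp_rna, _ = make_hairpin(design)
        hp_dna = seqtools.rna_to_dna(hp_rna)
        insert = hp_dna if strand == "+" else seqtools.revcomp(hp_dna)
        chrom_seq = _flank_seq(rng, PAD) + insert + _flank_seq(rng, PAD)
        genome[chrom] = chrom_seq
        begin, end = PAD, PAD + hlen

        def genomic(rel_b: int, rel_e: int) -> tuple[int, int]:
            if strand == "+":
                return begin + rel_b, begin + rel_e
            return end - rel_e, end - rel_b

        m5 = Mature(f"syn-mir-{g + 1}-5p", *genomic(*design.mature5p))
        m3 = Mature(f"syn-mir-{g + 1}-3p", *genomic(*design.mature3p))
        loop_b, loop_e = genomic(*design.loop)
        gene = MiRNAGene(f"syn-mir-{g + 1}", chrom, strand, begin, end,
                         m5, m3, loop_b, loop_e)
        genes.append(gene)

        for cls in classes:
            rel_pos, annotation = _expected_for_class(cls, design)
            gpos = genomic(rel_pos, rel_pos + 1)[0]
            ref = chrom_seq[gpos]
            # pair-breaking substitutions (G<->C, A<->C swaps) on the genome strand
            alt = {"A": "C", "C": "A", "G": "C", "T": "A"}[ref]
            variant = GenomicVariant(chrom, gpos, gpos + 1, "snp", ref, alt)
            variants.append(variant)
            expected.append((variant, gene.name, annotation))

    db = MiRNADatabase(genes)
    paths = FixturePaths(
        fasta=out / "genome.fa",
        db_tsv=out / "mirna_db.tsv",
        variants_tsv=out / "variants.tsv",
        expected_tsv=out / "expected_locations.tsv",
    )
    with open(paths.fasta, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    write_db_tsv(db, paths.db_tsv)
    write_variants_tsv(variants, paths.variants_tsv)
    with open(paths.expected_tsv, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chromosome", "begin", "end", "type", "ref", "alt",
                    "mir_name", "expected_location"])
        for v, name, ann in expected:
            w.writerow([v.chrom, v.begin, v.end, v.type, v.ref, v.alt, name, ann])
    return paths, genome, db, variants, expected
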