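"""miRNA gene database: functional-region models of hairpins.

A miRNA gene is a hairpin interval on a chromosome with up to two mature
miRNAs (one per arm), a terminal loop and, derived from those, a 5'->3'
segmentation into the functional regions used by the annotation grammar:
flank, arm (lower/upper), mature (with seed = mature nt 2-7), loop.

Databases are read either from miRBase-dialect GFF3 (which carries no
loop; the loop is then inferred from the MFE fold of the bare hairpin)
or from a TSV dialect that stores every region explicitly, so a curated
database can be supplied. All stored coordinates are genomic, zero-based
half-open; region models work in gene-relative coordinates (position 0 =
first hairpin base in gene orientation).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional

from intervaltree import IntervalTree

from . import seqtools

logger = logging.getLogger(__name__)

__all__ = [
    "Mature",
    "MiRNAGene",
    "MiRNADatabase",
    "RegionModel",
    "Segment",
    "RefBoundary",
    "infer_loop",
    "convert_gff3",
    "read_db_tsv",
    "write_db_tsv",
    "find_nearby_genes",
]

DEFAULT_WINDOW = 2000  # nt outside the hairpin still reported as upstream/downstream

_FAR = 10**12  # sentinel bound for the unbounded upstream/downstream segments


@dataclass(frozen=True)
class Mature:
    """One mature miRNA: genomic interval within its hairpin."""

    name: str
    begin: int
    end: int


@dataclass(frozen=True)
class MiRNAGene:
    """A miRNA hairpin with strand, matures, and terminal loop.

    ``loop_flagged`` marks loops that could not be inferred from a fold
    (no base pairs): the loop then spans the whole hairpin.
    """

    name: str
    chrom: str
    strand: str
    begin: int
    end: int
    mature5p: Optional[Mature] = None
    mature3p: Optional[Mature] = None
    loop_begin: int = 0
    loop_end: int = 0
    loop_flagged: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: strand must be + or -, got {self.strand!r}")
        if self.end <= self.begin:
            raise ValueError(f"{self.name}: empty hairpin interval")
        for m in (self.mature5p, self.mature3p):
            if m is not None and not (self.begin <= m.begin < m.end <= self.end):
                raise ValueError(f"{self.name}: mature {m.name} outside hairpin")
        if not (self.begin <= self.loop_begin <= self.loop_end <= self.end):
            raise ValueError(f"{self.name}: loop outside hairpin")
        for m in (self.mature5p, self.mature3p):
            if m is not None and m.begin < self.loop_end and self.loop_begin < m.end:
                raise ValueError(f"{self.name}: loop overlaps mature {m.name}")
        # 5p mature precedes the loop in gene orientation
        if self.mature5p is not None:
            b, _ = self.rel_interval(self.mature5p.begin, self.mature5p.end)
            lb, _ = self.rel_interval(self.loop_begin, self.loop_end)
            if b > lb:
                raise ValueError(f"{self.name}: 5p mature does not precede loop")
        if self.mature3p is not None:
            _, e = self.rel_interval(self.mature3p.begin, self.mature3p.end)
            _, le = self.rel_interval(self.loop_begin, self.loop_end)
            if e < le:
                raise ValueError(f"{self.name}: 3p mature does not follow loop")

    @property
    def hairpin_length(self) -> int:
        return self.end - self.begin

    def rel_interval(self, begin: int, end: int) -> tuple[int, int]:
        """Genomic [begin, end) -> gene-relative (hairpin-anchored)."""
        if self.strand == "+":
            return begin - self.begin, end - self.begin
        return self.end - end, self.end - begin

    def rel_point(self, pos: int) -> int:
        """Genomic insertion point -> gene-relative insertion point."""
        if self.strand == "+":
            return pos - self.begin
        return self.end - pos

    def genomic_interval(self, rel_begin: int, rel_end: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.begin + rel_begin, self.begin + rel_end
        return self.end - rel_end, self.end - rel_begin


class RefBoundary(NamedTuple):
    """A named region boundary offsets are counted from.

    ``letter`` is a (arm), m (mature) or l (loop); ``anchor`` the
    gene-relative boundary position; ``sign`` +1 when offsets count
    downstream of the anchor, -1 when they count upstream.
    """

    letter: str
    anchor: int
    sign: int


class Segment(NamedTuple):
    """One tile of the 5'->3' segmentation, gene-relative half-open."""

    key: str      # internal: distinguishes lower/upper arm halves
    region: str   # rendered region name of the annotation grammar
    begin: int
    end: int
    refs: tuple[RefBoundary, ...]


class RegionModel:
    """Gene-relative segmentation of a miRNA gene plus flanks.

    Segments tile [-flank5p, hairpin_length + flank3p) without gaps or
    overlaps; unbounded ``upstream``/``downstream`` pseudo-segments
    extend beyond the flanks for location-only annotation. Absent
    matures collapse their arm subdivision into a single arm segment.
    """

    def __init__(self, gene: MiRNAGene, flank5p: int, flank3p: int) -> None:
        if flank5p < 0 or flank3p < 0:
            raise ValueError("flanks must be >= 0")
        self.gene = gene
        self.flank5p = flank5p
        self.flank3p = flank3p
        hlen = gene.hairpin_length
        lb, le = gene.rel_interval(gene.loop_begin, gene.loop_end)
        m5 = gene.rel_interval(gene.mature5p.begin, gene.mature5p.end) if gene.mature5p else None
        m3 = gene.rel_interval(gene.mature3p.begin, gene.mature3p.end) if gene.mature3p else None

        segs: list[Segment] = [
            Segment("upstream", "upstream", -_FAR, -flank5p, (RefBoundary("a", 0, -1),)),
            Segment("flank5p", "flank5p", -flank5p, 0, (RefBoundary("a", 0, -1),)),
        ]
        if m5 is not None:
            segs += [
                Segment("arm5p_lower", "arm5p", 0, m5[0], (RefBoundary("m", m5[0], -1),)),
                Segment("mature5p", "mature5p", m5[0], m5[1], (RefBoundary("a", m5[0], +1),)),
                Segment("arm5p_upper", "arm5p", m5[1], lb,
                        (RefBoundary("m", m5[1], +1), RefBoundary("l", lb, -1))),
            ]
        else:
            segs.append(Segment("arm5p", "arm5p", 0, lb, (RefBoundary("l", lb, -1),)))
        segs.append(Segment("loop", "loop", lb, le, (RefBoundary("a", lb, +1),)))
        if m3 is not None:
            segs += [
                Segment("arm3p_upper", "arm3p", le, m3[0],
                        (RefBoundary("l", le, +1), RefBoundary("m", m3[0], -1))),
                Segment("mature3p", "mature3p", m3[0], m3[1], (RefBoundary("a", m3[0], +1),)),
                Segment("arm3p_lower", "arm3p", m3[1], hlen, (RefBoundary("m", m3[1], +1),)),
            ]
        else:
            segs.append(Segment("arm3p", "arm3p", le, hlen, (RefBoundary("l", le, +1),)))
        segs += [
            Segment("flank3p", "flank3p", hlen, hlen + flank3p, (RefBoundary("a", hlen, +1),)),
            Segment("downstream", "downstream", hlen + flank3p, _FAR, (RefBoundary("a", hlen, +1),)),
        ]
        self.segments: tuple[Segment, ...] = tuple(s for s in segs if s.end > s.begin)
        # seed = mature nt 2-7 in gene orientation, gene-relative half-open
        self.seed_intervals: tuple[tuple[int, int], ...] = tuple(
            (m[0] + 1, min(m[0] + 7, m[1])) for m in (m5, m3) if m is not None
        )
        self.hairpin_length = hlen
        self.context_begin = -flank5p
        self.context_end = hlen + flank3p

    def segment_at(self, pos: int) -> Segment:
        for seg in self.segments:
            if seg.begin <= pos < seg.end:
                return seg
        raise ValueError(f"position {pos} outside model")  # pragma: no cover

    def in_seed(self, begin: int, end: int) -> bool:
        return any(begin < se and sb < end for sb, se in self.seed_intervals)

    def validate_tiling(self) -> None:
        """Assert segments tile the modelled interval exactly."""
        prev = None
        for seg in self.segments:
            if prev is not None and seg.begin != prev:
                raise AssertionError(f"gap/overlap at {prev} vs {seg}")
            prev = seg.end


def _terminal_loops(structure: str) -> list[tuple[int, int]]:
    """All hairpin (terminal) loops of a dot-bracket structure.

    A terminal loop is the unpaired run enclosed by an innermost base
    pair: '(' at j, ')' at i with only dots in between.
    """
    loops = []
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            if i - j > 1 and all(ch == "." for ch in structure[j + 1 : i]):
                loops.append((j + 1, i))
    return loops


def infer_loop(
    hairpin_seq: str,
    mature_intervals: Iterable[tuple[int, int]],
    fold_backend,
) -> tuple[tuple[int, int], bool]:
    """Infer the terminal-loop interval of a bare hairpin sequence.

    The loop is the maximal unpaired run enclosed by the innermost base
    pair of the MFE fold of the hairpin alone. With several terminal
    loops, the one lying between the two matures is preferred (else the
    largest). A loop overlapping a mature is shifted outside it, so the
    loop never cuts into a mature. Returns ``((begin, end), flagged)``
    in gene-relative coordinates; a pair-free fold yields the whole
    hairpin, flagged.
    """
    if not hairpin_seq:
        raise ValueError("empty hairpin sequence")
    matures = sorted(mature_intervals)
    structure = fold_backend.fold(hairpin_seq).mfe_structure
    loops = _terminal_loops(structure)
    if not loops:
        return (0, len(hairpin_seq)), True
    chosen = None
    if len(matures) >= 2:
        lo, hi = matures[0][1], matures[-1][0]
        between = [lp for lp in loops if lp[0] >= lo and lp[1] <= hi]
        if between:
            chosen = max(between, key=lambda lp: lp[1] - lp[0])
    if chosen is None:
        chosen = max(loops, key=lambda lp: lp[1] - lp[0])
    lb, le = chosen
    for mb, me in matures:
        if mb < le and lb < me:  # overlap: shift the overlapping end outside
            if mb <= lb:
                lb = max(lb, me)
            else:
                le = min(le, mb)
    if lb > le:
        lb = le
    return (lb, le), False


@dataclass
class MiRNADatabase:
    """Container of miRNA genes with per-chromosome interval lookup."""

    genes: list[MiRNAGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.begin, g.end, g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, name: str) -> MiRNAGene:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def nearby(self, chrom: str, begin: int, end: int, window: int = DEFAULT_WINDOW):
        """Genes whose hairpin expanded by ``window`` intersects [begin, end)."""
        if window < 0:
            raise ValueError("window must be >= 0")
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        qb, qe = begin - window, end + window
        hits = tree.at(qb) if qb == qe else tree.overlap(qb, qe)
        return sorted((iv.data for iv in hits), key=lambda g: (g.begin, g.name))


def find_nearby_genes(db: MiRNADatabase, variant, window: int = DEFAULT_WINDOW):
    """All database genes within ``window`` nt of a variant (any overlap)."""
    return db.nearby(variant.chrom, variant.begin, variant.end, window)


# ---------------------------------------------------------------------------
# GFF3 conversion (miRBase dialect)

def convert_gff3(gff3_path, genome, fold_backend) -> MiRNADatabase:
    """Build a database from a miRBase-dialect GFF3 and a genome.

    One gene per ``miRNA_primary_transcript``; ``miRNA`` features are
    attached via their Derives_from attribute (falling back to
    coordinate containment) and assigned to arms by their position
    relative to the inferred loop. GFF3 coordinates (1-based inclusive)
    are converted to zero-based half-open.
    """
    import gffutils

    gdb = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )

    def attr(feat, key):
        vals = feat.attributes.get(key)
        return vals[0] if vals else feat.id

    hairpins = list(gdb.features_of_type("miRNA_primary_transcript"))
    by_id = {h.id: h for h in hairpins}
    children: dict[str, list] = {h.id: [] for h in hairpins}
    for m in gdb.features_of_type("miRNA"):
        parent = None
        derives = m.attributes.get("Derives_from")
        if derives and derives[0] in by_id:
            parent = derives[0]
        else:
            for h in hairpins:
                if h.seqid == m.seqid and h.start <= m.start and m.end <= h.end:
                    parent = h.id
                    break
        if parent is None:
            logger.warning("mature %s not contained in any hairpin; skipped", attr(m, "Name"))
            continue
        h = by_id[parent]
        if not (h.seqid == m.seqid and h.start <= m.start and m.end <= h.end):
            logger.warning("mature %s not contained in hairpin %s; skipped",
                           attr(m, "Name"), attr(h, "Name"))
            continue
        children[parent].append(m)

    genes: list[MiRNAGene] = []
    for h in hairpins:
        begin, end = h.start - 1, h.end
        strand = h.strand if h.strand in "+-" else "+"
        if not seqtools.has_chrom(genome, h.seqid):
            raise ValueError(f"genome lacks chromosome {h.seqid}")
        gene = MiRNAGene(attr(h, "Name"), h.seqid, strand, begin, end,
                         loop_begin=begin, loop_end=begin)
        seq = seqtools.fetch(genome, h.seqid, begin, end)
        if strand == "-":
            seq = seqtools.revcomp(seq)
        hairpin_rna = seqtools.dna_to_rna(seq)
        mats = []
        for m in children[h.id]:
            mb, me = gene.rel_interval(m.start - 1, m.end)
            mats.append((mb, me, attr(m, "Name"), m.start - 1, m.end))
        mats.sort()
        (lb, le), flagged = infer_loop(hairpin_rna, [(mb, me) for mb, me, *_ in mats],
                                       fold_backend)
        loop_b, loop_e = gene.genomic_interval(lb, le)
        mature5p = mature3p = None
        for mb, me, name, gb, ge in mats:
            if (mb + me) / 2 <= (lb + le) / 2:
                if mature5p is not None:
                    logger.warning("%s: second 5p mature %s ignored", gene.name, name)
                    continue
                mature5p = Mature(name, gb, ge)
            else:
                if mature3p is not None:
                    logger.warning("%s: second 3p mature %s ignored", gene.name, name)
                    continue
                mature3p = Mature(name, gb, ge)
        genes.append(replace(gene, mature5p=mature5p, mature3p=mature3p,
                             loop_begin=loop_b, loop_end=loop_e, loop_flagged=flagged))
    return MiRNADatabase(genes)


# ---------------------------------------------------------------------------
# TSV dialect

DB_COLUMNS = [
    "name", "chrom", "strand", "hairpin_begin", "hairpin_end",
    "mature5p_begin", "mature5p_end", "mature3p_begin", "mature3p_end",
    "loop_begin", "loop_end",
]


def write_db_tsv(db: MiRNADatabase, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(DB_COLUMNS)
        for g in db:
            m5, m3 = g.mature5p, g.mature3p
            w.writerow([
                g.name, g.chrom, g.strand, g.begin, g.end,
                m5.begin if m5 else "", m5.end if m5 else "",
                m3.begin if m3 else "", m3.end if m3 else "",
                g.loop_begin, g.loop_end,
            ])


def read_db_tsv(path) -> MiRNADatabase:
    genes = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != DB_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0]):
                continue
            if len(row) != len(DB_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(DB_COLUMNS)} fields")
            try:
                name, chrom, strand = row[0], row[1], row[2]
                begin, end = int(row[3]), int(row[4])
                if end <= begin:
                    raise ValueError("hairpin end <= begin")
                m5 = Mature(f"{name}-5p", int(row[5]), int(row[6])) if row[5] else None
                m3 = Mature(f"{name}-3p", int(row[7]), int(row[8])) if row[7] else None
                genes.append(MiRNAGene(name, chrom, strand, begin, end, m5, m3,
                                       int(row[9]), int(row[10])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return MiRNADatabase(genes)
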