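"""Method core: locate variants, diff structures, render annotations.

The annotation grammar describes where a sequence change or a structural
change lies within a miRNA gene, in gene orientation::

    region(reference +|- offsets)[seed]

``region`` is one of upstream, flank5p, arm5p, mature5p, loop, mature3p,
arm3p, flank3p, downstream. ``reference`` names the boundary offsets are
counted from: a (hairpin arm junction), m (mature), l (loop); positive
offsets count downstream of the boundary, negative upstream, 1-based.
Offsets are singletons (``2``) or ranges (``8:9``), comma-separated;
``e`` marks an offset that reaches or crosses a region edge. Components
for different regions/references are joined with ``&``; a mature
component whose positions touch nt 2-7 of the mature carries the
``seed`` suffix.

Structural change is defined on paired-versus-unpaired status: a
position changed iff it is paired in one structure and unpaired in the
other, after realigning variant to reference coordinates for indels.
A '(' <-> ')' flip alone is not a change.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .fold import REPRESENTATIONS, FoldResult, pair_status
from .mirna_db import DEFAULT_WINDOW, MiRNAGene, RegionModel, Segment
from .variant_io import GenomicVariant, TranscriptContext, apply_variant, extract_context

__all__ = [
    "OffsetItem",
    "AnnotationComponent",
    "Annotation",
    "StructureDiff",
    "RepresentationResult",
    "ImpactRecord",
    "locate_variant",
    "choose_reference_boundary",
    "diff_structures",
    "annotate_changes",
    "highest_impact",
    "conservation",
    "analyze_variant",
]

IMPACT_ORDER = ("seed", "mature", "arm", "loop", "flank", "none")


# ---------------------------------------------------------------------------
# Grammar

@dataclass(frozen=True)
class OffsetItem:
    """One offset or offset range (1-based magnitudes, component sign)."""

    start: int
    stop: int
    start_e: bool = False
    stop_e: bool = False

    def __str__(self) -> str:
        if self.start == self.stop:
            return f"{self.start}{'e' if (self.start_e or self.stop_e) else ''}"
        return (f"{self.start}{'e' if self.start_e else ''}:"
                f"{self.stop}{'e' if self.stop_e else ''}")


@dataclass(frozen=True)
class AnnotationComponent:
    region: str
    ref: str          # a | m | l
    sign: int         # +1 downstream of boundary, -1 upstream
    items: tuple[OffsetItem, ...]
    seed: bool = False

    def __str__(self) -> str:
        offs = ",".join(str(i) for i in self.items)
        sign = "+" if self.sign > 0 else "-"
        return f"{self.region}({self.ref}{sign}{offs}){'seed' if self.seed else ''}"


_COMPONENT_RE = re.compile(
    r"^(?P<region>upstream|downstream|flank5p|flank3p|arm5p|arm3p|loop|"
    r"mature5p|mature3p)"
    r"\((?P<ref>[aml])(?P<sign>[+-])(?P<items>[0-9e:,]+)\)(?P<seed>seed)?$"
)


@dataclass(frozen=True)
class Annotation:
    """A parsed/parseable annotation string (possibly empty)."""

    components: tuple[AnnotationComponent, ...] = ()

    def __str__(self) -> str:
        return "&".join(str(c) for c in self.components)

    def __bool__(self) -> bool:
        return bool(self.components)

    @classmethod
    def parse(cls, text: str) -> "Annotation":
        if not text:
            return cls(())
        comps = []
        for part in text.split("&"):
            m = _COMPONENT_RE.match(part)
            if m is None:
                raise ValueError(f"unparseable annotation component {part!r}")
            items = []
            for item in m["items"].split(","):
                ends = item.split(":")
                if len(ends) > 2 or not ends[0]:
                    raise ValueError(f"bad offset item {item!r} in {part!r}")

                def _num(tok: str) -> tuple[int, bool]:
                    e = tok.endswith("e")
                    return int(tok[:-1] if e else tok), e

                start, start_e = _num(ends[0])
                if len(ends) == 2:
                    stop, stop_e = _num(ends[1])
                else:
                    stop, stop_e = start, start_e
                items.append(OffsetItem(start, stop, start_e, stop_e))
            comps.append(AnnotationComponent(
                m["region"], m["ref"], +1 if m["sign"] == "+" else -1,
                tuple(items), bool(m["seed"]),
            ))
        return cls(tuple(comps))


# ---------------------------------------------------------------------------
# Interval -> grammar

def choose_reference_boundary(segment: Segment, begin: int, end: int):
    """Pick the reference boundary for an interval within a segment.

    Arm segments between a mature and the loop carry two candidate
    boundaries; the nearer one wins, ties go to the upstream boundary.
    Regions whose flanking boundaries share a letter (mature, loop: both
    arm junctions) count from the upstream one, which is the single
    candidate stored on the segment.
    """
    refs = segment.refs
    if len(refs) == 1:
        return refs[0]
    d_up = begin - segment.begin
    d_down = segment.end - end
    return refs[0] if d_up <= d_down else refs[1]


def _interval_components(model: RegionModel, begin: int, end: int
                         ) -> list[AnnotationComponent]:
    """Split [begin, end) at region boundaries into grammar components.

    Each piece gets offsets from its chosen reference boundary; ``e``
    flags mark offsets where the interval reaches or crosses a region
    edge (on the entry side only when the interval starts there, on the
    exit side when it continues into the next region or ends on the
    region's last base).
    """
    if end <= begin:
        raise ValueError("empty interval")
    pieces = []
    for seg in model.segments:
        pb, pe = max(begin, seg.begin), min(end, seg.end)
        if pe > pb:
            pieces.append((seg, pb, pe))
    comps = []
    last = len(pieces) - 1
    for i, (seg, pb, pe) in enumerate(pieces):
        ref = choose_reference_boundary(seg, pb, pe)
        if ref.sign > 0:
            o_start, o_stop = pb - ref.anchor + 1, pe - ref.anchor
        else:
            o_start, o_stop = ref.anchor - pb, ref.anchor - pe + 1
        start_e = i == 0 and pb == seg.begin
        stop_e = i < last or pe == seg.end
        comps.append(AnnotationComponent(
            seg.region, ref.letter, ref.sign,
            (OffsetItem(o_start, o_stop, start_e, stop_e),),
            seed=seg.region.startswith("mature") and model.in_seed(pb, pe),
        ))
    return comps


def locate_variant(model: RegionModel, begin: int, end: int) -> Annotation:
    """Annotate a variant's gene-relative interval.

    Insertions (``begin == end``) are annotated at the base immediately
    3' of the insertion point in gene orientation.
    """
    if begin == end:
        begin, end = begin, begin + 1
    return Annotation(tuple(_interval_components(model, begin, end)))


def annotate_changes(model: RegionModel, runs: Sequence[tuple[int, int]]) -> Annotation:
    """Render changed-position runs (gene-relative, half-open) as a grammar string.

    Pieces falling in the same region with the same reference boundary
    are merged into one parenthesized offset list, ordered 5'->3';
    components are joined with ``&`` in 5'->3' order of first
    occurrence.
    """
    groups: dict[tuple[str, str, int], dict] = {}
    order: list[tuple[str, str, int]] = []
    for rb, re_ in sorted(runs):
        for comp in _interval_components(model, rb, re_):
            key = (comp.region, comp.ref, comp.sign)
            if key not in groups:
                groups[key] = {"items": [], "seed": False}
                order.append(key)
            groups[key]["items"].extend(comp.items)
            groups[key]["seed"] |= comp.seed
    comps = tuple(
        AnnotationComponent(region, ref, sign, tuple(groups[key]["items"]),
                            groups[key]["seed"])
        for key in order
        for region, ref, sign in [key]
    )
    return Annotation(comps)


def highest_impact(annotation: Annotation) -> str:
    """Most important region class present: seed > mature > arm > loop > flank."""
    best = "none"
    rank = {name: i for i, name in enumerate(IMPACT_ORDER)}
    for comp in annotation.components:
        if comp.seed:
            cls = "seed"
        elif comp.region.startswith("mature"):
            cls = "mature"
        elif comp.region.startswith("arm"):
            cls = "arm"
        elif comp.region == "loop":
            cls = "loop"
        else:
            cls = "flank"
        if rank[cls] < rank[best]:
            best = cls
    return best


# ---------------------------------------------------------------------------
# Structure comparison

@dataclass(frozen=True)
class StructureDiff:
    """Reference-transcript positions whose pairing status changed."""

    changed_positions: frozenset[int]
    runs: tuple[tuple[int, int], ...]  # maximal half-open runs


def diff_structures(ref_structure: str, var_structure: str,
                    position_map: Sequence[Optional[int]]) -> StructureDiff:
    """Compare pairing status per reference position after realignment.

    ``position_map[i]`` is the variant-structure index aligned to
    reference position i, or None for deleted bases (excluded from the
    comparison, like inserted bases, which have no reference image).
    """
    if len(position_map) != len(ref_structure):
        raise ValueError("position_map length does not match reference structure")
    ref_paired = pair_status(ref_structure)
    var_paired = pair_status(var_structure)
    changed = []
    for i, j in enumerate(position_map):
        if j is None:
            continue
        if j < 0 or j >= len(var_structure):
            raise ValueError(f"position_map[{i}]={j} outside variant structure")
        if ref_paired[i] != var_paired[j]:
            changed.append(i)
    runs = []
    for p in changed:
        if runs and p == runs[-1][1]:
            runs[-1][1] = p + 1
        else:
            runs.append([p, p + 1])
    return StructureDiff(frozenset(changed), tuple((a, b) for a, b in runs))


def conservation(flanked_structure: str, bare_structure: str, flank5p: int) -> str:
    """Compare the hairpin's pairing pattern with and without flanks.

    The hairpin-covering slice of the flanked structure is compared to
    the fold of the bare hairpin; identical pairing gives "conserved",
    otherwise "changed(N)" with N the number of differing hairpin bases.
    """
    n = len(bare_structure)
    window = flanked_structure[flank5p : flank5p + n]
    if len(window) != n:
        raise ValueError("flanked structure does not cover the hairpin")
    diffs = sum(
        1 for a, b in zip(pair_status(window), pair_status(bare_structure)) if a != b
    )
    return "conserved" if diffs == 0 else f"changed({diffs})"


# ---------------------------------------------------------------------------
# Per-variant orchestration

@dataclass(frozen=True)
class RepresentationResult:
    """Structural-impact fields for one representation (CEN/MEA/MFE)."""

    highest_impact: str
    impact: str
    conservation: str
    ref_deltaG: float
    var_deltaG: float


@dataclass
class ImpactRecord:
    """One output row per (variant, miRNA gene).

    ``by_representation`` is empty for variants beyond the chosen flanks
    (location annotation only, no structure prediction); ``detail``
    carries in-process rendering payload for the HTML report and is not
    serialized.
    """

    variant: GenomicVariant
    mir_name: str
    mir_location: str
    by_representation: dict[str, RepresentationResult] = field(default_factory=dict)
    ref_mfefreq: Optional[float] = None
    var_mfefreq: Optional[float] = None
    detail: Optional[dict] = None

    @property
    def has_structure(self) -> bool:
        return bool(self.by_representation)


def _variant_rel_interval(gene: MiRNAGene, variant: GenomicVariant) -> tuple[int, int]:
    if variant.type == "ins":
        p = gene.rel_point(variant.begin)
        return p, p
    return gene.rel_interval(variant.begin, variant.end)


def analyze_variant(
    variant: GenomicVariant,
    gene: MiRNAGene,
    genome,
    flank5p: int = 100,
    flank3p: int = 100,
    backend=None,
    window: int = DEFAULT_WINDOW,
    keep_detail: bool = False,
) -> Optional[ImpactRecord]:
    """Full impact analysis of one variant against one miRNA gene.

    Folds reference and variant transcripts (hairpin +/- flanks) and the
    bare hairpin (for conservation), then diffs and annotates per
    representation. Variants beyond the flanks but within ``window`` nt
    of the hairpin yield a location-only record; variants beyond the
    window yield None.
    """
    if backend is None:
        from .fold import ViennaRNAFold

        backend = ViennaRNAFold()

    rb, re_ = _variant_rel_interval(gene, variant)
    hlen = gene.hairpin_length
    if re_ < -window or rb > hlen + window:
        return None
    model = RegionModel(gene, flank5p, flank3p)
    location = locate_variant(model, rb, re_)

    if variant.type == "ins":
        inside = model.context_begin <= rb <= model.context_end
    else:
        inside = rb < model.context_end and re_ > model.context_begin
    if not inside:
        return ImpactRecord(variant, gene.name, str(location))

    context = extract_context(genome, gene, flank5p, flank3p)
    var_seq, position_map = apply_variant(context, variant)
    ref_fold = backend.fold(context.sequence)
    var_fold = backend.fold(var_seq)
    bare_fold = backend.fold(
        context.sequence[context.flank5p : context.flank5p + hlen]
    )

    by_rep: dict[str, RepresentationResult] = {}
    diffs: dict[str, StructureDiff] = {}
    for rep in REPRESENTATIONS:
        ref_s, var_s = ref_fold.structure(rep), var_fold.structure(rep)
        diff = diff_structures(ref_s, var_s, position_map)
        diffs[rep] = diff
        rel_runs = [
            (context.transcript_to_gene_relative(a), context.transcript_to_gene_relative(b))
            for a, b in diff.runs
        ]
        impact = annotate_changes(model, rel_runs)
        by_rep[rep] = RepresentationResult(
            highest_impact=highest_impact(impact),
            impact=str(impact),
            conservation=conservation(ref_s, bare_fold.structure(rep), context.flank5p),
            ref_deltaG=ref_fold.energy(rep),
            var_deltaG=var_fold.energy(rep),
        )

    detail = None
    if keep_detail:
        detail = {
            "context": context,
            "model": model,
            "ref_fold": ref_fold,
            "var_fold": var_fold,
            "position_map": position_map,
            "variant_transcript_interval": (rb + context.flank5p, re_ + context.flank5p),
            "diffs": diffs,
        }
    return ImpactRecord(
        variant, gene.name, str(location), by_rep,
        ref_mfefreq=ref_fold.mfe_frequency,
        var_mfefreq=var_fold.mfe_frequency,
        detail=detail,
    )
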