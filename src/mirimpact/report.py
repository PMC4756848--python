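"""Serialization of impact records: tabular output and HTML overview.

The tab-separated file has one row per (variant, miRNA gene); the
columns replicated per structure representation (highest impact, impact,
conservation, reference/variant free energy) appear for centroid (CEN),
MEA and MFE, plus the MFE-structure ensemble frequency once per allele.
Energies are rendered with one decimal (kcal/mol). Variants beyond the
flanks keep empty structure cells.

The HTML overview replaces 2-D structure drawings with annotated linear
dot-bracket renderings: per-base region colouring, the variant in red
(for indels the bases flanking the edit), changed bases highlighted.
"""

from __future__ import annotations

import html
import os
from dataclasses import dataclass, field

import pandas as pd

from .annotate import ImpactRecord, RepresentationResult
from .fold import REPRESENTATIONS
from .variant_io import GenomicVariant

__all__ = ["ReportConfig", "result_columns", "write_tsv", "read_tsv", "write_html"]

DEFAULT_COLORS = {
    "seed": "#ff8c00",      # orange
    "mature": "#ff00ff",    # magenta
    "loop": "#00008b",      # dark blue
    "hairpin": "#00bbbb",   # cyan (hairpin arms)
    "flank": "#888888",
    "variant": "#ff0000",   # red
    "changed": "#000000",   # black
}


@dataclass
class ReportConfig:
    outdir: str = "."
    tsv: bool = True
    html: bool = True
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))

    def __post_init__(self) -> None:
        missing = set(DEFAULT_COLORS) - set(self.colors)
        if missing:
            raise ValueError(f"color map lacks classes: {sorted(missing)}")


def result_columns() -> list[str]:
    cols = ["chromosome", "begin", "end", "type", "ref", "alt",
            "mir_location", "mir_name"]
    for rep in REPRESENTATIONS:
        cols += [f"{rep}_highest_impact", f"{rep}_impact", f"{rep}_conservation",
                 f"ref_{rep}_deltaG", f"var_{rep}_deltaG"]
    cols += ["ref_mfefreq", "var_mfefreq"]
    return cols


def _fmt_energy(x: float) -> str:
    return f"{x + 0.0:.1f}"  # +0.0 folds -0.0 into 0.0


def _fmt_freq(x: float) -> str:
    return f"{x:.6g}"


def record_to_row(record: ImpactRecord) -> dict[str, str]:
    v = record.variant
    row = {
        "chromosome": v.chrom, "begin": str(v.begin), "end": str(v.end),
        "type": v.type, "ref": v.ref, "alt": v.alt,
        "mir_location": record.mir_location, "mir_name": record.mir_name,
    }
    for rep in REPRESENTATIONS:
        r = record.by_representation.get(rep)
        row[f"{rep}_highest_impact"] = r.highest_impact if r else ""
        row[f"{rep}_impact"] = r.impact if r else ""
        row[f"{rep}_conservation"] = r.conservation if r else ""
        row[f"ref_{rep}_deltaG"] = _fmt_energy(r.ref_deltaG) if r else ""
        row[f"var_{rep}_deltaG"] = _fmt_energy(r.var_deltaG) if r else ""
    row["ref_mfefreq"] = _fmt_freq(record.ref_mfefreq) if record.ref_mfefreq is not None else ""
    row["var_mfefreq"] = _fmt_freq(record.var_mfefreq) if record.var_mfefreq is not None else ""
    return row


def write_tsv(records, path) -> None:
    cols = result_columns()
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            row = record_to_row(rec)
            fh.write("\t".join(row[c] for c in cols) + "\n")


def read_tsv(path) -> list[ImpactRecord]:
    """Read a results TSV back into ImpactRecords (modulo float rendering)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        variant = GenomicVariant(row["chromosome"], int(row["begin"]), int(row["end"]),
                                 row["type"], row["ref"], row["alt"])
        by_rep = {}
        if row["MFE_impact"] != "" or row["MFE_conservation"] != "":
            for rep in REPRESENTATIONS:
                by_rep[rep] = RepresentationResult(
                    highest_impact=row[f"{rep}_highest_impact"],
                    impact=row[f"{rep}_impact"],
                    conservation=row[f"{rep}_conservation"],
                    ref_deltaG=float(row[f"ref_{rep}_deltaG"]),
                    var_deltaG=float(row[f"var_{rep}_deltaG"]),
                )
        records.append(ImpactRecord(
            variant, row["mir_name"], row["mir_location"], by_rep,
            ref_mfefreq=float(row["ref_mfefreq"]) if row["ref_mfefreq"] else None,
            var_mfefreq=float(row["var_mfefreq"]) if row["var_mfefreq"] else None,
        ))
    return records


# ---------------------------------------------------------------------------
# HTML

def _region_class(model, pos: int) -> str:
    seg = model.segment_at(pos)
    if seg.region.startswith("mature"):
        return "seed" if model.in_seed(pos, pos + 1) else "mature"
    if seg.region == "loop":
        return "loop"
    if seg.region.startswith("arm"):
        return "hairpin"
    return "flank"


def _span(text: str, color: str, background: str | None = None) -> str:
    style = f"color:{color}"
    if background:
        style += f";background:{background};color:#ffffff"
    return f'<span style="{style}">{html.escape(text)}</span>'


def _render_string(chars, classes, variant_pos, changed_pos, colors) -> str:
    out = []
    for i, ch in enumerate(chars):
        if i in changed_pos:
            out.append(_span(ch, colors["changed"], colors["changed"]))
        elif i in variant_pos:
            out.append(_span(ch, colors["variant"]))
        else:
            out.append(_span(ch, colors[classes[i]]))
    return "".join(out)


def _variant_page(record: ImpactRecord, colors) -> str:
    det = record.detail
    context, model = det["context"], det["model"]
    position_map = det["position_map"]
    tb, te = det["variant_transcript_interval"]
    vtype = record.variant.type
    n = context.length
    ref_classes = [_region_class(model, context.transcript_to_gene_relative(i))
                   for i in range(n)]
    # variant highlighting on the reference string; for indels also the
    # bases surrounding the edited region
    if vtype == "snp":
        ref_vpos = set(range(tb, te))
    else:
        ref_vpos = set(range(max(tb - 1, 0), min(te + 1, n)))

    var_len = len(det["var_fold"].sequence)
    inv = {j: i for i, j in enumerate(position_map) if j is not None}
    var_classes = []
    for j in range(var_len):
        i = inv.get(j)
        if i is None:  # inserted base: colour by nearest mapped neighbour
            k = next((inv[x] for x in range(j - 1, -1, -1) if x in inv), 0)
            var_classes.append(ref_classes[k] if ref_classes else "flank")
        else:
            var_classes.append(ref_classes[i])
    mapped = [position_map[i] for i in range(tb, te) if position_map[i] is not None]
    if vtype == "snp":
        var_vpos = set(mapped)
    elif vtype == "ins":
        ins_at = position_map[tb] if tb < n else var_len
        k = len(record.variant.alt)
        var_vpos = set(range(max(ins_at - k - 1, 0), min(ins_at + 1, var_len)))
    else:  # del: bases surrounding the removed region
        left = position_map[tb - 1] if tb > 0 else None
        right = position_map[te] if te < n else None
        var_vpos = {p for p in (left, right) if p is not None}

    v = record.variant
    parts = [
        "<html><head><meta charset='utf-8'><title>"
        f"{html.escape(record.mir_name)} {html.escape(v.chrom)}:{v.begin}</title></head>",
        "<body style='font-family:monospace;white-space:pre'>",
        f"<h2>{html.escape(record.mir_name)} — {html.escape(v.chrom)}:{v.begin}-{v.end} "
        f"{v.type} {html.escape(v.ref)}&gt;{html.escape(v.alt)}</h2>",
        f"<p>location: {html.escape(record.mir_location)}</p>",
    ]
    for rep in REPRESENTATIONS:
        res = record.by_representation[rep]
        diff = det["diffs"][rep]
        changed_ref = diff.changed_positions
        changed_var = {position_map[i] for i in changed_ref if position_map[i] is not None}
        ref_s = det["ref_fold"].structure(rep)
        var_s = det["var_fold"].structure(rep)
        parts.append(f"<h3>{rep}</h3>")
        parts.append(
            f"<div>impact: {html.escape(res.impact) or '-'} "
            f"(highest: {res.highest_impact}; conservation: {res.conservation}; "
            f"dG ref {res.ref_deltaG:.1f} / var {res.var_deltaG:.1f} kcal/mol)</div>"
        )
        parts.append("<div>reference:</div>")
        parts.append("<div>" + _render_string(context.sequence, ref_classes, ref_vpos,
                                              set(), colors) + "</div>")
        parts.append("<div>" + _render_string(ref_s, ref_classes, ref_vpos,
                                              changed_ref, colors) + "</div>")
        parts.append("<div>variant:</div>")
        parts.append("<div>" + _render_string(det["var_fold"].sequence, var_classes,
                                              var_vpos, set(), colors) + "</div>")
        parts.append("<div>" + _render_string(var_s, var_classes, var_vpos,
                                              changed_var, colors) + "</div>")
    parts.append("</body></html>")
    return "\n".join(parts)


def write_html(records, outdir, config: ReportConfig | None = None) -> None:
    """Index page plus one page per (variant, gene) with coloured structures.

    Records lacking in-process detail (e.g. read back from TSV, or
    beyond-flank variants) are listed on the index without a structure
    page.
    """
    colors = (config or ReportConfig()).colors
    os.makedirs(outdir, exist_ok=True)
    vdir = os.path.join(outdir, "variants")
    os.makedirs(vdir, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        v = rec.variant
        label = f"{v.chrom}:{v.begin}-{v.end} {v.type} {rec.mir_name}"
        if rec.detail is not None:
            page = f"variant_{i}.html"
            with open(os.path.join(vdir, page), "w") as fh:
                fh.write(_variant_page(rec, colors))
            link = f'<a href="variants/{page}">{html.escape(label)}</a>'
        else:
            link = html.escape(label) + " (no structure prediction)"
        hi = rec.by_representation.get("MFE")
        rows.append(
            f"<tr><td>{link}</td><td>{html.escape(rec.mir_location)}</td>"
            f"<td>{hi.highest_impact if hi else ''}</td></tr>"
        )
    legend = " ".join(
        _span(name, col) for name, col in colors.items() if name not in ("changed",)
    ) + " " + _span("changed", colors["changed"], colors["changed"])
    index = (
        "<html><head><meta charset='utf-8'><title>miRNA variant impact</title></head>"
        "<body><h1>miRNA variant impact predictions</h1>"
        f"<p>legend: {legend}</p>"
        "<table border='1'><tr><th>variant</th><th>location</th>"
        "<th>MFE highest impact</th></tr>"
        + "".join(rows) + "</table></body></html>"
    )
    with open(os.path.join(outdir, "index.html"), "w") as fh:
        fh.write(index)
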