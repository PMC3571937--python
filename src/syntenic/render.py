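"""Scale-exact gene maps (SVG + PDF) and tabular export.

Every row of a report is drawn with one shared horizontal scale
(``px_per_kb``), so a gene of 1800 bp is exactly twice as wide as one of
900 bp in *any* row — which is what makes gene fusions visible by eye: a
fusion's arrow is as wide as its parent arrows combined.  Rows are aligned
on the anchor (query) hit center; the anchor gene is stroked bold.  Genes
are strand-oriented arrows, filled with their ortholog-component color or
neutral grey when uncolored, clipped visually at the window edge while
keeping their true coordinates in the embedded metadata.

The palette holds 24 maximally distinct colors; beyond 24 components the
palette cycles with a progressive shade shift so color identity (not
exact hue) stays unambiguous within one report.
"""
from __future__ import annotations

import csv
import io
from typing import Iterable

from .synteny import Segment, SyntenyReport

PALETTE = (
    "#e6194b", "#3cb44b", "#ffe119", "#4363d8", "#f58231", "#911eb4",
    "#42d4f4", "#f032e6", "#bfef45", "#fabed4", "#469990", "#dcbeff",
    "#9a6324", "#fffac8", "#800000", "#aaffc3", "#808000", "#ffd8b1",
    "#000075", "#a9a9a9", "#5c2893", "#1f6f50", "#b85e00", "#6a9fb5",
)
NEUTRAL = "#cccccc"

LABEL_W = 300.0
MARGIN = 15.0
TRACK_H = 40.0
GENE_H = 14.0
HEADER_H = 58.0


def color_for(color_id: int | None) -> str:
    """Hex fill for a color id; cycles with shade variation beyond 24."""
    if color_id is None:
        return NEUTRAL
    idx = (color_id - 1) % len(PALETTE)
    cycle = (color_id - 1) // len(PALETTE)
    hexcol = PALETTE[idx]
    if cycle == 0:
        return hexcol
    # blend toward white, 22 % per extra cycle (capped), keeping hue identity
    frac = min(0.22 * cycle, 0.66)
    r, g, b = (int(hexcol[i : i + 2], 16) for i in (1, 3, 5))
    blend = lambda c: int(round(c + (255 - c) * frac))  # noqa: E731
    return f"#{blend(r):02x}{blend(g):02x}{blend(b):02x}"


def _gene_polygon(
    x1: float, x2: float, y: float, strand: int, clip0: float, clip1: float
) -> list[tuple[float, float]]:
    """Strand-oriented arrow covering [x1, x2], clipped to [clip0, clip1]."""
    h = GENE_H / 2.0
    head = min(9.0, 0.45 * (x2 - x1))
    if strand >= 0:
        pts = [
            (x1, y - h), (x2 - head, y - h), (x2, y), (x2 - head, y + h), (x1, y + h)
        ]
    else:
        pts = [
            (x2, y - h), (x1 + head, y - h), (x1, y), (x1 + head, y + h), (x2, y + h)
        ]
    return [(min(max(x, clip0), clip1), yy) for x, yy in pts]


def _row_geometry(report: SyntenyReport, px_per_kb: float):
    """Shared x-layout: every row's anchor center sits at the same x."""
    scale = px_per_kb / 1000.0
    anchor_off = []
    for seg in report.rows:
        if seg.anchor is not None:
            anchor_off.append(seg.display_offset(seg.anchor.center_bp))
        else:
            anchor_off.append(seg.window_length // 2)
    left = max((off * scale for off in anchor_off), default=0.0)
    right = max(
        ((seg.window_length - off) * scale for seg, off in zip(report.rows, anchor_off)),
        default=0.0,
    )
    x_anchor = LABEL_W + MARGIN + left
    return scale, anchor_off, x_anchor, x_anchor + right + MARGIN


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;").replace('"', "&quot;")
    )


def render_svg(report: SyntenyReport, px_per_kb: float = 40.0) -> str:
    """Render the report as an SVG 1.1 document (deterministic text).

    Each gene arrow carries its metadata (locus tag, product, coordinates,
    normalized score) both as a ``<title>`` child — the tooltip surrogate —
    and as ``data-`` attributes for programmatic use.
    """
    scale, anchor_off, x_anchor, width = _row_geometry(report, px_per_kb)
    width = max(width, LABEL_W + 2 * MARGIN + 200)
    nf_h = 20.0 + 16.0 * len(report.not_found) if report.not_found else 0.0
    height = HEADER_H + TRACK_H * len(report.rows) + nf_h + MARGIN
    out: list[str] = []
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width:.0f}" height="{height:.0f}" '
        f'font-family="Helvetica, Arial, sans-serif">'
    )
    p = report.params
    out.append(
        f'<text x="{MARGIN}" y="18" font-size="14" font-weight="bold">'
        f"Synteny report — query {len(report.query)} aa</text>"
    )
    out.append(
        f'<text x="{MARGIN}" y="36" font-size="11">threshold '
        f'{p.get("min_norm_score")}% · mode {p.get("mode")} · window '
        f'{p.get("window_bp")} bp · scale {px_per_kb:g} px/kb</text>'
    )
    y = HEADER_H
    for rank, (seg, off) in enumerate(zip(report.rows, anchor_off), start=1):
        yc = y + TRACK_H / 2.0
        x0 = x_anchor - off * scale
        x1 = x0 + seg.window_length * scale
        best = f"{seg.anchor.norm_score:.1f}%" if seg.anchor else "—"
        label = f"{rank}. {seg.organism} ({seg.accession}) {best}"
        out.append(
            f'<text x="{MARGIN}" y="{yc + 4:.1f}" font-size="11">{_esc(label)}</text>'
        )
        out.append(
            f'<line x1="{x0:.2f}" y1="{yc:.1f}" x2="{x1:.2f}" y2="{yc:.1f}" '
            f'stroke="#999999" stroke-width="1"/>'
        )
        for gene in seg.genes:
            f = gene.feature
            gx1 = x0 + seg.display_offset(f.start) * scale
            gx2 = gx1 + f.length_bp * scale
            pts = _gene_polygon(gx1, gx2, yc, f.strand, x0, x1)
            pts_str = " ".join(f"{px:.2f},{py:.2f}" for px, py in pts)
            stroke_w = 2.5 if gene.is_anchor else 0.8
            norm = "" if gene.norm_score is None else f"{gene.norm_score:.2f}"
            colorid = "" if gene.color is None else str(gene.color)
            title = (
                f"{f.locus_tag} | {f.product} | {f.start}-{f.end} "
                f"strand {'+' if f.strand > 0 else '-'}"
                + (f" | norm {norm}%" if norm else "")
            )
            out.append(
                f'<polygon points="{pts_str}" fill="{color_for(gene.color)}" '
                f'stroke="#000000" stroke-width="{stroke_w}" '
                f'data-locus="{_esc(f.locus_tag)}" data-start="{f.start}" '
                f'data-end="{f.end}" data-strand="{f.strand}" '
                f'data-color="{colorid}" data-norm="{norm}" '
                f'data-width-px="{f.length_bp * scale:.3f}">'
                f"<title>{_esc(title)}</title></polygon>"
            )
        y += TRACK_H
    if report.not_found:
        out.append(
            f'<text x="{MARGIN}" y="{y + 16:.1f}" font-size="12" font-weight="bold">'
            f"Synteny not found in:</text>"
        )
        for i, (acc, org) in enumerate(report.not_found):
            out.append(
                f'<text x="{MARGIN + 10}" y="{y + 32 + 16 * i:.1f}" font-size="11" '
                f'class="not-found">{_esc(f"{org} ({acc})")}</text>'
            )
    out.append("</svg>")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# CSV export

CSV_FIELDS = (
    "rank",
    "accession",
    "organism",
    "locus_tag",
    "start",
    "end",
    "strand",
    "color",
    "norm_score",
    "product",
)


def export_csv(report: SyntenyReport) -> str:
    """One row per gene (rank order), then not-found genomes with empty gene fields."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_FIELDS)
    for rank, seg in enumerate(report.rows, start=1):
        for gene in seg.genes:
            f = gene.feature
            writer.writerow(
                [
                    rank,
                    seg.accession,
                    seg.organism,
                    f.locus_tag,
                    f.start,
                    f.end,
                    f.strand,
                    "" if gene.color is None else gene.color,
                    "" if gene.norm_score is None else f"{gene.norm_score:.2f}",
                    f.product,
                ]
            )
    for acc, org in report.not_found:
        writer.writerow(["", acc, org, "", "", "", "", "", "", ""])
    return buf.getvalue()


def read_report_csv(text: str) -> tuple[list[dict], list[tuple[str, str]]]:
    """Parse an exported CSV back into gene rows + not-found list."""
    rows = list(csv.reader(io.StringIO(text)))
    if not rows or tuple(rows[0]) != CSV_FIELDS:
        raise ValueError("not a recognized synteny CSV export")
    genes: list[dict] = []
    not_found: list[tuple[str, str]] = []
    for row in rows[1:]:
        rec = dict(zip(CSV_FIELDS, row))
        if rec["rank"] == "":
            not_found.append((rec["accession"], rec["organism"]))
            continue
        genes.append(
            {
                "rank": int(rec["rank"]),
                "accession": rec["accession"],
                "organism": rec["organism"],
                "locus_tag": rec["locus_tag"],
                "start": int(rec["start"]),
                "end": int(rec["end"]),
                "strand": int(rec["strand"]),
                "color": None if rec["color"] == "" else int(rec["color"]),
                "norm_score": None if rec["norm_score"] == "" else float(rec["norm_score"]),
                "product": rec["product"],
            }
        )
    return genes, not_found


# ---------------------------------------------------------------------------
# PDF report

def render_pdf(report: SyntenyReport, path: str, px_per_kb: float = 40.0) -> None:
    """Write a paginated vector PDF with the same layout contract as the SVG.

    The first page carries a header with the run parameters and the full
    query sequence; the query is also stored in the document's Subject
    field.  Output is byte-identical across runs (creation/modification
    dates are omitted from the metadata).
    """
    import matplotlib
    from matplotlib.backends.backend_pdf import PdfPages
    from matplotlib.figure import Figure
    from matplotlib.patches import Polygon as MplPolygon

    scale, anchor_off, x_anchor, width = _row_geometry(report, px_per_kb)
    page_w, page_h = max(width + MARGIN, 680.0), 820.0
    rows_first = 8
    rows_later = 13
    chunks: list[list[tuple[int, Segment, float]]] = []
    indexed = [
        (rank, seg, off)
        for rank, (seg, off) in enumerate(zip(report.rows, anchor_off), start=1)
    ]
    if indexed:
        chunks.append(indexed[:rows_first])
        rest = indexed[rows_first:]
        while rest:
            chunks.append(rest[:rows_later])
            rest = rest[rows_later:]
    if not chunks:
        chunks = [[]]

    p = report.params
    with matplotlib.rc_context({"pdf.compression": 0, "pdf.fonttype": 3}):
        with PdfPages(
            path,
            metadata={
                "Title": "Synteny report",
                "Subject": f"query={report.query}",
                "Creator": "syntenic",
                "Producer": "syntenic",
                "CreationDate": None,
                "ModDate": None,
            },
        ) as pdf:
            for page_no, chunk in enumerate(chunks):
                fig = Figure(figsize=(page_w / 72.0, page_h / 72.0))
                ax = fig.add_axes([0, 0, 1, 1])
                ax.set_xlim(0, page_w)
                ax.set_ylim(page_h, 0)
                ax.axis("off")
                y = MARGIN + 10
                if page_no == 0:
                    ax.text(MARGIN, y, "Synteny report", fontsize=14, fontweight="bold")
                    y += 18
                    ax.text(
                        MARGIN,
                        y,
                        f"threshold {p.get('min_norm_score')}% · mode {p.get('mode')} · "
                        f"window {p.get('window_bp')} bp · scale {px_per_kb:g} px/kb",
                        fontsize=9,
                    )
                    y += 16
                    ax.text(MARGIN, y, f"Query ({len(report.query)} aa):", fontsize=9)
                    y += 12
                    for i in range(0, max(len(report.query), 1), 70):
                        ax.text(
                            MARGIN, y, report.query[i : i + 70], fontsize=7, family="monospace"
                        )
                        y += 9
                    y += 8
                for rank, seg, off in chunk:
                    yc = y + TRACK_H / 2.0
                    x0 = x_anchor - off * scale
                    x1 = x0 + seg.window_length * scale
                    best = f"{seg.anchor.norm_score:.1f}%" if seg.anchor else "—"
                    ax.text(
                        MARGIN,
                        yc,
                        f"{rank}. {seg.organism} ({seg.accession}) {best}",
                        fontsize=8,
                        va="center",
                    )
                    ax.plot([x0, x1], [yc, yc], color="#999999", linewidth=0.8)
                    for gene in seg.genes:
                        f = gene.feature
                        gx1 = x0 + seg.display_offset(f.start) * scale
                        gx2 = gx1 + f.length_bp * scale
                        pts = _gene_polygon(gx1, gx2, yc, f.strand, x0, x1)
                        ax.add_patch(
                            MplPolygon(
                                pts,
                                closed=True,
                                facecolor=color_for(gene.color),
                                edgecolor="#000000",
                                linewidth=1.6 if gene.is_anchor else 0.5,
                            )
                        )
                    y += TRACK_H
                if page_no == len(chunks) - 1 and report.not_found:
                    y += 10
                    ax.text(
                        MARGIN, y, "Synteny not found in:", fontsize=9, fontweight="bold"
                    )
                    y += 14
                    for acc, org in report.not_found:
                        ax.text(MARGIN + 10, y, f"{org} ({acc})", fontsize=8)
                        y += 12
                pdf.savefig(fig)


def write_outputs(
    report: SyntenyReport,
    out_dir: str,
    formats: Iterable[str] = ("svg", "csv", "json"),
    px_per_kb: float = 40.0,
) -> list[str]:
    """Write the requested report formats into ``out_dir``; returns paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for fmt in formats:
        target = out / f"report.{fmt}"
        if fmt == "svg":
            target.write_text(render_svg(report, px_per_kb))
        elif fmt == "csv":
            target.write_text(export_csv(report))
        elif fmt == "json":
            target.write_text(report.to_json())
        elif fmt == "pdf":
            render_pdf(report, str(target), px_per_kb)
        else:
            raise ValueError(f"unknown output format {fmt!r}")
        written.append(str(target))
    return written
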