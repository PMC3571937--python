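"""Window extraction and star-topology ortholog coloring.

The pipeline extracts a fixed-width genomic window (default 15 kb)
centered on each retained translated-search hit.  The window of the
top-ranked genome is the *reference*: its proteins are compared all
against all with SWG, pairs at or above the normalized-score threshold
become edges, and each connected component receives one color (so paralogs
within the reference share a color).  Every other window is then compared
*only* to the reference (a star topology — segments are never compared to
each other): each of its proteins inherits the color of its best-scoring
reference protein when that score reaches the threshold, and stays neutral
otherwise.

Pairwise scores are normalized by the self-score of the *longer* sequence
of the pair.  This matters for fusion proteins: a fusion of two reference
genes scores only moderately (roughly the fraction of the fusion that each
part covers) rather than 100, so fusions are still colored after their
better half while remaining visibly longer on the scale-exact map.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .alignment import AlignmentParams, normalized_score, sw_gotoh
from .genome_io import CDSFeature, GenomeRecord, translate_cds
from .search import (
    GenomicHit,
    SearchParams,
    merge_hits,
    rank_genomes,
    self_score,
    translated_search,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 15000
MAX_GENOMES = 100


@dataclass
class SegmentGene:
    """A CDS inside a window, with its protein and (after coloring) color."""

    feature: CDSFeature
    protein: str
    color: int | None = None
    norm_score: float | None = None
    is_anchor: bool = False


@dataclass
class Segment:
    """A genomic window around a hit, carrying the genes that overlap it.

    ``window_start`` + ``window_length`` may run past the replicon end on a
    circular replicon (wrap-around window, re-linearized for display);
    gene coordinates are kept unclipped so drawing can clip visually.
    """

    accession: str
    organism: str
    window_start: int
    window_length: int
    genome_length: int
    circular: bool
    genes: list[SegmentGene] = field(default_factory=list)
    anchor: GenomicHit | None = None
    syntenic: bool = True

    @property
    def window_end(self) -> int:
        return self.window_start + self.window_length

    def display_offset(self, pos: int) -> int:
        """Map a genomic coordinate onto the window's 0-based display axis."""
        if self.circular:
            return (pos - self.window_start) % self.genome_length
        return pos - self.window_start


@dataclass
class ColorMap:
    """Colors of the reference proteins: locus_tag -> dense color id from 1."""

    by_locus: dict[str, int] = field(default_factory=dict)
    next_color: int = 1


def _intervals_overlap(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def extract_segment(
    genome: GenomeRecord,
    center_bp: int,
    width: int = DEFAULT_WINDOW_BP,
    anchor: GenomicHit | None = None,
) -> Segment:
    """Extract the window of ``width`` bp centered on ``center_bp``.

    Linear replicons clip at the sequence ends; circular replicons always
    yield exactly ``min(width, length)`` bp, wrapping across the origin
    when needed.  All CDS overlapping the window by >= 1 bp are included
    with full (unclipped) coordinates and their translated proteins.
    """
    L = genome.length_bp
    if not (0 <= center_bp < L):
        raise ValueError(f"center {center_bp} outside genome [0, {L})")
    if genome.is_circular:
        w = min(width, L)
        start = 0 if w == L else (center_bp - w // 2) % L
        length = w
    else:
        start = max(0, center_bp - width // 2)
        end = min(L, center_bp + width // 2)
        length = end - start
    seg = Segment(
        accession=genome.accession,
        organism=genome.organism_name,
        window_start=start,
        window_length=length,
        genome_length=L,
        circular=genome.is_circular,
        anchor=anchor,
    )
    win0, win1 = start, start + length
    for f in genome.features:
        overlaps = _intervals_overlap(f.start, f.end, win0, win1) or (
            genome.is_circular and _intervals_overlap(f.start + L, f.end + L, win0, win1)
        )
        if not overlaps:
            continue
        prot = f.translation or translate_cds(f, genome)
        gene = SegmentGene(feature=f, protein=prot)
        if anchor is not None:
            c = anchor.center_bp
            gene.is_anchor = f.start <= c < f.end or (
                genome.is_circular and f.start <= c + L < f.end + L and f.end > L
            )
        seg.genes.append(gene)
    seg.genes.sort(key=lambda g: (seg.display_offset(g.feature.start), g.feature.end))
    return seg


class _PairScorer:
    """Caches self-scores and normalizes each pair by the longer sequence."""

    def __init__(self, params: AlignmentParams):
        self.params = params
        self._self: dict[str, int] = {}

    def self_of(self, protein: str) -> int:
        if protein not in self._self:
            self._self[protein] = sw_gotoh(protein, protein, self.params).score
        return self._self[protein]

    def norm(self, a: str, b: str) -> float:
        longer = a if (len(a), self.self_of(a)) >= (len(b), self.self_of(b)) else b
        denom = self.self_of(longer)
        if denom <= 0:
            return 0.0
        return normalized_score(sw_gotoh(a, b, self.params).score, denom)


def build_reference_colors(
    reference: Segment,
    threshold: float,
    params: AlignmentParams | None = None,
    scorer: _PairScorer | None = None,
) -> ColorMap:
    """Color the reference window: one color per >=threshold component.

    All reference proteins are compared pairwise; pairs whose normalized
    score (by the longer self-score) reaches ``threshold`` are edges, and
    each connected component of that graph gets one color, assigned in
    left-to-right gene order.  Reference genes are colored in place and
    given norm_score 100 (self-identity).
    """
    if not reference.genes:
        raise ValueError("reference segment has no genes to color")
    scorer = scorer or _PairScorer(params or AlignmentParams())
    n = len(reference.genes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if scorer.norm(reference.genes[i].protein, reference.genes[j].protein) >= threshold:
                parent[find(i)] = find(j)

    colors = ColorMap()
    for i, gene in enumerate(reference.genes):
        root = find(i)
        first = min(k for k in range(n) if find(k) == root)
        if reference.genes[first].color is None:
            reference.genes[first].color = colors.next_color
            colors.next_color += 1
        gene.color = reference.genes[first].color
        gene.norm_score = 100.0
        colors.by_locus[gene.feature.locus_tag] = gene.color
    reference.syntenic = True
    return colors


def propagate_colors(
    colors: ColorMap,
    reference: Segment,
    other: Segment,
    threshold: float,
    params: AlignmentParams | None = None,
    scorer: _PairScorer | None = None,
) -> Segment:
    """Color a non-reference window against the reference (star topology).

    Each protein of ``other`` is aligned to every reference protein; when
    the best normalized score reaches ``threshold`` the gene inherits that
    reference protein's color (ties go to the leftmost reference gene),
    otherwise it stays neutral.  A window with no colored gene is flagged
    non-syntenic.
    """
    scorer = scorer or _PairScorer(params or AlignmentParams())
    any_colored = False
    for gene in other.genes:
        best_norm = -1.0
        best_ref: SegmentGene | None = None
        for ref_gene in reference.genes:
            norm = scorer.norm(gene.protein, ref_gene.protein)
            if norm > best_norm:  # strict: ties keep the leftmost reference gene
                best_norm = norm
                best_ref = ref_gene
        if best_ref is not None and best_norm >= threshold:
            gene.color = colors.by_locus[best_ref.feature.locus_tag]
            gene.norm_score = best_norm
            any_colored = True
        else:
            gene.color = None
            gene.norm_score = None
    other.syntenic = any_colored
    return other


@dataclass
class SyntenyReport:
    """The full result of one synteny run, serializable to JSON/CSV."""

    query: str
    params: dict
    rows: list[Segment] = field(default_factory=list)
    not_found: list[tuple[str, str]] = field(default_factory=list)
    colors: ColorMap = field(default_factory=ColorMap)

    def to_json(self) -> str:
        def seg_dict(s: Segment) -> dict:
            return {
                "accession": s.accession,
                "organism": s.organism,
                "window_start": s.window_start,
                "window_length": s.window_length,
                "genome_length": s.genome_length,
                "circular": s.circular,
                "syntenic": s.syntenic,
                "anchor": None
                if s.anchor is None
                else {
                    "center_bp": s.anchor.center_bp,
                    "frame": s.anchor.frame,
                    "raw_score": s.anchor.raw_score,
                    "norm_score": s.anchor.norm_score,
                },
                "genes": [
                    {
                        "locus_tag": g.feature.locus_tag,
                        "product": g.feature.product,
                        "start": g.feature.start,
                        "end": g.feature.end,
                        "strand": g.feature.strand,
                        "protein": g.protein,
                        "color": g.color,
                        "norm_score": g.norm_score,
                        "is_anchor": g.is_anchor,
                    }
                    for g in s.genes
                ],
            }

        return json.dumps(
            {
                "query": self.query,
                "params": self.params,
                "rows": [seg_dict(s) for s in self.rows],
                "not_found": [list(nf) for nf in self.not_found],
                "colors": self.colors.by_locus,
            },
            indent=2,
        )


def run_synteny(
    query: str,
    genomes: Sequence[GenomeRecord],
    search_params: SearchParams | None = None,
    align_params: AlignmentParams | None = None,
    width: int = DEFAULT_WINDOW_BP,
) -> SyntenyReport:
    """Run the full synteny pipeline over a set of replicons.

    self-score -> per-genome translated search -> genome ranking -> window
    extraction (best hit, or all merged hits in all_hits mode) -> reference
    coloring on the top-ranked genome -> star propagation to every other
    window.  At most 100 genomes per job, checked before any computation.
    """
    search_params = search_params or SearchParams()
    align_params = align_params or AlignmentParams()
    if not genomes:
        raise ValueError("no genomes supplied")
    if len(genomes) > MAX_GENOMES:
        raise ValueError(
            f"{len(genomes)} genomes selected; at most {MAX_GENOMES} per job"
        )
    accessions = [g.accession for g in genomes]
    if len(set(accessions)) != len(accessions):
        raise ValueError("duplicate genome accessions in selection")
    by_acc = {g.accession: g for g in genomes}

    t0 = time.perf_counter()
    q_self = self_score(query, align_params)
    hits_by = {
        g.accession: translated_search(query, g, align_params, search_params, q_self)
        for g in genomes
    }
    logger.info(
        "translated search over %d genomes in %.2fs", len(genomes), time.perf_counter() - t0
    )
    ranked, not_found_acc = rank_genomes(hits_by)

    params_used = {
        "min_norm_score": search_params.min_norm_score,
        "mode": search_params.mode,
        "window_bp": width,
        "gap_open": align_params.gap_open,
        "gap_extend": align_params.gap_extend,
        "query_self_score": q_self,
    }
    report = SyntenyReport(
        query=query,
        params=params_used,
        not_found=[(acc, by_acc[acc].organism_name) for acc in not_found_acc],
    )
    if not ranked:
        return report

    rows: list[Segment] = []
    for accession, best in ranked:
        genome = by_acc[accession]
        if search_params.mode == "all_hits":
            retained = merge_hits(hits_by[accession], width)
        else:
            retained = [best]
        for hit in retained:
            rows.append(extract_segment(genome, hit.center_bp, width, anchor=hit))

    reference = rows[0]
    scorer = _PairScorer(align_params)
    if reference.genes:
        colors = build_reference_colors(
            reference, search_params.min_norm_score, align_params, scorer=scorer
        )
        for seg in rows[1:]:
            propagate_colors(
                colors, reference, seg, search_params.min_norm_score, align_params, scorer=scorer
            )
    else:  # hit in an unannotated region: nothing to color against
        colors = ColorMap()
    report.rows = rows
    report.colors = colors
    return report
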