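"""Translated search of a protein query against genome DNA, and ranking.

The query is first aligned to itself to obtain the self-score that anchors
all normalization.  The genome is then translated in all six reading
frames; stop codons split each frame into blocks, every block of at least
10 residues is locally aligned to the query, and alignments reaching the
normalized-score threshold become :class:`GenomicHit` records whose
midpoint is mapped back to genomic coordinates (frame- and strand-aware).
This is the same operation class as TBLASTN, run exactly (full dynamic
programming per block) rather than heuristically — practical because the
per-genome search space here is a handful of megabases at most.

Genomes are ranked by the normalized score of their best hit; genomes with
no hit above threshold form the "not found" list that accompanies every
report.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Seq import Seq

from .alignment import AlignmentParams, normalized_score, sw_gotoh
from .genome_io import GenomeRecord, reverse_complement

#: stop-delimited translated blocks shorter than this are noise and skipped
MIN_BLOCK_RESIDUES = 10
#: shortest query accepted, measured after cleaning
MIN_QUERY_RESIDUES = 10

MODES = ("best_hit", "all_hits")


@dataclass(frozen=True)
class GenomicHit:
    """One translated-search match, with raw and normalized scores.

    ``frame`` is +-1/2/3 (sign = strand); ``start``/``end`` delimit the
    genomic interval covered by the aligned codons and ``center_bp`` is its
    midpoint.
    """

    accession: str
    center_bp: int
    frame: int
    raw_score: int
    norm_score: float
    start: int = 0
    end: int = 0


@dataclass(frozen=True)
class SearchParams:
    """User-facing search knobs: orthology threshold and hit mode.

    ``min_norm_score`` is the minimal normalized score (percentage) for a
    hit to count; accepted range [10, 100], default 30 — the discriminant
    value commonly used to call bona fide orthology from normalized
    genomic search scores.
    """

    min_norm_score: float = 30.0
    mode: str = "best_hit"

    def __post_init__(self) -> None:
        if not (10.0 <= self.min_norm_score <= 100.0):
            raise ValueError(
                f"min_norm_score must be within [10, 100], got {self.min_norm_score}"
            )
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


def self_score(query: str, params: AlignmentParams | None = None) -> int:
    """Score of the query aligned to itself; anchors all normalization."""
    if len(query) < MIN_QUERY_RESIDUES:
        raise ValueError(
            f"query too short: {len(query)} residues (< {MIN_QUERY_RESIDUES})"
        )
    score = sw_gotoh(query, query, params).score
    if score <= 0:
        raise ValueError("query self-score is not positive; check the sequence")
    return score


def _frame_blocks(protein: str) -> Iterable[tuple[int, str]]:
    """Yield (offset_in_frame_residues, block) for stop-delimited blocks."""
    start = 0
    for m in re.finditer(r"\*", protein):
        if m.start() - start >= MIN_BLOCK_RESIDUES:
            yield start, protein[start : m.start()]
        start = m.end()
    if len(protein) - start >= MIN_BLOCK_RESIDUES:
        yield start, protein[start:]


def translated_search(
    query: str,
    genome: GenomeRecord,
    align_params: AlignmentParams | None = None,
    search_params: SearchParams | None = None,
    query_self_score: int | None = None,
) -> list[GenomicHit]:
    """Six-frame translated search of ``query`` against one replicon.

    Returns hits with norm_score >= the threshold, sorted by decreasing
    normalized score (ties by genomic position).  ``query_self_score`` may
    be passed to avoid recomputing it per replicon.
    """
    align_params = align_params or AlignmentParams()
    search_params = search_params or SearchParams()
    if query_self_score is None:
        query_self_score = self_score(query, align_params)
    L = genome.length_bp
    if L < 3:
        return []
    hits: list[GenomicHit] = []
    for strand, seq in ((1, genome.sequence), (-1, reverse_complement(genome.sequence))):
        for f in range(3):
            sub = seq[f : f + 3 * ((L - f) // 3)]
            if not sub:
                continue
            protein = str(Seq(sub).translate(table=11))
            for offset, block in _frame_blocks(protein):
                res = sw_gotoh(query, block, align_params)
                if res.score <= 0:
                    continue
                norm = normalized_score(res.score, query_self_score)
                if norm < search_params.min_norm_score:
                    continue
                aa0 = offset + res.target_span[0]
                aa1 = offset + res.target_span[1]
                nt0 = f + 3 * aa0
                nt1 = f + 3 * aa1
                if strand == 1:
                    g0, g1 = nt0, nt1
                else:
                    g0, g1 = L - nt1, L - nt0
                hits.append(
                    GenomicHit(
                        accession=genome.accession,
                        center_bp=(g0 + g1) // 2,
                        frame=strand * (f + 1),
                        raw_score=res.score,
                        norm_score=norm,
                        start=g0,
                        end=g1,
                    )
                )
    hits.sort(key=lambda h: (-h.norm_score, h.center_bp, h.frame))
    return hits


def merge_hits(hits: list[GenomicHit], window_bp: int) -> list[GenomicHit]:
    """Collapse hits whose windows would overlap by more than half.

    Hits are taken in decreasing score order; a hit is dropped when its
    prospective window shares more than 50 % of its width with a window
    already kept (the kept, higher-scoring center wins).
    """
    kept: list[GenomicHit] = []
    for h in sorted(hits, key=lambda x: (-x.norm_score, x.center_bp, x.frame)):
        if all(abs(h.center_bp - k.center_bp) >= window_bp / 2 for k in kept):
            kept.append(h)
    return kept


def rank_genomes(
    hits_by_genome: Mapping[str, list[GenomicHit]],
) -> tuple[list[tuple[str, GenomicHit]], list[str]]:
    """Order genomes by their best normalized hit score.

    Returns (ranked, not_found): ``ranked`` pairs each accession with its
    best hit, sorted by decreasing norm_score with ties broken by
    ascending accession; ``not_found`` lists hitless accessions sorted
    ascending.
    """
    ranked = []
    not_found = []
    for accession in sorted(hits_by_genome):
        hits = hits_by_genome[accession]
        if hits:
            best = max(hits, key=lambda h: (h.norm_score, -h.center_bp, -h.frame))
            ranked.append((accession, best))
        else:
            not_found.append(accession)
    ranked.sort(key=lambda pair: (-pair[1].norm_score, pair[0]))
    return ranked, not_found
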