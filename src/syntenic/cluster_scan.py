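"""Multi-query gene-cluster detection by inter-hit distance chaining.

Given several query proteins (e.g. the four subunits of a multiprotein
complex), every replicon is searched with each query; all above-threshold
hits are pooled, sorted by genomic position, and greedily chained while
the center-to-center distance between consecutive hits stays strictly
below ``max_gap`` (default 8000 bp).  A chain covering every query at
least once is a *complete* cluster — the genomic signature of the whole
complex being encoded in one neighborhood.  Paralogous hits of a single
query may legitimately appear several times in one chain.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .alignment import AlignmentParams
from .genome_io import GenomeRecord
from .search import GenomicHit, SearchParams, self_score, translated_search

DEFAULT_MAX_GAP = 8000


@dataclass(frozen=True)
class ClusterHit:
    """One chain of co-located hits on a replicon."""

    accession: str
    members: tuple[tuple[str, GenomicHit], ...]  # (query id, hit), position order
    span: tuple[int, int]
    complete: bool

    @property
    def span_bp(self) -> int:
        return self.span[1] - self.span[0]

    @property
    def queries_found(self) -> tuple[str, ...]:
        return tuple(sorted({qid for qid, _ in self.members}))


def scan_clusters(
    queries: Sequence[tuple[str, str]],
    genome: GenomeRecord,
    max_gap: int = DEFAULT_MAX_GAP,
    min_norm: float = 30.0,
    align_params: AlignmentParams | None = None,
) -> list[ClusterHit]:
    """Chain the pooled hits of several queries on one replicon.

    ``queries`` is a list of (id, protein) pairs, at least two.  Chains are
    maximal under the strict ``< max_gap`` center-to-center rule; every
    chain (including singletons) is reported with its completeness flag.
    """
    if len(queries) < 2:
        raise ValueError("cluster scan needs at least 2 queries")
    ids = [qid for qid, _ in queries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate query ids")
    align_params = align_params or AlignmentParams()
    search_params = SearchParams(min_norm_score=min_norm, mode="all_hits")
    pooled: list[tuple[str, GenomicHit]] = []
    for qid, protein in queries:
        qss = self_score(protein, align_params)
        for hit in translated_search(protein, genome, align_params, search_params, qss):
            pooled.append((qid, hit))
    pooled.sort(key=lambda item: (item[1].center_bp, item[0]))

    all_ids = set(ids)
    clusters: list[ClusterHit] = []
    chain: list[tuple[str, GenomicHit]] = []

    def emit() -> None:
        if not chain:
            return
        clusters.append(
            ClusterHit(
                accession=genome.accession,
                members=tuple(chain),
                span=(min(h.start for _, h in chain), max(h.end for _, h in chain)),
                complete={qid for qid, _ in chain} == all_ids,
            )
        )

    for qid, hit in pooled:
        if chain and hit.center_bp - chain[-1][1].center_bp >= max_gap:
            emit()
            chain = []
        chain.append((qid, hit))
    emit()
    return clusters


def scan_library(
    queries: Sequence[tuple[str, str]],
    genomes: Sequence[GenomeRecord],
    max_gap: int = DEFAULT_MAX_GAP,
    min_norm: float = 30.0,
    align_params: AlignmentParams | None = None,
) -> pd.DataFrame:
    """Scan a genome library and tabulate the best cluster per replicon.

    One row per replicon with the number of chains, whether a complete
    chain exists, and the span of the best chain (most queries covered,
    then shortest).  Sorted complete-first, then by span, then accession.
    """
    accs = [g.accession for g in genomes]
    if len(set(accs)) != len(accs):
        raise ValueError("duplicate genome accessions in library")
    rows = []
    for genome in genomes:
        clusters = scan_clusters(queries, genome, max_gap, min_norm, align_params)
        best = None
        if clusters:
            best = max(
                clusters, key=lambda c: (c.complete, len(c.queries_found), -c.span_bp)
            )
        rows.append(
            {
                "accession": genome.accession,
                "organism": genome.organism_name,
                "n_hits": sum(len(c.members) for c in clusters),
                "n_clusters": len(clusters),
                "complete": bool(best.complete) if best else False,
                "queries_found": ";".join(best.queries_found) if best else "",
                "best_span_bp": best.span_bp if best else 0,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "accession",
            "organism",
            "n_hits",
            "n_clusters",
            "complete",
            "queries_found",
            "best_span_bp",
        ],
    )
    if not df.empty:
        df = df.sort_values(
            ["complete", "best_span_bp", "accession"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df
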