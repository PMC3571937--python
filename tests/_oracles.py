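"""Independent reference implementations used only to check the package.

These deliberately use a different algorithmic route than the library:
the alignment oracle enumerates every gap length explicitly (cubic time),
and the component oracle hands the thresholded score matrix to networkx.
"""
from __future__ import annotations

import numpy as np

from syntenic.alignment import EXTENDED_ALPHABET, encode_protein


def naive_local_affine(a: str, b: str, matrix: np.ndarray, gap_open: int, gap_extend: int) -> int:
    """Cubic local-affine DP: a gap of length k costs gap_open + k*gap_extend."""
    ea, eb = encode_protein(a), encode_protein(b)
    n, m = len(ea), len(eb)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cand = H[i - 1, j - 1] + matrix[ea[i - 1], eb[j - 1]]
            for k in range(1, i + 1):
                cand = max(cand, H[i - k, j] - gap_open - k * gap_extend)
            for k in range(1, j + 1):
                cand = max(cand, H[i, j - k] - gap_open - k * gap_extend)
            H[i, j] = max(0, cand)
            best = max(best, H[i, j])
    return int(best)


def component_partition(proteins: list[str], norm, threshold: float) -> list[set[int]]:
    """Connected components of the thresholded pairwise score graph (networkx)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(proteins)))
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            if norm(proteins[i], proteins[j]) >= threshold:
                g.add_edge(i, j)
    return sorted(
        (set(c) for c in nx.connected_components(g)), key=lambda c: min(c)
    )
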