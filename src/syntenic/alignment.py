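"""Affine-gap protein alignment and normalized-score computation.

Every orthology decision in this package rests on two primitives defined
here: the Smith-Waterman-Gotoh (SWG) local alignment score of two protein
sequences under an affine gap model, and its normalization by a
self-alignment score.  The normalized score

    norm(a, b) = 100 * SWG(a, b) / SWG(ref, ref)

is a percentage in [0, 100]; a sequence aligned to itself scores exactly
100, and the value is approximately invariant to the overall scale of the
substitution matrix, which makes a single user threshold meaningful across
matrices.

A gap of length ``k`` costs ``gap_open + k * gap_extend``, so the shortest
possible gap already pays both the opening and one extension.  The default
matrix is BLOSUM62 with the ``X`` (unknown residue) and ``*`` (stop) rows
forced to zero: annotation artifacts must neither help nor hurt an
alignment.

The dynamic-programming kernels are compiled with numba; the module-level
functions are plain Python and accept ordinary strings.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import TextIO, Union

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

#: The 20 standard amino acids, in the row order used by the score matrices.
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
#: Internal alphabet: the 20 standard residues plus X (unknown) and * (stop).
EXTENDED_ALPHABET = AA_ALPHABET + "X*"

_CODE = {aa: i for i, aa in enumerate(EXTENDED_ALPHABET)}
_X = _CODE["X"]
_NEG = -(10**9)

_LOOKUP = np.full(128, _X, dtype=np.int8)
for _aa, _i in _CODE.items():
    _LOOKUP[ord(_aa)] = _i


def encode_protein(seq: str) -> np.ndarray:
    """Encode a protein string into the internal integer alphabet.

    Characters outside the 20+X+* alphabet map to X (score 0 against
    everything); input validation with explicit errors happens at the query
    boundary, not here.
    """
    try:
        raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise ValueError(f"non-ASCII character in protein sequence: {exc}") from None
    return _LOOKUP[raw & 0x7F]


@lru_cache(maxsize=1)
def _blosum62() -> np.ndarray:
    raw = substitution_matrices.load("BLOSUM62")
    n = len(EXTENDED_ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            mat[i, j] = int(raw[a, b])
    return mat


def default_matrix() -> np.ndarray:
    """BLOSUM62 over the internal alphabet, X/* scoring 0 vs everything."""
    return _blosum62().copy()


def load_matrix(source: Union[str, Path, TextIO]) -> np.ndarray:
    """Load a substitution matrix from NCBI matrix text format.

    Letters absent from the file keep score 0; X and * are always forced
    to 0 regardless of the file's own values.
    """
    if hasattr(source, "read"):
        handle = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        handle = io.StringIO(text)
    raw = substitution_matrices.read(handle)
    n = len(EXTENDED_ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for a in raw.alphabet:
        for b in raw.alphabet:
            if a in _CODE and b in _CODE and a not in "X*" and b not in "X*":
                mat[_CODE[a], _CODE[b]] = int(raw[a, b])
    return mat


@dataclass
class AlignmentParams:
    """Scoring parameters for Smith-Waterman-Gotoh alignment.

    gap_open / gap_extend are positive penalties; a length-k gap costs
    ``gap_open + k * gap_extend``.  ``mode`` is ``"local"`` (the mode used
    throughout the pipeline) or ``"global"`` (Needleman-Wunsch-Gotoh,
    retained as an auditable switch; global scores may be negative).
    """

    matrix: np.ndarray = field(default_factory=default_matrix)
    gap_open: int = 11
    gap_extend: int = 1
    mode: str = "local"

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.int32)
        if self.matrix.shape != (len(EXTENDED_ALPHABET),) * 2:
            raise ValueError(
                f"matrix must be {len(EXTENDED_ALPHABET)}x{len(EXTENDED_ALPHABET)} "
                f"over {EXTENDED_ALPHABET!r}"
            )
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.mode not in ("local", "global"):
            raise ValueError(f"mode must be 'local' or 'global', got {self.mode!r}")


@dataclass(frozen=True)
class AlignmentResult:
    """Score and the 0-based half-open spans of the optimal alignment."""

    score: int
    query_span: tuple[int, int]
    target_span: tuple[int, int]


@njit(cache=True)
def _local_kernel(a, b, mat, go, ge):  # pragma: no cover - exercised via sw_gotoh
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros(m + 1, dtype=np.int64)
    F = np.full(m + 1, _NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        diag = H[0]
        h_left = 0
        e = _NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            f = F[j] - ge
            up = H[j] - go - ge
            if up > f:
                f = up
            F[j] = f
            e = e - ge
            left = h_left - go - ge
            if left > e:
                e = left
            h = diag + mat[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            h_left = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _global_kernel(a, b, mat, go, ge):  # pragma: no cover - exercised via sw_gotoh
    n = a.shape[0]
    m = b.shape[0]
    H = np.empty(m + 1, dtype=np.int64)
    F = np.full(m + 1, _NEG, dtype=np.int64)
    H[0] = 0
    for j in range(1, m + 1):
        H[j] = -(go + j * ge)
    for i in range(1, n + 1):
        diag = H[0]
        H[0] = -(go + i * ge)
        h_left = H[0]
        e = _NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            f = F[j] - ge
            up = H[j] - go - ge
            if up > f:
                f = up
            F[j] = f
            e = e - ge
            left = h_left - go - ge
            if left > e:
                e = left
            h = diag + mat[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            diag = H[j]
            H[j] = h
            h_left = h
    return H[m]


def sw_gotoh(a: str, b: str, params: AlignmentParams | None = None) -> AlignmentResult:
    """Optimal affine-gap alignment of two protein sequences.

    In local mode the returned spans delimit the optimal local alignment
    (recovered by re-aligning the reversed prefixes ending at the optimum,
    so no traceback matrix is stored).  An empty input or an all-negative
    scoring landscape yields score 0 with empty spans.  The score is
    symmetric in its arguments.
    """
    if params is None:
        params = AlignmentParams()
    ea = encode_protein(a)
    eb = encode_protein(b)
    if params.mode == "global":
        score = int(_global_kernel(ea, eb, params.matrix, params.gap_open, params.gap_extend))
        return AlignmentResult(score, (0, len(a)), (0, len(b)))
    if len(ea) == 0 or len(eb) == 0:
        return AlignmentResult(0, (0, 0), (0, 0))
    best, bi, bj = _local_kernel(ea, eb, params.matrix, params.gap_open, params.gap_extend)
    if best == 0:
        return AlignmentResult(0, (0, 0), (0, 0))
    ra = np.ascontiguousarray(ea[:bi][::-1])
    rb = np.ascontiguousarray(eb[:bj][::-1])
    _, ri, rj = _local_kernel(ra, rb, params.matrix, params.gap_open, params.gap_extend)
    return AlignmentResult(int(best), (bi - ri, bi), (bj - rj, bj))


def normalized_score(hit_score: int, self_score: int) -> float:
    """Express ``hit_score`` as a percentage of ``self_score``, clipped to [0, 100]."""
    if self_score <= 0:
        raise ValueError(f"self_score must be positive, got {self_score}")
    if hit_score < 0:
        hit_score = 0
    return min(100.0, 100.0 * hit_score / self_score)
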