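"""Pairwise alignment: global (for distance input) and local best-hit scoring.

The global aligner is an affine-gap Needleman–Wunsch (Gotoh) with a fixed,
documented tie-break order — diagonal, then up (gap in the second sequence),
then left — so distance matrices are reproducible to the byte.  The local
score, used as the BLAST1 stand-in, is exact Smith–Waterman computed by
Bio.Align.PairwiseAligner with a custom IUPAC substitution matrix; no
heuristic seeding, so similarity rankings are deterministic.

A gap of length g costs ``gap_open + (g-1)*gap_extend``.  Ambiguity codes
score as a match whenever the two symbols' nucleotide sets intersect.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "AlignedPair",
    "needleman_wunsch",
    "smith_waterman_score",
    "ALPHABET",
    "IUPAC_SETS",
]

ALPHABET = "ACGTRYSWKMBDHVN"

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_INDEX = {c: i for i, c in enumerate(ALPHABET)}


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores.  Defaults are megablast-like: +1/−2 with a 5,2
    affine gap; all four are configurable."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def __post_init__(self) -> None:
        if not self.match > 0:
            raise ValueError("match score must be positive")
        if not self.mismatch < 0:
            raise ValueError("mismatch score must be negative")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")

    def substitution_matrix(self) -> np.ndarray:
        """(15, 15) score matrix over :data:`ALPHABET` with the
        set-intersection rule for ambiguity codes."""
        return _sub_matrix(self.match, self.mismatch)


@lru_cache(maxsize=None)
def _sub_matrix(match: float, mismatch: float) -> np.ndarray:
    n = len(ALPHABET)
    mat = np.full((n, n), mismatch)
    for i, x in enumerate(ALPHABET):
        for j, y in enumerate(ALPHABET):
            if IUPAC_SETS[x] & IUPAC_SETS[y]:
                mat[i, j] = match
    mat.setflags(write=False)
    return mat


@dataclass(frozen=True)
class AlignedPair:
    """A gapped pair of equal length with no all-gap column."""

    seq_a: str
    seq_b: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        for x, y in zip(self.seq_a, self.seq_b):
            if x == "-" and y == "-":
                raise ValueError("gap-in-both column in aligned pair")


def _encode(seq: str, name: str) -> np.ndarray:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    try:
        return np.fromiter((_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"{name}: invalid or gapped symbol {exc.args[0]!r}") from exc


def needleman_wunsch(a: str, b: str, scheme: ScoringScheme | None = None) -> AlignedPair:
    """Optimal global alignment under affine-gap scoring.

    Ties are broken deterministically: diagonal (substitution) over up (gap
    in ``b``) over left (gap in ``a``), applied at every traceback step.
    """
    scheme = scheme or ScoringScheme()
    ai = _encode(a, "a")
    bi = _encode(b, "b")
    sub = scheme.substitution_matrix()
    go, ge = scheme.gap_open, scheme.gap_extend
    n, m = len(ai), len(bi)
    NEG = -np.inf

    # State M: column (a_i, b_j); Ix: (a_i, -) "up"; Iy: (-, b_j) "left".
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    js = np.arange(m + 1)

    for i in range(n + 1):
        if i > 0:
            prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
            M[i, 1:] = prev_best[:-1] + sub[ai[i - 1], bi]
            M[i, 0] = NEG
            Ix[i] = np.maximum(
                np.maximum(M[i - 1] + go, Iy[i - 1] + go), Ix[i - 1] + ge
            )
        # Horizontal-gap state via max-plus prefix scan over the current row.
        base = np.maximum(M[i], Ix[i])
        c = base + go - (js + 1) * ge
        run = np.maximum.accumulate(c)
        Iy[i, 1:] = ge * js[1:] + run[:-1]
        Iy[i, 0] = NEG

    # Traceback with fixed preference order M > Ix > Iy.
    TOL = 1e-6
    i, j = n, m
    here = max(M[n, m], Ix[n, m], Iy[n, m])
    if M[n, m] >= here - TOL:
        state = "M"
    elif Ix[n, m] >= here - TOL:
        state = "Ix"
    else:
        state = "Iy"
    score = float(here)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - sub[ai[i - 1], bi[j - 1]]
            i, j = i - 1, j - 1
            cands = (("M", M[i, j]), ("Ix", Ix[i, j]), ("Iy", Iy[i, j]))
        elif state == "Ix":
            out_a.append(a[i - 1])
            out_b.append("-")
            target = Ix[i, j]
            i -= 1
            cands = (("M", M[i, j] + go), ("Ix", Ix[i, j] + ge), ("Iy", Iy[i, j] + go))
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            target = Iy[i, j]
            j -= 1
            cands = (("M", M[i, j] + go), ("Ix", Ix[i, j] + go), ("Iy", Iy[i, j] + ge))
        if i == 0 and j == 0:
            break
        for name, val in cands:
            if abs(val - target) <= TOL:
                state = name
                break
        else:  # pragma: no cover - defensive; DP and traceback use same arithmetic
            raise RuntimeError("traceback failed to find a predecessor state")
    return AlignedPair(seq_a="".join(reversed(out_a)), seq_b="".join(reversed(out_b)), score=score)


@lru_cache(maxsize=None)
def _local_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    mat = substitution_matrices.Array(
        alphabet=ALPHABET, dims=2, data=scheme.substitution_matrix()
    )
    aligner.substitution_matrix = mat
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def smith_waterman_score(
    query: str, subject: str, scheme: ScoringScheme | None = None
) -> float:
    """Maximal local alignment score; 0 when no segment scores positively."""
    scheme = scheme or ScoringScheme()
    _encode(query, "query")
    _encode(subject, "subject")
    score = _local_aligner(scheme).score(query, subject)
    return max(0.0, float(score))
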