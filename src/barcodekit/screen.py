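"""Profile-HMM screen for contaminant-like sequences.

A Plan7-style profile — match states with position-specific emissions,
insert and delete states, and background-emitting N/C flanks — is trained
from a small curated alignment of the contaminant family (e.g. fungal ITS2)
with Laplace pseudocounts.  Sequences are scored by the forward algorithm in
local mode (uniform entry to any match state, a fixed per-state exit
probability), as log2 odds against an i.i.d. background model; scores at or
above a cutoff are flagged as contaminant-like.

The default cutoff is calibrated per profile from the training sequences'
own scores rather than fixed at 0 bits: the forward score sums over the
full alignment-path ensemble, and that ensemble's entropy lifts the score
of even unrelated sequences well above their single-best-path (Viterbi)
log-odds, so the raw sign of the log-odds is not a reliable decision
boundary.  The contract is the screen's behaviour with respect to its own
training profile: training-like sequences score near the training scores,
sequences from a sufficiently diverged family score far below the cutoff.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from barcodekit.taxa import BarcodeRecord

__all__ = [
    "ProfileHMM",
    "ScreenResult",
    "build_profile_hmm",
    "forward_log_odds",
    "viterbi_log_odds",
    "screen",
]

_NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(_NT)}
# Fractional residue attribution for ambiguity codes during training.
_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_M, _I, _D = 0, 1, 2
_LOG_HALF = math.log(0.5)


@dataclass
class ProfileHMM:
    """Trained profile parameters (probability space).

    ``transitions[k]`` is the 3x3 row-stochastic matrix of
    match/insert/delete transitions from profile position ``k+1`` to
    ``k+2`` (self for insert), for ``k = 0..K-2``; local entry is uniform
    over match states and every match state exits with probability ``tau``
    (the last with probability 1).
    """

    match_emissions: np.ndarray  # (K, 4)
    insert_emissions: np.ndarray  # (4,)
    background: np.ndarray  # (4,)
    transitions: np.ndarray  # (K-1, 3, 3)
    tau: float = 0.05
    #: calibrated screening cutoff (bits); set by the builder from the
    #: training sequences' own scores, None for an uncalibrated profile
    cutoff_bits: float | None = None

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        K = self.n_match_states
        if K < 1:
            raise ValueError("profile needs at least one match state")
        if self.transitions.shape != (max(K - 1, 0), 3, 3):
            raise ValueError("transitions must have shape (K-1, 3, 3)")
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")
        for name, dist in (
            ("match_emissions", self.match_emissions),
            ("insert_emissions", self.insert_emissions[None, :]),
            ("background", self.background[None, :]),
        ):
            if not np.allclose(dist.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
        if K > 1 and not np.allclose(self.transitions.sum(axis=-1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")

    @property
    def n_match_states(self) -> int:
        return self.match_emissions.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "match_emissions": self.match_emissions.tolist(),
                "insert_emissions": self.insert_emissions.tolist(),
                "background": self.background.tolist(),
                "transitions": self.transitions.tolist(),
                "tau": self.tau,
                "cutoff_bits": self.cutoff_bits,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        d = json.loads(text)
        return cls(
            match_emissions=np.array(d["match_emissions"]),
            insert_emissions=np.array(d["insert_emissions"]),
            background=np.array(d["background"]),
            transitions=np.array(d["transitions"]),
            tau=d["tau"],
            cutoff_bits=d.get("cutoff_bits"),
        )


def _residue_weights(symbol: str) -> np.ndarray:
    targets = _AMBIG.get(symbol)
    if targets is None:
        raise ValueError(f"invalid training symbol {symbol!r}")
    w = np.zeros(4)
    for c in targets:
        w[_NT_INDEX[c]] = 1.0 / len(targets)
    return w


def build_profile_hmm(
    training_msa: Sequence[BarcodeRecord] | Sequence[str],
    gap_column_threshold: float = 0.5,
    pseudocount: float = 1.0,
    tau: float = 0.05,
) -> ProfileHMM:
    """Train a profile from an aligned family.

    Columns whose gap fraction is strictly below ``gap_column_threshold``
    become match states; other columns are treated as inserts.  Emission and
    transition probabilities are Laplace-smoothed observed counts.  Inserts
    before the first and after the last match column are ignored for
    transition training (local entry/exit replaces them).

    The returned profile carries a calibrated screening cutoff: half the
    minimum forward score of the (ungapped) training sequences.  Raw
    forward log-odds are inflated for *any* input by the entropy of the
    alignment-path ensemble, so a fixed absolute threshold near zero
    over-flags; anchoring the cutoff to what the profile's own family
    scores is stable across profile lengths and divergences.
    """
    seqs = [
        r.sequence if isinstance(r, BarcodeRecord) else str(r) for r in training_msa
    ]
    if len(seqs) < 2:
        raise ValueError("training alignment needs at least 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("training sequences must be aligned to equal length")
    ncol = lengths.pop()
    cols = np.array([list(s) for s in seqs])
    gap_frac = (cols == "-").mean(axis=0)
    match_cols = np.flatnonzero(gap_frac < gap_column_threshold)
    K = match_cols.size
    if K == 0:
        raise ValueError("no column qualifies as a match state")

    em = np.full((K, 4), float(pseudocount))
    for k, col in enumerate(match_cols):
        for sym in cols[:, col]:
            if sym != "-":
                em[k] += _residue_weights(sym)
    em /= em.sum(axis=1, keepdims=True)

    bg = np.full(4, float(pseudocount))
    for s in seqs:
        for sym in s:
            if sym != "-":
                bg += _residue_weights(sym)
    bg /= bg.sum()

    # Per-position transition counts from each training sequence's state path.
    trans = np.full((max(K - 1, 0), 3, 3), float(pseudocount))
    is_match = np.zeros(ncol, dtype=bool)
    is_match[match_cols] = True
    match_rank = np.cumsum(is_match)  # 1-based match position at each column
    for s in seqs:
        path: list[tuple[int, int]] = []  # (state, position k in 1..K)
        for col, sym in enumerate(s):
            if is_match[col]:
                path.append((_M if sym != "-" else _D, match_rank[col]))
            elif sym != "-":
                k = match_rank[col]
                if 1 <= k < K:  # ignore flanking inserts
                    path.append((_I, k))
        for (s0, k0), (s1, _k1) in zip(path, path[1:]):
            if 1 <= k0 <= K - 1:
                trans[k0 - 1, s0, s1] += 1.0
    if K > 1:
        trans /= trans.sum(axis=2, keepdims=True)

    hmm = ProfileHMM(
        match_emissions=em,
        insert_emissions=bg.copy(),
        background=bg,
        transitions=trans,
        tau=tau,
    )
    train_scores = [forward_log_odds(hmm, s.replace("-", "")) for s in seqs]
    hmm.cutoff_bits = 0.5 * min(train_scores)
    return hmm


def _encode_strict(seq: str) -> np.ndarray:
    if not seq:
        raise ValueError("empty sequence")
    out = np.empty(len(seq), dtype=np.intp)
    for i, c in enumerate(seq):
        if c not in _AMBIG or c == "-":
            raise ValueError(f"invalid symbol {c!r} in sequence")
        # Ambiguity codes are scored as their most general reading: emit the
        # first base of the code set (rare in practice; gaps are rejected).
        out[i] = _NT_INDEX[_AMBIG[c][0]]
    return out


def _log(p: np.ndarray | float) -> np.ndarray | float:
    with np.errstate(divide="ignore"):
        return np.log(p)


def _score(hmm: ProfileHMM, seq: str, viterbi: bool = False) -> float:
    """Forward (sum over paths) or Viterbi (best path) log2 odds.

    The delete-state chain within each emission step is a max-plus /
    log-sum-exp prefix scan, so the whole recursion is vectorised over
    profile positions.
    """
    x = _encode_strict(seq)
    n = x.size
    K = hmm.n_match_states
    NEG = -np.inf
    lem = _log(hmm.match_emissions)  # (K, 4)
    lei = _log(hmm.insert_emissions)
    lbg = _log(hmm.background)
    ltau = math.log(hmm.tau)
    lkeep = math.log1p(-hmm.tau)
    lt = _log(hmm.transitions) if K > 1 else np.zeros((0, 3, 3))
    lentry = -math.log(K)

    if viterbi:
        pair, reduce_, accum = np.maximum, np.max, np.maximum.accumulate
    else:
        pair, reduce_, accum = (
            np.logaddexp,
            np.logaddexp.reduce,
            np.logaddexp.accumulate,
        )

    if K > 1:
        tMM = lkeep + lt[:, _M, _M]
        tMI = lkeep + lt[:, _M, _I]
        tMD = lkeep + lt[:, _M, _D]
        tIM, tII, tID = lt[:, _I, _M], lt[:, _I, _I], lt[:, _I, _D]
        tDM, tDI, tDD = lt[:, _D, _M], lt[:, _D, _I], lt[:, _D, _D]
        cumDD = np.cumsum(tDD)  # Pc[k] = sum of D->D log-probs up to position k

    fN_prev = NEG
    B_prev = _LOG_HALF  # start -> B before any emission
    fM_prev = np.full(K, NEG)
    fI_prev = np.full(max(K - 1, 0), NEG)
    fD_prev = np.full(K, NEG)
    E_prev = NEG
    fC_prev = NEG

    with np.errstate(invalid="ignore"):
        for i in range(1, n + 1):
            xi = x[i - 1]
            start_to_N = _LOG_HALF if i == 1 else NEG
            fN = lbg[xi] + pair(start_to_N, fN_prev + _LOG_HALF)
            B = fN + _LOG_HALF
            entry = B_prev + lentry
            fM = np.full(K, NEG)
            fM[0] = lem[0, xi] + entry
            if K > 1:
                incoming = pair(
                    pair(fM_prev[:-1] + tMM, fI_prev + tIM), fD_prev[:-1] + tDM
                )
                fM[1:] = lem[1:, xi] + pair(incoming, entry)
                fI = lei[xi] + pair(
                    pair(fM_prev[:-1] + tMI, fI_prev + tII), fD_prev[:-1] + tDI
                )
                # fD[k] = pair(g[k], fD[k-1] + tDD[k-1]) as a prefix scan:
                g = pair(fM[:-1] + tMD, fI + tID)
                fD = np.full(K, NEG)
                fD[1:] = cumDD + accum(g - cumDD)
                E = pair(pair(fM[K - 1], fD[K - 1]), reduce_(fM[:-1] + ltau))
            else:
                fI = fI_prev
                fD = np.full(K, NEG)
                E = fM[0]
            fC = lbg[xi] + pair(E_prev + _LOG_HALF, fC_prev + _LOG_HALF)
            fN_prev, B_prev, fM_prev, fI_prev, fD_prev, E_prev, fC_prev = (
                float(fN), float(B), fM, fI, fD, float(E), float(fC),
            )

    total = float(pair(E_prev + _LOG_HALF, fC_prev + _LOG_HALF))
    null = float(lbg[x].sum())
    return (total - null) / math.log(2.0)


def forward_log_odds(hmm: ProfileHMM, seq: str) -> float:
    """log2 P(seq | profile) / P(seq | background), summed over all paths."""
    return _score(hmm, seq, viterbi=False)


def viterbi_log_odds(hmm: ProfileHMM, seq: str) -> float:
    """log2 odds of the single best state path (always <= forward)."""
    return _score(hmm, seq, viterbi=True)


@dataclass(frozen=True)
class ScreenResult:
    kept: tuple[BarcodeRecord, ...]
    flagged: tuple[BarcodeRecord, ...]
    scores: dict[str, float] = field(default_factory=dict)

    def to_tsv(self, stream) -> None:
        stream.write("record_id\tscore_bits\tflagged\n")
        flagged_ids = {r.record_id for r in self.flagged}
        for rid, s in self.scores.items():
            stream.write(f"{rid}\t{s:.4f}\t{int(rid in flagged_ids)}\n")


def screen(
    records: Iterable[BarcodeRecord],
    hmm: ProfileHMM,
    threshold_bits: float | None = None,
) -> ScreenResult:
    """Partition records into (kept, flagged) by forward log-odds.

    Records scoring at or above the threshold are flagged as
    contaminant-like.  The default threshold is the profile's calibrated
    cutoff (see :func:`build_profile_hmm`); pass an explicit value (e.g.
    ``0.0`` for the raw log-odds sign) to override.  Screening is
    deterministic given the profile and threshold.
    """
    if threshold_bits is None:
        threshold_bits = hmm.cutoff_bits if hmm.cutoff_bits is not None else 0.0
    kept: list[BarcodeRecord] = []
    flagged: list[BarcodeRecord] = []
    scores: dict[str, float] = {}
    for rec in records:
        s = forward_log_odds(hmm, rec.sequence)
        scores[rec.record_id] = s
        (flagged if s >= threshold_bits else kept).append(rec)
    return ScreenResult(kept=tuple(kept), flagged=tuple(flagged), scores=scores)
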