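"""Kimura 2-parameter distances and distance-matrix assembly.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions.
With P and Q the observed proportions of transition- and transversion-
differing sites among comparable sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites where either sequence shows a gap or a non-ACGT symbol are excluded
pair-by-pair (complete-pair deletion within each pair, not listwise across
the alignment).  Saturated pairs, where a log argument is non-positive, and
pairs with no comparable sites yield an *undefined* distance, represented as
NaN and excluded (with a count) from every downstream summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from barcodekit.align import AlignedPair, ScoringScheme, needleman_wunsch
from barcodekit.taxa import BarcodeDataset

__all__ = [
    "SiteCounts",
    "DistanceMatrix",
    "count_site_patterns",
    "k2p_distance",
    "distance_matrix",
    "encode_acgt",
    "site_counts_from_arrays",
]

# A,C,G,T -> 0..3; everything else (gaps, ambiguity codes) -> 255.
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENC[_c] = _i
_PURINE = np.array([True, False, True, False])  # A, G purines; C, T pyrimidines


def encode_acgt(seq: str) -> np.ndarray:
    """uint8 encoding with A,C,G,T -> 0..3 and any other symbol -> 255."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SiteCounts:
    """Comparable-site tally for one aligned pair."""

    L: int
    n_ts: int
    n_tv: int

    def __post_init__(self) -> None:
        if self.n_ts + self.n_tv > self.L:
            raise ValueError("differing sites exceed comparable sites")

    @property
    def P(self) -> float:
        """Transition proportion n_ts/L (0 when L=0)."""
        return self.n_ts / self.L if self.L else 0.0

    @property
    def Q(self) -> float:
        """Transversion proportion n_tv/L (0 when L=0)."""
        return self.n_tv / self.L if self.L else 0.0


def count_site_patterns(pair: AlignedPair) -> SiteCounts:
    """Count comparable sites, transitions, and transversions in a pair.

    Columns with a gap or non-ACGT symbol on either side are dropped from L.
    """
    ea, eb = encode_acgt(pair.seq_a), encode_acgt(pair.seq_b)
    return site_counts_from_arrays(ea, eb)


def site_counts_from_arrays(ea: np.ndarray, eb: np.ndarray) -> SiteCounts:
    """Vectorised site-pattern counting over encoded sequences (0..3 / 255)."""
    ok = (ea < 4) & (eb < 4)
    a, b = ea[ok], eb[ok]
    diff = a != b
    same_class = _PURINE[a] == _PURINE[b]
    n_ts = int(np.count_nonzero(diff & same_class))
    n_tv = int(np.count_nonzero(diff & ~same_class))
    return SiteCounts(L=int(ok.sum()), n_ts=n_ts, n_tv=n_tv)


def k2p_distance(counts: SiteCounts) -> float:
    """K2P distance in substitutions/site; NaN when undefined.

    Undefined when there are no comparable sites or the distance is
    saturated (1-2P-Q <= 0 or 1-2Q <= 0).
    """
    if counts.L == 0:
        return math.nan
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise-distance matrix with explicit undefined entries.

    ``values`` is a square float array aligned with ``ids``; undefined
    distances are NaN (never silently zero); the diagonal is zero.
    ``metadata`` records provenance (alignment mode, scoring scheme).
    """

    ids: list[str]
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.diag(v), 0.0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        if not np.array_equal(np.isnan(v), np.isnan(v.T)) or not np.allclose(
            np.nan_to_num(v), np.nan_to_num(v.T)
        ):
            raise ValueError("matrix must be symmetric")
        self.values = v
        self._pos = {rid: i for i, rid in enumerate(self.ids)}

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._pos[id_a], self._pos[id_b]])

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path_or_buf) -> None:
        self.to_dataframe().to_csv(path_or_buf, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path_or_buf) -> "DistanceMatrix":
        df = pd.read_csv(path_or_buf, sep="\t", index_col=0, na_values=["NA"])
        return cls(ids=[str(c) for c in df.columns], values=df.to_numpy(dtype=float))


def _pairwise_global(records, scheme: ScoringScheme) -> np.ndarray:
    n = len(records)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = needleman_wunsch(records[i].sequence, records[j].sequence, scheme)
            d = k2p_distance(count_site_patterns(pair))
            out[i, j] = out[j, i] = d
    return out


def _pre_aligned(records) -> np.ndarray:
    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        raise ValueError(
            f"pre-aligned mode requires equal-length sequences, got lengths {sorted(lengths)}"
        )
    enc = np.stack([encode_acgt(r.sequence) for r in records])
    ok = enc < 4
    purine = np.where(ok, _PURINE[np.where(ok, enc, 0)], False)
    n = len(records)
    out = np.zeros((n, n))
    for i in range(n):
        both = ok[i] & ok[i + 1 :]
        diff = (enc[i] != enc[i + 1 :]) & both
        ts = diff & (purine[i] == purine[i + 1 :])
        L = both.sum(axis=1)
        n_ts = ts.sum(axis=1)
        n_tv = diff.sum(axis=1) - n_ts
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(L > 0, n_ts / np.maximum(L, 1), 0.0)
            Q = np.where(L > 0, n_tv / np.maximum(L, 1), 0.0)
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        d = np.where((L > 0) & (w1 > 0) & (w2 > 0), d, np.nan)
        out[i, i + 1 :] = d
        out[i + 1 :, i] = d
    return out


def distance_matrix(
    dataset: BarcodeDataset,
    mode: str = "pairwise-global",
    scheme: ScoringScheme | None = None,
) -> DistanceMatrix:
    """K2P distances over all record pairs of a dataset.

    ``pairwise-global`` (default) aligns each pair with Needleman-Wunsch and
    is self-contained; ``pre-aligned`` expects equal-length gapped input from
    an upstream multiple alignment.  The two agree exactly when input
    sequences are gap-free and of equal length.
    """
    if mode not in {"pairwise-global", "pre-aligned"}:
        raise ValueError(f"unknown mode {mode!r}")
    scheme = scheme or ScoringScheme()
    records = list(dataset.records)
    if mode == "pairwise-global":
        values = _pairwise_global(records, scheme)
    else:
        values = _pre_aligned(records)
    return DistanceMatrix(
        ids=[r.record_id for r in records],
        values=values,
        metadata={
            "model": "K2P",
            "mode": mode,
            "deletion": "complete-pair, per pair",
            "scheme": None if mode == "pre-aligned" else vars(scheme) | {},
        },
    )
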