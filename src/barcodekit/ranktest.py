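"""Wilcoxon signed-rank comparison of marker divergences.

Markers are compared on paired per-genus mean inter-specific distances: each
genus qualifying (>= 2 species) under *both* markers contributes one paired
observation.  The default test is the two-sided normal approximation

    z = (W+ - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24)

with zero differences dropped before ranking, midranks for ties, and — by
design — no continuity correction and no tie correction to the variance:
this is the variant whose p-values match the published per-marker
comparisons digit-for-digit.  An exact-null p (full sign-flip distribution)
is available for n <= 25, computed by the generating-polynomial count, which
is identical to enumerating all 2^n sign assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from barcodekit.divergence import InterMetrics

__all__ = [
    "RankTestResult",
    "wilcoxon_signed_rank",
    "exact_null_pvalue",
    "paired_divergence_vectors",
    "pairwise_marker_tests",
]


@dataclass(frozen=True)
class RankTestResult:
    W_plus: float
    W_minus: float
    n: int
    z: float
    p_two_sided: float
    direction: str  # "first > second" | "second > first" | "equal"
    method: str = "normal-approx"

    def __post_init__(self) -> None:
        if self.W_plus < 0 or self.W_minus < 0:
            raise ValueError("rank sums must be non-negative")


def _signed_ranks(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = x - y
    d = d[d != 0.0]
    ranks = stats.rankdata(np.abs(d)) if d.size else np.array([])
    return d, ranks


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "normal-approx",
    tie_correction: bool = False,
) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test of paired samples.

    ``method`` is ``"normal-approx"`` (default; no continuity correction;
    variance tie correction only if ``tie_correction``) or ``"exact"``
    (full null distribution, n <= 25; midranks are handled by doubling).
    All-zero differences give the degenerate result (n=0, p=1, equal).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("x and y must be equal-length 1-d sequences, length >= 1")
    d, ranks = _signed_ranks(x, y)
    n = int(d.size)
    if n == 0:
        return RankTestResult(0.0, 0.0, 0, 0.0, 1.0, "equal", method)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    if w_plus > w_minus:
        direction = "first > second"
    elif w_minus > w_plus:
        direction = "second > first"
    else:
        direction = "equal"

    if method == "normal-approx":
        z, p = _normal_approx(w_plus, n, ranks if tie_correction else None)
    elif method == "exact":
        if n > 25:
            raise ValueError(f"exact method allowed for n <= 25, got n={n}")
        p = _exact_pvalue_from_ranks(w_plus, ranks)
        z = _normal_approx(w_plus, n, None)[0]
    else:
        raise ValueError(f"unknown method {method!r}")
    return RankTestResult(w_plus, w_minus, n, z, p, direction, method)


def _normal_approx(
    w_plus: float, n: int, ranks: np.ndarray | None
) -> tuple[float, float]:
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    if ranks is not None:
        # Standard tie correction: subtract sum(t^3 - t)/48 over tie groups.
        _, counts = np.unique(ranks, return_counts=True)
        var -= float(((counts**3 - counts) / 48.0).sum())
    if var <= 0:
        return 0.0, 1.0
    z = (w_plus - mean) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return float(z), float(p)


def _wplus_counts(weights: np.ndarray) -> np.ndarray:
    """Number of sign assignments reaching each value of W+ (integer weights).

    Generating-polynomial product of (1 + t^w); equivalent to enumerating
    all 2^n sign vectors.
    """
    total = int(weights.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for w in weights:
        w = int(w)
        new = counts.copy()
        new[w:] += counts[: total + 1 - w]
        counts = new
    return counts


def _exact_pvalue_from_ranks(w_plus: float, ranks: np.ndarray) -> float:
    # Midranks are multiples of 1/2: double everything to stay integral.
    doubled = np.round(ranks * 2).astype(int)
    counts = _wplus_counts(doubled)
    total = counts.sum()
    w2 = int(round(w_plus * 2))
    p_le = counts[: w2 + 1].sum() / total
    p_ge = counts[w2:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def exact_null_pvalue(W: float, n: int) -> float:
    """Two-sided exact p for W+ = ``W`` under the tie-free null, 1 <= n <= 25."""
    if not 1 <= n <= 25:
        raise ValueError(f"n must be in 1..25, got {n}")
    max_w = n * (n + 1) // 2
    if not 0 <= W <= max_w:
        raise ValueError(f"W must be in 0..{max_w}, got {W}")
    return _exact_pvalue_from_ranks(float(W), np.arange(1, n + 1, dtype=float))


def paired_divergence_vectors(
    metrics_a: InterMetrics, metrics_b: InterMetrics
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Paired per-genus mean inter-specific distances for two markers.

    Only genera qualifying (>= 2 species with defined distances) under both
    markers are paired; the genus order (sorted) is returned for audit.
    """
    shared = sorted(set(metrics_a.per_genus) & set(metrics_b.per_genus))
    if not shared:
        raise ValueError("no genus qualifies under both markers")
    x = np.array([metrics_a.per_genus[g][0] for g in shared])
    y = np.array([metrics_b.per_genus[g][0] for g in shared])
    return x, y, shared


def pairwise_marker_tests(
    inter_by_marker: Mapping[str, InterMetrics],
    method: str = "normal-approx",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All marker-pair signed-rank tests, one row per unordered pair.

    The verdict column reads "A>B" / "B>A" when significant at ``alpha``,
    else "A=B".  No multiple-testing adjustment is applied.
    """
    markers = list(inter_by_marker)
    rows = []
    for i, a in enumerate(markers):
        for b in markers[i + 1 :]:
            x, y, genera = paired_divergence_vectors(
                inter_by_marker[a], inter_by_marker[b]
            )
            res = wilcoxon_signed_rank(x, y, method=method)
            if res.p_two_sided < alpha and res.direction == "first > second":
                verdict = f"{a}>{b}"
            elif res.p_two_sided < alpha and res.direction == "second > first":
                verdict = f"{b}>{a}"
            else:
                verdict = f"{a}={b}"
            rows.append(
                {
                    "marker_a": a,
                    "marker_b": b,
                    "W_plus": res.W_plus,
                    "W_minus": res.W_minus,
                    "n": res.n,
                    "n_shared_genera": len(genera),
                    "z": res.z,
                    "p": res.p_two_sided,
                    "verdict": verdict,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "marker_a", "marker_b", "W_plus", "W_minus", "n",
            "n_shared_genera", "z", "p", "verdict",
        ],
    )
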