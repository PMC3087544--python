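"""The six inter-/intra-specific divergence metrics of a barcoding-gap analysis.

Intra-specific variation (species with >= 2 individuals only):
  * average intra-specific distance — all conspecific pairs pooled,
  * theta — per-species mean pairwise distance, averaged over species
    (removes unequal-sampling bias),
  * average coalescent depth — per-species maximum pairwise distance,
    averaged over species.

Inter-specific divergence (genera with >= 2 species only):
  * average inter-specific distance — all congeneric heterospecific pairs
    pooled,
  * theta prime — per-genus mean pairwise distance, averaged over genera
    (removes unequal-species-count bias),
  * minimum inter-specific distance — per-genus smallest heterospecific
    distance, averaged over genera.

Undefined (NaN) distances are skipped and counted, never treated as zero.
When no species (resp. genus) qualifies, the aggregate metrics are NaN and
the qualifying-group count is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from barcodekit.k2p import DistanceMatrix
from barcodekit.taxa import BarcodeDataset

__all__ = [
    "IntraMetrics",
    "InterMetrics",
    "intraspecific_metrics",
    "interspecific_metrics",
    "divergence_table",
]


@dataclass(frozen=True)
class IntraMetrics:
    avg_intra: float
    theta: float
    avg_coalescent_depth: float
    #: species -> (mean, max, n_pairs) over defined conspecific pairs
    per_species: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    n_species: int = 0
    n_pairs: int = 0
    n_undefined: int = 0

    @property
    def computable(self) -> bool:
        return self.n_species > 0


@dataclass(frozen=True)
class InterMetrics:
    avg_inter: float
    theta_prime: float
    min_inter: float
    #: genus -> (mean, min, n_pairs) over defined heterospecific pairs
    per_genus: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    n_genera: int = 0
    n_pairs: int = 0
    n_undefined: int = 0

    @property
    def computable(self) -> bool:
        return self.n_genera > 0


def _pair_distances(matrix: DistanceMatrix, pairs) -> tuple[list[float], int]:
    vals: list[float] = []
    n_undef = 0
    for a, b in pairs:
        d = matrix.get(a, b)
        if math.isnan(d):
            n_undef += 1
        else:
            vals.append(d)
    return vals, n_undef


def intraspecific_metrics(
    matrix: DistanceMatrix, dataset: BarcodeDataset
) -> IntraMetrics:
    """Pooled, species-averaged, and maximum intra-specific distances."""
    per_species: dict[str, tuple[float, float, int]] = {}
    pooled: list[float] = []
    n_undef = 0
    for species, ids in dataset.species_index.items():
        if len(ids) < 2:
            continue
        vals, undef = _pair_distances(matrix, combinations(ids, 2))
        n_undef += undef
        if not vals:
            continue
        per_species[species] = (float(np.mean(vals)), float(np.max(vals)), len(vals))
        pooled.extend(vals)
    if not per_species:
        return IntraMetrics(math.nan, math.nan, math.nan, {}, 0, 0, n_undef)
    means = [m for m, _, _ in per_species.values()]
    maxes = [mx for _, mx, _ in per_species.values()]
    return IntraMetrics(
        avg_intra=float(np.mean(pooled)),
        theta=float(np.mean(means)),
        avg_coalescent_depth=float(np.mean(maxes)),
        per_species=per_species,
        n_species=len(per_species),
        n_pairs=len(pooled),
        n_undefined=n_undef,
    )


def interspecific_metrics(
    matrix: DistanceMatrix,
    dataset: BarcodeDataset,
    include_conspecific: bool = False,
) -> InterMetrics:
    """Pooled, genus-averaged, and minimum inter-specific distances.

    Pairs are individual-level record pairs of *different* species within the
    same genus.  ``include_conspecific=True`` switches theta-prime (and the
    other two aggregates) to the all-pairs-within-genus variant.
    """
    species_of = {rec.record_id: rec.species for rec in dataset}
    per_genus: dict[str, tuple[float, float, int]] = {}
    pooled: list[float] = []
    n_undef = 0
    genus_species: dict[str, set[str]] = {}
    for rec in dataset:
        genus_species.setdefault(rec.genus, set()).add(rec.species)
    for genus, ids in dataset.genus_index.items():
        if len(genus_species[genus]) < 2:
            continue
        pairs = [
            (a, b)
            for a, b in combinations(ids, 2)
            if include_conspecific or species_of[a] != species_of[b]
        ]
        vals, undef = _pair_distances(matrix, pairs)
        n_undef += undef
        if not vals:
            continue
        per_genus[genus] = (float(np.mean(vals)), float(np.min(vals)), len(vals))
        pooled.extend(vals)
    if not per_genus:
        return InterMetrics(math.nan, math.nan, math.nan, {}, 0, 0, n_undef)
    means = [m for m, _, _ in per_genus.values()]
    mins = [mn for _, mn, _ in per_genus.values()]
    return InterMetrics(
        avg_inter=float(np.mean(pooled)),
        theta_prime=float(np.mean(means)),
        min_inter=float(np.mean(mins)),
        per_genus=per_genus,
        n_genera=len(per_genus),
        n_pairs=len(pooled),
        n_undefined=n_undef,
    )


def divergence_table(
    metrics: Mapping[str, tuple[IntraMetrics, InterMetrics]]
) -> pd.DataFrame:
    """One row per marker with the six metrics plus group/pair counts."""
    rows = []
    for marker, (intra, inter) in metrics.items():
        rows.append(
            {
                "marker": marker,
                "avg_inter": inter.avg_inter,
                "theta_prime": inter.theta_prime,
                "min_inter": inter.min_inter,
                "avg_intra": intra.avg_intra,
                "theta": intra.theta,
                "avg_coalescent_depth": intra.avg_coalescent_depth,
                "n_genera": inter.n_genera,
                "n_inter_pairs": inter.n_pairs,
                "n_species": intra.n_species,
                "n_intra_pairs": intra.n_pairs,
                "n_undefined": intra.n_undefined + inter.n_undefined,
            }
        )
    columns = [
        "marker", "avg_inter", "theta_prime", "min_inter",
        "avg_intra", "theta", "avg_coalescent_depth",
        "n_genera", "n_inter_pairs", "n_species", "n_intra_pairs", "n_undefined",
    ]
    return pd.DataFrame(rows, columns=columns)
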