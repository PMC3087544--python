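"""Taxonomically structured sequence simulation with known truth.

Datasets are generated on star phylogenies at each rank: a uniform-random
root, genus ancestors diverged from it by ``genus_branch`` expected
substitutions/site, species ancestors diverged from their genus ancestor by
``inter_branch``, and individuals diverged from their species ancestor by
``intra_branch`` — all under the Kimura 2-parameter substitution process
with transition/transversion rate ratio ``kappa`` (exact closed-form site
transition probabilities, so the expected pairwise divergence between two
tips is analytically known: the sum of the branch lengths separating them).

Star topologies and exact site probabilities are deliberate: they keep every
expected divergence analytic, which is what the downstream property checks
need.  No indels are simulated, so every emitted set is trivially aligned
(equal length, gap-free).

All randomness flows from one seed through named sub-streams, so adding new
operations never perturbs existing fixtures, and the same seed reproduces a
dataset byte-for-byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from barcodekit.taxa import BarcodeRecord

__all__ = [
    "SimConfig",
    "TruthEntry",
    "TruthTable",
    "substream",
    "k2p_site_probs",
    "evolve",
    "simulate_dataset",
    "plant_cross_species_identicals",
    "simulate_contaminants",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def substream(seed: int, *names: str) -> np.random.Generator:
    """Named child RNG of a global seed (stable across code changes)."""
    key = tuple(zlib.crc32(n.encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated marker dataset.

    Branch lengths are expected substitutions/site; two conspecific
    individuals are separated by ``2*intra_branch``, two congeneric
    individuals of different species by ``2*(inter_branch + intra_branch)``.
    Defaults emulate a small herbarium-style survey: a few dozen genera with
    one to a few species each, one to a few individuals per species, ~250 bp
    marker sequences, intra-specific divergence well below inter-specific.
    """

    marker: str = "SIM"
    n_genera: int = 20
    species_per_genus: int | tuple[int, int] = (1, 4)
    individuals_per_species: int | tuple[int, int] = (1, 3)
    seq_length: int = 250
    genus_branch: float = 0.15
    inter_branch: float = 0.05
    intra_branch: float = 0.005
    kappa: float = 2.0
    contaminant_branch: float = 0.02
    n_cross_species_identicals: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genus_branch", "inter_branch", "intra_branch", "contaminant_branch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")
        if self.seq_length < 100:
            raise ValueError("seq_length must be >= 100 (default length filter)")
        if self.n_genera < 1:
            raise ValueError("n_genera must be >= 1")
        if self.n_cross_species_identicals < 0:
            raise ValueError("n_cross_species_identicals must be >= 0")
        for name in ("species_per_genus", "individuals_per_species"):
            v = getattr(self, name)
            if isinstance(v, int):
                ok = v >= 1
            else:
                ok = len(v) == 2 and 1 <= v[0] <= v[1]
            if not ok:
                raise ValueError(f"{name} must be a count >= 1 or an increasing range")


@dataclass
class TruthEntry:
    genus: str
    species: str
    partner: str | None = None  # planted identical-sequence partner record id
    origin: str = "plant"  # "plant" | "contaminant"


@dataclass
class TruthTable:
    """record id -> true labels, plus the simulation's root sequence."""

    entries: dict[str, TruthEntry] = field(default_factory=dict)
    root_sequence: str = ""

    def to_tsv(self, stream) -> None:
        stream.write("record_id\tgenus\tspecies\tpartner\torigin\n")
        for rid, e in self.entries.items():
            stream.write(
                f"{rid}\t{e.genus}\t{e.species}\t{e.partner or 'none'}\t{e.origin}\n"
            )


def k2p_site_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(total transversion)) after branch length ``d``.

    Closed-form K2P site probabilities with the rate matrix scaled to one
    expected substitution per site per unit branch length.
    """
    beta = 1.0 / (kappa + 2.0)
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (kappa + 1.0) * beta * d)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.5 - 0.5 * e1
    return float(p_ts), float(p_tv)


def evolve(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded (0..3) sequence along a branch of length ``d``."""
    p_ts, p_tv = k2p_site_probs(d, kappa)
    u = rng.random(seq.size)
    out = seq.copy()
    # With A,C,G,T -> 0..3: XOR 2 is the transition partner; XOR 1 and XOR 3
    # are the two transversion partners.
    out[u < p_ts] ^= 2
    out[(u >= p_ts) & (u < p_ts + 0.5 * p_tv)] ^= 1
    out[(u >= p_ts + 0.5 * p_tv) & (u < p_ts + p_tv)] ^= 3
    return out


def _decode(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


def _draw_count(spec: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(spec, int):
        return spec
    return int(rng.integers(spec[0], spec[1] + 1))


def _root(config: SimConfig) -> np.ndarray:
    rng = substream(config.seed, "root", config.marker)
    return rng.integers(0, 4, size=config.seq_length).astype(np.uint8)


def simulate_dataset(config: SimConfig) -> tuple[list[BarcodeRecord], TruthTable]:
    """Generate a marker dataset plus its truth table.

    The taxonomy layout (how many species per genus, individuals per
    species) is drawn from a marker-independent sub-stream, so two configs
    differing only in ``marker`` share samples — which is what cross-marker
    pairing and combination analyses require.
    """
    layout_rng = substream(config.seed, "taxonomy")
    evo_rng = substream(config.seed, "evolve", config.marker)
    root = _root(config)
    records: list[BarcodeRecord] = []
    truth = TruthTable(root_sequence=_decode(root))
    for g in range(1, config.n_genera + 1):
        genus = f"Genus{g:02d}"
        genus_anc = evolve(root, config.genus_branch, config.kappa, evo_rng)
        n_species = _draw_count(config.species_per_genus, layout_rng)
        for s in range(1, n_species + 1):
            species = f"{genus} species{s}"
            species_anc = evolve(genus_anc, config.inter_branch, config.kappa, evo_rng)
            n_ind = _draw_count(config.individuals_per_species, layout_rng)
            for i in range(1, n_ind + 1):
                tip = evolve(species_anc, config.intra_branch, config.kappa, evo_rng)
                sample = f"g{g:02d}s{s:02d}i{i:02d}"
                rid = f"{config.marker}-{sample}"
                records.append(
                    BarcodeRecord(
                        record_id=rid,
                        marker=config.marker,
                        genus=genus,
                        species=species,
                        sequence=_decode(tip),
                    )
                )
                truth.entries[rid] = TruthEntry(genus=genus, species=species)
    if config.n_cross_species_identicals:
        plant_rng = substream(config.seed, "plant-identicals", config.marker)
        records, truth = plant_cross_species_identicals(
            records, truth, config.n_cross_species_identicals, plant_rng
        )
    return records, truth


def plant_cross_species_identicals(
    records: list[BarcodeRecord],
    truth: TruthTable,
    k: int,
    rng: np.random.Generator,
) -> tuple[list[BarcodeRecord], TruthTable]:
    """Make ``k`` record pairs in different species of the same genus
    sequence-identical (the failure mode behind sub-100% success rates).

    Pairs are species-disjoint, so expected identification failures are
    exactly 2k records.  Raises when fewer than ``k`` such pairs exist.
    """
    if k == 0:
        return records, truth
    by_genus: dict[str, dict[str, list[int]]] = {}
    for idx, rec in enumerate(records):
        by_genus.setdefault(rec.genus, {}).setdefault(rec.species, []).append(idx)
    candidates: list[tuple[int, int]] = []
    used_species: set[str] = set()
    genera = sorted(by_genus)
    rng.shuffle(genera)
    for genus in genera:
        species = sorted(s for s in by_genus[genus] if s not in used_species)
        rng.shuffle(species)
        while len(species) >= 2 and len(candidates) < k:
            sa, sb = species.pop(), species.pop()
            ia = by_genus[genus][sa][0]
            ib = by_genus[genus][sb][0]
            candidates.append((ia, ib))
            used_species.update((sa, sb))
        if len(candidates) >= k:
            break
    if len(candidates) < k:
        raise ValueError(
            f"cannot plant {k} cross-species identical pairs: only "
            f"{len(candidates)} disjoint congeneric species pairs available"
        )
    records = list(records)
    for ia, ib in candidates:
        donor, receiver = records[ia], records[ib]
        records[ib] = replace(receiver, sequence=donor.sequence)
        truth.entries[donor.record_id].partner = receiver.record_id
        truth.entries[receiver.record_id].partner = donor.record_id
    return records, truth


def simulate_contaminants(
    profile_divergence: float,
    n: int,
    config: SimConfig,
    truth: TruthTable | None = None,
    stream: str = "contaminants",
) -> list[BarcodeRecord]:
    """Sequences evolved from a contaminant root ``profile_divergence``
    substitutions/site away from the plant root.

    The contaminant root is derived from its own sub-stream, so repeated
    calls (e.g. a training set and a test set, distinguished by ``stream``)
    share one contaminant lineage.  Each record sits ``contaminant_branch``
    from that root.  When ``truth`` is given, entries with origin
    ``"contaminant"`` are added.
    """
    if n == 0:
        return []
    root_rng = substream(config.seed, "contaminant-root", config.marker)
    contam_root = evolve(_root(config), profile_divergence, config.kappa, root_rng)
    rng = substream(config.seed, stream, config.marker)
    out: list[BarcodeRecord] = []
    for i in range(1, n + 1):
        tip = evolve(contam_root, config.contaminant_branch, config.kappa, rng)
        rid = f"{config.marker}-{stream}-{i:03d}"
        rec = BarcodeRecord(
            record_id=rid,
            marker=config.marker,
            genus="Fungalis",
            species="Fungalis simulatus",
            sequence=_decode(tip),
        )
        out.append(rec)
        if truth is not None:
            truth.entries[rid] = TruthEntry(
                genus=rec.genus, species=rec.species, origin="contaminant"
            )
    return out
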