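"""Taxonomy-annotated FASTA I/O, quality filtering, and dataset bookkeeping.

Barcode sequence sets arrive as multi-FASTA whose headers carry an opaque
identifier (typically a GenBank accession) plus the Latin binomial of the
source organism.  This module parses those headers into :class:`BarcodeRecord`
objects, applies the standard download hygiene filters (minimum length,
ambiguous-base cap, unnamed "sp." taxa), and builds the species/genus indices
every downstream divergence and identification step relies on.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from Bio import SeqIO

__all__ = [
    "BarcodeRecord",
    "FilterReport",
    "BarcodeDataset",
    "DatasetSummary",
    "HEADER_SCHEMES",
    "parse_fasta",
    "write_fasta",
    "quality_filter",
    "dataset_summary",
]

# IUPAC nucleotide codes, N, and the gap character used in aligned FASTA.
_VALID_CHARS = frozenset("ACGTRYSWKMBDHVN-")

#: Built-in header schemes.  Each regex must expose ``id`` and ``binomial``
#: named groups.  "pipe" parses ``>AB123|Aster tataricus``; "whitespace"
#: parses ``>AB123 Aster tataricus``.
HEADER_SCHEMES: dict[str, str] = {
    "pipe": r"^(?P<id>[^|]+)\|(?P<binomial>\S+(?:\s+\S+)+)\s*$",
    "whitespace": r"^(?P<id>\S+)\s+(?P<binomial>\S+(?:\s+\S+)+)\s*$",
}


class FastaParseError(ValueError):
    """Raised for malformed FASTA entries or headers not matching the scheme."""


@dataclass
class BarcodeRecord:
    """One barcode sequence with its taxonomic labels.

    ``genus`` is always the first whitespace-delimited token of ``species``
    (the Latin binomial); the constructor enforces this invariant.
    """

    record_id: str
    marker: str
    genus: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.record_id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"record {self.record_id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        first = self.species.split()[0] if self.species.split() else ""
        if self.genus != first:
            raise ValueError(
                f"record {self.record_id!r}: genus {self.genus!r} is not the "
                f"first token of species {self.species!r}"
            )

    @property
    def ungapped_length(self) -> int:
        return len(self.sequence) - self.sequence.count("-")

    @property
    def n_ambiguous(self) -> int:
        """Count of 'N' symbols (the download-hygiene ambiguity measure)."""
        return self.sequence.count("N")


@dataclass
class FilterReport:
    """Tally of the quality filter; each record counts under the first rule
    that removes it (short -> ambiguous -> unnamed)."""

    n_input: int = 0
    n_too_short: int = 0
    n_too_ambiguous: int = 0
    n_unnamed: int = 0
    n_kept: int = 0

    def __post_init__(self) -> None:
        total = self.n_too_short + self.n_too_ambiguous + self.n_unnamed + self.n_kept
        if total != self.n_input:
            raise ValueError(
                f"filter report categories sum to {total}, expected {self.n_input}"
            )

    def to_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_too_short": self.n_too_short,
            "n_too_ambiguous": self.n_too_ambiguous,
            "n_unnamed": self.n_unnamed,
            "n_kept": self.n_kept,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        d = self.to_dict()
        return "\t".join(d) + "\n" + "\t".join(str(v) for v in d.values()) + "\n"


@dataclass
class BarcodeDataset:
    """A marker's records plus species and genus indices (id partitions)."""

    marker: str
    records: list[BarcodeRecord]
    species_index: dict[str, list[str]] = field(init=False)
    genus_index: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ValueError(f"duplicate record id {rec.record_id!r}")
            seen.add(rec.record_id)
        self.species_index = {}
        self.genus_index = {}
        for rec in self.records:
            self.species_index.setdefault(rec.species, []).append(rec.record_id)
            self.genus_index.setdefault(rec.genus, []).append(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self, record_id: str) -> BarcodeRecord:
        for rec in self.records:
            if rec.record_id == record_id:
                return rec
        raise KeyError(record_id)

    @property
    def record_ids(self) -> list[str]:
        return [rec.record_id for rec in self.records]


@dataclass(frozen=True)
class DatasetSummary:
    """Dataset composition counts: total sequences, sequences in genera with
    >1 species, sequences in species with >1 sample, and distinct taxa."""

    n_total: int
    n_in_multispecies_genera: int
    n_in_multisample_species: int
    n_species: int
    n_genera: int

    def to_dict(self) -> dict[str, int]:
        return {
            "n_total": self.n_total,
            "n_in_multispecies_genera": self.n_in_multispecies_genera,
            "n_in_multisample_species": self.n_in_multisample_species,
            "n_species": self.n_species,
            "n_genera": self.n_genera,
        }


def _normalize_sequence(raw: str, where: str) -> str:
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise FastaParseError(f"entry {where!r}: empty sequence")
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise FastaParseError(
            f"entry {where!r}: invalid sequence characters {sorted(bad)!r}"
        )
    return seq


def parse_fasta(
    stream: TextIO | str,
    marker: str = "unknown",
    header_scheme: str = "pipe",
) -> list[BarcodeRecord]:
    """Parse taxonomy-annotated FASTA into records.

    Parameters
    ----------
    stream : text stream or path
    marker : marker name stored on every record (not encoded in FASTA headers)
    header_scheme : a key of :data:`HEADER_SCHEMES` or a custom regex with
        named groups ``id`` and ``binomial``.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``.  Genus is
    derived as the first token of the binomial.  Malformed entries raise
    :class:`FastaParseError` naming the offending header.
    """
    pattern = re.compile(HEADER_SCHEMES.get(header_scheme, header_scheme))
    if not {"id", "binomial"} <= set(pattern.groupindex):
        raise ValueError(
            f"header scheme must define 'id' and 'binomial' groups: {header_scheme!r}"
        )
    records: list[BarcodeRecord] = []
    for entry in SeqIO.parse(stream, "fasta"):
        header = entry.description
        m = pattern.match(header)
        if m is None:
            raise FastaParseError(
                f"header {header!r} does not match scheme {header_scheme!r}"
            )
        seq = _normalize_sequence(str(entry.seq), header)
        binomial = m.group("binomial").strip()
        records.append(
            BarcodeRecord(
                record_id=m.group("id").strip(),
                marker=marker,
                genus=binomial.split()[0],
                species=binomial,
                sequence=seq,
            )
        )
    return records


def write_fasta(records: Iterable[BarcodeRecord], stream: TextIO) -> None:
    """Write records in the ``>id|Genus species`` pipe scheme.

    Round-trips with :func:`parse_fasta` (same marker argument) field-for-field.
    """
    for rec in records:
        stream.write(f">{rec.record_id}|{rec.species}\n{rec.sequence}\n")


def _is_unnamed(species: str) -> bool:
    # Exact token "sp." anywhere in the name, case-insensitive.  "cf." and
    # "aff." qualifiers denote tentative but *named* taxa and are kept.
    return any(tok.lower() == "sp." for tok in species.split())


def quality_filter(
    records: Iterable[BarcodeRecord],
    min_len: int = 100,
    max_ambig: int = 15,
    drop_unnamed: bool = True,
) -> tuple[list[BarcodeRecord], FilterReport]:
    """Apply the download hygiene filters.

    Removes, in order: sequences shorter than ``min_len`` (strictly; exactly
    ``min_len`` is kept), sequences with more than ``max_ambig`` ``N`` symbols
    (exactly ``max_ambig`` is kept), and — when ``drop_unnamed`` — sequences
    of unnamed species ("sp." token in the binomial).  Lengths ignore gap
    characters so aligned input filters identically to unaligned input.
    """
    kept: list[BarcodeRecord] = []
    n_short = n_ambig = n_unnamed = 0
    records = list(records)
    for rec in records:
        if rec.ungapped_length < min_len:
            n_short += 1
        elif rec.n_ambiguous > max_ambig:
            n_ambig += 1
        elif drop_unnamed and _is_unnamed(rec.species):
            n_unnamed += 1
        else:
            kept.append(rec)
    report = FilterReport(
        n_input=len(records),
        n_too_short=n_short,
        n_too_ambiguous=n_ambig,
        n_unnamed=n_unnamed,
        n_kept=len(kept),
    )
    return kept, report


def dataset_summary(dataset: BarcodeDataset) -> DatasetSummary:
    """Composition counts analogous to a per-marker dataset table row."""
    n_total = len(dataset)
    genus_species: dict[str, set[str]] = {}
    for rec in dataset:
        genus_species.setdefault(rec.genus, set()).add(rec.species)
    n_multi_genus = sum(
        1 for rec in dataset if len(genus_species[rec.genus]) >= 2
    )
    n_multi_species = sum(
        1 for rec in dataset if len(dataset.species_index[rec.species]) >= 2
    )
    return DatasetSummary(
        n_total=n_total,
        n_in_multispecies_genera=n_multi_genus,
        n_in_multisample_species=n_multi_species,
        n_species=len(dataset.species_index),
        n_genera=len(dataset.genus_index),
    )
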