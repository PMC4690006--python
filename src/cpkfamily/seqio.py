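"""Protein FASTA input/output and the packaged gene-family-size table.

All user-facing coordinates in this package are 1-based and inclusive.
Sequences are case-normalized to upper case on input. The accepted residue
alphabet is the 20 standard amino acids plus ``X`` (unknown); aligned
sequences may additionally contain the gap character ``-``. Other ambiguity
codes (``B``, ``Z``, ``U``, ``*``) are rejected with an explicit error.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = STANDARD_AA | {"X"}
GAP = "-"

CLADES = frozenset(
    {"dicot", "monocot", "lower-eukaryote", "bryophyte", "pteridophyte", "gymnosperm"}
)


class FastaError(ValueError):
    """Malformed FASTA input (duplicate id, illegal residue, empty file...)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identifier and optional free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FastaError(f"record id must be a non-empty token, got {self.id!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise FastaError(f"record {self.id!r} has an empty sequence")
        allowed = PROTEIN_ALPHABET | {GAP}
        for pos, c in enumerate(self.sequence, start=1):
            if c not in allowed:
                raise FastaError(
                    f"record {self.id!r}: illegal character {c!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_gapped(self) -> bool:
        return GAP in self.sequence

    def ungapped(self) -> "ProteinRecord":
        return ProteinRecord(self.id, self.sequence.replace(GAP, ""), self.description)


@dataclass(frozen=True)
class Alignment:
    """An ordered collection of equal-length gapped protein records."""

    records: tuple[ProteinRecord, ...]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise FastaError("an alignment needs at least 2 records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            bad = [r.id for r in self.records if len(r) != len(self.records[0])]
            raise FastaError(f"ragged alignment: records {bad} differ in length")
        _check_unique_ids(self.records)
        object.__setattr__(self, "length", len(self.records[0]))

    def __len__(self) -> int:
        return len(self.records)

    def column(self, i: int) -> str:
        """Residues of 1-based column ``i``, top to bottom, gaps included."""
        return "".join(r.sequence[i - 1] for r in self.records)


@dataclass(frozen=True)
class FamilySizeRecord:
    """One species row of the packaged genome-size / CPK-count table."""

    species: str
    clade: str
    genome_mb: float
    loci: int
    cpk_count: int

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise ValueError(f"unknown clade {self.clade!r} for {self.species!r}")
        if self.genome_mb <= 0:
            raise ValueError(f"{self.species!r}: genome size must be positive")
        if self.loci < 0 or self.cpk_count < 0:
            raise ValueError(f"{self.species!r}: counts must be non-negative")


def _check_unique_ids(records: Iterable[ProteinRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise FastaError(f"duplicate record id {r.id!r}")
        seen.add(r.id)


def _parse_fasta(path: str | Path, allow_gaps: bool) -> list[ProteinRecord]:
    path = Path(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not allow_gaps and GAP in seq:
            raise FastaError(f"record {rec.id!r}: gap character in unaligned FASTA")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(rec.id, seq, desc))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    _check_unique_ids(records)
    return records


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read unaligned protein FASTA; order preserved, sequences upper-cased."""
    return _parse_fasta(path, allow_gaps=False)


def read_alignment(path: str | Path) -> Alignment:
    """Read aligned (gapped) FASTA into an :class:`Alignment`."""
    return Alignment(tuple(_parse_fasta(path, allow_gaps=True)))


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, sequence lines wrapped at 60 columns."""
    _check_unique_ids(records)
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(seqrecords, fh, "fasta")


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    write_fasta(alignment.records, path)


def load_table1_fixture() -> list[FamilySizeRecord]:
    """Load the packaged 40-species genome-size / CPK-family-size table.

    The table is reproduced verbatim from its printed source; its cpk_count
    column sums to 951 (see docs/methods.md for the one-off discrepancy with
    the 950 headline figure).
    """
    rows: list[FamilySizeRecord] = []
    with resources.files("cpkfamily.data").joinpath("family_sizes.tsv").open(
        "r", encoding="utf-8"
    ) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                FamilySizeRecord(
                    species=row["species"],
                    clade=row["clade"],
                    genome_mb=float(row["genome_mb"]),
                    loci=int(row["loci"]),
                    cpk_count=int(row["cpk_count"]),
                )
            )
    return rows
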