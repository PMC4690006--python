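"""Orthology-based CPK naming.

Each query gene is named ``<prefix>CPK<number>[-<suffix>]``:

* the prefix is the genus initial (upper case) plus the species initial
  (lower case), extended with further species letters on collision
  (``Cr`` for Capsella rubella, ``Crein`` for Chlamydomonas reinhardtii);
* the ortholog number is taken from the best-scoring labeled reference
  (Oryza-set for monocots, Arabidopsis-set otherwise), scored by global
  alignment (BLOSUM62, affine gaps, BLAST-style open 11 / extend 1, so a
  length-L gap costs 11 + L);
* co-orthologous paralogs sharing one (prefix, number) receive suffixes
  -1, -2, ... ordered by descending score, then input order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import ProteinRecord, read_fasta

_LABEL_RE = re.compile(r"CPK(\d+)$")


@dataclass(frozen=True)
class ReferenceEntry:
    label: str  # e.g. "CPK16"
    number: int
    record: ProteinRecord


@dataclass(frozen=True)
class NamingReference:
    """A labeled reference set (``Arabidopsis-set`` or ``Oryza-set``)."""

    source: str
    entries: tuple[ReferenceEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("reference set must be non-empty")
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("reference labels must be unique")

    @classmethod
    def from_records(cls, records: Sequence[ProteinRecord], source: str) -> "NamingReference":
        entries = []
        for r in records:
            m = _LABEL_RE.match(r.id) or _LABEL_RE.search(r.id)
            if not m:
                raise ValueError(
                    f"reference id {r.id!r} carries no CPK<number> label"
                )
            entries.append(ReferenceEntry(label=f"CPK{int(m.group(1))}",
                                          number=int(m.group(1)), record=r))
        return cls(source=source, entries=tuple(entries))

    @classmethod
    def from_fasta(cls, path: str | Path, source: str) -> "NamingReference":
        return cls.from_records(read_fasta(path), source)


@dataclass(frozen=True)
class AssignedName:
    query_id: str
    prefix: str
    ortholog_number: int
    paralog_suffix: Optional[int]
    full_name: str
    best_score: float
    reference_label: str


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST convention: a gap of length L costs gap_open + L * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align_score(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Optimal global alignment score under affine gap costs (deterministic)."""
    sa = a.sequence if isinstance(a, ProteinRecord) else a.upper()
    sb = b.sequence if isinstance(b, ProteinRecord) else b.upper()
    if not sa or not sb:
        raise ValueError("alignment score undefined for an empty sequence")
    return float(_aligner(matrix, gap_open, gap_extend).score(sa, sb))


class PrefixRegistry:
    """Deterministic genus/species prefix assignment with collision resolution.

    The candidate prefix is the genus initial (upper) plus the species
    initial (lower); on collision the species part is extended letter by
    letter until unique. ``species_letters`` forces a longer species part up
    front (the published ``Crein`` form takes four species letters at once).
    Repeated calls for the same (genus, species) return the registered
    prefix unchanged.
    """

    def __init__(self) -> None:
        self._by_species: dict[tuple[str, str], str] = {}
        self._taken: set[str] = set()

    def assign(self, genus: str, species: str, species_letters: int = 1) -> str:
        if not genus.isalpha() or not species.isalpha():
            raise ValueError("genus and species must be non-empty alphabetic")
        key = (genus.lower(), species.lower())
        if key in self._by_species:
            return self._by_species[key]
        for k in range(species_letters, len(species) + 1):
            candidate = genus[0].upper() + species[:k].lower()
            if candidate not in self._taken:
                self._taken.add(candidate)
                self._by_species[key] = candidate
                return candidate
        raise ValueError(
            f"cannot build a unique prefix for {genus} {species}: species epithet exhausted"
        )


def make_prefix(genus: str, species: str, registry: PrefixRegistry,
                species_letters: int = 1) -> str:
    """Assign (or look up) the naming prefix for one species."""
    return registry.assign(genus, species, species_letters)


def name_genes(
    queries: Sequence[ProteinRecord],
    genus: str,
    species: str,
    is_monocot: bool,
    references: Sequence[NamingReference],
    registry: Optional[PrefixRegistry] = None,
    species_letters: int = 1,
) -> list[AssignedName]:
    """Assign orthology-based names to all queries of one species.

    The reference set is the Oryza-set for monocots, the Arabidopsis-set
    otherwise. Score ties go to the smaller ortholog number.
    """
    if not queries:
        return []
    wanted = "Oryza-set" if is_monocot else "Arabidopsis-set"
    by_source = {ref.source: ref for ref in references}
    if wanted not in by_source:
        raise ValueError(f"no reference set with source {wanted!r}")
    refset = by_source[wanted]
    registry = registry or PrefixRegistry()
    prefix = make_prefix(genus, species, registry, species_letters)

    best: list[tuple[int, float, str]] = []  # (number, score, label) per query
    for q in queries:
        scores = [(e.number, global_align_score(q, e.record), e.label)
                  for e in refset.entries]
        # maximal score; ties toward the smaller reference number
        number, score, label = max(scores, key=lambda s: (s[1], -s[0]))
        best.append((number, score, label))

    by_number: dict[int, list[int]] = {}
    for qi, (number, _score, _label) in enumerate(best):
        by_number.setdefault(number, []).append(qi)

    names: list[Optional[AssignedName]] = [None] * len(queries)
    for number, members in by_number.items():
        if len(members) == 1:
            qi = members[0]
            names[qi] = AssignedName(
                query_id=queries[qi].id,
                prefix=prefix,
                ortholog_number=number,
                paralog_suffix=None,
                full_name=f"{prefix}CPK{number}",
                best_score=best[qi][1],
                reference_label=best[qi][2],
            )
        else:
            ordered = sorted(members, key=lambda qi: (-best[qi][1], qi))
            for suffix, qi in enumerate(ordered, start=1):
                names[qi] = AssignedName(
                    query_id=queries[qi].id,
                    prefix=prefix,
                    ortholog_number=number,
                    paralog_suffix=suffix,
                    full_name=f"{prefix}CPK{number}-{suffix}",
                    best_score=best[qi][1],
                    reference_label=best[qi][2],
                )
    return [n for n in names if n is not None]


def demo_reference_set(source: str = "Arabidopsis-set", seed: int = 101,
                       numbers: Sequence[int] = (1, 2, 3, 4, 16, 17)) -> NamingReference:
    """A tiny synthetic demonstration reference set (not real proteomes).

    Deterministically generated CPK-like sequences labeled CPK<n>; useful for
    examples and tests where a labeled ortholog panel is needed offline.
    """
    from . import synthgen

    records = []
    for i, n in enumerate(numbers):
        rec, _truth = synthgen.generate_cpk("higher", seed=seed + i, mutation_rate=0.0)
        records.append(ProteinRecord(f"CPK{n}", rec.sequence, "synthetic reference"))
    return NamingReference.from_records(records, source)
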