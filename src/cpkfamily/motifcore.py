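"""Dash-delimited positional motif notation: parsing, matching, catalogs.

The notation covers the forms used throughout the CPK literature for
position-specific conserved motifs:

* exact residues: ``D-x-D`` (aspartate, anything, aspartate)
* alternations: ``D/E-E-L`` (D or E, then E, then L), including mid-pattern
  forms like ``D-V/I-W-S``
* wildcard runs: ``E-D-x_(4)_-A-F`` expands the ``x_(4)`` token to four
  wildcard positions
* an alternation with the wildcard (``V/x``, ``L/x``) is unrestricted and is
  parsed as a plain wildcard

Matching is positional and exhaustive: every (possibly overlapping) start is
reported. ``X`` (unknown residue) is matched only by wildcard positions —
exact and alternation positions never match it (conservative annotation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .seqio import GAP, STANDARD_AA, ProteinRecord

# A position spec: frozenset of allowed residues, or None for a wildcard.
PositionSpec = Optional[frozenset]

_XRUN = re.compile(r"^x_?\((\d+)\)_?$", re.IGNORECASE)


class MotifParseError(ValueError):
    """Raised for malformed dash-notation motif text."""


@dataclass(frozen=True)
class MotifPattern:
    """A parsed positional pattern; ``positions[i] is None`` means wildcard."""

    text: str
    positions: tuple[PositionSpec, ...]

    @property
    def length(self) -> int:
        return len(self.positions)

    def matches_at(self, sequence: str, start0: int) -> bool:
        """Whether the pattern matches ``sequence`` at 0-based ``start0``."""
        if start0 < 0 or start0 + self.length > len(sequence):
            return False
        for spec, residue in zip(self.positions, sequence[start0:start0 + self.length]):
            if spec is not None and residue not in spec:
                return False
        return True


@dataclass(frozen=True)
class MotifHit:
    """A located occurrence of a pattern (1-based, inclusive coordinates)."""

    pattern_text: str
    start: int
    end: int
    matched: str


@dataclass(frozen=True)
class MotifCatalog:
    name: str
    patterns: tuple[MotifPattern, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"catalog {self.name!r} has no patterns")


def _parse_token(token: str) -> list[PositionSpec]:
    if token == "x":
        return [None]
    m = _XRUN.match(token)
    if m:
        k = int(m.group(1))
        if k < 1:
            raise MotifParseError(f"wildcard run {token!r}: count must be >= 1")
        return [None] * k
    if "/" in token:
        members = token.split("/")
        if any(not m for m in members):
            raise MotifParseError(f"malformed alternation token {token!r}")
        if any(m == "x" for m in members):
            # "V/x" = V or anything = unrestricted
            return [None]
        residues = frozenset(members)
        if not residues <= STANDARD_AA:
            raise MotifParseError(f"unknown residue in alternation token {token!r}")
        if len(residues) < 2:
            raise MotifParseError(f"alternation token {token!r} needs 2 distinct residues")
        return [residues]
    if token in STANDARD_AA:
        return [frozenset(token)]
    raise MotifParseError(f"unknown token {token!r}")


def parse_pattern(text: str) -> MotifPattern:
    """Parse dash-delimited motif ``text`` into a :class:`MotifPattern`."""
    if not text or not text.strip():
        raise MotifParseError("empty motif text")
    positions: list[PositionSpec] = []
    for token in text.strip().split("-"):
        positions.extend(_parse_token(token))
    return MotifPattern(text.strip(), tuple(positions))


def find_matches(pattern: MotifPattern, seq: ProteinRecord | str) -> list[MotifHit]:
    """All (overlapping) occurrences of ``pattern`` in ``seq``, sorted by start."""
    sequence = seq.sequence if isinstance(seq, ProteinRecord) else seq.upper()
    if GAP in sequence:
        raise ValueError("find_matches requires an ungapped sequence")
    hits = []
    for start0 in range(len(sequence) - pattern.length + 1):
        if pattern.matches_at(sequence, start0):
            hits.append(
                MotifHit(
                    pattern_text=pattern.text,
                    start=start0 + 1,
                    end=start0 + pattern.length,
                    matched=sequence[start0:start0 + pattern.length],
                )
            )
    return hits


# --------------------------------------------------------------------------
# Built-in catalogs.
#
# The canonical pattern strings are the wildcard (in-text) forms; figure
# captions sometimes show fully resolved variants of the same motifs (e.g.
# C-S-G-G-E-L-F-D-R-I for C-x-G-G-E-L-x-D-R-I) which are not duplicated here.

KINASE_HIGHER = (
    "C-x-G-G-E-L-x-D-R-I",
    "H-R-D-L-K-P-E-N-F-L",
    "D-x-V-G-S-x-Y-Y",
    "A-P-E-V-L",
    "D-V/I-W-S",
    "G-V-I-x-Y-I-L-L",
    "G-x-P-P-F-W",
    "P-W-P-x-I-S",
    "A-K-D-L-V",
    "H-P-W",
)

KINASE_LOWER = (
    "M-E-L-C-x-G-G-E-L-F",
    "H-R-D-L-K-P-E-N-F-L",
    "D-F-G-L-S-V/x",
    "A-P-E-V-L/x",
    "D-I-W-S-x-G-V",
    "P-F-W",
)

AUTOINHIBITORY_HIGHER = ("K-P-L-D", "F-S-A-M-N-K-L", "A-L-x-x-I-A")

AUTOINHIBITORY_LOWER = ("A-M-N-K-L",)

EFHAND_COMMON = (
    "E-E-I/x",
    "E-M-F",
    "D-x-D",
    "G-x-I",
    "D-E-L",
    "D/E-E-L",
    "D/E-x-E",
    "D-x-x-E-F",
    "D-Y-x-E-F",
    "D-x-x-E",
    "E-D-x_(4)_-A-F",
    "F-D-x-D",
    "E-E-L",
    "D-G-x-I",
    "D-G-R/x-I",
    "Y-x-E-F-x-x-M-M",
)

# N-terminal acylation consensus strings (exact prefixes of the protein).
ACYLATION_CONSENSUS = (
    "MGNC",
    "MGNCC",
    "MGC",
    "MGNTCV",
    "QFGTTYLC",
    "MGNCCR",
    "MGLC",
    "MGGC",
    "MGNNC",
    "MGSC",
    "MGNSC",
    "QFGTTFLC",
    "MGIC",
    "MGNCNAC",
    "MGQC",
    "MGNAC",
    "QFGTTYQC",
    "MGNVC",
    "MGVC",
    "MGNQC",
    "QFGVTYLC",
    "QFGITYLC",
    "VHLVMELC",
    "MGNCNTC",
    "MELC",
)

_CATALOG_SOURCES: dict[str, tuple[str, ...]] = {
    "kinase-higher": KINASE_HIGHER,
    "kinase-lower": KINASE_LOWER,
    "autoinhibitory-higher": AUTOINHIBITORY_HIGHER,
    "autoinhibitory-lower": AUTOINHIBITORY_LOWER,
    "efhand-common": EFHAND_COMMON,
    "acylation": tuple("-".join(s) for s in ACYLATION_CONSENSUS),
}


def builtin_catalogs() -> list[MotifCatalog]:
    """All built-in catalogs, parsed and ready for matching."""
    return [
        MotifCatalog(name, tuple(parse_pattern(t) for t in texts))
        for name, texts in _CATALOG_SOURCES.items()
    ]


def get_catalog(name: str) -> MotifCatalog:
    try:
        texts = _CATALOG_SOURCES[name]
    except KeyError:
        raise KeyError(
            f"unknown catalog {name!r}; available: {sorted(_CATALOG_SOURCES)}"
        ) from None
    return MotifCatalog(name, tuple(parse_pattern(t) for t in texts))


def format_catalog(catalog: MotifCatalog) -> str:
    """Render a catalog as a plain-text motif list (one pattern per line)."""
    lines = [f"# catalog: {catalog.name}"]
    lines += [p.text for p in catalog.patterns]
    return "\n".join(lines) + "\n"


def parse_catalog_text(text: str, name: str = "custom") -> MotifCatalog:
    """Parse a plain-text motif list ('#' comments and blank lines ignored)."""
    patterns = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        patterns.append(parse_pattern(line))
    return MotifCatalog(name, tuple(patterns))
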