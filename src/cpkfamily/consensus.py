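"""Position-indexed consensus calling from a protein alignment.

Re-expresses the classical high/low consensus-level procedure as explicit
per-column frequency rules so that positional motifs (D-x-D, D/E-E-L, ...)
can be re-derived from data:

* residue fraction >= theta_high (default 0.90)   -> exact call, 'D'
* D+E pooled fraction >= theta_high, both present -> acidic alternation 'D/E'
* residue fraction >= theta_low (default 0.50)    -> low-consensus call, 'd'
* otherwise                                       -> wildcard 'x'

Gaps are excluded from the denominator; an all-gap column is a wildcard with
zero depth. Motif strings are then extracted as runs of columns anchored on
high-consensus symbols (low-consensus symbols and wildcards are emitted as
'x'), broken wherever more than two consecutive unanchored columns occur.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

from .motifcore import MotifPattern, parse_pattern
from .seqio import GAP, Alignment


@dataclass(frozen=True)
class ConsensusConfig:
    theta_high: float = 0.90
    theta_low: float = 0.50
    acidic_pooling: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_low < self.theta_high <= 1.0):
            raise ValueError(
                "thresholds must satisfy 0 < theta_low < theta_high <= 1"
            )


@dataclass(frozen=True)
class ConsensusColumn:
    """One alignment column: residue counts (gaps excluded) and its symbol.

    Symbol forms: upper-case residue (high consensus), 'D/E' (pooled acidic
    high consensus), lower-case residue (low consensus), 'x' (wildcard).
    """

    column: int  # 1-based
    counts: Mapping[str, int]
    symbol: str

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def is_anchor(self) -> bool:
        """High-consensus columns anchor emitted motifs."""
        return self.symbol == "D/E" or (len(self.symbol) == 1 and self.symbol.isupper())


@dataclass(frozen=True)
class ConsensusMotif:
    """A motif emitted from consensus columns, with its 1-based start column."""

    start_column: int
    pattern: MotifPattern


def column_consensus(counts: Mapping[str, int], config: ConsensusConfig = ConsensusConfig()) -> str:
    """Consensus symbol for one column's residue counts (gaps excluded)."""
    depth = sum(counts.values())
    if depth < 1:
        raise ValueError("empty column: non-gap depth must be >= 1")
    top_count = max(counts.values())
    # count ties break toward the alphabetically first residue
    top_res = min(r for r, c in counts.items() if c == top_count)
    if top_count / depth >= config.theta_high:
        return top_res
    if config.acidic_pooling:
        acidic = counts.get("D", 0) + counts.get("E", 0)
        if (
            acidic / depth >= config.theta_high
            and counts.get("D", 0) > 0
            and counts.get("E", 0) > 0
        ):
            return "D/E"
    if top_count / depth >= config.theta_low:
        return top_res.lower()
    return "x"


def derive_consensus(
    alignment: Alignment, config: ConsensusConfig = ConsensusConfig()
) -> list[ConsensusColumn]:
    """One :class:`ConsensusColumn` per alignment column."""
    columns = []
    for i in range(1, alignment.length + 1):
        counts = Counter(alignment.column(i))
        counts.pop(GAP, None)
        if not counts:
            columns.append(ConsensusColumn(i, {}, "x"))
        else:
            columns.append(ConsensusColumn(i, dict(counts), column_consensus(counts, config)))
    return columns


def consensus_to_motifs(
    columns: list[ConsensusColumn],
    min_anchored: int = 2,
    max_span: int = 10,
) -> list[ConsensusMotif]:
    """Extract dash-notation motifs from consensus columns.

    Anchors are high-consensus columns; runs of anchors separated by at most
    two unanchored columns are grouped, trimmed to start and end on anchors,
    and emitted when they carry at least ``min_anchored`` anchors within a
    span of at most ``max_span`` columns. Over-long groups are split greedily
    from the left.
    """
    anchor_idx = [i for i, c in enumerate(columns) if c.is_anchor]
    groups: list[list[int]] = []
    for idx in anchor_idx:
        if groups and idx - groups[-1][-1] - 1 <= 2:
            groups[-1].append(idx)
        else:
            groups.append([idx])

    motifs: list[ConsensusMotif] = []
    for group in groups:
        start = 0
        while start < len(group):
            # extend from group[start] while the span stays within max_span
            end = start
            while end + 1 < len(group) and group[end + 1] - group[start] + 1 <= max_span:
                end += 1
            anchors = group[start:end + 1]
            if len(anchors) >= min_anchored:
                first, last = anchors[0], anchors[-1]
                tokens = [
                    columns[i].symbol if columns[i].is_anchor else "x"
                    for i in range(first, last + 1)
                ]
                motifs.append(
                    ConsensusMotif(
                        start_column=columns[first].column,
                        pattern=parse_pattern("-".join(tokens)),
                    )
                )
            start = end + 1
    return motifs


def consensus_string(columns: list[ConsensusColumn]) -> str:
    """Whole-alignment consensus rendered in dash notation, for inspection."""
    return "-".join(c.symbol for c in columns)
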