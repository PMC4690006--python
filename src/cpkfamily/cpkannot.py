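"""CPK architecture annotation.

A protein qualifies as a CPK when it shows, in order along the sequence:
kinase-domain evidence (>= 3 distinct catalog motifs), an auto-inhibitory
junction motif, and exactly four calcium-binding EF-hands. Each EF-hand is
modeled as a 26-residue frame with 1-based internal positions; the acidic
loop signature D-x-D sits at frame positions 14-16 and D/E-E-L at 24-26.
The lower-eukaryote variant D-x-x-E is anchored to the same frame as
D at 14 with E at 17.

Lineage profile is called from the EF-hand flags:

* higher-plant: all four hands carry D-x-D and at least two carry D/E-E-L;
* lower-eukaryote: exactly two hands carry D-x-D and at least one carries
  D-x-x-E;
* otherwise indeterminate.

The annotator also calls N-terminal acylation (myristoylation requires G at
position 2; palmitoylation additionally requires an N-terminal consensus
prefix or a cysteine at positions 3-6, and is conditional on myristoylation)
and computes physico-chemical properties (average molecular mass, isoelectric
point by bisection, residue composition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from . import motifcore
from .motifcore import MotifHit, find_matches, get_catalog
from .seqio import GAP, ProteinRecord

logger = logging.getLogger(__name__)

EF_WINDOW = 26
ACIDIC = frozenset("DE")

# Candidate EF-hand frames must satisfy at least 3 of these 4 core rules
# (1-based frame positions): D@14, D@16, acidic@24-or-25, L@26. The 3-of-4
# threshold keeps lower-eukaryote hands (no full D/E-E-L) detectable.
CORE_SCORE_THRESHOLD = 3

REJECT_NO_KINASE = "no kinase evidence"
REJECT_NO_AUTOINHIB = "no auto-inhibitory evidence"
REJECT_FEW_EFHANDS = "fewer than 4 EF-hands"

# pKa convention (EMBOSS-style) for the isoelectric point.
_PKA_POSITIVE = {"nterm": 8.6, "H": 6.5, "K": 10.8, "R": 12.5}
_PKA_NEGATIVE = {"cterm": 3.6, "C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1}
_PI_TOL = 0.001


def core_score(window: str) -> int:
    """Count of satisfied core EF-hand rules for a 26-residue frame."""
    if len(window) != EF_WINDOW:
        raise ValueError(f"EF-hand frame must be {EF_WINDOW} residues")
    score = 0
    score += window[13] == "D"
    score += window[15] == "D"
    score += (window[23] in ACIDIC) or (window[24] in ACIDIC)
    score += window[25] == "L"
    return score


@dataclass(frozen=True)
class EFHandAnnotation:
    """One detected EF-hand window with its positional motif flags."""

    index: int  # 1..4
    start: int  # 1-based position of the frame in the protein
    window: str
    has_dxd: bool = field(init=False)
    has_del: bool = field(init=False)
    has_dxxe: bool = field(init=False)
    specific_flags: dict = field(init=False)

    def __post_init__(self) -> None:
        w = self.window
        if len(w) != EF_WINDOW:
            raise ValueError(f"EF-hand window must be {EF_WINDOW} residues")
        object.__setattr__(self, "has_dxd", w[13] == "D" and w[15] == "D")
        object.__setattr__(
            self, "has_del", w[23] in ACIDIC and w[24] == "E" and w[25] == "L"
        )
        object.__setattr__(self, "has_dxxe", w[13] == "D" and w[16] == "E")
        specific: dict[str, bool] = {}
        if self.index == 1:
            # E-E-I/x at 1-3 ("I/x" leaves position 3 unrestricted); E-M-F at 8-10
            specific["ee_i"] = w[0] == "E" and w[1] == "E"
            specific["emf"] = w[7:10] == "EMF"
        elif self.index == 2:
            specific["exe"] = w[2] == "E" and w[4] == "E"
        elif self.index == 3:
            specific["xed"] = w[2] == "E" and w[3] == "D"
        elif self.index == 4:
            specific["de_11_12"] = w[10] in ACIDIC and w[11] in ACIDIC
        object.__setattr__(self, "specific_flags", specific)


@dataclass(frozen=True)
class AcylationCall:
    myristoylation: bool
    palmitoylation_motif: Optional[str]
    palmitoylation: bool

    def __post_init__(self) -> None:
        if self.palmitoylation and not self.myristoylation:
            raise ValueError("palmitoylation requires myristoylation")


@dataclass(frozen=True)
class PhyschemProfile:
    length_aa: int
    mass_kda: Optional[float]
    pi: Optional[float]
    composition: dict
    note: Optional[str] = None


@dataclass(frozen=True)
class CPKAnnotation:
    record_id: str
    is_cpk: bool
    reject_reason: Optional[str]
    lineage_profile: str  # higher-plant | lower-eukaryote | indeterminate
    clade_used: str  # higher | lower (catalog set the evidence came from)
    kinase_hits: tuple[MotifHit, ...]
    kinase_motifs_matched: tuple[str, ...]
    autoinhibitory_hits: tuple[MotifHit, ...]
    ef_hands: tuple[EFHandAnnotation, ...]
    acylation: AcylationCall
    physchem: PhyschemProfile


def detect_ef_hands(
    seq: ProteinRecord | str, search_start: int = 1
) -> list[EFHandAnnotation]:
    """Detect up to four non-overlapping EF-hand frames from ``search_start``.

    Slides a 26-residue frame, scores each against the four core rules, keeps
    frames with score >= 3 as candidates, and greedily selects up to four
    mutually non-overlapping candidates preferring higher score, then smaller
    start. Returns the selection in sequence order with all flags computed.
    """
    sequence = seq.sequence if isinstance(seq, ProteinRecord) else seq.upper()
    if GAP in sequence:
        raise ValueError("detect_ef_hands requires an ungapped sequence")
    if search_start < 1:
        raise ValueError("search_start must be >= 1")
    candidates: list[tuple[int, int]] = []  # (start0, score)
    for start0 in range(search_start - 1, len(sequence) - EF_WINDOW + 1):
        score = core_score(sequence[start0:start0 + EF_WINDOW])
        if score >= CORE_SCORE_THRESHOLD:
            candidates.append((start0, score))
    selected: list[int] = []
    for start0, _score in sorted(candidates, key=lambda c: (-c[1], c[0])):
        if len(selected) == 4:
            break
        if all(abs(start0 - s) >= EF_WINDOW for s in selected):
            selected.append(start0)
    selected.sort()
    return [
        EFHandAnnotation(index=i, start=s + 1, window=sequence[s:s + EF_WINDOW])
        for i, s in enumerate(selected, start=1)
    ]


def call_acylation(seq: ProteinRecord | str) -> AcylationCall:
    """N-terminal acylation flags from the first residues of the protein."""
    sequence = seq.sequence if isinstance(seq, ProteinRecord) else seq.upper()
    if len(sequence) < 2:
        raise ValueError("acylation call needs a sequence of length >= 2")
    myristoylation = sequence[1] == "G"
    motif = None
    for consensus in sorted(motifcore.ACYLATION_CONSENSUS, key=len, reverse=True):
        if sequence.startswith(consensus):
            motif = consensus
            break
    cys_3_6 = "C" in sequence[2:6]
    palmitoylation = myristoylation and (motif is not None or cys_3_6)
    return AcylationCall(myristoylation, motif, palmitoylation)


def _isoelectric_point(sequence: str) -> float:
    from collections import Counter

    counts = Counter(sequence)

    def net_charge(ph: float) -> float:
        charge = 1.0 / (1.0 + 10 ** (ph - _PKA_POSITIVE["nterm"]))
        for res in "HKR":
            charge += counts[res] / (1.0 + 10 ** (ph - _PKA_POSITIVE[res]))
        charge -= 1.0 / (1.0 + 10 ** (_PKA_NEGATIVE["cterm"] - ph))
        for res in "CDEY":
            charge -= counts[res] / (1.0 + 10 ** (_PKA_NEGATIVE[res] - ph))
        return charge

    lo, hi = 0.0, 14.0
    while hi - lo > _PI_TOL:
        mid = (lo + hi) / 2.0
        if net_charge(mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def physchem(seq: ProteinRecord | str) -> PhyschemProfile:
    """Length, average molecular mass (kDa), pI, and residue composition.

    Mass and pI are undefined (None, with a note) when the sequence contains
    unknown residues; composition tolerates ``X``.
    """
    sequence = seq.sequence if isinstance(seq, ProteinRecord) else seq.upper()
    if GAP in sequence:
        raise ValueError("physchem requires an ungapped sequence")
    n = len(sequence)
    composition = {res: sequence.count(res) / n for res in sorted(set(sequence))}
    if "X" in sequence:
        return PhyschemProfile(
            length_aa=n,
            mass_kda=None,
            pi=None,
            composition=composition,
            note="mass/pI undefined: sequence contains unknown residues (X)",
        )
    mass_da = ProteinAnalysis(sequence).molecular_weight()
    return PhyschemProfile(
        length_aa=n,
        mass_kda=mass_da / 1000.0,
        pi=_isoelectric_point(sequence),
        composition=composition,
    )


def _kinase_evidence(sequence: str, clade: str) -> tuple[tuple[str, ...], list[MotifHit]]:
    catalog = get_catalog(f"kinase-{clade}")
    matched: list[str] = []
    hits: list[MotifHit] = []
    for pattern in catalog.patterns:
        phits = find_matches(pattern, sequence)
        if phits:
            matched.append(pattern.text)
            hits.extend(phits)
    hits.sort(key=lambda h: (h.start, h.end))
    return tuple(matched), hits


def annotate(
    seq: ProteinRecord, clade_hint: Optional[str] = None
) -> CPKAnnotation:
    """Full CPK architecture verdict for one protein.

    Kinase evidence requires >= 3 distinct motifs from one clade's kinase
    catalog (both catalogs are tried when no hint is given; the clade with
    more distinct motifs wins, ties to higher). Auto-inhibitory evidence is
    a catalog motif downstream of the first kinase hit; among such hits the
    one whose downstream region yields the most EF-hands is kept (ties to
    the latest hit, i.e. the one closest to the EF-hand region).
    """
    if seq.is_gapped:
        raise ValueError("annotate requires an ungapped sequence")
    if clade_hint is not None and clade_hint not in ("higher", "lower"):
        raise ValueError("clade_hint must be 'higher' or 'lower'")
    sequence = seq.sequence

    clades = (clade_hint,) if clade_hint else ("higher", "lower")
    evidence = {c: _kinase_evidence(sequence, c) for c in clades}
    clade = max(clades, key=lambda c: (len(evidence[c][0]), c == "higher"))
    kinase_motifs, kinase_hits = evidence[clade]

    acylation = call_acylation(seq) if len(sequence) >= 2 else AcylationCall(False, None, False)
    phys = physchem(seq)

    def build(
        is_cpk: bool,
        reason: Optional[str],
        lineage: str,
        autoinhib: list[MotifHit],
        hands: list[EFHandAnnotation],
    ) -> CPKAnnotation:
        logger.debug(
            "%s: clade=%s kinase_motifs=%d autoinhib=%d ef_hands=%d -> %s",
            seq.id, clade, len(kinase_motifs), len(autoinhib), len(hands),
            reason or "CPK",
        )
        return CPKAnnotation(
            record_id=seq.id,
            is_cpk=is_cpk,
            reject_reason=reason,
            lineage_profile=lineage,
            clade_used=clade,
            kinase_hits=tuple(kinase_hits),
            kinase_motifs_matched=kinase_motifs,
            autoinhibitory_hits=tuple(autoinhib),
            ef_hands=tuple(hands),
            acylation=acylation,
            physchem=phys,
        )

    if len(kinase_motifs) < 3:
        return build(False, REJECT_NO_KINASE, "indeterminate", [], [])

    first_kinase_end = kinase_hits[0].end
    autoinhib_catalog = get_catalog(f"autoinhibitory-{clade}")
    autoinhib_hits: list[MotifHit] = []
    for pattern in autoinhib_catalog.patterns:
        autoinhib_hits.extend(
            h for h in find_matches(pattern, sequence) if h.start > first_kinase_end
        )
    autoinhib_hits.sort(key=lambda h: (h.start, h.end))
    if not autoinhib_hits:
        return build(False, REJECT_NO_AUTOINHIB, "indeterminate", [], [])

    best_hit = None
    best_hands: list[EFHandAnnotation] = []
    for hit in autoinhib_hits:
        hands = detect_ef_hands(sequence, search_start=hit.end + 1)
        if best_hit is None or len(hands) >= len(best_hands):
            best_hit, best_hands = hit, hands
    assert best_hit is not None

    if len(best_hands) < 4:
        return build(False, REJECT_FEW_EFHANDS, "indeterminate", [best_hit], best_hands)

    n_dxd = sum(h.has_dxd for h in best_hands)
    n_del = sum(h.has_del for h in best_hands)
    n_dxxe = sum(h.has_dxxe for h in best_hands)
    if n_dxd == 4 and n_del >= 2:
        lineage = "higher-plant"
    elif n_dxd == 2 and n_dxxe >= 1:
        lineage = "lower-eukaryote"
    else:
        lineage = "indeterminate"
    return build(True, None, lineage, [best_hit], best_hands)
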