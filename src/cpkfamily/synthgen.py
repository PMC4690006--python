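"""Synthetic CPK-like sequence generation with a ground-truth ledger.

Every generated protein follows the canonical CPK layout: an N-terminal
acylation prefix drawn from the consensus catalog, a variable linker, a
kinase block carrying several catalog motifs embedded in random background,
an auto-inhibitory junction motif, four 26-residue EF-hand windows carrying
the profile's positional motifs, and a C-terminal tail. Profiles:

* ``higher`` (higher plant): all four windows carry D@14/D@16 (D-x-D) and
  D/E@24-E@25-L@26 (D/E-E-L), plus the per-hand extras (E-E at 1-2 and
  E-M-F at 8-10 in hand 1, E@3/E@5 in hand 2, E@3/D@4 in hand 3,
  acidic 11-12 in hand 4);
* ``lower`` (lower eukaryote): D@14 in all four windows, D@16 only in
  windows 3 and 4 (exactly two D-x-D), E@17 in window 1 (the D-x-x-E form).

Background residues are uniform over the 20 standard amino acids. Point
substitutions are applied i.i.d. at ``mutation_rate`` after assembly; the
truth ledger always records pre-mutation positions. A rate-0 draft is
verified against the annotator before being accepted (spurious motif
collisions in random background are resampled), so at mutation rate 0 the
annotation recovers the planted architecture exactly — the module's
defining contract.

All randomness flows from one master seed; per-record streams are derived
with ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import cpkannot
from .motifcore import MotifPattern, get_catalog
from .seqio import Alignment, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.array(list(AA))

PROFILES = ("higher", "lower")
NEGATIVE_KINDS = ("kinase_only", "no_autoinhibitory", "three_efhands", "random")

_PROFILE_NAMES = {"higher": "higher-plant", "lower": "lower-eukaryote"}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated sequence (pre-mutation positions)."""

    record_id: str
    profile: str  # higher-plant | lower-eukaryote | negative-<kind>
    kinase_motifs: tuple[tuple[str, int], ...]  # (pattern text, 1-based start)
    autoinhibitory_motif: Optional[str]
    autoinhibitory_start: Optional[int]
    ef_hand_starts: tuple[int, ...]
    acylation_prefix: Optional[str]
    mutation_rate: float
    seed: int


class GenerationError(RuntimeError):
    pass


def _rand_residues(rng: np.random.Generator, n: int) -> str:
    if n == 0:
        return ""
    return "".join(_AA_ARR[rng.integers(0, 20, n)])


def _instantiate(pattern: MotifPattern, rng: np.random.Generator) -> str:
    out = []
    for spec in pattern.positions:
        if spec is None:
            out.append(AA[rng.integers(0, 20)])
        else:
            members = sorted(spec)
            out.append(members[rng.integers(0, len(members))])
    return "".join(out)


def _choice(rng: np.random.Generator, items: Sequence[str]) -> str:
    return items[rng.integers(0, len(items))]


def _build_window(profile: str, index: int, rng: np.random.Generator) -> str:
    w = list(_rand_residues(rng, cpkannot.EF_WINDOW))
    if profile == "higher":
        w[13] = "D"
        w[15] = "D"
        w[23] = _choice(rng, "DE")
        w[24] = "E"
        w[25] = "L"
        if index == 1:
            w[0] = "E"
            w[1] = "E"
            w[7], w[8], w[9] = "E", "M", "F"
        elif index == 2:
            w[2] = "E"
            w[4] = "E"
        elif index == 3:
            w[2] = "E"
            w[3] = "D"
        elif index == 4:
            w[10] = _choice(rng, "DE")
            w[11] = _choice(rng, "DE")
    elif profile == "lower":
        w[13] = "D"
        w[24] = "E"
        w[25] = "L"
        if index in (3, 4):
            w[15] = "D"
        else:
            while w[15] == "D":  # exactly two D-x-D hands overall
                w[15] = AA[rng.integers(0, 20)]
        if index == 1:
            w[16] = "E"  # the D-x-x-E form, anchored D@14 / E@17
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return "".join(w)


def _mutate(sequence: str, rng: np.random.Generator, rate: float) -> str:
    if rate == 0.0:
        return sequence
    if not 0.0 <= rate < 0.5:
        raise ValueError("mutation_rate must be in [0, 0.5)")
    chars = np.array(list(sequence))
    hit = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hit:
        alternatives = [c for c in AA if c != chars[i]]
        chars[i] = alternatives[rng.integers(0, 19)]
    return "".join(chars)


@dataclass
class _Draft:
    sequence: str
    kinase_motifs: list[tuple[str, int]]
    autoinhibitory_motif: Optional[str]
    autoinhibitory_start: Optional[int]
    ef_hand_starts: list[int]
    acylation_prefix: Optional[str]


def _assemble(
    profile: str,
    rng: np.random.Generator,
    n_ef_hands: int = 4,
    with_autoinhib: bool = True,
    with_ef_region: bool = True,
) -> _Draft:
    from .motifcore import ACYLATION_CONSENSUS

    parts: list[str] = []
    pos = 0  # 0-based length so far

    def push(fragment: str) -> int:
        """Append and return the 1-based start of the fragment."""
        nonlocal pos
        parts.append(fragment)
        start = pos + 1
        pos += len(fragment)
        return start

    prefix = _choice(rng, ACYLATION_CONSENSUS)
    push(prefix)
    push(_rand_residues(rng, int(rng.integers(8, 31))))

    kinase_catalog = get_catalog(f"kinase-{profile}")
    n_motifs = 5 if profile == "higher" else len(kinase_catalog.patterns)
    order = rng.permutation(len(kinase_catalog.patterns))[:n_motifs]
    kinase_motifs: list[tuple[str, int]] = []
    for idx in order:
        pattern = kinase_catalog.patterns[idx]
        start = push(_instantiate(pattern, rng))
        kinase_motifs.append((pattern.text, start))
        push(_rand_residues(rng, int(rng.integers(4, 13))))

    autoinhib_motif = autoinhib_start = None
    if with_autoinhib:
        push(_rand_residues(rng, int(rng.integers(3, 11))))
        catalog = get_catalog(f"autoinhibitory-{profile}")
        pattern = catalog.patterns[rng.integers(0, len(catalog.patterns))]
        autoinhib_start = push(_instantiate(pattern, rng))
        autoinhib_motif = pattern.text

    ef_starts: list[int] = []
    if with_ef_region:
        push(_rand_residues(rng, int(rng.integers(2, 9))))
        for index in range(1, n_ef_hands + 1):
            ef_starts.append(push(_build_window(profile, index, rng)))
            if index < n_ef_hands:
                push(_rand_residues(rng, int(rng.integers(0, 7))))

    push(_rand_residues(rng, int(rng.integers(8, 26))))
    return _Draft(
        sequence="".join(parts),
        kinase_motifs=kinase_motifs,
        autoinhibitory_motif=autoinhib_motif,
        autoinhibitory_start=autoinhib_start,
        ef_hand_starts=ef_starts,
        acylation_prefix=prefix,
    )


def _verify_cpk(draft: _Draft, profile: str, record_id: str) -> bool:
    """Rate-0 cleanliness check: the annotator must recover the plant exactly."""
    ann = cpkannot.annotate(ProteinRecord(record_id, draft.sequence))
    return (
        ann.is_cpk
        and ann.lineage_profile == _PROFILE_NAMES[profile]
        and tuple(h.start for h in ann.ef_hands) == tuple(draft.ef_hand_starts)
    )


_MAX_ATTEMPTS = 80


def _generate_cpk_with_rng(
    profile: str,
    rng: np.random.Generator,
    mutation_rate: float,
    record_id: str,
    seed: int,
    length_range: Optional[tuple[int, int]] = None,
) -> tuple[ProteinRecord, SyntheticTruth]:
    if profile not in PROFILES:
        raise ValueError(f"profile must be one of {PROFILES}")
    for _attempt in range(_MAX_ATTEMPTS):
        draft = _assemble(profile, rng)
        if length_range is not None:
            lo, hi = length_range
            if len(draft.sequence) > hi:
                raise GenerationError(
                    f"length_range {length_range} cannot accommodate the "
                    f"assembled architecture ({len(draft.sequence)} residues)"
                )
            if len(draft.sequence) < lo:
                draft.sequence += _rand_residues(rng, lo - len(draft.sequence))
        if _verify_cpk(draft, profile, record_id):
            break
    else:  # pragma: no cover - would indicate a systematic defect
        raise GenerationError(f"could not generate a clean {profile} sequence")
    mutated = _mutate(draft.sequence, rng, mutation_rate)
    record = ProteinRecord(record_id, mutated)
    truth = SyntheticTruth(
        record_id=record_id,
        profile=_PROFILE_NAMES[profile],
        kinase_motifs=tuple(draft.kinase_motifs),
        autoinhibitory_motif=draft.autoinhibitory_motif,
        autoinhibitory_start=draft.autoinhibitory_start,
        ef_hand_starts=tuple(draft.ef_hand_starts),
        acylation_prefix=draft.acylation_prefix,
        mutation_rate=mutation_rate,
        seed=seed,
    )
    return record, truth


def generate_cpk(
    profile: str,
    seed: int,
    mutation_rate: float = 0.0,
    length_range: Optional[tuple[int, int]] = None,
) -> tuple[ProteinRecord, SyntheticTruth]:
    """Generate one CPK-like protein with its ground-truth ledger entry."""
    rng = np.random.default_rng(seed)
    return _generate_cpk_with_rng(
        profile, rng, mutation_rate, f"syn-{profile}-s{seed}", seed, length_range
    )


def generate_family(
    n: int,
    profile_mix: Optional[dict] = None,
    seed: int = 0,
    mutation_rate: float = 0.0,
) -> tuple[list[ProteinRecord], list[SyntheticTruth]]:
    """Generate ``n`` records (ids syn0001...) with per-record derived seeds.

    ``profile_mix`` maps profile name to weight, default 50/50 higher/lower.
    The profile sequence and per-record random streams are fully determined
    by the master seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = profile_mix or {"higher": 0.5, "lower": 0.5}
    if not set(mix) <= set(PROFILES):
        raise ValueError(f"profiles must be among {PROFILES}")
    weights = np.array([mix.get(p, 0.0) for p in PROFILES], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("profile_mix weights must sum to a positive value")
    weights = weights / weights.sum()

    master = np.random.SeedSequence(seed)
    children = master.spawn(n + 1)
    assign_rng = np.random.default_rng(children[0])
    counts = np.floor(weights * n).astype(int)
    while counts.sum() < n:  # distribute rounding remainder deterministically
        counts[int(np.argmax(weights * n - counts))] += 1
    profiles = [p for p, c in zip(PROFILES, counts) for _ in range(c)]
    assign_rng.shuffle(profiles)

    records, truths = [], []
    for i, profile in enumerate(profiles, start=1):
        rng = np.random.default_rng(children[i])
        rec, truth = _generate_cpk_with_rng(
            profile, rng, mutation_rate, f"syn{i:04d}", seed
        )
        records.append(rec)
        truths.append(truth)
    return records, truths


def generate_negative(kind: str, seed: int) -> tuple[ProteinRecord, SyntheticTruth]:
    """Generate a sequence violating exactly one CPK architecture requirement."""
    if kind not in NEGATIVE_KINDS:
        raise ValueError(f"kind must be one of {NEGATIVE_KINDS}")
    rng = np.random.default_rng(seed)
    record_id = f"neg-{kind}-s{seed}"
    for _attempt in range(_MAX_ATTEMPTS):
        if kind == "kinase_only":
            draft = _assemble("higher", rng, with_autoinhib=False, with_ef_region=False)
            expected_reason = cpkannot.REJECT_NO_AUTOINHIB
        elif kind == "no_autoinhibitory":
            draft = _assemble("higher", rng, with_autoinhib=False)
            expected_reason = cpkannot.REJECT_NO_AUTOINHIB
        elif kind == "three_efhands":
            draft = _assemble("higher", rng, n_ef_hands=3)
            expected_reason = cpkannot.REJECT_FEW_EFHANDS
        else:  # random
            draft = _Draft(_rand_residues(rng, 300), [], None, None, [], None)
            expected_reason = None
        ann = cpkannot.annotate(ProteinRecord(record_id, draft.sequence))
        ok = not ann.is_cpk and (
            expected_reason is None or ann.reject_reason == expected_reason
        )
        if kind == "kinase_only":
            ok = ok and len(ann.kinase_hits) > 0
        if ok:
            truth = SyntheticTruth(
                record_id=record_id,
                profile=f"negative-{kind}",
                kinase_motifs=tuple(draft.kinase_motifs),
                autoinhibitory_motif=draft.autoinhibitory_motif,
                autoinhibitory_start=draft.autoinhibitory_start,
                ef_hand_starts=tuple(draft.ef_hand_starts),
                acylation_prefix=draft.acylation_prefix,
                mutation_rate=0.0,
                seed=seed,
            )
            return ProteinRecord(record_id, draft.sequence), truth
    raise GenerationError(f"could not generate a clean negative of kind {kind!r}")


def generate_neutral_alignment(
    n: int, L: int, seed: int, p_var: float = 0.2
) -> Alignment:
    """Gap-free alignment with i.i.d. exchangeable columns for neutrality tests.

    Each column is monomorphic with probability 1 - p_var; otherwise a single
    alternative residue is carried by k of the n sequences, with k drawn from
    the neutral infinite-sites frequency spectrum P(k) proportional to 1/k
    (k = 1..n-1) and the carrier subset uniform given k. Under this column
    model E[pi - S/a1] = 0, so Tajima's D is centred on zero by construction.
    """
    if n < 4 or L < 1:
        raise ValueError("need n >= 4 sequences and L >= 1 columns")
    if not 0.0 <= p_var <= 1.0:
        raise ValueError("p_var must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k_values = np.arange(1, n)
    k_weights = (1.0 / k_values) / np.sum(1.0 / k_values)
    mat = np.empty((n, L), dtype="<U1")
    for j in range(L):
        base = AA[rng.integers(0, 20)]
        mat[:, j] = base
        if rng.random() < p_var:
            alt = base
            while alt == base:
                alt = AA[rng.integers(0, 20)]
            k = int(rng.choice(k_values, p=k_weights))
            carriers = rng.choice(n, size=k, replace=False)
            mat[carriers, j] = alt
    width = len(str(n))
    records = tuple(
        ProteinRecord(f"taxon{i + 1:0{width}d}", "".join(mat[i]))
        for i in range(n)
    )
    return Alignment(records)


def generate_efhand_alignment(
    n: int,
    ef_index: int = 4,
    profile: str = "higher",
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> Alignment:
    """Gap-free alignment of n independent 26-column EF-hand windows."""
    if n < 2:
        raise ValueError("need n >= 2 windows")
    if ef_index not in (1, 2, 3, 4):
        raise ValueError("ef_index must be 1..4")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        window = _build_window(profile, ef_index, rng)
        records.append(ProteinRecord(f"win{i + 1:04d}", _mutate(window, rng, mutation_rate)))
    return Alignment(tuple(records))
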