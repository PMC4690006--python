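"""Molecular-evolution and family-size statistics.

Implements, from their defining formulas:

* Tajima's relative rate test for three aligned sequences — lineage-specific
  (unique) substitution counts of two ingroup sequences against an outgroup,
  compared by chi^2 = (n_A - n_B)^2 / (n_A + n_B) with 1 degree of freedom;
* Tajima's test of neutrality (D) on amino-acid alignments under complete
  deletion, contrasting mean pairwise diversity pi with the segregating-site
  estimator S/a1, with |D| > 2 flagged significant;
* Pearson correlation and the paired t statistic for the genome-size vs
  family-size comparison, with Student-t critical values;
* the 2^-ddCt relative-expression formula.

Columns containing a gap or an unknown residue (X) in any sequence are
removed before site statistics are computed (complete deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .seqio import GAP, Alignment, FamilySizeRecord, ProteinRecord

MISSING = frozenset({GAP, "X"})

SIGNIFICANT_ABS_D = 2.0


@dataclass(frozen=True)
class SiteCounts:
    """Per-column classification of a three-sequence alignment."""

    identical: int
    divergent_all: int
    unique_a: int
    unique_b: int
    unique_c: int
    excluded: int

    @property
    def total(self) -> int:
        return (
            self.identical
            + self.divergent_all
            + self.unique_a
            + self.unique_b
            + self.unique_c
            + self.excluded
        )


@dataclass(frozen=True)
class RelRateResult:
    counts: Optional[SiteCounts]
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class TajimaDResult:
    n_sequences: int
    total_sites: int
    segregating_sites: int
    p_s: float
    theta_per_site: float
    pi_per_site: float
    D: float
    significant: bool
    diagnostics: dict


@dataclass(frozen=True)
class FamilyStatsResult:
    r: float
    t: float
    df: int
    alpha: float
    t_critical: float
    significant: bool


@dataclass(frozen=True)
class ExpressionResult:
    delta_delta_ct: float
    fold_change: float


def _as_seq(s: ProteinRecord | str) -> str:
    return s.sequence if isinstance(s, ProteinRecord) else s.upper()


def classify_sites(
    a: ProteinRecord | str, b: ProteinRecord | str, c: ProteinRecord | str
) -> SiteCounts:
    """Classify each column of three aligned sequences (complete deletion)."""
    sa, sb, sc = _as_seq(a), _as_seq(b), _as_seq(c)
    if not (len(sa) == len(sb) == len(sc)):
        raise ValueError("the three sequences must have equal lengths")
    identical = divergent = ua = ub = uc = excluded = 0
    for ra, rb, rc in zip(sa, sb, sc):
        if MISSING & {ra, rb, rc}:
            excluded += 1
        elif ra == rb == rc:
            identical += 1
        elif ra != rb and rb != rc and ra != rc:
            divergent += 1
        elif rb == rc:
            ua += 1
        elif ra == rc:
            ub += 1
        else:
            uc += 1
    return SiteCounts(identical, divergent, ua, ub, uc, excluded)


def relative_rate_test(counts: SiteCounts) -> RelRateResult:
    """Tajima's relative rate test from unique-difference counts."""
    na, nb = counts.unique_a, counts.unique_b
    if na + nb == 0:
        raise ValueError("test undefined: no unique differences in A or B")
    chi2 = (na - nb) ** 2 / (na + nb)
    p = float(sps.chi2.sf(chi2, df=1))
    return RelRateResult(counts=counts, chi2=chi2, df=1, p=p)


def relative_rate_from_counts(unique_a: int, unique_b: int) -> RelRateResult:
    """Relative rate test directly from two printed unique-difference counts."""
    counts = SiteCounts(0, 0, unique_a, unique_b, 0, 0)
    return relative_rate_test(counts)


def _alignment_matrix(alignment: Alignment) -> np.ndarray:
    return np.array([list(r.sequence) for r in alignment.records])


def diversity_stats(alignment: Alignment) -> tuple[int, int, float]:
    """(L, S, pi_per_site) after complete deletion of gap/X columns.

    L is the number of retained columns, S the number of retained columns
    with at least two distinct residues, and pi the mean over all sequence
    pairs of the fraction of retained columns at which they differ.
    """
    if len(alignment) < 4:
        raise ValueError("diversity statistics need an alignment of n >= 4")
    mat = _alignment_matrix(alignment)
    keep = ~np.isin(mat, sorted(MISSING)).any(axis=0)
    mat = mat[:, keep]
    L = mat.shape[1]
    if L == 0:
        raise ValueError("no columns retained after complete deletion")
    S = int(sum(len(set(mat[:, j])) > 1 for j in range(L)))
    n = mat.shape[0]
    total_diff = 0
    for i in range(n):
        total_diff += (mat[i + 1:] != mat[i]).sum()
    n_pairs = n * (n - 1) // 2
    pi = float(total_diff) / (n_pairs * L)
    return L, S, pi


def tajima_d(n: int, L: int, S: int, pi_per_site: float) -> TajimaDResult:
    """Tajima's D from summary inputs (sequence count, sites, S, per-site pi).

    The constants follow the standard derivation: a1 = sum 1/i, a2 = sum
    1/i^2 (i = 1..n-1), b1 = (n+1)/3(n-1), b2 = 2(n^2+n+3)/9n(n-1),
    c1 = b1 - 1/a1, c2 = b2 - (n+2)/(a1 n) + a2/a1^2, e1 = c1/a1,
    e2 = c2/(a1^2 + a2); D = (pi L - S/a1) / sqrt(e1 S + e2 S(S-1)).
    """
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4 sequences")
    if S < 1:
        raise ValueError("D undefined: no segregating sites")
    if L < S:
        raise ValueError("total sites L must be >= segregating sites S")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    k = pi_per_site * L  # mean pairwise differences per alignment
    D = (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    p_s = S / L
    theta = p_s / a1
    return TajimaDResult(
        n_sequences=n,
        total_sites=L,
        segregating_sites=S,
        p_s=p_s,
        theta_per_site=theta,
        pi_per_site=pi_per_site,
        D=D,
        significant=abs(D) > SIGNIFICANT_ABS_D,
        diagnostics={"a1": a1, "a2": a2, "b1": b1, "b2": b2,
                     "c1": c1, "c2": c2, "e1": e1, "e2": e2},
    )


def tajima_d_from_alignment(alignment: Alignment) -> TajimaDResult:
    """End-to-end Tajima's D: complete deletion, then the summary formulas."""
    L, S, pi = diversity_stats(alignment)
    return tajima_d(len(alignment), L, S, pi)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant list")
    return float(np.corrcoef(x, y)[0, 1])


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int]:
    """Paired t statistic and df = n - 1 (sample sd, n - 1 denominator)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired t needs n >= 2 pairs of equal length")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        # the t -> 0/0 limit is conventionally reported as t = 0, but a
        # zero-variance difference means the test carries no information
        raise ValueError("paired t undefined: differences have zero variance")
    t = float(d.mean() / (sd / math.sqrt(len(d))))
    return t, len(d) - 1


def t_critical(alpha: float, df: int, two_tailed: bool = True) -> float:
    """Student-t critical value with total tail mass ``alpha``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    tail = alpha / 2 if two_tailed else alpha
    return float(sps.t.ppf(1.0 - tail, df))


def family_stats(
    records: Sequence[FamilySizeRecord], alpha: float = 0.001
) -> FamilyStatsResult:
    """Genome-size vs CPK-family-size statistics on a species table.

    Pearson r and the paired t statistic between genome size (Mb) and CPK
    count, with the two-tailed critical value at ``alpha`` and df = n - 1.
    """
    genome = [r.genome_mb for r in records]
    cpk = [float(r.cpk_count) for r in records]
    r = pearson_r(genome, cpk)
    t, df = paired_t(genome, cpk)
    crit = t_critical(alpha, df, two_tailed=True)
    return FamilyStatsResult(
        r=r, t=t, df=df, alpha=alpha, t_critical=crit, significant=abs(t) > crit
    )


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> ExpressionResult:
    """Relative expression by the 2^-ddCt method."""
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(v):
            raise ValueError("all Ct values must be finite")
    ddct_value = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return ExpressionResult(delta_delta_ct=ddct_value, fold_change=2.0 ** -ddct_value)
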