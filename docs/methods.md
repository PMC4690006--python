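# Methods

This note records the models, rules and numerical conventions behind
`cpkfamily`, the choices made where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate about real data.

## Sequence model and coordinates

Proteins are strings over the 20 standard one-letter residues plus `X`
(unknown); aligned records may contain `-`. All user-facing coordinates are
1-based and inclusive. `X` is deliberately conservative everywhere: it is
matched only by motif wildcards, it disqualifies mass/pI computation, and
columns containing it are removed (with gap columns) before site statistics
("complete deletion").

## Motif notation

Dash-delimited positional patterns: exact residues, `A/B` alternations,
`x` wildcards, and `x_(k)` wildcard runs. Two grammar decisions:

* mid-pattern alternations (`D-V/I-W-S`) parse exactly like leading ones;
* an alternation containing the wildcard (`V/x`, `L/x`, `I/x`) is
  unrestricted and parses as a plain wildcard — "V or anything" constrains
  nothing.

Matching reports every (possibly overlapping) occurrence; downstream logic
selects by position, because all EF-hand reasoning is positional rather
than greedy. The built-in catalogs store the wildcard (in-text) forms of
the kinase, auto-inhibitory, EF-hand and acylation motif sets as canonical;
figure-style fully resolved variants (e.g. `C-S-G-G-E-L-F-D-R-I`) are
particular instances of those patterns and are not duplicated.

## EF-hand model

Each EF-hand is a fixed 26-position frame (the loop plus flanks), with the
acidic Ca²⁺-coordination signature D-x-D at frame positions 14–16 and
D/E-E-L at 24–26. Hand-specific extras: E-E at 1–2 and E-M-F at 8–10
(hand 1), E@3/E@5 (hand 2), E@3/D@4 (hand 3), acidic 11–12 (hand 4). The
lower-eukaryote D-x-x-E form has no published frame anchor; it is anchored
here as D@14 with E@17, i.e. the same frame as D-x-D. Published 12-residue
loop spans are not reconciled with this frame; the 26-position frame is
canonical throughout the package.

Detection slides the frame and scores four core rules — D@14, D@16,
acidic at 24 or 25, L@26 — keeping frames with score ≥ 3 so that
lower-eukaryote hands (which lack the full D/E-E-L) remain discoverable.
Up to four mutually non-overlapping candidates are selected greedily,
preferring higher score and then smaller start; the selection equals a
brute-force enumeration over all frames (tested).

Lineage is called from flag counts rather than hand indices: the source
literature is internally inconsistent about *which* two hands carry D-x-D
in lower eukaryotes (second/third in one place, third/fourth in another),
so the classifier uses the count (exactly two, plus ≥ 1 D-x-x-E).

## CPK verdict

`is_cpk` requires kinase evidence AND an auto-inhibitory junction AND
exactly four EF-hands. Thresholds the literature leaves implicit were fixed
as follows:

* kinase evidence: ≥ 3 distinct motifs from one clade's kinase catalog.
  With no clade hint both catalogs are tried and the clade with more
  distinct motifs wins (tie → higher-plant);
* auto-inhibitory placement: the junction must lie downstream of the first
  kinase hit. Because EF-hands are themselves detected downstream of the
  junction, "between the kinase and the EF region" is operationalised as:
  every auto-inhibitory hit after the first kinase hit is tried, EF-hands
  are detected downstream of each, and the hit maximizing the EF-hand count
  is kept (ties → the latest hit, the one closest to the EF region). This
  makes the verdict robust to spurious short-motif matches inside the EF
  region.

Reject reasons are exactly one of: no kinase evidence, no auto-inhibitory
evidence, fewer than 4 EF-hands.

## Acylation and physico-chemistry

Myristoylation: G at position 2. Palmitoylation: conditional on
myristoylation (the experimental prerequisite), plus either a catalogued
N-terminal consensus prefix (the longest one matching) or any Cys at
positions 3–6.

Mass is the average (not monoisotopic) residue-mass sum plus one water,
reported in kDa to 3 decimals. The isoelectric point is found by bisection
of the net-charge function on pH ∈ [0, 14] to 0.001, with a fixed
EMBOSS-style pKa set (N-term 8.6, C-term 3.6; C 8.5, D 3.9, E 4.1, H 6.5,
K 10.8, R 12.5, Y 10.1). The original survey used an unspecified external
calculator; a fixed documented convention was chosen instead, so absolute
pI values are convention-dependent but internally consistent.

## Consensus calling

Per column (gaps excluded from the denominator): exact call at fraction
≥ θ_high (default 0.90), pooled `D/E` when the combined D+E fraction
reaches θ_high with both present, lowercase at ≥ θ_low (default 0.50),
else wildcard. Count ties break toward the alphabetically first residue.
Acidic pooling is limited to {D, E}; other alternations in the catalogs are
transcribed, not derived. Motif extraction anchors on high-consensus
symbols only (low-consensus symbols emit as `x`), breaks runs at more than
two consecutive unanchored columns, trims to anchors, and enforces
≥ 2 anchors within a span of ≤ 10 columns (the longest catalogued motif
spans 8). These defaults make the emitted strings directly comparable to
the catalogued motif notation.

## Evolution statistics

`classify_sites` buckets each retained three-sequence column as identical,
all-divergent, or unique-to-A/B/C; the relative rate χ² uses only the two
ingroup unique counts and takes its upper-tail probability from the χ²₁
distribution (scipy). The test accepts either sequences or printed counts.

Tajima's D uses the standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂).
π is carried per site and multiplied back by L in the numerator — the only
reading under which the published π, Θ and D values are mutually
consistent. The summary-input entry point (n, L, S, π) is deliberate: the
published all-CPK table implies L = S = 24 after complete deletion without
stating L, and the explicit entry point makes that assumption visible.
Significance is |D| > 2, following the source convention rather than a
distributional quantile.

`family_stats` reports df = n − 1 = 39 for the 40-pair paired t test. The
published table prints "degree of freedom 40" alongside its critical value
3.551 (which corresponds to df = 40); both the printed t and the
significance verdict are unaffected, and the standalone `t_critical`
function reproduces 3.551 at df = 40. Note the published correlation
r = 0.4487 is not reproducible from the printed species table: Pearson r
on those 40 rows is 0.4357 under every plausible pairing and transform we
tried, while the paired t (5.9835 vs printed 5.9796) does reproduce. The
packaged fixture reproduces the table verbatim — including a cpk_count
column that sums to 951 against the 950 headline count — and the
discrepancies are recorded rather than "corrected".

Student-t quantiles and χ² tails are delegated to scipy's incomplete-beta
and error-function machinery; the values are pinned by table-value tests
(12.706 at df 1, 1.960 in the normal limit, 3.551 at df 40, α = 0.001).

## Nomenclature

Similarity to labelled references uses optimal global alignment
(Needleman–Wunsch) with BLOSUM62 and BLAST-style affine gaps: gap open 11,
extend 1, so a length-L gap costs 11 + L (aligner `open_gap_score = −12`,
`extend_gap_score = −1`). This replaces the original database best-hit
step with a self-contained equivalent. Ties in score go to the smaller
ortholog number; paralog suffixes order by descending score then input
order. Prefix collisions extend the species epithet letter by letter; the
published `Crein` form (four species letters at once, chosen for
pronunciation) is reproduced via an explicit per-species extension length,
since "pronounceability" is not a computable rule. The package ships no
real reference proteomes; `demo_reference_set` generates a small labelled
synthetic panel.

## Synthetic data generator

`generate_cpk` assembles: an acylation prefix sampled from the consensus
catalog ⊕ linker (8–30) ⊕ five (higher) or six (lower) distinct kinase
motifs instantiated with random wildcards, separated by 4–12 residue
linkers ⊕ an auto-inhibitory motif ⊕ four 26-residue EF-hand windows with
the profile's positional residues planted (linkers 0–6) ⊕ a C-terminal
tail (8–25). Background residues are uniform over the 20 amino acids —
chosen for analytic tractability over empirical CPK composition, which
makes spurious-motif probabilities computable. Point substitutions are
applied i.i.d. after assembly, uniformly over positions and the 19
alternative residues; the truth ledger always stores pre-mutation
positions, so recovery curves are meaningful.

The generator *guarantees* its defining contract — at mutation rate 0 the
annotator recovers the planted architecture exactly — by verifying each
rate-0 draft against `annotate` and resampling on the rare spurious
collision (about 1 % of draws, e.g. a random score-3 frame straddling two
planted windows). Mutation is applied only after verification, so noisy
recovery rates reflect mutation alone. All randomness derives from one
master seed via `SeedSequence` spawning; identical arguments give
byte-identical output.

`generate_neutral_alignment` draws i.i.d. columns: monomorphic with
probability 1 − p_var (default p_var = 0.2), otherwise one alternative
residue carried by k of n sequences with k drawn from the neutral
infinite-sites frequency spectrum P(k) ∝ 1/k and the carrier subset
uniform given k. Under this spectrum E[π − S/a₁] = 0 exactly, so Tajima's
D is centred on zero by construction; a size-uniform subset would bias D
strongly positive and defeat the generator's purpose as a neutral null.

What passing synthetic tests show — and don't: they validate the
positional rules, the selection logic, the statistics and their mutual
consistency under a clean planted model with uniform background and no
indels, domain rearrangements, compositional bias or phylogenetic
correlation. They do not certify recovery rates on real proteomes, where
motif degeneracy and lineage-specific variants are richer than the
catalogs.

## Problem sizes used in tests

Recovery contracts run on 200 generated sequences (mixed profiles) at
mutation rates 0/0.02/0.05/0.10; the consensus re-derivation property uses
alignments of 200 EF-hand windows at rate 0.05 across seeds 0–9 (200
windows puts the expected 90 %-consensus calls safely away from binomial
borderline at n = 50); the neutral-D band uses 200 replicates of n = 20,
L = 200. The whole suite runs in well under a minute.

## Known limitations

* The motif catalogs are transcriptions of a single survey's tables; they
  are not profile models and carry no scores.
* EF-hand detection assumes the fixed 26-position frame; genuinely
  non-canonical hand spacings would be mis-framed.
* The pI convention is one of several in circulation; compare only values
  computed with the same pKa set.
* The naming scheme's ortholog numbers are only as good as the supplied
  reference panel; it performs no reciprocal-best-hit or tree-based
  orthology inference.
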