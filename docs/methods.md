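# Methods

This note documents the models implemented in `splicedex`, the defaults
that matter, and the design choices made where the design was genuinely
open.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Panel representation and design rules

A splice event is a cassette exon (0-based half-open genomic interval)
assayed by one primer pair producing two amplicons: inclusion
(flank + cassette + flank) and exclusion (flanks joined), so
`inclusion_len = exclusion_len + cassette_len` is a structural invariant.
Validation applies two rules. The *proximity* rule — at least one primer
3′ end strictly less than 125 nt from the cassette exon — is mandatory,
because junction bases must fall early in a 150-nt read where base
quality is high.  We measure the distance from the primer's 3′ terminus
on the inclusion isoform; the alternative (primer 5′ start) differs only
by primer length and the choice is recorded here because the rule's
anchor point is not standardized.  The *length* rule (amplicons ≥ 400 bp,
for sequencer cluster generation) is advisory and produces a warning
only.

Pool assignment balances read counts across a ~4000-fold range of
transcript abundance: events are ranked by abundance (ties broken by
event id for determinism) and split into four near-equal rank quartiles;
the most abundant quartile receives the fewest PCR cycles (pool D, 12
cycles; then C 13, B 15, A 17).  Primer-dimer conflicts are supplied
externally as pairs (no thermodynamic prediction is attempted); a
conflicting pair in one pool is resolved by moving the less abundant
member to the nearest-cycle conflict-free pool.  A clique of more than
four mutually conflicting primer sets is unsatisfiable and is reported as
an error.  Panel summaries use sample (n−1) standard deviations.

## Read classification and PSI

Each event's reference is the pair of isoform sequences with recorded
junction offsets (two exon–cassette junctions on the inclusion isoform,
one skipping junction on the exclusion isoform).  A read is informative
for an isoform iff (i) it has a primary alignment to it, (ii) the aligned
span covers one of that isoform's junctions with at least `min_overhang`
(default 8) nt on each side, and (iii) its alignment score strictly beats
the other isoform (`score_margin > 0`).  Ties are ambiguous — there is no
probabilistic rescue — and junction-free reads are uninformative; both
categories are reported as diagnostics but never counted.  Paired mates
share a read id and are merged per isoform (best mate score, junction
coverage by either mate), so conflicting mate evidence collapses to
ambiguous.  PSI is `n_inc / (n_inc + n_exc)` on the [0, 1] scale
(percent only at the reporting layer), with an exact Clopper–Pearson 95%
interval, and is flagged undefined below `min_reads` (default 20)
informative reads — the assay typically yields thousands per event, so
the floor only triggers on dropouts.  Coordinates are 0-based half-open
and all sequences are handled in transcript (sense) orientation;
minus-strand genes must be reverse-complemented upstream.

Detection bias against an orthogonal PSI source (conventional RNA-seq)
is the per-event mean of (targeted − reference) in percentage points,
with pairwise exclusion of undefined values, plus the overall mean.

## The composite splicing index (mDSI)

For event *j*, the anchors are `psi_wt_j` (median over wild-type
reference samples) and `psi_dm95_j` (95th percentile of most-affected
PSI over the disease-model reference cohort).  Severity direction is
event-specific, so the 95th percentile is computed on the signed shift
`direction_j * (psi − psi_wt_j)` and mapped back:
`psi_dm95_j = psi_wt_j + direction_j * Q95`.  Percentiles use linear
interpolation between order statistics (the common default; stable at
the reference cohort sizes of ~100 used here).  Events whose anchor
separation falls below `epsilon = 0.02` are dropped with a reason, which
prevents score blow-up on non-responsive events.  Scores are the exact
ratio with no clamping (wild-type-like samples scatter around 0, samples
beyond the reference severity exceed 1).  mDSI is the arithmetic mean of
defined test-event scores — the negative-control event is excluded by
role, undefined scores are excluded rather than imputed — and anchors
are frozen to TSV after fitting so treated samples are always scored
against the same reference.

## Dose–response modeling

PSI versus mDSI (the proxy for residual splicing-factor activity,
x ≥ 0; slightly negative index values are clipped to 0 at the join) is
fitted with the four-parameter logistic in the form
`init + (final − init)·xʰ/(xʰ + EC50ʰ)`, chosen over the usual
exp/logistic parameterization because it is defined and equals `init`
exactly at x = 0, is monotone for h > 0, and satisfies
PSI(EC50) = (init + final)/2 identically.  Fitting is bounded least
squares (asymptotes in [−0.2, 1.2] to absorb sampling noise outside
[0, 1]; EC50 in (0, 10·max x]; Hill in (0, 100]) from a deterministic
multi-start grid — Hill ∈ {0.5, 1, 2, 4} × EC50 at the 25th/50th/75th
percentiles of positive x — keeping the lowest-RSS solution; no RNG is
involved.  A constant response is reported as `degenerate` (EC50/Hill
unidentifiable); if no start converges, the least-squares line is
recorded as a `failed` fallback.  Sigmoidal-vs-linear classification
uses the extra-sum-of-squares F test against the straight line,
F = ((RSS_line − RSS_4PL)/2)/(RSS_4PL/(n−4)), calling sigmoidal at
p < α (default 0.05); degenerate fits are linear by convention, and a
numerically perfect line (both RSS at machine zero) is linear.

One identifiability caveat, verified by simulation: the index axis is a
monotone but nonlinear image of the underlying activity (it is a mean of
per-event sigmoids), so the raw (EC50, Hill) tuple of a refit against
mDSI is only defined up to that reparameterization.  Axis-invariant
summaries — the half-shift point and the fitted curve's predictions —
are recovered accurately and are what the end-to-end tests check.

## Motif enrichment

Four regions flank each exon in sense orientation: 350 nt of upstream
intron, 50 nt of exon at each edge, 350 nt of downstream intron
(truncation near short introns is tolerated and flagged).  All 1024 DNA
pentamers are scanned at every offset (overlaps counted; windows
touching N yield no occurrence); an occurrence is *conserved* when the
mean per-base phyloP over its 5 bases is ≥ 0.5.  The conservation filter
is applied per occurrence, not per pentamer identity averaged over all
occurrences — the per-occurrence reading keeps a locally conserved site
informative even when the same 5-mer also occurs in unconserved
sequence.

Positional enrichment uses 50-nt sliding windows at step 1 (traces per
position).  Per pentamer × region × window start, the 2×2 table counts
*exons* with/without at least one conserved occurrence starting in the
window, foreground versus background — presence/absence rather than
occurrence counts, the natural unit when exon sets are being compared —
and is tested with the two-sided Fisher exact test.  BH correction runs
over the full pentamer × position family of one call; increased- and
decreased-inclusion foreground sets are analyzed in separate calls.
Fold enrichment is the ratio of with-fractions (0/0 undefined and
flagged).  For efficiency, Fisher p-values are precomputed once per
(n_fg, n_bg) pair for all (a, c) tables and looked up.

Predictive ranking counts conserved occurrences over 200 nt of intron
plus 50 nt of exon on each side, fits ΔPSI ~ upstream + downstream by
OLS per pentamer independently (no combined multi-pentamer model), and
ranks by adjusted R² (n, p = 2 correction) descending with lexicographic
tie-breaks; constant counts give adjusted R² = 0 by convention.
Pentamers are handled in the DNA alphabet and presented in RNA (T→U)
only at the reporting layer.

## Simulators

All generators take a `numpy.random.Generator` and are byte-deterministic
given it; every dataset is paired with a truth table.

**Reads.**  Amplification bias is modeled as per-cycle efficiency
decaying exponentially with amplicon length, `e(L) = e_max·exp(−λL)`
(defaults `e_max = 0.9`; λ = 0 for unbiased runs), giving isoform weight
`(1 + e(L))^cycles` and observed inclusion probability
`ψ·w_inc / (ψ·w_inc + (1−ψ)·w_exc)` — the simplest mechanism that makes
under-detection grow with cassette length.  The calibrated default
λ = 2×10⁻⁴ puts per-event bias on the scale targeted assays exhibit in
practice (about −2 points for a 45 nt cassette to −10 points for a
300 nt cassette at 15 cycles, around −5 on average at ψ = 0.5).  Reads
are error-free 150-mers (the classifier keys on junction identity; base
errors are orthogonal to the contracts under test) with start positions
uniform over the junction-spanning starts of the chosen isoform, the two
inclusion junctions weighted exactly as uniform fragmentation would.
Conditioning on junction coverage keeps the informative tally binomial
in the pool inclusion fraction, so the estimator is unbiased at λ = 0.

**Cohorts.**  Each group carries a latent activity x ∈ [0, 1.2]
(0 = wild type, 1 = severe reference); each event's mean PSI at x comes
from a truth 4PL curve; realized PSI adds beta noise (the beta keeps PSI
in [0, 1] naturally) parameterized by a target standard deviation
(default 0.03), and reported PSI is a binomial draw at the configured
read depth.  Default truth curves shift by 0.3–0.5 PSI with EC50 in
[0.2, 0.6] and a Hill coefficient drawn so the curve reaches ≥ 90% of
its shift by x = 1 — panel events revert essentially fully in the most
severe models, which is what anchors the index at 1 — and the negative
control is flat.

**Flanks.**  Background sequence is i.i.d. uniform ACGT; the per-base
conservation track mixes a conserved component (mean 0.9, weight 0.25)
with a neutral one (mean 0), so unplanted sequence still yields some
conserved occurrences and the null enrichment analysis exercises real
tables.  Planted motifs overwrite the sequence at a uniform position in
their window at the configured per-exon rate with conservation set near
1.2; ΔPSI is a linear combination of the record's conserved counts over
the predictive regions plus Gaussian noise (default sd 0.02).

**The bundled synthetic panel** is a frozen artifact (fixed internal
seed): 36 events — 23 chosen for large PSI shifts, 12 patient-validated,
one negative control in *Brd2* — with cassette sizes for the
well-characterized exons set to their described lengths (Ryr1 15,
Dctn4 21, Bin1 45, Clcn1 79, Brd2 92, Mbnl2 95, Map3k4 156, Fn1 270,
Trim55 288, Ttn 303 nt) and the remainder fixed once so the panel
realizes the assay's design statistics (cassette ≈ 14 ± 11% of amplicon
length; amplicons ≈ 617 ± 87 bp).  All sequences and primers are
synthetic; the panel emulates the design structure of a real targeted
DM1 panel, not its genomic sequence, so sequence-specific effects
(primer thermodynamics, paralogy, intron retention) are out of scope for
what passing tests demonstrate.  The dystrophic-control table
(`mdx_psi_table`) likewise encodes the documented comparison: exactly
four myopathy-responsive events (Clasp1, Eya4, Opa1, Trim55) shift by
more than 10 percentage points, all others drift within ~4.

## Problem sizes and limitations

Simulated checks run at deliberately modest scale chosen to keep the
statistical contrasts decisive: 10–20 samples per severity level,
10³–2×10⁴ reads per event, 100–200 exons per motif set, 1000 replicates
for interval coverage.  Known limitations: no sequencing-error or GC
model; intron-retention isoforms are outside the two-isoform reference
(real targeted assays miss them too); no de novo primer design; human
index variants and cross-species anchor transfer are not implemented;
dose–response reports point estimates and RSS without confidence bands.
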