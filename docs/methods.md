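# Methods

## The phenotypes

A lickometer records each tongue contact to the nearest millisecond.
Successive contacts define inter-lick intervals (ILIs). Mouse licking is
organized into bursts of highly rhythmic licks separated by pauses; the
rhythm itself shows up as a "primary" mode of the ILI distribution at
roughly 50–160 ms, while pause intervals are much longer. The phenotypes
extracted are:

* **MPI** (mean primary inter-lick interval, ms): the arithmetic mean of
  ILIs inside the primary window. Both window bounds are treated as
  inclusive — the convention is not forced by the data (ILIs are integer
  ms, so the choice moves single boundary intervals only) and the
  inclusive rule is the simplest to state and test. A session with no
  in-window ILI has an *undefined* MPI (NaN plus a flag), never zero.
* **Total licks**: contacts per session.
* **VPL** (volume per lick, µL): 1000 x spillage-corrected volume (mL) /
  total licks. Spillage correction is an upstream measurement, not a
  computation here. VPL outliers are rejected in a single pass at ±3
  sample SDs from the mean, pooled across animals within one stimulus
  condition, with a strict inequality (a value exactly at the cut
  survives). The rejection is deliberately non-iterative: recomputing
  after removal would reject further values and is a different (and
  unstated) procedure.
* ILI histograms use half-open 5-ms bins on [0, 250); intervals at or
  above the upper edge are excluded from the counts but kept in the
  total, so the histogram is conservative by construction.

Day 1 is a training day with unstable licking; its sessions are retained
in the phenotype table but excluded from strain means used for mapping
(water = day 2, sucrose = day 3).

## Heritability

For a panel of inbred strains, broad-sense heritability is estimated as

    h² = V_A / (V_A + 2 V_E)

with variance components from a one-way random-effects ANOVA of
animal-level values grouped by strain: `V_E = MS_within`, and
`V_A = (MS_between − MS_within) / n0`, where
`n0 = (N − Σ n_i²/N) / (a − 1)` corrects for unbalanced strain sizes.
Negative moment estimates of `V_A` are clamped to zero. The factor 2
reflects the doubling of additive variance among fully inbred lines
relative to an outbred population, which makes the estimate conservative.
The estimator is applied to raw animal-level data rather than strain
means; the two differ when strain sizes vary.

The repeated-measures effect size is
`η² = SS_condition / (SS_total − SS_subjects)` — the share of variance
explained by a within-subject factor after removing stable subject
differences — and requires a complete subjects x conditions layout.
Correlation matrices are Pearson with pairwise-complete deletion and a
minimum of 3 complete pairs per cell (cells below that are NaN).

## Genome scans

The mapping unit is the unweighted strain mean, one value per strain.
Genotypes are coded B/B = −1, D/D = +1; residual heterozygous (H) and
unknown (U) calls are missing, and strains missing the test genotype are
dropped from both the null and the single-locus model at that locus so
the likelihood comparison stays nested. At each locus,

    LRS = n · ln(RSS₀ / RSS₁),      LOD = LRS / (2 ln 10),

where RSS₀/RSS₁ are the residual sums of squares of the mean-only and
the single-locus regression over the n informative strains. The additive
effect is the regression slope — half the D/D − B/B group-mean difference
— so a positive value means the D allele raises the trait; prose
reporting of a "B-allele effect" is its negation. Degenerate loci (one
genotype class) are skipped and flagged. A perfect fit (RSS₁ = 0) is
reported as the capped value `n·ln(1/ε)` with ε = 1e−12 and a
`perfect_fit` flag, never infinity.

**Interval mode** tests pseudomarkers on a 1-cM grid using the expected
dosage given the flanking markers (Haley–Knott style). The conditional
expectation uses the two-state Markov chain of an RI genome: for a gap of
d cM, Haldane's `r = (1 − e^(−2d/100))/2` and the sib-mating expansion
`R = 4r/(1+6r)` give the flank-to-grid transition probabilities; a
missing flank contributes a flat 1/2 prior.

**Thresholds.** Strain phenotype values are permuted against genotype
rows (10,000 permutations by default; analyses here use 1000); each
permutation's genome-wide maximum LRS forms the null sample, and the
significant / suggestive thresholds are its empirical 0.95 / 0.37
quantiles (inverse-ECDF, i.e. order statistics). Genome-wide p-values use
the add-one estimator `(1 + #{null ≥ obs}) / (1 + n_perm)`. Because the
observed arrangement is exchangeable with the permutations under the
null, the significant threshold's exceedance rate is
`(n_perm+1−⌈0.95·n_perm⌉)/(n_perm+1) ≈ 0.051` by construction; the
calibration tests verify this empirically.

**Support intervals** are 1.5-LOD drops: the widest contiguous run of
loci around the peak whose LOD stays within 1.5 of the peak, truncated at
chromosome ends (ties at the peak resolve to the leftmost locus).
**Bootstrap** confidence in the peak position resamples strains with
replacement and tallies the peak locus; degenerate resamples (fewer than
two distinct strains, or no informative locus) are redrawn and counted.

**Composite scans** add control-marker genotypes as covariates to both
the null and the full model, removing variance associated with a known
QTL so secondary loci emerge; the implementation residualizes phenotype
and test dosages on the controls (Frisch–Waugh–Lovell), which is exact
for least squares. Loci collinear with a control (including the control
itself) report LRS 0 with a `collinear` flag.

**Two-locus model.** `y = μ + a₁x₁ + a₂x₂ + i·x₁x₂` by least squares
over strains complete at both markers. The interaction LRS compares full
vs additive models; each locus's additive LRS and variance-explained
share are sequential after the other locus (variance explained =
reduction in RSS relative to the total sum of squares). If the product
column is rank-deficient against the main effects, the interaction is
dropped and flagged. The exhaustive pair scan fits every pair from a
marker set thinned to one marker per 5 cM (configurable), ranked by total
LRS — a deliberate replacement of global optimization with an exact
desk-scale search. Epistasis significance, where needed, comes from
permuting the pair-scan maximum, not from asymptotics.

## Candidate screening by partial correlation

A candidate gene near the QTL can correlate with the phenotype merely
because both are linked to the locus (for microarrays, probes overlapping
sequence variants make this worse). First-order partial correlation
controlling the numeric genotype at a named marker,

    r_xy·z = (r_xy − r_xz·r_yz) / √((1 − r_xz²)(1 − r_yz²)),

removes that shared variance; multi-marker control residualizes on all
controls jointly, which reduces to the formula above for one control.
The two-sided p uses the t transform on n − 2 − k degrees of freedom.
Collinear controls make the partial undefined; the screen flags the row
instead of dropping it. No multiple-testing correction is applied — the
screen reports raw partial p per probe, as candidate tables in this
setting conventionally do. Each probe also gets a cis-LRS (the peak of a
genome scan of its expression) and the additive effect of genotype on
expression.

## The synthetic generator

The generator emulates the statistical skeleton of an RI licking study:

* **Genotypes.** Per chromosome, a two-state Markov chain over the
  ordered markers: the first marker is B or D with probability 1/2 and
  adjacent markers disagree with probability `R = 4r/(1+6r)` (BXD-style
  lines are sib-mated; this is the matching map expansion). Only
  homozygous codes are generated — H/U handling is exercised through the
  `.geno` parser instead.
* **Phenotypes.** Strain mean = baseline + Σ effect_j·x_j + polygenic
  N(0, σ²_strain); animals add N(0, σ²_env). The planted loci are real
  markers, so the between-strain genetic variance is
  σ²_strain + Σ effect_j² (x = ±1).
* **Lick streams.** A fixed number of bursts of fixed length; within-burst
  ILIs are Normal(true MPI, within-burst SD) truncated to the primary
  window, and pauses (between bursts, plus a small per-ILI replacement
  probability) are 161 ms + Exponential(pause mean − 160), strictly
  outside the primary window so window filtering is exercised
  deterministically. Timestamps are integer ms, strictly increasing.

**Preset ("paper_matched").** 64 strains x 6 mice on a 19-chromosome,
5-cM-spaced map; baseline MPI 110 ms; one planted locus mid-chromosome 1
whose D allele lowers MPI by 4.35 ms; total between-strain genetic
variance 32.6 ms² (so residual polygenic variance is
32.6 − 4.35² = 13.68 ms²) and within-strain variance 10 ms². These give
h² = 32.6/(32.6 + 20) = 0.62 and a D/D vs B/B group difference of
2 x 4.35 ≈ 9 ms — the recovery targets of the acceptance checks. Burst
structure (20 bursts x 30 licks, within-burst SD 8 ms, 2% pause
replacement, 1.5-s mean pauses) is calibrated only so MPI is estimable
with sub-millisecond session noise; real lick microstructure statistics
are not reported quantitatively in this setting and no claim is made to
match them. A small sucrose shift (+0.66 ms) distinguishes the stimuli.

One master seed drives everything; per-stage substreams (genotypes,
phenotypes, lick streams, session bookkeeping) are spawned at fixed
offsets, so identical (config, seed) pairs give byte-identical outputs.

**What passing tests do and do not show.** The generator's noise is
Gaussian, sessions are homogeneous, and lick counts are fixed by
construction; real panels add motivational variation in lick counts,
day effects, missing genotypes and related strains (kinship). Recovery
results here validate the estimators and their calibration under the
stated model, not robustness to those real-data features (kinship-aware
mapping is explicitly out of scope).

## Problem sizes and numerical choices

The acceptance script uses 200 replicate panels for the heritability
mean, 100 for effect recovery, and 1500 null panels x 1000 permutations
for threshold calibration — sizes chosen so Monte-Carlo standard errors
(≈0.003 on h², ≈0.05 ms on the effect, ≈0.006 on the type-I rate) are
small relative to the quantities themselves while the whole script runs
in well under a minute. The test suite uses the same designs at somewhat
smaller replicate counts with 3-SE binomial bounds. Quantiles are type-1
(inverted CDF); permutations and bootstraps are vectorized when no
genotype is missing and fall back to per-locus fits otherwise; all
integer seeds stay below 2³¹.

## Known limitations

* Strain means are unweighted; panels with very uneven strain sizes
  would justify weighted or mixed-model mapping.
* No kinship correction: related RI strains violate the independence
  assumption of the permutation null in real panels.
* The pair scan's marker thinning trades resolution for exhaustiveness;
  a peak falling between retained markers is represented by a linked
  neighbor.
* The partial-correlation p assumes bivariate normality of the
  residualized traits; permutation-based p-values would relax this.
* X-chromosome inheritance and sex as a mapping covariate are not
  modeled.
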