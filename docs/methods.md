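# Methods

## Damage model

Two post-mortem processes dominate DNA decay in dried plant tissue and are
modelled separately.

**Fragmentation.** Hydrolytic depurination nicks the backbone independently
at each phosphodiester bond. If each site breaks with probability λ, a
surviving fragment of length L has probability proportional to (1−λ)^L —
a geometric law, the discrete exponential. On a log scale the
length-frequency spectrum is a straight line with slope −λ (for λ ≪ 1,
ln(1−λ) ≈ −λ). λ is therefore estimated as minus the OLS slope of
ln(count) on length. Accumulation over time is summarised by the decay
rate k (per site per year) via λ = k·age; k is the slope of the λ-on-age
regression across libraries.

**Deamination.** Cytosines in the single-stranded overhangs at fragment
ends deaminate to uracil, read as C>T at 5′ ends and, in double-stranded
libraries, as a mirrored G>A excess at 3′ ends. The positional profile is
modelled as f(p) = A·e^(−r(p−1)) + c with A, r, c ≥ 0: A is the first-base
excess, r the per-position decay of single-strandedness, c the interior
background. The damage proxy carried into cohort statistics is the
*observed* first-base frequency f_CT(1), not the fitted amplitude; the fit
exists only to authenticate samples.

**Divergence baseline.** Sample-to-reference evolutionary distance plus
sequencing error adds a roughly uniform background to all twelve
substitution types. The baseline b is the mean frequency of the ten
non-deamination types over positions 1–20 at both termini (zero-denominator
cells excluded); the corrected deamination estimate is
d_corr = max(0, f_CT(1) − b). Adding any uniform divergence to all types
shifts f_CT(1) and b equally, so d_corr is invariant to it (up to the zero
floor).

## Per-sample estimation and gates

- **Positions** are 1-based from each terminus in read orientation;
  reverse-strand records are complemented and index-flipped before
  tallying. Only the first 20 positions are stored, and a base in a read
  shorter than 40 bp is assigned to the nearer terminus (ties to 5′), so
  no base is double-counted. Insertions, deletions and soft-clipped bases
  carry no aligned reference base and are excluded; substitution context
  comes from the MD tag.
- **λ fit range** defaults to [modal length, maximum observed length]: the
  left flank of the spectrum is truncated by the read-merging minimum and
  mapping limits, while the right tail is where exponential decay of
  surviving fragments is actually expressed. The range is configurable.
- **Started log.** The regression uses ln(count + 0.5) with empty bins
  inside the range retained. On sampled histograms the naive
  drop-zero-bins ln-count fit is biased upward in the sparse tail (ln of
  small counts plus zero-truncation), which propagates into an
  age-correlated bias in λ and a measurable bias in k; the half-count
  offset removes almost all of it while leaving noiseless exponential
  inputs recoverable to better than four significant figures.
  `pseudo_count=0` restores the pure log-linear fit, which is exactly
  scale-invariant and is the right choice for dense, noise-free spectra.
  The default is tuned to bounded merge-window spectra (~30–150 bp); on
  unbounded spectra with hundreds of near-empty tail bins the pure fit
  over occupied bins is preferable.
- **Gates** use strict inequalities: λ fit accepted when R² > 0.95 and the
  two-sided slope-t P < 0.05; deamination fit accepted when R² > 0.5 and
  the one-sided amplitude-t P < 0.05 (t = Â/SE(Â), n−3 df, H1: A > 0).
  Retention additionally requires more than 5,000 mapped merged reads, the
  depth at which terminal frequencies become reliable. All gates are
  applied jointly and every failed gate is recorded per sample.
- **Nonlinear fit initialisation**: A₀ = f(1) − mean f(last 10), c₀ = mean
  f(last 10), r₀ ∈ {0.1, 0.3, 1.0}; the start with the lowest residual sum
  of squares wins. Non-convergent fits are flagged and fail the gate.

## Cohort statistics

- **Decay rate.** The λ-on-age regression includes an intercept by default
  (λ estimates carry baseline offsets from the truncated fit window); a
  through-origin mode reflecting the idealised λ = k·age is available.
  Because per-sample λ noise grows with age, the slope's confidence
  interval uses an HC3 heteroscedasticity-consistent standard error; the
  classical OLS error is also reported.
- **ANCOVA.** metric ~ age × genus with sequential (Type I) sums of
  squares in the order covariate → factor → interaction, each tested
  against the full-model residual mean square (Type II available). The
  nested comparison of `age*genus` against `age + genus` decides the
  reported model: when the interaction P exceeds 0.05 the simpler model is
  chosen and slopes are declared parallel. With a two-level factor the
  nested F-test coincides with the sequential interaction test; both are
  reported.
- **Variance partitioning.** For 2–4 named blocks of covariates, every
  non-empty block subset is regressed against the response and its R²
  converted to adjusted R² (Ezekiel). Unique and shared fractions are
  obtained by inclusion–exclusion over the subset measures (solved as a
  linear system), so the 2^B − 1 cells plus the residual sum to one at
  machine precision; cells can be negative, as usual on the adjusted
  scale. Unique fractions and the full model are tested by Freedman–Lane
  permutation: residuals of the reduced model (all other blocks) are
  permuted, added back to its fitted values, and the partial F recomputed;
  P = (hits + 1)/(n_perm + 1) with 999 permutations by default. The genus
  factor enters as treatment-coded dummies; climate covariates are used
  complete-case.

## Synthetic cohorts

The generator emulates a two-genus herbarium study: a temperate genus
(default n = 211, k = 2.64e-4 per site per year, collection-site
temperature ~ N(12, 5) °C) and a tropical genus (n = 245, k = 1.79e-4,
temperature ~ N(25, 4) °C), ages uniform over roughly two centuries,
fragment lengths truncated-geometric on 30–150 bp (the merge-window range
of short-insert libraries), 20,000 mapped reads per library by default,
endogenous fractions Beta(8, 2) independent of age, and per-species
divergence baselines of 0.55% and 0.78%. The deamination amplitude is
A = α_genus + β_age·age + β_T·temperature with defaults producing
first-base C>T around 1–2.5%, a genus-specific β_age (the tropical genus
accumulates deamination faster), and genus-structured temperatures that
deliberately confound genus with climate — the shared variance-partition
fractions this produces are a feature of the design, not an artefact.
Reference-base denominators use a uniform base composition by default, and
both termini are generated with equal damage (double-stranded "mirrored"
convention).

Two sampling paths exist: an aggregate path (multinomial reference counts,
binomial substitution counts per position) for speed, and a per-read path
(`keep_reads=True`) that renders each read with its planted mismatches and
can emit toy single-end SAM with consistent CIGAR/MD, so the alignment
parser can be verified against planted counts exactly.

By default λ_i = k·age_i exactly, so all λ scatter comes from finite-read
sampling; this makes genus differences in k easy to detect at default
sizes. Real herbarium cohorts show large age-independent λ scatter
(λ-on-age R² around 0.1–0.2), reproducible via `lambda_noise_sd`; tests of
null behaviour in the λ channel use a value of 2e-3, which also keeps the
interaction F-test correctly calibrated (pure measurement noise is
age-heteroscedastic and mildly inflates its size).

What the generator does *not* emulate: sequencer error profiles and
quality scores, indels, position-dependent base composition, microbial
metagenome structure in the exogenous fraction (unmapped reads are
abstracted to a count), and library-preparation length biases. Passing
tests therefore certify the statistical machinery, not robustness to every
artefact of real libraries.

## Numerical choices and degenerate inputs

- Flat spectra (all ln-counts equal) return λ = 0, R² = 0, P = 1 rather
  than NaN; fewer than four usable bins flags the fit "insufficient".
- Zero-residual ANCOVA fits (noise-free inputs) report F = 0, P = 1 for
  terms with zero extra sum of squares instead of 0/0.
- The empirical median uses the lower-median convention; the lognormal fit
  is the closed-form MLE on log lengths.
- A degenerate amplitude standard error in the deamination fit (parameter
  pinned at a bound, singular covariance) yields P = 1 unless the fit is
  exact, never a spurious pass.
- Problem sizes in the test suite (200-sample cohorts at 1e4 reads, 100
  seed replicates, 999 permutations) are chosen so the full suite
  completes in a few minutes on one CPU while leaving planted-truth
  recovery checks well-powered.

## Known limitations

- The three-parameter exponential is a pragmatic authentication model; it
  is not derived from a mechanistic overhang-length distribution, and its
  amplitude test assumes approximate normality of the estimator.
- λ from log-linear OLS is a method-of-moments-style estimator; a
  truncated-geometric MLE would be more efficient but would no longer
  yield the R²-based fit diagnostic used for gating.
- ANCOVA and variance partitioning assume homoscedastic Gaussian
  residuals; the decay-rate CI is robustified, the F-tests are not.
- Single-stranded library chemistry (no mirrored 3′ G>A) and UDG-treated
  libraries (damage excised) are out of scope.
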