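# Methods

## The scientific question

Nuclear genes whose products work inside mitochondria are not inherited the
way mtDNA is. mtDNA passes strictly through mothers; an X-linked nuclear
allele passes through the same parent as the mtDNA in 2/3 of transmitted
copies (daughters receive an X from each parent, sons only from their
mother), an autosomal allele in 1/2, and a Y-linked allele never. Two rival
hypotheses follow. Under *coadaptation* (CA), selection for co-transmission
of well-matched mito-nuclear allele pairs favors X-linkage of
mito-interacting genes. Under *sexual conflict* (SC), the maternal
inheritance of mtDNA lets male-harming, female-benign mutations accumulate
("Mother's Curse"), and nuclear genes that must counter-adapt through males
are favored to sit *off* the X.

The package tests these predictions the way the field does: classify a
background gene universe by membership in a focal list × a binary property
(X-linkage, membership of a second list, testis-biased expression), and ask
whether the 2×2 cross-classification departs from independence.

## Exact enrichment statistics

`enrichment_core` builds the 2×2 tables and computes:

* **Sample odds ratio** `a·d/(b·c)` — the cross-product ratio, reported as
  the primary estimate. Reconstructions of published tables match the
  printed values at two decimals under this convention (0.8185→0.82,
  1.2556→1.26), which is why it was chosen over alternatives the source
  analyses never specify. When a cell is zero the Haldane–Anscombe +0.5 is
  added to all four cells and flagged.
* **Two-sided Fisher exact P.** With all margins fixed, cell `a` is
  hypergeometric; the P-value sums point probabilities not exceeding that of
  the observed table (point-probability rule, the dominant convention in
  exact-test software). All probability arithmetic is in log-space via
  log-gamma, so 15 000-gene backgrounds are numerically safe; ties are
  detected with a relative tolerance of 1e-9, far above the ~1e-14
  round-off of equal log-probabilities and far below the minimal relative
  gap between genuinely distinct probabilities at small counts. The modal
  table returns exactly 1.0; results are clipped to (0, 1].
* **Conditional MLE odds ratio** (diagnostic): the maximizer of Fisher's
  noncentral hypergeometric likelihood, found by monotone root search on
  the score equation E_ψ[a] = a with tolerance 1e-8 on the log-odds.
  Observed counts at the edge of their support return the 0/∞ sentinel with
  a boundary flag. At survey scale the conditional MLE and sample OR agree
  within 1%, so the choice of estimator does not drive any conclusion.

Percentages follow the published convention: the background percentage is
`(a+c)/n` over the *whole* background, focal genes included, while the
rows of the table partition the background into focal vs non-focal.

## Count reconstruction

Published reports often print only list sizes and percentages. For a focal
list of size `n_f` with `p_f`% carrying the property, against a background
of `n_b` genes at `p_b`%, `reconstruct_counts` rebuilds the table as
`a = round(n_f·p_f/100)`, `a+c = round(n_b·p_b/100)` (half away from zero),
remaining cells by subtraction; negative cells mean the printed numbers are
inconsistent and raise. Because a percentage printed at 1 dp can move the
implied count by several genes, reconstructed odds ratios can drift from
printed ones; drifts beyond 0.02 are reported as warnings, not errors. The
bundled `configs/reference_counts.yaml` carries the reconstructions whose
printed inputs are complete; comparisons whose background baseline was
never printed for the relevant gene universe (testis-bias rates within the
expression-chip subset) are omitted rather than guessed.

## Bootstrap odds-ratio densities

`resampling` implements stratified case resampling: each replicate redraws,
with replacement and independently, the focal genes from the focal set and
the non-focal genes from the rest of the background, preserving both
stratum sizes (the focal-vs-rest contrast is the quantity of interest; the
source figures never state their resampling scheme, and this is the
simplest one consistent with a per-list OR density). Since resampled genes
are i.i.d. within a stratum, the replicate X-counts are binomial in the
observed stratum proportions, and the implementation draws them as two
binomial variates per replicate — algebraically identical to enumerating
resampled gene lists and far cheaper. Every replicate OR carries the +0.5
correction so degenerate resamples stay finite; at survey-scale counts this
moves the OR by under 0.3%.

Summaries are the replicate median and equal-tailed percentile interval
(default level 0.95, default R = 10 000, seed mandatory in the CLI).
Densities are estimated on the log-OR scale (ORs are ratio-scaled) with a
Silverman-bandwidth Gaussian KDE, renormalized to unit trapezoid integral,
and transformed back to the OR scale as `f_OR(x) = f_log(ln x)/x` on
request. Zero-variance replicate vectors return a flagged point-mass
("spike") summary instead of a continuous density. Percentile intervals are
known to undercover slightly at moderate counts; BCa or studentized
intervals are out of scope.

## Stratified exclusions

`apply_exclusion` removes genes matching a criterion — a gene set (e.g. the
123 mito-annotated duplicates) or an annotation flag (`testis_biased`,
`duplicate`) — from focal lists *and* from the background table, so all
subsequent denominators shrink. This matches the published sensitivity
analyses, whose post-exclusion background X percentages change, and is the
only convention that reproduces such shifted baselines. Exclusion is
idempotent and commutes with background restriction. No multiple-testing
correction gates anything; a Benjamini–Hochberg column is emitted alongside
raw exact P-values for transparency.

## Co-segregation model

`cosegregation` exposes the closed forms (X 2/3, autosome 1/2, Y 0) and a
Monte-Carlo verifier: non-overlapping generations, even initial sex ratio,
panmixia, Mendelian transmission, strict maternal mtDNA. The counting unit
is the *transmitted gene copy*, not the offspring: a daughter contributes
two X copies (one maternal), a son one (maternal); it is this convention
that yields 2/3 under an even sex ratio. Realized offspring sex ratios
fluctuate, so the simulated X fraction varies ~binomially around 2/3 while
the autosomal fraction is exactly 1/2 by construction and the Y fraction
exactly 0. Single-sex generations are redrawn (logged) and the simulation
aborts after 100 redraws. Selection, gene relocation dynamics, and ZW
systems are out of scope.

## Synthetic worlds

`synthetic_data.generate_world` draws a genome of `n_genes` with arms
i.i.d. from a probability vector (default: D. melanogaster-like fractions
with X at 0.155), testis-biased flags Bernoulli (default base rate 0.161 —
the published genome-wide rate), and named gene sets of exact sizes via
exponential-keys weighted sampling without replacement. A gene's log-weight
in a set is `x_log_odds·1[X] + testis_log_odds·1[testis]` plus pairwise
latent tilts. Fixed set sizes mirror the fixed sizes of published lists.

Pairwise overlap is induced by a shared latent Bernoulli "pathway"
indicator per tilted set pair. The latent rate equals the smaller member's
genome fraction (so high overlaps remain feasible), and the member tilt is
solved from the rare-set mixture formula
`(ρ·e^{2a}+1)/(ρ·e^a+1)² = e^λ`, which caps at `1/ρ`. Pools are
composition-neutral in X and testis status: provided the tilt stays below
the saturation cap, a member's own x/testis log-odds act identically inside
and outside the pool, so overlap structure does not contaminate marginal
enrichments. The price is that very high overlap targets (e.g. the
published ~58% overlap between the core-proteome and mito-annotated lists)
are deliberately not reached — the survey-shaped world realizes ~19%
there — because pushing into saturation would attenuate the members'
marginal X odds ratios away from their generative values. Marginal
fidelity was prioritized: it is the quantity every estimator-recovery check
relies on.

Because exponential-keys sampling is successive sampling (multivariate
Wallenius), realized enrichments are very mildly attenuated at high
sampling fractions; for the largest list (1211 of 12 150 at OR 0.82) the
effect is ≈0.01 on the OR scale, well inside measurement noise.

`survey_shaped_world(seed)` is a convenience wrapper with the published
dimensions: 15 493 genes, a uniformly drawn 12 150-gene expression-chip
subset, lists of 524 (mito-annotated, X-OR 1.01), 419 (core proteome,
X-OR 1.26), 1211 (mito-sensitive, X-OR 0.82, drawn within the chip), 123
flagged duplicates, plus Y-sensitive (705) and male-fitness (717) lists at
their chip base rates, with testis odds ratios at the published point
estimates. The chip subset is uniform; any compositional bias of the real
array is out of generative scope, as are expression values, array noise,
and differential-expression calling — the generator emulates the *lists*,
so passing tests demonstrate correct statistics on list-shaped data, not
robustness to upstream transcriptomic artifacts.

## Calibration harnesses and problem sizes

`recovery.recovery_summary` (CLI: `mitonux recover`) generates 100
survey-shaped worlds, re-estimates each tracked list's X odds ratio against
its proper background with a 2000-replicate bootstrap, and reports mean
estimate, bias, and 95%-CI coverage. Observed biases are below 0.02 with
coverage 91–98%. `recovery.null_calibration` draws 1000 null worlds
(12 150 genes, one 1211-gene set, all effects zero) and reports the exact
test's rejection rate at α = 0.05; the realized size is ≈4.7% — slightly
conservative, as expected for a discrete two-sided exact test — with the
exact conditional size at these margins computed independently at ≈4.75%.
These problem sizes (100 worlds × R = 2000; 1000 null worlds) were chosen
as the smallest at which the Monte-Carlo error of the summary statistics is
comfortably below the effect sizes being checked.

## Determinism

Every stochastic operation takes an explicit seed (NumPy `default_rng`);
identical configurations and seeds produce byte-identical TSV/JSON reports.
Timestamps live only in the run manifest, alongside SHA-256 digests of the
configuration and input files.

## Known limitations

* Counts-mode reconstruction inherits printed-percentage rounding; some
  published odds ratios are reproducible only to ±0.03, and a few printed
  values (e.g. an OR of 1.01 alongside percentages 15.2% vs 15.5%, which
  imply OR < 1) appear internally inconsistent in the source and are
  flagged as warnings rather than resolved.
* Post-exclusion published odds ratios cannot be reconstructed from counts
  (the overlap sizes between excluded and focal lists were never printed);
  exclusion analyses run only in list mode, on real or synthetic lists.
* The generator's overlap calibration is approximate (rare-set formula);
  overlap odds ratios are monotone in the requested log-odds but not exact,
  and high-overlap targets are deliberately capped (see above).
* One printed list size is ambiguous in the source (1211 vs 1212 genes for
  the mito-sensitive list); all fixtures use 1211, the number entering the
  published statistics.
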