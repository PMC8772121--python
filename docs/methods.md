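# Methods

This note records the models the package implements, the conventions
and defaults it commits to, what the synthetic generators do and do not
emulate, and the design choices made where more than one defensible
option existed.

## Coordinates, genotypes and filtering

All internal coordinates are 0-based half-open; VCF and GFF3 positions
are converted on ingestion and printed back 1-based inclusive in
tables.  Diploid genotypes are stored as alt-allele dosage in
{0, 1, 2}; any genotype with an unknown allele — `./.` or a half call
like `0/.` — is treated as fully missing, which avoids fractional
dosages at the cost of discarding half the information in half calls
(rare in practice).

Site filtering retains sites with missing fraction strictly below 0.10
and minor allele frequency strictly above 0.01, the standard
resequencing QC thresholds; MAF is computed over non-missing alleles
only.  Read-depth filtering belongs to variant calling and is out of
scope here: the pipeline starts from called genotypes.

Sliding windows start at 0 and advance by the step; the final window is
truncated at the chromosome end.  Defaults are 40 kb / 20 kb for π and
Fst and 20 kb / 10 kb for the sweep scan.

## Nucleotide diversity

Per site, π = n_ref·n_alt / C(n, 2) with n the non-missing allele
count; this equals the mean pairwise difference over all allele pairs
(the test suite checks this by exhaustive enumeration).  The window
value divides the per-site sum by the **window length in bp**, so
windows are comparable regardless of SNP density; a per-variant-site
denominator is available via a flag.  Windows with no usable site
report π = 0 with n_sites = 0 rather than NaN, matching how windowed-π
tools treat invariant windows.

## Weir–Cockerham Fst

The 1984 variance-component estimator, computed per site from
per-population sample sizes, allele frequencies and observed
heterozygote proportions.  Populations with no called genotype at a
site drop out of that site; sites with fewer than two informative
populations, or mean per-population sample size ≤ 1, contribute
nothing.  Windowed and genome-wide values are ratios of summed
components Σa / Σ(a+b+c) — the "ratio of averages" — which is stable,
standard, and can produce small negative values for undifferentiated
pairs; negatives are reported as-is, never clamped, because real
surveys print them.  A `window_mean` alternative (mean of per-window
ratios) is exposed for comparison, but genome-wide ratio-of-sums is
the default for pairwise matrices.

The implementation is cross-checked at 1e-12 against an independent
scalar transcription of the component formulas, and at ±0.02 against a
Balding–Nichols truth-record oracle (below).

## Heterozygosity and inbreeding

Per site and population, expected heterozygosity is He = 2p(1−p) with p
the population allele frequency and no small-sample correction.  Per
individual, only its called sites count: expected homozygosity is
Σ(1 − He_site), observed homozygosity is the homozygous-call count, and
F = (obs_hom − exp_hom)/(n_used − exp_hom).  Population He/Ho/F are
unweighted means across sites/individuals; individuals with a zero
denominator get F = NaN and are excluded from the mean.  Ho is always
reported as a proportion in [0, 1].

## LD decay

r² is the squared Pearson correlation of the two dosage vectors over
samples called at both sites — the composite (Burrows-style) genotype
r², chosen because the input is unphased and the package deliberately
contains no phasing or haplotype EM.  Composite r² and haplotype r²
agree closely under random mating, but the two are not identical;
curves from phased tools will differ in detail.  Pairs are binned by
physical distance up to `max_dist`; the decay distance is the midpoint
of the first populated bin whose mean r² falls below the threshold
(default 0.1), NaN if never crossed.  For independent loci the expected
r² is ≈ 1/n, which the tests verify by simulation.

## Genotype PCA

Missing dosages are mean-imputed per site; sites are centered by their
mean dosage 2p̂ and scaled by √(2p̂(1−p̂)) (drift-variance
standardization, the convention for genotype PCA); monomorphic sites
drop out.  Scores come from the SVD of the standardized samples × sites
matrix; explained-variance fractions are the normalized squared
singular values.

## Sweep scan

Per window the scan computes W&C Fst between candidate and reference
cohorts and π within each.  Windows with fewer than 10 usable SNPs
(stabilizes the π ratio), non-finite Fst, or zero diversity in either
cohort are excluded from ranking — excluded rather than pseudocounted,
to avoid infinite log ratios; the exclusion count is reported.  Fst
values are Z-transformed across the rankable windows (sample sd, n−1);
the diversity ratio is log₂(π_reference / π_candidate), oriented so
that a candidate-cohort sweep gives a large **positive** value (the
orientation is configurable).  Selection thresholds are the empirical
(1−q) quantiles of Z(Fst) and of the log₂ ratio (marginal thresholds,
intersected), with the "higher" quantile convention so each threshold
is an observed value and ties at the threshold are included.  Since the
Z-transform is monotone, thresholding Z(Fst) is rank-equivalent to
thresholding raw Fst.  π selection is one-tailed (candidate-depleted)
by default; a two-tailed flag selects both tails at q each for scans
where reference-depleted windows are also of interest.  Selected
windows merge when they overlap or abut (configurable gap); genes are
assigned to regions on ≥ 1 bp overlap, strand ignored, and the flat
gene list is deduplicated and sorted.

## Synthetic genotypes

The generator uses the Balding–Nichols model: ancestral frequency p ~
Uniform(0.05, 0.95) per SNP, population frequency ~
Beta(p(1−F)/F, (1−p)(1−F)/F) so the expected divergence from the
ancestral pool is F, genotypes Binomial(2, pop frequency), missingness
i.i.d.  It was chosen over coalescent simulation because it gives
closed-form control of the target Fst at negligible cost and the
pipeline's statistics are frequency-based; there is no recombination or
haplotype structure, so LD-decay behaviour on simulated data reflects
independence, not a genetic map.  Default scenario: 2 populations × 20
diploids, 5000 SNPs on a 2-Mb chromosome, F = 0.05 — densities and
divergences typical of a regional resequencing panel.

Sweep injection modifies frequencies, not haplotypes: inside the sweep
interval the candidate population's frequencies are redrawn with the
elevated local divergence F_local (default 0.6), then pushed toward the
nearer fixation point so that p'(1−p') = p(1−p)·(1−F_bg)/((1−F_local)·d),
where d is the diversity-reduction factor.  The correction term makes
the expected sweep heterozygosity exactly 1/d of the expected
background heterozygosity (the naive composition would conflate the
divergence redraw with the diversity reduction); the realized ratio is
verified at ±20% over 20 replicates.  The truth record stores the
final per-site per-population frequencies.

The truth-record Fst oracle predicts the genome-wide value as a ratio
of per-site sums with numerator s² (sample variance of the true
frequencies across populations, r−1 divisor) and denominator
p̄(1−p̄) + s²/r.  Under Balding–Nichols these have expectations
F·p(1−p) and p(1−p), so the ratio targets exactly the parameter the
W&C estimator estimates — a per-site *mean* of naive Fst values would
be biased for ratio statistics and is not used.

## Synthetic landmarks

Each specimen is the template shape plus its group's mean-shape offset
plus isotropic Gaussian landmark noise; the perturbed shape is
re-centered, normalized to unit centroid size and multiplied by the
specimen's true CS drawn from a linear model in site latitude,
longitude and altitude.  Measured CS therefore equals the recorded
truth exactly, which makes the noiseless regression-recovery contract
exact.  Nuisance rotation and translation are applied last; nuisance
*scale* is deliberately the CS channel itself — scaling again after CS
assignment would break the truth record.  Landmark noise is expressed
in template coordinate units; the default 20-landmark wing template
spans a few units (CS ≈ 5), so sd = 0.01 corresponds to roughly 0.2% of
size, a realistic digitization error.  What the generator does not
emulate: allometry (shape–size covariation), correlated landmark
errors, digitizer drift between sessions, and asymmetry — so passing
tests demonstrate algorithmic correctness, not robustness to those
real-data effects.

## Procrustes analysis

GPA centers each configuration, scales it to unit CS (full Procrustes —
size is analysed separately through CS, so keeping scale in the shape
space would double-count it), and iteratively rotates each onto the GLS
consensus with the closed-form orthogonal-Procrustes rotation
constrained to det +1 (no reflection: a reflected wing is a different
biological object).  The consensus is the coordinate-wise mean,
re-centered, re-normalized, and re-oriented to the previous consensus
so the convergence criterion (root-sum-square change, tol 1e-8, max 100
iterations) measures shape change rather than rotational drift.
Non-convergence returns a flagged result with a warning rather than an
error.  Bookstein baseline registration (two landmarks sent to (0,0)
and (1,0)) is provided for parity with classical workflows, but GPA
operates on raw coordinates by default — the two inputs differ only by
a similarity transform, which GPA removes anyway.

## ANOVA, LSD and the letter display

One-way ANOVA uses the textbook decomposition; F is undefined (error)
only when every group has zero internal variance.  Fisher's LSD
pairwise tests use the pooled within-group mean square with the ANOVA
within-group degrees of freedom and — by definition of the method — no
multiplicity correction; a corrected variant can be layered on by the
caller via the returned p-values.  The compact letter display sorts
group means descending and assigns one letter per maximal run of
mutually non-different groups; two groups share a letter iff no LSD
test separates them, under the (checked) assumption that significance
is monotone along the mean ordering.

## Stepwise regression of CS on geography

Forward stepwise OLS with backward checks: the candidate with the
smallest partial-F p-value enters if it clears alpha_enter = 0.05;
after each entry, any term with p > alpha_remove = 0.10 is dropped.
Exactly collinear candidates never enter.  The entry threshold is
Bonferroni-shared across the candidates examined at each step (default
on): with three candidates tested at a raw 0.05 each, the family-wise
probability of admitting pure noise would be ≈ 14%, so the adjustment
keeps the null entry rate near the nominal 5% — the package treats
this selection-inflation guard as the correct default, with
`adjust_entry=False` available for strict parity with classical
stepwise software.  In the noiseless single-covariate case the
residual variance is zero, the entering p-value degenerates to 0 and
the generating coefficient is recovered exactly; p-values of further
candidates on a perfect fit are NaN and are treated as 1.

## Validation problem sizes

The bundled checks run at desk scale by design: oracle equivalence on
≤ 3 populations × ≤ 6 samples × ≤ 20 SNPs; parameter recovery at 2 × 20
diploids and 5000 SNPs for F ∈ {0.05, 0.1, 0.2, 0.3}; sweep recovery on
20 replicates of the default 2-Mb scenario; GPA recovery at 50
specimens; stepwise null behaviour over 200 replicates of 30
observations.  Genome-scale quantities from real surveys (millions of
SNPs, hundreds of samples) are inputs to the summary functions, not
recomputed.

## Known limitations

- LD is composite genotype r²; no phasing, no haplotype statistics.
- The sweep scan is frequency-based (Fst + π ratio); no XP-EHH or
  other haplotype scans.
- The simulator has no recombination map, demographic history or
  selection dynamics; sweeps are injected at the frequency level.
- Gene overlap is purely positional; no functional annotation or
  enrichment.
- Morphometrics covers 2-D landmarks only; no semilandmarks,
  thin-plate-spline grids or discriminant analysis.
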