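# Methods and design notes

## Generative model (synthio)

The synthetic generator produces data with exactly the statistical
structure the downstream analysis assumes, nothing more.

**Allele-frequency clines.**  Each SNP s has a logit-linear frequency
surface `logit p_s(lat, lon) = a_s + b_s·lat + c_s·lon` (slopes in logit
units per decimal degree).  Frequencies are evaluated per population
coordinate and validated to lie strictly in (0, 1).  The pipeline default
draws baseline frequencies uniformly in [0.15, 0.5], small random slopes
(SD 0.015/degree latitude, 0.008/degree longitude), and gives the causal
SNPs a positive mean latitude slope of 0.03 logit/degree, so the risk
alleles — and hence the population mean score — rise towards the north.
That northward cline of the mean GRS is the population-level phenomenon
the spatial stages are designed to detect.

**Linkage disequilibrium.**  Haplotypes come from a latent Gaussian
copula: within each contiguous block the latent vector follows an AR(1)
process with parameter ρ ∈ [0, 1) (`z_t = ρ z_{t−1} + √(1−ρ²) e_t`), and
allele s is the alternate iff `z_s < Φ⁻¹(p_s)`.  This gives exact marginal
frequencies, tunable adjacent-SNP r² that decays geometrically within a
block, and exact independence across blocks and individuals.  No attempt
is made at coalescent realism (recombination hot-spots, allele-frequency–
dependent LD); what matters for testing the r²-based pruning rules is a
controllable blockwise r² structure, which this supplies.  Default blocks
of 5 SNPs with ρ = 0.6 give adjacent dosage r² around 0.3 — comfortably
below the 0.8 association prefilter and above the 0.2 score-pruning
threshold, so both filters are exercised.

**Case-control studies.**  Disease follows an additive logistic model
`logit P(case) = β₀ + Σ β_s g_s + β_age·age + β_sex·sex` with age ~
Normal(60, 10) years and sex ~ Bernoulli(0.5) (the cohorts being emulated
are age/sex-matched middle-aged samples; these are generic defaults, not
estimates).  Individuals are sampled in batches and accumulated until the
case and control quotas are both full; total attempts are capped at
100·(n_cases + n_controls) so a saturated β₀ fails fast instead of
looping forever.  Pipeline defaults: β₀ = −1, four causal SNPs with
log-OR 0.2–0.5, β_age = 0.01/year, β_sex = 0.3.

**Missingness and event rates.**  Genotypes are masked completely at
random at a configurable rate (default 5%).  Population event-rate tables
couple the per-population mean score linearly:
`rate = intercept + slope·mean GRS + Normal(0, σ)` per sex stratum, with
defaults 20 + 30·GRS ± 8 events/100,000/year — rates in the 150–250 range
for mean scores near 5–7, the right order of magnitude for middle-aged
coronary event surveillance.  Negative draws are truncated at zero with a
warning, since rates are physical quantities.

Because the generator has no confounding, no population stratification
within studies, no genotyping batch effects and MCAR (not informative)
missingness, passing tests demonstrate the *correctness of the machinery*
under the stated model — not robustness of the scientific conclusions to
violations of it.

## QC and imputation (geno_qc)

Call rates, minor allele frequencies and the Hardy-Weinberg exact test are
computed from observed hard calls only.  The HWE test is the standard
exact conditional test: given the allele counts, the probabilities of all
heterozygote counts of matching parity are summed over configurations no
more probable than the observed one (no mid-p correction); it is computed
with log-factorials and verified against a full-enumeration oracle.
Thresholds follow the protocol being emulated: SNPs and samples with call
rate strictly below 0.75 are removed, monomorphic SNPs are removed, and
the optional imputation-quality filter keeps scores strictly above 0.6.
Filtering runs variants → samples → variants-recheck, making the output a
fixed point of both filters.  HWE p-values are reported but never used
for automatic exclusion (no exclusion threshold is defined for this
protocol; users can filter on the reported column).

LD r² is the squared Pearson correlation of unphased dosage vectors
(composite LD) over pairwise-complete samples — deterministic, phase-free
and close to haplotype r² under HWE.

Missing genotypes are filled with the expected dosage 2·p̂, where p̂ is the
observed alternate-allele frequency within the sample's own population
group — a dosage-level stand-in for within-population reference
imputation.  Imputed entries are fractional, flagged in a separate mask,
and used as dosages downstream (association and scoring), mirroring
dosage-based analysis of imputed data.  Haplotype-based imputation is out
of scope.

## Association and meta-analysis (assoc_meta)

The logistic fitter is Newton/IRLS with step-halving, which makes the
log-likelihood provably non-decreasing per iteration (asserted);
convergence is max |score| < 1e-8 or 100 iterations; Wald standard errors
come from the inverse observed information.  Quasi-complete separation is
detected as any |β| > 15 during iteration.  The "adjusted for age, gender
and the remaining genetic variables" model is implemented as one joint fit
containing every scanned SNP dosage plus age and sex, with per-SNP Wald
statistics read off that fit; if the joint design is collinear or
separates, the scan falls back (with a warning) to per-SNP models adjusted
for age and sex.

Before scanning, SNPs are greedily prefiltered in genomic order at
r² < 0.8 (first kept wins ties).  Across studies the tested allele is
canonicalised to the lexicographically smallest alternate observed; betas
from ref/alt-swapped studies are sign-flipped and SNPs whose alleles are
not a plain swap are excluded.  Pooling is inverse-variance fixed-effects
on the log-odds scale (weights 1/SE²), the scheme whose pooled effect and
SE structure matches standard GWAS meta-analysis output; random-effects
models and heterogeneity statistics are deliberately absent.

## Risk score and prediction (grs)

Candidates must reach p < 0.1 with concordant effect direction in *every*
replicate meta-analysis (replicates emulate re-imputed versions of the
same data); the risk allele is the one with positive pooled log-odds.
Pruning is greedy in ascending minimum-across-replicates p: a candidate is
kept iff r² < 0.2 (in a designated LD-reference panel) against everything
already kept.  The score is the unweighted risk-allele dosage sum —
homozygote reference 0, heterozygote 1, homozygote risk 2, fractional for
imputed dosages — so it ranges over [0, 2m]; a beta-weighted variant
exists but is off by default.  Per-group normality is assessed by the
Anderson-Darling composite test (NaN for n < 8).

Nagelkerke R² rescales Cox-Snell `1 − exp((2/n)(ll₀ − ll₁))` by its
maximum `1 − exp((2/n)·ll₀)`; perfect separation is reported as R² = 1
with a flag rather than an exception.  AUC is the tie-corrected rank
statistic (ties count one half), with a Hanley-McNeil confidence interval
truncated to [0, 1]; DeLong intervals were considered and skipped as the
extra precision is immaterial at these sample sizes.

## Spatial statistics (spatial)

Distances are haversine great-circle km on a sphere of radius
6371.0088 km.  The default weight matrix is row-standardized inverse
distance; binary-threshold and distance-class schemes are available.
Moran's I and Geary's C use the classical formulas and are verified
against O(n²) double-loop oracles to 1e-12.  Randomization tests permute
values over locations with `p = (1 + #extreme)/(n_perm + 1)` (observed
counted among permutations, so p is never zero and is exactly reproducible
given the seed); the default alternatives are one-sided for positive
autocorrelation (greater for I, less for C).  Correlograms split the
n(n−1)/2 pairwise distances into six equal-count classes (stable sort
breaks ties) and compute both statistics with two-sided permutation p per
class, since a cline produces positive short-range and negative long-range
classes.

## Kriging (kriging)

The empirical semivariogram uses equal-width lag bins up to half the
maximum pairwise distance.  The spherical model
`γ(h) = c0 + c1(1.5 h/a − 0.5 (h/a)³)` for h ≤ a is fitted by least
squares weighted by pair counts N(h) (Cressie weights N/h² were judged
unnecessary at ≤ ~40 sites), with a deterministic multi-start grid —
nugget ∈ {0, .25, .5} and partial sill ∈ {.5, 1} of the empirical sill
proxy max γ̂, range ∈ {.25, .5, 1} of the maximum lag — to avoid local
minima.  Ordinary kriging solves the standard constrained system per grid
node with all sites (no neighborhood truncation); weights sum to 1 by
construction and are asserted to 1e-8; kriging variances are clipped at
the −1e-9 numerical floor.  Great-circle distances feed the system
directly — at regional scales the spherical variogram remains valid on
sphere distances, and implementing a map projection would buy nothing for
the tests performed here.  Grids are node-centered regular lat/lon boxes
(population bounding box padded 5% per side, 100 columns by default, one
common cell size so the ESRI ASCII export is well-formed).

## Ecological regression (ecoreg)

Per sex stratum: Spearman rho (mid-ranks, two-sided t-approximation p) and
univariate OLS per predictor; predictors with univariate slope p < 0.05
enter one multivariate OLS model; adjusted R² is
`1 − (1−R²)(n−1)/(n−k−1)`.  Outliers are flagged by externally studentized
residuals of the GRS univariate model with Bonferroni-adjusted
p = min(1, n·p) < 0.01; under the exclude-and-refit policy the flagged
populations are removed and the whole stratum analysis reruns (the report
policy leaves data untouched).  Predictors are not standardized: the
reported quantities (rank correlations, significance, R²) are scale-free.
Sex strata are fully independent analyses.

## Pipeline, seeds, determinism

One master seed; each stage derives sub-seeds by fixed integer offsets, so
stages are individually reproducible and two runs with identical config
and seed produce byte-identical outputs (verified by SHA-256 manifest
hashes).  The replicate structure of the association stage — two dosage
sets per study differing only in the missingness-mask sub-seed before
expected-dosage imputation — exists to exercise the across-replicate
intersection rule in score selection.  Config files are YAML with unknown
keys rejected and all validation errors reported at once.

## Problem sizes

Defaults were chosen as the smallest sizes at which every stage operates
in its intended regime: three studies of 2000/2000 give per-study dosage
SEs near 0.05 so log-ORs of 0.2–0.5 are reliably detected after pooling;
30 populations of 40 give per-population mean-GRS standard errors (~0.13)
well below the simulated cline amplitude; 60 SNPs in blocks of 5 exercise
both LD filters.  The test suite scales some scenarios down further
(e.g. 24 SNPs / 12 populations for determinism checks) where the property
under test does not depend on size.

## Known limitations

* Expected-dosage imputation ignores LD; it is unbiased under MCAR but
  less accurate than haplotype imputation, and integer-valued imputed
  dosages are indistinguishable from hard calls after a VCF round trip.
* The score does not rescale for residually missing genotypes (they
  contribute their group expectation), so per-individual completeness is
  not reflected in the score's variance.
* The spatial weighting scheme and correlogram class definitions are
  package defaults, not inferences about any particular published map.
* Plain OLS on population aggregates inherits the usual ecological-
  inference caveats; no spatially correlated-error models are provided.
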