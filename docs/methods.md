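# Methods

`admixsv` studies how two-way admixture shapes structural variation
(SV): allele-frequency expectations, selection-like deviations, the
dependence of SV diversity on ancestry proportion, SV creation at
ancestry junctions by non-allelic homologous recombination (NAHR),
regulatory impact (cis-eQTL, ancestry-specific variant combinations),
and SV age stratification.  Because cohort-scale SV genotypes of the
kind this analysis needs are rarely redistributable, the package pairs
every analysis with a forward-in-time generator whose ground truth the
estimators must recover; all quantitative claims in the test suite are
claims about that recovery.

## The admixture model

An admixed cohort formed from a Western (W) and an Eastern (E) source
with genome-wide ancestry proportions m_W + m_E = 1 has, for a neutral
variant with source frequencies f_W and f_E, the expected cohort
frequency

    E[f_adm] = m_W f_W + m_E f_E.

Ancestry proportions are inferred by least squares of the cohort VAF
vector on the source VAF matrix over the probability simplex (SLSQP
with non-negativity and sum-to-one constraints; loci polymorphic in at
least one source and with cohort MAF > 0.01 by default).  K-way
solutions are collapsed to two ancestries by a declared label mapping.

Deviation of an SV's observed frequency from this expectation is scored
with an ancestry-biased F_ST in the two-deme Nei form,

    p = (f_obs + f_exp)/2,  H_T = 2p(1-p),
    H_S = [2 f_obs (1-f_obs) + 2 f_exp (1-f_exp)]/2,
    F = 1 - H_S / H_T   (0 when H_T = 0).

Drift alone produces non-zero values, so the calling threshold is the
(1 - alpha) quantile of the statistic under a two-wave Wright-Fisher
null: the frequency starts at the wave-mixed source value, is
binomially resampled with 2N gene copies per generation (with later
waves re-mixing a fraction of the gene pool), and is finally sampled at
the cohort size.  Null values are pooled within 20 expected-VAF strata
because the null scale depends on allele frequency; each locus is
compared against its stratum's quantile.  Only loci with a positive
expected VAF are scanned: a locus absent from both source panels
carries no admixture expectation to deviate from.

## The generator

**Sites and sources.** Shared variants draw an ancestral frequency from
Beta(0.8, 1.2) (mildly rare-skewed, as in a merged cohort callset after
polymorphism filtering) and per-source frequencies from a
Balding-Nichols Beta draw with divergence F (default 0.08 per Eurasian
source, 0.04 for the African outgroup).  A configurable fraction of
variants (default 0.39, matching the large unshared fraction typical of
admixed-cohort callsets) is forced ancestry-specific; both sources
receive equal-sized specific sets with a shared, paired frequency
spectrum — log-uniform on (0.03, 0.12), the rare-skew expected of
young, population-specific alleles — making the two ancestral
contributions exchangeable ("symmetric sources").  SV types follow a
fixed mix (DEL 0.55, DUP 0.18, INS 0.15, INV 0.06, mCNV 0.06) with
lognormal lengths (median ~0.7 kb, capped at 100 kb).

**Admixture.** The admixed population is simulated individual by
individual: founders at the oldest wave are pure-source migrants; each
generation is formed by random mating with per-meiosis Poisson
crossovers (default 1 cM/Mb) on a diploid genome of two 50-Mb
chromosomes; later waves replace a fraction of newborns with fresh
migrants.  Wave compositions are exact up to rounding (migrant pools
come from effectively infinite sources), and the founding gene pool is
frequency-exact: each variant receives exactly round(f n) carrier
founder haplotypes per side.  Drift therefore acts purely through
descent, and the pure-drift null above matches the generator's step
count exactly.  Local-ancestry tracts are tracked exactly through every
meiosis; a sample's global ancestry is its tract-length-weighted WEST
fraction.  Genotypes are materialized by founder descent (each founder
haplotype draws its alleles once), so admixture LD and drift are
structural rather than resampled.

**NAHR and background SV creation.** Non-overlapping homologous repeat
pairs (default 5 per Mb, 500-bp repeats, log-uniform inner spans of
2-20 kb) are placed before the simulation.  Every crossover landing in
a pair is logged as a candidate event and transmitted like a mutation;
candidates are realized as a DEL or DUP between the repeats' inner
edges with probability theta_nahr, so the repeats flank the breakpoints
— the NAHR signature that `breakpoint_homology` detects by local
alignment (match +1, mismatch -1, gap -2; flag at >= 100 aligned
columns and >= 80% identity).  Background new SVs arise at rate
theta_bg per meiosis, uniformly placed and never homology-flanked.
Non-NAHR SVs carry a background homology-flank annotation at rate 0.2,
the stand-in for genome-wide repeat context.

**Expression.** A fraction of genes (default 0.3) receives one causal
cis variant within 1 Mb of the TSS with effect N(0, 0.8) floored at
|beta| >= 0.3 and unit residual noise; a sub-fraction instead receives
a same-direction pair of variants specific to different ancestries, the
planted USVC signal.

## Scenario presets

Each headline analysis is most informative under a different cohort
design, frozen in `admixsv.scenarios`:

* **parabola** — diversity vs ancestry needs wide between-individual
  ancestry variance and a large callset: a single balanced pulse five
  generations back in a population of 1600, low effective recombination
  (0.003 crossovers/Mb, giving individual ancestry sd ~ 0.24), a
  40 000-SV callset, and an ancestry-stratified 80-sample cohort
  (even quantiles of the ancestry spectrum).  In this regime the
  sliding-window series of segregating sites is dominated by the
  concave discovery curve rather than by per-sample private-variant
  noise, which is what makes the quadratic-vs-linear contrast and the
  vertex identifiable from 41 overlapping windows.
* **hotspot / hotspot_uniform** — the deeper two-wave history
  (60 and 30 generations, recent contribution 0.3, N = 200) with
  theta_nahr = 0.6 and no background events, versus the same new-SV
  budget spent uniformly.  Deep histories maximize crossover-generations
  and hence NAHR opportunities.
* **neutral** — the two-wave history with no post-admixture SV
  creation, for scan calibration.
* **estimation** — a single unbalanced pulse (default 0.6/0.4) four
  generations back in a population of 8000 with 2 cM/Mb, sampled at
  n = 300: large N and a young pulse keep the realized cohort ancestry
  within ~0.01 of the wave fraction, the regime in which
  proportion-recovery accuracy is a property of the estimator rather
  than of demographic drift.

## Analysis procedures and their knobs

* **Merging**: single-linkage within SV type at >= 50% reciprocal
  overlap (symmetric min-ratio); representative = median-start member.
  Single linkage makes the result order-independent and idempotent.
* **Diversity parabola**: samples ranked by Eastern ancestry; sliding
  subgroups of k = 40 (step 1); segregating sites exclude duplications
  (mCNVs count when >= 2 distinct copy numbers are present); OLS
  quadratic vs linear; concavity tested by permuting the
  sample-to-ancestry assignment, rebuilding windows and refitting, with
  the R² gain of the quadratic as the statistic (add-one P).
* **Pre/post classification** (stringent sharing): pre = same-type
  >= 50%-overlap match polymorphic in either source panel; post = no
  panel match and absent from every supplied external catalog;
  otherwise ambiguous.  Panels are checked before catalogs.
* **Switch-point hotspot**: per SV, the minimum distance from the start
  breakpoint to an interior ancestry-switch point over carrier
  haplotypes (both haplotypes of each carrier; phase not assumed);
  statistic = fraction of post SVs within 50 kb; null = circular
  rotation of SV positions per chromosome within the callset's own
  positional span, tracts fixed.  Pre-admixture SVs are checked for
  uniformity against their own rotation null (two-sample KS).
* **cis-eQTL**: OLS of z-scored expression on allele count (plus
  covariates) within 1 Mb of the TSS; BH over all tested pairs,
  eSV at adjusted P < 0.05.  The eSV-ratio analysis re-runs the scan on
  repeated downsamples matched to the comparison cohort's size.
* **Heritability partition**: per gene, SV fixed effect plus a cis-SNV
  random effect with a standardized-genotype relatedness matrix;
  REML on the eigenbasis of K (scalar bounded search over the variance
  ratio), with a Haseman-Elston moment estimator as the recorded
  fallback; lead-SV when the SV share exceeds the SNV share.
* **USVC**: pairs of variants specific to different ancestries
  (strict absence by default; a frequency-threshold mode for rare-allele
  leakage), in three classes (SNV inside a DEL/DUP; SV-SNV within 1 Mb;
  SV-SV within 1 Mb), kept when jointly carried by at least one sample;
  joint two-variant regression per cis gene with per-class BH and a
  dual adjusted-P < 0.1 rule; direction is `uni` when effects share a
  sign.
* **Age classes**: archaic -> ANCESTRAL, else African -> ANCIENT, else
  both sources -> OUT_OF_AFRICA, else one -> DERIVED, else
  ADMIXED_SPECIFIC; ordered-trend tests use Jonckheere-Terpstra with
  label-permutation P (normal approximation also reported).
* Permutation P-values use the add-one rule throughout; every
  stochastic routine takes an explicit seed.

## What the generator does and does not emulate

It reproduces the cohort structure that the estimators rely on: exact
local-ancestry tracts, founder-descent drift and admixture LD,
ancestry-specific site-frequency contrasts, NAHR coupling of new SVs to
crossovers, and additive cis regulation.  It does not model
haplotype-scale LD within the source populations (founder haplotypes
draw alleles independently), sequence-level mutation, recombination
hotspot maps, genotyping error, or selection; LD-dependent operations
(SNV tagging, GWAS-LD pairing) are therefore validated on constructed
fixtures rather than on generator output.  Passing tests show that the
statistics recover what was planted under these study conditions, not
that real callsets satisfy the model assumptions.

## Numerical choices and problem sizes

Coordinates are 1-based inclusive at file boundaries and 0-based
half-open internally; SVLEN is written only for insertions because
htslib derives END from SVLEN for other symbolic types under the
padding-base convention.  Missing genotypes are excluded from every
allele-count denominator.  Frequency classes are half-open
([0, 0.01), [0.01, 0.1), [0.1, 1]); divergence bins are half-open with
a single (0.3, 1] tail.  V_ST uses population variances (ddof 0) and
clips to [0, 1]; odds ratios use Haldane-Anscombe only when a cell is
zero.  Default problem sizes in the test suite — 20 replicate
simulations for recovery rates, 199-299 permutations per test, 2000
drift replicates for thresholds, three pooled cohorts for scan
calibration — were chosen so each recovery property is measured at
useful resolution while a full run of the suite stays desk-scale.

## Known limitations

The permutation null of the diversity-parabola test inherits heavy
ΔR² tails from the autocorrelation of overlapping windows, so the test
is conservative; detection needs the wide-ancestry-variance, large-
callset regime frozen in the parabola scenario.  The proportion
estimator recovers the realized cohort ancestry, which coincides with
the wave fraction only up to demographic drift (hence the large-N
estimation scenario).  With background SV creation disabled, every
post-admixture SV is NAHR-derived and homology-flanked, so the
breakpoint-homology contrast is taken against the pre-admixture group.
mCNV copy numbers are modeled as 2 + delta * (allele count) with a
per-site dosage delta, a deliberately simple multi-allelic model.
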