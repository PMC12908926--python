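# admixsv

Structural-variant (SV) population genetics for two-way admixed
cohorts — for statistical geneticists who want to ask how admixture
shapes SV diversity, frequency, creation and regulatory impact, with a
fully simulated test bed standing in for cohort genotype data that is
typically not redistributable.

Given SV/SNV genotypes, phased local-ancestry tracts, expression and
sample metadata (or a simulated cohort from the built-in generator),
the package computes:

* **Expected frequencies under admixture.** For ancestry proportions
  m_W + m_E = 1, a neutral variant with source frequencies f_W, f_E has
  expected cohort frequency E[f] = m_W·f_W + m_E·f_E.  Proportions are
  inferred by simplex-constrained least squares of cohort VAFs on
  source VAFs.
* **Ancestry-biased F_ST selection scan.**  F = 1 − H_S/H_T between the
  observed and expected VAF (two-deme Nei form), thresholded at the
  (1 − α) quantile of a two-wave Wright–Fisher pure-drift null,
  stratified by expected VAF.
* **Diversity vs ancestry proportion.**  Segregating SV sites in
  sliding subgroups of 40 samples ordered by ancestry; quadratic vs
  linear fits and a label-permutation test for the concave
  ("diversity peaks at balanced admixture") signal.
* **Ancestry-switch-point SV hotspots.**  Pre/post-admixture
  classification by a stringent sharing rule, carrier-haplotype
  distances to ancestry switches, a circular-rotation enrichment null,
  breakpoint-flank homology by local alignment, and Fisher tests for
  the NAHR (non-allelic homologous recombination) signature.
* **Regulatory analyses.**  cis-eQTL (1-Mb windows, BH), eSV ratios
  under downsampling, eSV proportion vs ancestral divergence,
  SV-vs-SNV heritability partition with lead-SV calls, and USVC —
  combinations of variants specific to different ancestries carried by
  one genome — with joint two-variant regression.
* **SV age stratification.**  Five ordered age classes from a sharing
  cascade (archaic → African → both sources → one source →
  admixed-specific), Jonckheere–Terpstra trend tests, GWAS-LD pairing
  and sharing-category enrichment.

The forward simulator (`admixsv.simpop`) is first-class: it tracks
local-ancestry tracts exactly through every meiosis, materializes
genotypes by founder descent, couples new-SV creation to crossovers
inside planted homologous repeat pairs, and plants cis-regulatory
effects — giving every estimator a ground truth to recover.
`admixsv.scenarios` freezes the cohort designs used by the test suite.

## Worked example

```python
import numpy as np
from admixsv import scenarios
from admixsv.simpop import simulate_cohort
from admixsv.core_io import vaf_matrix
from admixsv.admixstats import infer_admixture_proportions
from admixsv.dynamics import permutation_parabola_test

sim = simulate_cohort(scenarios.parabola(2))   # balanced two-way cohort

# ancestry proportions from SV frequencies alone
anc = [r for r in sim.sv_records
       if not r.id.startswith("postsv") and r.svtype != "mCNV"]
mask = (sim.panels.sv_sites["svtype"] != "mCNV").to_numpy()
fw = sim.panels.sv_geno["SRC_WEST"].mean(axis=0)[mask] / 2
fe = sim.panels.sv_geno["SRC_EAST"].mean(axis=0)[mask] / 2
ap = infer_admixture_proportions(vaf_matrix(anc),
                                 np.column_stack([fw, fe]),
                                 ["WEST", "EAST"])
print(f"m_west {ap.m_west:.3f}")

fit = permutation_parabola_test(sim.cohort.panel, sim.sv_records,
                                k=40, permutations=199, seed=2)
print(f"R2q {fit.r2_quad:.3f} R2l {fit.r2_lin:.3f} "
      f"vertex {fit.vertex:.3f} P {fit.p_permutation:.3f}")
```

prints

```
m_west 0.499
R2q 0.911 R2l 0.011 vertex 0.496 P 0.005
```

The cohort was simulated with a 0.5/0.5 admixture pulse, and the
frequency-based estimator recovers it (m̂_W = 0.499).  Across 41
sliding subgroups of 40 samples, segregating SV sites follow a concave
curve: the quadratic fit explains 91% of the variance against 1% for
the linear fit, the fitted maximum sits at an Eastern ancestry
proportion of 0.496 — diversity peaks where the two ancestral
contributions are balanced — and 199 permutations of the
sample-to-ancestry assignment never reach the observed quadratic gain
(P = 0.005).

A thin CLI covers the shell-level chores:

```
admixsv simulate --seed 7 --out cohort/     # write a full fixture set
admixsv validate cohort/*.vcf cohort/tracts.bed cohort/metadata.tsv
```

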