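"""Named generator scenarios for the package's headline analyses.

Each analysis interrogates a different aspect of admixture, and each is
most informative under a different (realistic) cohort design; these
presets freeze those designs so tests, examples and the reproduction
script all run the same study conditions.

* ``parabola``   — a recently admixed cohort (single balanced pulse five
  generations back, large population, ancestry-stratified sampling)
  with a large merged callset: the regime in which the diversity-vs-
  ancestry quadratic is identifiable from 41 sliding subgroups.
* ``hotspot``    — the deeper two-wave history with NAHR switched on
  (``theta_nahr > 0``) and background SV creation off, for switch-point
  enrichment and breakpoint-homology recovery; ``hotspot_uniform`` is
  its null twin (the same new-SV budget spent uniformly, no crossover
  coupling).
* ``neutral``    — the two-wave history with no post-admixture SV
  creation at all, for calibrating the ancestry-biased differentiation
  scan against its pure-drift null.
* ``estimation`` — a single older wave at an unbalanced fraction with a
  large population (little drift), for ancestry-proportion recovery.
"""

from __future__ import annotations

from admixsv.simpop import AdmixtureWave, SimConfig


def parabola(seed: int) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_sv=40_000, n_snv=500, n_genes=20,
        pop_size=1600,
        waves=(AdmixtureWave(5, 0.5, 1.0),),
        crossovers_per_mb=0.003,
        cohort_sampling="ancestry_stratified",
        theta_nahr=0.0, theta_bg=0.0,
    )


def hotspot(seed: int) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_sv=3000, n_snv=500, n_genes=20,
        pop_size=200,
        theta_nahr=0.6, theta_bg=0.0,
    )


def hotspot_uniform(seed: int) -> SimConfig:
    """Null twin of :func:`hotspot`: rates swapped so new SVs arise
    uniformly, never coupled to crossovers."""
    return SimConfig(
        seed=seed,
        n_sv=3000, n_snv=500, n_genes=20,
        pop_size=200,
        theta_nahr=0.0, theta_bg=0.6,
    )


def neutral(seed: int) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_sv=3000, n_snv=2000,
        pop_size=200,
        theta_nahr=0.0, theta_bg=0.0,
    )


def estimation(seed: int, west_fraction: float = 0.6) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_sv=2500, n_snv=500, n_genes=20,
        n_admixed=300,
        pop_size=8000,
        waves=(AdmixtureWave(4, west_fraction, 1.0),),
        crossovers_per_mb=0.02,
        theta_nahr=0.0, theta_bg=0.0,
    )
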