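"""Selection-related statistics on the admixed cohort.

An SV whose observed cohort VAF deviates strongly from the two-way
admixture expectation is a candidate for post-admixture selection.  The
deviation is measured with an ancestry-biased F_ST: the two-deme Nei
formulation applied to the observed and the expected VAF,

    p_bar = (f_obs + f_exp) / 2
    H_T   = 2 p_bar (1 - p_bar)
    H_S   = (2 f_obs (1 - f_obs) + 2 f_exp (1 - f_exp)) / 2
    F     = 1 - H_S / H_T          (0 when H_T = 0)

Genetic drift alone also produces non-zero values, so significance is
calibrated against a pure-drift two-wave Wright-Fisher null simulated at
the study's demographic parameters, pooled within expected-VAF strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from admixsv.core_io import MISSING, SVRecord, ValidationError
from admixsv.simpop import SimConfig, simulate_drift_null


def ancestry_biased_fst(f_obs, f_exp):
    """Two-deme Nei F_ST between observed and expected VAF.

    Symmetric in its arguments, zero when they agree, and strictly
    increasing in |f_obs - f_exp| at fixed mean.  Vectorized.
    """
    fo = np.asarray(f_obs, dtype=float)
    fe = np.asarray(f_exp, dtype=float)
    p_bar = (fo + fe) / 2
    h_t = 2 * p_bar * (1 - p_bar)
    h_s = (2 * fo * (1 - fo) + 2 * fe * (1 - fe)) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(h_t > 0, 1 - h_s / np.where(h_t > 0, h_t, 1), 0.0)
    return float(f) if f.ndim == 0 else f


@dataclass
class NeutralThreshold:
    """Frequency-stratified (1 - alpha) null quantiles of the
    ancestry-biased F_ST under pure drift."""

    alpha: float
    bin_edges: np.ndarray
    thresholds: np.ndarray
    replicates: int
    pop_size: int

    def threshold_for(self, f_exp) -> np.ndarray:
        idx = np.clip(np.digitize(np.atleast_1d(f_exp), self.bin_edges) - 1,
                      0, len(self.thresholds) - 1)
        return self.thresholds[idx]


def neutral_threshold(
    cfg: SimConfig,
    f_west: np.ndarray,
    f_east: np.ndarray,
    alpha: float = 0.01,
    replicates: int = 2000,
    seed: int | np.random.Generator = 0,
    n_bins: int = 20,
    n_sample: int | None = None,
    m_west: float | None = None,
) -> NeutralThreshold:
    """Simulate the neutral F_ST null per locus and pool per stratum.

    For every locus the admixed VAF evolves by two-wave Wright-Fisher
    drift from the wave-mixed source frequencies, F_ST is computed per
    replicate against the expected VAF, and null values are pooled in
    ``n_bins`` expected-VAF strata; the (1 - alpha) quantile per stratum
    is the calling threshold.
    """
    if replicates < int(2 / alpha):
        raise ValidationError(
            f"{replicates} replicates too few for the {1 - alpha} quantile")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if m_west is None:
        m_west = cfg.waves[-1].west_fraction
    f_exp = m_west * np.asarray(f_west) + (1 - m_west) * np.asarray(f_east)
    null_vaf = simulate_drift_null(cfg, f_west, f_east, replicates,
                                   rng=rng, n_sample=n_sample)
    null_fst = ancestry_biased_fst(null_vaf, f_exp[None, :])
    edges = np.linspace(0, f_exp.max() + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(f_exp, edges) - 1, 0, n_bins - 1)
    thresholds = np.empty(n_bins)
    overall = np.quantile(null_fst, 1 - alpha)
    for b in range(n_bins):
        vals = null_fst[:, which == b].ravel()
        thresholds[b] = np.quantile(vals, 1 - alpha) if vals.size else overall
    return NeutralThreshold(alpha, edges, thresholds, replicates, cfg.pop_size)


@dataclass
class DeviationResult:
    """Per-SV deviation scan output."""

    table: pd.DataFrame       # id, f_obs, f_exp, fst, direction, threshold, deviated
    threshold: NeutralThreshold | None = None


def deviation_scan(
    ids: Sequence[str],
    f_obs: np.ndarray,
    f_west: np.ndarray,
    f_east: np.ndarray,
    m_west: float,
    threshold: NeutralThreshold | float,
) -> DeviationResult:
    """Ancestry-biased F_ST per SV with the excess-ancestry direction.

    The direction says which source's allele is over-represented: when
    the observed VAF exceeds the expectation, the cohort carries more of
    the allele than its ancestry mix predicts, i.e. an excess of the
    ancestry in which the allele is more frequent.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    fw = np.asarray(f_west, dtype=float)
    fe = np.asarray(f_east, dtype=float)
    f_exp = m_west * fw + (1 - m_west) * fe
    fst = ancestry_biased_fst(f_obs, f_exp)
    excess_alt = f_obs > f_exp
    west_allele = fw > fe
    direction = np.where(
        f_obs == f_exp, "none",
        np.where(excess_alt == west_allele, "excess-WEST", "excess-EAST"))
    if isinstance(threshold, NeutralThreshold):
        thr = threshold.threshold_for(f_exp)
        thr_obj = threshold
    else:
        thr = np.full(len(f_obs), float(threshold))
        thr_obj = None
    table = pd.DataFrame({
        "id": list(ids), "f_obs": f_obs, "f_exp": f_exp, "fst": fst,
        "direction": direction, "threshold": thr,
        "deviated": fst >= thr,
    })
    return DeviationResult(table, thr_obj)


def call_deviated_svs(result: DeviationResult) -> pd.DataFrame:
    """The flagged subset of a deviation scan."""
    return result.table[result.table["deviated"]].reset_index(drop=True)


@dataclass
class VstResult:
    vst: float
    n1: int
    n2: int
    zero_variance: bool = False


def vst(cn1: np.ndarray, cn2: np.ndarray) -> VstResult:
    """Copy-number differentiation V_ST between two populations.

    V_ST = (V_T - (n1 V_1 + n2 V_2) / (n1 + n2)) / V_T with population
    variances (ddof 0); clipped to [0, 1]; 0 (flagged) when V_T = 0.
    Shift-invariant in the copy numbers.
    """
    a = np.asarray(cn1, dtype=float)
    b = np.asarray(cn2, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValidationError("V_ST needs >= 2 samples per population")
    v_t = np.concatenate([a, b]).var()
    if v_t == 0:
        return VstResult(0.0, n1, n2, zero_variance=True)
    within = (n1 * a.var() + n2 * b.var()) / (n1 + n2)
    return VstResult(float(np.clip((v_t - within) / v_t, 0, 1)), n1, n2)


def archaic_origin_cnvs(
    cnv_records: Sequence[SVRecord],
    introgressed_copies: pd.DataFrame,
    archaic_table: pd.DataFrame,
    r2_min: float = 0.8,
) -> pd.DataFrame:
    """Tag CNVs whose genotypes track archaic introgressed copy counts.

    ``introgressed_copies`` is variants x samples (index: variant id);
    ``archaic_table`` has columns id, lineage (Neanderthal/Denisovan).
    A CNV is assigned an archaic origin iff the squared Pearson
    correlation between its genotype and the introgressed-copy vector is
    >= r2_min AND the variant appears in the archaic table; pairs with a
    zero-variance vector are skipped.
    """
    lineage_of = dict(zip(archaic_table["id"], archaic_table["lineage"]))
    rows = []
    for rec in cnv_records:
        origin, r2 = "none", float("nan")
        if rec.id in introgressed_copies.index:
            g = np.where(rec.genotypes == MISSING, np.nan, rec.genotypes)
            ic = introgressed_copies.loc[rec.id].to_numpy(dtype=float)
            ok = ~np.isnan(g) & ~np.isnan(ic)
            if ok.sum() >= 3 and g[ok].std() > 0 and ic[ok].std() > 0:
                r2 = float(stats.pearsonr(g[ok], ic[ok])[0] ** 2)
                if r2 >= r2_min and rec.id in lineage_of:
                    origin = str(lineage_of[rec.id])
        rows.append({"id": rec.id, "r2": r2, "origin": origin})
    return pd.DataFrame(rows)
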