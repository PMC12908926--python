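"""Population-structure and admixture quantities.

The central model is two-way linear admixture of allele frequencies: an
admixed cohort with WEST ancestry fraction m_W has expected variant
allele frequency

    E[f_admixed] = m_W * f_west + (1 - m_W) * f_east

for a neutrally evolving variant.  Ancestry proportions are inferred by
constrained least squares of the admixed VAF vector on the source VAF
matrix over the probability simplex, the minimal faithful reading of a
frequency-based linear model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence
import warnings

import numpy as np
from scipy import optimize, stats

from admixsv.core_io import (
    MISSING,
    SVRecord,
    ValidationError,
    reciprocal_overlap,
)


@dataclass
class AncestryProportions:
    """Per-component mixing proportions plus their two-way aggregation."""

    labels: list[str]
    proportions: np.ndarray
    m_west: float
    m_east: float
    residual: float = float("nan")
    west_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if (self.proportions < -1e-9).any():
            raise ValidationError("proportions must be non-negative")
        if abs(self.proportions.sum() - 1) > 1e-9:
            raise ValidationError("proportions must sum to 1")
        if abs(self.m_west + self.m_east - 1) > 1e-9:
            raise ValidationError("two-way aggregation must sum to 1")


@dataclass
class SharingEstimate:
    """Fraction of admixed SVs found in ancestry-weighted source panels
    (a lower bound on ancestral sharing)."""

    fractions: np.ndarray
    mean: float
    sd: float


def pca_genotypes(G: np.ndarray, n_components: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """PCA of a samples x variants allele-count matrix.

    Columns are mean-centered and variance-standardized (monomorphic
    columns dropped); returns sample coordinates and the explained
    variance per component, with the deterministic sign convention that
    each component's largest-magnitude loading is positive.
    """
    G = np.asarray(G, dtype=float)
    sd = G.std(axis=0)
    keep = sd > 0
    X = (G[:, keep] - G[:, keep].mean(axis=0)) / sd[keep]
    rank = min(X.shape)
    if n_components > rank:
        raise ValidationError(
            f"requested {n_components} components exceeds rank {rank}")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    flip = np.sign(Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    coords = (U * S) * flip
    explained = S**2 / (X.shape[0] - 1)
    return coords[:, :n_components], explained[:n_components]


def aggregate_two_way(labels: Sequence[str], proportions: Sequence[float],
                      west_labels: Sequence[str]) -> tuple[float, float]:
    """Collapse K components onto WEST/EAST by the given label mapping."""
    props = np.asarray(proportions, dtype=float)
    m_w = float(sum(p for lab, p in zip(labels, props) if lab in set(west_labels)))
    return m_w, float(props.sum() - m_w)


def infer_admixture_proportions(
    f_admixed: np.ndarray,
    f_sources: np.ndarray,
    labels: Sequence[str],
    west_labels: Sequence[str] = ("WEST",),
    min_maf: float = 0.01,
) -> AncestryProportions:
    """Constrained least squares of the admixed VAF on source VAFs.

    Minimizes ||f_admixed - F m||^2 subject to m >= 0, sum(m) = 1.
    Loci are restricted to those polymorphic in at least one source and
    with admixed MAF above ``min_maf``.  Collinear source columns give a
    warning but a solution is still returned.
    """
    f = np.asarray(f_admixed, dtype=float)
    F = np.asarray(f_sources, dtype=float)
    if F.ndim != 2 or F.shape[1] < 2:
        raise ValidationError("need at least two source populations")
    if len(f) < F.shape[1]:
        raise ValidationError("need at least K variants for K sources")
    maf = np.minimum(f, 1 - f)
    keep = (F.max(axis=1) > 0) & (maf > min_maf) & ~np.isnan(f)
    f, F = f[keep], F[keep]
    if np.linalg.matrix_rank(F) < F.shape[1]:
        warnings.warn("collinear source frequency columns")
    K = F.shape[1]
    res = optimize.minimize(
        lambda m: float(np.sum((f - F @ m) ** 2)),
        x0=np.full(K, 1 / K),
        jac=lambda m: 2 * F.T @ (F @ m - f),
        bounds=[(0, 1)] * K,
        constraints=[{"type": "eq", "fun": lambda m: m.sum() - 1}],
        method="SLSQP",
    )
    m = np.clip(res.x, 0, None)
    m /= m.sum()
    m_w, m_e = aggregate_two_way(labels, m, west_labels)
    return AncestryProportions(list(labels), m, m_w, m_e,
                               residual=float(np.sum((f - F @ m) ** 2)),
                               west_labels=tuple(west_labels))


def expected_vaf(m_west: float, f_west, f_east):
    """Expected admixed VAF under two-way linear admixture:
    m_W * f_west + (1 - m_W) * f_east."""
    fw = np.asarray(f_west, dtype=float)
    fe = np.asarray(f_east, dtype=float)
    if not 0 <= m_west <= 1:
        raise ValidationError("m_west must lie in [0, 1]")
    if np.any((fw < 0) | (fw > 1)) or np.any((fe < 0) | (fe > 1)):
        raise ValidationError("frequencies must lie in [0, 1]")
    out = m_west * fw + (1 - m_west) * fe
    return float(out) if out.ndim == 0 else out


def expected_observed_agreement(expected: np.ndarray, observed: np.ndarray) -> float:
    """Pearson correlation between expected and observed VAF vectors."""
    e = np.asarray(expected, dtype=float)
    o = np.asarray(observed, dtype=float)
    if e.shape != o.shape or len(e) < 3:
        raise ValidationError("need equal-length vectors of length >= 3")
    if e.std() == 0 or o.std() == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(e, o)[0])


def _match_table(admixed_svs: Sequence[SVRecord], panel_svs: Sequence[SVRecord],
                 threshold: float = 0.5) -> list[list[int]]:
    """For each admixed SV, indices of same-type panel SVs at >= threshold
    reciprocal overlap."""
    by_key: dict[tuple[str, str], list[tuple[int, SVRecord]]] = {}
    for j, r in enumerate(panel_svs):
        by_key.setdefault((r.interval.chrom, r.svtype), []).append((j, r))
    out = []
    for r in admixed_svs:
        hits = [
            j for j, q in by_key.get((r.interval.chrom, r.svtype), ())
            if reciprocal_overlap(r.interval, q.interval) >= threshold
        ]
        out.append(hits)
    return out


def sharing_proportion(
    admixed_svs: Sequence[SVRecord],
    west_svs: Sequence[SVRecord],
    east_svs: Sequence[SVRecord],
    m_west: float,
    n_match: int,
    replicates: int = 100,
    seed: int | np.random.Generator = 0,
    threshold: float = 0.5,
) -> SharingEstimate:
    """Fraction of admixed SVs found in ancestry-weighted source panels.

    Per replicate, round(m_W * n_match) WEST and the remaining EAST
    samples are drawn; an admixed SV counts as ancestry-derived if a
    same-type >= 50%-reciprocal-overlap match is polymorphic (allele
    count >= 1) among the drawn samples.  The mean over replicates is a
    lower bound on the ancestral sharing fraction.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_w = int(round(m_west * n_match))
    n_e = n_match - n_w
    sizes = {
        "west": len(west_svs[0].genotypes) if west_svs else 0,
        "east": len(east_svs[0].genotypes) if east_svs else 0,
    }
    if n_w > sizes["west"] or n_e > sizes["east"]:
        raise ValidationError("n_match exceeds a panel size")
    west_hits = _match_table(admixed_svs, west_svs, threshold)
    east_hits = _match_table(admixed_svs, east_svs, threshold)
    Gw = np.array([np.where(r.genotypes == MISSING, 0, r.genotypes)
                   for r in west_svs]) if west_svs else np.zeros((0, 0))
    Ge = np.array([np.where(r.genotypes == MISSING, 0, r.genotypes)
                   for r in east_svs]) if east_svs else np.zeros((0, 0))
    fractions = np.empty(replicates)
    for b in range(replicates):
        iw = rng.choice(sizes["west"], size=n_w, replace=False)
        ie = rng.choice(sizes["east"], size=n_e, replace=False)
        pw = (Gw[:, iw].sum(axis=1) > 0) if n_w else np.zeros(len(west_svs), bool)
        pe = (Ge[:, ie].sum(axis=1) > 0) if n_e else np.zeros(len(east_svs), bool)
        found = [
            any(pw[j] for j in wh) or any(pe[j] for j in eh)
            for wh, eh in zip(west_hits, east_hits)
        ]
        fractions[b] = np.mean(found) if found else float("nan")
    return SharingEstimate(fractions, float(np.nanmean(fractions)),
                           float(np.nanstd(fractions)))
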