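"""Admixture-dynamics analyses.

Two headline questions about an admixed cohort:

1. How does SV diversity depend on ancestry proportion?  Sliding
   subgroups of k samples ordered by EAST ancestry give (mean ancestry,
   segregating-site count) points; a quadratic and a linear model are
   fitted and the concavity signal (the R-squared gain of the quadratic)
   is tested by permuting the sample-to-ancestry assignment.  Under
   balanced two-way admixture the diversity peaks near equal ancestry,
   so the fitted vertex sits near 0.5.

2. Are post-admixture SVs created at ancestry-switch points?  SVs are
   classified pre/post by a stringent sharing rule, each SV gets the
   minimum distance from its start breakpoint to an ancestry-switch
   point over carrier haplotypes, and enrichment of post SVs within a
   window of a switch point is tested against a circular-rotation null.
   NAHR leaves homologous breakpoint flanks, tested by local alignment
   of the outer flanks and a Fisher exact 2x2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from admixsv.core_io import (
    MISSING,
    AncestryTract,
    GenomicInterval,
    PopulationPanel,
    SVRecord,
    ValidationError,
    reciprocal_overlap,
    switch_points,
)


# ---------------------------------------------------------------------------
# diversity vs ancestry proportion
# ---------------------------------------------------------------------------

@dataclass
class DiversityPoint:
    east_mean: float
    segregating: int
    sample_idx: np.ndarray


@dataclass
class FitResult:
    quad_coef: tuple[float, float, float]   # a, b, c of a x^2 + b x + c
    r2_quad: float
    lin_coef: tuple[float, float]
    r2_lin: float
    vertex: float | None
    delta_r2: float
    p_permutation: float | None = None


def sequential_subpopulations(panel: PopulationPanel, k: int = 40) -> list[np.ndarray]:
    """Sliding windows of k consecutive samples ranked by EAST ancestry
    (step 1); window means are non-decreasing along the series."""
    if panel.ancestry_west is None:
        raise ValidationError("panel lacks ancestry proportions")
    n = len(panel)
    if n < k:
        raise ValidationError(f"cohort of {n} smaller than subgroup size {k}")
    east = 1 - panel.ancestry_west
    order = np.argsort(east, kind="stable")
    return [order[i:i + k] for i in range(n - k + 1)]


def segregating_sites(records: Sequence[SVRecord], sample_idx: np.ndarray,
                      exclude_types: frozenset[str] = frozenset({"DUP"})) -> int:
    """Variants polymorphic within the subset: 1..2n-1 alternate alleles
    among called alleles (mCNV: at least 2 distinct copy numbers)."""
    if len(sample_idx) == 0:
        raise ValidationError("empty sample subset")
    count = 0
    for r in records:
        if r.svtype in exclude_types:
            continue
        g = r.genotypes[sample_idx]
        called = g[g != MISSING]
        if called.size == 0:
            continue
        if r.svtype == "mCNV":
            count += len(np.unique(called)) >= 2
        else:
            ac = int(called.sum())
            count += 0 < ac < 2 * called.size
    return count


def diversity_points(records: Sequence[SVRecord], panel: PopulationPanel,
                     k: int = 40,
                     exclude_types: frozenset[str] = frozenset({"DUP"}),
                     ) -> list[DiversityPoint]:
    east = 1 - panel.ancestry_west
    return [
        DiversityPoint(float(east[idx].mean()),
                       segregating_sites(records, idx, exclude_types), idx)
        for idx in sequential_subpopulations(panel, k)
    ]


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1 - ss_res / ss_tot if ss_tot > 0 else 0.0


def fit_diversity_models(points: Sequence[DiversityPoint]) -> FitResult:
    """OLS quadratic vs linear fit of segregating sites on mean EAST
    ancestry; the vertex -b/(2a) is reported for concave fits."""
    if len(points) < 5:
        raise ValidationError("need at least 5 diversity points")
    x = np.array([p.east_mean for p in points])
    y = np.array([p.segregating for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("all ancestry means identical")
    qa, qb, qc = np.polyfit(x, y, 2)
    la, lb = np.polyfit(x, y, 1)
    r2q = _r2(y, np.polyval([qa, qb, qc], x))
    r2l = _r2(y, np.polyval([la, lb], x))
    vertex = float(-qb / (2 * qa)) if qa < 0 else None
    return FitResult((float(qa), float(qb), float(qc)), r2q,
                     (float(la), float(lb)), r2l, vertex,
                     delta_r2=max(r2q - r2l, 0.0))


def permutation_parabola_test(
    panel: PopulationPanel,
    records: Sequence[SVRecord],
    k: int = 40,
    permutations: int = 1000,
    seed: int | np.random.Generator = 0,
    exclude_types: frozenset[str] = frozenset({"DUP"}),
) -> FitResult:
    """Permutation P for the concavity signal.

    The observed R-squared gain of the quadratic over the linear fit is
    compared against refits under random permutation of the
    sample-to-ancestry-proportion assignment (add-one rule).
    """
    import warnings
    if permutations < 99:
        warnings.warn("fewer than 99 permutations: coarse P-value")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    obs = fit_diversity_models(diversity_points(records, panel, k, exclude_types))
    counter = _sliding_window_counter(records, k, exclude_types)
    east = 1 - panel.ancestry_west
    n = len(panel)
    exceed = 0
    for _ in range(permutations):
        perm_east = east[rng.permutation(n)]
        order = np.argsort(perm_east, kind="stable")
        ys = counter(order)
        xs = _sliding_means(perm_east[order], k)
        pts = [DiversityPoint(float(x), int(y), None)
               for x, y in zip(xs, ys)]
        try:
            fit = fit_diversity_models(pts)
        except ValidationError:
            continue
        if fit.delta_r2 >= obs.delta_r2:
            exceed += 1
    p = (1 + exceed) / (permutations + 1)
    return FitResult(obs.quad_coef, obs.r2_quad, obs.lin_coef, obs.r2_lin,
                     obs.vertex, obs.delta_r2, p_permutation=p)


def _sliding_means(sorted_vals: np.ndarray, k: int) -> np.ndarray:
    cs = np.concatenate([[0.0], np.cumsum(sorted_vals)])
    return (cs[k:] - cs[:-k]) / k


def _sliding_window_counter(records, k, exclude_types):
    """Segregating-site counts for all k-windows of a sample ordering.

    Biallelic types use cumulative allele/called counts; mCNVs use a
    sliding min/max (distinct copy numbers present iff max > min).
    Falls back to the per-window scan when genotypes contain missing
    calls, where the cumulative trick would miscount mCNVs.
    """
    bial = [r for r in records
            if r.svtype not in exclude_types and r.svtype != "mCNV"]
    mc = [r for r in records
          if r.svtype not in exclude_types and r.svtype == "mCNV"]
    G = (np.stack([r.genotypes for r in bial]).astype(np.int32)
         if bial else np.zeros((0, 1), np.int32))
    Gm = (np.stack([r.genotypes for r in mc]).astype(np.int32)
          if mc else None)
    has_missing = bool((G == MISSING).any()
                       or (Gm is not None and (Gm == MISSING).any()))

    if has_missing:
        def slow(order: np.ndarray) -> np.ndarray:
            return np.array([
                segregating_sites(records, order[i:i + k], exclude_types)
                for i in range(len(order) - k + 1)])
        return slow

    from numpy.lib.stride_tricks import sliding_window_view

    def fast(order: np.ndarray) -> np.ndarray:
        nwin = len(order) - k + 1
        total = np.zeros(nwin, dtype=np.int64)
        if G.shape[0]:
            g = G[:, order]
            cs = np.concatenate(
                [np.zeros((g.shape[0], 1), np.int64),
                 np.cumsum(g, axis=1, dtype=np.int64)], axis=1)
            ac = cs[:, k:] - cs[:, :-k]
            total += ((ac > 0) & (ac < 2 * k)).sum(axis=0)
        if Gm is not None and Gm.shape[0]:
            gm = Gm[:, order]
            win = sliding_window_view(gm, k, axis=1)
            total += (win.max(axis=2) > win.min(axis=2)).sum(axis=0)
        return total

    return fast


# ---------------------------------------------------------------------------
# pre/post classification and switch-point analysis
# ---------------------------------------------------------------------------

def classify_pre_post(
    admixed_svs: Sequence[SVRecord],
    west_svs: Sequence[SVRecord],
    east_svs: Sequence[SVRecord],
    catalogs: Sequence[Sequence[tuple[GenomicInterval, str]]] = (),
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Stringent sharing classification.

    pre: a same-type >= 50%-reciprocal-overlap match is polymorphic in
    either source panel.  post: no source-panel match AND absent from
    every provided external catalog.  Otherwise ambiguous (rule order
    fixed: panels are checked before catalogs).
    """
    def poly_index(panel_svs):
        out: dict[tuple[str, str], list[tuple[GenomicInterval, bool]]] = {}
        for r in panel_svs:
            g = r.genotypes[r.genotypes != MISSING]
            if r.svtype == "mCNV":
                poly = bool(g.size and (g != 2).any())
            else:
                poly = bool(g.size and g.sum() > 0)
            out.setdefault((r.interval.chrom, r.svtype), []).append(
                (r.interval, poly))
        return out

    west_ix, east_ix = poly_index(west_svs), poly_index(east_svs)
    cat_ix: list[dict] = []
    for cat in catalogs:
        d: dict[tuple[str, str], list[GenomicInterval]] = {}
        for iv, t in cat:
            d.setdefault((iv.chrom, t), []).append(iv)
        cat_ix.append(d)

    labels = []
    for r in admixed_svs:
        key = (r.interval.chrom, r.svtype)
        in_source = any(
            poly and reciprocal_overlap(r.interval, iv) >= threshold
            for ix in (west_ix, east_ix)
            for iv, poly in ix.get(key, ())
        )
        if in_source:
            labels.append("pre")
            continue
        in_catalog = any(
            reciprocal_overlap(r.interval, iv) >= threshold
            for d in cat_ix for iv in d.get(key, ())
        )
        labels.append("ambiguous" if in_catalog else "post")
    return pd.DataFrame({"id": [r.id for r in admixed_svs], "label": labels})


def switch_distance(
    sv: SVRecord,
    boundaries: Mapping[tuple[str, int, str], np.ndarray],
    samples: Sequence[str],
) -> float:
    """Minimum distance from the SV start breakpoint to an interior
    ancestry-switch point over carrier haplotypes (both haplotypes of a
    carrier; phase is not assumed).  inf when no carrier haplotype has
    a switch on the SV's chromosome."""
    carrier_idx = np.flatnonzero(
        (sv.genotypes != MISSING)
        & (sv.genotypes != (2 if sv.svtype == "mCNV" else 0)))
    if carrier_idx.size == 0:
        raise ValidationError(f"{sv.id}: no carrier samples")
    chrom = sv.interval.chrom
    pos = sv.interval.start
    best = float("inf")
    found_tracts = False
    for i in carrier_idx:
        for hap in (0, 1):
            key = (samples[i], hap, chrom)
            if key in boundaries:
                found_tracts = True
                pts = boundaries[key]
                if pts.size:
                    j = np.searchsorted(pts, pos)
                    for cand in (j - 1, j):
                        if 0 <= cand < pts.size:
                            best = min(best, abs(int(pts[cand]) - pos))
    if not found_tracts:
        raise ValidationError(f"{sv.id}: carriers have no ancestry tracts")
    return best


@dataclass
class SwitchAnalysis:
    statistic: float               # fraction of post SVs within the window
    null: np.ndarray
    p_value: float
    window: int
    distances_post: np.ndarray
    distances_pre: np.ndarray
    pre_uniformity_p: float | None


def switch_enrichment_test(
    post_svs: Sequence[SVRecord],
    pre_svs: Sequence[SVRecord],
    tracts: Sequence[AncestryTract],
    samples: Sequence[str],
    chrom_lengths: dict[str, int],
    window: int = 50_000,
    permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> SwitchAnalysis:
    """Enrichment of post-admixture SVs near ancestry-switch points.

    Statistic: fraction of post SVs whose carrier-haplotype switch
    distance is <= window.  Null: SV positions circularly rotated along
    each chromosome (one offset per chromosome per replicate) with the
    tract mosaic fixed; one-sided add-one P.  Pre-admixture SVs are
    additionally tested for uniformity of distances against their own
    rotation null (two-sample KS).
    """
    if not post_svs:
        raise ValidationError("no post-admixture SVs to test")
    boundaries = switch_points(tracts)
    if not any(v.size for v in boundaries.values()):
        raise ValidationError("tracts contain no ancestry switches anywhere")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    def merged_boundaries(sv: SVRecord) -> np.ndarray:
        """Union of switch points over the SV's carrier haplotypes; the
        minimum carrier-haplotype distance is the nearest union point."""
        carrier_idx = np.flatnonzero(
            (sv.genotypes != MISSING)
            & (sv.genotypes != (2 if sv.svtype == "mCNV" else 0)))
        pts = [boundaries[(samples[i], hap, sv.interval.chrom)]
               for i in carrier_idx for hap in (0, 1)
               if (samples[i], hap, sv.interval.chrom) in boundaries]
        return (np.unique(np.concatenate(pts)) if pts
                else np.array([], dtype=np.int64))

    def nearest(pts: np.ndarray, pos: np.ndarray) -> np.ndarray:
        if pts.size == 0:
            return np.full(np.shape(pos), np.inf)
        j = np.clip(np.searchsorted(pts, pos), 1, pts.size - 1)
        lo = np.abs(pos - pts[j - 1])
        hi = np.abs(pts[np.minimum(j, pts.size - 1)] - pos)
        return np.minimum(lo, hi).astype(float)

    chroms = sorted(chrom_lengths)
    ci = {c: i for i, c in enumerate(chroms)}
    # rotation domain: the callset's own positional span per chromosome,
    # so the null respects any margins in where SVs can sit
    dom_lo = {c: chrom_lengths[c] for c in chroms}
    dom_hi = {c: 0 for c in chroms}
    for sv in list(post_svs) + list(pre_svs):
        c = sv.interval.chrom
        dom_lo[c] = min(dom_lo[c], sv.interval.start)
        dom_hi[c] = max(dom_hi[c], sv.interval.start + 1)
    for c in chroms:
        if dom_hi[c] <= dom_lo[c]:
            dom_lo[c], dom_hi[c] = 0, chrom_lengths[c]
    offsets = np.column_stack([
        rng.integers(1, max(dom_hi[c] - dom_lo[c], 2), size=permutations)
        for c in chroms])

    def dist_matrix(svs) -> tuple[np.ndarray, np.ndarray]:
        """(observed distances, permutations x n_sv null distances)."""
        d_obs = np.empty(len(svs))
        d_null = np.empty((permutations, len(svs)))
        for i, sv in enumerate(svs):
            pts = merged_boundaries(sv)
            c = sv.interval.chrom
            pos = sv.interval.start
            d_obs[i] = nearest(pts, np.array([pos]))[0]
            span = dom_hi[c] - dom_lo[c]
            rot = dom_lo[c] + (pos - dom_lo[c] + offsets[:, ci[c]]) % span
            d_null[:, i] = nearest(pts, rot)
        return d_obs, d_null

    d_post, null_post = dist_matrix(post_svs)
    finite = np.isfinite(d_post)
    if not finite.any():
        raise ValidationError("no post SV has a carrier haplotype with switches")
    obs = float((d_post[finite] <= window).mean())
    nf = np.isfinite(null_post)
    with np.errstate(invalid="ignore"):
        null = np.where(
            nf.any(axis=1),
            np.nansum((null_post <= window) & nf, axis=1)
            / np.maximum(nf.sum(axis=1), 1),
            0.0)
    p = (1 + int((null >= obs).sum())) / (permutations + 1)

    pre_p = None
    d_pre = np.array([])
    if pre_svs:
        d_pre, null_pre = dist_matrix(pre_svs)
        pool = null_pre[:min(50, permutations)].ravel()
        a, bb = d_pre[np.isfinite(d_pre)], pool[np.isfinite(pool)]
        if a.size >= 5 and bb.size >= 5:
            pre_p = float(stats.ks_2samp(a, bb).pvalue)
    return SwitchAnalysis(obs, null, float(p), window, d_post, d_pre, pre_p)


# ---------------------------------------------------------------------------
# breakpoint homology
# ---------------------------------------------------------------------------

def breakpoint_homology(
    sv: SVRecord,
    reference: Mapping[str, str],
    flank: int = 500,
    min_len: int = 100,
    min_ident: float = 0.8,
) -> dict:
    """NAHR signature: local alignment of the two outer breakpoint
    flanks (match +1, mismatch -1, gap -2); flagged iff the best
    alignment covers >= min_len columns at >= min_ident identity.
    Flanks truncated by a contig edge are shortened and noted.
    """
    seq = reference[sv.interval.chrom]
    ls = max(0, sv.interval.start - flank)
    left = seq[ls:sv.interval.start]
    right = seq[sv.interval.end:sv.interval.end + flank]
    truncated = len(left) < flank or len(right) < flank
    if not left or not right:
        return {"id": sv.id, "homologous": False, "score": 0.0,
                "columns": 0, "identity": 0.0, "truncated": True}
    aligner = Align.PairwiseAligner(mode="local", match_score=1,
                                    mismatch_score=-1, open_gap_score=-2,
                                    extend_gap_score=-2)
    aln = aligner.align(left, right)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    return {
        "id": sv.id,
        "homologous": bool(columns >= min_len and identity >= min_ident),
        "score": float(aln.score),
        "columns": int(columns),
        "identity": float(identity),
        "truncated": truncated,
    }


def homology_enrichment_fisher(
    at_switch_flags: Sequence[bool],
    elsewhere_flags: Sequence[bool],
) -> dict:
    """Fisher exact test of flanking homology: SVs at a switch point vs
    SVs elsewhere.  Two-sided P with the one-sided (enrichment) value
    also reported; odds ratio uses the Haldane-Anscombe correction when
    a cell is zero."""
    a = int(np.sum(at_switch_flags))          # at switch, homologous
    b = len(at_switch_flags) - a
    c = int(np.sum(elsewhere_flags))          # elsewhere, homologous
    d = len(elsewhere_flags) - c
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValidationError(f"empty margin in table [[{a},{b}],[{c},{d}]]")
    table = np.array([[a, b], [c, d]])
    p_two = float(stats.fisher_exact(table, alternative="two-sided")[1])
    p_greater = float(stats.fisher_exact(table, alternative="greater")[1])
    if 0 in (a, b, c, d):
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        corrected = True
    else:
        orr = (a * d) / (b * c)
        corrected = False
    return {"table": table, "odds_ratio": float(orr), "p_two_sided": p_two,
            "p_one_sided": p_greater, "haldane_anscombe": corrected}
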