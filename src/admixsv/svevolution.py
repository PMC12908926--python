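"""Evolutionary stratification of SVs and trend tests.

SVs in the admixed cohort are assigned one of five ordered age classes
by a sharing cascade over presence in progressively younger panels
(archaic hominin, African outgroup, both Eurasian sources, one source,
admixed-only), and properties such as length, frequency, regulatory
effect size and predicted pathogenicity are tested for a monotone trend
across the ordered classes with the Jonckheere-Terpstra statistic
(permutation P by default).  GWAS relevance is assessed through strong
genotype LD between SVs and trait-associated SNVs, with sharing-category
enrichment odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from admixsv.core_io import MISSING, SNVRecord, SVRecord, ValidationError
from admixsv.callset import ld_r2

AGE_CLASSES = ("ANCESTRAL", "ANCIENT", "OUT_OF_AFRICA", "DERIVED",
               "ADMIXED_SPECIFIC")

SHARING_CATEGORIES = ("ADMIXED_SPECIFIC", "WEST_SHARED", "EAST_SHARED",
                      "EURASIAN_SHARED")


def assign_age_class(archaic: bool, african: bool, west: bool, east: bool,
                     admixed: bool) -> str:
    """Sharing cascade, oldest first.

    archaic -> ANCESTRAL; else African -> ANCIENT; else both sources ->
    OUT_OF_AFRICA; else one source -> DERIVED; else ADMIXED_SPECIFIC.
    Classes are defined on the admixed callset, so the variant must be
    present there.
    """
    if not admixed:
        raise ValidationError("age classes are defined on the admixed callset")
    if archaic:
        return "ANCESTRAL"
    if african:
        return "ANCIENT"
    if west and east:
        return "OUT_OF_AFRICA"
    if west or east:
        return "DERIVED"
    return "ADMIXED_SPECIFIC"


def sharing_category(west: bool, east: bool) -> str:
    """Four-way sharing with the two source panels."""
    if west and east:
        return "EURASIAN_SHARED"
    if west:
        return "WEST_SHARED"
    if east:
        return "EAST_SHARED"
    return "ADMIXED_SPECIFIC"


@dataclass
class TrendResult:
    jt: float
    p_permutation: float
    p_normal: float
    group_sizes: list[int]
    direction: str       # increasing | decreasing | none


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    """Sum over ordered group pairs of Mann-Whitney counts, ties 1/2."""
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i][:, None], groups[j][None, :]
            jt += float((a < b).sum()) + 0.5 * float((a == b).sum())
    return jt


def jonckheere_trend(
    groups: Sequence[np.ndarray],
    permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> TrendResult:
    """Jonckheere-Terpstra test for a monotone trend across ordered
    groups.

    JT sums the pairwise Mann-Whitney counts over ordered group pairs
    (at two groups JT equals the Mann-Whitney U).  The default P comes
    from permuting group labels (add-one rule, two-sided via the larger
    tail doubled is not used: trend direction is one-sided toward
    increase, with the decreasing direction reported symmetrically);
    the normal approximation is also reported.  Empty groups are
    dropped with a note.
    """
    import warnings
    gs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in gs):
        warnings.warn("dropping empty groups")
        gs = [g for g in gs if len(g)]
    if len(gs) < 2:
        raise ValidationError("need at least 2 nonempty groups")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    jt = _jt_statistic(gs)
    sizes = [len(g) for g in gs]
    n = sum(sizes)
    mean = (n * n - sum(s * s for s in sizes)) / 4
    var = (n * n * (2 * n + 3) - sum(s * s * (2 * s + 3) for s in sizes)) / 72
    z = (jt - mean) / np.sqrt(var) if var > 0 else 0.0
    p_norm = float(2 * stats.norm.sf(abs(z)))

    pooled = np.concatenate(gs)
    bounds = np.cumsum([0] + sizes)
    exceed = 0
    dev_obs = abs(jt - mean)
    for _ in range(permutations):
        perm = pooled[rng.permutation(n)]
        pg = [perm[bounds[i]:bounds[i + 1]] for i in range(len(sizes))]
        if abs(_jt_statistic(pg) - mean) >= dev_obs:
            exceed += 1
    p_perm = (1 + exceed) / (permutations + 1)
    direction = "increasing" if jt > mean else ("decreasing" if jt < mean
                                                else "none")
    return TrendResult(jt, float(p_perm), p_norm, sizes, direction)


def gwas_ld_pairs(
    svs: Sequence[SVRecord],
    gwas_snvs: Sequence[SNVRecord],
    window: int = 1_000_000,
    r2_min: float = 0.8,
    source_genotypes: Mapping[str, Mapping[str, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """SV - GWAS-SNV pairs in strong genotype LD (r^2 >= r2_min,
    inclusive) within the window of either SV breakpoint.

    ``source_genotypes`` maps panel name -> {variant id -> genotype
    vector}; when provided, each pair also reports whether it is in
    strong LD within at least one source panel (the pre-admixture
    haplotype-configuration decomposition).
    """
    by_chrom: dict[str, list[SNVRecord]] = {}
    for s in gwas_snvs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for c in by_chrom:
        by_chrom[c].sort(key=lambda s: s.pos)
    rows = []
    for sv in svs:
        if sv.svtype == "mCNV":
            continue
        lo = sv.interval.start - window
        hi = sv.interval.end + window
        for s in by_chrom.get(sv.interval.chrom, ()):
            if s.pos < lo:
                continue
            if s.pos > hi:
                break
            r2 = ld_r2(sv.genotypes, s.genotypes)
            if r2 == r2 and r2 >= r2_min:
                row = {"sv": sv.id, "snv": s.id, "r2": r2}
                if source_genotypes is not None:
                    in_src = False
                    for panel in source_genotypes.values():
                        gsv = panel.get(sv.id)
                        gsnv = panel.get(s.id)
                        if gsv is not None and gsnv is not None:
                            src_r2 = ld_r2(gsv, gsnv)
                            if src_r2 == src_r2 and src_r2 >= r2_min:
                                in_src = True
                                break
                    row["ld_in_source"] = in_src
                rows.append(row)
    return pd.DataFrame(rows, columns=(["sv", "snv", "r2", "ld_in_source"]
                                       if source_genotypes is not None
                                       else ["sv", "snv", "r2"]))


def category_enrichment(
    associated: Mapping[str, bool],
    categories: Mapping[str, str],
    vaf: Mapping[str, float] | None = None,
    frequency_match: bool = False,
    seed: int | np.random.Generator = 0,
    resamples: int = 200,
) -> pd.DataFrame:
    """Per-category 2x2 enrichment of GWAS-associated SVs.

    For each sharing category: table of (in category vs rest) x
    (associated vs not); odds ratio with Woolf log-interval 95% CI and
    Fisher exact P.  Zero cells get the Haldane-Anscombe correction
    (flagged).  With ``frequency_match`` the comparison set is resampled
    to the category's VAF decile profile (seeded) and the mean resampled
    table is tested, removing frequency confounding.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ids = sorted(set(associated) & set(categories))
    assoc = np.array([bool(associated[i]) for i in ids])
    cats = np.array([categories[i] for i in ids])
    if frequency_match:
        if vaf is None:
            raise ValidationError("frequency matching requires VAFs")
        v = np.array([vaf[i] for i in ids])
        deciles = np.quantile(v, np.linspace(0, 1, 11))
        decile_of = np.clip(np.digitize(v, deciles[1:-1]), 0, 9)
    rows = []
    for cat in SHARING_CATEGORIES:
        inc = cats == cat
        if not inc.any():
            continue
        rest = ~inc
        if frequency_match and rest.any():
            # resample the rest to the category's decile profile
            want = np.bincount(decile_of[inc], minlength=10).astype(float)
            want /= want.sum()
            rest_idx = np.flatnonzero(rest)
            probs = want[decile_of[rest_idx]]
            if probs.sum() == 0:
                continue
            probs = probs / probs.sum()
            draws = rng.choice(rest_idx, size=(resamples, rest_idx.size),
                               replace=True, p=probs)
            c_assoc = float(assoc[draws].mean(axis=1).mean() * rest_idx.size)
            c = c_assoc
            d = rest_idx.size - c
        else:
            c = int((rest & assoc).sum())
            d = int((rest & ~assoc).sum())
        a = int((inc & assoc).sum())
        b = int((inc & ~assoc).sum())
        if (a + b) == 0 or (c + d) == 0:
            continue
        corrected = 0 in (a, b) or c == 0 or d == 0
        aa, bb, cc, dd = ((a + 0.5, b + 0.5, c + 0.5, d + 0.5)
                          if corrected else (a, b, c, d))
        orr = (aa * dd) / (bb * cc)
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        ci = (float(np.exp(np.log(orr) - 1.96 * se)),
              float(np.exp(np.log(orr) + 1.96 * se)))
        p = float(stats.fisher_exact(
            np.round([[a, b], [c, d]]).astype(int))[1])
        rows.append({"category": cat, "a": a, "b": b, "c": float(c),
                     "d": float(d), "odds_ratio": float(orr),
                     "ci_low": ci[0], "ci_high": ci[1], "p": p,
                     "haldane_anscombe": corrected})
    return pd.DataFrame(rows)


def length_controlled_compare(
    pre_lengths: np.ndarray,
    pre_values: np.ndarray,
    post_lengths: np.ndarray,
    post_values: np.ndarray,
    n_bins: int = 6,
    permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Compare a metric between pre- and post-admixture SVs controlling
    SV length.

    SVs are binned by log-length into ``n_bins`` bins over the combined
    range; within bins the metric is compared by a Mann-Whitney rank
    test; the pooled P comes from a stratified permutation (labels
    shuffled within bins) of the difference of means.  Bins where one
    group is empty are dropped with a note.
    """
    import warnings
    if len(pre_values) == 0 or len(post_values) == 0:
        raise ValidationError("both SV sets must be nonempty")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ll = np.log10(np.concatenate([pre_lengths, post_lengths]).astype(float))
    edges = np.linspace(ll.min(), ll.max() + 1e-9, n_bins + 1)
    lab = np.concatenate([np.zeros(len(pre_values), int),
                          np.ones(len(post_values), int)])
    vals = np.concatenate([pre_values, post_values]).astype(float)
    binof = np.clip(np.digitize(ll, edges) - 1, 0, n_bins - 1)

    per_bin = []
    used = np.zeros(len(vals), dtype=bool)
    for b in range(n_bins):
        inb = binof == b
        a = vals[inb & (lab == 0)]
        c = vals[inb & (lab == 1)]
        if len(a) == 0 or len(c) == 0:
            if inb.any():
                warnings.warn(f"bin {b}: one group empty, dropped")
            continue
        used |= inb
        u, p = stats.mannwhitneyu(a, c, alternative="two-sided")
        per_bin.append({"bin": b, "lo_bp": float(10 ** edges[b]),
                        "hi_bp": float(10 ** edges[b + 1]),
                        "n_pre": len(a), "n_post": len(c),
                        "mean_pre": float(a.mean()), "mean_post": float(c.mean()),
                        "p": float(p)})

    def stat(labels: np.ndarray) -> float:
        diffs, weights = [], []
        for b in range(n_bins):
            inb = used & (binof == b)
            a = vals[inb & (labels == 0)]
            c = vals[inb & (labels == 1)]
            if len(a) and len(c):
                diffs.append(c.mean() - a.mean())
                weights.append(inb.sum())
        if not diffs:
            return 0.0
        return float(np.average(diffs, weights=weights))

    obs = stat(lab)
    exceed = 0
    for _ in range(permutations):
        perm = lab.copy()
        for b in range(n_bins):
            inb = np.flatnonzero(used & (binof == b))
            perm[inb] = perm[inb[rng.permutation(inb.size)]]
        if abs(stat(perm)) >= abs(obs):
            exceed += 1
    p_pooled = (1 + exceed) / (permutations + 1)
    return {"per_bin": pd.DataFrame(per_bin), "pooled_diff": obs,
            "p_pooled": float(p_pooled)}
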