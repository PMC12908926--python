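"""Population SV callset assembly and annotation.

Per-sample calls are merged into SV regions by single-linkage clustering
at 50% reciprocal overlap within each SV type; regions are classified as
known/novel against a catalog, annotated against genomic elements with a
permutation depletion test, and summarized into frequency tables with
the rare (< 0.01) / moderate (0.01-0.1) / common (> 0.1) classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from admixsv.core_io import (
    MISSING,
    GenomicInterval,
    PopulationPanel,
    SNVRecord,
    SVRecord,
    ValidationError,
    reciprocal_overlap,
)


@dataclass
class SVRegion:
    """One merged population SV region."""

    representative: SVRecord
    member_ids: list[str]

    @property
    def interval(self) -> GenomicInterval:
        return self.representative.interval

    @property
    def svtype(self) -> str:
        return self.representative.svtype

    @property
    def genotypes(self) -> np.ndarray:
        return self.representative.genotypes


def _overlap_components(records: list[SVRecord], threshold: float) -> list[list[int]]:
    """Single-linkage components under reciprocal_overlap >= threshold.

    Records must share chromosome and svtype.  A sweep over start-sorted
    records bounds the candidate pairs: overlap requires interval
    intersection, so only records whose intervals intersect can link.
    """
    order = sorted(range(len(records)), key=lambda i: records[i].interval.start)
    parent = list(range(len(records)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    active: list[int] = []
    for i in order:
        ri = records[i].interval
        active = [j for j in active if records[j].interval.end > ri.start]
        for j in active:
            if reciprocal_overlap(ri, records[j].interval) >= threshold:
                union(i, j)
        active.append(i)
    comps: dict[int, list[int]] = {}
    for i in range(len(records)):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def _merge_genotypes(members: list[SVRecord]) -> np.ndarray:
    """Per-sample genotype of a region: elementwise maximum over member
    calls, treating missing as absent unless all members are missing."""
    G = np.stack([m.genotypes for m in members])
    any_called = (G != MISSING).any(axis=0)
    merged = np.where(G == MISSING, 0, G).max(axis=0).astype(np.int16)
    merged[~any_called] = MISSING
    return merged


def merge_calls(calls: Sequence[SVRecord], threshold: float = 0.5) -> list[SVRegion]:
    """Merge intersecting same-type calls into SV regions.

    Single-linkage clustering within (chromosome, svtype) under
    reciprocal overlap >= threshold; the representative is the member
    with the median start (ties: smaller start).  Merging never joins
    different SV types and is idempotent.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("merge threshold must lie in (0, 1]")
    by_key: dict[tuple[str, str], list[SVRecord]] = {}
    for r in calls:
        by_key.setdefault((r.interval.chrom, r.svtype), []).append(r)
    regions: list[SVRegion] = []
    for group in by_key.values():
        for comp in _overlap_components(group, threshold):
            members = sorted((group[i] for i in comp),
                             key=lambda r: (r.interval.start, r.id))
            starts = [m.interval.start for m in members]
            med = float(np.median(starts))
            rep = min(members,
                      key=lambda m: (abs(m.interval.start - med), m.interval.start))
            merged = SVRecord(rep.id, rep.interval, rep.svtype, rep.length,
                              _merge_genotypes(members))
            regions.append(SVRegion(merged, [m.id for m in members]))
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.svtype))
    return regions


def classify_novelty(regions: Sequence[SVRegion],
                     catalog: Sequence[tuple[GenomicInterval, str]],
                     threshold: float = 0.5) -> pd.DataFrame:
    """Flag each region novel iff no same-type catalog entry reaches the
    reciprocal-overlap threshold."""
    import warnings
    if not catalog:
        warnings.warn("empty catalog: every region classified novel")
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv, t in catalog:
        by_key.setdefault((iv.chrom, t), []).append(iv)
    rows = []
    for reg in regions:
        best = 0.0
        for iv in by_key.get((reg.interval.chrom, reg.svtype), ()):
            best = max(best, reciprocal_overlap(reg.interval, iv))
        rows.append({"id": reg.representative.id, "best_overlap": best,
                     "novel": best < threshold})
    return pd.DataFrame(rows)


def element_depletion_test(
    regions: Sequence[SVRegion],
    elements: pd.DataFrame,
    chrom_lengths: dict[str, int],
    permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Permutation test for SV depletion in genomic elements.

    Observed statistic: number of regions overlapping any element.  The
    null uniformly re-places each region on its own chromosome
    preserving its length; the depletion P-value follows the add-one
    rule P = (1 + #{null <= observed}) / (B + 1).  Regions longer than
    their chromosome are skipped with a warning.
    """
    import warnings
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in elements.itertuples():
        by_chrom.setdefault(str(r.chrom), []).append((int(r.start), int(r.end)))
    sorted_elems = {
        c: (np.array(sorted(s for s, _ in v)), np.array([e for _, e in sorted(v)]))
        for c, v in by_chrom.items()
    }

    def overlaps_any(chrom: str, start: int, end: int) -> bool:
        if chrom not in sorted_elems:
            return False
        starts, ends = sorted_elems[chrom]
        i = np.searchsorted(starts, end)   # elements starting before region end
        return bool((ends[:i] > start).any())

    usable = []
    for reg in regions:
        L = len(reg.interval)
        if L > chrom_lengths.get(reg.interval.chrom, 0):
            warnings.warn(f"{reg.representative.id} longer than its chromosome, skipped")
            continue
        usable.append(reg)
    observed = sum(
        overlaps_any(r.interval.chrom, r.interval.start, r.interval.end)
        for r in usable)
    null = np.empty(permutations, dtype=int)
    for b in range(permutations):
        count = 0
        for r in usable:
            L = len(r.interval)
            maxs = chrom_lengths[r.interval.chrom] - L
            s = int(rng.integers(0, maxs + 1))
            count += overlaps_any(r.interval.chrom, s, s + L)
        null[b] = count
    p_depletion = (1 + int((null <= observed).sum())) / (permutations + 1)
    return {"observed": int(observed), "null_mean": float(null.mean()),
            "null": null, "p_depletion": float(p_depletion)}


FREQ_CLASSES = (("rare", 0.0, 0.01), ("moderate", 0.01, 0.1), ("common", 0.1, 1.0001))


def frequency_class(vaf: float) -> str:
    """Half-open frequency bins: rare [0, 0.01), moderate [0.01, 0.1),
    common [0.1, 1]."""
    for name, lo, hi in FREQ_CLASSES:
        if lo <= vaf < hi:
            return name
    return "common"


def frequency_table(regions: Sequence[SVRegion], panel: PopulationPanel) -> pd.DataFrame:
    """Per-region VAF in each population, MAF and frequency class."""
    pops = sorted(set(panel.population))
    rows = []
    for reg in regions:
        g = reg.genotypes
        row: dict = {"id": reg.representative.id, "svtype": reg.svtype}
        for pop in pops:
            idx = panel.indices_of(pop)
            sub = g[idx]
            called = sub[sub != MISSING]
            row[f"vaf_{pop}"] = (float(called.sum() / (2 * len(called)))
                                 if reg.svtype != "mCNV" and called.size
                                 else float("nan"))
        called = g[g != MISSING]
        vaf = (float(called.sum() / (2 * len(called)))
               if reg.svtype != "mCNV" and called.size else float("nan"))
        row["vaf"] = vaf
        row["maf"] = min(vaf, 1 - vaf) if vaf == vaf else float("nan")
        row["freq_class"] = frequency_class(vaf) if vaf == vaf else "NA"
        rows.append(row)
    return pd.DataFrame(rows)


def annotate_category(regions: Sequence[SVRegion],
                      exons: pd.DataFrame, genes: pd.DataFrame) -> list[str]:
    """Assign each SV the most gene-proximal category it touches:
    exonic > intronic > intergenic."""
    def to_arrays(df):
        out = {}
        for r in df.itertuples():
            out.setdefault(str(r.chrom), []).append((int(r.start), int(r.end)))
        return {c: (np.array([s for s, _ in sorted(v)]),
                    np.array([e for _, e in sorted(v)]))
                for c, v in out.items()}

    ex, gn = to_arrays(exons), to_arrays(genes)

    def touches(tbl, chrom, start, end):
        if chrom not in tbl:
            return False
        starts, ends = tbl[chrom]
        i = np.searchsorted(starts, end)
        return bool((ends[:i] > start).any())

    cats = []
    for r in regions:
        iv = r.interval
        if touches(ex, iv.chrom, iv.start, iv.end):
            cats.append("exonic")
        elif touches(gn, iv.chrom, iv.start, iv.end):
            cats.append("intronic")
        else:
            cats.append("intergenic")
    return cats


def stratified_counts(
    regions: Sequence[SVRegion],
    panel: PopulationPanel,
    categories: Sequence[str],
    n_per_population: int,
    samplings: int = 100,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Counts by population x frequency class x genomic category on
    equal-size subsamples; reports mean and sd over samplings."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pops = sorted(set(panel.population))
    for pop in pops:
        if n_per_population > len(panel.indices_of(pop)):
            raise ValidationError(f"{pop}: subsample exceeds population size")
    all_keys = [
        (pop, fc, cat)
        for pop in pops
        for fc, _, _ in FREQ_CLASSES
        for cat in ("exonic", "intronic", "intergenic")
    ]
    acc: dict[tuple, list[int]] = {k: [] for k in all_keys}
    for _ in range(samplings):
        for pop in pops:
            idx = rng.choice(panel.indices_of(pop), size=n_per_population,
                             replace=False)
            tally: dict[tuple, int] = {}
            for reg, cat in zip(regions, categories):
                if reg.svtype == "mCNV":
                    continue
                g = reg.genotypes[idx]
                called = g[g != MISSING]
                if called.size == 0 or called.sum() == 0:
                    continue
                vaf = float(called.sum() / (2 * len(called)))
                key = (pop, frequency_class(vaf), cat)
                tally[key] = tally.get(key, 0) + 1
            for key in all_keys:
                if key[0] == pop:
                    acc[key].append(tally.get(key, 0))
    rows = [
        {"population": k[0], "freq_class": k[1], "category": k[2],
         "mean_count": float(np.mean(v)), "sd_count": float(np.std(v))}
        for k, v in sorted(acc.items())
    ]
    return pd.DataFrame(rows)


def ld_r2(genotypes_a: np.ndarray, genotypes_b: np.ndarray) -> float:
    """Squared Pearson correlation of two allele-count vectors over
    samples called in both; NaN when either is monomorphic."""
    a = np.asarray(genotypes_a, dtype=float)
    b = np.asarray(genotypes_b, dtype=float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def snv_tagging(
    svs: Sequence[SVRecord],
    snvs: Sequence[SNVRecord],
    window: int = 1_000_000,
    r2_threshold: float = 0.8,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """Best flanking-SNV r^2 per SV and the tagged flag (best r^2 above
    the threshold among SNVs within the window of either breakpoint).
    SVs are MAF-filtered (> min_maf) before tagging; mCNVs and
    zero-variance pairs are skipped."""
    by_chrom: dict[str, list[SNVRecord]] = {}
    for s in snvs:
        by_chrom.setdefault(s.chrom, []).append(s)
    for c in by_chrom:
        by_chrom[c].sort(key=lambda s: s.pos)
    rows = []
    for sv in svs:
        if sv.svtype == "mCNV":
            continue
        vaf = sv.vaf()
        if not (min(vaf, 1 - vaf) > min_maf):
            continue
        cands = by_chrom.get(sv.interval.chrom, [])
        lo = sv.interval.start - window
        hi = sv.interval.end + window
        best, best_id = 0.0, ""
        for s in cands:
            if s.pos < lo:
                continue
            if s.pos > hi:
                break
            r2 = ld_r2(sv.genotypes, s.genotypes)
            if r2 == r2 and r2 > best:
                best, best_id = r2, s.id
        rows.append({"id": sv.id, "best_r2": best, "best_snv": best_id,
                     "tagged": best > r2_threshold})
    return pd.DataFrame(rows)
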