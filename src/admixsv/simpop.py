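"""Synthetic cohorts for admixture-driven SV analysis.

The generator emulates the study design this package analyzes: two
diverged Eurasian-like source panels plus an outgroup panel, an admixed
cohort produced by an explicit forward-in-time two-wave admixture with
per-meiosis recombination (local-ancestry tracts are tracked exactly),
post-admixture SV creation coupled to crossovers inside pre-placed
homologous repeat pairs (NAHR) plus a background new-SV process, and
gene expression driven by additive planted SV/SNV effects.

Source-population allele frequencies follow a Balding–Nichols draw
around a shared ancestral frequency, with a configurable fraction of
variants forced ancestry-specific.  A separate pure-drift Wright–Fisher
resampler (:func:`simulate_drift_null`) provides the neutral null for
the ancestry-biased differentiation scan.

Every stochastic operation takes an explicit seed or generator; there is
no global random state.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from admixsv.core_io import (
    MISSING,
    AncestryTract,
    ExpressionMatrix,
    GenomicInterval,
    PopulationPanel,
    SNVRecord,
    SVRecord,
    ValidationError,
    merge_adjacent_tracts,
    write_expression_tsv,
    write_metadata_tsv,
    write_snv_vcf,
    write_sv_vcf,
    write_tracts_bed,
)

WEST, EAST = 0, 1
_ANC_NAME = {WEST: "WEST", EAST: "EAST"}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdmixtureWave:
    """One admixture pulse: ``generation`` generations before present a
    fraction ``contribution`` of the gene pool is replaced by migrants of
    which ``west_fraction`` carry WEST ancestry."""

    generation: int
    west_fraction: float
    contribution: float = 1.0


@dataclass
class SimConfig:
    """All generator knobs.

    Defaults describe a desk-scale cohort shaped like the study system:
    a ~0.5/0.5 two-wave admixed population (an older founding pulse and
    a more recent one roughly 750 years before present at ~25 years per
    generation), two source panels diverged at F ~ 0.08, and a high
    ancestry-specific variant fraction consistent with the large share
    of admixed-cohort CNVs not observed in either source panel.
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (50_000_000, 50_000_000)
    # panel sizes
    n_admixed: int = 80
    n_west: int = 100
    n_east: int = 100
    n_african: int = 30
    pop_size: int = 200          # diploid size of the admixed population
    # variants
    n_sv: int = 3000
    n_snv: int = 2000
    f_div_west: float = 0.08     # Balding–Nichols divergence per source
    f_div_east: float = 0.08
    f_div_african: float = 0.04
    frac_specific: float = 0.39  # forced ancestry-specific (split evenly)
    specific_freq_range: tuple[float, float] = (0.03, 0.12)
    shared_sfs_beta: tuple[float, float] = (0.8, 1.2)
    sv_type_weights: dict = field(default_factory=lambda: {
        "DEL": 0.55, "DUP": 0.18, "INS": 0.15, "INV": 0.06, "mCNV": 0.06})
    sv_len_log_mean: float = 6.6   # lognormal of SV length, ~750 bp median
    sv_len_log_sd: float = 1.1
    sv_len_max: int = 100_000
    archaic_fraction: float = 0.15  # shared ancestral SVs also seen in archaics
    # admixture history (generations strictly decreasing toward present)
    waves: tuple[AdmixtureWave, ...] = (
        AdmixtureWave(60, 0.5, 1.0),
        AdmixtureWave(30, 0.5, 0.3),
    )
    crossovers_per_mb: float = 0.01   # per meiosis (1 cM/Mb)
    # NAHR substrate and new-SV rates
    homology_pairs_per_mb: float = 5.0
    repeat_length: int = 500
    pair_spacing: tuple[int, int] = (2_000, 20_000)  # log-uniform inner span
    theta_nahr: float = 0.3    # P(crossover in a homology pair spawns a DEL/DUP)
    theta_bg: float = 0.05     # background new SVs per meiosis
    hom_background: float = 0.2  # homology-flank rate among non-NAHR SVs
    # expression
    cohort_sampling: str = "random"   # or "ancestry_stratified"
    n_genes: int = 100
    frac_egenes: float = 0.3
    frac_usvc_genes: float = 0.1   # of eGenes, driven by a specific SV+SNV pair
    beta_sd: float = 0.8
    beta_min: float = 0.3
    resid_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("crossovers_per_mb", "theta_nahr", "theta_bg",
                     "homology_pairs_per_mb", "resid_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        gens = [w.generation for w in self.waves]
        if gens != sorted(gens, reverse=True) or len(set(gens)) != len(gens):
            raise ValidationError(
                "wave generations must be strictly decreasing toward present")
        for w in self.waves:
            if not 0 < w.west_fraction < 1:
                raise ValidationError("wave west_fraction must lie in (0, 1)")
            if not 0 < w.contribution <= 1:
                raise ValidationError("wave contribution must lie in (0, 1]")
        if self.pop_size < 2:
            raise ValidationError("pop_size must be >= 2")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    """Ground truth for parameter-recovery tests.

    ``sv_truth`` has one row per SV in the admixed callset with columns
    origin (ancestral-shared / west-derived / east-derived /
    post-admixture), at_crossover, homology_flanked, creation_generation
    (post-admixture only, else -1) and inter_ancestry (whether the
    creating crossover joined different ancestries).
    """

    sv_truth: pd.DataFrame
    eqtl: pd.DataFrame
    tracts: list[AncestryTract]


# ---------------------------------------------------------------------------
# variant site tables and ancestral panels
# ---------------------------------------------------------------------------

def _draw_sites(cfg: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SV and SNV site tables with per-source population frequencies."""
    chroms = cfg.chrom_names
    lens = np.asarray(cfg.chrom_lengths, dtype=float)
    pchrom = lens / lens.sum()

    def bn_freq(p: np.ndarray, f: float) -> np.ndarray:
        if f <= 0:
            return p.copy()
        a = p * (1 - f) / f
        b = (1 - p) * (1 - f) / f
        return np.clip(rng.beta(a, b), 0.0, 1.0)

    def make(n: int, is_sv: bool) -> pd.DataFrame:
        ci = rng.choice(len(chroms), size=n, p=pchrom)
        pos = (rng.random(n) * (lens[ci] - 200_000) + 100_000).astype(np.int64)
        # shared ancestral frequency: mildly rare-skewed, as in a merged
        # population callset after polymorphism filtering
        p = np.clip(rng.beta(*cfg.shared_sfs_beta, size=n), 0.01, 0.99)
        fw = bn_freq(p, cfg.f_div_west)
        fe = bn_freq(p, cfg.f_div_east)
        fa = bn_freq(p, cfg.f_div_african)
        origin = np.full(n, "ancestral-shared", dtype=object)
        # symmetric sources: equal-sized specific sets per side with a
        # shared (paired) frequency spectrum, making the two ancestral
        # contributions exchangeable
        n_spec = 2 * (int(round(cfg.frac_specific * n)) // 2)
        spec = rng.choice(n, size=n_spec, replace=False)
        west_side = np.repeat([True, False], n_spec // 2)
        # log-uniform (density ~ 1/f): the rare-skew of young,
        # population-specific variants
        lo, hi = cfg.specific_freq_range
        half = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_spec // 2))
        f_spec = np.concatenate([half, half])
        fw[spec] = np.where(west_side, f_spec, 0.0)
        fe[spec] = np.where(west_side, 0.0, f_spec)
        fa[spec] = 0.0
        origin[spec] = np.where(west_side, "west-derived", "east-derived")
        df = pd.DataFrame({
            "chrom": [chroms[i] for i in ci],
            "pos": pos, "f_west": fw, "f_east": fe, "f_african": fa,
            "origin": origin,
        })
        if is_sv:
            length = np.minimum(
                rng.lognormal(cfg.sv_len_log_mean, cfg.sv_len_log_sd, size=n),
                cfg.sv_len_max).astype(np.int64)
            length = np.maximum(length, 50)
            types = list(cfg.sv_type_weights)
            w = np.array([cfg.sv_type_weights[t] for t in types], dtype=float)
            df["svtype"] = rng.choice(types, size=n, p=w / w.sum())
            df["length"] = length
            df["end"] = np.where(df["svtype"] == "INS", pos + 1, pos + length)
            # mCNV dosage direction: copy number = 2 + delta * allele count
            df["mcnv_delta"] = rng.choice([-1, 1, 2], size=n, p=[0.45, 0.45, 0.1])
            df["homology_flanked"] = (
                rng.random(n) < cfg.hom_background)
            df["archaic_present"] = (
                (df["origin"] == "ancestral-shared")
                & (rng.random(n) < cfg.archaic_fraction))
            df["id"] = [f"sv{i:05d}" for i in range(n)]
        else:
            df["id"] = [f"snv{i:06d}" for i in range(n)]
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        return df

    return make(cfg.n_sv, True), make(cfg.n_snv, False)


def _genotypes_from_freq(f: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n samples x len(f) matrix of binomial(2, f) allele counts."""
    return rng.binomial(2, f[None, :], size=(n, len(f))).astype(np.int16)


def _sv_records(sites: pd.DataFrame, G: np.ndarray) -> list[SVRecord]:
    recs = []
    for j, row in enumerate(sites.itertuples()):
        g = G[:, j]
        if row.svtype == "mCNV":
            g = np.clip(2 + row.mcnv_delta * g.astype(np.int32), 0, None).astype(np.int16)
        recs.append(SVRecord(
            row.id, GenomicInterval(row.chrom, int(row.pos), int(row.end)),
            row.svtype, int(row.length), g))
    return recs


def _snv_records(sites: pd.DataFrame, G: np.ndarray) -> list[SNVRecord]:
    return [
        SNVRecord(row.id, row.chrom, int(row.pos), "A", "G", G[:, j])
        for j, row in enumerate(sites.itertuples())
    ]


@dataclass
class AncestralPanels:
    """Site tables plus drawn genotypes for the three non-admixed panels."""

    sv_sites: pd.DataFrame
    snv_sites: pd.DataFrame
    sv_geno: dict[str, np.ndarray]    # population -> n x L allele counts
    snv_geno: dict[str, np.ndarray]
    panels: dict[str, PopulationPanel]

    def sv_records(self, population: str) -> list[SVRecord]:
        return _sv_records(self.sv_sites, self.sv_geno[population])

    def snv_records(self, population: str) -> list[SNVRecord]:
        return _snv_records(self.snv_sites, self.snv_geno[population])


def simulate_ancestral_panels(cfg: SimConfig,
                              rng: np.random.Generator | None = None) -> AncestralPanels:
    """Draw site tables and genotype the WEST/EAST/AFRICAN panels."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sv_sites, snv_sites = _draw_sites(cfg, rng)
    sizes = {"SRC_WEST": cfg.n_west, "SRC_EAST": cfg.n_east,
             "AFRICAN": cfg.n_african}
    fcol = {"SRC_WEST": "f_west", "SRC_EAST": "f_east", "AFRICAN": "f_african"}
    sv_geno, snv_geno, panels = {}, {}, {}
    prefix = {"SRC_WEST": "W", "SRC_EAST": "E", "AFRICAN": "A"}
    for pop, n in sizes.items():
        sv_geno[pop] = _genotypes_from_freq(
            sv_sites[fcol[pop]].to_numpy(), n, rng)
        snv_geno[pop] = _genotypes_from_freq(
            snv_sites[fcol[pop]].to_numpy(), n, rng)
        panels[pop] = PopulationPanel(
            samples=[f"{prefix[pop]}{i:03d}" for i in range(n)],
            population=[pop] * n,
            sex=list(rng.choice(["F", "M"], size=n)),
        )
    return AncestralPanels(sv_sites, snv_sites, sv_geno, snv_geno, panels)


# ---------------------------------------------------------------------------
# forward simulation of the admixed population
# ---------------------------------------------------------------------------

class _Hap:
    """One haplotype of one chromosome: tract ends (last equals the
    chromosome length), per-tract ancestry and founder-haplotype id, and
    the candidate new-SV events it carries (uid -> position).

    ``own_muts`` implements copy-on-write: a crossover-free meiosis
    shares the parent's structures, so the event dict is copied before
    the first in-place addition."""

    __slots__ = ("ends", "anc", "fid", "muts", "own_muts")

    def __init__(self, ends, anc, fid, muts, own_muts=True):
        self.ends = ends
        self.anc = anc
        self.fid = fid
        self.muts = muts
        self.own_muts = own_muts

    def add_mut(self, uid: int, pos: int) -> None:
        if not self.own_muts:
            self.muts = dict(self.muts)
            self.own_muts = True
        self.muts[uid] = pos


@dataclass
class _CandidateEvent:
    uid: int
    chrom_idx: int
    pos: int
    generation: int
    pair_idx: int       # homology pair index, -1 for background events
    inter_ancestry: bool


@dataclass
class AdmixedCohort:
    """Sampled admixed individuals with exact tract truth.

    ``haps`` is a list (per sample) of lists (per chromosome) of
    ``(hap0, hap1)``; ``founder_ancestry`` maps founder-haplotype id to
    WEST/EAST codes; ``candidates`` logs every potential post-admixture
    SV event created at a crossover (NAHR candidate) or as background.
    """

    cfg: SimConfig
    panel: PopulationPanel
    haps: list
    founder_ancestry: np.ndarray
    candidates: list[_CandidateEvent]
    homology_pairs: list[np.ndarray]   # per chrom: (n_pairs, 2) span start/end
    tracts: list[AncestryTract]

    def global_west_fraction(self) -> np.ndarray:
        total = float(sum(self.cfg.chrom_lengths))
        out = np.zeros(len(self.panel))
        for i, per_chrom in enumerate(self.haps):
            west = 0
            for c, (h0, h1) in enumerate(per_chrom):
                for h in (h0, h1):
                    prev = 0
                    for e, a in zip(h.ends, h.anc):
                        if a == WEST:
                            west += e - prev
                        prev = e
            out[i] = west / (2 * total)
        return out


def _anc_at(h: _Hap, pos: int) -> int:
    return h.anc[bisect_right(h.ends, pos)]


def _copy_segments(h: _Hap, a: int, b: int, ends, anc, fid, muts) -> None:
    """Append tracts and events of ``h`` restricted to [a, b)."""
    i = bisect_right(h.ends, a)
    while True:
        e = h.ends[i]
        ends.append(min(e, b))
        anc.append(h.anc[i])
        fid.append(h.fid[i])
        if e >= b:
            break
        i += 1
    if h.muts:
        for uid, pos in h.muts.items():
            if a <= pos < b:
                muts[uid] = pos


def _meiosis(pair, L, xs, start_hap):
    h0, h1 = pair
    if not xs:
        h = (h0, h1)[start_hap]
        return _Hap(h.ends, h.anc, h.fid, h.muts, own_muts=False)  # share
    ends, anc, fid, muts = [], [], [], {}
    haps = (h0, h1)
    cur = start_hap
    prev = 0
    for x in list(xs) + [L]:
        if x > prev:
            _copy_segments(haps[cur], prev, x, ends, anc, fid, muts)
        prev = x
        cur ^= 1
    return _Hap(ends, anc, fid, muts)


def simulate_admixture(cfg: SimConfig, rng: np.random.Generator | None = None,
                       sample_names: Sequence[str] | None = None) -> AdmixedCohort:
    """Forward-simulate the admixed population and sample the cohort.

    Founders at the oldest wave are pure-source individuals; each later
    generation is formed by random mating with Poisson crossovers at the
    configured rate per Mb.  Later waves replace a fraction of newborns
    with fresh migrants.  Crossovers landing inside a pre-placed
    homologous repeat pair are logged as NAHR candidate events and
    transmitted like mutations; background candidates arise at rate
    ``theta_bg`` per meiosis.  Use :func:`inject_post_admixture_svs` to
    turn candidates into SV records.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    N = cfg.pop_size
    n_chrom = len(cfg.chrom_lengths)
    lens = cfg.chrom_lengths
    lam = [cfg.crossovers_per_mb * L / 1e6 for L in lens]
    plen = np.asarray(lens, dtype=float)
    pchrom = plen / plen.sum()

    # homology-pair substrate, non-overlapping spans per chromosome
    pairs: list[np.ndarray] = []
    for L in lens:
        n_pairs = int(cfg.homology_pairs_per_mb * L / 1e6)
        lo, hi = cfg.pair_spacing
        span = (np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_pairs))
                + 2 * cfg.repeat_length).astype(np.int64)
        starts = np.sort(rng.integers(0, L - int(span.max()) - 1, size=n_pairs))
        keep_s, keep_e, last = [], [], -1
        for s, w in zip(starts, span):
            if s > last:
                keep_s.append(s)
                keep_e.append(s + w)
                last = s + w
        pairs.append(np.column_stack([keep_s, keep_e]).astype(np.int64))

    founder_anc: list[int] = []
    uid_counter = 0
    candidates: list[_CandidateEvent] = []

    def new_migrant(ancestry: int):
        ind = []
        for L in lens:
            h0 = _Hap([L], [ancestry], [len(founder_anc)], {})
            founder_anc.append(ancestry)
            h1 = _Hap([L], [ancestry], [len(founder_anc)], {})
            founder_anc.append(ancestry)
            ind.append((h0, h1))
        return ind

    def migrant_ancestries(n: int, west_fraction: float) -> np.ndarray:
        """Exact-composition pulse: migrants come from effectively
        infinite source populations, so the wave fraction is exact up to
        rounding rather than binomially noisy."""
        n_w = int(round(west_fraction * n))
        a = np.array([WEST] * n_w + [EAST] * (n - n_w), dtype=np.int8)
        rng.shuffle(a)
        return a

    waves = {w.generation: w for w in cfg.waves}
    g_start = cfg.waves[0].generation
    pop = [new_migrant(int(a))
           for a in migrant_ancestries(N, cfg.waves[0].west_fraction)]

    for gen in range(g_start - 1, -1, -1):
        wave = waves.get(gen)
        parents = rng.integers(0, N, size=(N, 2))
        # one Poisson count per child x parent x chromosome
        xo_counts = rng.poisson(lam, size=(N, 2, n_chrom))
        migrant = np.zeros(N, dtype=bool)
        if wave is not None:
            n_mig = int(round(wave.contribution * N))
            migrant[rng.choice(N, size=n_mig, replace=False)] = True
            mig_anc = iter(migrant_ancestries(n_mig, wave.west_fraction))
        nxt = []
        for i in range(N):
            if migrant[i]:
                nxt.append(new_migrant(int(next(mig_anc))))
                continue
            child = []
            for c in range(n_chrom):
                chrom_haps = []
                for side in range(2):
                    par = pop[parents[i, side]]
                    k = xo_counts[i, side, c]
                    xs = (sorted(rng.integers(1, lens[c], size=k).tolist())
                          if k else [])
                    start = int(rng.integers(0, 2))
                    h = _meiosis(par[c], lens[c], xs, start)
                    # NAHR candidates at crossovers inside homology pairs
                    for x in xs:
                        ps = pairs[c]
                        j = int(np.searchsorted(ps[:, 0], x, side="right")) - 1
                        if j >= 0 and x < ps[j, 1]:
                            uid = uid_counter
                            uid_counter += 1
                            pos = int(ps[j, 0]) + cfg.repeat_length // 2
                            h.add_mut(uid, pos)
                            inter = (_anc_at(par[c][0], x)
                                     != _anc_at(par[c][1], x))
                            candidates.append(_CandidateEvent(
                                uid, c, pos, gen, j, inter))
                    chrom_haps.append(h)
                child.append(tuple(chrom_haps))
            # background new-SV candidates, one meiosis pair per child
            nb = rng.poisson(cfg.theta_bg * 2)
            for _ in range(nb):
                c = int(rng.choice(n_chrom, p=pchrom))
                pos = int(rng.integers(50_000, lens[c] - 150_000))
                side = int(rng.integers(0, 2))
                child[c][side].add_mut(uid_counter, pos)
                candidates.append(_CandidateEvent(
                    uid_counter, c, pos, gen, -1, False))
                uid_counter += 1
            nxt.append(child)
        pop = nxt

    if cfg.cohort_sampling == "ancestry_stratified":
        # even ancestry quantiles: a stratified cohort design with
        # symmetric coverage of the ancestry spectrum
        west = np.empty(N)
        total = float(sum(lens))
        for i, ind in enumerate(pop):
            w = 0
            for c, (h0, h1) in enumerate(ind):
                for h in (h0, h1):
                    prev = 0
                    for e, a in zip(h.ends, h.anc):
                        if a == WEST:
                            w += e - prev
                        prev = e
            west[i] = w / (2 * total)
        order = np.argsort(west, kind="stable")
        take = np.round(np.linspace(0, N - 1, cfg.n_admixed)).astype(int)
        idx = order[take]
    else:
        idx = rng.choice(N, size=cfg.n_admixed, replace=False)
    if sample_names is None:
        sample_names = [f"ADM{i:03d}" for i in range(cfg.n_admixed)]
    sampled = [pop[i] for i in idx]

    tracts: list[AncestryTract] = []
    chrom_names = cfg.chrom_names
    for s, ind in zip(sample_names, sampled):
        for c, (h0, h1) in enumerate(ind):
            for hap_i, h in enumerate((h0, h1)):
                prev = 0
                for e, a in zip(h.ends, h.anc):
                    if e > prev:
                        tracts.append(AncestryTract(
                            s, hap_i,
                            GenomicInterval(chrom_names[c], prev, e),
                            _ANC_NAME[a]))
                    prev = e
    tracts = merge_adjacent_tracts(tracts)

    panel = PopulationPanel(
        samples=list(sample_names),
        population=["ADMIXED"] * cfg.n_admixed,
        sex=list(rng.choice(["F", "M"], size=cfg.n_admixed)),
    )
    cohort = AdmixedCohort(cfg, panel, sampled,
                           np.asarray(founder_anc, dtype=np.int8),
                           candidates, pairs, tracts)
    cohort.panel.ancestry_west = cohort.global_west_fraction()
    return cohort


def admixed_genotypes(cohort: AdmixedCohort, panels: AncestralPanels,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Materialize ancestral-variant genotypes for the sampled cohort.

    Each founder haplotype draws its alleles once from its source
    frequencies; sampled haplotypes copy by descent through the recorded
    tracts, so drift and admixture LD are structural, not resampled.
    Returns (SV allele-count matrix, SNV allele-count matrix).
    """
    cfg = cohort.cfg
    founder_anc = cohort.founder_ancestry
    n_f = len(founder_anc)

    out = []
    for sites in (panels.sv_sites, panels.snv_sites):
        L = len(sites)
        fw = sites["f_west"].to_numpy()
        fe = sites["f_east"].to_numpy()
        # frequency-exact founding: per variant, exactly round(f * n)
        # carrier haplotypes among each side's founders (migrant pools
        # realize their source frequencies exactly; drift then acts
        # through descent)
        founder_alleles = np.zeros((n_f, L), dtype=np.int8)
        for anc, f in ((WEST, fw), (EAST, fe)):
            side = np.flatnonzero(founder_anc == anc)
            if side.size == 0:
                continue
            k = np.round(f * side.size).astype(np.int64)
            base = np.arange(side.size)[:, None] < k[None, :]
            founder_alleles[side] = rng.permuted(base, axis=0)
        # variant index per chromosome
        by_chrom = {}
        for c, name in enumerate(cfg.chrom_names):
            m = sites["chrom"].to_numpy() == name
            by_chrom[c] = (np.flatnonzero(m),
                           sites["pos"].to_numpy()[m])
        G = np.zeros((len(cohort.panel), L), dtype=np.int16)
        for i, ind in enumerate(cohort.haps):
            for c, (h0, h1) in enumerate(ind):
                vidx, vpos = by_chrom[c]
                if len(vidx) == 0:
                    continue
                for h in (h0, h1):
                    seg = np.searchsorted(np.asarray(h.ends), vpos, side="right")
                    fids = np.asarray(h.fid)[seg]
                    G[i, vidx] += founder_alleles[fids, vidx]
        out.append(G)
    return out[0], out[1]


def inject_post_admixture_svs(
    cfg: SimConfig, cohort: AdmixedCohort, rng: np.random.Generator,
) -> tuple[list[SVRecord], pd.DataFrame]:
    """Resolve candidate events into post-admixture SV records.

    Each NAHR candidate (a crossover inside a homology pair) becomes a
    DEL or DUP between the paired repeats with probability
    ``theta_nahr``; background candidates are always realized.  Only
    events carried by at least one sampled haplotype yield a record.
    All realized events were singletons in their creation generation.
    """
    accepted: dict[int, _CandidateEvent] = {}
    for ev in cohort.candidates:
        if ev.pair_idx >= 0:
            if rng.random() < cfg.theta_nahr:
                accepted[ev.uid] = ev
        else:
            accepted[ev.uid] = ev

    carriers: dict[int, np.ndarray] = {}
    for i, ind in enumerate(cohort.haps):
        for c, (h0, h1) in enumerate(ind):
            for h in (h0, h1):
                for uid in h.muts:
                    if uid in accepted:
                        carriers.setdefault(
                            uid, np.zeros(len(cohort.panel), dtype=np.int16))[i] += 1

    records: list[SVRecord] = []
    truth_rows = []
    chrom_names = cfg.chrom_names
    for k, uid in enumerate(sorted(carriers)):
        ev = accepted[uid]
        g = np.minimum(carriers[uid], 2)
        chrom = chrom_names[ev.chrom_idx]
        svtype = "DEL" if rng.random() < 0.5 else "DUP"
        if ev.pair_idx >= 0:
            # breakpoints at the inner repeat edges: the repeats flank
            # the rearranged segment, the NAHR signature
            s, e = cohort.homology_pairs[ev.chrom_idx][ev.pair_idx]
            interval = GenomicInterval(chrom, int(s) + cfg.repeat_length,
                                       int(e) - cfg.repeat_length)
            length = len(interval)
            hom = True
        else:
            length = max(50, min(int(rng.lognormal(
                cfg.sv_len_log_mean, cfg.sv_len_log_sd)), cfg.sv_len_max))
            interval = GenomicInterval(chrom, ev.pos, ev.pos + length)
            hom = False
        rec = SVRecord(f"postsv{k:04d}", interval, svtype, length, g)
        records.append(rec)
        truth_rows.append({
            "id": rec.id, "origin": "post-admixture",
            "at_crossover": ev.pair_idx >= 0,
            "homology_flanked": hom,
            "creation_generation": ev.generation,
            "inter_ancestry": ev.inter_ancestry,
            "archaic_present": False,
        })
    truth = pd.DataFrame(
        truth_rows, columns=["id", "origin", "at_crossover", "homology_flanked",
                             "creation_generation", "inter_ancestry",
                             "archaic_present"])
    return records, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    cfg: SimConfig,
    sv_records: Sequence[SVRecord],
    snv_records: Sequence[SNVRecord],
    panel: PopulationPanel,
    rng: np.random.Generator,
    specificity: dict[str, str] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Additive-effect expression: per gene, y = sum beta_v g_v + noise.

    A ``frac_egenes`` fraction of genes receives one causal cis variant
    (SV or SNV within 1 Mb of the TSS); of those, ``frac_usvc_genes``
    instead receive a same-direction pair of variants specific to the
    two different ancestries when ``specificity`` labels are provided.
    Effect sizes are N(0, beta_sd) with magnitude floored at beta_min.
    Planted variants that are monomorphic in the cohort are dropped with
    a warning.
    """
    n = len(panel)
    lens = dict(zip(cfg.chrom_names, cfg.chrom_lengths))
    gpos = {}
    for i in range(cfg.n_genes):
        chrom = cfg.chrom_names[int(rng.integers(len(lens)))]
        gpos[f"gene{i:04d}"] = (chrom, int(rng.integers(
            1_000_000, lens[chrom] - 1_000_000)))
    genes = sorted(gpos)

    variants: list[tuple[str, str, int, np.ndarray]] = []
    for r in sv_records:
        if r.svtype != "mCNV":
            variants.append((r.id, r.interval.chrom, r.interval.start,
                             r.genotypes))
    for r in snv_records:
        variants.append((r.id, r.chrom, r.pos, r.genotypes))

    def draw_beta() -> float:
        b = rng.normal(0, cfg.beta_sd)
        return float(np.sign(b) or 1.0) * max(abs(b), cfg.beta_min)

    e_genes = [g for g in genes if rng.random() < cfg.frac_egenes]
    effects = []
    values = rng.normal(0, cfg.resid_sd, size=(len(genes), n))
    gi = {g: i for i, g in enumerate(genes)}
    for g in e_genes:
        chrom, tss = gpos[g]
        cis = [v for v in variants
               if v[1] == chrom and abs(v[2] - tss) <= 1_000_000]
        cis = [v for v in cis if len(np.unique(v[3][v[3] != MISSING])) > 1]
        if not cis:
            warnings.warn(f"{g}: no polymorphic cis variant, effect dropped")
            continue
        chosen: list[tuple[str, str, int, np.ndarray]] = []
        betas: list[float] = []
        want_usvc = (specificity is not None
                     and rng.random() < cfg.frac_usvc_genes)
        if want_usvc:
            ws = [v for v in cis if specificity.get(v[0]) == "WEST"]
            es = [v for v in cis if specificity.get(v[0]) == "EAST"]
            if ws and es:
                b = draw_beta()
                chosen = [ws[int(rng.integers(len(ws)))],
                          es[int(rng.integers(len(es)))]]
                betas = [b, b]   # same direction: the USVC signature
        if not chosen:
            chosen = [cis[int(rng.integers(len(cis)))]]
            betas = [draw_beta()]
        for (vid, _, _, gvec), b in zip(chosen, betas):
            gv = np.where(gvec == MISSING, 0, gvec).astype(float)
            values[gi[g]] += b * gv
            effects.append({"gene": g, "variant": vid, "beta": b})

    expr = ExpressionMatrix(
        genes, [gpos[g][0] for g in genes],
        np.array([gpos[g][1] for g in genes]),
        list(panel.samples), values, normalization="raw")
    return expr, pd.DataFrame(effects, columns=["gene", "variant", "beta"])


# ---------------------------------------------------------------------------
# pure-drift null
# ---------------------------------------------------------------------------

def simulate_drift_null(
    cfg: SimConfig,
    f_west: np.ndarray | float,
    f_east: np.ndarray | float,
    replicates: int,
    rng: np.random.Generator | None = None,
    n_sample: int | None = None,
) -> np.ndarray:
    """Neutral admixed VAFs under the configured wave history.

    The frequency starts at the oldest wave's mixture, is resampled
    binomially (2N gene copies) each generation, re-mixed at later
    waves, and finally sampled at the cohort size.  Returns an array of
    shape (replicates, n_loci).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if replicates < 100:
        warnings.warn("fewer than 100 replicates: unstable null quantiles")
    fw = np.atleast_1d(np.asarray(f_west, dtype=float))
    fe = np.atleast_1d(np.asarray(f_east, dtype=float))
    if np.any((fw < 0) | (fw > 1) | (fe < 0) | (fe > 1)):
        raise ValidationError("source frequencies must lie in [0, 1]")
    two_n = 2 * cfg.pop_size
    waves = {w.generation: w for w in cfg.waves}
    g_start = cfg.waves[0].generation
    f = np.broadcast_to(np.zeros_like(fw), (replicates, len(fw))).copy()
    for gen in range(g_start, 0, -1):
        w = waves.get(gen)
        if w is not None:
            mix = w.west_fraction * fw + (1 - w.west_fraction) * fe
            f = (1 - w.contribution) * f + w.contribution * mix
        f = rng.binomial(two_n, f) / two_n
    n = 2 * (n_sample if n_sample is not None else cfg.n_admixed)
    return rng.binomial(n, f) / n


# ---------------------------------------------------------------------------
# one-call cohort simulation and fixture writing
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Everything the downstream modules consume, plus ground truth."""

    cfg: SimConfig
    panels: AncestralPanels
    cohort: AdmixedCohort
    sv_records: list[SVRecord]       # admixed callset: ancestral + post
    snv_records: list[SNVRecord]
    expression: ExpressionMatrix
    truth: TruthSet


def simulate_cohort(cfg: SimConfig) -> SimResult:
    """Run the full generator: panels, admixture, post-admixture SVs,
    expression.  Deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    panels = simulate_ancestral_panels(cfg, rng)
    cohort = simulate_admixture(cfg, rng)
    G_sv, G_snv = admixed_genotypes(cohort, panels, rng)
    sv_records = _sv_records(panels.sv_sites, G_sv)
    snv_records = _snv_records(panels.snv_sites, G_snv)
    post_records, post_truth = inject_post_admixture_svs(cfg, cohort, rng)

    anc_truth = panels.sv_sites[["id", "origin"]].copy()
    anc_truth["at_crossover"] = False
    anc_truth["homology_flanked"] = panels.sv_sites["homology_flanked"].to_numpy()
    anc_truth["creation_generation"] = -1
    anc_truth["inter_ancestry"] = False
    anc_truth["archaic_present"] = panels.sv_sites["archaic_present"].to_numpy()
    truth_df = pd.concat([anc_truth, post_truth], ignore_index=True)

    all_sv = sv_records + post_records
    spec = {}
    for row in panels.sv_sites.itertuples():
        if row.origin == "west-derived":
            spec[row.id] = "WEST"
        elif row.origin == "east-derived":
            spec[row.id] = "EAST"
    for row in panels.snv_sites.itertuples():
        if row.origin == "west-derived":
            spec[row.id] = "WEST"
        elif row.origin == "east-derived":
            spec[row.id] = "EAST"
    expr, eqtl = simulate_expression(
        cfg, all_sv, snv_records, cohort.panel, rng, specificity=spec)
    truth = TruthSet(truth_df, eqtl, cohort.tracts)
    return SimResult(cfg, panels, cohort, all_sv, snv_records, expr, truth)


def write_fixture_set(cfg: SimConfig, outdir: str | Path) -> SimResult:
    """Emit a complete, self-consistent input set for every downstream
    module; deterministic given the seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_cohort(cfg)
    contigs = dict(zip(cfg.chrom_names, cfg.chrom_lengths))

    write_sv_vcf(sim.sv_records, sim.cohort.panel, out / "admixed_svs.vcf", contigs)
    write_snv_vcf(sim.snv_records, sim.cohort.panel, out / "admixed_snvs.vcf", contigs)
    for pop, stem in (("SRC_WEST", "west"), ("SRC_EAST", "east"),
                      ("AFRICAN", "african")):
        write_sv_vcf(sim.panels.sv_records(pop), sim.panels.panels[pop],
                     out / f"{stem}_svs.vcf", contigs)
        write_snv_vcf(sim.panels.snv_records(pop), sim.panels.panels[pop],
                      out / f"{stem}_snvs.vcf", contigs)
    write_tracts_bed(sim.cohort.tracts, out / "tracts.bed")
    write_expression_tsv(sim.expression, out / "expression.tsv")
    meta = PopulationPanel(
        samples=(sim.cohort.panel.samples
                 + sum((p.samples for p in sim.panels.panels.values()), [])),
        population=(sim.cohort.panel.population
                    + sum((p.population for p in sim.panels.panels.values()), [])),
        sex=(sim.cohort.panel.sex
             + sum((p.sex for p in sim.panels.panels.values()), [])),
        ancestry_west=np.concatenate([
            sim.cohort.panel.ancestry_west,
            np.full(sum(len(p) for p in sim.panels.panels.values()), np.nan)]),
    )
    write_metadata_tsv(meta, out / "metadata.tsv")
    sim.truth.sv_truth.to_csv(out / "truth_svs.tsv", sep="\t", index=False)
    sim.truth.eqtl.to_csv(out / "truth_eqtl.tsv", sep="\t", index=False)
    return sim
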