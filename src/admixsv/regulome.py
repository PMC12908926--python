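"""Regulatory analyses: cis-eQTL, eSV diversity, heritability partition
and ancestry-specific variant combinations (USVC).

cis associations are ordinary least squares of z-scored expression on
the variant allele count plus covariates, tested within 1 Mb of the
gene TSS and Benjamini-Hochberg adjusted over all tested pairs.  A USVC
is the co-occurrence, in one admixed genome, of two variants each
specific to a different ancestral population; its regulatory impact is
assessed by a joint two-variant regression with per-class BH adjustment
and a dual significance rule (both adjusted P below the FDR level).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from admixsv.core_io import (
    MISSING,
    ExpressionMatrix,
    SNVRecord,
    SVRecord,
    ValidationError,
)

CIS_WINDOW = 1_000_000


def _variant_position(v: SVRecord | SNVRecord) -> tuple[str, int]:
    if isinstance(v, SVRecord):
        return v.interval.chrom, v.interval.start
    return v.chrom, v.pos


def _ols_beta_p(y: np.ndarray, g: np.ndarray, C: np.ndarray | None):
    """beta, se, P for the genotype term of y ~ 1 + g + C."""
    n = len(y)
    cols = [np.ones(n), g]
    if C is not None and C.size:
        cols.extend(C.T)
    X = np.column_stack(cols)
    df = n - X.shape[1]
    if df < 1:
        raise ValidationError("not enough samples for the covariate set")
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return float("nan"), float("nan"), float("nan")
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return float(beta[1]), float(se[1]), float(p[1])


def cis_eqtl(
    expression: ExpressionMatrix,
    variants: Sequence[SVRecord | SNVRecord],
    covariates: np.ndarray | None = None,
    window: int = CIS_WINDOW,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """cis association scan for every (gene, variant) pair within the
    window of the gene TSS.

    Expression is z-scored per gene if not already; monomorphic variants
    are skipped; BH adjustment runs over all tested pairs.  The eSV/eQTL
    set is the variants with at least one gene at adjusted P < fdr.
    """
    if expression.normalization != "z-score":
        expression = expression.zscore()
    n = len(expression.samples)
    n_cov = 0 if covariates is None else np.atleast_2d(covariates).shape[1]
    if n < n_cov + 3:
        raise ValidationError("fewer samples than covariates + 3")
    by_chrom: dict[str, list[tuple[int, str, np.ndarray]]] = {}
    for v in variants:
        chrom, pos = _variant_position(v)
        if v.genotypes.shape[0] != n:
            raise ValidationError(f"{v.id}: genotype length != sample count")
        by_chrom.setdefault(chrom, []).append((pos, v.id, v.genotypes))
    rows = []
    for gi, gene in enumerate(expression.genes):
        chrom = expression.tss_chrom[gi]
        tss = int(expression.tss_pos[gi])
        y_full = expression.values[gi]
        for pos, vid, geno in by_chrom.get(chrom, ()):
            if abs(pos - tss) > window:
                continue
            ok = (geno != MISSING) & ~np.isnan(y_full)
            g = geno[ok].astype(float)
            if len(np.unique(g)) < 2:
                continue
            C = covariates[ok] if covariates is not None else None
            beta, se, p = _ols_beta_p(y_full[ok], g, C)
            if p == p:
                rows.append({"gene": gene, "variant": vid, "beta": beta,
                             "se": se, "p": p})
    out = pd.DataFrame(rows, columns=["gene", "variant", "beta", "se", "p"])
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < fdr
    else:
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def esv_set(eqtl_table: pd.DataFrame) -> set[str]:
    """Variants with at least one significant cis gene."""
    if not len(eqtl_table):
        return set()
    return set(eqtl_table.loc[eqtl_table["significant"], "variant"])


def esv_ratio(
    admixed_expr: ExpressionMatrix,
    admixed_svs: Sequence[SVRecord],
    source_expr: ExpressionMatrix,
    source_svs: Sequence[SVRecord],
    n_match: int,
    samplings: int = 100,
    seed: int | np.random.Generator = 0,
    fdr: float = 0.05,
    covariates: np.ndarray | None = None,
) -> dict:
    """Admixed / source ratios of eSV counts and of polymorphic SV
    counts under repeated downsampling of the admixed cohort to the
    source sample size.  Reports mean and sd over samplings."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_adm = len(admixed_expr.samples)
    if n_match > n_adm:
        raise ValidationError("n_match exceeds the admixed cohort size")
    src_eqtl = cis_eqtl(source_expr, source_svs, fdr=fdr)
    src_esv = max(len(esv_set(src_eqtl)), 1)
    src_poly = max(_polymorphic_count(source_svs, None), 1)
    esv_ratios = np.empty(samplings)
    poly_ratios = np.empty(samplings)
    for b in range(samplings):
        idx = rng.choice(n_adm, size=n_match, replace=False)
        sub_expr = admixed_expr.subset_samples(idx)
        sub_svs = [
            SVRecord(r.id, r.interval, r.svtype, r.length, r.genotypes[idx])
            for r in admixed_svs
        ]
        C = covariates[idx] if covariates is not None else None
        tab = cis_eqtl(sub_expr, sub_svs, covariates=C, fdr=fdr)
        esv_ratios[b] = len(esv_set(tab)) / src_esv
        poly_ratios[b] = _polymorphic_count(sub_svs, None) / src_poly
    return {
        "esv_ratio_mean": float(esv_ratios.mean()),
        "esv_ratio_sd": float(esv_ratios.std()),
        "sv_ratio_mean": float(poly_ratios.mean()),
        "sv_ratio_sd": float(poly_ratios.std()),
        "esv_ratios": esv_ratios,
        "sv_ratios": poly_ratios,
    }


def _polymorphic_count(svs: Sequence[SVRecord], idx) -> int:
    count = 0
    for r in svs:
        g = r.genotypes if idx is None else r.genotypes[idx]
        called = g[g != MISSING]
        if not called.size:
            continue
        if r.svtype == "mCNV":
            count += len(np.unique(called)) >= 2
        else:
            count += 0 < called.sum()
    return count


def esv_vs_divergence(
    esv_flags: Mapping[str, bool],
    f_west: Mapping[str, float],
    f_east: Mapping[str, float],
    bin_width: float = 0.025,
    last_bin_start: float = 0.3,
) -> dict:
    """eSV proportion as a function of ancestral allele-frequency
    divergence |f_west - f_east|, binned at ``bin_width`` (half-open
    bins) except a single last bin (last_bin_start, 1]; Spearman rho of
    bin midpoint vs proportion.  Empty bins are dropped with a note."""
    ids = [v for v in esv_flags if v in f_west and v in f_east]
    div = np.array([abs(f_west[v] - f_east[v]) for v in ids])
    flag = np.array([bool(esv_flags[v]) for v in ids])
    edges = list(np.arange(0, last_bin_start + 1e-12, bin_width)) + [1.0 + 1e-12]
    rows, dropped = [], 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        inb = (div >= lo) & (div < hi)
        if not inb.any():
            dropped += 1
            continue
        rows.append({"bin_lo": lo, "bin_hi": min(hi, 1.0),
                     "midpoint": (lo + min(hi, 1.0)) / 2,
                     "n": int(inb.sum()),
                     "esv_proportion": float(flag[inb].mean())})
    table = pd.DataFrame(rows)
    if len(table) >= 3:
        rho, p = stats.spearmanr(table["midpoint"], table["esv_proportion"])
    else:
        rho, p = float("nan"), float("nan")
    return {"table": table, "rho": float(rho), "p": float(p),
            "dropped_bins": dropped}


# ---------------------------------------------------------------------------
# heritability partition
# ---------------------------------------------------------------------------

def partition_heritability(
    y: np.ndarray,
    sv_genotype: np.ndarray,
    snv_genotypes: np.ndarray,
    genetic_floor: float = 0.05,
) -> dict:
    """Variance partition of one gene: SV fixed effect + cis-SNV random
    effect.

    Model: y = b0 + b1 g_sv + u + e with u ~ N(0, sigma_g^2 K), K the
    standardized cis-SNV relatedness matrix.  Variance components by
    restricted maximum likelihood on the eigenbasis of K; a
    Haseman-Elston moment estimator is the recorded fallback.  The SV
    share is b1^2 var(g_sv) / var(y); a gene counts as genetic when the
    total genetic share exceeds ``genetic_floor``; the lead-SV flag
    marks SV share > SNV share.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(sv_genotype, dtype=float)
    Z = np.asarray(snv_genotypes, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValidationError("need at least 2 cis SNVs")
    n = len(y)
    sd = Z.std(axis=0)
    Zs = (Z[:, sd > 0] - Z[:, sd > 0].mean(axis=0)) / sd[sd > 0]
    if Zs.shape[1] < 1:
        raise ValidationError("all cis SNVs monomorphic")
    K = Zs @ Zs.T / Zs.shape[1]

    X = np.column_stack([np.ones(n), g]) if g.std() > 0 else np.ones((n, 1))
    vals, vecs = np.linalg.eigh(K)
    yr = vecs.T @ y
    Xr = vecs.T @ X

    def negreml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        d = lam * vals + 1.0
        XtDX = (Xr.T / d) @ Xr
        try:
            beta = np.linalg.solve(XtDX, (Xr.T / d) @ yr)
        except np.linalg.LinAlgError:
            return 1e10
        r = yr - Xr @ beta
        dfree = n - X.shape[1]
        s2 = float(r @ (r / d)) / dfree
        _, ld_xdx = np.linalg.slogdet(XtDX)
        return (dfree * np.log(s2) + np.log(d).sum() + ld_xdx) / 2

    method = "reml"
    try:
        res = optimize.minimize_scalar(negreml, bounds=(-10, 10),
                                       method="bounded")
        lam = float(np.exp(res.x))
        d = lam * vals + 1.0
        XtDX = (Xr.T / d) @ Xr
        beta = np.linalg.solve(XtDX, (Xr.T / d) @ yr)
        r = yr - Xr @ beta
        sigma_e2 = float(r @ (r / d)) / (n - X.shape[1])
        sigma_g2 = lam * sigma_e2
        if not np.isfinite(sigma_g2):
            raise FloatingPointError
    except (FloatingPointError, np.linalg.LinAlgError):
        # Haseman-Elston moment fallback on the residuals of the fixed part
        method = "haseman-elston"
        bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ bhat
        off = ~np.eye(n, dtype=bool)
        kk = K[off]
        sigma_g2 = float(np.sum(kk * np.outer(r, r)[off]) / np.sum(kk * kk))
        sigma_g2 = max(sigma_g2, 0.0)
        sigma_e2 = max(float(r.var()) - sigma_g2, 1e-12)
        beta = bhat

    var_y = float(y.var())
    if var_y == 0:
        raise ValidationError("expression has zero variance")
    sv_share = (float(beta[1]) ** 2 * float(g.var()) / var_y
                if X.shape[1] == 2 else 0.0)
    snv_share = float(sigma_g2 * np.mean(np.diag(K)) / var_y)
    total = min(sv_share + snv_share, 1.0)
    return {
        "sv_share": float(np.clip(sv_share, 0, 1)),
        "snv_share": float(np.clip(snv_share, 0, 1)),
        "total_genetic": float(total),
        "is_genetic": bool(total > genetic_floor),
        "lead_sv": bool(sv_share > snv_share),
        "method": method,
    }


def hwe_expected_hom(q: float) -> float:
    """Expected homozygote frequency q^2 under Hardy-Weinberg."""
    if not 0 <= q <= 1:
        raise ValidationError("allele frequency must lie in [0, 1]")
    return q * q


# ---------------------------------------------------------------------------
# ancestry-specific alleles and USVC
# ---------------------------------------------------------------------------

def ancestry_specific_alleles(
    variants: Sequence[SVRecord | SNVRecord],
    west_genotypes: Mapping[str, np.ndarray],
    east_genotypes: Mapping[str, np.ndarray],
    max_other: float = 0,
    frequency_mode: bool = False,
) -> dict[str, str]:
    """Label variants WEST- or EAST-specific.

    Strict mode (default): specific iff the alternate allele is present
    (count > 0) in one source panel and at most ``max_other`` alternate
    alleles occur in the other.  ``frequency_mode`` applies the same
    rule to VAFs (``max_other`` then is a frequency, e.g. 0.05 for the
    rare/low-frequency relaxation).  Unlabeled variants are omitted.
    """
    labels: dict[str, str] = {}
    for v in variants:
        gw = west_genotypes.get(v.id)
        ge = east_genotypes.get(v.id)
        if gw is None or ge is None:
            continue
        def level(g):
            called = g[g != MISSING]
            if called.size == 0:
                return 0.0
            s = float(called.sum())
            return s / (2 * called.size) if frequency_mode else s
        w, e = level(np.asarray(gw)), level(np.asarray(ge))
        if w > max_other and e <= max_other:
            labels[v.id] = "WEST"
        elif e > max_other and w <= max_other:
            labels[v.id] = "EAST"
    return labels


@dataclass
class USVCRecord:
    """One ancestry-specific variant combination."""

    usvc_class: str          # overlap-DEL-SNV | cis-SV-SNV | cis-SV-SV
    variant_a: str           # the SV (or first SV)
    ancestry_a: str
    variant_b: str           # the SNV (or second SV)
    ancestry_b: str
    joint_carriers: list[str]


def enumerate_usvc(
    svs: Sequence[SVRecord],
    snvs: Sequence[SNVRecord],
    specificity: Mapping[str, str],
    samples: Sequence[str],
    window: int = CIS_WINDOW,
) -> list[USVCRecord]:
    """Enumerate ancestry-specific variant combinations.

    Classes: (a) overlap: an SNV positioned inside a DEL/DUP interval;
    (b) cis-SV-SNV within the window of the SV position; (c) cis-SV-SV.
    The two variants must be specific to different ancestries and
    jointly carried (both non-reference) by at least one sample.
    """
    def carrier_mask(v) -> np.ndarray:
        g = v.genotypes
        if isinstance(v, SVRecord) and v.svtype == "mCNV":
            return (g != MISSING) & (g != 2)
        return (g != MISSING) & (g > 0)

    labeled_svs = [v for v in svs if v.id in specificity]
    labeled_snvs = [v for v in snvs if v.id in specificity]
    out: list[USVCRecord] = []

    def emit(cls, a, b):
        la, lb = specificity[a.id], specificity[b.id]
        if la == lb:
            return
        joint = carrier_mask(a) & carrier_mask(b)
        if not joint.any():
            return
        out.append(USVCRecord(
            cls, a.id, la, b.id, lb,
            [samples[i] for i in np.flatnonzero(joint)]))

    for sv in labeled_svs:
        for snv in labeled_snvs:
            if snv.chrom != sv.interval.chrom:
                continue
            if (sv.svtype in ("DEL", "DUP")
                    and sv.interval.start <= snv.pos < sv.interval.end):
                emit("overlap-DEL-SNV", sv, snv)
            elif abs(snv.pos - sv.interval.start) <= window:
                emit("cis-SV-SNV", sv, snv)
    for i, a in enumerate(labeled_svs):
        for b in labeled_svs[i + 1:]:
            if (a.interval.chrom == b.interval.chrom
                    and abs(b.interval.start - a.interval.start) <= window
                    and a.id != b.id):
                emit("cis-SV-SV", a, b)
    return out


def joint_usvc_model(
    records: Sequence[USVCRecord],
    expression: ExpressionMatrix,
    genotypes: Mapping[str, np.ndarray],
    covariates: np.ndarray | None = None,
    fdr: float = 0.1,
    window: int = CIS_WINDOW,
    variant_positions: Mapping[str, tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Joint two-variant regression per USVC and cis gene.

    Fits expression ~ variant_a + variant_b + covariates; BH adjustment
    of each variant's P within its USVC class; a combination is
    significant iff both adjusted Ps are below ``fdr``; direction is
    ``uni`` when the two effects share a sign.  Perfectly collinear
    genotype pairs are flagged untestable.
    """
    if expression.normalization != "z-score":
        expression = expression.zscore()
    n = len(expression.samples)
    rows = []
    for k, rec in enumerate(records):
        ga = np.asarray(genotypes[rec.variant_a], dtype=float)
        gb = np.asarray(genotypes[rec.variant_b], dtype=float)
        if variant_positions is None:
            gene_idx = range(len(expression.genes))
        else:
            chrom, pos = variant_positions[rec.variant_a]
            gene_idx = [
                gi for gi in range(len(expression.genes))
                if expression.tss_chrom[gi] == chrom
                and abs(int(expression.tss_pos[gi]) - pos) <= window
            ]
        ok0 = (ga != MISSING) & (gb != MISSING)
        corr = (np.corrcoef(ga[ok0], gb[ok0])[0, 1]
                if ok0.sum() > 2 and ga[ok0].std() > 0 and gb[ok0].std() > 0
                else np.nan)
        untestable = bool(corr == corr and corr ** 2 > 1 - 1e-12)
        for gi in gene_idx:
            y = expression.values[gi]
            ok = ok0 & ~np.isnan(y)
            if untestable or ok.sum() < 5:
                rows.append({
                    "record": k, "usvc_class": rec.usvc_class,
                    "gene": expression.genes[gi],
                    "variant_a": rec.variant_a, "variant_b": rec.variant_b,
                    "beta_a": np.nan, "beta_b": np.nan,
                    "p_a": np.nan, "p_b": np.nan, "untestable": True,
                })
                continue
            cols = [np.ones(int(ok.sum())), ga[ok], gb[ok]]
            if covariates is not None:
                cols.extend(np.atleast_2d(covariates)[ok].T)
            X = np.column_stack(cols)
            if np.linalg.matrix_rank(X) < X.shape[1] or len(y[ok]) <= X.shape[1]:
                rows.append({
                    "record": k, "usvc_class": rec.usvc_class,
                    "gene": expression.genes[gi],
                    "variant_a": rec.variant_a, "variant_b": rec.variant_b,
                    "beta_a": np.nan, "beta_b": np.nan,
                    "p_a": np.nan, "p_b": np.nan, "untestable": True,
                })
                continue
            XtX_inv = np.linalg.inv(X.T @ X)
            beta = XtX_inv @ (X.T @ y[ok])
            resid = y[ok] - X @ beta
            df = int(ok.sum()) - X.shape[1]
            se = np.sqrt(float(resid @ resid) / df * np.diag(XtX_inv))
            t = beta / se
            p = 2 * stats.t.sf(np.abs(t), df)
            rows.append({
                "record": k, "usvc_class": rec.usvc_class,
                "gene": expression.genes[gi],
                "variant_a": rec.variant_a, "variant_b": rec.variant_b,
                "beta_a": float(beta[1]), "beta_b": float(beta[2]),
                "p_a": float(p[1]), "p_b": float(p[2]), "untestable": False,
            })
    out = pd.DataFrame(rows)
    if not len(out):
        return out
    out["p_a_adj"] = np.nan
    out["p_b_adj"] = np.nan
    for cls in out["usvc_class"].unique():
        m = (out["usvc_class"] == cls) & ~out["untestable"]
        if m.any():
            out.loc[m, "p_a_adj"] = multipletests(out.loc[m, "p_a"],
                                                  method="fdr_bh")[1]
            out.loc[m, "p_b_adj"] = multipletests(out.loc[m, "p_b"],
                                                  method="fdr_bh")[1]
    out["significant"] = (out["p_a_adj"] < fdr) & (out["p_b_adj"] < fdr)
    out["direction"] = np.where(
        np.sign(out["beta_a"]) == np.sign(out["beta_b"]), "uni", "opposite")
    out.loc[out["untestable"], "direction"] = "NA"
    return out
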