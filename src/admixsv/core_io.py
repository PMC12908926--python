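"""Domain types, coordinate conventions and file I/O.

Coordinates are 1-based inclusive at every file boundary (VCF convention)
and 0-based half-open internally.  The printed span of an interval in kb
therefore equals ``(end - start) / 1000`` of the internal representation,
which is identical to ``end1 - start1 + 1`` of the 1-based inclusive form.

Genotypes are stored as small integer arrays: alternate-allele counts
0/1/2 for biallelic variants, non-negative integer copy numbers for
multi-allelic CNVs (mCNV).  Missing calls are encoded as -1 and are
excluded from every allele-count denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

MISSING = -1

SV_TYPES = ("DEL", "DUP", "mCNV", "INS", "INV")
MIN_SV_LENGTH = 50  # bp; variants below this are not structural variants

ANCESTRIES = ("WEST", "EAST")


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


class ValidationError(ValueError):
    """An in-memory object violated a domain invariant."""


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open 0-based interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name must be nonempty")
        if not self.start < self.end:
            raise ValidationError(
                f"interval requires start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def interval_length_1based(interval: GenomicInterval) -> int:
    """Span of the interval in bp.

    Equals ``end - start`` of the internal half-open interval, which is the
    inclusive span ``end1 - start1 + 1`` of its 1-based on-disk form.
    """
    return interval.end - interval.start


def format_kb(bp: int) -> str:
    """Display helper: 3407 -> '3.4 kb'."""
    return f"{round(bp / 1000, 1)} kb"


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when disjoint or on
    different chromosomes (a documented convention, not an error)."""
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


# ---------------------------------------------------------------------------
# variant records
# ---------------------------------------------------------------------------

@dataclass
class SVRecord:
    """One structural variant with per-sample genotypes.

    ``genotypes`` holds alternate-allele counts 0/1/2 (DEL/DUP/INS/INV) or
    integer copy numbers (mCNV); -1 marks a missing call.  ``length`` is
    the affected length in bp: for INS the inserted-sequence length (the
    interval is a 1-bp anchor), otherwise the interval span.
    """

    id: str
    interval: GenomicInterval
    svtype: str
    length: int
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValidationError(f"{self.id}: unknown svtype {self.svtype!r}")
        if self.length < MIN_SV_LENGTH:
            raise ValidationError(
                f"{self.id}: length {self.length} below the {MIN_SV_LENGTH}-bp rule"
            )
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        called = self.genotypes[self.genotypes != MISSING]
        if self.svtype == "mCNV":
            if called.size and called.min() < 0:
                raise ValidationError(f"{self.id}: negative copy number")
        else:
            if called.size and (called.min() < 0 or called.max() > 2):
                raise ValidationError(f"{self.id}: allele counts must be 0/1/2")

    @property
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def vaf(self) -> float:
        """Alternate alleles over called alleles (biallelic types only)."""
        if self.svtype == "mCNV":
            raise ValidationError(f"{self.id}: VAF undefined for mCNV")
        called = self.genotypes[self.genotypes != MISSING]
        if called.size == 0:
            return float("nan")
        return float(called.sum() / (2 * called.size))


@dataclass
class SNVRecord:
    """One biallelic SNV; ``pos`` is internal 0-based."""

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        called = self.genotypes[self.genotypes != MISSING]
        if called.size and (called.min() < 0 or called.max() > 2):
            raise ValidationError(f"{self.id}: allele counts must be 0/1/2")

    def vaf(self) -> float:
        called = self.genotypes[self.genotypes != MISSING]
        if called.size == 0:
            return float("nan")
        return float(called.sum() / (2 * called.size))


def vaf_matrix(records: Sequence[SVRecord | SNVRecord]) -> np.ndarray:
    """Per-record VAF vector over called alleles (NaN for mCNV, whose
    genotypes are copy numbers rather than allele counts)."""
    out = np.empty(len(records))
    for i, r in enumerate(records):
        out[i] = (np.nan if getattr(r, "svtype", None) == "mCNV" else r.vaf())
    return out


# ---------------------------------------------------------------------------
# ancestry tracts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncestryTract:
    """One contiguous local-ancestry segment on one haplotype."""

    sample: str
    hap: int
    interval: GenomicInterval
    ancestry: str

    def __post_init__(self) -> None:
        if self.ancestry not in ANCESTRIES:
            raise ValidationError(f"unknown ancestry label {self.ancestry!r}")
        if self.hap not in (0, 1):
            raise ValidationError("haplotype index must be 0 or 1")


def tracts_by_haplotype(
    tracts: Iterable[AncestryTract],
) -> dict[tuple[str, int, str], list[AncestryTract]]:
    """Group tracts per (sample, hap, chrom), sorted by start."""
    out: dict[tuple[str, int, str], list[AncestryTract]] = {}
    for t in tracts:
        out.setdefault((t.sample, t.hap, t.interval.chrom), []).append(t)
    for key in out:
        out[key].sort(key=lambda t: t.interval.start)
    return out


def merge_adjacent_tracts(tracts: Sequence[AncestryTract]) -> list[AncestryTract]:
    """Merge adjacent same-ancestry tracts and validate coverage.

    Tracts of one haplotype must be non-overlapping and contiguous
    (no gaps) — a gap or overlap raises :class:`ValidationError`.
    """
    merged: list[AncestryTract] = []
    for key, group in tracts_by_haplotype(tracts).items():
        sample, hap, chrom = key
        current = group[0]
        for t in group[1:]:
            if t.interval.start < current.interval.end:
                raise ValidationError(
                    f"overlapping tracts on {sample} hap {hap} {chrom}: "
                    f"{current.interval} vs {t.interval}"
                )
            if t.interval.start > current.interval.end:
                raise ValidationError(
                    f"coverage gap on {sample} hap {hap} {chrom} at "
                    f"[{current.interval.end}, {t.interval.start})"
                )
            if t.ancestry == current.ancestry:
                current = AncestryTract(
                    sample, hap,
                    GenomicInterval(chrom, current.interval.start, t.interval.end),
                    t.ancestry,
                )
            else:
                merged.append(current)
                current = t
        merged.append(current)
    merged.sort(key=lambda t: (t.sample, t.hap, t.interval))
    return merged


def switch_points(tracts: Sequence[AncestryTract]) -> dict[tuple[str, int, str], np.ndarray]:
    """Interior boundaries between tracts of different ancestry,
    per (sample, hap, chrom)."""
    out = {}
    for key, group in tracts_by_haplotype(tracts).items():
        pts = [
            a.interval.end
            for a, b in zip(group, group[1:])
            if a.ancestry != b.ancestry
        ]
        out[key] = np.asarray(pts, dtype=np.int64)
    return out


# ---------------------------------------------------------------------------
# panels and expression
# ---------------------------------------------------------------------------

@dataclass
class PopulationPanel:
    """Sample sheet: ids, population labels, sex, and — for admixed
    samples — the global WEST ancestry fraction."""

    samples: list[str]
    population: list[str]
    sex: list[str] = field(default_factory=list)
    ancestry_west: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids in panel")
        if not self.sex:
            self.sex = ["U"] * len(self.samples)
        if self.ancestry_west is not None:
            self.ancestry_west = np.asarray(self.ancestry_west, dtype=float)
            ok = np.isnan(self.ancestry_west) | (
                (self.ancestry_west >= 0) & (self.ancestry_west <= 1)
            )
            if not ok.all():
                raise ValidationError("ancestry proportions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.samples)

    def indices_of(self, population: str) -> np.ndarray:
        return np.array(
            [i for i, p in enumerate(self.population) if p == population], dtype=int
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with TSS coordinates per gene."""

    genes: list[str]
    tss_chrom: list[str]
    tss_pos: np.ndarray
    samples: list[str]
    values: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.tss_pos = np.asarray(self.tss_pos, dtype=np.int64)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError("expression matrix shape mismatch")
        if self.normalization not in ("raw", "z-score"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")

    def zscore(self) -> "ExpressionMatrix":
        """Z-score each gene across samples (NaN-aware)."""
        mu = np.nanmean(self.values, axis=1, keepdims=True)
        sd = np.nanstd(self.values, axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        return ExpressionMatrix(
            self.genes, self.tss_chrom, self.tss_pos, list(self.samples),
            (self.values - mu) / sd, normalization="z-score",
        )

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            self.genes, self.tss_chrom, self.tss_pos,
            [self.samples[i] for i in idx], self.values[:, idx],
            normalization=self.normalization,
        )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_SYMBOLIC = {"<DEL>": "DEL", "<DUP>": "DUP", "<INS>": "INS",
             "<INV>": "INV", "<CNV>": "mCNV"}
_ALT_OF = {v: k for k, v in _SYMBOLIC.items()}


def _sv_header(panel: PopulationPanel, contigs: dict[str, int]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for name, length in contigs.items():
        h.contigs.add(name, length=length)
    h.info.add("END", 1, "Integer", "End position of the variant (1-based inclusive)")
    h.info.add("SVTYPE", 1, "String", "Type of structural variant")
    h.info.add("SVLEN", 1, "Integer", "Length of the variant in bp")
    h.formats.add("GT", 1, "String", "Genotype")
    h.formats.add("CN", 1, "Integer", "Integer copy number")
    for alt in ("DEL", "DUP", "INS", "INV", "CNV"):
        h.add_line(f"##ALT=<ID={alt},Description=\"{alt} structural variant\">")
    for s in panel.samples:
        h.add_sample(s)
    return h


_GT_OF_COUNT = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_sv_vcf(records: Sequence[SVRecord], panel: PopulationPanel,
                 path: str | Path, contigs: dict[str, int] | None = None) -> None:
    """Write SVs as VCF 4.2 with symbolic ALTs; 1-based inclusive on disk."""
    if contigs is None:
        contigs = {}
        for r in records:
            contigs[r.interval.chrom] = max(
                contigs.get(r.interval.chrom, 0), r.interval.end + 1
            )
    header = _sv_header(panel, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in sorted(records, key=lambda r: (r.interval.chrom, r.interval.start, r.id)):
            rec = out.new_record(
                contig=r.interval.chrom,
                start=r.interval.start,       # pysam takes 0-based start
                stop=r.interval.end,
                alleles=("N", _ALT_OF[r.svtype]),
                id=r.id,
            )
            rec.info["SVTYPE"] = "CNV" if r.svtype == "mCNV" else r.svtype
            if r.svtype == "INS":
                # non-INS lengths are carried by END; htslib would derive
                # END from SVLEN under the padding-base convention
                rec.info["SVLEN"] = r.length
            for i, s in enumerate(panel.samples):
                g = int(r.genotypes[i])
                if r.svtype == "mCNV":
                    rec.samples[s]["GT"] = (None,)
                    if g != MISSING:
                        rec.samples[s]["CN"] = g
                else:
                    rec.samples[s]["GT"] = (
                        (None, None) if g == MISSING else _GT_OF_COUNT[g]
                    )
                    rec.samples[s].phased = False
            out.write(rec)


def read_sv_vcf(path: str | Path) -> tuple[list[SVRecord], list[str]]:
    """Read an SV VCF with symbolic ALTs.

    Returns the accepted records plus the header sample order.  Records
    shorter than 50 bp are rejected with a logged reason; malformed
    symbolic ALTs or a missing END for DEL/DUP/INV raise FormatError.
    """
    records: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if len(rec.alts or ()) != 1 or rec.alts[0] not in _SYMBOLIC:
                raise FormatError(
                    f"{rec.id or rec.pos}: malformed symbolic ALT {rec.alts!r}"
                )
            svtype = _SYMBOLIC[rec.alts[0]]
            end = rec.info.get("END", rec.stop)
            if svtype in ("DEL", "DUP", "INV", "mCNV") and end is None:
                raise FormatError(f"{rec.id}: missing END for {svtype}")
            if svtype == "INS":
                interval = GenomicInterval(rec.contig, rec.start, rec.start + 1)
            else:
                interval = GenomicInterval(rec.contig, rec.start, rec.stop)
            length = rec.info.get("SVLEN")
            if length is None:
                length = len(interval)
            length = abs(int(length))
            if length < MIN_SV_LENGTH:
                log.warning(
                    "rejecting %s: length %d below the %d-bp rule",
                    rec.id, length, MIN_SV_LENGTH,
                )
                continue
            gts = np.full(len(samples), MISSING, dtype=np.int16)
            for i, s in enumerate(samples):
                if svtype == "mCNV":
                    cn = rec.samples[s].get("CN")
                    if cn is not None:
                        gts[i] = cn
                else:
                    alleles = rec.samples[s].get("GT") or ()
                    if alleles and None not in alleles:
                        gts[i] = sum(1 for a in alleles if a and a > 0)
            records.append(
                SVRecord(rec.id or f"sv_{rec.contig}_{rec.pos}", interval,
                         svtype, length, gts)
            )
    return records, samples


def write_snv_vcf(records: Sequence[SNVRecord], panel: PopulationPanel,
                  path: str | Path, contigs: dict[str, int] | None = None) -> None:
    if contigs is None:
        contigs = {}
        for r in records:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.pos + 2)
    h = pysam.VariantHeader()
    for name, length in contigs.items():
        h.contigs.add(name, length=length)
    h.formats.add("GT", 1, "String", "Genotype")
    for s in panel.samples:
        h.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=h) as out:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.id)):
            rec = out.new_record(
                contig=r.chrom, start=r.pos, stop=r.pos + 1,
                alleles=(r.ref, r.alt), id=r.id,
            )
            for i, s in enumerate(panel.samples):
                g = int(r.genotypes[i])
                rec.samples[s]["GT"] = (
                    (None, None) if g == MISSING else _GT_OF_COUNT[g]
                )
                rec.samples[s].phased = False
            out.write(rec)


def read_snv_vcf(path: str | Path) -> tuple[list[SNVRecord], list[str]]:
    records: list[SNVRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise FormatError(f"{rec.id}: SNVs must be biallelic")
            gts = np.full(len(samples), MISSING, dtype=np.int16)
            for i, s in enumerate(samples):
                alleles = rec.samples[s].get("GT") or ()
                if alleles and None not in alleles:
                    gts[i] = sum(1 for a in alleles if a and a > 0)
            records.append(
                SNVRecord(rec.id or f"snv_{rec.contig}_{rec.pos}",
                          rec.contig, rec.start, rec.ref, rec.alts[0], gts)
            )
    return records, samples


# ---------------------------------------------------------------------------
# tract BED and TSV I/O
# ---------------------------------------------------------------------------

_TRACT_COLS = ["chrom", "start", "end", "sample", "hap", "ancestry"]


def write_tracts_bed(tracts: Sequence[AncestryTract], path: str | Path) -> None:
    """BED-like: chrom, start, end (0-based half-open), sample, hap, ancestry."""
    rows = [
        (t.interval.chrom, t.interval.start, t.interval.end,
         t.sample, t.hap, t.ancestry)
        for t in sorted(tracts, key=lambda t: (t.sample, t.hap, t.interval))
    ]
    pd.DataFrame(rows, columns=_TRACT_COLS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_tracts_bed(path: str | Path) -> list[AncestryTract]:
    """Read, normalize (merge adjacent same-label tracts) and validate."""
    df = pd.read_csv(path, sep="\t", header=None, names=_TRACT_COLS,
                     dtype={"chrom": str, "sample": str, "ancestry": str})
    tracts = [
        AncestryTract(str(r.sample), int(r.hap),
                      GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
                      str(r.ancestry))
        for r in df.itertuples()
    ]
    return merge_adjacent_tracts(tracts)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.genes, columns=expr.samples)
    df.insert(0, "tss_chrom", expr.tss_chrom)
    df.insert(1, "tss_pos", expr.tss_pos)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path: str | Path,
                        panel: PopulationPanel | None = None) -> ExpressionMatrix:
    """Read a genes x samples TSV; realigned to panel order when given.

    Panel samples absent from the file are reported via FormatError;
    duplicated gene ids are an error; NA cells stay NaN (masked downstream).
    """
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicated gene ids: {dups}")
    tss_chrom = df.pop("tss_chrom").astype(str).tolist()
    tss_pos = df.pop("tss_pos").to_numpy(dtype=np.int64)
    samples = list(df.columns)
    if panel is not None:
        missing = [s for s in panel.samples if s not in df.columns]
        if missing:
            raise FormatError(f"expression file lacks samples: {missing}")
        samples = list(panel.samples)
        df = df[samples]
    return ExpressionMatrix(
        list(df.index), tss_chrom, tss_pos, samples, df.to_numpy(dtype=float)
    )


def write_metadata_tsv(panel: PopulationPanel, path: str | Path) -> None:
    anc = (panel.ancestry_west if panel.ancestry_west is not None
           else np.full(len(panel), np.nan))
    pd.DataFrame({
        "sample_id": panel.samples,
        "population": panel.population,
        "sex": panel.sex,
        "ancestry_west": anc,
    }).to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> PopulationPanel:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    anc = df["ancestry_west"].to_numpy(dtype=float) if "ancestry_west" in df else None
    return PopulationPanel(
        samples=df["sample_id"].tolist(),
        population=df["population"].tolist(),
        sex=df["sex"].astype(str).tolist() if "sex" in df else [],
        ancestry_west=anc,
    )
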