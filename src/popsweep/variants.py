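"""VCF input/output, the genotype matrix container, and SNP quality-control filters.

Genotypes are coded 0 (hom ref), 1 (het), 2 (hom alt) and :data:`MISSING` (-1).
Only biallelic SNPs are kept; multiallelic and non-SNP records are skipped
and counted on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: missing-genotype sentinel in the calls matrix
MISSING = -1

#: depth sentinel when neither DP nor AD is present
DEPTH_UNKNOWN = np.nan

_VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "qual"]
_NUCLEOTIDES = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP genotype calls plus site and depth metadata.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers.
    variants : pandas.DataFrame
        One row per site with columns ``chrom, pos, ref, alt, qual``
        (pos 1-based).
    calls : ndarray of int8, shape (n_samples, n_variants)
        Genotype codes; ``MISSING`` for no-calls.
    depth : ndarray of float, shape (n_samples, n_variants)
        Per-sample supporting-read counts; NaN when unknown.
    """

    samples: list[str]
    variants: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def validate(self) -> None:
        """Raise ``ValueError`` on dimension mismatch or unsorted positions."""
        if self.calls.shape != (self.n_samples, self.n_variants):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{self.n_samples} samples x {self.n_variants} variants"
            )
        if self.depth.shape != self.calls.shape:
            raise ValueError("depth shape does not match calls shape")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset by a boolean mask or integer index over variants (order kept)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index].copy(),
            depth=self.depth[:, index].copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            variants=self.variants.copy(),
            calls=self.calls[idx, :].copy(),
            depth=self.depth[idx, :].copy(),
        )

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.samples.index(s) for s in sample_ids], dtype=int)


@dataclass
class FilterReport:
    """Accounting of the quality-control pass: removals attributed to the
    first failing rule, applied in order quality, support, maf, missing."""

    n_input: int
    n_pass: int
    removed: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows.append(("pass", self.n_pass))
        return pd.DataFrame(rows, columns=["item", "count"])


class VcfParseError(ValueError):
    pass


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are skipped (logged with counts).
    ``./.`` genotypes become :data:`MISSING`.  Per-sample depth is taken from
    FORMAT/DP, falling back to the sum of FORMAT/AD, else NaN.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise VcfParseError(f"cannot open VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"VCF {path!r} contains zero samples")

    rows = []
    calls_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    n_multiallelic = 0
    n_nonsnp = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
            n_nonsnp += 1
            continue
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        dp = _record_depth(rec, len(samples))
        rows.append((rec.CHROM, rec.POS, ref, alt, rec.QUAL if rec.QUAL is not None else np.nan))
        calls_cols.append(gt)
        depth_cols.append(dp)

    if n_multiallelic or n_nonsnp:
        logger.info(
            "read_vcf skipped %d multiallelic and %d non-SNP records",
            n_multiallelic,
            n_nonsnp,
        )

    variants = pd.DataFrame(rows, columns=_VARIANT_COLUMNS)
    n = len(samples)
    calls = (
        np.stack(calls_cols, axis=1) if calls_cols else np.empty((n, 0), dtype=np.int8)
    )
    depth = (
        np.stack(depth_cols, axis=1) if depth_cols else np.empty((n, 0), dtype=float)
    )
    g = GenotypeMatrix(samples=samples, variants=variants, calls=calls, depth=depth)
    g.validate()
    return g


def _record_depth(rec, n_samples: int) -> np.ndarray:
    dp = None
    try:
        dp = rec.format("DP")
    except KeyError:
        dp = None
    if dp is not None:
        out = dp.astype(float).reshape(n_samples)
        out[out < 0] = np.nan  # cyvcf2 encodes '.' as a negative sentinel
        return out
    try:
        ad = rec.format("AD")
    except KeyError:
        ad = None
    if ad is not None:
        ad = ad.astype(float)
        ad[ad < 0] = np.nan
        return np.nansum(ad, axis=1).reshape(n_samples)
    return np.full(n_samples, DEPTH_UNKNOWN)


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a plain-text VCF 4.2 with GT:DP:AD fields.

    AD is fabricated consistently with the genotype call and recorded depth,
    so files round-trip through :func:`read_vcf`.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, sub in g.variants.groupby("chrom", sort=False):
            # contig length: at least the last variant position
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(g.n_variants):
            v = g.variants.iloc[j]
            qual = "." if pd.isna(v.qual) else f"{v.qual:g}"
            fields = [str(v.chrom), str(int(v.pos)), ".", v.ref, v.alt, qual, "PASS", ".", "GT:DP:AD"]
            for i in range(g.n_samples):
                call = int(g.calls[i, j])
                d = g.depth[i, j]
                if np.isnan(d):
                    dp_s, ad_s = ".", ".,."
                else:
                    d = int(round(d))
                    dp_s = str(d)
                    if call == 0:
                        ad_s = f"{d},0"
                    elif call == 1:
                        ad_s = f"{d - d // 2},{d // 2}"
                    elif call == 2:
                        ad_s = f"0,{d}"
                    else:
                        ad_s = ".,."
                fields.append(f"{gt_strings[call]}:{dp_s}:{ad_s}")
            fh.write("\t".join(fields) + "\n")


def filter_variants(
    g: GenotypeMatrix,
    min_quality: float = 20.0,
    min_support: float = 4.0,
    min_maf: float = 0.05,
    max_missing: float = 0.1,
    support_mode: str = "mean",
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply SNP quality-control filters; removals attributed to the first
    failing rule in order quality, support, maf, missing.

    ``support_mode='mean'`` requires the mean per-sample depth at the site to
    be >= ``min_support`` (the site-level reading of a caller-level depth
    flag; the alternative ``'per_sample'`` mode requires every genotyped
    sample to reach it individually).
    """
    if g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    if support_mode not in ("mean", "per_sample"):
        raise ValueError(f"unknown support_mode {support_mode!r}")

    qual = g.variants["qual"].to_numpy(dtype=float)
    ok_qual = np.nan_to_num(qual, nan=np.inf) >= min_quality

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN depth columns
        if support_mode == "mean":
            site_support = np.nanmean(g.depth, axis=0)
        else:
            site_support = np.nanmin(g.depth, axis=0)
    # unknown depth passes (no evidence against the site)
    ok_support = ~(site_support < min_support)

    freq = allele_frequencies(g)
    maf = np.minimum(freq, 1.0 - freq)
    ok_maf = maf >= min_maf  # NaN freq (all-missing) fails here via comparison
    ok_maf = np.where(np.isnan(maf), False, ok_maf)

    miss_frac = np.mean(g.calls == MISSING, axis=0)
    ok_missing = miss_frac <= max_missing

    removed = {"quality": 0, "support": 0, "maf": 0, "missing": 0}
    keep = np.ones(g.n_variants, dtype=bool)
    for j in range(g.n_variants):
        if not ok_qual[j]:
            removed["quality"] += 1
        elif not ok_support[j]:
            removed["support"] += 1
        elif not ok_maf[j]:
            removed["maf"] += 1
        elif not ok_missing[j]:
            removed["missing"] += 1
        else:
            continue
        keep[j] = False

    out = g.take_variants(keep)
    report = FilterReport(n_input=g.n_variants, n_pass=out.n_variants, removed=removed)
    if out.n_variants == 0:
        warnings.warn("all variants removed by filtering", stacklevel=2)
    return out, report


def allele_frequencies(
    g: GenotypeMatrix, subset: Sequence[str] | None = None
) -> np.ndarray:
    """Per-variant alt-allele frequency over non-missing calls.

    Returns NaN for variants with zero non-missing calls in the subset.
    """
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("subset of samples must be nonempty")
        calls = g.calls[g.sample_indices(subset), :]
    else:
        calls = g.calls
    present = calls != MISSING
    n_called = present.sum(axis=0)
    alt = np.where(present, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = alt / (2.0 * n_called)
    return np.where(n_called == 0, np.nan, freq)
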