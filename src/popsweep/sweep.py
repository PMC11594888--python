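"""Sliding-window Fst / theta-pi selection screen.

Per-site Weir & Cockerham (1984) variance components are accumulated within
windows and combined as sum(a) / sum(a+b+c) — the weighted windowed estimate.
theta-pi is the per-site pairwise diversity summed over the window and
divided by the window length in bp, so monomorphic or absent sites
contribute zero.  Selection = intersection of the top quantile of Fst and of
the diversity statistic, run once per focal group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import GeneModel
from .variants import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

WINDOW_SIZE = 100_000
WINDOW_STEP = 50_000


@dataclass
class Window:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_snps: int = 0
    fst: float = np.nan
    pi: dict[str, float] = field(default_factory=dict)
    statistic: float = np.nan
    selected_for: str = "none"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SweepResult:
    windows: list[Window]
    fst_threshold: float
    stat_threshold: float
    selected: list[Window]
    genes: dict[int, list[str]] = field(default_factory=dict)  # window idx -> genes


def make_windows(
    chrom_lengths: dict[str, int], size: int = WINDOW_SIZE, step: int = WINDOW_STEP
) -> list[Window]:
    """Overlapping windows starting at 1, 1+step, ...; the final partial
    window is kept if it covers at least one bp."""
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    if step > size:
        raise ValueError("step must not exceed window size")
    windows = []
    for chrom, length in chrom_lengths.items():
        if length < 1:
            logger.warning("skipping zero-length chromosome %s", chrom)
            continue
        start = 1
        while start <= length:
            windows.append(Window(chrom=chrom, start=start, end=min(start + size - 1, length)))
            start += step
    return windows


def _pop_site_stats(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n called diploids, alt freq, observed het freq) for one pop."""
    present = calls != MISSING
    n = present.sum(axis=0).astype(float)
    alt = np.where(present, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / (2.0 * n)
        h = np.where(present, calls == 1, False).sum(axis=0) / n
    return n, p, h


def _wc_site_components(
    calls1: np.ndarray, calls2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham per-site variance components (a, a+b+c) for two pops.

    Sites where either population has no called genotypes (or nbar <= 1)
    yield NaN components.
    """
    n1, p1, h1 = _pop_site_stats(calls1)
    n2, p2, h2 = _pop_site_stats(calls2)
    nbar = (n1 + n2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = 2.0 * nbar - (n1**2 + n2**2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 / 2.0 - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    valid = (n1 > 0) & (n2 > 0) & (nbar > 1) & (nc > 0)
    a = np.where(valid, a, np.nan)
    abc = np.where(valid, a + b + c, np.nan)
    return a, abc


def _window_slices(g: GenotypeMatrix, windows: list[Window]) -> list[np.ndarray]:
    """Variant indices falling inside each window."""
    idx_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in g.variants.groupby("chrom", sort=False):
        idx_by_chrom[chrom] = (sub.index.to_numpy(), sub["pos"].to_numpy())
    out = []
    for w in windows:
        if w.chrom not in idx_by_chrom:
            out.append(np.empty(0, dtype=int))
            continue
        idx, pos = idx_by_chrom[w.chrom]
        lo = np.searchsorted(pos, w.start, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        out.append(idx[lo:hi])
    return out


def window_fst(
    g: GenotypeMatrix,
    pop1: list[str],
    pop2: list[str],
    windows: list[Window],
) -> np.ndarray:
    """Weighted windowed W-C Fst; also sets ``fst`` and ``n_snps`` on windows."""
    if not pop1 or not pop2:
        raise ValueError("both populations must be nonempty")
    calls1 = g.calls[g.sample_indices(pop1), :]
    calls2 = g.calls[g.sample_indices(pop2), :]
    a, abc = _wc_site_components(calls1, calls2)
    slices = _window_slices(g, windows)
    out = np.full(len(windows), np.nan)
    for k, (w, sl) in enumerate(zip(windows, slices)):
        w.n_snps = len(sl)
        if len(sl) == 0:
            continue
        num = np.nansum(a[sl])
        den = np.nansum(abc[sl])
        if den != 0 and np.any(~np.isnan(abc[sl])):
            out[k] = num / den
            w.fst = out[k]
    return out


def site_pi(calls: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity: c_ref * c_alt / C(n_chrom, 2)."""
    present = calls != MISSING
    n_chrom = 2.0 * present.sum(axis=0)
    alt = np.where(present, calls, 0).sum(axis=0)
    ref = n_chrom - alt
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = (ref * alt) / (n_chrom * (n_chrom - 1) / 2.0)
    return np.where(n_chrom >= 2, pi, 0.0)


def window_pi(
    g: GenotypeMatrix,
    pop: list[str],
    windows: list[Window],
    label: str | None = None,
) -> np.ndarray:
    """Per-bp windowed theta-pi for one population; sets ``pi[label]``."""
    if not pop:
        raise ValueError("population must be nonempty")
    calls = g.calls[g.sample_indices(pop), :]
    pi = site_pi(calls)
    slices = _window_slices(g, windows)
    out = np.zeros(len(windows))
    for k, (w, sl) in enumerate(zip(windows, slices)):
        out[k] = pi[sl].sum() / w.length
        if label is not None:
            w.pi[label] = out[k]
    return out


def fst_bins(windows: list[Window]) -> tuple[float, float, float]:
    """Fractions of defined-Fst windows in (<0.05, 0.05-0.15, >0.15)."""
    vals = np.array([w.fst for w in windows])
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("no window has a defined Fst")
    lo = np.mean(vals < 0.05)
    hi = np.mean(vals > 0.15)
    return float(lo), float(1.0 - lo - hi), float(hi)


def joint_select(
    windows: list[Window],
    focal_pop: str,
    quantile: float = 0.95,
    pi_mode: str = "ratio",
    min_snps: int = 5,
) -> SweepResult:
    """Windows in the top ``quantile`` of both Fst and the diversity statistic.

    In ratio mode the statistic is log2(pi_other / pi_focal), so depleted
    diversity in the focal population ranks high; in raw mode windows are
    ranked by low focal-population theta-pi directly.  Percentiles are pooled
    genome-wide over windows with at least ``min_snps`` SNPs and defined Fst.
    """
    if pi_mode not in ("ratio", "raw"):
        raise ValueError(f"unknown pi_mode {pi_mode!r}")
    eligible = [
        w
        for w in windows
        if w.n_snps >= min_snps and not np.isnan(w.fst) and focal_pop in w.pi
    ]
    if len(eligible) < 20:
        raise ValueError("need at least 20 windows with defined statistics")

    pops = set().union(*(w.pi.keys() for w in eligible))
    others = sorted(pops - {focal_pop})
    if pi_mode == "ratio":
        if len(others) != 1:
            raise ValueError("ratio mode needs exactly two populations with pi")
        other = others[0]
        all_pi = np.array([w.pi[p] for w in eligible for p in (focal_pop, other)])
        nonzero = all_pi[all_pi > 0]
        if len(nonzero) == 0:
            raise ValueError("all windowed pi values are zero")
        eps = nonzero.min() * 0.01
        n_zero = int((all_pi == 0).sum())
        if n_zero:
            logger.info("pseudocount %g applied to %d zero-pi windows", eps, n_zero)
        for w in eligible:
            pf = w.pi[focal_pop] or eps
            po = w.pi[other] or eps
            w.statistic = np.log2(po / pf)
    else:
        for w in eligible:
            w.statistic = -w.pi[focal_pop]

    fst_vals = np.array([w.fst for w in eligible])
    stat_vals = np.array([w.statistic for w in eligible])
    fst_thr = float(np.percentile(fst_vals, 100 * quantile))
    stat_thr = float(np.percentile(stat_vals, 100 * quantile))
    if quantile >= 1.0:
        # top 0%: select nothing
        selected = []
    else:
        selected = [
            w for w in eligible if w.fst >= fst_thr and w.statistic >= stat_thr
        ]
    for w in selected:
        w.selected_for = focal_pop
    return SweepResult(
        windows=windows,
        fst_threshold=fst_thr,
        stat_threshold=stat_thr,
        selected=selected,
    )


def windows_to_genes(
    selected: list[Window], models: list[GeneModel]
) -> tuple[dict[int, list[str]], list[str]]:
    """Genes whose transcript span overlaps each selected window by >= 1 bp.

    Returns (per-window gene lists keyed by window index, deduplicated
    genome-wide union).
    """
    per_window: dict[int, list[str]] = {}
    union: list[str] = []
    seen = set()
    for k, w in enumerate(selected):
        genes = []
        for m in models:
            if m.chrom == w.chrom and m.start <= w.end and m.end >= w.start:
                if m.gene_id not in genes:
                    genes.append(m.gene_id)
        per_window[k] = genes
        for gid in genes:
            if gid not in seen:
                seen.add(gid)
                union.append(gid)
    return per_window, union


def windows_frame(windows: list[Window]) -> pd.DataFrame:
    """Per-window stats as a tidy frame (chrom, start, end, n_snps, fst,
    pi_<pop>..., statistic, selected_for)."""
    pops = sorted(set().union(*(w.pi.keys() for w in windows)) if windows else set())
    rows = []
    for w in windows:
        row = dict(
            chrom=w.chrom,
            start=w.start,
            end=w.end,
            n_snps=w.n_snps,
            fst=w.fst,
            statistic=w.statistic,
            selected_for=w.selected_for,
        )
        for p in pops:
            row[f"pi_{p}"] = w.pi.get(p, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
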