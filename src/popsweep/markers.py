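"""Per-locus marker statistics and genotype-phenotype association.

Marker statistics follow the usual biallelic definitions: PIC, homozygosity
(sum of squared allele frequencies), expected heterozygosity, effective
allele number and the Hardy-Weinberg Pearson chi-square without continuity
correction.  The association analysis is a one-way fixed-effect model on
genotype class with LSD and Dunnett-T3 pairwise comparisons and compact
letter display.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class MarkerStats:
    locus: str
    p: float  # first-allele frequency
    q: float
    genotype_counts: tuple[int, int, int] | None  # (AA, Aa, aa)
    genotype_freqs: tuple[float, float, float] | None
    chi_square: float | None  # HWE, df=1; None without counts
    pic: float
    homozygosity: float
    heterozygosity: float
    effective_alleles: float


def _freq_stats(freqs: np.ndarray) -> tuple[float, float, float, float]:
    """(PIC, Ho, He, Ne) from allele frequencies (general k-allele formula)."""
    freqs = np.asarray(freqs, dtype=float)
    ho = float(np.sum(freqs**2))
    he = 1.0 - ho
    # PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2
    cross = 0.0
    for i in range(len(freqs)):
        for j in range(i + 1, len(freqs)):
            cross += 2.0 * freqs[i] ** 2 * freqs[j] ** 2
    pic = he - cross
    ne = 1.0 / ho if ho > 0 else float("inf")
    return pic, ho, he, ne


def marker_stats(
    counts: tuple[int, int, int], locus: str = "locus"
) -> MarkerStats:
    """Marker statistics from genotype counts (n_AA, n_Aa, n_aa).

    The HWE chi-square compares observed genotype counts to n*p^2, 2npq,
    n*q^2 (no continuity correction, df = 1); it is 0 for a monomorphic
    locus.
    """
    n_aa_, n_ab, n_bb = counts
    n = n_aa_ + n_ab + n_bb
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_aa_ + n_ab) / (2.0 * n)
    q = 1.0 - p
    pic, ho, he, ne = _freq_stats(np.array([p, q]))
    if p == 0.0 or q == 0.0:
        chi2 = 0.0
    else:
        expected = np.array([n * p**2, 2 * n * p * q, n * q**2])
        observed = np.array([n_aa_, n_ab, n_bb], dtype=float)
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return MarkerStats(
        locus=locus,
        p=p,
        q=q,
        genotype_counts=counts,
        genotype_freqs=(n_aa_ / n, n_ab / n, n_bb / n),
        chi_square=chi2,
        pic=pic,
        homozygosity=ho,
        heterozygosity=he,
        effective_alleles=ne,
    )


def marker_stats_from_freqs(p: float, locus: str = "locus") -> MarkerStats:
    """Marker statistics when only allele frequencies are known (no HWE test)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency outside [0, 1]")
    q = 1.0 - p
    pic, ho, he, ne = _freq_stats(np.array([p, q]))
    return MarkerStats(
        locus=locus,
        p=p,
        q=q,
        genotype_counts=None,
        genotype_freqs=None,
        chi_square=None,
        pic=pic,
        homozygosity=ho,
        heterozygosity=he,
        effective_alleles=ne,
    )


def leg_length(height: float, chest_depth: float) -> float:
    """Leg length in cm: body height minus chest depth."""
    if height <= 0 or chest_depth <= 0:
        raise ValueError("height and chest depth must be positive")
    value = height - chest_depth
    if value < 0:
        warnings.warn(f"negative leg length {value:.2f} cm", stacklevel=2)
    return value


@dataclass
class AssociationTable:
    groups: pd.DataFrame  # genotype, n, mean, sd, letters
    pairwise: pd.DataFrame  # genotype_a, genotype_b, lsd_p, t3_p
    anova_f: float
    anova_p: float


def glm_association(
    values: np.ndarray,
    genotypes: np.ndarray,
    alpha: float = 0.05,
    dispersion: str = "sd",
) -> AssociationTable:
    """One-way fixed-effect analysis of a trait on genotype class.

    Pairwise comparisons use LSD (pooled-variance t, df = N - k) and
    Dunnett's T3 (Welch t with a Studentized-maximum-modulus correction over
    the number of comparisons).  Significance letters at ``alpha`` follow the
    compact-letter-display convention, alphabetical by ascending mean.
    """
    values = np.asarray(values, dtype=float)
    genotypes = np.asarray(genotypes)
    levels = sorted(set(genotypes))
    groups = {lv: values[genotypes == lv] for lv in levels}
    sizes = {lv: len(v) for lv, v in groups.items()}
    usable = [lv for lv in levels if sizes[lv] >= 2]
    if len(usable) < 2:
        raise ValueError("need >= 2 genotype classes with >= 2 observations")
    singletons = [lv for lv in levels if sizes[lv] == 1]
    if singletons:
        warnings.warn(
            f"classes with n=1 excluded from Dunnett T3: {singletons}",
            stacklevel=2,
        )

    f_stat, f_p = stats.f_oneway(*(groups[lv] for lv in levels if sizes[lv] >= 1))

    # pooled within-class variance for LSD
    N = sum(sizes.values())
    k = len(levels)
    ss_within = sum(np.sum((groups[lv] - groups[lv].mean()) ** 2) for lv in levels)
    df_within = N - k
    mse = ss_within / df_within

    pairs = list(itertools.combinations(levels, 2))
    r = len(pairs)
    rows = []
    for a, b in pairs:
        va, vb = groups[a], groups[b]
        na, nb = sizes[a], sizes[b]
        diff = va.mean() - vb.mean()
        # LSD: pooled-variance t
        se_lsd = np.sqrt(mse * (1.0 / na + 1.0 / nb))
        if se_lsd == 0:
            lsd_p = 1.0
        else:
            t_lsd = diff / se_lsd
            lsd_p = float(2.0 * stats.t.sf(abs(t_lsd), df_within))
        # Dunnett T3: Welch t with SMM correction (independent-max form)
        if na >= 2 and nb >= 2:
            se2 = va.var(ddof=1) / na + vb.var(ddof=1) / nb
            if se2 == 0:
                t3_p = 1.0
            else:
                t_w = diff / np.sqrt(se2)
                df_w = se2**2 / (
                    (va.var(ddof=1) / na) ** 2 / (na - 1)
                    + (vb.var(ddof=1) / nb) ** 2 / (nb - 1)
                )
                p_single = 2.0 * stats.t.sf(abs(t_w), df_w)
                t3_p = float(1.0 - (1.0 - p_single) ** r) if p_single < 1 else 1.0
        else:
            t3_p = np.nan
        rows.append((a, b, diff, lsd_p, t3_p))
    pairwise = pd.DataFrame(
        rows, columns=["genotype_a", "genotype_b", "diff", "lsd_p", "t3_p"]
    )

    letters = _letter_display(levels, groups, pairwise, alpha)
    disp = {
        lv: (
            groups[lv].std(ddof=1) if dispersion == "sd"
            else groups[lv].std(ddof=1) / np.sqrt(sizes[lv])
        )
        if sizes[lv] >= 2
        else np.nan
        for lv in levels
    }
    gtable = pd.DataFrame(
        dict(
            genotype=levels,
            n=[sizes[lv] for lv in levels],
            mean=[groups[lv].mean() for lv in levels],
            dispersion=[disp[lv] for lv in levels],
            letters=[letters[lv] for lv in levels],
        )
    )
    return AssociationTable(
        groups=gtable, pairwise=pairwise, anova_f=float(f_stat), anova_p=float(f_p)
    )


def _letter_display(
    levels: list,
    groups: dict,
    pairwise: pd.DataFrame,
    alpha: float,
) -> dict:
    """Greedy interval clique cover over the non-significance graph (LSD p),
    letters assigned alphabetically by ascending group mean."""
    order = sorted(levels, key=lambda lv: groups[lv].mean())
    sig = {}
    for row in pairwise.itertuples(index=False):
        sig[frozenset((row.genotype_a, row.genotype_b))] = row.lsd_p < alpha

    # maximal non-significant intervals in mean order; j(i) is non-decreasing,
    # so an interval is maximal iff its right end advances
    cliques: list[list] = []
    prev_j = -1
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and not any(
            sig.get(frozenset((order[x], order[j + 1])), False)
            for x in range(i, j + 1)
        ):
            j += 1
        if j > prev_j or i == 0:
            cliques.append(order[i : j + 1])
            prev_j = j

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lv: "" for lv in levels}
    for c_idx, clique in enumerate(cliques):
        for lv in clique:
            letters[lv] += alphabet[c_idx % len(alphabet)]
    return letters


def stats_frame(stats_list: list[MarkerStats], ndigits: int = 2) -> pd.DataFrame:
    """Marker statistics as a table rounded for reporting."""
    rows = []
    for s in stats_list:
        rows.append(
            dict(
                locus=s.locus,
                p=round(s.p, ndigits),
                q=round(s.q, ndigits),
                chi_square=None if s.chi_square is None else round(s.chi_square, ndigits),
                pic=round(s.pic, ndigits),
                homozygosity=round(s.homozygosity, ndigits),
                heterozygosity=round(s.heterozygosity, ndigits),
                effective_alleles=round(s.effective_alleles, ndigits),
            )
        )
    return pd.DataFrame(rows)
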