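"""Hypergeometric overrepresentation of gene lists in user-supplied term sets.

Terms come from GMT-style flat files (term id, name, member genes); the test
is the exact upper tail P(X >= k) of the hypergeometric distribution.  Raw
p-values are primary (with an optional Benjamini-Hochberg column) since the
screening rule downstream is raw p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class TermSet:
    term_id: str
    name: str
    genes: set[str]


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail p-value P(X >= k) for X ~ Hypergeometric(N, n, K).

    k: selected genes in the term; K: selected genes; n: term size;
    N: universe size.
    """
    if K > N or n > N or not (0 <= k <= min(K, n) <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, n, K))


def enrich_table(
    selected: list[str],
    term_sets: list[TermSet],
    universe: list[str],
    alpha: float = 0.05,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-term enrichment of ``selected`` genes against ``universe``.

    One row per term with at least one selected member; columns
    (term_id, name, k, K, n, N, p, significant) plus ``p_bh`` when
    requested.  Raises when selected genes fall outside the universe.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    uni = set(universe)
    sel = set(selected)
    stray = sorted(sel - uni)
    if stray:
        raise ValueError(f"selected genes not in universe: {stray}")
    N = len(uni)
    K = len(sel)
    rows = []
    for t in term_sets:
        members = t.genes & uni
        hits = members & sel
        if not hits:
            continue
        p = hypergeom_test(len(hits), K, len(members), N)
        rows.append(
            dict(
                term_id=t.term_id,
                name=t.name,
                k=len(hits),
                K=K,
                n=len(members),
                N=N,
                p=p,
            )
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "name", "k", "K", "n", "N", "p"]
    )
    if bh and len(df):
        df["p_bh"] = _benjamini_hochberg(df["p"].to_numpy())
        logger.info("BH-adjusted p-values reported alongside raw p")
    df["significant"] = df["p"] < alpha if len(df) else pd.Series(dtype=bool)
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def _benjamini_hochberg(p):
    import numpy as np

    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def read_gmt(path: str) -> list[TermSet]:
    """Read a GMT flat file: term_id <TAB> name <TAB> gene1 <TAB> gene2 ..."""
    terms = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms.append(TermSet(term_id=parts[0], name=parts[1], genes=set(parts[2:])))
    return terms


def write_gmt(terms: list[TermSet], path: str) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.name] + sorted(t.genes)) + "\n")
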