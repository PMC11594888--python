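"""Population structure: genotype p-distance, neighbor-joining, PCA.

The pairwise genotype distance is 0 for identical homozygotes, 1 for opposite
homozygotes and 0.5 whenever a heterozygote is involved (including het-het
pairs).  Pairwise deletion handles missing calls in distances; PCA uses
mean-imputation so the standardized matrix stays dense.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .variants import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    n_loci: np.ndarray  # loci used per pair (pairwise deletion)

    def validate(self) -> None:
        v = self.values
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("distances must lie in [0, 1]")


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    coordinates: np.ndarray  # samples x components
    variance_explained: np.ndarray


def pair_distance(geno_i: int, geno_j: int) -> float:
    """Distance between two genotype calls: 0 same homozygote, 0.5 when a
    heterozygote is involved, 1 for opposite homozygotes."""
    if geno_i == MISSING or geno_j == MISSING:
        raise ValueError("missing calls must be excluded upstream")
    if geno_i == 1 or geno_j == 1:
        return 0.5
    return abs(geno_i - geno_j) / 2.0


def p_distance_matrix(g: GenotypeMatrix) -> DistanceMatrix:
    """Mean pairwise genotype distance over loci non-missing in both samples."""
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    calls = g.calls.astype(float)
    present = g.calls != MISSING
    n = g.n_samples
    values = np.zeros((n, n))
    n_loci = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            L = int(both.sum())
            if L == 0:
                raise ValueError(
                    f"samples {g.samples[i]!r} and {g.samples[j]!r} share no loci"
                )
            gi, gj = calls[i, both], calls[j, both]
            het = (gi == 1) | (gj == 1)
            d = np.where(het, 0.5, np.abs(gi - gj) / 2.0)
            values[i, j] = values[j, i] = d.mean()
            n_loci[i, j] = n_loci[j, i] = L
    dm = DistanceMatrix(list(g.samples), values, n_loci)
    dm.validate()
    return dm


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Rooted representation of the (unrooted) NJ tree; the root is the final
    trifurcation (or bifurcation for <4 taxa)."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _bl in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, with_support: bool = False) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf():
            return self.name
        parts = ",".join(
            f"{c._newick(with_support)}:{bl:.6g}" for c, bl in self.children
        )
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:.3g}"
        return f"({parts}){label}"

    def bipartitions(self) -> dict[frozenset, "TreeNode"]:
        """Internal-edge bipartitions, keyed by the leaf set below the edge."""
        all_leaves = frozenset(self.leaves())
        out: dict[frozenset, TreeNode] = {}

        def visit(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for child, _bl in node.children:
                below |= visit(child)
            if node is not self and 1 < len(below) < len(all_leaves) - 1:
                out[_canonical(below, all_leaves)] = node
            return below

        visit(self)
        return out


def _canonical(side: frozenset, universe: frozenset) -> frozenset:
    """Normalize a bipartition to the side not containing the smallest leaf."""
    anchor = min(universe)
    return universe - side if anchor in side else side


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Negative branch lengths are clamped to 0 with the deficit moved to the
    sibling branch (logged).  Ties in the Q matrix resolve to the lowest
    (row, column) pair.
    """
    n = len(d.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples for a tree")
    if not np.allclose(d.values, d.values.T):
        raise ValueError("distance matrix is not symmetric")

    nodes: list[TreeNode] = [TreeNode(name=s) for s in d.sample_ids]
    D = d.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) among minima for determinism
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        bi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = D[i, j] - bi
        bi, bj = _clamp_pair(bi, bj)
        new = TreeNode(children=[(nodes[i], bi), (nodes[j], bj)])
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.empty((m - 1, m - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = D_new[:-1, -1] = du[keep]
        D_new[-1, -1] = 0.0
        D = D_new
        nodes = [nodes[k] for k in keep] + [new]

    # closed-form trifurcation for the last three nodes
    d12, d13, d23 = D[0, 1], D[0, 2], D[1, 2]
    b1 = max(0.0, (d12 + d13 - d23) / 2.0)
    b2 = max(0.0, (d12 + d23 - d13) / 2.0)
    b3 = max(0.0, (d13 + d23 - d12) / 2.0)
    return TreeNode(children=[(nodes[0], b1), (nodes[1], b2), (nodes[2], b3)])


def _clamp_pair(bi: float, bj: float) -> tuple[float, float]:
    if bi < 0:
        logger.info("clamped negative branch length %g (moved to sibling)", bi)
        bj += bi
        bi = 0.0
    if bj < 0:
        logger.info("clamped negative branch length %g (moved to sibling)", bj)
        bi += bj
        bj = 0.0
    return bi, max(bj, 0.0)


def bootstrap_support(
    g: GenotypeMatrix, n_boot: int = 1000, seed: int | None = None
) -> dict[frozenset, float]:
    """Bipartition support of the full-data NJ tree under variant-column
    resampling with replacement."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    full_tree = nj_tree(p_distance_matrix(g))
    parts = full_tree.bipartitions()
    hits = {p: 0 for p in parts}
    for _ in range(n_boot):
        cols = rng.integers(0, g.n_variants, size=g.n_variants)
        rep = GenotypeMatrix(
            samples=list(g.samples),
            variants=g.variants.iloc[cols].reset_index(drop=True),
            calls=g.calls[:, cols],
            depth=g.depth[:, cols],
        )
        rep_parts = nj_tree(p_distance_matrix(rep)).bipartitions()
        for p in hits:
            if p in rep_parts:
                hits[p] += 1
    support = {p: hits[p] / n_boot for p in hits}
    for p, node in parts.items():
        node.support = support[p]
    return support


# ---------------------------------------------------------------------------
# PCA on standardized genotypes
# ---------------------------------------------------------------------------


def standardize_genotypes(g: GenotypeMatrix) -> np.ndarray:
    """Per-variant standardization of the 0/1/2 dosage matrix.

    Column k is transformed to (d - E(d)) / sqrt(2 * (E(d)/2) * (1 - E(d)/2))
    with E over non-missing calls; missing calls are imputed to the mean
    (0 after centering).  Monomorphic columns are dropped.
    """
    calls = g.calls.astype(float)
    present = g.calls != MISSING
    n_called = present.sum(axis=0)
    if np.any(n_called == 0):
        raise ValueError("variant with no called genotypes")
    mean = np.where(present, calls, 0.0).sum(axis=0) / n_called
    # monomorphic: no variation among called genotypes
    var = (
        np.where(present, (calls - mean[None, :]) ** 2, 0.0).sum(axis=0) / n_called
    )
    p_half = mean / 2.0
    scale = np.sqrt(2.0 * p_half * (1.0 - p_half))
    poly = (var > 0) & (scale > 0)
    if not np.any(poly):
        raise ValueError("all variants are monomorphic")
    M = np.where(present, calls, mean[None, :]) - mean[None, :]
    M = M[:, poly] / scale[None, poly]
    return M


def pca(M: np.ndarray, n_components: int = 3) -> PCAResult:
    """Eigendecomposition of the sample covariance X = M M^T / S.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue); components come
    out in descending eigenvalue order.
    """
    n, S = M.shape
    if n < 3:
        logger.warning("fewer than 3 samples; returning %d components", n)
        n_components = min(n_components, n)
    X = (M @ M.T) / S
    eigval, eigvec = np.linalg.eigh(X)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    k = min(n_components, n)
    coords = eigvec[:, :k] * np.sqrt(np.clip(eigval[:k], 0.0, None))[None, :]
    total = eigval.sum()
    varfrac = eigval[:k] / total if total > 0 else np.zeros(k)
    return PCAResult(eigenvalues=eigval, coordinates=coords, variance_explained=varfrac)
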