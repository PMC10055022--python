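"""Simple-matching genetic similarity, homozygosity, UPGMA and PCoA.

Genetic similarity (GS) between two individuals is Rohlf's simple matching
coefficient on allele-presence-coded genotypes: each biallelic locus expands
to two binary variables (A present, B present), so a genotype pair scores 1
when identical, 0.5 when homozygote meets heterozygote and 0 for opposite
homozygotes, averaged over loci. Clustering and ordination operate on the
complement distance D = 1 - GS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist, squareform

from .genotype import MISSING, GenotypeDataset


@dataclass
class SimilarityMatrix:
    sample_ids: list[str]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(m, m.T):
            raise ValueError("similarity matrix must be symmetric")
        if m.size and (m.min() < -1e-12 or m.max() > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0,1]")
        self.matrix = m

    def value(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.matrix[i, j])

    def to_distance(self) -> np.ndarray:
        return 1.0 - self.matrix

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)


def simple_matching_gs(ds: GenotypeDataset) -> SimilarityMatrix:
    """Pairwise Rohlf simple-matching similarity over all loci."""
    if ds.n_loci == 0:
        raise ValueError("dataset has no loci")
    if (ds.calls == MISSING).any():
        raise ValueError("dataset contains missing calls; run filter_complete_loci first")
    a = ds.allele_count_matrix().astype(float)
    # |x-y| on allele-A copies is 0 / 1 / 2 for identical / hom-het / opposite
    # hom, so GS = 1 - cityblock / (2L) reproduces the 1 / 0.5 / 0 scoring.
    dist = cdist(a, a, metric="cityblock") / (2 * ds.n_loci)
    gs = 1.0 - dist
    np.fill_diagonal(gs, 1.0)
    return SimilarityMatrix(list(ds.samples), gs)


def observed_homozygosity(ds: GenotypeDataset) -> pd.Series:
    """Fraction of loci at which each individual is homozygous (code 0 or 1)."""
    if ds.n_loci == 0:
        raise ValueError("dataset has no loci")
    hom = np.isin(ds.calls, (0, 1)).mean(axis=1)
    return pd.Series(hom, index=ds.samples, name="observed_homozygosity")


@dataclass
class GroupSimilaritySummary:
    """Mean GS within and among populations with standard errors.

    ``within`` has one row per population (n(n-1)/2 pairs, self-pairs
    excluded); ``among`` one row per unordered population pair (n1*n2
    pairs); ``homozygosity`` the per-population mean observed homozygosity.
    Populations of size 1 have undefined within-GS (NaN, flagged).
    """

    within: pd.DataFrame
    among: pd.DataFrame
    homozygosity: pd.DataFrame


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return math.nan, math.nan
    se = float(np.std(values, ddof=1) / math.sqrt(values.size)) if values.size > 1 else 0.0
    return float(values.mean()), se


def group_similarity_summary(
    sim: SimilarityMatrix, hom: pd.Series, populations: dict[str, str]
) -> GroupSimilaritySummary:
    ids = sim.sample_ids
    pops_ordered: dict[str, list[int]] = {}
    for i, s in enumerate(ids):
        pops_ordered.setdefault(populations[s], []).append(i)

    within_rows = []
    for pop, idx in pops_ordered.items():
        if len(idx) < 2:
            within_rows.append(
                {"population": pop, "mean_gs": math.nan, "se": math.nan,
                 "n_pairs": 0, "undefined": True}
            )
            continue
        sub = sim.matrix[np.ix_(idx, idx)]
        vals = sub[np.triu_indices(len(idx), k=1)]
        mean, se = _mean_se(vals)
        within_rows.append(
            {"population": pop, "mean_gs": mean, "se": se,
             "n_pairs": vals.size, "undefined": False}
        )

    among_rows = []
    pop_names = list(pops_ordered)
    for i in range(len(pop_names)):
        for j in range(i + 1, len(pop_names)):
            a, b = pop_names[i], pop_names[j]
            vals = sim.matrix[np.ix_(pops_ordered[a], pops_ordered[b])].ravel()
            mean, se = _mean_se(vals)
            among_rows.append(
                {"pop_a": a, "pop_b": b, "mean_gs": mean, "se": se, "n_pairs": vals.size}
            )

    hom_rows = []
    for pop, idx in pops_ordered.items():
        vals = hom.iloc[idx].to_numpy()
        mean, se = _mean_se(vals)
        hom_rows.append({"population": pop, "mean_hom": mean, "se": se, "n": vals.size})

    return GroupSimilaritySummary(
        within=pd.DataFrame(within_rows).set_index("population"),
        among=pd.DataFrame(among_rows),
        homozygosity=pd.DataFrame(hom_rows).set_index("population"),
    )


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class UpgmaTree:
    """Rooted ultrametric tree from average-linkage clustering.

    ``linkage`` is a SciPy linkage matrix on D = 1 - GS; node heights are
    merge distance / 2 so leaf-to-root path lengths are equal.
    """

    leaf_names: list[str]
    linkage: np.ndarray = field(repr=False)

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage)

        def build(node, parent_height: float) -> str:
            height = node.dist / 2.0
            length = parent_height - height
            if node.is_leaf():
                return f"{self.leaf_names[node.id]}:{parent_height:.10g}"
            left = build(node.left, height)
            right = build(node.right, height)
            return f"({left},{right}):{length:.10g}"

        height = root.dist / 2.0
        left = build(root.left, height)
        right = build(root.right, height)
        return f"({left},{right});"

    def leaf_heights(self) -> np.ndarray:
        """Root-to-leaf path length for every leaf (ultrametricity check)."""
        root = hierarchy.to_tree(self.linkage)
        heights = np.zeros(len(self.leaf_names))

        def walk(node, acc: float) -> None:
            h = node.dist / 2.0
            if node.is_leaf():
                heights[node.id] = acc + h  # acc is distance from root to node top
                return
            for child in (node.left, node.right):
                walk(child, acc + (h - child.dist / 2.0))

        walk(root, 0.0)
        return heights

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.leaf_names, (int(c) for c in labels)))

    @property
    def root_height(self) -> float:
        return float(self.linkage[-1, 2] / 2.0)


def upgma(sim: SimilarityMatrix) -> UpgmaTree:
    """Average-linkage (UPGMA) dendrogram on the distance complement of GS."""
    if len(sim.sample_ids) < 2:
        raise ValueError("UPGMA requires at least 2 samples")
    d = sim.to_distance()
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return UpgmaTree(list(sim.sample_ids), z)


def upgma_from_distance(sample_ids, distance: np.ndarray) -> UpgmaTree:
    """UPGMA directly from a distance matrix (same topology as via GS)."""
    distance = np.asarray(distance, dtype=float)
    if not np.allclose(distance, distance.T):
        raise ValueError("distance matrix must be symmetric")
    z = hierarchy.linkage(squareform(distance, checks=False), method="average")
    return UpgmaTree(list(sample_ids), z)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix.

    ``coordinates`` holds one row per sample on the retained axes (ordered
    by decreasing eigenvalue, each axis oriented so its largest-magnitude
    loading is positive); ``pct_variance`` divides each positive eigenvalue
    by the sum of positive eigenvalues. Negative eigenvalues (non-Euclidean
    distances) are excluded from that denominator and reported separately.
    """

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    negative_eigenvalue_sum: float
    degenerate: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"axis_{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(sim: SimilarityMatrix, n_axes: int = 2, sqrt_distance: bool = False) -> PcoaResult:
    """Metric embedding of D = 1 - GS via Gower double-centering.

    With ``sqrt_distance`` the embedding uses sqrt(1 - GS) instead, which
    is Euclidean for any simple-matching similarity.
    """
    d = sim.to_distance()
    if sqrt_distance:
        d = np.sqrt(d)
    return pcoa_from_distance(sim.sample_ids, d, n_axes=n_axes)


def pcoa_from_distance(sample_ids, d: np.ndarray, n_axes: int = 2) -> PcoaResult:
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-10 * abs(eigval).max()) if n else 1e-10
    positive = eigval > tol
    degenerate = not positive.any()
    pos_sum = eigval[positive].sum() if not degenerate else math.nan
    pct = 100 * eigval[positive] / pos_sum if not degenerate else np.array([])
    neg_sum = float(eigval[eigval < -tol].sum())

    rank = int(positive.sum())
    keep = min(n_axes, rank)
    coords = eigvec[:, :keep] * np.sqrt(eigval[:keep]) if keep else np.zeros((n, 0))
    # deterministic sign: largest-magnitude loading positive on each axis
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return PcoaResult(
        sample_ids=list(sample_ids),
        coordinates=coords,
        eigenvalues=eigval,
        pct_variance=pct,
        negative_eigenvalue_sum=neg_sum,
        degenerate=degenerate,
    )
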