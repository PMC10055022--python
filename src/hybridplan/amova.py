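"""Distance-based analysis of molecular variance (AMOVA) with permutation test.

Variation among inter-individual squared genotypic distances is partitioned
into among- and within-population components. The distance is the codominant
genotypic squared distance: per locus, 0 between identical genotypes, 1
between a homozygote and a heterozygote, and 4 between opposite homozygotes
(half the squared Euclidean distance between allele-count vectors), summed
over loci. PhiPT = var_among / var_total is tested by permuting whole
individuals across population labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .genotype import MISSING, GenotypeDataset


@dataclass
class SquaredDistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.sample_ids),) * 2:
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        self.matrix = m


def squared_distance_matrix(ds: GenotypeDataset) -> SquaredDistanceMatrix:
    """Pairwise codominant genotypic squared distances, summed over loci."""
    if (ds.calls == MISSING).any():
        raise ValueError("dataset contains missing calls; run filter_complete_loci first")
    a = ds.allele_count_matrix().astype(float)
    # per locus (x-y)^2 on allele-A copy number equals the 0/1/4 scoring
    d2 = cdist(a, a, metric="sqeuclidean")
    return SquaredDistanceMatrix(list(ds.samples), d2)


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    df_total: int
    ss_among: float
    ss_within: float
    ss_total: float
    ms_among: float
    ms_within: float
    n0: float
    var_among: float
    var_within: float
    var_total: float
    pct_among: float
    pct_within: float
    phi_pt: float
    p_value: float | None = None
    n_permutations: int | None = None
    floored: bool = False  # negative among-component clamped to zero
    degenerate: bool = False  # zero total variance


def _estimate_components(
    ss_among: float,
    ss_within: float,
    df_among: int,
    df_within: int,
    pop_sizes,
) -> AmovaResult:
    sizes = np.asarray(pop_sizes, dtype=float)
    n_total = float(sizes.sum())
    k = len(sizes)
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n_total - float((sizes**2).sum()) / n_total) / (k - 1)
    var_within = ms_within
    var_among = (ms_among - ms_within) / n0
    floored = var_among < 0
    if floored:
        var_among = 0.0
    var_total = var_among + var_within
    degenerate = var_total == 0
    pct_among = 100 * var_among / var_total if var_total > 0 else 0.0
    pct_within = 100 * var_within / var_total if var_total > 0 else 0.0
    phi_pt = var_among / var_total if var_total > 0 else 0.0
    return AmovaResult(
        df_among=df_among,
        df_within=df_within,
        df_total=df_among + df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        ss_total=ss_among + ss_within,
        ms_among=ms_among,
        ms_within=ms_within,
        n0=n0,
        var_among=var_among,
        var_within=var_within,
        var_total=var_total,
        pct_among=pct_among,
        pct_within=pct_within,
        phi_pt=phi_pt,
        floored=floored,
        degenerate=degenerate,
    )


def amova_from_summaries(
    ss_among: float,
    ss_within: float,
    df_among: int,
    df_within: int,
    pop_sizes,
) -> AmovaResult:
    """Variance components from already-computed sums of squares.

    Entry point for reconstructing published AMOVA tables: feed the printed
    SS and df together with the population sample sizes. No permutation
    p-value is available on this route.
    """
    sizes = list(pop_sizes)
    k = len(sizes)
    n_total = sum(sizes)
    if df_among != k - 1:
        raise ValueError(f"df_among {df_among} inconsistent with {k} populations")
    if df_within != n_total - k:
        raise ValueError(
            f"df_within {df_within} inconsistent with N={n_total}, k={k}"
        )
    return _estimate_components(ss_among, ss_within, df_among, df_within, sizes)


def _sums_of_squares(d2: np.ndarray, groups: np.ndarray):
    """Total and within-group SS from a squared-distance matrix.

    SS_total = sum_{i<j} d2_ij / N; SS_within sums the analogous term per
    group with its own size in the denominator.
    """
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return ss_total, ss_within


def amova(
    ds: GenotypeDataset,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """Full AMOVA from genotypes: distances, components and permutation test.

    The p-value is (number of permuted PhiPT >= observed + 1) divided by
    (n_permutations + 1), so the smallest reportable value with 999
    permutations is 0.001.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pops = ds.population_labels()
    if len(pops) < 2:
        raise ValueError("AMOVA requires at least 2 populations")
    sizes = [len(ds.samples_in(p)) for p in pops]
    if min(sizes) < 2:
        raise ValueError("every population needs at least 2 samples")
    d2 = squared_distance_matrix(ds).matrix
    pop_of = {p: i for i, p in enumerate(pops)}
    groups = np.array([pop_of[ds.populations[s]] for s in ds.samples])
    n = ds.n_samples
    k = len(pops)
    ss_total, ss_within = _sums_of_squares(d2, groups)
    res = _estimate_components(ss_total - ss_within, ss_within, k - 1, n - k, sizes)

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        p_ss_total, p_ss_within = _sums_of_squares(d2, perm)
        p_res = _estimate_components(
            p_ss_total - p_ss_within, p_ss_within, k - 1, n - k, sizes
        )
        if p_res.phi_pt >= res.phi_pt:
            count_ge += 1
    res.p_value = (count_ge + 1) / (n_permutations + 1)
    res.n_permutations = n_permutations
    return res
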