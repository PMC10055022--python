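"""Simple-matching similarity, homozygosity, UPGMA and PCoA."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from hybridplan import (
    MISSING,
    SimilarityMatrix,
    group_similarity_summary,
    observed_homozygosity,
    pcoa,
    pcoa_from_distance,
    simple_matching_gs,
    upgma,
    upgma_from_distance,
)

from conftest import make_dataset


def _binary_expansion_gs(calls):
    """Oracle: expand each locus to two allele-presence bits and count matches."""
    expand = {0: (1, 0), 1: (0, 1), 2: (1, 1)}
    rows = [[b for g in row for b in expand[g]] for row in calls]
    n = len(rows)
    gs = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        # simple matching on (presence_i == presence_j) with half-credit
        # arises from scoring each locus by shared band pattern
        per_locus = []
        for li in range(0, len(rows[i]), 2):
            a = rows[i][li : li + 2]
            b = rows[j][li : li + 2]
            if a == b:
                per_locus.append(1.0)
            elif (1 in a) and (1 in b) and (a != b) and (a == [1, 1] or b == [1, 1]):
                per_locus.append(0.5)
            else:
                per_locus.append(0.0)
        gs[i, j] = gs[j, i] = float(np.mean(per_locus))
    return gs


class TestSimpleMatching:
    def test_self_similarity_is_one(self):
        ds = make_dataset([[0, 1, 2], [2, 2, 0]])
        gs = simple_matching_gs(ds).matrix
        assert gs[0, 0] == 1.0 and gs[1, 1] == 1.0

    def test_opposite_homozygotes_have_zero_similarity(self):
        ds = make_dataset([[0, 0, 0], [1, 1, 1]])
        assert simple_matching_gs(ds).matrix[0, 1] == 0.0

    def test_half_credit_for_hom_vs_het(self):
        # per-locus scores (1, 0.5, 1) -> 0.8333
        ds = make_dataset([[0, 2, 1], [0, 0, 1]])
        assert simple_matching_gs(ds).matrix[0, 1] == pytest.approx(5 / 6)

    def test_matches_binary_expansion_oracle(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(6, 25)).astype(np.int8)
        ds = make_dataset(calls)
        gs = simple_matching_gs(ds).matrix
        oracle = _binary_expansion_gs(calls.tolist())
        assert np.allclose(gs, oracle, atol=1e-9)

    def test_complement_of_normalised_distance(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(5, 30)).astype(np.int8)
        ds = make_dataset(calls)
        gs = simple_matching_gs(ds).matrix
        # GS = 1 - d/(L) where d is the per-locus 0/0.5/1 distance summed
        d = np.zeros_like(gs)
        for i, j in itertools.combinations(range(5), 2):
            per = [
                0.0 if a == b else (0.5 if 2 in (a, b) else 1.0)
                for a, b in zip(calls[i], calls[j])
            ]
            d[i, j] = d[j, i] = sum(per) / 30
        assert np.allclose(gs, 1 - d, atol=1e-12)

    def test_missing_rejected(self):
        ds = make_dataset([[0], [MISSING]])
        with pytest.raises(ValueError):
            simple_matching_gs(ds)


class TestObservedHomozygosity:
    @pytest.mark.parametrize(
        "row, expected",
        [([0, 1, 0, 1], 1.0), ([2, 2, 0, 1], 0.5), ([0, 1, 2, 0], 0.75)],
    )
    def test_fraction_of_homozygous_loci(self, row, expected):
        ds = make_dataset([row])
        assert observed_homozygosity(ds).iloc[0] == expected


class TestGroupSummary:
    def test_identical_pair_within_gs(self):
        ds = make_dataset([[0, 1], [0, 1]], ["P1", "P1"])
        gss = group_similarity_summary(
            simple_matching_gs(ds), observed_homozygosity(ds), ds.populations
        )
        assert gss.within.loc["P1", "mean_gs"] == 1.0
        assert gss.within.loc["P1", "se"] == 0.0

    def test_opposite_populations_among_gs_zero(self):
        ds = make_dataset([[0, 0], [0, 0], [1, 1], [1, 1]], ["P1", "P1", "P2", "P2"])
        gss = group_similarity_summary(
            simple_matching_gs(ds), observed_homozygosity(ds), ds.populations
        )
        assert gss.among.iloc[0]["mean_gs"] == 0.0
        assert gss.among.iloc[0]["n_pairs"] == 4

    def test_three_sample_mean_is_pair_average(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.integers(0, 3, (3, 20)).astype(np.int8), ["P1"] * 3)
        sim = simple_matching_gs(ds)
        gss = group_similarity_summary(sim, observed_homozygosity(ds), ds.populations)
        pairs = [sim.matrix[i, j] for i, j in itertools.combinations(range(3), 2)]
        assert gss.within.loc["P1", "mean_gs"] == pytest.approx(np.mean(pairs))
        assert gss.within.loc["P1", "n_pairs"] == 3

    def test_singleton_population_flagged_undefined(self):
        ds = make_dataset([[0], [1], [2]], ["P1", "P2", "P2"])
        gss = group_similarity_summary(
            simple_matching_gs(ds), observed_homozygosity(ds), ds.populations
        )
        assert gss.within.loc["P1", "undefined"]
        assert math.isnan(gss.within.loc["P1", "mean_gs"])


def _toy_similarity(dist):
    dist = np.asarray(dist, dtype=float)
    ids = [f"s{i}" for i in range(dist.shape[0])]
    return SimilarityMatrix(ids, 1 - dist)


class TestUpgma:
    def test_two_samples_merge_at_half_distance(self):
        tree = upgma(_toy_similarity([[0, 0.4], [0.4, 0]]))
        assert tree.root_height == pytest.approx(0.2)
        assert tree.to_newick() == "(s0:0.2,s1:0.2);"

    def test_three_sample_hand_clustering(self):
        d = [[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]]
        tree = upgma(_toy_similarity(d))
        assert tree.root_height == pytest.approx(0.25)
        clusters = tree.cut(2)
        assert clusters["s0"] == clusters["s1"] != clusters["s2"]
        newick = tree.to_newick()
        assert "s0:0.05" in newick and "s1:0.05" in newick

    def test_ultrametric_for_random_input(self):
        rng = np.random.default_rng(4)
        x = rng.random((7, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        tree = upgma(_toy_similarity(d / d.max()))
        heights = tree.leaf_heights()
        assert np.allclose(heights, tree.root_height, atol=1e-9)

    def test_similarity_and_distance_routes_agree(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, (6, 40)).astype(np.int8)
        ds = make_dataset(calls)
        sim = simple_matching_gs(ds)
        t1 = upgma(sim)
        t2 = upgma_from_distance(sim.sample_ids, sim.to_distance())
        assert t1.to_newick() == t2.to_newick()

    def test_non_symmetric_input_rejected(self):
        with pytest.raises(ValueError):
            upgma_from_distance(["a", "b"], np.array([[0, 1], [2, 0]]))


class TestPcoa:
    def test_identical_samples_are_degenerate(self):
        res = pcoa(_toy_similarity(np.zeros((4, 4))))
        assert res.degenerate

    def test_collinear_points_give_single_axis(self):
        # D(ab)=1, D(bc)=1, D(ac)=2: squared-distance-compatible line
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa_from_distance(["a", "b", "c"], d)
        assert len(res.pct_variance) == 1
        assert res.pct_variance[0] == pytest.approx(100.0)

    def test_full_rank_distances_are_reproduced(self):
        rng = np.random.default_rng(6)
        x = rng.random((4, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        res = pcoa_from_distance(list("abcd"), d, n_axes=3)
        coords = res.coordinates
        d_hat = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.allclose(d, d_hat, atol=1e-9)

    def test_positive_axis_percentages_sum_to_100(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 3, (8, 30)).astype(np.int8)
        res = pcoa(simple_matching_gs(make_dataset(calls)), n_axes=3)
        assert res.pct_variance.sum() == pytest.approx(100.0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)  # sorted descending

    def test_matches_independent_eigendecomposition(self):
        """Cross-check against scikit-bio's PCoA on the same distances."""
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        from skbio import DistanceMatrix

        rng = np.random.default_rng(8)
        calls = rng.integers(0, 3, (7, 50)).astype(np.int8)
        sim = simple_matching_gs(make_dataset(calls))
        res = pcoa(sim, n_axes=2)
        ref = skbio_ordination.pcoa(DistanceMatrix(sim.to_distance()))
        ref_eig = np.sort(ref.eigvals.to_numpy())[::-1]
        mine = res.eigenvalues[: len(ref_eig)]
        assert np.allclose(mine[:4], ref_eig[:4], atol=1e-8)
        for axis in range(2):
            ref_axis = ref.samples.iloc[:, axis].to_numpy()
            assert np.allclose(
                np.abs(res.coordinates[:, axis]), np.abs(ref_axis), atol=1e-8
            )

    def test_excess_axes_truncated_to_rank(self):
        res = pcoa_from_distance(["a", "b"], np.array([[0, 1.0], [1.0, 0]]), n_axes=5)
        assert res.coordinates.shape == (2, 1)
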