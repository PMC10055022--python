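"""Parental selection and Mendelian progeny-heterozygosity prediction."""

from __future__ import annotations

import numpy as np
import pytest

from hybridplan import (
    MISSING,
    cross_prediction_matrix,
    expected_progeny_het_locus,
    expected_progeny_heterozygosity,
    observed_homozygosity,
    select_parents,
    simple_matching_gs,
    simulate_mendelian_offspring,
    strategy_summary,
    synth_cohort,
    CohortConfig,
)

from conftest import make_dataset


class TestLocusPrediction:
    @pytest.mark.parametrize(
        "g1, g2, expected",
        [
            (0, 0, 0.0),
            (1, 1, 0.0),
            (0, 1, 1.0),
            (1, 0, 1.0),
            (0, 2, 0.5),
            (2, 1, 0.5),
            (2, 2, 0.5),
        ],
    )
    def test_mendelian_expectation_table(self, g1, g2, expected):
        assert expected_progeny_het_locus(g1, g2) == expected

    def test_het_by_het_agrees_with_punnett_enumeration(self):
        # Aa x Aa -> AA, Aa, aA, aa: heterozygote fraction 2/4
        gametes = ["A", "a"]
        offspring = [(m, p) for m in gametes for p in gametes]
        het = sum(1 for m, p in offspring if m != p) / len(offspring)
        assert expected_progeny_het_locus(2, 2) == het

    def test_missing_input_rejected(self):
        with pytest.raises(ValueError):
            expected_progeny_het_locus(MISSING, 0)


class TestCrossPrediction:
    def test_selfing_fully_homozygous_parent_gives_zero(self):
        ds = make_dataset([[0, 1, 0, 1]])
        assert expected_progeny_heterozygosity(ds, "S1", "S1") == 0.0

    def test_selfing_fully_heterozygous_parent_gives_half(self):
        ds = make_dataset([[2, 2, 2]])
        assert expected_progeny_heterozygosity(ds, "S1", "S1") == 0.5

    def test_opposite_homozygotes_give_classic_f1(self):
        ds = make_dataset([[0, 0, 0], [1, 1, 1]])
        assert expected_progeny_heterozygosity(ds, "S1", "S2") == 1.0

    def test_symmetry_and_selfing_identity_on_cohort(self, small_cohort):
        ds, _ = small_cohort
        hom = observed_homozygosity(ds)
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = rng.choice(ds.samples, 2, replace=False)
            assert expected_progeny_heterozygosity(ds, a, b) == pytest.approx(
                expected_progeny_heterozygosity(ds, b, a)
            )
        for s in ds.samples:
            self_he = expected_progeny_heterozygosity(ds, s, s)
            assert self_he == pytest.approx((1 - hom[s]) / 2, abs=1e-12)

    def test_monte_carlo_offspring_agree_with_prediction(self, small_cohort):
        ds, _ = small_cohort
        n = 20000
        rng = np.random.default_rng(1)
        for trial in range(5):
            p1, p2 = rng.choice(ds.samples, 2, replace=False)
            pred = expected_progeny_heterozygosity(ds, p1, p2)
            het_counts = simulate_mendelian_offspring(ds, p1, p2, n, seed=trial)
            observed = het_counts.sum() / (n * ds.n_loci)
            i, j = ds.sample_index(p1), ds.sample_index(p2)
            per_locus = np.array(
                [
                    expected_progeny_het_locus(int(a), int(b))
                    for a, b in zip(ds.calls[i], ds.calls[j])
                ]
            )
            se = np.sqrt((per_locus * (1 - per_locus)).sum() / n) / ds.n_loci
            assert abs(observed - pred) <= 3 * max(se, 1e-9)


class TestSelectParents:
    def _toy(self):
        # 6 highly similar homozygous plants + 2 divergent heterozygous ones
        calls = np.zeros((8, 20), dtype=np.int8)
        calls[1, 0] = 2  # slight variation keeps GS just below 1
        calls[2, 1] = 2
        calls[6] = 2  # low homozygosity, low GS to the block
        calls[7] = 1
        return make_dataset(calls)

    def test_cohesive_high_homozygosity_subset_selected(self):
        ds = self._toy()
        sim = simple_matching_gs(ds)
        hom = observed_homozygosity(ds)
        sel = select_parents(ds, sim, hom, k=6, gs_threshold=0.90)["PopA"]
        assert "S7" not in sel.selected  # heterozygous outlier excluded
        assert not sel.relaxed
        assert len(sel.selected) == 6

    def test_identical_individuals_selected_in_input_order(self):
        ds = make_dataset(np.zeros((5, 10), dtype=np.int8))
        sel = select_parents(
            ds, simple_matching_gs(ds), observed_homozygosity(ds), k=3
        )["PopA"]
        assert sel.selected == ["S1", "S2", "S3"]
        assert not sel.relaxed

    def test_small_population_returns_everyone_with_shortfall(self):
        ds = make_dataset(np.zeros((7, 5), dtype=np.int8))
        sel = select_parents(
            ds, simple_matching_gs(ds), observed_homozygosity(ds), k=10
        )["PopA"]
        assert len(sel.selected) == 7
        assert sel.shortfall == 3

    def test_relaxation_flag_when_cohesion_unreachable(self):
        calls = np.zeros((4, 10), dtype=np.int8)
        calls[2:] = 1  # two opposite-homozygote camps: GS across camps = 0
        ds = make_dataset(calls)
        sel = select_parents(
            ds, simple_matching_gs(ds), observed_homozygosity(ds), k=3
        )["PopA"]
        assert sel.relaxed
        assert len(sel.selected) == 3

    def test_invalid_k_rejected(self):
        ds = make_dataset([[0]])
        with pytest.raises(ValueError):
            select_parents(ds, simple_matching_gs(ds), observed_homozygosity(ds), k=0)


class TestCrossPredictionMatrix:
    def test_extreme_pair(self):
        ds = make_dataset([[0, 0], [1, 1]], ["P1", "P2"])
        cpm = cross_prediction_matrix(ds, ["S1", "S2"])
        assert cpm.progeny_he(0, 1) == 1.0  # above diagonal
        assert cpm.gs(0, 1) == 0.0  # below diagonal

    def test_strategy_cell_counts_for_two_by_two(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, (4, 10)).astype(np.int8)
        ds = make_dataset(calls, ["P1", "P1", "P2", "P2"])
        cpm = cross_prediction_matrix(ds, ds.samples)
        kinds = [cpm.strategy(i, j) for i in range(4) for j in range(i + 1, 4)]
        assert kinds.count("FS") == 2 and kinds.count("F1") == 4

    def test_cells_reproduce_underlying_operations(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, (4, 15)).astype(np.int8)
        ds = make_dataset(calls, ["P1", "P1", "P2", "P2"])
        cpm = cross_prediction_matrix(ds, ds.samples)
        sim = simple_matching_gs(ds)
        for i in range(4):
            for j in range(i + 1, 4):
                assert cpm.progeny_he(i, j) == pytest.approx(
                    expected_progeny_heterozygosity(ds, ds.samples[i], ds.samples[j])
                )
                assert cpm.gs(i, j) == pytest.approx(sim.matrix[i, j])

    def test_duplicate_parents_rejected(self):
        ds = make_dataset([[0], [1]])
        with pytest.raises(ValueError):
            cross_prediction_matrix(ds, ["S1", "S1"])


class TestStrategySummary:
    def test_selfing_below_fullsib_below_f1_on_divergent_cohort(self, small_cohort):
        ds, _ = small_cohort
        sim = simple_matching_gs(ds)
        hom = observed_homozygosity(ds)
        sel = select_parents(ds, sim, hom, k=5)
        cpm = cross_prediction_matrix(ds, sel)
        summary = strategy_summary(cpm)
        mean_by = summary.groupby("strategy")["mean"].mean()
        assert mean_by["S"] <= mean_by["FS"] + 1e-9
        assert mean_by["FS"] < mean_by["F1"]

    def test_selfing_he_is_half_own_heterozygosity(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, (3, 40)).astype(np.int8)
        ds = make_dataset(calls)
        cpm = cross_prediction_matrix(ds, ds.samples)
        summary = strategy_summary(cpm)
        s_vals = summary[summary["strategy"] == "S"].iloc[0]
        het = (calls == 2).mean(axis=1)
        assert s_vals["mean"] == pytest.approx(het.mean() / 2)

    def test_related_populations_give_fs_like_f1(self):
        # an offshoot population derived from its source shows F1 predictions
        # comparable to within-population full-sib crosses
        config = CohortConfig(
            n_loci=600, pop_sizes=(10, 10, 10), fst=0.5, sib_generations=1,
            missing_rate=0.0, seed=21, admixture=None,
        )
        ds, _ = synth_cohort(config)
        # make Pop1 an offshoot of Pop2: copy genotypes with slight resampling
        from hybridplan import AdmixtureSpec, simulate_admixture

        ds = simulate_admixture(ds, AdmixtureSpec("Pop1", ("Pop2", "Pop2"), 1.0), seed=3)
        cpm = cross_prediction_matrix(ds, ds.samples)
        summary = strategy_summary(cpm).set_index(["strategy", "group"])
        f1_related = summary.loc[("F1", "Pop1xPop2"), "mean"]
        f1_distant = summary.loc[("F1", "Pop2xPop3"), "mean"]
        fs_pop2 = summary.loc[("FS", "Pop2"), "mean"]
        assert f1_related < f1_distant
        assert abs(f1_related - fs_pop2) < 0.25 * f1_distant
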