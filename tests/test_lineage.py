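import math
from collections import Counter
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from persistlab.lineage import (
    FractionWithSE,
    LineageTable,
    classify_population,
    classify_pre_exposure,
    compare_division_rates,
    division_rate,
    non_growing_fraction,
    path_division_rate,
    persister_frequency_from_chambers,
    rank_sum_test,
    sample_independent_lineages,
    shape_metrics,
)
from persistlab.simulate import PopulationSimConfig, simulate_chamber_lineages

from conftest import round_sig


class TestLineageTable:
    def test_cycle_rejected(self):
        cells = pd.DataFrame(
            [
                ("a", "b", "ch", 0.0, 1.0, "division", False),
                ("b", "a", "ch", 1.0, 1.0, "division", False),
            ],
            columns=["cell_id", "parent_id", "chamber_id", "birth_h", "end_h", "fate", "persister"],
        )
        with pytest.raises(ValueError, match="cycle"):
            LineageTable(cells=cells)

    def test_duplicate_id_rejected(self):
        cells = pd.DataFrame(
            [
                ("a", None, "ch", 0.0, 1.0, "censored", False),
                ("a", None, "ch", 0.0, 1.0, "censored", False),
            ],
            columns=["cell_id", "parent_id", "chamber_id", "birth_h", "end_h", "fate", "persister"],
        )
        with pytest.raises(ValueError, match="duplicate"):
            LineageTable(cells=cells)

    def test_unknown_parent_rejected(self):
        cells = pd.DataFrame(
            [("a", "ghost", "ch", 0.0, 1.0, "censored", False)],
            columns=["cell_id", "parent_id", "chamber_id", "birth_h", "end_h", "fate", "persister"],
        )
        with pytest.raises(ValueError, match="unknown parent"):
            LineageTable(cells=cells)

    def test_birth_must_match_parent_division(self):
        cells = pd.DataFrame(
            [
                ("a", None, "ch", 0.0, 1.0, "division", False),
                ("b", "a", "ch", 1.5, 2.0, "censored", False),
            ],
            columns=["cell_id", "parent_id", "chamber_id", "birth_h", "end_h", "fate", "persister"],
        )
        with pytest.raises(ValueError, match="birth"):
            LineageTable(cells=cells)

    def test_founders_and_children(self, small_table):
        assert set(small_table.founders["cell_id"]) == {"F1", "F2", "F3"}
        assert set(small_table.children("F1")) == {"B", "C"}
        assert small_table.ancestors("D") == ["D", "B", "F1"]

    def test_alive_at(self, small_table):
        alive = set(small_table.alive_at(2.0)["cell_id"])
        assert alive == {"C", "D", "E", "F2"}
        assert set(small_table.alive_at(0.5)["cell_id"]) == {"F1", "F2", "F3"}

    def test_nonpositive_area_rejected(self, small_table):
        frames = small_table.frames.copy()
        frames.loc[0, "area_um2"] = -1.0
        with pytest.raises(ValueError, match="area"):
            LineageTable(cells=small_table.cells, frames=frames)


class TestDivisionRate:
    def test_arithmetic(self):
        assert division_rate(3, 1.5) == pytest.approx(2.0)
        assert division_rate(0, 2.0) == 0.0

    def test_zero_duration(self):
        with pytest.raises(ValueError):
            division_rate(1, 0.0)

    def test_path_rate(self, small_table):
        # F1 -> B -> D: two divisions (1.0, 1.4) in [0, 2]
        assert path_division_rate(small_table, ["F1", "B", "D"], 0.0, 2.0) == pytest.approx(1.0)
        assert path_division_rate(small_table, ["F2"], 0.0, 2.0) == 0.0

    def test_simulator_rate_recovery(self):
        cfg = PopulationSimConfig(
            n_founders=500, p_nongrowing=0.0, division_rate=2.0,
            t_pre=1.5, t_exposure=0.5, t_post=0.0, seed=4, emit_frames=False,
        )
        sim = simulate_chamber_lineages(cfg)
        paths = sample_independent_lineages(sim.table, t_exposure=1.5, seed=0)
        rates = [path_division_rate(sim.table, p, 0.0, 1.5) for p in paths]
        assert np.mean(rates) == pytest.approx(2.0, rel=0.05)


class TestSampleIndependentLineages:
    def test_no_division_returns_founder(self, small_table):
        paths = sample_independent_lineages(small_table, t_exposure=2.0, seed=0,
                                            founders=["F2"])
        assert paths == [["F2"]]

    def test_one_path_per_founder(self, small_table):
        paths = sample_independent_lineages(small_table, t_exposure=2.0, seed=0)
        assert len(paths) == 3

    def test_uniform_over_leaves(self, binary_tree_table):
        counts = Counter()
        n_seeds = 4000
        for seed in range(n_seeds):
            (path,) = sample_independent_lineages(
                binary_tree_table, t_exposure=2.0, seed=seed
            )
            counts[path[-1]] += 1
        assert len(counts) == 8
        for leaf, c in counts.items():
            assert abs(c / n_seeds - 1 / 8) < 0.02, leaf

    def test_deterministic(self, binary_tree_table):
        a = sample_independent_lineages(binary_tree_table, 2.0, seed=42)
        b = sample_independent_lineages(binary_tree_table, 2.0, seed=42)
        assert a == b


class TestClassifyPreExposure:
    def test_division_in_window_is_growing(self, small_table):
        assert classify_pre_exposure(small_table, "D", t_exposure=2.0) == "growing"
        assert classify_pre_exposure(small_table, "C", t_exposure=2.0) == "growing"

    def test_constant_area_non_growing(self, small_table):
        assert classify_pre_exposure(small_table, "F2", t_exposure=2.0) == "non_growing"

    def test_tracking_lost_indeterminate(self, small_table):
        assert classify_pre_exposure(small_table, "F3", t_exposure=2.0) == "indeterminate"

    def test_window_outside_observation_raises(self, small_table):
        with pytest.raises(ValueError, match="window"):
            classify_pre_exposure(small_table, "F2", t_exposure=1.0, window=4.0)

    def test_elongation_threshold(self, small_table):
        # C grows from 1.2 to 1.5 within [0.5, 2.0] via frames at 1.0..2.0:
        # first frame in window is 1.0 (area 1.0), last 2.0 (area 1.5): +50%
        assert (
            classify_pre_exposure(small_table, "C", t_exposure=2.0, window=1.0)
            == "growing"
        )
        # with a huge threshold the same cell counts as non-growing
        assert (
            classify_pre_exposure(
                small_table, "C", t_exposure=2.0, window=1.0, elongation_threshold=5.0
            )
            == "non_growing"
        )

    def test_population_matches_single_cell(self, small_table):
        labels = classify_population(small_table, t_exposure=2.0)
        for row in labels.itertuples():
            assert row.label == classify_pre_exposure(
                small_table, row.cell_id, t_exposure=2.0
            )

    def test_simulator_recovery_of_nongrowing_fraction(self):
        cfg = PopulationSimConfig(
            n_founders=800, p_nongrowing=0.61, division_rate=1.0,
            t_pre=1.5, t_exposure=0.5, t_post=0.0, seed=9,
        )
        sim = simulate_chamber_lineages(cfg)
        labels = classify_population(sim.table, t_exposure=1.5)
        est = non_growing_fraction(labels["label"])
        truth = sim.cell_truth["state_at_exposure"].eq("non_growing").mean()
        assert abs(est.fraction - truth) < 3 * max(est.se, 1e-3)


class TestNonGrowingFraction:
    def test_printed_post_exponential_value(self):
        frac = FractionWithSE.from_counts(4, 13650)
        assert round_sig(frac.fraction, 2) == 2.9e-4
        assert round_sig(frac.se, 2) == 1.5e-4

    def test_printed_late_stationary_value(self):
        frac = FractionWithSE.from_counts(318, 521)
        assert frac.fraction == pytest.approx(0.610, abs=5e-4)
        assert frac.se == pytest.approx(0.0214, abs=1e-4)

    def test_zero_numerator(self):
        frac = FractionWithSE.from_counts(0, 100)
        assert frac.fraction == 0.0 and frac.se == 0.0

    def test_labels_and_exclusion(self):
        labels = ["non_growing"] * 3 + ["growing"] * 6 + ["indeterminate"] * 2
        frac = non_growing_fraction(labels)
        assert frac.fraction == pytest.approx(1 / 3)
        assert frac.denominator == 9
        assert frac.excluded == 2

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            non_growing_fraction(["growing", "mystery"])

    def test_all_indeterminate(self):
        with pytest.raises(ValueError):
            non_growing_fraction(["indeterminate"])

    @given(k=st.integers(min_value=0, max_value=100))
    def test_se_maximal_at_half(self, k):
        n = 100
        assert FractionWithSE.from_counts(k, n).se <= FractionWithSE.from_counts(50, n).se


class TestPersisterFrequencyFromChambers:
    def test_worked_example(self):
        counts = [25.3] * 20
        frac = persister_frequency_from_chambers(6, counts, 15000)
        assert frac.denominator == pytest.approx(3.795e5)
        assert round_sig(frac.denominator, 2) == 3.8e5
        assert frac.fraction == pytest.approx(6 / 379500)
        assert round_sig(frac.fraction, 2) == 1.6e-5

    def test_zero_persisters(self):
        frac = persister_frequency_from_chambers(0, [20.0] * 20, 1000)
        assert frac.fraction == 0.0

    def test_equal_counts_exact_total(self):
        frac = persister_frequency_from_chambers(1, [30.0] * 20, 100)
        assert frac.denominator == 3000.0

    def test_errors(self):
        with pytest.raises(ValueError):
            persister_frequency_from_chambers(1, [], 100)
        with pytest.raises(ValueError):
            persister_frequency_from_chambers(-1, [10.0], 100)


class TestShapeMetrics:
    def test_unit_square(self):
        m = shape_metrics([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert m.area_um2 == pytest.approx(1.0)
        assert m.perimeter_um == pytest.approx(4.0)
        assert m.circularity == pytest.approx(math.pi / 4, abs=1e-9)

    def test_rectangle_1x4(self):
        m = shape_metrics([(0, 0), (4, 0), (4, 1), (0, 1)])
        assert m.circularity == pytest.approx(16 * math.pi / 100, abs=1e-9)

    @pytest.mark.parametrize("n", [5, 8, 24, 96])
    def test_regular_polygon(self, n):
        ang = np.linspace(0, 2 * math.pi, n, endpoint=False)
        verts = np.column_stack([np.cos(ang), np.sin(ang)])
        m = shape_metrics(verts)
        assert m.circularity == pytest.approx(math.pi / (n * math.tan(math.pi / n)), rel=1e-9)

    def test_duplicate_vertices_dropped(self):
        m = shape_metrics([(0, 0), (0, 0), (1, 0), (1, 1), (1, 1), (0, 1), (0, 0)])
        assert m.area_um2 == pytest.approx(1.0)

    def test_self_intersecting_rejected(self):
        with pytest.raises(ValueError):
            shape_metrics([(0, 0), (1, 1), (1, 0), (0, 1)])  # bow-tie

    def test_isoperimetric_bound_random_convex(self):
        rng = np.random.default_rng(12)
        from scipy.spatial import ConvexHull

        for _ in range(1000):
            pts = rng.normal(size=(12, 2))
            hull = ConvexHull(pts)
            m = shape_metrics(pts[hull.vertices])
            assert m.circularity <= 1.0 + 1e-12


def _exact_two_sided_p(x, y):
    """Brute-force enumeration oracle for the rank-sum p-value."""
    pooled = sorted(x) + sorted(y)
    n = len(x)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    def u_of(subset):
        r = sum(ranks[pooled[i]] for i in subset)
        return r - n * (n + 1) / 2
    observed = u_of(range(n))
    us = [u_of(c) for c in combinations(range(len(pooled)), n)]
    mean_u = len(x) * len(y) / 2
    dev = abs(observed - mean_u)
    extreme = sum(1 for u in us if abs(u - mean_u) >= dev - 1e-12)
    return extreme / len(us)


class TestRankSumTest:
    def test_exact_small_sample(self):
        u, p = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)
        assert p == pytest.approx(_exact_two_sided_p([1, 2], [3, 4]))

    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, p = rank_sum_test(x, x)
        assert p > 0.9

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            _, p = rank_sum_test(x, y)
            assert p == pytest.approx(_exact_two_sided_p(list(x), list(y)), abs=1e-9)

    def test_exact_vs_asymptotic_agreement(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.normal(size=9)
            y = rng.normal(size=10)
            from scipy.stats import mannwhitneyu

            p_exact = mannwhitneyu(x, y, method="exact").pvalue
            p_asym = mannwhitneyu(x, y, method="asymptotic", use_continuity=True).pvalue
            assert abs(p_exact - p_asym) < 0.02

    def test_null_p_uniform(self):
        rng = np.random.default_rng(10)
        ps = []
        for _ in range(2000):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            ps.append(rank_sum_test(x, y)[1])
        assert kstest(ps, "uniform").statistic < 0.03

    def test_empty_sample(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


def _two_group_table(rate_pers, rate_non, n_pers, n_non, t_exp, seed):
    """Merge two simulations into one table with labelled founder groups."""
    sim_p = simulate_chamber_lineages(
        PopulationSimConfig(
            n_founders=n_pers, p_nongrowing=0.0, division_rate=rate_pers,
            t_pre=t_exp, t_exposure=0.5, t_post=0.0, seed=seed, emit_frames=False,
        )
    )
    sim_n = simulate_chamber_lineages(
        PopulationSimConfig(
            n_founders=n_non, p_nongrowing=0.0, division_rate=rate_non,
            t_pre=t_exp, t_exposure=0.5, t_post=0.0, seed=seed + 1, emit_frames=False,
        )
    )
    cp = sim_p.table.cells.copy()
    cp["cell_id"] = "p" + cp["cell_id"].astype(str)
    cp["parent_id"] = "p" + cp["parent_id"].astype("string")
    cp["parent_id"] = cp["parent_id"].where(cp["parent_id"].notna(), None)
    cp["persister"] = True
    cn = sim_n.table.cells.copy()
    cn["cell_id"] = "n" + cn["cell_id"].astype(str)
    cn["parent_id"] = "n" + cn["parent_id"].astype("string")
    cn["parent_id"] = cn["parent_id"].where(cn["parent_id"].notna(), None)
    cn["persister"] = False
    return LineageTable(cells=pd.concat([cp, cn], ignore_index=True))


class TestCompareDivisionRates:
    def test_identical_groups(self):
        table = _two_group_table(1.5, 1.5, 40, 40, t_exp=2.0, seed=0)
        res = compare_division_rates(table, t_exposure=2.0, seed=0)
        assert res.p_value > 0.05
        assert abs(res.mean_persisters - res.mean_non_persisters) < 3 * (
            res.se_persisters + res.se_non_persisters
        )

    def test_power_on_separated_rates(self):
        table = _two_group_table(2.3, 0.9, 50, 50, t_exp=3.0, seed=1)
        res = compare_division_rates(table, t_exposure=3.0, seed=0)
        assert res.p_value < 0.01
        assert res.mean_persisters > res.mean_non_persisters

    def test_coverage_of_equal_rates(self):
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            table = _two_group_table(1.8, 1.8, 30, 30, t_exp=2.0, seed=seed * 7)
            res = compare_division_rates(table, t_exposure=2.0, seed=seed)
            se = math.hypot(res.se_persisters, res.se_non_persisters)
            if abs(res.mean_persisters - res.mean_non_persisters) <= 2 * se:
                hits += 1
        assert hits / n_seeds >= 0.90

    def test_requires_both_groups(self, small_table):
        with pytest.raises(ValueError):
            compare_division_rates(small_table, t_exposure=2.0)
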