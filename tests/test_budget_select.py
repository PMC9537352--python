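import numpy as np
import pytest

from costaware import (
    FeatureCostTable,
    apply_pseudocosts,
    brute_force_select,
    greedy_select,
    group_knapsack_select,
    knapsack_select,
)


def random_instance(rng, m):
    phi = rng.uniform(0, 5, size=m)
    costs = rng.integers(1, 20, size=m) / 4.0  # exact multiples of the DP resolution
    table = FeatureCostTable(tuple(f"f{i}" for i in range(m)), costs.astype(float))
    k = float(rng.uniform(0, costs.sum()))
    return phi, table, k


class TestKnapsack:
    def test_beats_single_expensive_feature(self, simple_table):
        sol = knapsack_select([3.0, 2.0, 2.0], simple_table, 2.0)
        assert sol.selected == ("f2", "f3")
        assert sol.total_importance == 4.0 and sol.realized_cost == 2.0

    def test_zero_budget_empty(self, simple_table):
        sol = knapsack_select([3.0, 2.0, 2.0], simple_table, 0.0)
        assert sol.selected == () and sol.total_importance == 0.0

    def test_unconstrained_budget_selects_everything(self, simple_table):
        sol = knapsack_select([3.0, 2.0, 2.0], simple_table, 100.0)
        assert sol.selected == ("f1", "f2", "f3")

    def test_bad_resolution_rejected(self, simple_table):
        with pytest.raises(ValueError):
            knapsack_select([1.0, 1.0, 1.0], simple_table, 2.0, resolution=0.0)

    def test_monotone_in_budget(self, rng):
        phi, table, _ = random_instance(rng, 10)
        imps = [
            knapsack_select(phi, table, k).total_importance
            for k in np.linspace(0, float(table.costs.sum()), 15)
        ]
        assert np.all(np.diff(imps) >= -1e-12)

    def test_oracle_equivalence_random_instances(self, rng):
        for _ in range(60):
            m = int(rng.integers(2, 13))
            phi, table, k = random_instance(rng, m)
            dp = knapsack_select(phi, table, k, resolution=0.25)
            bf = brute_force_select(phi, table, k)
            assert dp.total_importance == pytest.approx(bf.total_importance)
            assert dp.realized_cost <= k + 1e-9
            assert dp.selected == bf.selected  # shared tie-break policy


class TestGreedy:
    def test_ratio_tie_trap(self):
        # all ratios equal 2; greedy grabs the big feature and strands budget
        table = FeatureCostTable(("f1", "f2", "f3"), np.array([5.0, 3.0, 3.0]))
        g = greedy_select([10.0, 6.0, 6.0], table, 6.0)
        assert g.selected == ("f1",) and g.total_importance == 10.0
        d = knapsack_select([10.0, 6.0, 6.0], table, 6.0)
        assert d.selected == ("f2", "f3") and d.total_importance == 12.0

    def test_single_affordable_feature(self):
        table = FeatureCostTable(("a", "b"), np.array([10.0, 1.0]))
        assert greedy_select([5.0, 1.0], table, 1.0).selected == ("b",)

    def test_skip_and_continue_vs_stop(self):
        table = FeatureCostTable(("a", "b", "c"), np.array([2.0, 3.0, 1.0]))
        phi = [4.0, 4.5, 1.0]  # ratios 2.0, 1.5, 1.0
        assert greedy_select(phi, table, 3.0).selected == ("a", "c")
        assert greedy_select(phi, table, 3.0, stop_at_first_failure=True).selected == ("a",)

    def test_zero_cost_without_pseudocost_rejected(self):
        table = FeatureCostTable(("a", "b"), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="pseudocost"):
            greedy_select([1.0, 1.0], table, 1.0)
        ok = greedy_select([1.0, 1.0], apply_pseudocosts(table), 1.0)
        assert "a" in ok.selected  # essentially free, high ratio

    def test_never_beats_knapsack(self, rng):
        for _ in range(40):
            phi, table, k = random_instance(rng, 9)
            g = greedy_select(phi, table, k)
            d = knapsack_select(phi, table, k, resolution=0.25)
            assert g.total_importance <= d.total_importance + 1e-9
            assert g.realized_cost <= k + 1e-9

    def test_equal_costs_make_greedy_optimal(self, rng):
        phi = rng.uniform(0, 5, size=8)
        table = FeatureCostTable(tuple(f"f{i}" for i in range(8)), np.full(8, 2.0))
        for k in (0.0, 4.0, 6.0, 16.0):
            g = greedy_select(phi, table, k)
            d = knapsack_select(phi, table, k)
            assert g.total_importance == pytest.approx(d.total_importance)


class TestGroupKnapsack:
    def make_grouped(self):
        return FeatureCostTable(
            ("a", "b", "c"),
            np.array([2.0, 2.0, 2.0]),
            {"a": "g1", "b": "g1", "c": "g2"},
            {"g1": 2.0, "g2": 2.0},
        )

    def test_group_importance_is_member_sum(self):
        sol = group_knapsack_select([1.0, 2.0, 2.5], self.make_grouped(), 2.0)
        assert sol.selected_groups == ("g1",)  # phi_g1 = 3 > phi_g2 = 2.5
        assert sol.selected == ("a", "b")
        assert sol.realized_cost == 2.0  # one group cost, not per member

    def test_zero_budget(self):
        sol = group_knapsack_select([1.0, 2.0, 2.5], self.make_grouped(), 0.0)
        assert sol.selected == () and sol.selected_groups == ()

    def test_singleton_groups_reduce_to_plain_knapsack(self, rng):
        for _ in range(20):
            phi, table, k = random_instance(rng, 8)
            grouped = FeatureCostTable(
                table.feature_ids,
                table.costs,
                {f: f"g_{f}" for f in table.feature_ids},
                {f"g_{f}": table.cost_of(f) for f in table.feature_ids},
            )
            a = knapsack_select(phi, table, k, resolution=0.25)
            b = group_knapsack_select(phi, grouped, k, resolution=0.25)
            assert a.selected == b.selected
            assert a.total_importance == pytest.approx(b.total_importance)

    def test_ungrouped_table_rejected(self, simple_table):
        with pytest.raises(ValueError):
            group_knapsack_select([1.0, 1.0, 1.0], simple_table, 1.0)


class TestBruteForce:
    def test_zero_budget(self, simple_table):
        assert brute_force_select([1.0, 1.0, 1.0], simple_table, 0.0).selected == ()

    def test_symmetric_tie_breaks_by_file_order(self):
        table = FeatureCostTable(tuple(f"f{i}" for i in range(5)), np.ones(5))
        sol = brute_force_select(np.ones(5), table, 3.0)
        assert sol.selected == ("f0", "f1", "f2")

    def test_too_many_features_rejected(self):
        table = FeatureCostTable(tuple(f"f{i}" for i in range(21)), np.ones(21))
        with pytest.raises(ValueError):
            brute_force_select(np.ones(21), table, 3.0)

    def test_negative_importance_rejected(self, simple_table):
        with pytest.raises(ValueError):
            brute_force_select([-1.0, 1.0, 1.0], simple_table, 2.0)
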