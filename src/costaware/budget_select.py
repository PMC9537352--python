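"""Budget-constrained feature selection.

Given a global importance vector phi and a feature-cost table, pick the
subset S maximizing sum(phi_i, i in S) subject to sum(c_i, i in S) <= k — a
0/1 knapsack. Solved by dynamic programming over integer-scaled costs
(deterministic and exactly optimal for the scaled instance), with a greedy
importance-per-cost baseline, a grouped-cost variant that selects whole
acquisition groups, and an exhaustive oracle for testing.

Tie-breaking is fixed for reproducibility: among equal-importance
solutions, prefer lower realized cost, then features earlier in cost-table
(file) order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cost_model import FeatureCostTable

__all__ = [
    "BudgetSolution",
    "knapsack_select",
    "greedy_select",
    "group_knapsack_select",
    "brute_force_select",
]

# DP table capacity guard: resolution is coarsened, never exceeded, past this
MAX_DP_CAPACITY = 2_000_000


@dataclass(frozen=True)
class BudgetSolution:
    """A feature (or group) subset chosen within a cost budget."""

    selected: tuple[str, ...]
    realized_cost: float
    total_importance: float
    budget: float
    selector: str
    selected_groups: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.realized_cost > self.budget + 1e-9:
            raise ValueError("solution exceeds its budget")


def _check_inputs(phi, table: FeatureCostTable, k: float) -> np.ndarray:
    phi = np.asarray(phi, dtype=float).ravel()
    if phi.shape[0] != table.n_features:
        raise ValueError("importance vector must align with the cost table")
    if np.any(phi < 0):
        raise ValueError("importances must be nonnegative")
    if k < 0:
        raise ValueError("budget must be nonnegative")
    if table.has_missing:
        raise ValueError("cost table has missing costs; impute first")
    return phi


def _dp_knapsack(values: np.ndarray, weights: np.ndarray, cap: int) -> list[int]:
    """0/1 knapsack over integer weights; returns chosen item indices.

    Maximizes total value, then minimizes total weight; on exact ties the
    backtrack prefers *excluding* later items, so earlier (file-order)
    items win.
    """
    n = len(values)
    dp_val = np.zeros(cap + 1)
    dp_wt = np.zeros(cap + 1, dtype=np.int64)  # weight actually used
    take = np.zeros((n, cap + 1), dtype=bool)
    for i in range(n):
        w, v = int(weights[i]), float(values[i])
        if w > cap:
            continue
        cand_val = np.full(cap + 1, -np.inf)
        cand_wt = np.zeros(cap + 1, dtype=np.int64)
        cand_val[w:] = dp_val[: cap + 1 - w] + v
        cand_wt[w:] = dp_wt[: cap + 1 - w] + w
        better = (cand_val > dp_val + 1e-12) | (
            (np.abs(cand_val - dp_val) <= 1e-12) & (cand_wt < dp_wt)
        )
        take[i] = better
        dp_val = np.where(better, cand_val, dp_val)
        dp_wt = np.where(better, cand_wt, dp_wt)
    # backtrack
    chosen: list[int] = []
    w = cap
    for i in range(n - 1, -1, -1):
        if take[i, w]:
            chosen.append(i)
            w -= int(weights[i])
    return chosen[::-1]


def _scaled(costs: np.ndarray, k: float, resolution: float | None) -> tuple[np.ndarray, int]:
    positive = costs[costs > 0]
    if resolution is None:
        base = float(positive.min()) if positive.size else 1.0
        resolution = base * 1e-3
        # keep the DP table bounded; coarser resolution on huge budgets
        if k / resolution > MAX_DP_CAPACITY:
            resolution = k / MAX_DP_CAPACITY
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    weights = np.ceil(np.round(costs / resolution, 9)).astype(np.int64)
    cap = int(math.floor(round(k / resolution, 9)))
    return weights, cap


def knapsack_select(
    phi,
    costs: FeatureCostTable,
    k: float,
    resolution: float | None = None,
) -> BudgetSolution:
    """Importance-maximizing feature subset within budget ``k``.

    Dynamic programming over costs scaled to integers by ``resolution``
    (default: 1e-3 of the smallest nonzero cost). Selection feasibility
    uses pseudocost-adjusted costs; the reported realized cost uses the
    original ones.
    """
    phi = _check_inputs(phi, costs, k)
    eff = costs.effective_costs
    # zero-importance features can never raise the objective
    candidates = np.flatnonzero(phi > 0)
    weights, cap = _scaled(eff, k, resolution)
    feasible = candidates[weights[candidates] <= cap]
    chosen_local = _dp_knapsack(phi[feasible], weights[feasible], cap) if cap >= 0 else []
    idx = feasible[chosen_local] if len(chosen_local) else np.array([], dtype=int)
    idx = np.sort(idx)
    selected = tuple(costs.feature_ids[i] for i in idx)
    return BudgetSolution(
        selected=selected,
        realized_cost=float(costs.costs[idx].sum()),
        total_importance=float(phi[idx].sum()),
        budget=float(k),
        selector="knapsack",
    )


def greedy_select(
    phi,
    costs: FeatureCostTable,
    k: float,
    stop_at_first_failure: bool = False,
) -> BudgetSolution:
    """Greedy selection by importance-per-cost ratio omega_i = phi_i / c_i.

    Features are scanned from highest to lowest ratio (ties broken by file
    order); each is added if its cost fits the remaining budget. By default
    a feature that does not fit is skipped and the scan continues
    (``stop_at_first_failure=True`` stops instead).
    """
    phi = _check_inputs(phi, costs, k)
    eff = costs.effective_costs
    if np.any(eff <= 0):
        raise ValueError("zero effective cost: apply pseudocosts before greedy selection")
    ratio = phi / eff
    order = np.lexsort((np.arange(len(ratio)), -ratio))
    remaining = float(k)
    idx: list[int] = []
    for i in order:
        if eff[i] <= remaining + 1e-12:
            idx.append(int(i))
            remaining -= eff[i]
        elif stop_at_first_failure:
            break
    idx = sorted(idx)
    selected = tuple(costs.feature_ids[i] for i in idx)
    return BudgetSolution(
        selected=selected,
        realized_cost=float(costs.costs[idx].sum()),
        total_importance=float(phi[idx].sum()),
        budget=float(k),
        selector="greedy",
    )


def group_knapsack_select(
    phi,
    costs: FeatureCostTable,
    k: float,
    resolution: float | None = None,
) -> BudgetSolution:
    """Knapsack over acquisition groups, expanded back to features.

    Group importance is the sum of member importances, group cost the
    single acquisition cost c_g; the winning group set F' is expanded to
    the feature set F = union of members. Realized cost is the sum of
    selected group costs.
    """
    phi = _check_inputs(phi, costs, k)
    if not costs.grouped:
        raise ValueError("cost table has no groups")
    groups = costs.group_ids
    g_index = {g: j for j, g in enumerate(groups)}
    g_phi = np.zeros(len(groups))
    for i, f in enumerate(costs.feature_ids):
        g_phi[g_index[costs.group_of[f]]] += phi[i]
    g_cost = np.array([costs.group_costs[g] for g in groups], dtype=float)

    weights, cap = _scaled(g_cost, k, resolution)
    candidates = np.flatnonzero(g_phi > 0)
    feasible = candidates[weights[candidates] <= cap]
    chosen_local = _dp_knapsack(g_phi[feasible], weights[feasible], cap) if cap >= 0 else []
    gidx = np.sort(feasible[chosen_local]) if len(chosen_local) else np.array([], dtype=int)
    chosen_groups = tuple(groups[j] for j in gidx)
    gset = set(chosen_groups)
    feat_idx = [i for i, f in enumerate(costs.feature_ids) if costs.group_of[f] in gset]
    selected = tuple(costs.feature_ids[i] for i in feat_idx)
    return BudgetSolution(
        selected=selected,
        realized_cost=float(g_cost[gidx].sum()),
        total_importance=float(phi[feat_idx].sum()),
        budget=float(k),
        selector="group_knapsack",
        selected_groups=chosen_groups,
    )


def brute_force_select(phi, costs: FeatureCostTable, k: float) -> BudgetSolution:
    """Exhaustive-enumeration optimum — the test oracle for the DP solver.

    Feasibility uses pseudocost-adjusted costs, like ``knapsack_select``.
    Ties: maximum importance, then minimum cost, then lexicographically
    earliest feature indices (file order).
    """
    phi = _check_inputs(phi, costs, k)
    m = costs.n_features
    if m > 20:
        raise ValueError("brute force is capped at 20 features")
    eff = costs.effective_costs
    best: tuple[float, float, tuple[int, ...]] | None = None
    for mask in range(2**m):
        idx = tuple(i for i in range(m) if mask >> i & 1)
        c = float(eff[list(idx)].sum()) if idx else 0.0
        if c > k + 1e-12:
            continue
        v = float(phi[list(idx)].sum()) if idx else 0.0
        key = (-v, c, idx)
        if best is None or key < (-best[0], best[1], best[2]):
            best = (v, c, idx)
    assert best is not None
    v, _, idx = best
    return BudgetSolution(
        selected=tuple(costs.feature_ids[i] for i in idx),
        realized_cost=float(costs.costs[list(idx)].sum()),
        total_importance=v,
        budget=float(k),
        selector="brute_force",
    )
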