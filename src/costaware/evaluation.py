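"""Discrimination metrics, tradeoff-curve comparison, deployment arithmetic.

Cost-performance curves from different methods (or replicates) rarely share
x-coordinates, so curves are aligned by previous-value interpolation onto a
common linearly spaced cost grid — each grid point takes the performance of
the most expensive model not exceeding it, a conservative estimate — and
compared with a paired-samples t-test on per-replicate mean AUROC, paired
by train/test split.

Deployment extrapolation converts a model's recall at a fixed precision
target (alert-fatigue control) into an expected count of positive cases
caught nationwide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_auc_score

__all__ = [
    "auroc",
    "recall_at_precision",
    "deployment_extrapolation",
    "warned_difference",
    "align_curves",
    "compare_curves",
    "CurveComparison",
    "TuningSearchSpec",
    "SearchResult",
    "budget_binary_search",
]


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int).ravel()
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    labels = _check_labels(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float).ravel()))


def recall_at_precision(scores, labels, precision_target: float) -> float:
    """Maximum recall over thresholds whose precision meets the target.

    The target expresses tolerable alert fatigue: a 4:1 false:true positive
    ratio is precision 0.2. Returns 0 when no threshold attains it.
    """
    if not 0 < precision_target <= 1:
        raise ValueError("precision target must be in (0, 1]")
    labels = _check_labels(labels)
    precision, recall, _ = precision_recall_curve(labels, np.asarray(scores, dtype=float))
    ok = precision >= precision_target
    return float(recall[ok].max()) if ok.any() else 0.0


def deployment_extrapolation(recall: float, national_positives: int) -> int:
    """Positive cases a deployed model would catch nationwide.

    Recall times the national count of positive cases, rounded half away
    from zero.
    """
    if not 0 <= recall <= 1:
        raise ValueError("recall must be in [0, 1]")
    if national_positives < 0:
        raise ValueError("positive count must be nonnegative")
    x = recall * national_positives
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def warned_difference(warned_a: int, warned_b: int) -> int:
    """How many more cases model A catches than model B."""
    return int(warned_a) - int(warned_b)


def align_curves(curves, n_grid: int = 100, extend_below: bool = False):
    """Previous-value interpolation of cost-performance curves on one grid.

    Parameters
    ----------
    curves
        One ``(costs, performances)`` pair per replicate; costs need not be
        sorted or shared across replicates.
    n_grid
        Number of linearly spaced grid costs between the global cheapest
        and most expensive model.
    extend_below
        Grid points cheaper than a replicate's cheapest model are NaN
        (masked) by default; set True to carry the cheapest model's value
        down instead.

    Returns
    -------
    grid : (n_grid,) array of costs
    aligned : (n_replicates, n_grid) array; entry = performance of the most
        expensive model with cost <= grid point.
    """
    prepared = []
    for costs, perf in curves:
        costs = np.asarray(costs, dtype=float).ravel()
        perf = np.asarray(perf, dtype=float).ravel()
        if costs.size == 0 or costs.shape != perf.shape:
            raise ValueError("each curve needs matching, nonempty costs and performances")
        order = np.argsort(costs, kind="stable")
        prepared.append((costs[order], perf[order]))
    lo = min(c[0] for c, _ in prepared)
    hi = max(c[-1] for c, _ in prepared)
    grid = np.linspace(lo, hi, n_grid)
    aligned = np.full((len(prepared), n_grid), np.nan)
    for r, (costs, perf) in enumerate(prepared):
        # index of the last model with cost <= grid point
        pos = np.searchsorted(costs, grid + 1e-12, side="right") - 1
        valid = pos >= 0
        aligned[r, valid] = perf[pos[valid]]
        if extend_below and not valid.all():
            aligned[r, ~valid] = perf[0]
    return grid, aligned


@dataclass(frozen=True)
class CurveComparison:
    t: float
    p: float
    mean_a: np.ndarray
    mean_b: np.ndarray
    degenerate: bool = False


def compare_curves(aligned_a, aligned_b) -> CurveComparison:
    """Two-sided paired t-test on per-replicate mean AUROC of aligned curves.

    Rows are replicates paired by train/test split; each row is reduced to
    its mean over the (unmasked) grid before testing. Zero variance of the
    paired differences is flagged as degenerate: identical curves give
    ``t=0, p=1``; a constant nonzero shift gives ``t=±inf, p=0``.
    """
    a = np.asarray(aligned_a, dtype=float)
    b = np.asarray(aligned_b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("curve sets must have the same number of replicates")
    if a.shape[0] < 2:
        raise ValueError("paired test needs at least 2 replicates")
    mean_a = np.nanmean(a, axis=1)
    mean_b = np.nanmean(b, axis=1)
    diff = mean_a - mean_b
    if np.allclose(diff.std(ddof=1), 0):
        if np.allclose(diff, 0):
            return CurveComparison(0.0, 1.0, mean_a, mean_b, degenerate=True)
        t = math.copysign(math.inf, diff.mean())
        return CurveComparison(t, 0.0, mean_a, mean_b, degenerate=True)
    t, p = stats.ttest_rel(mean_a, mean_b)
    return CurveComparison(float(t), float(p), mean_a, mean_b)


# ---------------------------------------------------------------------------
# budget-targeted tuning of opaque cost-penalized learners


@dataclass(frozen=True)
class TuningSearchSpec:
    """Bisection bounds for a unitless cost/accuracy tradeoff parameter.

    Defaults follow the published harness: bounds (0, 1e6), start 1,
    at most 128 trainings. ``cost_rtol`` stops the search once a feasible
    model's cost is within that relative tolerance of the target budget.
    """

    budget: float
    lam_min: float = 0.0
    lam_max: float = 1e6
    lam_0: float = 1.0
    max_trainings: int = 128
    cost_rtol: float = 0.01

    def __post_init__(self) -> None:
        if not self.lam_min <= self.lam_0 <= self.lam_max:
            raise ValueError("need lam_min <= lam_0 <= lam_max")
        if self.max_trainings < 1:
            raise ValueError("max_trainings must be >= 1")


@dataclass(frozen=True)
class SearchResult:
    feasible: bool
    lam: float | None
    cost: float | None
    performance: float | None
    n_trainings: int
    history: tuple[tuple[float, float, float], ...]  # (lam, cost, performance)


def budget_binary_search(trainer, spec: TuningSearchSpec) -> SearchResult:
    """Bisection on a tradeoff parameter to hit a cost budget.

    ``trainer(lam) -> (model_cost, performance)`` is an opaque,
    deterministic training run whose cost and accuracy both decrease as the
    penalty ``lam`` grows. Standard bisection on (lo, hi): a feasible run
    (cost <= budget) is recorded and ``hi`` moves down to ``lam``;
    otherwise ``lo`` moves up. Returns the best-performing feasible model
    found and the number of trainings spent — the price other frameworks
    pay for the budget targeting that a two-training attribution+knapsack
    fit gets directly.
    """
    lo, hi = spec.lam_min, spec.lam_max
    lam = spec.lam_0
    best: tuple[float, float, float] | None = None  # (performance, lam, cost)
    history: list[tuple[float, float, float]] = []
    n = 0
    for _ in range(spec.max_trainings):
        cost, perf = trainer(lam)
        n += 1
        history.append((lam, cost, perf))
        if cost <= spec.budget:
            if best is None or perf > best[0]:
                best = (perf, lam, cost)
            hi = lam
            if abs(cost - spec.budget) <= spec.cost_rtol * max(spec.budget, 1e-12):
                break
        else:
            lo = lam
        if hi - lo <= 1e-12 * max(1.0, spec.lam_max):  # interval collapsed
            break
        lam = (lo + hi) / 2.0
    if best is None:
        return SearchResult(False, None, None, None, n, tuple(history))
    perf, lam, cost = best
    return SearchResult(True, lam, cost, perf, n, tuple(history))
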