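"""End-to-end cost-aware model building.

The core procedure turns any fitted risk model into a budget-constrained
one in exactly two trainings:

1. fit the base model once on *all* features;
2. compute additive per-feature attributions on held-out samples and reduce
   them to a global importance vector;
3. solve a knapsack: pick the feature (or acquisition-group) subset with
   maximum total importance whose cost fits the budget;
4. retrain a fresh model of the same class, same hyperparameters, on the
   selected features only.

Because step 1–2 results are cached, a sweep over B budgets costs 1 + B
trainings. Alternate strategies — greedy ratio selection, recursive
feature elimination by importance-per-cost, and knapsack without
retraining (masking unselected inputs with training means) — are provided
for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression

from . import attribution as attr
from .budget_select import (
    BudgetSolution,
    greedy_select,
    group_knapsack_select,
    knapsack_select,
)
from .cost_model import FeatureCostTable, apply_pseudocosts, impute_missing_costs, total_cost
from .evaluation import auroc

__all__ = [
    "Dataset",
    "preprocess",
    "encoded_cost_table",
    "BaseModelAdapter",
    "gbm_adapter",
    "linear_adapter",
    "AttributionConfig",
    "CoAIModel",
    "CoAIRunner",
    "fit_coai",
    "fit_coai_no_retrain",
    "fit_coai_rfe",
    "sweep_budgets",
    "importance_by_budget",
    "predict_risk",
]


# ---------------------------------------------------------------------------
# data preparation


@dataclass(frozen=True)
class Dataset:
    """Preprocessed cohort: encoded design matrix, labels, split tags."""

    X: pd.DataFrame
    y: np.ndarray
    split: np.ndarray  # 'train' | 'val' | 'test' per sample
    group_of: dict[str, str]  # encoded column -> raw feature it came from
    train_means: np.ndarray  # per-column mean over the train split (post-processing)

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(self.X.columns)

    def rows(self, tag: str) -> np.ndarray:
        return np.flatnonzero(self.split == tag)

    def matrix(self, tag: str) -> np.ndarray:
        return self.X.to_numpy(float)[self.rows(tag)]

    def labels(self, tag: str) -> np.ndarray:
        return self.y[self.rows(tag)]


def _derive_seeds(seed: int) -> tuple[int, int, int]:
    """One pipeline seed -> (split, model, attribution) seeds, all < 2^31."""
    ss = np.random.SeedSequence(seed)
    a, b, c = (int(s) % (2**31 - 1) for s in ss.generate_state(3))
    return a, b, c


def preprocess(
    raw: pd.DataFrame,
    label: str,
    categorical: Sequence[str] | None = None,
    fractions: tuple[float, float, float] = (0.64, 0.16, 0.20),
    seed: int = 0,
    standardize: bool = True,
) -> Dataset:
    """Encode, split, impute and standardize a raw cohort.

    Categorical columns (autodetected from dtype unless listed) are one-hot
    encoded; all indicator columns of one categorical share its group — and
    hence, downstream, its acquisition cost. Samples are split by a seeded
    shuffle into train/validation/test (default 64/16/20). Missing values
    are imputed with *train-split* means and standardization uses
    *train-split* statistics, so nothing about validation or test samples
    leaks into the transform.
    """
    if label not in raw.columns:
        raise ValueError(f"label column {label!r} not in data")
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f <= 0 for f in fractions):
        raise ValueError("split fractions must be positive and sum to 1")
    y = pd.to_numeric(raw[label]).to_numpy()
    if set(np.unique(y[~np.isnan(y)])) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    y = y.astype(int)
    feats = raw.drop(columns=[label])

    if categorical is None:
        categorical = [
            c
            for c in feats.columns
            if isinstance(feats[c].dtype, pd.CategoricalDtype) or feats[c].dtype == object
        ]
    categorical = list(categorical)

    group_of: dict[str, str] = {}
    encoded = {}
    for c in feats.columns:
        if c in categorical:
            col = feats[c].astype("category")
            if col.isna().any():
                col = col.cat.add_categories(["__missing__"]).fillna("__missing__")
            dummies = pd.get_dummies(col, prefix=c, dtype=float)
            for dc in dummies.columns:
                group_of[dc] = c
                encoded[dc] = dummies[dc]
        else:
            encoded[c] = pd.to_numeric(feats[c]).astype(float)
            group_of[c] = c
    X = pd.DataFrame(encoded, index=feats.index)

    n = len(X)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    split = np.empty(n, dtype=object)
    split[perm[:n_train]] = "train"
    split[perm[n_train : n_train + n_val]] = "val"
    split[perm[n_train + n_val :]] = "test"

    train_rows = split == "train"
    if len(np.unique(y[train_rows])) < 2:
        raise ValueError("train split must contain both classes")

    values = X.to_numpy(float)
    train_block = values[train_rows]
    if np.isnan(train_block).all(axis=0).any():
        bad = X.columns[np.isnan(train_block).all(axis=0)]
        raise ValueError(f"all-missing feature(s) in train split: {list(bad)}")
    means = np.nanmean(train_block, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(values))
    values[nan_r, nan_c] = means[nan_c]
    if standardize:
        mu = values[train_rows].mean(axis=0)
        sd = values[train_rows].std(axis=0)
        constant = sd == 0
        if constant.any():
            warnings.warn(
                f"constant feature(s) standardized to zeros: {list(X.columns[constant])}",
                stacklevel=2,
            )
        sd = np.where(constant, 1.0, sd)
        values = (values - mu) / sd
        values[:, constant] = 0.0
    X = pd.DataFrame(values, columns=X.columns, index=X.index)
    train_means = values[train_rows].mean(axis=0)
    return Dataset(X=X, y=y, split=split.astype(str), group_of=group_of, train_means=train_means)


def encoded_cost_table(raw_costs: FeatureCostTable, data: Dataset) -> FeatureCostTable:
    """Map a raw-feature cost table onto the encoded design matrix.

    Every encoded column inherits the cost of the raw feature it came from.
    Indicator columns of one categorical form a group priced once (you
    cannot buy half a categorical); raw acquisition groups are preserved.
    The result is grouped whenever any raw feature expanded or the raw
    table was grouped.
    """
    raw_ids = set(raw_costs.feature_ids)
    unknown = {g for g in data.group_of.values()} - raw_ids
    if unknown:
        raise ValueError(f"features missing from the cost table: {sorted(unknown)}")
    cols = list(data.feature_ids)
    costs = np.array([raw_costs.cost_of(data.group_of[c]) for c in cols])
    expanded = any(data.group_of[c] != c for c in cols)
    if not expanded and not raw_costs.grouped:
        return FeatureCostTable(tuple(cols), costs)
    if raw_costs.grouped:
        group_of = {c: raw_costs.group_of[data.group_of[c]] for c in cols}
        group_costs = dict(raw_costs.group_costs)
    else:
        group_of = {c: data.group_of[c] for c in cols}
        group_costs = {data.group_of[c]: raw_costs.cost_of(data.group_of[c]) for c in cols}
    return FeatureCostTable(tuple(cols), costs, group_of, group_costs)


# ---------------------------------------------------------------------------
# base models


class BaseModelAdapter:
    """Wraps an sklearn-style classifier; counts every fit.

    Each ``fit`` clones the prototype, so every (re)training uses the same
    model class with the same hyperparameters. ``predict_score`` prefers
    the decision function (margin / log-odds) over predicted probability:
    ranking metrics are unchanged and linear models stay exactly linear in
    their inputs, which makes the closed-form attribution exact.
    """

    def __init__(self, prototype):
        self.prototype = prototype
        self.training_count = 0

    def fit(self, X, y):
        est = clone(self.prototype)
        est.fit(np.asarray(X, dtype=float), np.asarray(y))
        self.training_count += 1
        return est

    @staticmethod
    def predict_score(est, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(X), dtype=float).ravel()
        return np.asarray(est.predict_proba(X), dtype=float)[:, 1]

    @staticmethod
    def is_linear(est) -> bool:
        return hasattr(est, "coef_") and hasattr(est, "intercept_")


def gbm_adapter(seed: int = 0, **overrides) -> BaseModelAdapter:
    """Gradient-boosted trees: learning rate 0.01, <=1000 trees, early stopping 100."""
    params = dict(
        learning_rate=0.01,
        max_iter=1000,
        early_stopping=True,
        n_iter_no_change=100,
        validation_fraction=0.15,
        random_state=seed,
    )
    params.update(overrides)
    return BaseModelAdapter(HistGradientBoostingClassifier(**params))


def linear_adapter(seed: int = 0, **overrides) -> BaseModelAdapter:
    """L2 logistic regression; scored on the log-odds scale."""
    params = dict(C=1.0, max_iter=2000, random_state=seed)
    params.update(overrides)
    return BaseModelAdapter(LogisticRegression(**params))


# ---------------------------------------------------------------------------
# attribution of a fitted model to a global importance vector


@dataclass(frozen=True)
class AttributionConfig:
    """How per-feature importances are computed on a fitted model.

    ``method='auto'`` uses the exact closed form for linear estimators and
    permutation sampling otherwise. Importances are computed on the
    validation split (never test), against a background sampled from the
    train split.
    """

    method: str = "auto"  # auto | linear | sampled | exact
    reduction: str = "mean_abs"  # or sum_abs
    eval_split: str = "val"
    max_eval_samples: int = 200
    n_background: int = 50
    n_permutations: int = 30


def _global_phi(
    adapter: BaseModelAdapter,
    est,
    data: Dataset,
    feature_idx: np.ndarray,
    config: AttributionConfig,
    seed: int,
) -> np.ndarray:
    """Global importance of each feature in ``feature_idx`` for ``est``."""
    rng = np.random.default_rng(seed)
    X_eval = data.matrix(config.eval_split)[:, feature_idx]
    if X_eval.shape[0] > config.max_eval_samples:
        pick = rng.choice(X_eval.shape[0], config.max_eval_samples, replace=False)
        X_eval = X_eval[pick]
    X_train = data.matrix("train")[:, feature_idx]

    method = config.method
    if method == "auto":
        method = "linear" if adapter.is_linear(est) else "sampled"
    if method == "linear":
        if not adapter.is_linear(est):
            raise ValueError("linear attribution requires a linear estimator")
        w = np.asarray(est.coef_, dtype=float).ravel()
        mu = X_train.mean(axis=0)
        values = w[None, :] * (X_eval - mu[None, :])
        intercept = float(np.ravel(est.intercept_)[0])
        A = attr.AttributionMatrix(values, intercept + float(w @ mu))
    else:
        n_bg = min(config.n_background, X_train.shape[0])
        bg = attr.BackgroundSet(X_train[rng.choice(X_train.shape[0], n_bg, replace=False)])
        fn = lambda rows: adapter.predict_score(est, rows)  # noqa: E731
        A = attr.attribute_samples(
            fn,
            X_eval,
            bg,
            method=method,
            n_permutations=config.n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
    return attr.global_importance(A, config.reduction)


# ---------------------------------------------------------------------------
# fitted cost-aware models


@dataclass(frozen=True)
class CoAIModel:
    """One budget-constrained model: the selection plus its predictor."""

    budget: float
    solution: BudgetSolution
    strategy: str
    feature_ids: tuple[str, ...]  # selected, in design-matrix order
    estimator: object | None
    attribution_meta: dict = field(default_factory=dict)
    no_retrain: bool = False
    full_feature_ids: tuple[str, ...] | None = None
    train_means: np.ndarray | None = None  # aligned with full_feature_ids
    constant_score: float | None = None
    adapter: BaseModelAdapter | None = None

    @property
    def realized_cost(self) -> float:
        return self.solution.realized_cost


def predict_risk(model: CoAIModel, X) -> np.ndarray:
    """Score new samples with a fitted budget-constrained model.

    ``X`` may be a data frame with (at least) the model's selected columns,
    or an array aligned with the full design matrix the model was built
    from. Columns outside the selection are ignored (or, for a no-retrain
    model, replaced by training means).
    """
    if model.estimator is None:
        n = len(X)
        return np.full(n, 0.0 if model.constant_score is None else model.constant_score)
    full = list(model.full_feature_ids or model.feature_ids)
    if isinstance(X, pd.DataFrame):
        if model.no_retrain:
            missing = [c for c in full if c not in X.columns]
            if missing:
                raise KeyError(f"missing model features: {missing}")
            mat = X[full].to_numpy(float)
        else:
            missing = [c for c in model.feature_ids if c not in X.columns]
            if missing:
                raise KeyError(f"missing model features: {missing}")
            mat = X[list(model.feature_ids)].to_numpy(float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.shape[1] != len(full):
            raise ValueError(
                f"array input must have the {len(full)} columns of the full design matrix"
            )
        if not model.no_retrain:
            sel = [full.index(f) for f in model.feature_ids]
            mat = mat[:, sel]
    if model.no_retrain:
        sel = np.isin(np.array(full), np.array(model.feature_ids))
        masked = np.where(sel[None, :], mat, model.train_means[None, :])
        return model.adapter.predict_score(model.estimator, masked)
    return model.adapter.predict_score(model.estimator, mat)


# ---------------------------------------------------------------------------
# the runner: caches the full model and its importances across budgets


class CoAIRunner:
    """Caches the full-feature fit and its importance vector across budgets.

    The first budget costs two trainings (full fit + restricted refit);
    every further budget reuses the cached attribution and costs one.
    """

    def __init__(
        self,
        data: Dataset,
        costs: FeatureCostTable,
        base: BaseModelAdapter,
        attribution: AttributionConfig | None = None,
        seed: int = 0,
    ):
        if set(costs.feature_ids) != set(data.feature_ids):
            raise ValueError("cost table must cover exactly the design-matrix columns")
        table = impute_missing_costs(costs)
        if (table.effective_costs == 0).any():
            table = apply_pseudocosts(table)
        # align cost-table order with the design matrix
        order = [table.index_of(f) for f in data.feature_ids]
        self.costs = FeatureCostTable(
            tuple(data.feature_ids),
            table.costs[order],
            dict(table.group_of) if table.grouped else None,
            dict(table.group_costs) if table.grouped else None,
            table.pseudocosts[order],
        )
        self.data = data
        self.base = base
        self.attribution = attribution or AttributionConfig()
        _, self._model_seed, self._attr_seed = _derive_seeds(seed)
        self._full_est = None
        self._phi: np.ndarray | None = None

    # -- cached pieces ----------------------------------------------------

    @property
    def full_model(self):
        if self._full_est is None:
            self._full_est = self.base.fit(self.data.matrix("train"), self.data.labels("train"))
        return self._full_est

    @property
    def importances(self) -> np.ndarray:
        if self._phi is None:
            m = len(self.data.feature_ids)
            self._phi = _global_phi(
                self.base,
                self.full_model,
                self.data,
                np.arange(m),
                self.attribution,
                self._attr_seed,
            )
        return self._phi

    # -- selection + refit --------------------------------------------------

    def _select(self, phi: np.ndarray, k: float, strategy: str) -> BudgetSolution:
        if strategy in ("knapsack", "knapsack_no_retrain"):
            if self.costs.grouped:
                return group_knapsack_select(phi, self.costs, k)
            return knapsack_select(phi, self.costs, k)
        if strategy == "greedy":
            return greedy_select(phi, self.costs, k)
        raise ValueError(f"unknown strategy: {strategy!r}")

    def _meta(self) -> dict:
        return {
            "method": self.attribution.method,
            "reduction": self.attribution.reduction,
            "eval_split": self.attribution.eval_split,
            "seed": self._attr_seed,
        }

    def _refit(self, solution: BudgetSolution, k: float, strategy: str) -> CoAIModel:
        ids = list(self.data.feature_ids)
        if not solution.selected:
            base_rate = float(self.data.labels("train").mean())
            return CoAIModel(
                budget=k,
                solution=solution,
                strategy=strategy,
                feature_ids=(),
                estimator=None,
                attribution_meta=self._meta(),
                constant_score=base_rate,
            )
        sel = [ids.index(f) for f in solution.selected]
        est = self.base.fit(self.data.matrix("train")[:, sel], self.data.labels("train"))
        return CoAIModel(
            budget=k,
            solution=solution,
            strategy=strategy,
            feature_ids=tuple(solution.selected),
            estimator=est,
            attribution_meta=self._meta(),
            adapter=self.base,
        )

    def fit(self, k: float, strategy: str = "knapsack") -> CoAIModel:
        """Build one budget-k model; see module docstring for the recipe."""
        if strategy == "rfe":
            return self._fit_rfe(k)
        solution = self._select(self.importances, k, strategy)
        affordable = np.any(self.costs.effective_costs <= k)
        if not solution.selected and k > 0 and affordable and self.importances.max() > 0:
            raise RuntimeError("empty selection despite affordable informative features")
        if strategy == "knapsack_no_retrain":
            return CoAIModel(
                budget=k,
                solution=solution,
                strategy=strategy,
                feature_ids=tuple(solution.selected),
                estimator=self.full_model,
                attribution_meta=self._meta(),
                no_retrain=True,
                full_feature_ids=self.data.feature_ids,
                train_means=self.data.train_means,
                adapter=self.base,
            )
        return self._refit(solution, k, strategy)

    def _fit_rfe(self, k: float) -> CoAIModel:
        """Recursive elimination of the worst importance-per-cost feature.

        Refits and re-attributes at every step, so feature dependence is
        tracked: removing one feature can change the others' importances.
        Grouped tables eliminate whole groups. Stops once the surviving
        set's cost fits the budget, then refits on the survivors.
        """
        data, costs = self.data, self.costs
        ids = list(data.feature_ids)
        current = list(range(len(ids)))
        grouped = costs.grouped

        def current_cost(idx: list[int]) -> float:
            return total_cost(costs, [ids[i] for i in idx])

        while current and current_cost(current) > k:
            est = self.base.fit(data.matrix("train")[:, current], data.labels("train"))
            phi = _global_phi(
                self.base, est, data, np.array(current), self.attribution, self._attr_seed
            )
            eff = costs.effective_costs[current]
            if grouped:
                # quality of a group: summed importance over its members / c_g
                by_group: dict[str, list[int]] = {}
                for pos, i in enumerate(current):
                    by_group.setdefault(costs.group_of[ids[i]], []).append(pos)
                worst_g, worst_q = None, np.inf
                for g, members in by_group.items():
                    q = phi[members].sum() / costs.group_costs[g]
                    if q < worst_q - 1e-15:
                        worst_q, worst_g = q, g
                drop = set(by_group[worst_g])
                current = [i for pos, i in enumerate(current) if pos not in drop]
            else:
                omega = phi / eff
                worst = int(np.flatnonzero(omega == omega.min())[-1])
                current.pop(worst)
        selected = tuple(ids[i] for i in current)
        groups = None
        if grouped and selected:
            seen: dict[str, None] = {}
            for f in selected:
                seen.setdefault(costs.group_of[f], None)
            groups = tuple(seen)
        solution = BudgetSolution(
            selected=selected,
            realized_cost=current_cost(current),
            total_importance=float("nan"),
            budget=float(k),
            selector="rfe",
            selected_groups=groups,
        )
        return self._refit(solution, k, "rfe")

    def sweep(self, budgets: Sequence[float], strategy: str = "knapsack"):
        """One model per budget, plus a (budget, realized cost, AUROC) curve."""
        budgets = list(budgets)
        if not budgets:
            raise ValueError("budget list is empty")
        models = [self.fit(k, strategy) for k in budgets]
        X_test = self.data.X.iloc[self.data.rows("test")]
        y_test = self.data.labels("test")
        rows = []
        for m in models:
            scores = predict_risk(m, X_test)
            a = 0.5 if np.ptp(scores) == 0 else auroc(scores, y_test)
            rows.append((m.budget, m.realized_cost, a))
        curve = pd.DataFrame(rows, columns=["budget", "realized_cost", "auroc"])
        return models, curve


# ---------------------------------------------------------------------------
# functional façade


def fit_coai(
    data: Dataset,
    costs: FeatureCostTable,
    k: float,
    base: BaseModelAdapter,
    strategy: str = "knapsack",
    attribution: AttributionConfig | None = None,
    seed: int = 0,
) -> CoAIModel:
    """Fit one budget-constrained model (two trainings for the knapsack path)."""
    if strategy == "knapsack_no_retrain":
        return fit_coai_no_retrain(data, costs, k, base, attribution, seed)
    return CoAIRunner(data, costs, base, attribution, seed).fit(k, strategy)


def fit_coai_no_retrain(
    data: Dataset,
    costs: FeatureCostTable,
    k: float,
    base: BaseModelAdapter,
    attribution: AttributionConfig | None = None,
    seed: int = 0,
) -> CoAIModel:
    """Knapsack selection without retraining: one training total.

    At prediction time the unselected features are replaced by their
    train-split means before scoring with the full model — faster to build
    than a retrained model, usually worse.
    """
    return CoAIRunner(data, costs, base, attribution, seed).fit(k, "knapsack_no_retrain")


def fit_coai_rfe(
    data: Dataset,
    costs: FeatureCostTable,
    k: float,
    base: BaseModelAdapter,
    attribution: AttributionConfig | None = None,
    seed: int = 0,
) -> CoAIModel:
    """Recursive feature elimination by importance-per-cost until under budget."""
    return CoAIRunner(data, costs, base, attribution, seed).fit(k, "rfe")


def sweep_budgets(
    data: Dataset,
    costs: FeatureCostTable,
    budgets: Sequence[float],
    base: BaseModelAdapter,
    strategy: str = "knapsack",
    attribution: AttributionConfig | None = None,
    seed: int = 0,
):
    """Fit one model per budget (cached full fit) and report the tradeoff curve."""
    runner = CoAIRunner(data, costs, base, attribution, seed)
    return runner.sweep(budgets, strategy)


def importance_by_budget(
    models: Sequence[CoAIModel],
    data: Dataset,
    base: BaseModelAdapter,
    attribution: AttributionConfig | None = None,
    seed: int = 0,
    aggregate_zero_cost: FeatureCostTable | None = None,
) -> pd.DataFrame:
    """Features x budgets importance matrix of the retrained models.

    Column k holds the global importance of every feature *in the budget-k
    model*, zero for unselected features. Membership need not be monotone
    in k: a feature picked at a small budget can be crowded out at a larger
    one. If ``aggregate_zero_cost`` is given, all its zero-cost features
    are summed into one ``zero_cost`` row.
    """
    config = attribution or AttributionConfig()
    _, _, attr_seed = _derive_seeds(seed)
    ids = list(data.feature_ids)
    mat = np.zeros((len(ids), len(models)))
    for j, m in enumerate(models):
        if m.estimator is None or not m.feature_ids:
            continue
        if m.no_retrain:
            raise ValueError("importance-by-budget needs retrained models")
        sel = np.array([ids.index(f) for f in m.feature_ids])
        phi = _global_phi(base, m.estimator, data, sel, config, attr_seed)
        mat[sel, j] = phi
    out = pd.DataFrame(mat, index=ids, columns=[m.budget for m in models])
    if aggregate_zero_cost is not None:
        zero = [f for f in ids if aggregate_zero_cost.cost_of(f) == 0]
        if zero:
            agg = out.loc[zero].sum(axis=0)
            out = out.drop(index=zero)
            out.loc["zero_cost"] = agg
    return out
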