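"""Feature acquisition-cost tables.

Costs are the budget currency of cost-aware model building: minutes of
provider time, dollars of lab fees, or simply a count of features. This
module loads and conditions per-feature cost tables — mean-imputation of
missing costs, tiny "pseudocosts" that make zero-cost features rankable,
uniform (count-the-features) costs, and grouped costs where one acquisition
action (e.g. a lab panel) unlocks several features at a single price.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FeatureCostTable",
    "load_cost_table",
    "load_group_costs",
    "impute_missing_costs",
    "apply_pseudocosts",
    "uniform_costs",
    "total_cost",
]


@dataclass(frozen=True)
class FeatureCostTable:
    """Per-feature acquisition costs, in file order.

    Parameters
    ----------
    feature_ids
        Ordered feature identifiers. File order is authoritative: it breaks
        ranking ties everywhere downstream.
    costs
        Nonnegative cost per feature; ``nan`` marks a missing (not zero)
        cost.
    group_of
        Optional map feature id -> group id. When present, every feature
        must belong to exactly one group and every referenced group must
        have a cost in ``group_costs``.
    group_costs
        Optional map group id -> nonnegative cost of acquiring the whole
        group in one action.
    pseudocosts
        Per-feature pseudocost amounts (zero until
        :func:`apply_pseudocosts` runs).
    """

    feature_ids: tuple[str, ...]
    costs: np.ndarray
    group_of: dict[str, str] | None = None
    group_costs: dict[str, float] | None = None
    pseudocosts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = tuple(str(f) for f in self.feature_ids)
        object.__setattr__(self, "feature_ids", ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in cost table")
        costs = np.asarray(self.costs, dtype=float)
        if costs.shape != (len(ids),):
            raise ValueError("costs must align with feature_ids")
        if np.any(costs[~np.isnan(costs)] < 0):
            raise ValueError("negative feature cost")
        object.__setattr__(self, "costs", costs)
        if self.pseudocosts is None:
            object.__setattr__(self, "pseudocosts", np.zeros(len(ids)))
        else:
            ps = np.asarray(self.pseudocosts, dtype=float)
            if ps.shape != costs.shape:
                raise ValueError("pseudocosts must align with feature_ids")
            object.__setattr__(self, "pseudocosts", ps)
        if (self.group_of is None) != (self.group_costs is None):
            raise ValueError("group_of and group_costs must be given together")
        if self.group_of is not None:
            missing = set(ids) - set(self.group_of)
            if missing:
                raise ValueError(f"features without a group: {sorted(missing)}")
            groups = set(self.group_of[f] for f in ids)
            uncosted = groups - set(self.group_costs)
            if uncosted:
                raise ValueError(f"groups without a cost: {sorted(uncosted)}")
            if any(c < 0 for c in self.group_costs.values()):
                raise ValueError("negative group cost")

    # -- convenience views -------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.costs).any())

    @property
    def grouped(self) -> bool:
        return self.group_of is not None

    @property
    def pseudocost_applied(self) -> bool:
        return bool(np.any(self.pseudocosts > 0))

    @property
    def effective_costs(self) -> np.ndarray:
        """Costs used for ranking/selection: original + pseudocosts."""
        return self.costs + self.pseudocosts

    @property
    def group_ids(self) -> tuple[str, ...]:
        """Groups in order of first appearance in the feature list."""
        if not self.grouped:
            raise ValueError("table has no groups")
        seen: dict[str, None] = {}
        for f in self.feature_ids:
            seen.setdefault(self.group_of[f], None)
        return tuple(seen)

    def index_of(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature id: {feature_id!r}") from None

    def cost_of(self, feature_id: str) -> float:
        return float(self.costs[self.index_of(feature_id)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature": self.feature_ids, "cost": self.costs})
        if self.grouped:
            df["group"] = [self.group_of[f] for f in self.feature_ids]
        if self.pseudocost_applied:
            df["pseudocost"] = self.pseudocosts
        return df


def load_cost_table(
    path,
    *,
    sep: str = ",",
    group_costs_path=None,
) -> FeatureCostTable:
    """Read a delimited cost file with header ``feature,cost[,group]``.

    Blank or NA cost cells are recorded as missing (``nan``), not zero.
    When a ``group`` column is present, a separate ``group,cost`` file must
    supply the group costs.
    """
    df = pd.read_csv(path, sep=sep)
    cols = {c.strip().lower(): c for c in df.columns}
    if "feature" not in cols or "cost" not in cols:
        raise ValueError("cost file must have columns 'feature' and 'cost'")
    features = df[cols["feature"]].astype(str).tolist()
    costs = pd.to_numeric(df[cols["cost"]], errors="coerce").to_numpy(float)
    # distinguish unparseable junk from genuinely blank cells
    raw = df[cols["cost"]]
    bad = np.isnan(costs) & ~raw.isna().to_numpy() & (raw.astype(str).str.strip() != "").to_numpy()
    if bad.any():
        raise ValueError(f"unparseable cost for features {list(np.array(features)[bad])}")

    group_of = None
    group_costs = None
    if "group" in cols:
        gcol = df[cols["group"]]
        if gcol.isna().any() or (gcol.astype(str).str.strip() == "").any():
            raise ValueError("group column is partially filled")
        group_of = dict(zip(features, gcol.astype(str)))
        if group_costs_path is None:
            raise ValueError("grouped cost file requires a group-cost file")
        group_costs = load_group_costs(group_costs_path, sep=sep)
    return FeatureCostTable(tuple(features), costs, group_of, group_costs)


def load_group_costs(path, *, sep: str = ",") -> dict[str, float]:
    """Read a ``group,cost`` delimited file into a mapping."""
    df = pd.read_csv(path, sep=sep)
    cols = {c.strip().lower(): c for c in df.columns}
    if "group" not in cols or "cost" not in cols:
        raise ValueError("group-cost file must have columns 'group' and 'cost'")
    groups = df[cols["group"]].astype(str)
    if groups.duplicated().any():
        raise ValueError("duplicate group ids in group-cost file")
    costs = pd.to_numeric(df[cols["cost"]], errors="raise").astype(float)
    return dict(zip(groups, costs))


def impute_missing_costs(table: FeatureCostTable) -> FeatureCostTable:
    """Replace missing costs with the mean of the non-missing ones.

    Idempotent; raises if every cost is missing.
    """
    costs = table.costs
    mask = np.isnan(costs)
    if not mask.any():
        return table
    if mask.all():
        raise ValueError("cannot impute: all costs are missing")
    filled = costs.copy()
    filled[mask] = costs[~mask].mean()
    return replace(table, costs=filled)


def apply_pseudocosts(table: FeatureCostTable) -> FeatureCostTable:
    """Give each zero-cost feature a tiny positive pseudocost.

    Zero-cost features (e.g. information already present at dispatch) are
    always free to include, but a zero cost makes importance-per-cost
    ratios undefined and leaves zero-cost features unrankable. Each one
    receives ``eps = g / (2 * (z + 1))`` where ``g`` is the minimum gap
    between distinct nonzero costs and ``z`` the number of zero-cost
    features, so the *sum* of pseudocosts stays strictly below ``g`` and no
    feasible selection at any budget that separates two nonzero costs is
    altered. With fewer than two distinct nonzero costs the gap is taken to
    be the minimum nonzero cost.
    """
    if table.has_missing:
        raise ValueError("impute missing costs before applying pseudocosts")
    costs = table.costs
    zero = costs == 0
    if not zero.any():
        return table
    nonzero = np.unique(costs[costs > 0])
    if nonzero.size == 0:
        raise ValueError("all costs are zero: no gap to derive a pseudocost from")
    if nonzero.size >= 2:
        gap = float(np.diff(nonzero).min())
    else:
        gap = float(nonzero.min())
    z = int(zero.sum())
    eps = gap / (2.0 * (z + 1))
    pseudo = np.where(zero, eps, 0.0)
    return replace(table, pseudocosts=pseudo)


def uniform_costs(feature_ids) -> FeatureCostTable:
    """Unit cost per feature, so budgets simply count features."""
    ids = tuple(str(f) for f in feature_ids)
    if not ids:
        raise ValueError("empty feature list")
    return FeatureCostTable(ids, np.ones(len(ids)))


def total_cost(table: FeatureCostTable, subset) -> float:
    """Total acquisition cost of a subset of feature ids (or group ids).

    With grouped costs, a feature subset is charged once per distinct group
    touched — acquiring one member of a panel acquires the panel.
    """
    subset = list(subset)
    if not subset:
        return 0.0
    ids = set(table.feature_ids)
    if table.grouped:
        groups = set(table.group_costs)
        if all(s in groups for s in subset) and not all(s in ids for s in subset):
            touched = set(subset)
        else:
            unknown = [s for s in subset if s not in ids]
            if unknown:
                raise KeyError(f"unknown ids: {unknown}")
            touched = {table.group_of[f] for f in subset}
        return float(sum(table.group_costs[g] for g in touched))
    unknown = [s for s in subset if s not in ids]
    if unknown:
        raise KeyError(f"unknown ids: {unknown}")
    idx = [table.index_of(f) for f in subset]
    return float(table.costs[idx].sum())
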