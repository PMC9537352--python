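"""Synthetic clinical-style tabular cohorts with known ground truth.

Real cohorts for budget-constrained risk modelling (prehospital trauma, ICU
mortality, outpatient survey follow-up) are access-controlled, so every
pipeline stage is exercised instead on generated data whose optimal answers
are known in closed form.

The generative model is class-conditional independent Gaussians: a binary
outcome ``y ~ Bernoulli(prevalence)`` and feature ``j ~ Normal(d_j * y,
1)``, where ``d_j`` is the feature's effect size (class-mean separation in
SD units). Under this model the Bayes-optimal score on a feature subset S
is linear, and its AUROC is ``Phi(||d_S||_2 / sqrt(2))`` — an exact oracle
for what any budgeted model can achieve. Categorical features are emulated
by quantile-binning a latent Gaussian; all indicator columns of one
categorical share its group and cost. An optional equicorrelation mode
exists for stress tests but carries no closed-form claims.

Templates mirror the structure of three clinical settings: a trauma-like
cohort (~45 mixed features, per-feature time costs in minutes including
zero-cost dispatch/procedure information), an ICU-like cohort (unit costs —
budget counts features), and an outpatient-like cohort (27 acquisition
groups giving 35 features, expanding to ~118 one-hot columns, dollar
costs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cost_model import FeatureCostTable, total_cost

__all__ = [
    "FeatureBlock",
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "bayes_auroc",
    "true_best_subset",
    "trauma_like",
    "icu_like",
    "outpatient_like",
]


@dataclass(frozen=True)
class FeatureBlock:
    """One generated feature: effect size, acquisition cost, optional group."""

    name: str
    effect: float
    cost: float
    group: str | None = None
    kind: str = "continuous"  # or "categorical"
    levels: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect):
            raise ValueError("effect size must be finite")
        if self.cost < 0:
            raise ValueError("cost must be nonnegative")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown feature kind: {self.kind!r}")
        if self.kind == "categorical" and self.levels < 2:
            raise ValueError("categorical features need >= 2 levels")


@dataclass(frozen=True)
class SyntheticSpec:
    """A stated world: cohort size, per-feature effects/costs, prevalence."""

    blocks: tuple[FeatureBlock, ...]
    n_samples: int = 5000
    prevalence: float = 0.06
    noise_features: int = 0
    noise_cost: float = 1.0
    correlation: float = 0.0  # equicorrelation of the Gaussian noise
    label: str = "outcome"

    def __post_init__(self) -> None:
        blocks = tuple(self.blocks)
        object.__setattr__(self, "blocks", blocks)
        if not blocks or all(b.effect == 0 for b in blocks):
            raise ValueError("need at least one informative feature block")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be strictly inside (0, 1)")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0 <= self.correlation < 1:
            raise ValueError("equicorrelation must be in [0, 1)")
        names = [b.name for b in self.all_blocks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")

    @property
    def all_blocks(self) -> tuple[FeatureBlock, ...]:
        noise = tuple(
            FeatureBlock(f"noise_{i+1}", 0.0, self.noise_cost)
            for i in range(self.noise_features)
        )
        return self.blocks + noise

    @property
    def is_independent_gaussian(self) -> bool:
        return self.correlation == 0 and all(
            b.kind == "continuous" for b in self.all_blocks
        )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows: per-feature effects, costs, groups."""

    effects: dict[str, float]
    costs: dict[str, float]
    group_of: dict[str, str | None]
    prevalence: float


def _cost_table(spec: SyntheticSpec) -> FeatureCostTable:
    blocks = spec.all_blocks
    ids = tuple(b.name for b in blocks)
    costs = np.array([b.cost for b in blocks], dtype=float)
    if any(b.group is not None for b in blocks):
        group_of = {b.name: (b.group if b.group is not None else b.name) for b in blocks}
        group_costs: dict[str, float] = {}
        for b in blocks:
            g = group_of[b.name]
            if g in group_costs and group_costs[g] != b.cost:
                raise ValueError(f"group {g!r} has inconsistent member costs")
            group_costs[g] = b.cost
        return FeatureCostTable(ids, costs, group_of, group_costs)
    return FeatureCostTable(ids, costs)


def generate(
    spec: SyntheticSpec, seed: int = 0
) -> tuple[pd.DataFrame, FeatureCostTable, GroundTruth]:
    """Draw one cohort; bit-identical for a fixed seed.

    Returns a raw data frame (label column included, categoricals as string
    levels), the matching cost table, and the generating ground truth.
    """
    rng = np.random.default_rng(seed)
    blocks = spec.all_blocks
    n, m = spec.n_samples, len(blocks)
    y = (rng.random(n) < spec.prevalence).astype(int)
    d = np.array([b.effect for b in blocks])
    if spec.correlation > 0:
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, m))
        noise = np.sqrt(spec.correlation) * shared + np.sqrt(1 - spec.correlation) * own
    else:
        noise = rng.standard_normal((n, m))
    latent = d[None, :] * y[:, None] + noise

    df = pd.DataFrame(index=np.arange(n))
    for j, b in enumerate(blocks):
        col = latent[:, j]
        if b.kind == "categorical":
            qs = np.quantile(col, np.linspace(0, 1, b.levels + 1)[1:-1])
            codes = np.searchsorted(qs, col)
            df[b.name] = pd.Categorical(
                [f"L{c}" for c in codes], categories=[f"L{i}" for i in range(b.levels)]
            )
        else:
            df[b.name] = col
    df[spec.label] = y

    truth = GroundTruth(
        effects={b.name: b.effect for b in blocks},
        costs={b.name: b.cost for b in blocks},
        group_of={b.name: b.group for b in blocks},
        prevalence=spec.prevalence,
    )
    return df, _cost_table(spec), truth


def bayes_auroc(spec: SyntheticSpec, subset) -> float:
    """AUROC of the Bayes-optimal score restricted to ``subset``.

    For independent unit-variance Gaussians with class-mean shift d_j, the
    optimal score is d_S . x_S; its class-conditional distributions are
    Normal(0, ||d_S||^2) and Normal(||d_S||^2, ||d_S||^2), giving
    AUROC = Phi(||d_S||_2 / sqrt(2)). The empty subset scores 0.5.
    """
    if not spec.is_independent_gaussian:
        raise ValueError("closed-form AUROC needs the independent-Gaussian spec")
    effects = {b.name: b.effect for b in spec.all_blocks}
    unknown = [s for s in subset if s not in effects]
    if unknown:
        raise KeyError(f"unknown features: {unknown}")
    d = np.array([effects[s] for s in subset])
    if d.size == 0 or np.all(d == 0):
        return 0.5
    return float(norm.cdf(np.linalg.norm(d) / np.sqrt(2)))


def true_best_subset(spec: SyntheticSpec, k: float) -> tuple[str, ...]:
    """Brute-force feature set maximizing Bayes AUROC within budget ``k``.

    Equivalently maximizes ||d_S||_2 subject to total cost <= k (grouped
    costs charged once per group). Ties: lower cost, then file order —
    matching the selectors' tie-break. Capped at 20 features.
    """
    blocks = spec.all_blocks
    if not spec.is_independent_gaussian:
        raise ValueError("closed-form subset oracle needs the independent-Gaussian spec")
    m = len(blocks)
    if m > 20:
        raise ValueError("brute-force oracle is capped at 20 features")
    table = _cost_table(spec)
    d2 = np.array([b.effect**2 for b in blocks])
    best: tuple[float, float, tuple[int, ...]] | None = None
    for mask in range(2**m):
        idx = tuple(i for i in range(m) if mask >> i & 1)
        names = [blocks[i].name for i in idx]
        c = total_cost(table, names)
        if c > k + 1e-12:
            continue
        v = float(d2[list(idx)].sum())
        key = (-v, c, idx)
        if best is None or key < (-best[0], best[1], best[2]):
            best = (v, c, idx)
    assert best is not None
    return tuple(blocks[i].name for i in best[2])


# ---------------------------------------------------------------------------
# cohort templates


def trauma_like(n_samples: int = 5000, prevalence: float = 0.06) -> SyntheticSpec:
    """Prehospital-trauma-style cohort: 45 features, time costs in minutes.

    Six dispatch/procedure features carry zero cost (the information is
    already present when the call comes in); vitals and exam features cost
    0.25–3 minutes. Effect sizes taper so that which features are worth the
    time depends on the budget.
    """
    blocks = []
    for i in range(6):
        blocks.append(FeatureBlock(f"dispatch_{i+1}", 0.9 - 0.1 * i, 0.0))
    vital_costs = [0.25, 0.5, 0.5, 0.75, 1.0, 1.0, 1.5, 1.5, 2.0, 2.0, 2.5, 3.0]
    for i, c in enumerate(vital_costs):
        blocks.append(FeatureBlock(f"vital_{i+1}", 1.0 - 0.06 * i, c))
    for i in range(27):
        blocks.append(FeatureBlock(f"exam_{i+1}", max(0.3 - 0.012 * i, 0.0), 0.5 + 0.1 * (i % 5)))
    return SyntheticSpec(tuple(blocks), n_samples=n_samples, prevalence=prevalence)


def icu_like(n_samples: int = 5000, prevalence: float = 0.09) -> SyntheticSpec:
    """ICU-style cohort: 43 features, unit costs — the budget counts features."""
    blocks = [
        FeatureBlock(f"icu_{i+1}", max(1.1 * 0.88**i, 0.02), 1.0) for i in range(43)
    ]
    return SyntheticSpec(tuple(blocks), n_samples=n_samples, prevalence=prevalence)


def outpatient_like(n_samples: int = 5000, prevalence: float = 0.2) -> SyntheticSpec:
    """Outpatient-style cohort with grouped dollar costs.

    27 acquisition groups (exam findings and lab panels) give rise to 35
    raw features; 12 of them are categorical and one-hot expand the design
    matrix to 118 columns. Zero-dollar exam groups coexist with costly lab
    panels.
    """
    blocks: list[FeatureBlock] = []
    # 19 singleton continuous groups: free exam findings + priced labs
    for i in range(10):
        blocks.append(FeatureBlock(f"exam_{i+1}", 0.55 - 0.04 * i, 0.0, group=f"g_exam_{i+1}"))
    for i in range(9):
        blocks.append(
            FeatureBlock(f"lab_{i+1}", 0.8 - 0.06 * i, 8.0 + 3.0 * i, group=f"g_lab_{i+1}")
        )
    # 8 multi-feature groups (panels) covering the remaining 16 features;
    # 12 of these are categorical with level counts summing to 95, so the
    # one-hot design is 23 continuous + 95 indicators = 118 columns.
    levels = [8, 8, 8, 8, 8, 8, 8, 8, 8, 8, 8, 7]
    for p in range(8):
        gname = f"g_panel_{p+1}"
        gcost = 15.0 + 5.0 * p
        for q in range(2):
            j = 2 * p + q  # first 12 of the 16 panel features are categorical
            blocks.append(
                FeatureBlock(
                    f"panel_{p+1}_{q+1}",
                    0.5 - 0.025 * j,
                    gcost,
                    group=gname,
                    kind="categorical" if j < 12 else "continuous",
                    levels=levels[j] if j < 12 else 0,
                )
            )
    return SyntheticSpec(tuple(blocks), n_samples=n_samples, prevalence=prevalence)
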