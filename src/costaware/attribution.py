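"""Additive per-feature attribution for arbitrary scoring functions.

A fitted risk model's output for one patient is decomposed into per-feature
Shapley values: the permutation-averaged change in the (background-masked)
model output when a feature's value is revealed. Summing a sample's
attributions plus the base value reproduces the model output exactly (local
accuracy), and reducing |phi_ij| over samples gives the global importance
vector that drives budget-constrained feature selection.

Masking is interventional: a feature outside the "observed" subset S is
replaced by values drawn from a background set (typically the training
split or its mean), matching the mean-imputation used at preprocessing.

Three computational routes are provided:

- :func:`shapley_exact` — the subset-weighted reformulation of the
  permutation average, exact up to float error; 2^M model evaluations, so
  capped at M <= 12.
- :func:`shapley_sampled` — an unbiased Monte-Carlo estimate over random
  feature permutations; the portable route for any model.
- :func:`linear_attribution` — closed form for linear scores,
  phi_i = w_i (x_i - mean_i).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BackgroundSet",
    "AttributionMatrix",
    "masked_score",
    "shapley_exact",
    "shapley_sampled",
    "linear_attribution",
    "global_importance",
    "attribute_samples",
]

EXACT_MODE_LIMIT = 12

ScoringFn = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class BackgroundSet:
    """Reference samples used to estimate masked (conditional) expectations."""

    samples: np.ndarray

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if arr.size == 0:
            raise ValueError("background set must be nonempty")
        object.__setattr__(self, "samples", arr)

    @property
    def n_features(self) -> int:
        return self.samples.shape[1]

    @property
    def means(self) -> np.ndarray:
        return self.samples.mean(axis=0)


@dataclass(frozen=True)
class AttributionMatrix:
    """Per-sample attributions phi_ij plus the no-features base value."""

    values: np.ndarray  # samples x features
    base_values: np.ndarray  # per sample (constant for a fixed background)
    feature_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        b = np.broadcast_to(np.asarray(self.base_values, dtype=float), (v.shape[0],)).copy()
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "base_values", b)

    def to_frame(self) -> pd.DataFrame:
        cols = self.feature_ids or [f"f{i}" for i in range(self.values.shape[1])]
        df = pd.DataFrame(self.values, columns=list(cols))
        df["base_value"] = self.base_values
        return df


def _as_fn(fn: ScoringFn) -> ScoringFn:
    return fn


def _check_x(x, m: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != m:
        raise ValueError(f"feature vector has {x.shape[0]} entries, expected {m}")
    return x


def masked_score(fn: ScoringFn, x, S: Sequence[int], bg: BackgroundSet) -> float:
    """E[f | features in S observed], via interventional replacement.

    Background rows keep their own values outside ``S``; coordinates in
    ``S`` are overwritten with ``x``. With ``S`` = all features this is
    ``fn(x)`` exactly; with ``S`` empty it is the background mean score.
    """
    x = _check_x(x, bg.n_features)
    S = np.asarray(sorted(set(int(i) for i in S)), dtype=int)
    if S.size and (S.min() < 0 or S.max() >= bg.n_features):
        raise ValueError("subset indices out of range")
    rows = bg.samples.copy()
    if S.size:
        rows[:, S] = x[S]
    return float(np.mean(fn(rows)))


def _all_masked_scores(fn: ScoringFn, x: np.ndarray, bg: BackgroundSet) -> np.ndarray:
    """Masked score for every one of the 2^M feature subsets (bitmask order)."""
    m = bg.n_features
    n_bg = bg.samples.shape[0]
    masks = np.arange(2**m, dtype=np.int64)
    observed = (masks[:, None] >> np.arange(m)) & 1  # 2^M x M
    big = np.repeat(bg.samples[None, :, :], 2**m, axis=0)  # 2^M x n_bg x M
    big = np.where(observed[:, None, :].astype(bool), x[None, None, :], big)
    scores = fn(big.reshape(-1, m)).reshape(2**m, n_bg)
    return scores.mean(axis=1)


def shapley_exact(fn: ScoringFn, x, bg: BackgroundSet) -> tuple[np.ndarray, float]:
    """Exact Shapley attribution of ``fn(x)`` against the background.

    Computes the permutation average through its subset reformulation:
    phi_i = sum over S not containing i of |S|!(M-|S|-1)!/M! *
    [v(S + i) - v(S)], where v is :func:`masked_score`. Returns
    ``(phi, base)`` with ``base = v(empty)``; ``phi.sum() + base``
    equals ``fn(x)`` to float precision.
    """
    x = _check_x(x, bg.n_features)
    m = bg.n_features
    if m > EXACT_MODE_LIMIT:
        raise ValueError(
            f"exact mode is capped at M={EXACT_MODE_LIMIT} features "
            f"(got {m}); use shapley_sampled"
        )
    v = _all_masked_scores(fn, x, bg)
    masks = np.arange(2**m, dtype=np.int64)
    sizes = np.array([bin(mask).count("1") for mask in masks])
    fact = np.array([math.factorial(i) for i in range(m + 1)], dtype=float)
    phi = np.zeros(m)
    for i in range(m):
        bit = 1 << i
        without = masks[(masks & bit) == 0]
        s = sizes[without]
        w = fact[s] * fact[m - s - 1] / fact[m]
        phi[i] = float(np.sum(w * (v[without | bit] - v[without])))
    return phi, float(v[0])


def shapley_sampled(
    fn: ScoringFn,
    x,
    bg: BackgroundSet,
    n_permutations: int = 200,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, float]:
    """Monte-Carlo Shapley attribution over random feature permutations.

    Unbiased for the exact value; the standard error of each phi_i shrinks
    as 1/sqrt(n_permutations). Deterministic for a fixed seed.
    """
    x = _check_x(x, bg.n_features)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    m = bg.n_features
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_bg = bg.samples.shape[0]
    phi = np.zeros(m)
    base = float(np.mean(fn(bg.samples)))
    for _ in range(n_permutations):
        order = rng.permutation(m)
        # stage t has the first t features of the permutation revealed
        stages = np.repeat(bg.samples[None, :, :], m + 1, axis=0)
        revealed = np.zeros(m, dtype=bool)
        for t, j in enumerate(order, start=1):
            revealed = revealed.copy()
            revealed[j] = True
            stages[t, :, revealed] = x[revealed, None]
        scores = fn(stages.reshape(-1, m)).reshape(m + 1, n_bg).mean(axis=1)
        phi[order] += np.diff(scores)
    return phi / n_permutations, base


def shapley_enumerated(fn: ScoringFn, x, bg: BackgroundSet) -> tuple[np.ndarray, float]:
    """Average over *all* M! permutations — a brute-force oracle for tests."""
    x = _check_x(x, bg.n_features)
    m = bg.n_features
    if m > 6:
        raise ValueError("full permutation enumeration is only for tiny M")
    phi = np.zeros(m)
    base = masked_score(fn, x, [], bg)
    for order in itertools.permutations(range(m)):
        prev = base
        S: list[int] = []
        for j in order:
            S.append(j)
            cur = masked_score(fn, x, S, bg)
            phi[j] += cur - prev
            prev = cur
    return phi / math.factorial(m), base


def linear_attribution(weights, intercept: float, bg_means, x) -> tuple[np.ndarray, float]:
    """Closed-form attribution for a linear score w.x + b.

    phi_i = w_i (x_i - mean_i); base = b + w.means. Coincides with the
    exact Shapley value of the linear function under interventional
    masking, for any background with the given means.
    """
    w = np.asarray(weights, dtype=float).ravel()
    mu = np.asarray(bg_means, dtype=float).ravel()
    x = _check_x(x, w.shape[0])
    if mu.shape != w.shape:
        raise ValueError("bg means must align with weights")
    phi = w * (x - mu)
    base = float(intercept + w @ mu)
    return phi, base


def global_importance(A: AttributionMatrix, reduction: str = "mean_abs") -> np.ndarray:
    """Reduce per-sample attributions to one nonnegative importance per feature.

    ``mean_abs`` (default) and ``sum_abs`` differ by the constant factor n,
    so any budget-constrained selection is invariant to the choice.
    """
    vals = A.values
    if vals.shape[0] == 0:
        raise ValueError("attribution matrix has no samples")
    if reduction == "mean_abs":
        return np.abs(vals).mean(axis=0)
    if reduction == "sum_abs":
        return np.abs(vals).sum(axis=0)
    raise ValueError(f"unknown reduction: {reduction!r}")


def attribute_samples(
    fn: ScoringFn,
    X,
    bg: BackgroundSet,
    method: str = "sampled",
    n_permutations: int = 200,
    seed: int = 0,
    feature_ids: tuple[str, ...] | None = None,
) -> AttributionMatrix:
    """Attribute every row of ``X``, returning an :class:`AttributionMatrix`."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rng = np.random.default_rng(seed)
    rows = []
    base = 0.0
    for x in X:
        if method == "exact":
            phi, base = shapley_exact(fn, x, bg)
        elif method == "sampled":
            phi, base = shapley_sampled(fn, x, bg, n_permutations, rng)
        else:
            raise ValueError(f"unknown attribution method: {method!r}")
        rows.append(phi)
    return AttributionMatrix(np.array(rows), base, feature_ids)
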