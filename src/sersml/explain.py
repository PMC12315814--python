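"""Model interpretation: Shapley values (local attribution) and partial-
dependence curves (global response).

Shapley values use the interventional (marginal) convention: a feature absent
from a coalition is imputed from background rows.  Exact enumeration is
available up to 12 features; beyond that a permutation-sampling estimator is
used.  ``model_fn`` must accept an (m, p) matrix of feature rows and return m
scalar scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, InputError

EXACT_FEATURE_LIMIT = 12


@dataclass
class ShapleyExplanation:
    feature_ids: np.ndarray
    phi: np.ndarray
    baseline_value: float          # mean model output over the background set
    prediction: float              # model output at the query point
    target_class: str | None = None
    phi_se: np.ndarray | None = None  # Monte-Carlo standard error (sampled mode)


@dataclass
class PDPCurve:
    feature_id: object
    grid: np.ndarray
    values: np.ndarray


def _as_background(background: np.ndarray) -> np.ndarray:
    bg = np.atleast_2d(np.asarray(background, float))
    if bg.size == 0:
        raise InputError("background set must be non-empty")
    return bg


def shapley_values(
    model_fn,
    background: np.ndarray,
    x_query: np.ndarray,
    mode: str = "exact",
    n_perm: int = 2000,
    seed: int = 0,
    feature_ids: np.ndarray | None = None,
    target_class: str | None = None,
) -> ShapleyExplanation:
    """Per-feature attribution of ``model_fn(x_query)`` against the background
    mean, satisfying efficiency: ``sum(phi) = f(x) - baseline`` (exactly in
    exact mode, to Monte-Carlo tolerance in sampled mode)."""
    background = _as_background(background)
    x = np.asarray(x_query, float).ravel()
    p = x.size
    if background.shape[1] != p:
        raise InputError("background and query dimensions differ")
    ids = np.arange(p) if feature_ids is None else np.asarray(feature_ids)
    baseline = float(np.mean(model_fn(background)))
    prediction = float(np.asarray(model_fn(x[None, :])).ravel()[0])
    if mode == "exact":
        if p > EXACT_FEATURE_LIMIT:
            raise ConfigurationError(
                f"exact mode supports at most {EXACT_FEATURE_LIMIT} features, got {p}"
            )
        phi = _shapley_exact(model_fn, background, x)
        se = None
    elif mode == "sampled":
        phi, se = _shapley_sampled(model_fn, background, x, n_perm, seed)
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    return ShapleyExplanation(ids, phi, baseline, prediction, target_class, se)


def _shapley_exact(model_fn, background: np.ndarray, x: np.ndarray) -> np.ndarray:
    p = x.size
    n_bg = background.shape[0]
    n_subsets = 1 << p
    # v[S] = mean over background rows of f(row with S features from x)
    v = np.empty(n_subsets)
    masks = np.zeros((n_subsets, p), dtype=bool)
    for s in range(n_subsets):
        masks[s] = [(s >> i) & 1 for i in range(p)]
    chunk = max(1, 2**22 // max(1, n_bg * p))
    for start in range(0, n_subsets, chunk):
        block = masks[start : start + chunk]                       # (B, p)
        z = np.where(block[:, None, :], x[None, None, :], background[None, :, :])
        flat = z.reshape(-1, p)
        v[start : start + len(block)] = (
            np.asarray(model_fn(flat)).reshape(len(block), n_bg).mean(axis=1)
        )
    fact = [math.factorial(i) for i in range(p + 1)]
    weight = np.array(
        [fact[s] * fact[p - s - 1] / fact[p] for s in range(p)]
    )
    sizes = masks.sum(axis=1)
    phi = np.zeros(p)
    for i in range(p):
        without = ~masks[:, i]
        s_idx = np.flatnonzero(without)
        phi[i] = np.sum(weight[sizes[s_idx]] * (v[s_idx | (1 << i)] - v[s_idx]))
    return phi


def _shapley_sampled(
    model_fn, background: np.ndarray, x: np.ndarray, n_perm: int, seed: int
) -> np.ndarray:
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    p = x.size
    rng = np.random.default_rng(seed)
    total = np.zeros(p)
    total_sq = np.zeros(p)
    for _ in range(n_perm):
        order = rng.permutation(p)
        row = background[rng.integers(background.shape[0])]
        # p+1 states: feature j of the permutation switched on at step j+1
        states = np.tile(row, (p + 1, 1))
        switched = np.zeros(p, dtype=bool)
        for step, feat in enumerate(order):
            switched[feat] = True
            states[step + 1, switched] = x[switched]
        values = np.asarray(model_fn(states)).ravel()
        contrib = np.empty(p)
        contrib[order] = np.diff(values)
        total += contrib
        total_sq += contrib**2
    phi = total / n_perm
    if n_perm > 1:
        var = (total_sq - n_perm * phi**2) / (n_perm - 1)
        se = np.sqrt(np.maximum(var, 0.0) / n_perm)
    else:
        se = np.full(p, np.inf)
    return phi, se


def shapley_summary(explanations: list[ShapleyExplanation]) -> list[tuple[object, float]]:
    """Rank features by the mean of |phi| across explanations, descending;
    ties broken by ascending feature id."""
    if not explanations:
        raise InputError("need at least one explanation")
    ids = explanations[0].feature_ids
    for e in explanations[1:]:
        if len(e.feature_ids) != len(ids) or not np.all(e.feature_ids == ids):
            raise InputError("explanations have mismatched feature sets")
    mean_abs = np.mean([np.abs(e.phi) for e in explanations], axis=0)
    order = sorted(range(len(ids)), key=lambda i: (-mean_abs[i], ids[i]))
    return [(ids[i], float(mean_abs[i])) for i in order]


def partial_dependence(
    model_fn, x: np.ndarray, feature: int, grid: np.ndarray
) -> PDPCurve:
    """PDP(v) = mean over data rows of ``model_fn(row with feature := v)``."""
    x = np.atleast_2d(np.asarray(x, float))
    if x.size == 0:
        raise InputError("X must be non-empty")
    grid = np.asarray(grid, float)
    if not np.all(np.diff(grid) > 0):
        raise ConfigurationError("grid must be strictly increasing")
    lo, hi = x[:, feature].min(), x[:, feature].max()
    if grid[0] < lo or grid[-1] > hi:
        warnings.warn(
            f"grid extends beyond the observed range [{lo:g}, {hi:g}] of feature {feature}"
        )
    values = np.empty(grid.size)
    for g, v in enumerate(grid):
        mod = x.copy()
        mod[:, feature] = v
        values[g] = float(np.mean(model_fn(mod)))
    return PDPCurve(feature_id=feature, grid=grid, values=values)
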