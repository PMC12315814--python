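"""Soft-margin support vector machine solved in the dual by sequential
minimal optimization (SMO), with 5-fold cross-validated error (CVloss),
Gaussian-process Bayesian hyperparameter search, and Platt score calibration.

The dual problem, for labels y in {-1,+1} and Gram matrix G:

    max_alpha  sum_j alpha_j - 1/2 sum_{j,k} alpha_j alpha_k y_j y_k G(x_j, x_k)
    s.t.       sum_j alpha_j y_j = 0,   0 <= alpha_j <= C

The score of a new sample z is ``f(z) = sum_j alpha_j y_j G(x_j, z) + b``.
``kernel_scale`` divides every feature before inner products (so the gaussian
kernel is exp(-||x - z||^2 / s^2)).  Multiclass problems are handled
one-vs-one with majority voting, ties broken by the smallest class index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .exceptions import ConfigurationError, InputError, LabelError

logger = logging.getLogger("sersml")


@dataclass
class SVMConfig:
    kernel: str = "linear"           # linear | gaussian
    box_constraint: float = 1.0      # C
    kernel_scale: float = 1.0        # s, divides features before inner products

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "gaussian"):
            raise ConfigurationError(f"unknown kernel {self.kernel!r}")
        if self.box_constraint <= 0 or self.kernel_scale <= 0:
            raise ConfigurationError("box_constraint and kernel_scale must be > 0")


def gram_matrix(a: np.ndarray, b: np.ndarray, config: SVMConfig) -> np.ndarray:
    u = np.atleast_2d(a) / config.kernel_scale
    v = np.atleast_2d(b) / config.kernel_scale
    if config.kernel == "linear":
        return u @ v.T
    return np.exp(-cdist(u, v, "sqeuclidean"))


# ---------------------------------------------------------------------------
# SMO solver (binary)
# ---------------------------------------------------------------------------


@numba.njit(cache=True)
def _smo_core(kernel, y, c, tol, max_iter):  # pragma: no cover - exercised via _smo
    n = y.size
    alpha = np.zeros(n)
    f = np.zeros(n)  # f_i = sum_j alpha_j y_j K_ij (no bias)
    gap = np.inf
    for _ in range(max_iter):
        # first index: largest violation among the "up" set
        i = -1
        m_up = -np.inf
        for t in range(n):
            if (y[t] > 0 and alpha[t] < c - 1e-12) or (y[t] < 0 and alpha[t] > 1e-12):
                v = y[t] - f[t]
                if v > m_up:
                    m_up = v
                    i = t
        # second index: maximal second-order gain among the "low" set
        j = -1
        m_low = np.inf
        best_gain = 0.0
        for t in range(n):
            if (y[t] < 0 and alpha[t] < c - 1e-12) or (y[t] > 0 and alpha[t] > 1e-12):
                v = y[t] - f[t]
                if v < m_low:
                    m_low = v
                diff = m_up - v
                if diff > 0:
                    eta = kernel[i, i] + kernel[t, t] - 2.0 * kernel[i, t]
                    if eta <= 1e-15:
                        eta = 1e-15
                    gain = diff * diff / eta
                    if gain > best_gain:
                        best_gain = gain
                        j = t
        if i < 0 or m_low == np.inf:
            gap = 0.0
            break
        gap = m_up - m_low
        if gap <= tol or j < 0:
            break
        e_i = f[i] - y[i]
        e_j = f[j] - y[j]
        eta = kernel[i, i] + kernel[j, j] - 2.0 * kernel[i, j]
        if eta <= 1e-15:
            eta = 1e-15
        aj_new = alpha[j] + y[j] * (e_i - e_j) / eta
        if y[i] != y[j]:
            lo = max(0.0, alpha[j] - alpha[i])
            hi = min(c, c + alpha[j] - alpha[i])
        else:
            lo = max(0.0, alpha[i] + alpha[j] - c)
            hi = min(c, alpha[i] + alpha[j])
        if aj_new > hi:
            aj_new = hi
        elif aj_new < lo:
            aj_new = lo
        ai_new = alpha[i] + y[i] * y[j] * (alpha[j] - aj_new)
        d_i = ai_new - alpha[i]
        d_j = aj_new - alpha[j]
        if abs(d_j) < 1e-15 and abs(d_i) < 1e-15:
            break
        alpha[i] = ai_new
        alpha[j] = aj_new
        for t in range(n):
            f[t] += d_i * y[i] * kernel[i, t] + d_j * y[j] * kernel[j, t]
    return alpha, f, max(gap, 0.0)


def _smo(
    kernel: np.ndarray,
    y: np.ndarray,
    c: float,
    tol: float | None = None,
    max_passes: int = 10_000,
) -> tuple[np.ndarray, float, float]:
    """Maximise the dual by second-order working-set SMO.

    Returns (alpha, bias, final KKT gap).  Stops when the maximum KKT
    violation (the up/low gap in score units) falls below ``tol`` or after
    ``max_passes`` passes (n pair updates each).
    """
    kernel = np.ascontiguousarray(kernel, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if tol is None:
        # score-unit tolerance scaled to the problem's magnitude
        tol = 1e-7 * max(1.0, c * float(np.abs(kernel).max()))
    alpha, f, gap = _smo_core(kernel, y, float(c), float(tol),
                              int(max_passes) * y.size)
    # bias from free support vectors, falling back to all support vectors
    free = (alpha > 1e-9 * c) & (alpha < c * (1 - 1e-9))
    sv = alpha > 1e-9 * c
    if free.any():
        bias = float(np.mean(y[free] - f[free]))
    elif sv.any():
        bias = float(np.mean(y[sv] - f[sv]))
    else:
        bias = 0.0
    return alpha, bias, float(gap)


@dataclass
class BinarySVM:
    """One trained pairwise separator: class_pos gets score > 0."""

    alphas: np.ndarray
    bias: float
    labels_pm1: np.ndarray
    training_vectors: np.ndarray
    config: SVMConfig
    class_pos: str
    class_neg: str
    kkt_gap: float = 0.0

    @property
    def support_indices(self) -> np.ndarray:
        return np.flatnonzero(self.alphas > 1e-9 * self.config.box_constraint)

    def decision(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, float))
        if z.shape[1] != self.training_vectors.shape[1]:
            raise InputError(
                f"feature dimension {z.shape[1]} does not match "
                f"training dimension {self.training_vectors.shape[1]}"
            )
        k = gram_matrix(self.training_vectors, z, self.config)
        return (self.alphas * self.labels_pm1) @ k + self.bias

    def dual_objective(self) -> float:
        k = gram_matrix(self.training_vectors, self.training_vectors, self.config)
        ay = self.alphas * self.labels_pm1
        return float(self.alphas.sum() - 0.5 * ay @ k @ ay)


@dataclass
class SVMModel:
    """Trained SVM: one :class:`BinarySVM` per class pair (one for binary)."""

    class_names: list[str]
    machines: list[BinarySVM]
    config: SVMConfig

    @property
    def binary(self) -> BinarySVM:
        if len(self.machines) != 1:
            raise InputError("model is multiclass; no single binary machine")
        return self.machines[0]


def train_svm(x: np.ndarray, y: np.ndarray, config: SVMConfig | None = None) -> SVMModel:
    """Fit the dual soft-margin SVM (one-vs-one for > 2 classes)."""
    config = config or SVMConfig()
    x = np.atleast_2d(np.asarray(x, float))
    y = np.asarray(y)
    if x.shape[0] != y.size:
        raise InputError("X rows and y length differ")
    if not np.all(np.isfinite(x)):
        raise InputError("features must be finite")
    class_names = [str(c) for c in np.unique(y.astype(str))]
    if len(class_names) < 2:
        raise LabelError("training needs at least two classes")
    machines = []
    y_str = y.astype(str)
    for a_idx in range(len(class_names)):
        for b_idx in range(a_idx + 1, len(class_names)):
            # second class of the pair is the positive one (score > 0)
            pos, neg = class_names[b_idx], class_names[a_idx]
            mask = (y_str == pos) | (y_str == neg)
            xs = x[mask]
            ys = np.where(y_str[mask] == pos, 1.0, -1.0)
            k = gram_matrix(xs, xs, config)
            alphas, bias, gap = _smo(k, ys, config.box_constraint)
            machines.append(
                BinarySVM(alphas, bias, ys, xs, config, pos, neg, kkt_gap=gap)
            )
    return SVMModel(class_names, machines, config)


def svm_predict(model: SVMModel, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score new samples.

    Returns ``(scores, classes)``: one score column per trained pair and the
    voted class per row (sign for binary; majority one-vs-one vote otherwise,
    ties broken by the smallest class index).
    """
    z = np.atleast_2d(np.asarray(z, float))
    scores = np.column_stack([m.decision(z) for m in model.machines])
    index = {name: i for i, name in enumerate(model.class_names)}
    votes = np.zeros((z.shape[0], len(model.class_names)), dtype=int)
    for col, m in enumerate(model.machines):
        # score == 0 falls to the negative class, i.e. the smaller class index
        winner = np.where(scores[:, col] > 0, index[m.class_pos], index[m.class_neg])
        votes[np.arange(z.shape[0]), winner] += 1
    classes = np.array([model.class_names[i] for i in votes.argmax(axis=1)], dtype=object)
    return scores, classes


def cv_loss(
    x: np.ndarray,
    y: np.ndarray,
    config: SVMConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Pooled k-fold cross-validated misclassification fraction."""
    x = np.atleast_2d(np.asarray(x, float))
    y = np.asarray(y).astype(str)
    n = y.size
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    if n < folds:
        raise ConfigurationError(f"need at least {folds} samples for {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_indices = np.array_split(order, folds)
    errors = 0
    counted = 0
    for held in fold_indices:
        train_mask = np.ones(n, dtype=bool)
        train_mask[held] = False
        if len(np.unique(y[train_mask])) < 2:
            warnings.warn("fold dropped: training split has a single class")
            continue
        model = train_svm(x[train_mask], y[train_mask], config)
        _, pred = svm_predict(model, x[held])
        errors += int(np.sum(pred != y[held]))
        counted += held.size
    if counted == 0:
        raise LabelError("no fold had two training classes")
    return errors / counted


# ---------------------------------------------------------------------------
# Bayesian hyperparameter optimization
# ---------------------------------------------------------------------------


@dataclass
class OptimizationTrace:
    points: np.ndarray        # (n_eval, 2) in (log10 C, log10 s)
    objectives: np.ndarray    # (n_eval,)
    best_so_far: np.ndarray   # (n_eval,), non-increasing
    surrogate_summary: str = ""


def bayes_optimize(
    x: np.ndarray | None,
    y: np.ndarray | None,
    space: tuple[tuple[float, float], tuple[float, float]] = ((-3.0, 6.0), (-3.0, 6.0)),
    n_iter: int = 30,
    seed: int = 0,
    kernel: str = "linear",
    folds: int = 5,
    objective=None,
    n_initial: int = 5,
) -> tuple[SVMConfig, OptimizationTrace]:
    """Minimise CVloss over (log10 C, log10 s) with a GP surrogate.

    Starts from ``min(n_initial, n_iter)`` seeded uniform points, then picks
    each next point by maximising expected improvement of a squared-
    exponential Gaussian process fitted to all evaluations so far.  Returns
    the evaluated point with the smallest objective.  ``objective`` may
    override the default CVloss objective (it receives ``log10_c, log10_s``).
    """
    if n_iter < 1:
        raise ConfigurationError("n_iter must be >= 1")
    (lc_lo, lc_hi), (ls_lo, ls_hi) = space
    if not (np.isfinite([lc_lo, lc_hi, ls_lo, ls_hi]).all() and lc_lo < lc_hi and ls_lo < ls_hi):
        raise ConfigurationError("space bounds must be finite with lower < upper")
    rng = np.random.default_rng(seed)
    if objective is None:
        if x is None or y is None:
            raise ConfigurationError("X and y are required without an explicit objective")

        def objective(log_c: float, log_s: float) -> float:
            cfg = SVMConfig(kernel=kernel, box_constraint=10.0**log_c,
                            kernel_scale=10.0**log_s)
            return cv_loss(x, y, cfg, folds=folds, seed=seed)

    lows = np.array([lc_lo, ls_lo])
    highs = np.array([lc_hi, ls_hi])
    points: list[np.ndarray] = []
    values: list[float] = []
    n_init = min(n_initial, n_iter)
    for _ in range(n_init):
        points.append(rng.uniform(lows, highs))
        values.append(float(objective(*points[-1])))

    gp_kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
        length_scale=[1.0, 1.0], length_scale_bounds=(1e-2, 1e2)
    ) + WhiteKernel(1e-6, (1e-10, 1e-1))
    gp = None
    for _ in range(n_iter - n_init):
        gp = GaussianProcessRegressor(
            kernel=gp_kernel, normalize_y=True, random_state=0, alpha=1e-10
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.array(points), np.array(values))
        candidates = rng.uniform(lows, highs, size=(1024, 2))
        mu, sd = gp.predict(candidates, return_std=True)
        best = min(values)
        sd = np.maximum(sd, 1e-12)
        improve = best - mu
        zscore = improve / sd
        ei = improve * norm.cdf(zscore) + sd * norm.pdf(zscore)
        points.append(candidates[int(np.argmax(ei))])
        values.append(float(objective(*points[-1])))

    arr_p = np.array(points)
    arr_v = np.array(values)
    best_idx = int(np.argmin(arr_v))
    best_cfg = SVMConfig(
        kernel=kernel,
        box_constraint=10.0 ** arr_p[best_idx, 0],
        kernel_scale=10.0 ** arr_p[best_idx, 1],
    )
    trace = OptimizationTrace(
        points=arr_p,
        objectives=arr_v,
        best_so_far=np.minimum.accumulate(arr_v),
        surrogate_summary=str(gp.kernel_) if gp is not None else "no surrogate fitted",
    )
    logger.info(
        "bayes_optimize: best CVloss %.4f at log10C=%.2f log10s=%.2f",
        arr_v[best_idx], arr_p[best_idx, 0], arr_p[best_idx, 1],
    )
    return best_cfg, trace


# ---------------------------------------------------------------------------
# Platt calibration
# ---------------------------------------------------------------------------


@dataclass
class PlattCalibration:
    """Sigmoid posterior map p(y=+1 | score) = 1 / (1 + exp(-(A*score + B)))."""

    a: float
    b: float

    def __call__(self, scores: np.ndarray) -> np.ndarray:
        z = self.a * np.asarray(scores, float) + self.b
        return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def platt_calibrate(model: SVMModel, x: np.ndarray, y: np.ndarray) -> PlattCalibration:
    """Fit Platt's sigmoid to a binary model's decision scores by regularized
    maximum likelihood (target smoothing (N+ + 1)/(N+ + 2), 1/(N- + 2))."""
    machine = model.binary
    y = np.asarray(y).astype(str)
    pos = y == machine.class_pos
    if pos.all() or not pos.any():
        raise LabelError("calibration needs both classes present")
    scores = machine.decision(np.atleast_2d(np.asarray(x, float)))
    if not np.all(np.isfinite(scores)):
        raise InputError("scores must be finite")
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params: np.ndarray) -> float:
        z = params[0] * scores + params[1]
        # log(1 + exp(z)) computed stably
        log1pexp = np.logaddexp(0.0, z)
        return float(np.sum(log1pexp - t * z))

    result = minimize(nll, x0=np.array([1.0, 0.0]), method="BFGS")
    return PlattCalibration(a=float(result.x[0]), b=float(result.x[1]))
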