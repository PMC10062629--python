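"""Distributionally robust multi-output regression ranking (DRMRR).

The scoring function is a linear multi-output map ``f(x) = B'x`` from a
p-dimensional feature vector to a K-vector of predicted deviation targets.
Training minimises the worst-case expected residual r-norm over a
Wasserstein ball of radius ``epsilon`` around the empirical distribution,
which is equivalent to the regularised program

    min_B  (1/N) sum_{q,d} || theta_d^q - B' x_d^q ||_r  +  epsilon * ||Btilde'||_s

with ``Btilde = (-B', I_K)``, ``1/r + 1/s = 1``, and ``|| . ||_s`` the
induced matrix norm. For r = 2 the regulariser is the spectral norm
``sqrt(1 + sigma_max(B)^2)``; epsilon = 0 recovers plain empirical risk
minimisation. The problem is convex and is solved with a first-order
subgradient method (diminishing steps, best-iterate tracking), optionally
polished by a smoothed quasi-Newton refinement for r = 2.

Ranking a test query uses the cyclic scoring procedure: predicted target
columns correspond to importance levels; rank 1 goes to the document
maximising column 1, rank 2 to the remaining document maximising column 2,
and so on, cycling back to column 1 after every K assignments.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.optimize

from .gtd import GTDConfig, GTDMatrix, gtd_matrix
from .letor_io import QueryDocList, RankingDataset
from .metrics import MetricReport, RankedList, mean_metrics

__all__ = [
    "DRMRRModel",
    "SolverConfig",
    "dual_exponent",
    "btilde_norm",
    "objective",
    "fit",
    "predict_gtd",
    "rank_by_gtd",
    "evaluate",
    "tune_epsilon",
]

_SUPPORTED_R = (1.0, 2.0, math.inf)


def dual_exponent(r: float) -> float:
    """Conjugate exponent s with 1/r + 1/s = 1 (r=1 pairs with s=inf)."""
    if r < 1:
        raise ValueError("norm order r must be >= 1")
    if r == 1:
        return math.inf
    if math.isinf(r):
        return 1.0
    return r / (r - 1.0)


@dataclass
class SolverConfig:
    """First-order solver settings.

    ``step0 = None`` picks the initial step from the data scale
    (mean target norm over mean squared feature norm). The subgradient
    phase uses diminishing steps ``step0 / sqrt(t+1)`` and returns the best
    iterate seen; ``polish`` additionally runs an L-BFGS refinement of a
    smoothed objective (r = 2 only), which sharpens the optimum without
    changing the problem.
    """

    max_iterations: int = 2000
    tolerance: float = 1e-10
    step0: float | None = None
    seed: int = 0
    polish: bool = True
    smoothing: float = 1e-9

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class DRMRRModel:
    """Fitted p x K scoring matrix with its norm order and robustness radius."""

    B: np.ndarray
    r: float
    epsilon: float
    config: GTDConfig
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    converged: bool = True
    objective_value: float = math.nan
    objective_trace: list[float] = field(default_factory=list)

    @property
    def s(self) -> float:
        return dual_exponent(self.r)

    @property
    def p(self) -> int:
        return self.B.shape[0]

    @property
    def K(self) -> int:
        return self.B.shape[1]

    def save(self, path: str | Path) -> None:
        doc = {
            "B": [[float(v) for v in row] for row in self.B],
            "r": None if math.isinf(self.r) else self.r,
            "epsilon": self.epsilon,
            "K": self.config.K,
            "alpha": self.config.alpha,
            "beta": self.config.beta,
            "y_hat": self.config.y_hat,
            "log_base": self.config.log_base,
            "ap_threshold": self.config.ap_threshold,
            "feature_mean": None if self.feature_mean is None else list(map(float, self.feature_mean)),
            "feature_scale": None if self.feature_scale is None else list(map(float, self.feature_scale)),
            "objective_value": self.objective_value,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DRMRRModel":
        doc = json.loads(Path(path).read_text())
        config = GTDConfig(
            K=doc["K"], alpha=doc["alpha"], beta=doc["beta"], y_hat=doc["y_hat"],
            log_base=doc["log_base"], ap_threshold=doc["ap_threshold"],
        )
        return cls(
            B=np.array(doc["B"], dtype=float),
            r=math.inf if doc["r"] is None else float(doc["r"]),
            epsilon=float(doc["epsilon"]),
            config=config,
            feature_mean=None if doc["feature_mean"] is None else np.array(doc["feature_mean"]),
            feature_scale=None if doc["feature_scale"] is None else np.array(doc["feature_scale"]),
            objective_value=float(doc["objective_value"]),
        )


# ---------------------------------------------------------------------------
# Objective and its subgradients


def btilde_norm(B: np.ndarray, s: float) -> float:
    """Induced l_s norm of Btilde' = [-B; I_K], the Eq-style regulariser.

    s = 2: sqrt(1 + sigma_max(B)^2) (spectral norm of the augmented map);
    s = inf: max(1, largest row l1-norm of B);
    s = 1: 1 + largest column l1-norm of B. Always >= 1.
    """
    B = np.asarray(B, dtype=float)
    if not np.all(np.isfinite(B)):
        raise ValueError("B has non-finite entries")
    if s == 2:
        smax = np.linalg.svd(B, compute_uv=False)[0] if B.size else 0.0
        return float(np.sqrt(1.0 + smax**2))
    if math.isinf(s):
        return float(max(1.0, np.abs(B).sum(axis=1).max()))
    if s == 1:
        return float(1.0 + np.abs(B).sum(axis=0).max())
    raise ValueError(f"unsupported dual exponent s={s}; use r in {{1, 2, inf}}")


def _residual_loss_grad(B, X, Theta, r, want_grad=True):
    """Mean residual r-norm over documents and one subgradient wrt B."""
    N = X.shape[0]
    R = Theta - X @ B
    if r == 2:
        norms = np.linalg.norm(R, axis=1)
        loss = norms.mean()
        if not want_grad:
            return loss, None
        safe = np.where(norms > 0, norms, 1.0)
        W = np.where(norms[:, None] > 0, R / safe[:, None], 0.0)
        return loss, -(X.T @ W) / N
    if r == 1:
        loss = np.abs(R).sum(axis=1).mean()
        if not want_grad:
            return loss, None
        return loss, -(X.T @ np.sign(R)) / N
    # r = inf: per-document max-abs coordinate
    absR = np.abs(R)
    loss = absR.max(axis=1).mean()
    if not want_grad:
        return loss, None
    kstar = absR.argmax(axis=1)
    S = np.zeros_like(R)
    rows = np.arange(N)
    S[rows, kstar] = np.sign(R[rows, kstar])
    return loss, -(X.T @ S) / N


def _regularizer_grad(B, s):
    """One subgradient of the induced-norm regulariser wrt B."""
    if s == 2:
        if not B.any():
            return np.zeros_like(B)
        U, sv, Vt = np.linalg.svd(B, full_matrices=False)
        smax = sv[0]
        scale = smax / np.sqrt(1.0 + smax**2)
        return scale * np.outer(U[:, 0], Vt[0])
    if math.isinf(s):
        row_sums = np.abs(B).sum(axis=1)
        G = np.zeros_like(B)
        if row_sums.max() > 1.0:
            i = int(row_sums.argmax())
            G[i] = np.sign(B[i])
        return G
    # s = 1
    col_sums = np.abs(B).sum(axis=0)
    k = int(col_sums.argmax())
    G = np.zeros_like(B)
    G[:, k] = np.sign(B[:, k])
    return G


def _objective_arrays(B, X, Theta, epsilon, r) -> float:
    loss, _ = _residual_loss_grad(B, X, Theta, r, want_grad=False)
    if epsilon:
        return loss + epsilon * btilde_norm(B, dual_exponent(r))
    return loss


def _stack_targets(dataset: RankingDataset, targets: list[GTDMatrix]):
    if len(targets) != dataset.T:
        raise ValueError("need one GTD matrix per query")
    X = np.vstack([q.features for q in dataset])
    Theta = np.vstack([t.values for t in targets])
    if Theta.shape[0] != X.shape[0]:
        raise ValueError("targets do not match the dataset's documents")
    return X, Theta


def objective(
    B: np.ndarray,
    dataset: RankingDataset,
    targets: list[GTDMatrix],
    epsilon: float,
    r: float = 2.0,
) -> float:
    """Exact value of the regularised training objective at ``B``."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    X, Theta = _stack_targets(dataset, targets)
    B = np.asarray(B, dtype=float)
    if B.shape != (X.shape[1], Theta.shape[1]):
        raise ValueError(f"B must have shape {(X.shape[1], Theta.shape[1])}, got {B.shape}")
    return _objective_arrays(B, X, Theta, epsilon, r)


# ---------------------------------------------------------------------------
# Solver


def _smoothed_value_grad(Bflat, shape, X, Theta, epsilon, mu):
    """Huberised r=2 objective for the quasi-Newton polish (smooth in B)."""
    B = Bflat.reshape(shape)
    N = X.shape[0]
    R = Theta - X @ B
    norms = np.sqrt((R * R).sum(axis=1) + mu * mu)
    val = (norms - mu).mean()
    G = -(X.T @ (R / norms[:, None])) / N
    if epsilon:
        U, sv, Vt = np.linalg.svd(B, full_matrices=False)
        smax = sv[0] if sv.size else 0.0
        val += epsilon * np.sqrt(1.0 + smax**2)
        if smax > 0:
            G = G + epsilon * (smax / np.sqrt(1.0 + smax**2)) * np.outer(U[:, 0], Vt[0])
    return val, G.ravel()


def _minimize_arrays(X, Theta, epsilon, r, solver: SolverConfig):
    p, K = X.shape[1], Theta.shape[1]
    s = dual_exponent(r)
    B = np.zeros((p, K))  # the regulariser's minimiser

    f0 = _objective_arrays(B, X, Theta, epsilon, r)
    best_val, best_B = f0, B.copy()
    if solver.step0 is None:
        # scale steps so the first move is O(target scale / feature scale)
        xscale = float((X * X).sum(axis=1).mean())
        step0 = f0 / max(xscale / X.shape[1], 1e-12) if f0 > 0 else 1.0
    else:
        step0 = solver.step0

    trace = [f0]
    prev = f0
    converged = False
    for t in range(solver.max_iterations):
        loss, G = _residual_loss_grad(B, X, Theta, r)
        if epsilon:
            G = G + epsilon * _regularizer_grad(B, s)
        gnorm = np.linalg.norm(G)
        if gnorm == 0:
            converged = True
            break
        B = B - (step0 / np.sqrt(t + 1.0)) * G / max(gnorm, 1e-30)
        val = _objective_arrays(B, X, Theta, epsilon, r)
        trace.append(val)
        if val < best_val:
            best_val, best_B = val, B.copy()
        if abs(prev - val) <= solver.tolerance * max(1.0, abs(val)) and t > 10:
            converged = True
            break
        prev = val

    if solver.polish and r == 2:
        res = scipy.optimize.minimize(
            _smoothed_value_grad,
            best_B.ravel(),
            args=((p, K), X, Theta, epsilon, solver.smoothing),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12},
        )
        cand = res.x.reshape(p, K)
        cand_val = _objective_arrays(cand, X, Theta, epsilon, r)
        if cand_val <= best_val:
            best_val, best_B = cand_val, cand
            converged = True
    return best_B, best_val, trace, converged


def fit(
    dataset: RankingDataset,
    config: GTDConfig,
    epsilon: float = 0.0,
    r: float = 2.0,
    solver: SolverConfig | None = None,
    standardize: bool = False,
    targets: list[GTDMatrix] | None = None,
) -> DRMRRModel:
    """Train the scoring matrix B on GTD targets built from ``dataset``.

    Degenerate queries (all grades zero) contribute zero-target rows to the
    loss but are excluded from evaluation averages elsewhere. With
    ``standardize`` each feature is z-scored using training statistics that
    are stored on the model and re-applied at prediction time.

    ``targets`` overrides the GTD construction with precomputed per-query
    target matrices (used for realizable synthetic benchmarks).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if r not in _SUPPORTED_R:
        raise ValueError(f"unsupported norm order r={r}; use 1, 2 or inf")
    if dataset.T == 0:
        raise ValueError("empty dataset")
    solver = solver or SolverConfig()

    if targets is None:
        targets = [gtd_matrix(q, config) for q in dataset]
        if all(t.degenerate for t in targets):
            raise ValueError("all queries are degenerate (every label zero)")
    X, Theta = _stack_targets(dataset, targets)

    feature_mean = feature_scale = None
    if standardize:
        feature_mean = X.mean(axis=0)
        feature_scale = X.std(axis=0)
        feature_scale = np.where(feature_scale > 0, feature_scale, 1.0)
        X = (X - feature_mean) / feature_scale

    B, val, trace, converged = _minimize_arrays(X, Theta, epsilon, r, solver)
    if not converged:
        warnings.warn("solver did not converge within max_iterations; returning best iterate")
    return DRMRRModel(
        B=B, r=float(r), epsilon=float(epsilon), config=config,
        feature_mean=feature_mean, feature_scale=feature_scale,
        converged=converged, objective_value=val, objective_trace=trace,
    )


# ---------------------------------------------------------------------------
# Prediction and scoring


def predict_gtd(model: DRMRRModel, features: np.ndarray) -> np.ndarray:
    """Predicted GTD matrix: row d is B'x_d (columns = importance levels)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.p:
        raise ValueError(f"feature dimension {X.shape[1]} != model p={model.p}")
    if model.feature_mean is not None:
        X = (X - model.feature_mean) / model.feature_scale
    return X @ model.B


def rank_by_gtd(theta_hat: np.ndarray) -> RankedList:
    """Cyclic scoring: assign rank j to the remaining document maximising
    column delta, where delta cycles 1..K as j runs over 1..n_t.

    Ties take the lowest remaining row index. With K = 1 this reduces to a
    descending sort on the single predicted score.
    """
    theta = np.atleast_2d(np.asarray(theta_hat, dtype=float))
    n, K = theta.shape
    if n == 0 or K == 0:
        raise ValueError("empty prediction matrix")
    remaining = list(range(n))
    order = []
    delta = 1
    for j in range(1, n + 1):
        col = theta[remaining, delta - 1]
        pick = remaining.pop(int(np.argmax(col)))
        order.append(pick)
        delta = 1 if j % K == 0 else delta + 1
    return RankedList(order=np.array(order))


def evaluate(model: DRMRRModel, dataset: RankingDataset, ks: list[int]) -> MetricReport:
    """Rank every query with the fitted model and report mean NDCG@k / AP@k."""
    rankings = [rank_by_gtd(predict_gtd(model, q.features)) for q in dataset]
    return mean_metrics(dataset, rankings, ks, model.config)


def tune_epsilon(
    train: RankingDataset,
    validation: RankingDataset,
    grid: list[float],
    config: GTDConfig,
    r: float = 2.0,
    solver: SolverConfig | None = None,
    standardize: bool = False,
) -> tuple[DRMRRModel, dict[float, dict[str, float]]]:
    """Grid-search epsilon, selecting by validation NDCG@5 then NDCG@10.

    Returns the winning refitted model and the per-epsilon validation means.
    """
    if not grid:
        raise ValueError("epsilon grid is empty")
    results: dict[float, dict[str, float]] = {}
    best_key, best_model = None, None
    for eps in grid:
        model = fit(train, config, epsilon=eps, r=r, solver=solver, standardize=standardize)
        report = evaluate(model, validation, ks=[5, 10])
        means = report.means
        results[eps] = means
        key = (means.get("NDCG@5", -1.0), means.get("NDCG@10", -1.0))
        if best_key is None or key > best_key:
            best_key, best_model = key, model
    return best_model, results
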