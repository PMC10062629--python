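"""Noise and attack protocols for stress-testing ranking models.

Four protocols, applied to copies of a dataset:

* Gaussian noise: i.i.d. Gaussian perturbation of every feature entry of a
  random 75% (by default) of queries, with a user-chosen mean and a small
  fixed standard deviation;
* universal FGSM: a pointwise linear regression of grade on features is fit
  on clean training data and its squared-error cost gradient drives a fast
  gradient sign perturbation ``x + sigma * sign(grad_x J)`` of the selected
  test queries;
* black-box FGSM: a substitute model is fit to imitate the victim model's
  observed outputs, then FGSM runs on the substitute's gradient (the
  substitute is pluggable; the default is linear least squares);
* label poisoning: training labels in {0, 1, 2} are independently
  resampled from a row-stochastic error table with retention probability e
  on the diagonal and off-diagonal mass concentrated on nearby grades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .letor_io import QueryDocList, RankingDataset

__all__ = [
    "AttackSpec",
    "LinearAdversary",
    "gaussian_attack",
    "fit_linear_adversary",
    "fgsm_perturb",
    "blackbox_attack",
    "label_noise_matrix",
    "poison_labels",
]

ATTACK_KINDS = ("gaussian", "universal_fgsm", "blackbox_fgsm", "label_noise")


@dataclass(frozen=True)
class AttackSpec:
    """One robustness protocol.

    ``magnitude`` is the noise mean for the Gaussian attack, sigma for the
    FGSM attacks, and the retention probability e for label noise.
    ``fraction`` is the share of test queries perturbed by feature attacks.
    """

    kind: str
    magnitude: float
    noise_sd: float = 0.001
    fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ATTACK_KINDS:
            raise ValueError(f"unknown attack kind {self.kind!r}; choose from {ATTACK_KINDS}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.kind in ("universal_fgsm", "blackbox_fgsm") and self.magnitude < 0:
            raise ValueError("FGSM magnitude sigma must be >= 0")
        if self.kind == "label_noise" and not 0.0 <= self.magnitude <= 1.0:
            raise ValueError("label-noise retention probability e must lie in [0, 1]")


@dataclass
class LinearAdversary:
    """Pointwise linear regression of grade on features; its squared-error
    cost J(x, y) = (w'x + b - y)^2 supplies FGSM gradients."""

    w: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.all(np.isfinite(self.w)) or not np.isfinite(self.intercept):
            raise ValueError("adversary coefficients must be finite")

    def gradient(self, x: np.ndarray, y: float) -> np.ndarray:
        """grad_x (w'x + b - y)^2 = 2 (w'x + b - y) w."""
        return 2.0 * (self.w @ x + self.intercept - y) * self.w


def _select_queries(T: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    n_sel = int(np.ceil(fraction * T))
    if n_sel == 0:
        return np.array([], dtype=int)
    return rng.choice(T, size=n_sel, replace=False)


def gaussian_attack(dataset: RankingDataset, spec: AttackSpec) -> RankingDataset:
    """Add i.i.d. Gaussian noise (mean, sd) to every feature entry of a
    random ceil(fraction * T) subset of queries; labels untouched."""
    if spec.kind != "gaussian":
        raise ValueError("spec.kind must be 'gaussian'")
    rng = np.random.default_rng(spec.seed)
    selected = set(_select_queries(dataset.T, spec.fraction, rng).tolist())
    queries = []
    for i, q in enumerate(dataset):
        if i in selected:
            noise = rng.normal(spec.magnitude, spec.noise_sd, size=q.features.shape)
            queries.append(QueryDocList(q.query_id, q.features + noise, q.labels.copy()))
        else:
            queries.append(QueryDocList(q.query_id, q.features.copy(), q.labels.copy()))
    return RankingDataset(queries)


def fit_linear_adversary(train: RankingDataset) -> LinearAdversary:
    """OLS fit of scalar grade on features, pooling all documents."""
    X, y = train.stacked()
    A = np.column_stack([X, np.ones(len(y))])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn("rank-deficient design; using the minimum-norm least-squares fit")
    return LinearAdversary(w=coef[:-1], intercept=float(coef[-1]))


def fgsm_perturb(dataset: RankingDataset, gradient_source, spec: AttackSpec) -> RankingDataset:
    """Fast gradient sign perturbation of the selected queries' features.

    Each feature entry of a perturbed document moves by exactly
    ``sigma * sign(grad_x J(x, y))`` — a value in {-sigma, 0, +sigma}.
    ``gradient_source`` must expose ``gradient(x, y) -> vector``.
    """
    sigma = spec.magnitude
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(spec.seed)
    selected = set(_select_queries(dataset.T, spec.fraction, rng).tolist())
    queries = []
    for i, q in enumerate(dataset):
        X = q.features.copy()
        if i in selected and sigma > 0:
            for d in range(q.n_docs):
                g = gradient_source.gradient(q.features[d], q.labels[d])
                X[d] = q.features[d] + sigma * np.sign(g)
        queries.append(QueryDocList(q.query_id, X, q.labels.copy()))
    return RankingDataset(queries)


def _linear_surrogate_trainer(X: np.ndarray, outputs: np.ndarray) -> LinearAdversary:
    """Default substitute: least-squares fit of the victim's outputs."""
    A = np.column_stack([X, np.ones(X.shape[0])])
    coef, *_ = np.linalg.lstsq(A, outputs, rcond=None)
    return LinearAdversary(w=coef[:-1], intercept=float(coef[-1]))


def blackbox_attack(
    dataset: RankingDataset,
    victim_outputs: np.ndarray,
    spec: AttackSpec,
    surrogate_trainer: Callable[[np.ndarray, np.ndarray], LinearAdversary] | None = None,
) -> RankingDataset:
    """Substitute-model attack: imitate the victim, then FGSM on the copy.

    ``victim_outputs`` are the deployed model's per-document scores on
    ``dataset``'s features (for a DRMRR victim, its first GTD column). The
    surrogate trainer maps (features, outputs) to a gradient source; the
    default is linear least squares.
    """
    victim_outputs = np.asarray(victim_outputs, dtype=float)
    X, _ = dataset.stacked()
    if victim_outputs.shape[0] != X.shape[0]:
        raise ValueError("need one victim output per document")
    trainer = surrogate_trainer or _linear_surrogate_trainer
    surrogate = trainer(X, victim_outputs)
    if not hasattr(surrogate, "gradient"):
        raise ValueError("surrogate must expose gradient(x, y)")
    return fgsm_perturb(dataset, surrogate, spec)


def label_noise_matrix(e: float) -> np.ndarray:
    """Row-stochastic 3x3 error table with retention probability e.

    Rows are the true grade (0, 1, 2); columns the observed grade. Misjudged
    labels land closer to the truth with higher probability: the extreme
    grades put 2/3 of the error mass on the middle grade, and the middle
    grade splits its error mass evenly.
    """
    if not 0.0 <= e <= 1.0:
        raise ValueError("e must lie in [0, 1]")
    q = 1.0 - e
    return np.array(
        [
            [e, 2.0 / 3.0 * q, 1.0 / 3.0 * q],
            [0.5 * q, e, 0.5 * q],
            [1.0 / 3.0 * q, 2.0 / 3.0 * q, e],
        ]
    )


def poison_labels(train: RankingDataset, e: float, seed: int = 0) -> RankingDataset:
    """Independently resample every training label from its error-table row.

    Labels must be in {0, 1, 2}; features are untouched.
    """
    P = label_noise_matrix(e)
    rng = np.random.default_rng(seed)
    queries = []
    for q in train:
        labels = q.labels.astype(int)
        if not np.all((q.labels == labels) & (labels >= 0) & (labels <= 2)):
            raise ValueError("label poisoning requires integer grades in {0, 1, 2}")
        new = np.array([rng.choice(3, p=P[g]) for g in labels], dtype=float)
        queries.append(QueryDocList(q.query_id, q.features.copy(), new))
    return RankingDataset(queries)
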