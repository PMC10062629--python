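"""Ground Truth Deviation (GTD) targets.

Instead of a scalar relevance grade per document, each document of a query
gets a length-K target vector whose i-th entry scores how well the document
fits rank i. The vector is the elementwise product of three factors, all
computed on the *ideally sorted* list (grades descending):

* swap-NDCG ``lambda_di`` — the NDCG of the ideal list after exchanging
  document d with the document at position i (gain G(s)=s, discount
  1/log(1+s)); equals 1 at d's own position and never exceeds 1;
* position deviation ``rho_di = alpha / cosh(min(beta*h, beta*h/2))`` with
  ``h = pos(d) - i`` — an asymmetric bell with maximum ``alpha`` at h=0,
  falling more steeply for negative offsets (a document ranked *below* its
  ideal slot is penalised more than one ranked above it);
* document importance ``xi_I = log(y_hat*y_d + 1) / log(y_hat^2 + 1)`` —
  0 for irrelevant documents, 1 at the maximum grade.

The per-position factors are truncated to the first K positions, or padded
by repeating the last element when the query is shorter than K, so every
target has length exactly K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .letor_io import QueryDocList

__all__ = [
    "GTDConfig",
    "GTDMatrix",
    "ideal_order",
    "swap_ndcg",
    "position_deviation",
    "importance_score",
    "gtd_vector",
    "gtd_matrix",
]


@dataclass(frozen=True)
class GTDConfig:
    """Parameters governing GTD construction and ranking metrics.

    Attributes
    ----------
    K:
        Number of importance levels (target length). A low K focuses the
        model on the most relevant documents; default 5.
    alpha:
        Maximum position-deviation score (peak of the bell), > 0.
    beta:
        Position-deviation penalty rate, > 0.
    y_hat:
        Maximum possible relevance grade, >= 1.
    log_base:
        Base of the logarithms in discounts and deviation scores. NDCG and
        swap-NDCG are invariant to it; only raw DCG values change.
    ap_threshold:
        Minimum grade counted as relevant when binarising for AP@k.
    """

    K: int = 5
    alpha: float = 10.0
    beta: float = 2.0
    y_hat: float = 2.0
    log_base: float = 2.0
    ap_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.y_hat < 1:
            raise ValueError("y_hat must be >= 1")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")

    def log(self, x):
        return np.log(x) / np.log(self.log_base)


@dataclass
class GTDMatrix:
    """Per-query n_q x K matrix of deviation targets (rows = documents)."""

    values: np.ndarray
    source_query: QueryDocList
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.source_query.n_docs:
            raise ValueError("row count must equal the query's document count")

    def savetxt(self, path, delimiter: str = "\t") -> None:
        """Write the target matrix as delimited text for inspection."""
        np.savetxt(path, self.values, delimiter=delimiter)


def ideal_order(labels: np.ndarray) -> np.ndarray:
    """Indices sorting ``labels`` descending; ties keep original order.

    Position r (1-based) of the ideal list holds document ``order[r-1]``.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels must be a non-empty vector")
    return np.argsort(-labels, kind="stable")


def _idcg(sorted_labels: np.ndarray, config: GTDConfig) -> float:
    ranks = np.arange(1, len(sorted_labels) + 1)
    return float(np.sum(sorted_labels / config.log(1.0 + ranks)))


def swap_ndcg(sorted_labels: np.ndarray, d_pos: int, i_pos: int, config: GTDConfig) -> float:
    """NDCG of the ideally sorted list after exchanging two positions.

    ``sorted_labels`` must already be in descending order; positions are
    1-based. Closed form:

        lambda = 1 + [ (y_d - y_i)/log(1+i) + (y_i - y_d)/log(1+pos_d) ] / IDCG
    """
    sorted_labels = np.asarray(sorted_labels, dtype=float)
    n = len(sorted_labels)
    if not (1 <= d_pos <= n and 1 <= i_pos <= n):
        raise ValueError(f"positions must lie in [1, {n}]")
    idcg = _idcg(sorted_labels, config)
    if idcg <= 0:
        raise ValueError("all-zero labels: swap-NDCG undefined (degenerate query)")
    y_d = sorted_labels[d_pos - 1]
    y_i = sorted_labels[i_pos - 1]
    delta = (y_d - y_i) / config.log(1.0 + i_pos) + (y_i - y_d) / config.log(1.0 + d_pos)
    return float(1.0 + delta / idcg)


def position_deviation(h: float, config: GTDConfig) -> float:
    """Asymmetric bell ``alpha / cosh(min(beta*h, beta*h/2))``.

    ``h = pos(d) - i`` is the signed offset between a document's ideal
    position and the rank being scored. The maximum ``alpha`` is attained at
    h = 0; positive offsets are tolerated more than negative ones
    (rho(+h) >= rho(-h)).
    """
    arg = min(config.beta * h, 0.5 * config.beta * h)
    return config.alpha / float(np.abs(np.cosh(arg)))


def importance_score(y_d: float, config: GTDConfig) -> float:
    """Document importance ``log(y_hat*y_d + 1) / log(y_hat^2 + 1)`` in [0, 1]."""
    if y_d < 0 or y_d > config.y_hat:
        raise ValueError(f"grade {y_d} outside [0, {config.y_hat}]")
    return float(np.log(config.y_hat * y_d + 1.0) / np.log(config.y_hat**2 + 1.0))


def _truncate_or_pad(v: np.ndarray, K: int) -> np.ndarray:
    if len(v) >= K:
        return v[:K]
    return np.concatenate([v, np.full(K - len(v), v[-1])])


def gtd_vector(query: QueryDocList, d: int, config: GTDConfig) -> np.ndarray:
    """GTD target ``theta_d = xi_I * (xi_D ∘ xi_Phi)`` for document ``d``.

    ``d`` is a 0-based document index into the query. Returns a length-K
    vector; all-zero when the query is degenerate (every grade zero) or the
    document is irrelevant (xi_I = 0).
    """
    order = ideal_order(query.labels)
    sorted_labels = query.labels[order]
    n_q = query.n_docs
    if np.all(sorted_labels == 0):
        return np.zeros(config.K)
    d_pos = int(np.where(order == d)[0][0]) + 1  # 1-based ideal position of d
    xi_i = importance_score(query.labels[d], config)
    positions = np.arange(1, n_q + 1)
    xi_phi = np.array([swap_ndcg(sorted_labels, d_pos, i, config) for i in positions])
    xi_d = np.array([position_deviation(d_pos - i, config) for i in positions])
    xi_phi = _truncate_or_pad(xi_phi, config.K)
    xi_d = _truncate_or_pad(xi_d, config.K)
    return xi_i * (xi_d * xi_phi)


def gtd_matrix(query: QueryDocList, config: GTDConfig) -> GTDMatrix:
    """Stack :func:`gtd_vector` rows into the query's n_q x K target matrix.

    A query whose grades are all zero has no ideal ranking to deviate from;
    it gets a zero matrix and is flagged degenerate (excluded from metric
    averages, kept as zero-target rows during training).
    """
    if query.is_degenerate():
        return GTDMatrix(
            values=np.zeros((query.n_docs, config.K)),
            source_query=query,
            degenerate=True,
        )
    rows = [gtd_vector(query, d, config) for d in range(query.n_docs)]
    return GTDMatrix(values=np.vstack(rows), source_query=query, degenerate=False)
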