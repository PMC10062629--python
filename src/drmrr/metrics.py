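"""Listwise evaluation metrics: DCG, NDCG@k, P@k, AP@k, and dataset means.

Conventions: gain G(s) = s, discount D(s) = 1/log(1+s) truncated to the
top k (D(s) = 0 for s > k). AP binarises grades at ``config.ap_threshold``
(grade >= threshold counts as relevant) and normalises by m, the number of
relevant documents *within the top k*. Queries where a metric is undefined
(IDCG@k = 0, or m = 0 for AP) are excluded from means and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gtd import GTDConfig, ideal_order
from .letor_io import QueryDocList, RankingDataset

__all__ = ["RankedList", "MetricReport", "dcg_at_k", "ndcg_at_k", "ap_at_k", "mean_metrics"]

#: Sentinel for queries where a metric is undefined rather than zero.
DEGENERATE = None


@dataclass
class RankedList:
    """A predicted ordering of one query's documents (position 1 first)."""

    order: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        n = len(self.order)
        if n == 0 or not np.array_equal(np.sort(self.order), np.arange(n)):
            raise ValueError("order must be a permutation of 0..n-1")

    def __len__(self) -> int:
        return len(self.order)


@dataclass
class MetricReport:
    """Per-query metric table plus means over evaluable queries."""

    per_query: pd.DataFrame
    means: dict[str, float]
    excluded: dict[str, int] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.per_query.to_csv(path, index=False)


def dcg_at_k(labels_in_ranked_order: np.ndarray, k: int, config: GTDConfig) -> float:
    """Discounted cumulative gain of the first k grades of a ranked list."""
    y = np.asarray(labels_in_ranked_order, dtype=float)
    if y.size == 0:
        raise ValueError("empty ranked list")
    if k < 1:
        raise ValueError("k must be >= 1")
    top = y[: min(k, len(y))]
    ranks = np.arange(1, len(top) + 1)
    return float(np.sum(top / config.log(1.0 + ranks)))


def ndcg_at_k(query: QueryDocList, ranking: RankedList, k: int, config: GTDConfig):
    """NDCG@k of a predicted ranking, or ``None`` when IDCG@k is zero."""
    if len(ranking) != query.n_docs:
        raise ValueError("ranking length must match the query")
    ideal = query.labels[ideal_order(query.labels)]
    idcg = dcg_at_k(ideal, k, config)
    if idcg <= 0:
        return DEGENERATE
    return dcg_at_k(query.labels[ranking.order], k, config) / idcg


def ap_at_k(query: QueryDocList, ranking: RankedList, k: int, config: GTDConfig):
    """Average precision at k with grades binarised at ``ap_threshold``.

    AP@k = (1/m) * sum_{j<=k} P@j * 1(relevant at j), with m the number of
    relevant documents in the top k; ``None`` when m = 0.
    """
    if len(ranking) != query.n_docs:
        raise ValueError("ranking length must match the query")
    rel = (query.labels[ranking.order] >= config.ap_threshold).astype(float)
    top = rel[: min(k, len(rel))]
    m = top.sum()
    if m == 0:
        return DEGENERATE
    j = np.arange(1, len(top) + 1)
    p_at_j = np.cumsum(top) / j
    return float(np.sum(p_at_j * top) / m)


def mean_metrics(
    dataset: RankingDataset,
    rankings: list[RankedList],
    ks: list[int],
    config: GTDConfig,
) -> MetricReport:
    """Evaluate NDCG@k and AP@k per query and average over evaluable ones."""
    if len(rankings) != dataset.T:
        raise ValueError("need exactly one ranking per query")
    rows = []
    for q, ranking in zip(dataset, rankings):
        for k in ks:
            rows.append((q.query_id, "NDCG", k, ndcg_at_k(q, ranking, k, config)))
            rows.append((q.query_id, "AP", k, ap_at_k(q, ranking, k, config)))
    table = pd.DataFrame(rows, columns=["query_id", "metric", "k", "value"])

    means: dict[str, float] = {}
    excluded: dict[str, int] = {}
    for (metric, k), grp in table.groupby(["metric", "k"]):
        vals = grp["value"].dropna()
        name = f"{metric}@{k}"
        excluded[name] = int(grp["value"].isna().sum())
        if len(vals):
            means[name] = float(vals.mean())
    if not means:
        raise ValueError("no evaluable queries")
    return MetricReport(per_query=table, means=means, excluded=excluded)
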