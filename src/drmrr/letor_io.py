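"""Query-grouped ranking data in the LETOR / SVMlight text dialect.

Each non-empty line describes one query-document pair::

    <label> qid:<id> <idx>:<val> <idx>:<val> ... [# comment]

Feature indices are 1-based in files (SVMlight convention) and 0-based in
memory. Missing indices are implicitly zero; the in-memory feature dimension
``p`` is the largest index seen anywhere in the file. Queries need not be
contiguous in the file: documents are grouped by ``qid`` value, preserving
file order within each query.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "QueryDocList",
    "RankingDataset",
    "LetorParseError",
    "read_letor",
    "write_letor",
    "kfold_split",
]


class LetorParseError(ValueError):
    """Raised for malformed LETOR/SVMlight input, naming the offending line."""


@dataclass
class QueryDocList:
    """One query: an ``n_q x p`` feature matrix and graded relevance labels.

    Labels are relevance grades in ``[0, y_hat]``, conventionally integers
    (0 irrelevant ... y_hat definitely relevant).
    """

    query_id: str
    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.labels.ndim != 1 or len(self.labels) != self.features.shape[0]:
            raise ValueError("labels must be one grade per document row")
        if self.n_docs < 1:
            raise ValueError(f"query {self.query_id!r} has no documents")
        if np.any(self.labels < 0):
            raise ValueError(f"query {self.query_id!r} has negative labels")

    @property
    def n_docs(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def is_degenerate(self) -> bool:
        """True when every label is zero (no ideal ranking signal)."""
        return bool(np.all(self.labels == 0))


@dataclass
class RankingDataset:
    """An ordered collection of queries sharing one feature dimension ``p``."""

    queries: list[QueryDocList] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.queries:
            p = self.queries[0].n_features
            for q in self.queries:
                if q.n_features != p:
                    raise ValueError(
                        f"query {q.query_id!r} has p={q.n_features}, expected {p}"
                    )

    @property
    def T(self) -> int:
        """Number of queries."""
        return len(self.queries)

    @property
    def N(self) -> int:
        """Total number of documents across queries."""
        return sum(q.n_docs for q in self.queries)

    @property
    def p(self) -> int:
        if not self.queries:
            raise ValueError("empty dataset has no feature dimension")
        return self.queries[0].n_features

    def __iter__(self) -> Iterator[QueryDocList]:
        return iter(self.queries)

    def __len__(self) -> int:
        return len(self.queries)

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All features (N x p) and labels (N,) pooled over queries."""
        X = np.vstack([q.features for q in self.queries])
        y = np.concatenate([q.labels for q in self.queries])
        return X, y


def _parse_line(line: str, lineno: int) -> tuple[float, str, dict[int, float]]:
    body = line.split("#", 1)[0].strip()
    tokens = body.split()
    if len(tokens) < 2:
        raise LetorParseError(f"line {lineno}: expected '<label> qid:<id> ...'")
    try:
        label = float(tokens[0])
    except ValueError:
        raise LetorParseError(f"line {lineno}: non-numeric label {tokens[0]!r}") from None
    if not tokens[1].startswith("qid:"):
        raise LetorParseError(f"line {lineno}: missing qid token, got {tokens[1]!r}")
    qid = tokens[1][4:]
    if not qid:
        raise LetorParseError(f"line {lineno}: empty qid")
    feats: dict[int, float] = {}
    for tok in tokens[2:]:
        idx_str, _, val_str = tok.partition(":")
        try:
            idx = int(idx_str)
            val = float(val_str)
        except ValueError:
            raise LetorParseError(f"line {lineno}: bad feature token {tok!r}") from None
        if idx < 1:
            raise LetorParseError(f"line {lineno}: feature index {idx} is not 1-based")
        feats[idx] = val
    return label, qid, feats


def read_letor(path: str | Path) -> RankingDataset:
    """Read a LETOR/SVMlight file into a :class:`RankingDataset`.

    Documents are grouped by qid, preserving file order within a query; the
    feature dimension is the maximum 1-based index seen. Labels are parsed
    as floats and validated as nonnegative; non-integer labels are accepted
    with a warning.
    """
    path = Path(path)
    rows: list[tuple[float, str, dict[int, float]]] = []
    max_idx = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.split("#", 1)[0].strip():
                continue
            label, qid, feats = _parse_line(raw, lineno)
            if label < 0:
                raise LetorParseError(f"line {lineno}: negative label {label}")
            rows.append((label, qid, feats))
            if feats:
                max_idx = max(max_idx, max(feats))
    if not rows:
        raise LetorParseError(f"{path}: no data lines")
    if any(label != int(label) for label, _, _ in rows):
        warnings.warn("non-integer relevance labels; metrics will use them as-is")

    p = max_idx
    by_qid: dict[str, list[tuple[float, dict[int, float]]]] = {}
    order: list[str] = []
    for label, qid, feats in rows:
        if qid not in by_qid:
            by_qid[qid] = []
            order.append(qid)
        by_qid[qid].append((label, feats))

    queries = []
    for qid in order:
        docs = by_qid[qid]
        X = np.zeros((len(docs), p))
        y = np.zeros(len(docs))
        for d, (label, feats) in enumerate(docs):
            y[d] = label
            for idx, val in feats.items():
                X[d, idx - 1] = val
        queries.append(QueryDocList(query_id=qid, features=X, labels=y))
    return RankingDataset(queries=queries)


def write_letor(dataset: RankingDataset, path: str | Path) -> None:
    """Write a dataset in the LETOR/SVMlight dialect.

    Zero feature values are omitted (sparse convention); ``read_letor``
    recovers them as 0. Round-trips labels and qids exactly and features to
    float-repr precision.
    """
    if dataset.T == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for q in dataset:
            for d in range(q.n_docs):
                label = q.labels[d]
                label_str = str(int(label)) if label == int(label) else repr(float(label))
                parts = [label_str, f"qid:{q.query_id}"]
                row = q.features[d]
                for j in np.nonzero(row)[0]:
                    parts.append(f"{j + 1}:{float(row[j])!r}")
                fh.write(" ".join(parts) + "\n")


def kfold_split(dataset: RankingDataset, n_folds: int, fold: int) -> tuple[RankingDataset, RankingDataset]:
    """Simple per-query K-fold helper: (train, test) for the given fold.

    Queries are assigned to folds round-robin by position; no shuffling.
    """
    if not 0 <= fold < n_folds:
        raise ValueError(f"fold {fold} out of range for {n_folds} folds")
    train = [q for i, q in enumerate(dataset) if i % n_folds != fold]
    test = [q for i, q in enumerate(dataset) if i % n_folds == fold]
    if not train or not test:
        raise ValueError("fold split produced an empty partition")
    return RankingDataset(train), RankingDataset(test)
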