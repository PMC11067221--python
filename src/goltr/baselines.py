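"""Frequency and homology-transfer baselines for function prediction.

Naive scores every test protein with the training-set relative frequency of
each term.  The BLAST baselines are pure scoring rules over a precomputed
tabular alignment hit table: BLAST-full copies the full annotation set of
the single best-scoring training hit; BLAST-partial scores each term by the
maximum sequence identity to any training protein carrying that term.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .ontology import AnnotationSet, LabelSpace

BLAST_COLUMNS = (
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass
class HitTable:
    """Filtered alignment hits: (query, subject, pident, evalue, bitscore)."""

    rows: list[tuple[str, str, float, float, float]]

    def by_query(self) -> dict[str, list[tuple[str, str, float, float, float]]]:
        out: dict[str, list] = {}
        for r in self.rows:
            out.setdefault(r[0], []).append(r)
        return out


def read_blast_tabular(stream, evalue_max: float = 0.001) -> HitTable:
    """Read 12-column tabular alignment output, dropping weak hits.

    Rows with e-value above ``evalue_max`` (default 0.001) are discarded.
    """
    if isinstance(stream, str) and "\t" in stream:
        stream = io.StringIO(stream)
    handle = open(stream) if isinstance(stream, str) else stream
    rows = []
    try:
        for ln, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"line {ln}: expected 12 columns, got {len(parts)}")
            try:
                pident = float(parts[2])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as e:
                raise ValueError(f"line {ln}: non-numeric field ({e})") from None
            if evalue > evalue_max:
                continue
            rows.append((parts[0], parts[1], pident, evalue, bitscore))
    finally:
        if isinstance(stream, str):
            handle.close()
    return HitTable(rows=rows)


def naive_scores(Y_train: np.ndarray, n_test: int) -> np.ndarray:
    """Every test row = training-set relative frequency of each term."""
    Y_train = np.asarray(Y_train, dtype=float)
    if Y_train.size == 0:
        raise ValueError("Y_train must be non-empty")
    freq = Y_train.mean(axis=0)
    return np.tile(freq, (n_test, 1))


def _best_hit(hits):
    """Best alignment: max bitscore, ties by min e-value then subject id."""
    return min(hits, key=lambda r: (-r[4], r[3], r[1]))


def blast_full(hits: HitTable, train_annots: AnnotationSet,
               space: LabelSpace, queries: list[str]) -> np.ndarray:
    """Transfer the whole label row of each query's best-scoring training hit."""
    by_q = hits.by_query()
    Y = np.zeros((len(queries), len(space)))
    for i, q in enumerate(queries):
        if q not in by_q:
            continue
        best = _best_hit(by_q[q])
        for t in train_annots.entries.get(best[1], ()):
            j = space.index.get(t)
            if j is not None:
                Y[i, j] = 1.0
    return Y


def blast_partial(hits: HitTable, train_annots: AnnotationSet,
                  space: LabelSpace, queries: list[str]) -> np.ndarray:
    """score(i, j) = max identity/100 over query i's hits to subjects with term j."""
    by_q = hits.by_query()
    S = np.zeros((len(queries), len(space)))
    for i, q in enumerate(queries):
        for (_, subj, pident, _, _) in by_q.get(q, ()):
            terms = train_annots.entries.get(subj)
            if not terms:
                continue
            sc = pident / 100.0
            for t in terms:
                j = space.index.get(t)
                if j is not None and sc > S[i, j]:
                    S[i, j] = sc
    return S


class NaiveFrequencyBaseline(BaseEstimator):
    """sklearn-style wrapper over :func:`naive_scores`."""

    def fit(self, X, Y):
        Y = np.asarray(Y, dtype=float)
        if Y.size == 0:
            raise ValueError("Y must be non-empty")
        self.frequencies_ = Y.mean(axis=0)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "frequencies_"):
            raise AttributeError("estimator is not fitted")
        n = len(X[0]) if isinstance(X, (list, tuple)) else len(X)
        return np.tile(self.frequencies_, (n, 1))


class BlastTransferBaseline(BaseEstimator):
    """sklearn-style wrapper over the BLAST scoring rules.

    ``mode="full"`` emits binary rows copied from the best hit;
    ``mode="partial"`` emits identity-scaled scores in [0, 1].
    """

    def __init__(self, mode: str = "partial"):
        self.mode = mode

    def fit(self, train_annots: AnnotationSet, space: LabelSpace):
        if self.mode not in ("full", "partial"):
            raise ValueError("mode must be 'full' or 'partial'")
        self.train_annots_ = train_annots
        self.space_ = space
        return self

    def predict(self, hits: HitTable, queries: list[str]) -> np.ndarray:
        if not hasattr(self, "train_annots_"):
            raise AttributeError("estimator is not fitted")
        fn = blast_full if self.mode == "full" else blast_partial
        return fn(hits, self.train_annots_, self.space_, queries)
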