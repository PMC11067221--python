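"""Per-view feature matrices, multi-view dataset assembly and homology-aware CV.

A "view" is one feature representation of a protein (sequence embedding,
binary domain fingerprint, PPI adjacency profile).  Cross-validation splits
operate on sequence clusters, never on individual proteins, so that no test
protein shares cluster membership (>=30% identity in the intended workflow)
with any training protein.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ViewMatrix:
    name: str
    roster: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.roster):
            raise ValueError(
                f"view {self.name}: {self.values.shape[0]} rows for "
                f"{len(self.roster)} roster proteins"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"view {self.name}: non-finite values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class MultiViewDataset:
    """Aligned views + binary labels (+ optional cluster ids) over one roster."""

    roster: list[str]
    views: list[ViewMatrix]
    Y: np.ndarray
    clusters: dict[str, str] | None = None

    def __post_init__(self):
        self.Y = np.asarray(self.Y)
        m = len(self.roster)
        if self.Y.shape[0] != m:
            raise ValueError("Y row count does not match roster")
        if not np.isin(self.Y, (0, 1)).all():
            raise ValueError("Y must be binary")
        for v in self.views:
            if v.roster != self.roster:
                raise ValueError(f"view {v.name} roster misaligned")

    @property
    def n_samples(self) -> int:
        return len(self.roster)

    @property
    def X(self) -> list[np.ndarray]:
        return [v.values for v in self.views]

    def subset(self, idx: Sequence[int]) -> "MultiViewDataset":
        idx = list(idx)
        roster = [self.roster[i] for i in idx]
        views = [ViewMatrix(v.name, roster, v.values[idx]) for v in self.views]
        clusters = (
            {p: self.clusters[p] for p in roster} if self.clusters else None
        )
        return MultiViewDataset(roster, views, self.Y[idx], clusters)


@dataclass
class FoldPlan:
    """Cluster-grouped train/validation/test partitions."""

    folds: list[tuple[list[str], list[str], list[str]]]
    n_folds: int
    seed: int


def binary_fingerprint_matrix(
    records: Mapping[str, set[str] | frozenset[str]],
    vocabulary: Sequence[str],
    name: str = "fingerprint",
    on_unknown: str = "drop",
) -> ViewMatrix:
    """0/1 indicator matrix: column j marks presence of vocabulary[j].

    Feature ids outside the vocabulary are dropped with a log line (default)
    or raise, depending on ``on_unknown``.
    """
    if not len(vocabulary):
        raise ValueError("vocabulary must be non-empty")
    col = {f: j for j, f in enumerate(vocabulary)}
    roster = list(records)
    X = np.zeros((len(roster), len(vocabulary)))
    n_unknown = 0
    for i, prot in enumerate(roster):
        for f in records[prot]:
            j = col.get(f)
            if j is None:
                if on_unknown == "error":
                    raise KeyError(f"feature {f} not in vocabulary")
                n_unknown += 1
                continue
            X[i, j] = 1.0
    if n_unknown:
        logger.info("fingerprint: dropped %d out-of-vocabulary features", n_unknown)
    return ViewMatrix(name, roster, X)


def ppi_adjacency(
    edges: Iterable[tuple],
    roster: Sequence[str],
    name: str = "ppi",
) -> ViewMatrix:
    """Symmetric m x m adjacency over ``roster`` from an edge list.

    Edge tuples are (a, b) or (a, b, weight); unweighted edges get weight 1.
    Edges touching proteins outside the roster, and self-loops, are dropped
    with a log line.  Proteins with no edges keep an all-zero row (absence of
    interaction evidence).
    """
    idx = {p: i for i, p in enumerate(roster)}
    A = np.zeros((len(roster), len(roster)))
    n_out = n_self = 0
    for e in edges:
        a, b = e[0], e[1]
        w = float(e[2]) if len(e) > 2 else 1.0
        if a == b:
            n_self += 1
            continue
        if a not in idx or b not in idx:
            n_out += 1
            continue
        A[idx[a], idx[b]] = w
        A[idx[b], idx[a]] = w
    if n_out or n_self:
        logger.info("ppi: dropped %d off-roster edges, %d self-loops", n_out, n_self)
    return ViewMatrix(name, list(roster), A)


def read_feature_table(stream, name: str = "view") -> ViewMatrix:
    """Read a tab-separated feature table (header row; first column protein_id)."""
    if isinstance(stream, str) and "\t" in stream:
        stream = io.StringIO(stream)
    df = pd.read_csv(stream, sep="\t", dtype={0: str})
    prot_col = df.columns[0]
    roster = df[prot_col].tolist()
    if len(set(roster)) != len(roster):
        raise ValueError("duplicate protein ids in feature table")
    values = df.drop(columns=[prot_col]).to_numpy(dtype=float)
    return ViewMatrix(name, roster, values)


def write_feature_table(view: ViewMatrix, path) -> None:
    df = pd.DataFrame(view.values,
                      columns=[f"f{j}" for j in range(view.n_features)])
    df.insert(0, "protein_id", view.roster)
    df.to_csv(path, sep="\t", index=False)


def read_clusters(stream) -> dict[str, str]:
    """Read a two-column TSV (representative, member) into member -> cluster id."""
    if isinstance(stream, str) and "\t" in stream:
        stream = io.StringIO(stream)
    out: dict[str, str] = {}
    handle = open(stream) if isinstance(stream, str) else stream
    try:
        for ln, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {ln}: expected 2 tab-separated fields")
            rep, member = parts
            out[member] = rep
    finally:
        if isinstance(stream, str):
            handle.close()
    return out


def cluster_cv_folds(
    clusters: Mapping[str, str],
    roster: Sequence[str],
    n_folds: int = 10,
    val_fraction: float = 0.10,
    seed: int = 0,
) -> FoldPlan:
    """Cluster-grouped k-fold splits with a cluster-wise validation carve-out.

    Clusters are shuffled with ``seed`` and dealt round-robin into ``n_folds``
    test groups (~1/n_folds of clusters each); per fold, the remaining
    clusters form the training side, from which ~``val_fraction`` of clusters
    are carved out as validation.  Whole clusters are never split across the
    train+validation / test boundary.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    missing = [p for p in roster if p not in clusters]
    if missing:
        raise ValueError(f"proteins without cluster id: {missing[:5]}")
    members: dict[str, list[str]] = {}
    for p in roster:
        members.setdefault(clusters[p], []).append(p)
    cluster_ids = sorted(members)
    if len(cluster_ids) < n_folds:
        raise ValueError(
            f"{len(cluster_ids)} clusters cannot support {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = [cluster_ids[i] for i in rng.permutation(len(cluster_ids))]

    folds = []
    for k in range(n_folds):
        test_clusters = order[k::n_folds]
        train_clusters = [c for c in order if c not in set(test_clusters)]
        n_val = max(1, round(val_fraction * len(train_clusters)))
        val_clusters = set(train_clusters[:n_val])
        train = [p for c in train_clusters if c not in val_clusters
                 for p in members[c]]
        val = [p for c in train_clusters if c in val_clusters
               for p in members[c]]
        test = [p for c in test_clusters for p in members[c]]
        folds.append((train, val, test))
    return FoldPlan(folds=folds, n_folds=n_folds, seed=seed)


def assemble_dataset(
    views: Sequence[ViewMatrix],
    Y: np.ndarray,
    roster: Sequence[str],
    clusters: Mapping[str, str] | None = None,
) -> MultiViewDataset:
    """Re-index all views to ``roster`` order and bundle with labels."""
    roster = list(roster)
    aligned = []
    for v in views:
        pos = {p: i for i, p in enumerate(v.roster)}
        missing = [p for p in roster if p not in pos]
        if missing:
            raise ValueError(
                f"protein {missing[0]} missing from view {v.name}"
            )
        idx = [pos[p] for p in roster]
        aligned.append(ViewMatrix(v.name, roster, v.values[idx]))
    cl = dict(clusters) if clusters is not None else None
    if cl is not None:
        cl = {p: cl[p] for p in roster}
    return MultiViewDataset(roster=roster, views=aligned,
                            Y=np.asarray(Y), clusters=cl)
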