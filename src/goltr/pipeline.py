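"""End-to-end orchestration: prepare, train, predict, evaluate, baseline.

Functions here implement the pipeline stages behind the command-line
interface; each consumes/produces plain files so runs are reproducible and
resumable.  Stage order mirrors the annotation workflow: evidence filtering,
true-path propagation, frequency-based label selection, label encoding,
dataset assembly and cluster-grouped fold construction.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import ontology as onto
from . import views as views_mod
from .baselines import (HitTable, blast_full, blast_partial, naive_scores,
                        read_blast_tabular)
from .ltr import LatentTensorReconstruction
from .metrics import EvalConfig, MetricsReport, evaluate
from .ontology import LabelSpace, propagate_scores_max
from .views import MultiViewDataset

logger = logging.getLogger(__name__)


def space_to_json(space: LabelSpace) -> dict:
    return {
        "namespace": space.namespace,
        "terms": space.terms,
        "ancestors_in_space": {
            str(i): sorted(a) for i, a in space.ancestors_in_space.items()
        },
        "ic": None if space.ic is None else [float(x) for x in space.ic],
    }


def space_from_json(obj: dict) -> LabelSpace:
    terms = obj["terms"]
    index = {t: i for i, t in enumerate(terms)}
    anc = {int(i): frozenset(a)
           for i, a in obj["ancestors_in_space"].items()}
    ic = None if obj.get("ic") is None else np.asarray(obj["ic"])
    return LabelSpace(namespace=obj["namespace"], terms=terms, index=index,
                      ancestors_in_space=anc, ic=ic)


def prepare(obo_path, annotations_path, view_paths, clusters_path,
            out_dir, namespace: str, min_count: int,
            n_folds: int = 10, seed: int = 0) -> dict:
    """Run the preparation pipeline and persist its artifacts.

    evidence filter -> true-path propagation -> label-space selection ->
    label encoding -> dataset assembly -> cluster-grouped folds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(obo_path) as fh:
        dag = onto.parse_obo(fh)
    with open(annotations_path) as fh:
        records = onto.read_annotation_table(fh)
    annots = onto.filter_evidence(records)
    annots = onto.propagate_true_path(annots, dag)
    space = onto.select_label_space(annots, dag, namespace, min_count)
    space.ic = onto.information_content(annots, dag, space)

    view_list = []
    for p in view_paths:
        view_list.append(views_mod.read_feature_table(p, name=Path(p).stem))
    roster = [p for p in view_list[0].roster if p in annots.entries]
    Y = onto.encode_labels(annots, space, roster)
    clusters = views_mod.read_clusters(str(clusters_path))
    dataset = views_mod.assemble_dataset(view_list, Y, roster, clusters)
    folds = views_mod.cluster_cv_folds(clusters, roster, n_folds=n_folds,
                                       seed=seed)

    (out / "space.json").write_text(json.dumps(space_to_json(space)) + "\n")
    arrays = {"Y": dataset.Y,
              "roster": np.array(dataset.roster, dtype=str)}
    for v in dataset.views:
        arrays[f"view_{v.name}"] = v.values
    np.savez(out / "dataset.npz", **arrays)
    (out / "folds.json").write_text(json.dumps({
        "seed": seed, "n_folds": n_folds,
        "folds": [{"train": tr, "val": va, "test": te}
                  for tr, va, te in folds.folds],
    }) + "\n")
    (out / "clusters.json").write_text(json.dumps(clusters) + "\n")
    return {"space": space, "dataset": dataset, "folds": folds}


def load_prepared(out_dir) -> tuple[LabelSpace, MultiViewDataset, list]:
    out = Path(out_dir)
    space = space_from_json(json.loads((out / "space.json").read_text()))
    with np.load(out / "dataset.npz", allow_pickle=False) as z:
        roster = [str(p) for p in z["roster"]]
        Y = z["Y"]
        views = [views_mod.ViewMatrix(k[len("view_"):], roster, z[k])
                 for k in z.files if k.startswith("view_")]
    clusters = json.loads((out / "clusters.json").read_text())
    dataset = MultiViewDataset(roster, views, Y, clusters)
    fold_obj = json.loads((out / "folds.json").read_text())
    folds = [(f["train"], f["val"], f["test"]) for f in fold_obj["folds"]]
    return space, dataset, folds


def _indices(roster: list[str], ids: list[str]) -> list[int]:
    pos = {p: i for i, p in enumerate(roster)}
    return [pos[p] for p in ids]


def train_fold(dataset: MultiViewDataset, fold: tuple, model_kwargs: dict,
               refit_on_full: bool = True
               ) -> LatentTensorReconstruction:
    """Fit on a fold's training side with validation-based model selection.

    When ``refit_on_full`` is set, after validation selection the model is
    retrained on train+validation (the final model evaluated on the test
    side); disable for speed in smoke runs.
    """
    train_ids, val_ids, _ = fold
    tr = dataset.subset(_indices(dataset.roster, train_ids))
    est = LatentTensorReconstruction(**model_kwargs)
    if val_ids:
        va = dataset.subset(_indices(dataset.roster, val_ids))
        est.fit(tr.X, tr.Y, X_val=va.X, Y_val=va.Y)
    else:
        est.fit(tr.X, tr.Y)
    if refit_on_full and val_ids:
        full = dataset.subset(
            _indices(dataset.roster, list(train_ids) + list(val_ids)))
        est = LatentTensorReconstruction(**model_kwargs)
        est.fit(full.X, full.Y)
    return est


def write_predictions(path, roster: list[str], scores: np.ndarray,
                      space: LabelSpace) -> None:
    """CAFA-style prediction TSV: protein, term, score to 3 decimals.

    Zero scores are omitted (submission convention); rounding is the
    half-even rounding of float formatting.
    """
    with open(path, "w") as fh:
        for i, prot in enumerate(roster):
            for j in range(scores.shape[1]):
                s = scores[i, j]
                if s > 0:
                    fh.write(f"{prot}\t{space.terms[j]}\t{s:.3f}\n")


def predict_consistent(est: LatentTensorReconstruction,
                       dataset: MultiViewDataset,
                       space: LabelSpace) -> np.ndarray:
    """Predict, clip to [0,1], and enforce hierarchical consistency."""
    S = est.predict(dataset.X)
    return propagate_scores_max(S, space)


def read_predictions(path, roster: list[str],
                     space: LabelSpace) -> np.ndarray:
    """Reconstruct a dense score matrix from a prediction TSV (missing = 0)."""
    S = np.zeros((len(roster), len(space)))
    pos = {p: i for i, p in enumerate(roster)}
    unknown: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            prot, term, score = line.split("\t")
            j = space.index.get(term)
            if j is None:
                unknown.add(term)
                continue
            if prot in pos:
                S[pos[prot], j] = float(score)
    if unknown:
        raise ValueError(f"unknown term ids in predictions: {sorted(unknown)[:5]}")
    return S


def evaluate_predictions(path, dataset: MultiViewDataset,
                         space: LabelSpace, test_ids: list[str],
                         cfg: EvalConfig | None = None) -> MetricsReport:
    idx = _indices(dataset.roster, test_ids)
    S = read_predictions(path, test_ids, space)
    return evaluate(dataset.Y[idx], S, ic=space.ic, cfg=cfg)


def baseline_scores(kind: str, dataset: MultiViewDataset, space: LabelSpace,
                    fold: tuple, hits: HitTable | None = None) -> np.ndarray:
    """Score the test side of one fold with a named baseline."""
    train_ids, val_ids, test_ids = fold
    tr_idx = _indices(dataset.roster, list(train_ids) + list(val_ids))
    if kind == "naive":
        return naive_scores(dataset.Y[tr_idx], len(test_ids))
    if hits is None:
        raise ValueError(f"baseline {kind!r} requires a hit table")
    train_annots = onto.AnnotationSet(entries={
        dataset.roster[i]: {space.terms[j]
                            for j in np.flatnonzero(dataset.Y[i])}
        for i in tr_idx
    })
    if kind == "blast-full":
        return blast_full(hits, train_annots, space, list(test_ids))
    if kind == "blast-partial":
        return blast_partial(hits, train_annots, space, list(test_ids))
    raise ValueError(f"unknown baseline kind {kind!r}")
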