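"""Synthetic data generation for desk-scale, download-free testing.

Generates every input the pipeline consumes: a toy is-a DAG (written as OBO
text), a planted low-rank latent-tensor model, multi-view Gaussian/Bernoulli
features, hierarchically consistent binary labels derived from the planted
model's scores, cluster assignments, and a synthetic alignment hit table.

Labels are made consistent by construction: planted scores are min-max
scaled per term, max-propagated up the DAG, and thresholded at a per-term
quantile, so every label row is ancestor-closed before (and after) optional
noise flips, which are re-closed upward/downward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ltr
from .ontology import (AnnotationSet, LabelSpace, OntologyDAG, parse_obo,
                       propagate_scores_max)
from .views import MultiViewDataset, ViewMatrix, write_feature_table

_NS_LONG = {"MFO": "molecular_function", "CCO": "cellular_component",
            "BPO": "biological_process"}


@dataclass
class SimConfig:
    """Study conditions for one synthetic bundle."""

    seed: int = 0
    m: int = 1000                      # proteins
    view_dims: tuple[int, ...] = (20, 20)
    n_t: int = 3                       # planted CP rank
    k_d: int | None = None
    n_y: int = 30                      # label-space size (non-root terms)
    dag_depth: int = 3
    dag_branching: int = 4
    multi_parent_fraction: float = 0.2
    namespace: str = "BPO"
    label_noise: float = 0.0           # per-entry flip probability
    positive_quantile: float = 0.8     # score quantile above which Y=1
    binary_views: tuple[bool, ...] | None = None
    n_clusters: int = 37

    def __post_init__(self):
        if not 0 <= self.label_noise <= 1:
            raise ValueError("label_noise must be a probability")
        if not 0 < self.positive_quantile <= 1:
            raise ValueError("positive_quantile must be in (0, 1]")


def _term_id(i: int) -> str:
    return f"GO:{i:07d}"


def make_toy_ontology(cfg: SimConfig) -> OntologyDAG:
    """Single-root layered is-a DAG with a fraction of multi-parent nodes."""
    if cfg.dag_depth < 1 or cfg.dag_branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    ns = cfg.namespace
    root = _term_id(1)
    terms: dict[str, tuple[str, str]] = {root: (f"{ns} root", ns)}
    parents: dict[str, frozenset[str]] = {root: frozenset()}
    layers = [[root]]
    next_id = 2
    for depth in range(cfg.dag_depth):
        layer = []
        for parent in layers[-1]:
            for _ in range(cfg.dag_branching):
                tid = _term_id(next_id)
                next_id += 1
                pset = {parent}
                # multi-parent: add a second parent from the same layer
                if (len(layers[-1]) > 1
                        and rng.random() < cfg.multi_parent_fraction):
                    other = layers[-1][rng.integers(len(layers[-1]))]
                    pset.add(other)
                terms[tid] = (f"term {next_id - 1}", ns)
                parents[tid] = frozenset(pset)
                layer.append(tid)
        layers.append(layer)
    return OntologyDAG(terms=terms, parents=parents, roots={ns: root})


def write_obo(dag: OntologyDAG, path=None) -> str:
    """Serialise an :class:`OntologyDAG` as OBO 1.2 text."""
    lines = ["format-version: 1.2", ""]
    for term in sorted(dag.terms):
        name, ns = dag.terms[term]
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {name}")
        lines.append(f"namespace: {_NS_LONG.get(ns, ns)}")
        for p in sorted(dag.parents[term]):
            lines.append(f"is_a: {p} ! {dag.terms[p][0]}")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text


def toy_label_space(dag: OntologyDAG, n_y: int | None = None) -> LabelSpace:
    """Label space of the first ``n_y`` non-root terms in topological order.

    A topological prefix is automatically ancestor-closed (minus the root),
    so ``ancestors_in_space`` is complete without further filtering.
    """
    ns = next(iter(dag.roots))
    root = dag.roots[ns]
    ordered = [t for t in dag.topological_order() if t != root]
    if n_y is not None:
        if n_y > len(ordered):
            raise ValueError(
                f"DAG has only {len(ordered)} non-root terms, need {n_y}"
            )
        ordered = ordered[:n_y]
    index = {t: i for i, t in enumerate(ordered)}
    anc = {
        i: frozenset(index[a] for a in dag.ancestors(t) if a in index)
        for t, i in index.items()
    }
    return LabelSpace(namespace=ns, terms=ordered, index=index,
                      ancestors_in_space=anc)


def plant_model(cfg: SimConfig, n_y: int | None = None) -> ltr.LTRParams:
    """Planted ground-truth model with identifiable (|lambda_t| >= 0.1) weights."""
    n_y = cfg.n_y if n_y is None else n_y
    params = ltr.init_params(
        list(cfg.view_dims), n_y, cfg.n_t, cfg.k_d, seed=cfg.seed
    )
    rng = np.random.default_rng(cfg.seed + 1)
    lam = rng.normal(size=cfg.n_t)
    lam = np.sign(lam) * np.maximum(np.abs(lam), 0.1)
    params.lam = lam
    return params


def sample_views(cfg: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    binary = cfg.binary_views or (False,) * len(cfg.view_dims)
    X = []
    for d, nx in enumerate(cfg.view_dims):
        if binary[d]:
            X.append(rng.binomial(1, 0.1, size=(cfg.m, nx)).astype(float))
        else:
            X.append(rng.normal(size=(cfg.m, nx)))
    return X


def sample_multiview(cfg: SimConfig, truth: ltr.LTRParams,
                     space: LabelSpace) -> MultiViewDataset:
    """Draw features, score with the planted model, derive consistent labels."""
    if truth.view_dims != list(cfg.view_dims):
        raise ValueError("planted model dims do not match config")
    if truth.Q.shape[0] != len(space):
        raise ValueError("planted model output dim does not match label space")
    rng = np.random.default_rng(cfg.seed + 2)
    X = sample_views(cfg, rng)
    raw = ltr.predict_scores(truth, X)

    lo, hi = raw.min(axis=0), raw.max(axis=0)
    span = hi - lo
    degenerate = span <= 0
    span = np.where(degenerate, 1.0, span)
    scaled = (raw - lo) / span
    consistent = propagate_scores_max(scaled, space)

    thresh = np.quantile(consistent, cfg.positive_quantile, axis=0)
    thresh = np.where(degenerate, np.inf, thresh)
    Y = (consistent >= thresh).astype(np.int8)
    # per-term thresholds can break closure (a child may clear its lower
    # threshold while the parent misses its higher one); close upward
    for j in range(Y.shape[1]):
        anc = sorted(space.ancestors_in_space[j])
        if anc:
            rows = Y[:, j] == 1
            Y[np.ix_(rows, anc)] = 1

    if cfg.label_noise > 0:
        Y = _apply_label_noise(Y, space, cfg.label_noise, rng)

    roster = [f"P{i:05d}" for i in range(cfg.m)]
    views = [ViewMatrix(f"view{d}", roster, X[d]) for d in range(len(X))]
    clusters = simulate_clusters(cfg.m, cfg.n_clusters, cfg.seed + 3,
                                 roster=roster)
    return MultiViewDataset(roster=roster, views=views, Y=Y,
                            clusters=clusters)


def _apply_label_noise(Y, space, p, rng):
    """Flip labels, then re-close: added terms pull in ancestors, removed
    terms drop their in-space descendants, keeping rows ancestor-closed."""
    Y = Y.copy()
    desc: dict[int, list[int]] = {j: [] for j in range(len(space))}
    for j in range(len(space)):
        for a in space.ancestors_in_space[j]:
            desc[a].append(j)
    flips = rng.random(Y.shape) < p
    for i in range(Y.shape[0]):
        for j in np.flatnonzero(flips[i]):
            if Y[i, j]:
                Y[i, j] = 0
                Y[i, desc[j]] = 0
            else:
                Y[i, j] = 1
                for a in space.ancestors_in_space[j]:
                    Y[i, a] = 1
    return Y


def simulate_clusters(m: int, n_clusters: int, seed: int,
                      roster: list[str] | None = None) -> dict[str, str]:
    """Seeded assignment of proteins to non-empty clusters."""
    if n_clusters > m:
        raise ValueError("more clusters than proteins")
    rng = np.random.default_rng(seed)
    roster = roster or [f"P{i:05d}" for i in range(m)]
    # guarantee non-empty clusters, then deal the rest multinomially
    assign = list(range(n_clusters))
    assign += rng.integers(n_clusters, size=m - n_clusters).tolist()
    assign = [assign[i] for i in rng.permutation(m)]
    return {p: f"C{c:04d}" for p, c in zip(roster, assign)}


def synthetic_hit_table(dataset: MultiViewDataset, seed: int,
                        n_hits_per_query: int = 3) -> str:
    """Synthetic 12-column tabular alignment text linking roster proteins.

    Hits are fabricated (random subjects, identities and e-values); they
    exercise the alignment-transfer scoring rules without running an aligner.
    """
    rng = np.random.default_rng(seed)
    roster = dataset.roster
    lines = []
    for q in roster:
        n = rng.integers(0, n_hits_per_query + 1)
        subjects = rng.choice(len(roster), size=n, replace=False)
        for si in subjects:
            s = roster[int(si)]
            if s == q:
                continue
            pident = float(rng.uniform(30, 100))
            evalue = float(10 ** rng.uniform(-30, 0))
            bits = float(rng.uniform(50, 500))
            lines.append(
                f"{q}\t{s}\t{pident:.1f}\t100\t5\t1\t1\t100\t1\t100\t"
                f"{evalue:.2e}\t{bits:.1f}"
            )
    return "\n".join(lines) + ("\n" if lines else "")


def annotations_from_labels(dataset: MultiViewDataset,
                            space: LabelSpace) -> AnnotationSet:
    """Annotation set (protein -> in-space terms) recovered from Y rows."""
    entries = {
        p: {space.terms[j] for j in np.flatnonzero(dataset.Y[i])}
        for i, p in enumerate(dataset.roster)
    }
    return AnnotationSet(entries=entries)


def write_fixture_bundle(cfg: SimConfig, directory) -> dict[str, str]:
    """Emit a complete on-disk input bundle readable by the CLI pipeline.

    Writes OBO ontology, annotation TSV (evidence code EXP), per-view
    feature tables, cluster TSV, a synthetic alignment hit table, and a
    manifest recording the seed and sizes.  Returns the path map.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dag = make_toy_ontology(cfg)
    space = toy_label_space(dag, cfg.n_y)
    truth = plant_model(cfg, n_y=len(space))
    dataset = sample_multiview(cfg, truth, space)

    paths = {}
    paths["obo"] = str(directory / "ontology.obo")
    write_obo(dag, paths["obo"])

    ann_lines = ["# protein_id\tterm_id\tevidence_code"]
    for i, p in enumerate(dataset.roster):
        for j in np.flatnonzero(dataset.Y[i]):
            ann_lines.append(f"{p}\t{space.terms[j]}\tEXP")
    paths["annotations"] = str(directory / "annotations.tsv")
    Path(paths["annotations"]).write_text("\n".join(ann_lines) + "\n")

    view_paths = []
    for v in dataset.views:
        p = directory / f"{v.name}.tsv"
        write_feature_table(v, p)
        view_paths.append(str(p))
    paths["views"] = view_paths

    paths["clusters"] = str(directory / "clusters.tsv")
    with open(paths["clusters"], "w") as fh:
        for prot, cl in dataset.clusters.items():
            fh.write(f"{cl}\t{prot}\n")

    paths["hits"] = str(directory / "hits.tsv")
    Path(paths["hits"]).write_text(
        synthetic_hit_table(dataset, cfg.seed + 4)
    )

    manifest = {
        "seed": cfg.seed, "m": cfg.m, "n_y": len(space),
        "view_dims": list(cfg.view_dims), "n_t": cfg.n_t,
        "namespace": cfg.namespace, "n_clusters": cfg.n_clusters,
        "files": paths,
    }
    paths["manifest"] = str(directory / "manifest.json")
    Path(paths["manifest"]).write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
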