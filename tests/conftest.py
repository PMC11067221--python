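"""Shared fixtures: toy ontologies, random DAGs and random score fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from goltr.ontology import LabelSpace, OntologyDAG
from goltr.synthetic import SimConfig, make_toy_ontology, toy_label_space


def random_dag(n_terms: int, seed: int, namespace: str = "BPO") -> OntologyDAG:
    """Random single-root DAG: each node picks 1-2 parents among earlier nodes."""
    rng = np.random.default_rng(seed)
    ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    terms = {t: (f"term {i}", namespace) for i, t in enumerate(ids)}
    parents: dict[str, frozenset[str]] = {ids[0]: frozenset()}
    for i in range(1, n_terms):
        k = 1 + int(rng.random() < 0.3 and i > 1)
        pars = rng.choice(i, size=min(k, i), replace=False)
        parents[ids[i]] = frozenset(ids[int(p)] for p in pars)
    return OntologyDAG(terms=terms, parents=parents,
                       roots={namespace: ids[0]})


def full_label_space(dag: OntologyDAG) -> LabelSpace:
    return toy_label_space(dag)


def bfs_ancestors(dag: OntologyDAG, term: str) -> set[str]:
    """Independent breadth-first ancestor closure used as an oracle."""
    seen: set[str] = set()
    frontier = [term]
    while frontier:
        nxt = []
        for t in frontier:
            for p in dag.parents[t]:
                if p not in seen:
                    seen.add(p)
                    nxt.append(p)
        frontier = nxt
    return seen


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """root <- a <- leaf chain in one namespace."""
    ns = "MFO"
    terms = {"GO:0000001": ("root", ns), "GO:0000002": ("a", ns),
             "GO:0000003": ("leaf", ns)}
    parents = {"GO:0000001": frozenset(),
               "GO:0000002": frozenset({"GO:0000001"}),
               "GO:0000003": frozenset({"GO:0000002"})}
    return OntologyDAG(terms=terms, parents=parents, roots={ns: "GO:0000001"})


@pytest.fixture
def toy_bundle():
    """Small toy ontology + label space + config used across modules."""
    cfg = SimConfig(seed=11, m=300, n_y=20, view_dims=(10, 12), n_t=2,
                    dag_depth=3, dag_branching=3)
    dag = make_toy_ontology(cfg)
    space = toy_label_space(dag, cfg.n_y)
    return cfg, dag, space
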