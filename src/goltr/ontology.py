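"""Gene Ontology DAG handling: parsing, true-path propagation, label spaces, IC.

The ontology is restricted to ``is_a`` edges within each namespace (MFO, CCO,
BPO).  Annotations propagated with the true-path rule form ancestor-closed
("consistent") sub-graphs of the DAG; label spaces are frequency-filtered term
lists excluding the namespace roots; information content is the conditional
surprisal of a term given that all of its parents are annotated.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger(__name__)

NAMESPACES = {
    "molecular_function": "MFO",
    "cellular_component": "CCO",
    "biological_process": "BPO",
}

#: Experimental / curated evidence codes accepted by default.
DEFAULT_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS", "IC",
     "HTP", "HDA", "HMP", "HGI", "HEP"}
)


class OntologyStructureError(ValueError):
    """Raised when the parsed ontology violates DAG structure requirements."""


class UnknownTermError(KeyError):
    """Raised when an annotation references a term absent from the ontology."""


@dataclass
class OntologyDAG:
    """is_a-only GO DAG.

    Attributes
    ----------
    terms : dict
        term id -> (name, namespace code in {MFO, CCO, BPO}).
    parents : dict
        term id -> frozenset of direct is_a parents (same namespace).
    roots : dict
        namespace code -> root term id (the unique parent-less term).
    alt_ids : dict
        alternate id -> canonical id.
    """

    terms: dict[str, tuple[str, str]]
    parents: dict[str, frozenset[str]]
    roots: dict[str, str]
    alt_ids: dict[str, str] = field(default_factory=dict)

    def canonical(self, term: str) -> str:
        """Map an (alternate) id to its canonical term id."""
        if term in self.terms:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise UnknownTermError(term)

    def namespace_of(self, term: str) -> str:
        return self.terms[self.canonical(term)][1]

    def ancestors(self, term: str) -> frozenset[str]:
        """All strict ancestors of ``term`` (self excluded) via is_a edges."""
        term = self.canonical(term)
        seen: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.parents[t])
        return frozenset(seen)

    def children_map(self) -> dict[str, set[str]]:
        kids: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, pars in self.parents.items():
            for p in pars:
                kids[p].add(child)
        return kids

    def topological_order(self) -> list[str]:
        """Parents before children; ties broken lexicographically by term id."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, pars in self.parents.items():
            for p in pars:
                g.add_edge(p, child)
        return list(nx.lexicographical_topological_sort(g))


@dataclass
class AnnotationSet:
    """Protein -> set-of-terms map, optionally carrying evidence codes."""

    entries: dict[str, set[str]]
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def proteins(self) -> list[str]:
        return list(self.entries)

    def count_annotated(self, term: str) -> int:
        return sum(1 for s in self.entries.values() if term in s)


@dataclass
class LabelSpace:
    """Ordered, root-free selection of terms from one namespace."""

    namespace: str
    terms: list[str]
    index: dict[str, int]
    ancestors_in_space: dict[int, frozenset[int]]
    ic: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def n_terms(self) -> int:
        return len(self.terms)


def parse_obo(stream) -> OntologyDAG:
    """Parse OBO 1.2 text into an is_a-only :class:`OntologyDAG`.

    ``relationship:`` tags (part_of etc.) and typedef stanzas are ignored;
    obsolete terms are dropped; ``alt_id`` tags populate the alias map.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    graph = obonet.read_obo(stream, ignore_obsolete=True)

    terms: dict[str, tuple[str, str]] = {}
    parents: dict[str, frozenset[str]] = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        ns_raw = data.get("namespace", "")
        ns = NAMESPACES.get(ns_raw, ns_raw)
        terms[node] = (data.get("name", node), ns)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node

    for node in terms:
        pars = set()
        # obonet edges run child -> parent keyed by relation type
        for _, parent, key in graph.out_edges(node, keys=True):
            if key != "is_a":
                continue
            if parent not in terms:
                raise OntologyStructureError(
                    f"term {node} references unknown parent {parent}"
                )
            pars.add(parent)
        parents[node] = frozenset(pars)

    dag_check = nx.DiGraph(
        (p, c) for c, ps in parents.items() for p in ps
    )
    if dag_check.number_of_edges() and not nx.is_directed_acyclic_graph(dag_check):
        cyc = nx.find_cycle(dag_check)
        raise OntologyStructureError(f"cycle detected through edge {cyc[0]}")

    roots: dict[str, str] = {}
    for term, (name, ns) in terms.items():
        if not parents[term]:
            if ns in roots:
                raise OntologyStructureError(
                    f"namespace {ns} has multiple roots: {roots[ns]}, {term}"
                )
            roots[ns] = term
    return OntologyDAG(terms=terms, parents=parents, roots=roots, alt_ids=alt_ids)


def read_annotation_table(stream) -> list[tuple[str, str, str]]:
    """Read tab-separated ``protein_id  term_id  evidence_code`` records.

    Lines starting with '#' are comments.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records = []
    for ln, line in enumerate(stream, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"line {ln}: expected 3 tab-separated fields")
        records.append((parts[0], parts[1], parts[2]))
    return records


def filter_evidence(
    records: Iterable[tuple[str, str, str]],
    allowed: frozenset[str] | set[str] = DEFAULT_EVIDENCE_CODES,
) -> AnnotationSet:
    """Keep records whose evidence code is in ``allowed``.

    Proteins left with no surviving record are dropped entirely.
    """
    if not allowed:
        raise ValueError("allowed evidence-code set must be non-empty")
    entries: dict[str, set[str]] = {}
    evidence: dict[tuple[str, str], str] = {}
    n_in = n_kept = 0
    for prot, term, code in records:
        n_in += 1
        if code not in allowed:
            continue
        n_kept += 1
        entries.setdefault(prot, set()).add(term)
        evidence[(prot, term)] = code
    logger.info("evidence filter: kept %d / %d records", n_kept, n_in)
    return AnnotationSet(entries=entries, evidence=evidence)


def propagate_true_path(annots: AnnotationSet, dag: OntologyDAG) -> AnnotationSet:
    """Close every protein's annotation set under is_a ancestors.

    Each annotated term implies all of its ancestors up to and including the
    namespace root; the operation is idempotent.
    """
    n_mapped = 0
    out: dict[str, set[str]] = {}
    for prot, terms in annots.entries.items():
        closed: set[str] = set()
        for t in terms:
            ct = dag.canonical(t)  # raises UnknownTermError on unknown ids
            if ct != t:
                n_mapped += 1
            closed.add(ct)
            closed |= dag.ancestors(ct)
        out[prot] = closed
    if n_mapped:
        logger.info("alt_id mapping applied to %d annotation(s)", n_mapped)
    return AnnotationSet(entries=out)


def select_label_space(
    annots: AnnotationSet,
    dag: OntologyDAG,
    namespace: str,
    min_count: int,
) -> LabelSpace:
    """Frequency-filter the terms of one namespace into an ordered label space.

    Keeps namespace terms annotated (after propagation) in at least
    ``min_count`` proteins, excluding the namespace root.  Order is
    topological with lexicographic tie-break, so matrices are reproducible.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    root = dag.roots.get(namespace)
    counts: dict[str, int] = {}
    for terms in annots.entries.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    selected = {
        t for t, c in counts.items()
        if c >= min_count and t != root and dag.namespace_of(t) == namespace
    }
    if not selected:
        raise ValueError(
            f"no labels survive threshold min_count={min_count} in {namespace}"
        )
    ordered = [t for t in dag.topological_order() if t in selected]
    index = {t: i for i, t in enumerate(ordered)}
    anc: dict[int, frozenset[int]] = {}
    for t, i in index.items():
        anc[i] = frozenset(index[a] for a in dag.ancestors(t) if a in index)
    return LabelSpace(namespace=namespace, terms=ordered, index=index,
                      ancestors_in_space=anc)


def encode_labels(
    annots: AnnotationSet, space: LabelSpace, roster: Sequence[str]
) -> np.ndarray:
    """Binary (m x n_y) label matrix for ``roster`` over ``space``."""
    Y = np.zeros((len(roster), len(space)), dtype=np.int8)
    for i, prot in enumerate(roster):
        if prot not in annots.entries:
            raise KeyError(f"protein {prot} missing from annotation set")
        for t in annots.entries[prot]:
            j = space.index.get(t)
            if j is not None:
                Y[i, j] = 1
    return Y


def information_content(
    annots: AnnotationSet, dag: OntologyDAG, space: LabelSpace
) -> np.ndarray:
    """Conditional information content I(v) = -log2 P(v | parents(v)), in bits.

    P is the empirical fraction of proteins annotated with v among proteins
    annotated with *all* parents of v (propagated sets make v imply all of
    its parents, so the ratio is a conditional probability).
    """
    prots = list(annots.entries)
    sets = [annots.entries[p] for p in prots]
    ic = np.zeros(len(space))
    for j, term in enumerate(space.terms):
        pars = dag.parents[term]
        n_v = sum(1 for s in sets if term in s)
        n_pa = sum(1 for s in sets if pars <= s)
        if n_pa == 0:
            raise ValueError(
                f"term {term} has no proteins annotated with all parents; "
                "it should have been excluded by the label-space threshold"
            )
        ic[j] = -np.log2(n_v / n_pa)
    # clip -0.0 and tiny negatives from float log
    return np.maximum(ic, 0.0)


def propagate_scores_max(scores: np.ndarray, space: LabelSpace) -> np.ndarray:
    """Enforce parent >= child on prediction scores by upward max-propagation.

    Each term's score becomes the maximum over itself and all of its in-space
    descendants.  Idempotent; never decreases any entry.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    out = scores.copy()
    # ancestors_in_space is transitively closed, so each term's in-space
    # descendant set is available directly; one pass is exact and idempotent.
    desc: dict[int, list[int]] = {j: [] for j in range(len(space))}
    for j in range(len(space)):
        for a in space.ancestors_in_space[j]:
            desc[a].append(j)
    for j, ds in desc.items():
        if ds:
            out[:, j] = np.maximum(out[:, j], np.max(scores[:, ds], axis=1))
    return out
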