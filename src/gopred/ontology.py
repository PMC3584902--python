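"""Gene Ontology DAG handling.

Loads the GO graph from OBO, restricted to ``is_a`` (parental) edges and to
the Molecular Function (MF) and Biological Process (BP) namespaces, and
provides the graph primitives the rest of the package is built on: ancestor
closure (the true-path rule), depth bookkeeping, and the signed
depth-difference relation between two terms used by the ensemble
propagation and incompatibility filter.

Depth is the shortest ``is_a`` path length from the namespace root; the
depth difference D(i, j) = depth(i) - depth(j) is defined only for pairs
where one term is an ``is_a`` ancestor of the other and neither is the
root itself (an ancestor path between two non-root terms never transits
the root).  A positive value means *i* is the deeper (more specific) term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: OBO namespace name -> short aspect code used throughout the package.
NAMESPACE_CODES = {
    "molecular_function": "MF",
    "biological_process": "BP",
}

#: GAF aspect column -> short namespace code.
ASPECT_CODES = {"F": "MF", "P": "BP", "C": "CC"}


class OntologyError(ValueError):
    """Structural problem in the ontology graph (cycle, missing root...)."""


@dataclass
class GoDag:
    """GO term DAG over ``is_a`` edges, restricted to MF and BP.

    Parameters
    ----------
    namespace
        Mapping term id -> namespace code (``"MF"`` or ``"BP"``) for every
        non-obsolete term.
    is_a_edges
        Child -> parent pairs; never crosses namespaces.
    obsolete
        Term ids retained for recognition but excluded from the graph.
    alt_ids
        Secondary id -> primary id.
    names
        Optional term id -> human-readable name (used when writing OBO).
    """

    namespace: dict[str, str]
    is_a_edges: list[tuple[str, str]]
    obsolete: set[str] = field(default_factory=set)
    alt_ids: dict[str, str] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._graph = nx.DiGraph()  # edges child -> parent
        self._graph.add_nodes_from(self.namespace)
        for child, parent in self.is_a_edges:
            if self.namespace.get(child) != self.namespace.get(parent):
                raise OntologyError(
                    f"is_a edge crosses namespaces: {child} -> {parent}"
                )
            self._graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            raise OntologyError(f"cyclic is_a closure involving {cycle[0][0]}")
        self.root: dict[str, str] = {}
        for term in self.namespace:
            if self._graph.out_degree(term) == 0:
                ns = self.namespace[term]
                if ns in self.root:
                    raise OntologyError(
                        f"namespace {ns} has multiple parentless terms: "
                        f"{self.root[ns]}, {term}"
                    )
                self.root[ns] = term
        for term, ns in self.namespace.items():
            if ns not in self.root:
                raise OntologyError(f"namespace {ns} has no root")
            if term != self.root[ns] and not nx.has_path(self._graph, term, self.root[ns]):
                raise OntologyError(f"term {term} does not reach its root")
        self._depth: dict[str, int] = {}
        for ns, root in self.root.items():
            # shortest is_a path from the root, measured on parent->child
            lengths = nx.single_source_shortest_path_length(self._graph.reverse(copy=False), root)
            self._depth.update(lengths)

    # -- lookups ---------------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self.namespace)

    def resolve(self, term: str) -> str:
        """Map a possibly-secondary id to its primary id."""
        return self.alt_ids.get(term, term)

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) in self.namespace

    def _require(self, term: str) -> str:
        term = self.resolve(term)
        if term not in self.namespace:
            raise KeyError(f"unknown GO term {term!r}")
        return term

    def is_root(self, term: str) -> bool:
        term = self._require(term)
        return self.root[self.namespace[term]] == term

    def depth(self, term: str) -> int:
        """Shortest is_a path length from the namespace root (root = 0)."""
        return self._depth[self._require(term)]

    # -- closures --------------------------------------------------------

    def ancestors(self, term: str) -> set[str]:
        """Reflexive-transitive is_a closure: the term, all its ancestors,
        and the namespace root."""
        term = self._require(term)
        if term in self.obsolete:
            raise KeyError(f"term {term!r} is obsolete")
        return nx.descendants(self._graph, term) | {term}

    def expand(self, terms: Iterable[str]) -> set[str]:
        """Union of ancestor closures of *terms* (the true-path expansion)."""
        out: set[str] = set()
        for t in terms:
            out |= self.ancestors(t)
        return out

    def is_ancestor(self, anc: str, desc: str) -> bool:
        """True when *anc* lies in the reflexive is_a closure of *desc*."""
        return self._require(anc) in self.ancestors(desc)

    # -- depth difference -------------------------------------------------

    def depth_difference(self, i: str, j: str) -> int | None:
        """Signed depth difference D(i, j), or ``None`` when undefined.

        Defined only when *i* and *j* share a namespace, one is an is_a
        ancestor of the other, and neither is the namespace root.  Positive
        means *i* is deeper (more specific) than *j*.
        """
        i, j = self._require(i), self._require(j)
        if self.namespace[i] != self.namespace[j]:
            return None
        if self.is_root(i) or self.is_root(j):
            return None
        if not (self.is_ancestor(j, i) or self.is_ancestor(i, j)):
            return None
        return self._depth[i] - self._depth[j]


def ancestors(dag: GoDag, term: str) -> set[str]:
    """Functional alias for :meth:`GoDag.ancestors`."""
    return dag.ancestors(term)


def depth_difference(dag: GoDag, i: str, j: str) -> int | None:
    """Functional alias for :meth:`GoDag.depth_difference`."""
    return dag.depth_difference(i, j)


def load_obo(path) -> GoDag:
    """Load a GO DAG from an OBO 1.2/1.4 file.

    Only ``[Term]`` stanzas are ingested and only ``is_a`` relationships
    become edges.  ``alt_id`` lines populate the secondary-id map, obsolete
    terms are retained but flagged and excluded from the graph, and
    cellular_component stanzas are ignored (with a logged count).
    """
    try:
        graph = obonet.read_obo(path, ignore_obsolete=False)
    except OSError:
        raise
    namespace: dict[str, str] = {}
    obsolete: set[str] = set()
    alt_ids: dict[str, str] = {}
    names: dict[str, str] = {}
    n_cc = 0
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace", "")
        if ns not in NAMESPACE_CODES:
            if ns == "cellular_component":
                n_cc += 1
            continue
        if "name" in data:
            names[term] = data["name"]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(term)
            continue
        namespace[term] = NAMESPACE_CODES[ns]
    if n_cc:
        logger.info("ignored %d cellular_component stanzas", n_cc)
    edges = [
        (child, parent)
        for child, parent, key in graph.edges(keys=True)
        if key == "is_a" and child in namespace and parent in namespace
    ]
    return GoDag(namespace=namespace, is_a_edges=edges, obsolete=obsolete,
                 alt_ids=alt_ids, names=names)


_CODE_TO_NAMESPACE = {v: k for k, v in NAMESPACE_CODES.items()}


def write_obo(dag: GoDag, path) -> None:
    """Serialize *dag* back to a minimal OBO 1.2 file (fixtures support)."""
    parents: dict[str, list[str]] = {}
    for child, parent in dag.is_a_edges:
        parents.setdefault(child, []).append(parent)
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: gopred-toy\n")
        for term in sorted(dag.namespace):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.names.get(term, term)}\n")
            fh.write(f"namespace: {_CODE_TO_NAMESPACE[dag.namespace[term]]}\n")
            for alt, primary in sorted(dag.alt_ids.items()):
                if primary == term:
                    fh.write(f"alt_id: {alt}\n")
            for parent in sorted(parents.get(term, [])):
                fh.write(f"is_a: {parent}\n")
        for term in sorted(dag.obsolete):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.names.get(term, term)}\n")
            fh.write("namespace: molecular_function\n")
            fh.write("is_obsolete: true\n")
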