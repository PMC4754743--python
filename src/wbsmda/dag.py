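"""Disease ontology DAG (MeSH-style term hierarchy) with disease anchors.

Each disease is anchored to one term of a directed acyclic term graph; its
semantic neighbourhood is the ancestor closure of that term (the term itself
plus everything reachable through child -> parent edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx


@dataclass
class DiseaseDAG:
    """Acyclic child->parent term graph plus disease -> term anchoring."""

    terms: set[str]
    edges: set[tuple[str, str]]
    anchors: dict[str, str]
    _graph: nx.DiGraph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.terms = set(self.terms)
        self.edges = {(c, p) for c, p in self.edges}
        for child, parent in self.edges:
            self.terms.add(child)
            self.terms.add(parent)
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.edges)  # edge direction: child -> parent
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            pretty = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[0][0]}"
            raise ValueError(f"term graph contains a cycle: {pretty}")
        for disease, term in self.anchors.items():
            if term not in self.terms:
                raise ValueError(
                    f"disease {disease!r} anchored to unknown term {term!r}"
                )
        self._graph = g

    def is_anchored(self, disease: str) -> bool:
        return disease in self.anchors

    def ancestor_closure(self, disease: str) -> set[str]:
        """T(D): the anchored term plus all its ancestors."""
        if disease not in self.anchors:
            raise KeyError(f"disease {disease!r} is not anchored in the DAG")
        term = self.anchors[disease]
        return {term} | nx.descendants(self._graph, term)

    def parents(self, term: str) -> set[str]:
        return set(self._graph.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self._graph.predecessors(term))


def read_disease_dag(path: str | Path) -> DiseaseDAG:
    """Read a DAG file: child-parent term pairs plus disease anchors.

    Format (TSV, ``#`` comments ignored): lines of ``child<TAB>parent`` for
    term edges; anchor lines are ``ANCHOR<TAB>disease<TAB>term``.  A term
    appearing only as a single-field line declares an isolated term (a root
    with no parent).
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    terms: set[str] = set()
    anchors: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if fields[0].upper() == "ANCHOR":
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}: line {lineno}: anchor needs disease and term"
                    )
                anchors[fields[1].casefold()] = fields[2]
            elif len(fields) == 1:
                terms.add(fields[0])
            elif len(fields) >= 2:
                edges.add((fields[0], fields[1]))
            else:
                raise ValueError(f"{path}: malformed line {lineno}")
    return DiseaseDAG(terms=terms, edges=edges, anchors=anchors)


def write_disease_dag(dag: DiseaseDAG, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# child\tparent\n")
        for child, parent in sorted(dag.edges):
            fh.write(f"{child}\t{parent}\n")
        covered = {t for e in dag.edges for t in e}
        for term in sorted(dag.terms - covered):
            fh.write(f"{term}\n")
        for disease, term in sorted(dag.anchors.items()):
            fh.write(f"ANCHOR\t{disease}\t{term}\n")
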