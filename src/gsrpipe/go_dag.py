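"""Minimal Gene Ontology handling.

Only the ontology operations the pipeline needs: offspring closure under
``is_a``/``part_of`` (to carve an immunofunctionome out of a functionome),
term depth (to exclude non-specific upper-level terms), an ancestor-closure
Jaccard semantic similarity (to merge related deregulated functions), and
name-based mapping from GMT-style set names (``GO_B_CELL_ACTIVATION``)
back to ontology term ids.

Parsing of OBO 1.2 files is delegated to :mod:`obonet`; the resulting
graph stores edges child -> parent, keyed by relation type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

#: The two ancestor terms whose offspring define the immunofunctionome.
IMMUNE_ANCESTORS = ("GO:0002376", "GO:0006954")


class OntologyError(ValueError):
    """Structural problem in the ontology (cycle, dangling edge, bad id)."""


@dataclass
class GoDag:
    """A Gene Ontology DAG with typed parent links.

    ``graph`` holds one node per non-obsolete term with ``name`` and
    ``namespace`` attributes, and directed edges child -> parent keyed by
    relation (``is_a`` / ``part_of``). Obsolete term ids are recorded but
    carry no nodes or edges.
    """

    graph: nx.MultiDiGraph
    obsolete_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for child, parent in self.graph.edges():
            for node in (child, parent):
                if "name" not in self.graph.nodes[node]:
                    raise OntologyError(f"edge endpoint {node!r} is not a defined term")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(f"ontology contains a cycle through {cycle[0][0]!r}")

    # -- introspection ----------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph.nodes

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def term_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def name(self, term_id: str) -> str:
        self._check(term_id)
        return self.graph.nodes[term_id]["name"]

    def _check(self, term_id: str) -> None:
        if term_id in self.obsolete_ids:
            raise OntologyError(f"term {term_id!r} is obsolete")
        if term_id not in self.graph.nodes:
            raise OntologyError(f"unknown term {term_id!r}")

    def parents(self, term_id: str,
                relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
        self._check(term_id)
        rel = set(relations)
        return {p for _, p, k in self.graph.out_edges(term_id, keys=True) if k in rel}

    def children(self, term_id: str,
                 relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
        self._check(term_id)
        rel = set(relations)
        return {c for c, _, k in self.graph.in_edges(term_id, keys=True) if k in rel}

    def roots(self, relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
        return {t for t in self.graph.nodes if not self.parents(t, relations)}

    # -- traversals --------------------------------------------------------

    def offspring(self, ancestor_ids: str | Iterable[str],
                  relations: Iterable[str] = DEFAULT_RELATIONS,
                  include_self: bool = True) -> set[str]:
        """All terms reachable from *ancestor_ids* by descending the chosen
        relation types, transitively; the ancestors themselves are included
        unless ``include_self=False``."""
        if isinstance(ancestor_ids, str):
            ancestor_ids = [ancestor_ids]
        rel = set(relations)
        result: set[str] = set()
        for anc in ancestor_ids:
            self._check(anc)
            frontier = [anc]
            seen = {anc}
            while frontier:
                term = frontier.pop()
                for child in self.children(term, rel):
                    if child not in seen:
                        seen.add(child)
                        frontier.append(child)
            if include_self:
                result |= seen
            else:
                result |= seen - {anc}
        return result

    def ancestors(self, term_id: str,
                  relations: Iterable[str] = DEFAULT_RELATIONS,
                  include_self: bool = True) -> set[str]:
        """Transitive parent closure of a term."""
        self._check(term_id)
        rel = set(relations)
        seen = {term_id}
        frontier = [term_id]
        while frontier:
            term = frontier.pop()
            for parent in self.parents(term, rel):
                if parent not in seen:
                    seen.add(parent)
                    frontier.append(parent)
        return seen if include_self else seen - {term_id}

    def depth(self, term_id: str,
              relations: Iterable[str] = DEFAULT_RELATIONS) -> int:
        """Length of the shortest parent path from *term_id* to any root."""
        self._check(term_id)
        rel = set(relations)
        level = {term_id}
        d = 0
        seen = set(level)
        while level:
            if any(not self.parents(t, rel) for t in level):
                return d
            nxt: set[str] = set()
            for t in level:
                nxt |= self.parents(t, rel) - seen
            seen |= nxt
            level = nxt
            d += 1
        raise OntologyError(f"no root reachable from {term_id!r}")  # pragma: no cover

    def semantic_similarity(self, term_a: str, term_b: str,
                            relations: Iterable[str] = DEFAULT_RELATIONS) -> float:
        """Jaccard index of the two terms' ancestor closures (each closure
        includes the term itself). Symmetric, in [0, 1], and 1 iff the
        closures coincide."""
        ca = self.ancestors(term_a, relations)
        cb = self.ancestors(term_b, relations)
        return len(ca & cb) / len(ca | cb)


# ---------------------------------------------------------------------------
# OBO input / output
# ---------------------------------------------------------------------------


def read_obo(path: str | Path) -> GoDag:
    """Load an OBO 1.2 ontology into a :class:`GoDag`.

    Obsolete terms are recorded in ``obsolete_ids`` and excluded from the
    graph; cycles and edges to undefined terms are errors.
    """
    raw = obonet.read_obo(Path(path), ignore_obsolete=False)
    graph = nx.MultiDiGraph()
    obsolete: set[str] = set()
    for node, data in raw.nodes(data=True):
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(node)
            continue
        graph.add_node(node, name=data.get("name", node),
                       namespace=data.get("namespace", ""))
    for child, parent, key in raw.edges(keys=True):
        if child in obsolete or parent in obsolete:
            continue
        graph.add_edge(child, parent, key=key)
    return GoDag(graph=graph, obsolete_ids=obsolete)


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Serialize a DAG as minimal OBO 1.2 (enough to round-trip read_obo)."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("format-version: 1.2\nontology: go-subset\n")
        for term in sorted(dag.graph.nodes):
            data = dag.graph.nodes[term]
            fh.write(f"\n[Term]\nid: {term}\nname: {data['name']}\n")
            if data.get("namespace"):
                fh.write(f"namespace: {data['namespace']}\n")
            for _, parent, key in sorted(dag.graph.out_edges(term, keys=True)):
                if key == "is_a":
                    fh.write(f"is_a: {parent} ! {dag.graph.nodes[parent]['name']}\n")
                else:
                    fh.write(f"relationship: {key} {parent} "
                             f"! {dag.graph.nodes[parent]['name']}\n")
        for term in sorted(dag.obsolete_ids):
            fh.write(f"\n[Term]\nid: {term}\nname: obsolete {term}\n"
                     "is_obsolete: true\n")


# ---------------------------------------------------------------------------
# Gene-set name -> term mapping
# ---------------------------------------------------------------------------


@dataclass
class TermMapping:
    """Mapping from gene-set ids to ontology term ids, with the leftovers."""

    mapping: dict[str, str]
    unmapped: list[str] = field(default_factory=list)

    def __getitem__(self, set_id: str) -> str:
        return self.mapping[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.mapping


def normalize_term_name(name: str, prefix: str = "GO_") -> str:
    """GMT-style set name for an ontology term name: uppercase,
    non-alphanumerics collapsed to underscores, ``GO_`` prefix."""
    slug = re.sub(r"[^0-9A-Za-z]+", "_", name).strip("_").upper()
    return prefix + slug


def map_collection_to_terms(collection, dag: GoDag,
                            explicit_mapping: Mapping[str, str] | None = None,
                            ) -> TermMapping:
    """Map every gene set in *collection* to an ontology term.

    An explicit mapping (set_id -> term_id) wins; otherwise set ids are
    matched against normalized term names. Two terms normalizing to the
    same name is an error; sets matching nothing are listed in
    ``unmapped`` rather than dropped silently.
    """
    by_name: dict[str, str] = {}
    collisions: dict[str, list[str]] = {}
    for term in dag.graph.nodes:
        key = normalize_term_name(dag.graph.nodes[term]["name"])
        if key in by_name:
            collisions.setdefault(key, [by_name[key]]).append(term)
        else:
            by_name[key] = term
    if collisions:
        raise OntologyError(
            "ambiguous normalized term names: "
            + "; ".join(f"{k} -> {sorted(v)}" for k, v in sorted(collisions.items()))
        )
    explicit = dict(explicit_mapping or {})
    mapping: dict[str, str] = {}
    unmapped: list[str] = []
    for s in collection:
        if s.set_id in explicit:
            term = explicit[s.set_id]
            if term not in dag:
                raise OntologyError(
                    f"explicit mapping for {s.set_id!r} targets unknown term {term!r}"
                )
            mapping[s.set_id] = term
        elif s.set_id in by_name:
            mapping[s.set_id] = by_name[s.set_id]
        else:
            unmapped.append(s.set_id)
    return TermMapping(mapping=mapping, unmapped=unmapped)


def read_term_mapping(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (set_id, term_id) into a dict."""
    out: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise OntologyError(f"mapping line {lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def write_term_mapping(mapping: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for set_id, term in mapping.items():
            fh.write(f"{set_id}\t{term}\n")
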