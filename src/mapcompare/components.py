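"""Shared mechanism areas as connected components of bipartite
element–reaction graphs.

Each map becomes a directed bipartite graph: reactant and modifier
elements send edges into their reaction node, and reaction nodes send
edges to their product elements.  Restricting the graph to the reactions
retained by the cross-map interaction comparison and taking connected
components of the undirected skeleton yields candidate map areas covering
similar mechanisms; components with fewer than three reactions are
discarded as too small to call an "area".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .interactions import SimilarityRecord
from .model import DiseaseMap, Role

ELEMENT = "element"
REACTION = "reaction"


@dataclass(frozen=True)
class ComponentResult:
    """One connected component of a (restricted) bipartite map graph."""

    component_id: str
    map_id: str
    reaction_ids: tuple[str, ...]
    element_ids: tuple[str, ...]

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)


@dataclass(frozen=True)
class ComponentMatch:
    """A pair of components (one per map) joined by >=1 similarity record."""

    component_a_id: str
    component_b_id: str
    n_linking_records: int


def build_bipartite(disease_map: DiseaseMap) -> nx.DiGraph:
    """Directed bipartite element–reaction graph of one map.

    Element nodes exist only for elements participating in at least one
    reaction; duplicate participant entries collapse to one edge.  Node ids
    are the map's element/reaction ids with a ``kind`` attribute; an id
    used both as an element and a reaction id would be ambiguous and raises.
    """
    g = nx.DiGraph(map_id=disease_map.map_id)
    element_ids = {el.element_id for el in disease_map.elements}
    for rx in disease_map.reactions:
        if rx.reaction_id in element_ids:
            raise ValueError(
                f"id {rx.reaction_id!r} is both an element and a reaction id"
            )
        g.add_node(rx.reaction_id, kind=REACTION)
        for p in rx.participants:
            g.add_node(p.element_id, kind=ELEMENT)
            if p.role in (Role.REACTANT, Role.MODIFIER):
                g.add_edge(p.element_id, rx.reaction_id)
            else:  # product
                g.add_edge(rx.reaction_id, p.element_id)
    return g


def restrict_to_reactions(graph: nx.DiGraph, keep: Iterable[str]) -> nx.DiGraph:
    """Drop reaction nodes outside *keep* (with incident edges), then drop
    element nodes left isolated."""
    keep = set(keep)
    g = graph.copy()
    drop = [
        n for n, d in g.nodes(data=True) if d["kind"] == REACTION and n not in keep
    ]
    g.remove_nodes_from(drop)
    isolated = [
        n
        for n, d in g.nodes(data=True)
        if d["kind"] == ELEMENT and g.degree(n) == 0
    ]
    g.remove_nodes_from(isolated)
    return g


def connected_components(
    graph: nx.DiGraph, min_reactions: int = 3
) -> list[ComponentResult]:
    """Weakly connected components with at least *min_reactions* reaction
    nodes, sorted by reaction count descending then smallest reaction id."""
    if min_reactions < 1:
        raise ValueError("min_reactions must be >= 1")
    map_id = graph.graph.get("map_id", "")
    results = []
    for nodes in nx.weakly_connected_components(graph):
        reactions = sorted(n for n in nodes if graph.nodes[n]["kind"] == REACTION)
        if len(reactions) < min_reactions:
            continue
        elements = sorted(n for n in nodes if graph.nodes[n]["kind"] == ELEMENT)
        results.append((reactions, elements))
    results.sort(key=lambda re: (-len(re[0]), re[0][0] if re[0] else ""))
    return [
        ComponentResult(
            component_id=f"{map_id}:c{i + 1}",
            map_id=map_id,
            reaction_ids=tuple(reactions),
            element_ids=tuple(elements),
        )
        for i, (reactions, elements) in enumerate(results)
    ]


def match_components(
    comps_a: Sequence[ComponentResult],
    comps_b: Sequence[ComponentResult],
    records: Sequence[SimilarityRecord],
) -> list[ComponentMatch]:
    """Pair components across two maps by the similarity records joining a
    reaction of one to a reaction of the other; one match per linked
    component pair, counting the linking records."""
    comp_of_a = {rid: c.component_id for c in comps_a for rid in c.reaction_ids}
    comp_of_b = {rid: c.component_id for c in comps_b for rid in c.reaction_ids}
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        ca = comp_of_a.get(rec.reaction_a)
        cb = comp_of_b.get(rec.reaction_b)
        if ca is None or cb is None:
            continue
        counts[(ca, cb)] = counts.get((ca, cb), 0) + 1
    return [
        ComponentMatch(component_a_id=ca, component_b_id=cb, n_linking_records=n)
        for (ca, cb), n in sorted(counts.items())
    ]


def shared_components(
    map_a: DiseaseMap,
    map_b: DiseaseMap,
    records: Sequence[SimilarityRecord],
    min_reactions: int = 3,
) -> tuple[list[ComponentResult], list[ComponentResult], list[ComponentMatch]]:
    """Full pipeline for one map pair: build both bipartite graphs,
    restrict each to its reactions retained in *records*, extract
    components and match them."""
    keep_a = {r.reaction_a for r in records}
    keep_b = {r.reaction_b for r in records}
    comps_a = connected_components(
        restrict_to_reactions(build_bipartite(map_a), keep_a), min_reactions
    )
    comps_b = connected_components(
        restrict_to_reactions(build_bipartite(map_b), keep_b), min_reactions
    )
    return comps_a, comps_b, match_components(comps_a, comps_b, records)
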