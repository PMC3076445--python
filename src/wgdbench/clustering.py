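"""Extend pairwise reciprocal pairs into multi-species orthogroups.

A predicted group is a connected component of the pair graph in which every
species contributes exactly one gene. When a component contains two or more
genes of one species the evidence is in conflict (e.g. gene A is reciprocal
best with C1 while gene B is reciprocal best with C2, both from species c);
the whole species is then dropped from the component. Removal can split a
component, which can create or dissolve further conflicts, so dropping is
iterated to a fixed point: each pass removes every currently conflicted
species from every component simultaneously, then components are recomputed.
The vertex set strictly shrinks, so the iteration terminates, and because
each pass removes a set determined only by the current component structure
the result does not depend on any processing order.

Final components with at least two genes are emitted as orthogroups, named
after their lexicographically smallest member.
"""
from __future__ import annotations

import itertools

import networkx as nx

from .model import Orthogroup, OrthologPair, SpeciesMap

__all__ = ["PairGraph", "build_pair_graph", "cluster", "brute_force_cluster"]


class PairGraph(nx.Graph):
    """Undirected gene graph; node attribute ``species``, edge attribute
    ``support``. No edge joins two genes of the same species."""


def build_pair_graph(pairs, species_map: SpeciesMap) -> PairGraph:
    """Duplicate pairs collapse keeping the maximum support; a same-species
    edge indicates an upstream bug and is a hard error."""
    g = PairGraph()
    for pair in pairs:
        x, y = pair.genes
        sx, sy = species_map.species_of(x), species_map.species_of(y)
        if sx == sy:
            raise ValueError(
                f"pair ({x}, {y}) joins two genes of species {sx!r}"
            )
        g.add_node(x, species=sx)
        g.add_node(y, species=sy)
        if g.has_edge(x, y):
            g[x][y]["support"] = max(g[x][y]["support"], pair.support)
        else:
            g.add_edge(x, y, support=pair.support)
    return g


def _conflicted(component, species_of) -> set[str]:
    """Genes belonging to species represented more than once in the component."""
    counts: dict[str, int] = {}
    for gene in component:
        sp = species_of(gene)
        counts[sp] = counts.get(sp, 0) + 1
    bad = {sp for sp, n in counts.items() if n > 1}
    return {g for g in component if species_of(g) in bad}


def _emit(components, min_size: int = 2) -> list[Orthogroup]:
    groups = [
        Orthogroup(min(comp), frozenset(comp))
        for comp in components
        if len(comp) >= min_size
    ]
    groups.sort(key=lambda g: g.group_id)
    return groups


def cluster(graph: PairGraph) -> list[Orthogroup]:
    """Iterated conflict removal to a fixed point (see module docstring)."""
    g = graph.copy()
    species_of = lambda gene: g.nodes[gene]["species"]
    while True:
        to_drop: set[str] = set()
        for comp in nx.connected_components(g):
            to_drop |= _conflicted(comp, species_of)
        if not to_drop:
            break
        g.remove_nodes_from(to_drop)
    return _emit(nx.connected_components(g))


# ---------------------------------------------------------------------------
# Independent oracle
# ---------------------------------------------------------------------------

def _components(vertices: set[str], adj: dict[str, set[str]]) -> list[set[str]]:
    seen: set[str] = set()
    comps: list[set[str]] = []
    for v in sorted(vertices):
        if v in seen:
            continue
        comp = {v}
        frontier = [v]
        while frontier:
            u = frontier.pop()
            for w in adj.get(u, ()):
                if w in vertices and w not in comp:
                    comp.add(w)
                    frontier.append(w)
        seen |= comp
        comps.append(comp)
    return comps


def brute_force_cluster(graph: PairGraph) -> list[Orthogroup]:
    """Exhaustive re-implementation of the same fixed point, built from plain
    set operations. Within each pass the (component, species) conflicts are
    frozen and their removals applied in every order, asserting the outcome
    is order-independent; passes repeat until no conflicts remain. Refuses
    graphs with more than 12 genes.
    """
    if graph.number_of_nodes() > 12:
        raise ValueError("brute-force oracle is limited to graphs of <= 12 genes")
    species = {v: graph.nodes[v]["species"] for v in graph.nodes}
    adj = {v: set(graph.adj[v]) for v in graph.nodes}
    vertices = set(graph.nodes)

    while True:
        removals: list[set[str]] = []  # one gene set per (component, species) conflict
        for comp in _components(vertices, adj):
            counts: dict[str, list[str]] = {}
            for gene in comp:
                counts.setdefault(species[gene], []).append(gene)
            for genes in counts.values():
                if len(genes) > 1:
                    removals.append(set(genes))
        if not removals:
            break
        outcomes = set()
        for order in itertools.permutations(range(len(removals))):
            remaining = set(vertices)
            for idx in order:
                remaining -= removals[idx]
            outcomes.add(frozenset(remaining))
        assert len(outcomes) == 1, "conflict removal must be order-independent"
        vertices = set(next(iter(outcomes)))

    return _emit(_components(vertices, adj))
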