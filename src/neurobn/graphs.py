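"""Directed acyclic graph structures, Markov blankets and CPDAG conversion.

A DAG over named variables is the structural half of a Gaussian Bayesian
network.  Markov-equivalent DAGs (same skeleton, same v-structures) encode
identical conditional-independence models; the equivalence class is
canonically represented by a CPDAG in which compelled arcs stay directed and
reversible ones become undirected edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import networkx as nx

Arc = tuple[str, str]


class CyclicGraphError(ValueError):
    """The proposed arc set contains a directed cycle."""


@dataclass(frozen=True)
class DAGStructure:
    """A labelled DAG: ordered variable names plus a set of (parent, child) arcs."""

    variables: tuple[str, ...]
    arcs: frozenset[Arc] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "arcs", frozenset(tuple(a) for a in self.arcs))
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names must be unique")
        known = set(self.variables)
        for p, c in self.arcs:
            if p == c:
                raise ValueError(f"self-loop on {p!r}")
            if p not in known or c not in known:
                raise ValueError(f"arc ({p!r}, {c!r}) references unknown variable")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise CyclicGraphError("arc set contains a directed cycle")

    # -- queries ---------------------------------------------------------
    def parents(self, node: str) -> set[str]:
        self._check_node(node)
        return {p for p, c in self.arcs if c == node}

    def children(self, node: str) -> set[str]:
        self._check_node(node)
        return {c for p, c in self.arcs if p == node}

    def skeleton(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(a) for a in self.arcs)

    def topological_order(self) -> list[str]:
        order = list(nx.lexicographical_topological_sort(self.to_networkx()))
        return order

    def _check_node(self, node: str) -> None:
        if node not in self.variables:
            raise ValueError(f"unknown variable {node!r}")

    # -- export ----------------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.arcs)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def to_dot(self) -> str:
        lines = ["digraph G {"]
        for v in self.variables:
            lines.append(f'  "{v}";')
        for p, c in sorted(self.arcs):
            lines.append(f'  "{p}" -> "{c}";')
        lines.append("}")
        return "\n".join(lines)

    def arc_list(self) -> list[Arc]:
        return sorted(self.arcs)


@dataclass(frozen=True)
class CPDAG:
    """Completed partially directed graph: compelled arcs + reversible edges."""

    variables: tuple[str, ...]
    directed: frozenset[Arc]
    undirected: frozenset[frozenset[str]]

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "directed", frozenset(tuple(a) for a in self.directed))
        object.__setattr__(
            self, "undirected", frozenset(frozenset(e) for e in self.undirected)
        )
        dir_pairs = {frozenset(a) for a in self.directed}
        if dir_pairs & self.undirected:
            raise ValueError("directed and undirected edge sets overlap")

    def adjacencies(self) -> frozenset[frozenset[str]]:
        return frozenset({frozenset(a) for a in self.directed} | self.undirected)

    def to_json(self) -> str:
        return json.dumps(
            {
                "variables": list(self.variables),
                "directed": sorted(map(list, self.directed)),
                "undirected": sorted(sorted(e) for e in self.undirected),
            },
            indent=1,
        )


def markov_blanket(structure: DAGStructure, node: str) -> set[str]:
    """Parents, children and spouses (co-parents of children) of ``node``.

    Conditioning on the blanket renders the node independent of every other
    variable in the network.
    """
    structure._check_node(node)
    pa = structure.parents(node)
    ch = structure.children(node)
    spouses: set[str] = set()
    for c in ch:
        spouses |= structure.parents(c)
    return (pa | ch | spouses) - {node}


def _vstructures(structure: DAGStructure) -> set[tuple[str, str, str]]:
    """Colliders a -> c <- b with a, b non-adjacent; returned as (a, b, c), a<b."""
    adj = structure.skeleton()
    out = set()
    for c in structure.variables:
        pa = sorted(structure.parents(c))
        for a, b in combinations(pa, 2):
            if frozenset((a, b)) not in adj:
                out.add((a, b, c))
    return out


def dag_to_cpdag(structure: DAGStructure) -> CPDAG:
    """Convert a DAG to the CPDAG of its Markov equivalence class.

    Starts from the skeleton with v-structure arcs directed and closes under
    the Meek orientation rules; every arc so compelled is directed
    identically in all equivalent DAGs, the rest are left undirected.
    """
    adj: dict[str, set[str]] = {v: set() for v in structure.variables}
    for p, c in structure.arcs:
        adj[p].add(c)
        adj[c].add(p)
    directed: set[Arc] = set()
    for a, b, c in _vstructures(structure):
        directed.add((a, c))
        directed.add((b, c))

    def is_dir(x, y):
        return (x, y) in directed

    def is_undir(x, y):
        return y in adj[x] and not is_dir(x, y) and not is_dir(y, x)

    changed = True
    while changed:
        changed = False
        for y in structure.variables:
            for z in sorted(adj[y]):
                if not is_undir(y, z):
                    continue
                oriented = False
                # R1: x -> y, y - z, x and z non-adjacent  =>  y -> z
                for x in sorted(adj[y]):
                    if is_dir(x, y) and z not in adj[x] and x != z:
                        oriented = True
                        break
                # R2: y -> w -> z with y - z  =>  y -> z
                if not oriented:
                    for w in sorted(adj[y] & adj[z]):
                        if is_dir(y, w) and is_dir(w, z):
                            oriented = True
                            break
                # R3: y - w1, y - w2, w1 -> z, w2 -> z, w1 and w2 non-adjacent
                if not oriented:
                    cands = [
                        w
                        for w in sorted(adj[y] & adj[z])
                        if is_undir(y, w) and is_dir(w, z)
                    ]
                    for w1, w2 in combinations(cands, 2):
                        if w2 not in adj[w1]:
                            oriented = True
                            break
                if oriented:
                    directed.add((y, z))
                    changed = True

    undirected = {
        frozenset((p, c))
        for p, c in structure.arcs
        if (p, c) not in directed and (c, p) not in directed
    }
    return CPDAG(structure.variables, frozenset(directed), frozenset(undirected))


def cpdag_by_enumeration(structure: DAGStructure) -> CPDAG:
    """Brute-force CPDAG: enumerate every same-skeleton, same-v-structure DAG.

    Exponential in the number of edges; intended as a test oracle at small n.
    """
    edges = sorted(tuple(sorted(e)) for e in structure.skeleton())
    target_v = _vstructures(structure)
    members: list[set[Arc]] = []
    for mask in range(2 ** len(edges)):
        arcs = set()
        for k, (a, b) in enumerate(edges):
            arcs.add((a, b) if (mask >> k) & 1 else (b, a))
        try:
            cand = DAGStructure(structure.variables, frozenset(arcs))
        except CyclicGraphError:
            continue
        if _vstructures(cand) == target_v:
            members.append(arcs)
    assert members, "equivalence class cannot be empty"
    common = set.intersection(*members) if members else set()
    undirected = {
        frozenset(e) for e in edges if tuple(e) not in common and tuple(e[::-1]) not in common
    }
    return CPDAG(structure.variables, frozenset(common), frozenset(undirected))


def enumerate_dags(variables: Iterable[str]) -> list[DAGStructure]:
    """All labelled DAGs over the given variables (feasible for n <= 4)."""
    variables = tuple(variables)
    if len(variables) > 4:
        raise ValueError("enumeration limited to n <= 4")
    pairs = list(combinations(variables, 2))
    out = []
    # each unordered pair: absent, a->b, or b->a
    def rec(i, arcs):
        if i == len(pairs):
            try:
                out.append(DAGStructure(variables, frozenset(arcs)))
            except CyclicGraphError:
                pass
            return
        a, b = pairs[i]
        rec(i + 1, arcs)
        rec(i + 1, arcs | {(a, b)})
        rec(i + 1, arcs | {(b, a)})

    rec(0, set())
    return out
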