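"""Score-based DAG search: tabu local search over add/delete/reverse moves.

The search optimizes the node-decomposable Gaussian BIC.  Starting from the
empty graph, each iteration applies the best legal single-arc move — even a
score-degrading one — while any move that would recreate a structure
visited within the last ``tabu_list_size`` iterations is tabu (unless it
would beat the best score seen, the usual aspiration criterion).  Keying
the tabu list on visited structures rather than on undoing operators blocks
the add/reverse/delete three-cycles that operator-based lists let through.
The search stops after ``max_nonimproving`` consecutive accepted moves that
fail to improve the best-seen score, and returns the best-seen structure.

Blacklisted variable pairs are barred in both directions.  Tie-breaking
among equal-score moves is lexicographic by (operation, child, parent)
variable name, so results are deterministic across platforms; the config
seed exists only for API symmetry with the bootstrap layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations

import pandas as pd

from .gbn import CovarianceScorer
from .graphs import DAGStructure


@dataclass(frozen=True)
class SearchConfig:
    tabu_list_size: int = 30
    max_nonimproving: int = 30
    blacklist: frozenset[frozenset[str]] = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self):
        if self.tabu_list_size < 0 or self.max_nonimproving < 0:
            raise ValueError("tabu_list_size and max_nonimproving must be >= 0")
        object.__setattr__(
            self, "blacklist", frozenset(frozenset(p) for p in self.blacklist)
        )


def _has_path(children: list[set[int]], src: int, dst: int) -> bool:
    if src == dst:
        return True
    stack = [src]
    seen = {src}
    while stack:
        u = stack.pop()
        for v in children[u]:
            if v == dst:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def tabu_search(
    data: pd.DataFrame,
    config: SearchConfig | None = None,
    scorer: CovarianceScorer | None = None,
) -> DAGStructure:
    """BIC-optimal-locally DAG via tabu search (see module docstring)."""
    config = config or SearchConfig()
    scorer = scorer or CovarianceScorer(data)
    names = scorer.columns
    n = len(names)
    order = sorted(range(n), key=lambda i: names[i])
    blacklist_idx = set()
    known = set(names)
    for pair in config.blacklist:
        a, b = tuple(pair)
        if a in known and b in known:
            blacklist_idx.add(frozenset((names.index(a), names.index(b))))

    parents: list[set[int]] = [set() for _ in range(n)]
    children: list[set[int]] = [set() for _ in range(n)]
    local = [scorer.local_score(i, frozenset()) for i in range(n)]
    score = sum(local)
    best_score = score
    best_arcs: set[tuple[int, int]] = set()
    arcs: set[tuple[int, int]] = set()
    visited: dict[frozenset, int] = {frozenset(): 0}  # structure -> last visit
    nonimproving = 0
    it = 0

    def child_delta(c: int, new_parents: frozenset[int]) -> float:
        return scorer.local_score(c, new_parents) - local[c]

    def usable(key: frozenset, candidate_score: float) -> bool:
        last = visited.get(key)
        if last is not None and it - last <= config.tabu_list_size:
            return candidate_score > best_score + 1e-12  # aspiration
        return True

    while nonimproving <= config.max_nonimproving:
        it += 1
        best_move = None
        best_delta = -math.inf
        for j in order:  # child
            pj = parents[j]
            for i in order:  # parent
                if i == j:
                    continue
                pair = frozenset((i, j))
                if i in pj:
                    # delete i -> j
                    d = child_delta(j, frozenset(pj - {i}))
                    if d > best_delta and usable(frozenset(arcs - {(i, j)}), score + d):
                        best_move, best_delta = ("del", i, j), d
                    # reverse i -> j (becomes j -> i)
                    children[i].discard(j)
                    cyclic = _has_path(children, i, j)
                    children[i].add(j)
                    if not cyclic:
                        d = child_delta(j, frozenset(pj - {i})) + child_delta(
                            i, frozenset(parents[i] | {j})
                        )
                        if d > best_delta and usable(
                            frozenset(arcs - {(i, j)} | {(j, i)}), score + d
                        ):
                            best_move, best_delta = ("rev", i, j), d
                elif j not in parents[i] and pair not in blacklist_idx:
                    # add i -> j
                    if not _has_path(children, j, i):
                        d = child_delta(j, frozenset(pj | {i}))
                        if d > best_delta and usable(frozenset(arcs | {(i, j)}), score + d):
                            best_move, best_delta = ("add", i, j), d
        if best_move is None or best_delta == -math.inf:
            break
        op, i, j = best_move
        if op == "add":
            parents[j].add(i)
            children[i].add(j)
            arcs.add((i, j))
            local[j] = scorer.local_score(j, frozenset(parents[j]))
        elif op == "del":
            parents[j].discard(i)
            children[i].discard(j)
            arcs.discard((i, j))
            local[j] = scorer.local_score(j, frozenset(parents[j]))
        else:  # reverse i -> j  =>  j -> i
            parents[j].discard(i)
            children[i].discard(j)
            parents[i].add(j)
            children[j].add(i)
            arcs.discard((i, j))
            arcs.add((j, i))
            local[j] = scorer.local_score(j, frozenset(parents[j]))
            local[i] = scorer.local_score(i, frozenset(parents[i]))
        # recompute from cached locals: identical structures then score
        # bit-identically, so round-off drift can never register as an
        # improvement and keep the search alive forever
        score = sum(local)
        visited[frozenset(arcs)] = it
        if score > best_score + 1e-12:
            best_score = score
            best_arcs = set(arcs)
            nonimproving = 0
        else:
            nonimproving += 1

    return DAGStructure(
        names, frozenset((names[p], names[c]) for p, c in best_arcs)
    )


def exhaustive_search(
    data: pd.DataFrame,
    blacklist: frozenset[frozenset[str]] = frozenset(),
) -> DAGStructure:
    """Globally BIC-optimal DAG by maximizing over topological orders (n <= 5).

    For every variable ordering, each node independently picks its best
    parent subset among its predecessors; the overall optimum over orders is
    the global optimum over DAGs.  Test oracle; refuses n > 5.
    """
    scorer = CovarianceScorer(data)
    names = scorer.columns
    n = len(names)
    if n > 5:
        raise ValueError("exhaustive search limited to n <= 5 variables")
    blk = {frozenset(tuple(names.index(v) for v in pair)) for pair in blacklist}

    def subsets(pool: tuple[int, ...]):
        out = [()]
        for r in range(1, len(pool) + 1):
            out.extend(combinations(pool, r))
        return out

    best_total = -math.inf
    best_arcs: set[tuple[int, int]] = set()
    for perm in permutations(sorted(range(n), key=lambda i: names[i])):
        total = 0.0
        arcs = set()
        for pos, child in enumerate(perm):
            pool = tuple(
                p for p in perm[:pos] if frozenset((p, child)) not in blk
            )
            node_best, node_parents = -math.inf, ()
            for ps in subsets(pool):
                s = scorer.local_score(child, frozenset(ps))
                if s > node_best:
                    node_best, node_parents = s, ps
            total += node_best
            arcs |= {(p, child) for p in node_parents}
        if total > best_total + 1e-12:
            best_total = total
            best_arcs = arcs
    return DAGStructure(
        names, frozenset((names[p], names[c]) for p, c in best_arcs)
    )
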