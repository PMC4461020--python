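"""Maximum-weight bipartite matching.

The optimization selects a vertex-disjoint set of association edges whose
total weight (publication support) is maximal:

    maximize   sum_{(i,j) in E} w_ij x_ij
    subject to sum_j x_ij <= 1  for every miRNA i
               sum_i x_ij <= 1  for every disease j
               x_ij in {0, 1}

The LP relaxation of this program is integral on bipartite graphs, so an
exact combinatorial solver is equivalent to the simplex route. Among
co-optimal matchings the one whose sorted pair list is lexicographically
smallest is returned, which makes every downstream result deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .core import GraphValidationError, MirnaDiseaseGraph

#: default guard for the exponential brute-force oracle
BRUTE_FORCE_MAX_EDGES = 20


@dataclass(frozen=True)
class MatchingSolution:
    """A vertex-disjoint edge selection and its total weight."""

    selected_pairs: frozenset[tuple[str, str]]
    objective_value: int

    @property
    def matched_diseases(self) -> set[str]:
        return {d for (_, d) in self.selected_pairs}

    @property
    def matched_mirnas(self) -> set[str]:
        return {m for (m, _) in self.selected_pairs}

    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.selected_pairs)


@dataclass
class Verdict:
    """Outcome of checking a solution against the matching invariants."""

    valid: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.valid


def _nx_optimum(graph: MirnaDiseaseGraph, exclude: set[str]) -> int:
    """Maximum matching weight on the graph minus ``exclude`` vertices."""
    g = nx.Graph()
    for (m, d), ev in graph.edges.items():
        if m not in exclude and d not in exclude:
            g.add_edge(m, d, weight=ev.weight)
    if g.number_of_edges() == 0:
        return 0
    matching = nx.max_weight_matching(g, maxcardinality=False)
    return sum(g[u][v]["weight"] for u, v in matching)


def solve(graph: MirnaDiseaseGraph) -> MatchingSolution:
    """Exact maximum-weight matching with a deterministic tie-break.

    The optimal objective is found combinatorially; the particular optimal
    matching is then pinned down by scanning edges in sorted order and
    keeping an edge whenever an optimal completion still exists, which
    yields the lexicographically smallest sorted pair list among all
    maximum-weight matchings.
    """
    graph.validate()
    if not graph.edges:
        return MatchingSolution(frozenset(), 0)
    optimum = _nx_optimum(graph, set())
    chosen: list[tuple[str, str]] = []
    chosen_weight = 0
    used: set[str] = set()
    for (m, d) in sorted(graph.edges):
        if m in used or d in used:
            continue
        w = graph.edges[(m, d)].weight
        rest = _nx_optimum(graph, used | {m, d})
        if chosen_weight + w + rest == optimum:
            chosen.append((m, d))
            chosen_weight += w
            used.update((m, d))
    assert chosen_weight == optimum
    return MatchingSolution(frozenset(chosen), chosen_weight)


def brute_force(
    graph: MirnaDiseaseGraph, max_edges: int = BRUTE_FORCE_MAX_EDGES
) -> MatchingSolution:
    """Exhaustive matching enumeration; the independent test oracle.

    Recursively includes/excludes each edge, keeping the maximum-weight
    matching under the same lexicographic tie-break as :func:`solve`.
    Refuses graphs above ``max_edges`` edges to bound the blow-up.
    """
    graph.validate()
    edges = sorted(graph.edges)
    if len(edges) > max_edges:
        raise GraphValidationError(
            f"brute force refused: {len(edges)} edges exceeds guard of {max_edges}"
        )
    weights = [graph.edges[e].weight for e in edges]
    best_pairs: list[tuple[str, str]] = []
    best_weight = 0

    def recurse(idx: int, current: list[tuple[str, str]], weight: int, used: set[str]) -> None:
        nonlocal best_pairs, best_weight
        if idx == len(edges):
            if weight > best_weight or (
                weight == best_weight and current < best_pairs
            ):
                best_pairs = list(current)
                best_weight = weight
            return
        m, d = edges[idx]
        if m not in used and d not in used:
            current.append((m, d))
            used.update((m, d))
            recurse(idx + 1, current, weight + weights[idx], used)
            used.difference_update((m, d))
            current.pop()
        recurse(idx + 1, current, weight, used)

    recurse(0, [], 0, set())
    return MatchingSolution(frozenset(best_pairs), best_weight)


def verify(graph: MirnaDiseaseGraph, solution: MatchingSolution) -> Verdict:
    """Check every matching invariant of ``solution`` against ``graph``."""
    violations: list[str] = []
    seen: dict[str, int] = {}
    total = 0
    for (m, d) in solution.sorted_pairs():
        if (m, d) not in graph.edges:
            violations.append(f"pair ({m},{d}) is not an edge of the graph")
        else:
            total += graph.edges[(m, d)].weight
        for v in (m, d):
            seen[v] = seen.get(v, 0) + 1
    for v, count in sorted(seen.items()):
        if count > 1:
            violations.append(f"vertex {v} repeated")
    if total != solution.objective_value:
        violations.append(
            f"objective {solution.objective_value} != sum of pair weights {total}"
        )
    return Verdict(valid=not violations, violations=violations)
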