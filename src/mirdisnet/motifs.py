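"""Motif census and significance analysis.

Connected 3- and 4-node induced subgraphs of a bipartite association
network fall into exactly four isomorphism classes: the 3-node path
(one miRNA regulating two diseases, or two miRNAs regulating one disease),
the 4-node path, the 3-star, and the 4-cycle ("square": two miRNAs sharing
two diseases). The census counts their occurrences and each node's
participation; significance is assessed against an ensemble of
degree-preserving double-edge-swap randomizations, in the spirit of the
classic mfinder/fanmod workflow: a class is a motif when it is strongly
over-represented (Z-score), rarely matched by the null (empirical p), and
occurs in enough edge-disjoint copies (uniqueness).

The same census runs on the one-mode disease projection, where the extra
triangle class can appear (the projection is not bipartite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import (
    GraphLike,
    GraphValidationError,
    MirnaDiseaseGraph,
    _as_networkx,
)
from .ranking import cumulative_impact

logger = logging.getLogger(__name__)


class MotifClass(Enum):
    """Connected simple subgraph classes on 3 and 4 nodes."""

    PATH3 = "path3"
    PATH4 = "path4"
    STAR4 = "star4"
    CYCLE4 = "cycle4"
    TRIANGLE = "triangle"  # only possible in non-bipartite (projected) graphs
    OTHER = "other"  # remaining non-bipartite 4-node shapes

    @property
    def node_count(self) -> int:
        return 3 if self in (MotifClass.PATH3, MotifClass.TRIANGLE) else 4


#: the classes realizable in a bipartite graph, in reporting order
BIPARTITE_CLASSES: tuple[MotifClass, ...] = (
    MotifClass.PATH3,
    MotifClass.PATH4,
    MotifClass.STAR4,
    MotifClass.CYCLE4,
)


@dataclass
class ClassStats:
    """Null-ensemble statistics for one motif class."""

    real_count: int
    random_mean: float
    random_std: float
    z_score: Optional[float]  # None when random_std == 0
    empirical_p: float
    uniqueness: int
    significant: Optional[bool]  # None when z undefined


@dataclass
class MotifCensus:
    """Subgraph counts, per-node participation, and optional null stats."""

    counts: dict[MotifClass, int]
    participation: dict[tuple[str, MotifClass], int]
    ensemble_stats: Optional[dict[MotifClass, ClassStats]] = None
    ensemble_size: Optional[int] = None
    seed: Optional[int] = None

    def participation_of(self, node: str, cls: MotifClass) -> int:
        return self.participation.get((node, cls), 0)

    def to_dataframe(self) -> pd.DataFrame:
        """Census report table: one row per class (external CSV interface)."""
        rows = []
        for cls in MotifClass:
            if cls not in self.counts:
                continue
            stats = (self.ensemble_stats or {}).get(cls)
            rows.append(
                {
                    "class": cls.value,
                    "real_count": self.counts[cls],
                    "random_mean": stats.random_mean if stats else np.nan,
                    "random_std": stats.random_std if stats else np.nan,
                    "z_score": (
                        stats.z_score
                        if stats and stats.z_score is not None
                        else np.nan
                    ),
                    "empirical_p": stats.empirical_p if stats else np.nan,
                    "uniqueness": stats.uniqueness if stats else np.nan,
                    "significant": stats.significant if stats else None,
                }
            )
        return pd.DataFrame(rows)


def _adjacency(graph: GraphLike) -> dict[str, set[str]]:
    g = _as_networkx(graph)
    return {v: set(g.neighbors(v)) for v in g.nodes}


def enumerate_subgraphs(graph: GraphLike, k: int) -> list[tuple[str, ...]]:
    """All connected induced subgraphs on k nodes, each node set once.

    Uses the ESU enumeration: grow from each root only through nodes larger
    than the root, keeping an exclusive extension set so every set is
    emitted exactly once. Output is a sorted list of sorted node tuples.
    """
    if k not in (3, 4):
        raise GraphValidationError(f"unsupported subgraph size {k}; only 3 and 4")
    adj = _adjacency(graph)
    order = {v: i for i, v in enumerate(sorted(adj))}
    results: list[tuple[str, ...]] = []

    def extend(sub: list[str], extension: set[str], root: str) -> None:
        if len(sub) == k:
            results.append(tuple(sorted(sub)))
            return
        ext = set(extension)
        while ext:
            w = ext.pop()
            # new candidates: neighbors of w beyond the root, not already
            # adjacent to the current subgraph
            new_ext = ext | {
                u
                for u in adj[w]
                if order[u] > order[root]
                and u not in sub
                and all(u not in adj[s] for s in sub)
            }
            extend(sub + [w], new_ext, root)

    for root in sorted(adj):
        extension = {u for u in adj[root] if order[u] > order[root]}
        extend([root], extension, root)
    return sorted(results)


def classify(graph: GraphLike, nodes: Iterable[str]) -> MotifClass:
    """Isomorphism class of the induced subgraph on ``nodes``.

    Classification is by size, edge count and degree sequence, which
    separates all connected simple graphs on 3 and 4 nodes that occur in
    bipartite or projected networks.
    """
    node_list = sorted(set(nodes))
    if len(node_list) not in (3, 4):
        raise GraphValidationError(f"motif must have 3 or 4 nodes, got {len(node_list)}")
    g = _as_networkx(graph)
    sub = g.subgraph(node_list)
    if sub.number_of_nodes() != len(node_list) or not nx.is_connected(sub):
        raise GraphValidationError(f"nodes {node_list} do not induce a connected subgraph")
    degs = tuple(sorted(d for _, d in sub.degree()))
    e = sub.number_of_edges()
    if len(node_list) == 3:
        return MotifClass.PATH3 if e == 2 else MotifClass.TRIANGLE
    if degs == (1, 1, 2, 2) and e == 3:
        return MotifClass.PATH4
    if degs == (1, 1, 1, 3):
        return MotifClass.STAR4
    if degs == (2, 2, 2, 2) and e == 4:
        return MotifClass.CYCLE4
    return MotifClass.OTHER


def census(graph: GraphLike) -> MotifCensus:
    """Count all 3- and 4-node connected subgraphs by class, with per-node
    participation counts. Null-ensemble statistics are not computed here."""
    g = _as_networkx(graph)
    if g.number_of_nodes() == 0:
        raise GraphValidationError("census undefined for an empty graph")
    counts: dict[MotifClass, int] = {cls: 0 for cls in BIPARTITE_CLASSES}
    participation: dict[tuple[str, MotifClass], int] = {}
    for k in (3, 4):
        for nodes in enumerate_subgraphs(g, k):
            cls = classify(g, nodes)
            counts[cls] = counts.get(cls, 0) + 1
            for v in nodes:
                key = (v, cls)
                participation[key] = participation.get(key, 0) + 1
    return MotifCensus(counts=counts, participation=participation)


def randomize(
    graph: MirnaDiseaseGraph, swap_factor: float, seed: Optional[int] = None
) -> MirnaDiseaseGraph:
    """Degree-preserving randomization by double edge swaps.

    round(swap_factor * E) swap attempts are made; each picks two edges
    (a,b) and (c,d) with a,c miRNAs and rewires them to (a,d) and (c,b)
    only if neither rewired edge already exists. Every node keeps its exact
    degree, and the graph stays bipartite and simple. Each edge's weight
    travels with its miRNA endpoint's slot.
    """
    if graph.n_edges < 2:
        raise GraphValidationError("cannot randomize a graph with fewer than 2 edges")
    rng = np.random.default_rng(seed)
    edges = sorted(graph.edges)  # deterministic starting order
    evidence = {e: graph.edges[e] for e in edges}
    edge_set = set(edges)
    attempts = int(round(swap_factor * len(edges)))
    for _ in range(attempts):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == c or b == d:
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.difference_update([(a, b), (c, d)])
        edge_set.update([(a, d), (c, b)])
        ev_ab, ev_cd = evidence.pop((a, b)), evidence.pop((c, d))
        evidence[(a, d)] = ev_ab
        evidence[(c, b)] = ev_cd
        edges[i] = (a, d)
        edges[j] = (c, b)
    out = MirnaDiseaseGraph()
    # carry partitions over so isolated nodes keep their (zero) degree
    for node in sorted(graph.mirna_ids):
        out._register(node, "mirna")
    for node in sorted(graph.disease_ids):
        out._register(node, "disease")
    for (m, d) in sorted(edge_set):
        out.add_edge(m, d, evidence[(m, d)])
    return out


def _edge_disjoint_packing(
    g: nx.Graph, occurrences: Sequence[tuple[str, ...]]
) -> int:
    """Greedy count of pairwise edge-disjoint occurrences, scanned in
    deterministic sorted order."""
    used: set[frozenset] = set()
    packed = 0
    for nodes in occurrences:
        sub_edges = {
            frozenset((u, v)) for u, v in g.subgraph(nodes).edges()
        }
        if sub_edges & used:
            continue
        used |= sub_edges
        packed += 1
    return packed


def significance(
    graph: MirnaDiseaseGraph,
    ensemble_size: int = 1000,
    swap_factor: float = 10.0,
    seed: Optional[int] = None,
    z_threshold: float = 2.0,
    p_threshold: float = 0.01,
    uniqueness_threshold: int = 4,
) -> MotifCensus:
    """Motif census with randomized-null significance statistics.

    For each class the mean and sample standard deviation of counts over
    ``ensemble_size`` independent degree-preserving randomizations give a
    Z-score; ``empirical_p`` is the fraction of random networks whose count
    reaches the real one; ``uniqueness`` is the greedy edge-disjoint packing
    count in the real network. The ``significant`` flag applies the three
    conventional thresholds together. Fully reproducible from ``seed``.
    """
    if ensemble_size < 2:
        raise GraphValidationError("ensemble_size must be >= 2 (std undefined below)")
    real = census(graph)
    g = _as_networkx(graph)
    occurrences_by_class: dict[MotifClass, list[tuple[str, ...]]] = {}
    for k in (3, 4):
        for nodes in enumerate_subgraphs(g, k):
            occurrences_by_class.setdefault(classify(g, nodes), []).append(nodes)

    child_seeds = np.random.SeedSequence(seed).spawn(ensemble_size)
    random_counts: dict[MotifClass, list[int]] = {c: [] for c in real.counts}
    for cs in child_seeds:
        rnd = randomize(graph, swap_factor, seed=np.random.default_rng(cs))
        rc = census(rnd)
        for cls in random_counts:
            random_counts[cls].append(rc.counts.get(cls, 0))

    stats: dict[MotifClass, ClassStats] = {}
    for cls, real_count in real.counts.items():
        arr = np.asarray(random_counts[cls], dtype=float)
        mean = float(arr.mean())
        std = float(arr.std(ddof=1))
        z = (real_count - mean) / std if std > 0 else None
        p = float(np.mean(arr >= real_count))
        uniq = _edge_disjoint_packing(
            g, sorted(occurrences_by_class.get(cls, []))
        )
        sig = (
            None
            if z is None
            else bool(z >= z_threshold and p <= p_threshold and uniq >= uniqueness_threshold)
        )
        stats[cls] = ClassStats(real_count, mean, std, z, p, uniq, sig)
    return MotifCensus(
        counts=real.counts,
        participation=real.participation,
        ensemble_stats=stats,
        ensemble_size=ensemble_size,
        seed=seed,
    )


def motif_prioritize(
    graph: MirnaDiseaseGraph,
    query: Iterable[str],
    classes: Optional[Iterable[MotifClass]] = None,
) -> list[tuple[str, int]]:
    """Rank diseases by motif participation within the query's subnetwork.

    The census is run on the induced subnetwork of the queried miRNAs plus
    their adjacent diseases; diseases are ordered by total participation
    across the requested classes (all four bipartite classes by default),
    descending, with a lexicographic tie-break. Diseases participating in no
    requested motif are omitted.
    """
    wanted = tuple(classes) if classes is not None else BIPARTITE_CLASSES
    ranking = cumulative_impact(graph, query)  # resolves/validates the query
    sub = graph.induced_subgraph(ranking.query_mirnas)
    if sub.n_edges == 0:
        logger.warning("queried miRNAs induce an empty subnetwork")
        return []
    c = census(sub)
    totals: dict[str, int] = {}
    for d in sub.disease_ids:
        total = sum(c.participation_of(d, cls) for cls in wanted)
        if total > 0:
            totals[d] = total
    return sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
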