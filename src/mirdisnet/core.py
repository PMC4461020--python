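"""Core graph types and topology operations for miRNA-disease networks.

The central container is :class:`MirnaDiseaseGraph`, a simple undirected
weighted bipartite graph whose two partitions are miRNAs and diseases and
whose edge weights count the publications supporting each association.
On top of it this module provides network density, degree summaries with an
optional descriptive power-law fit, the one-mode disease-disease projection,
and deterministic shortest-path queries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

DIRECTIONS = frozenset({"up", "down", "unspecified"})


class GraphValidationError(ValueError):
    """Raised when an input violates a graph invariant (bipartiteness,
    weight positivity, unknown identifiers, ...)."""


@dataclass(frozen=True)
class CitationRecord:
    """A single literature citation supporting a miRNA-disease association.

    ``direction`` records whether the publication reports the miRNA
    up-regulated, down-regulated, or with unspecified direction in the
    disease context.
    """

    pubmed_id: str
    direction: str = "unspecified"

    def __post_init__(self) -> None:
        if not str(self.pubmed_id).strip():
            raise GraphValidationError("citation requires a non-empty pubmed_id")
        if self.direction not in DIRECTIONS:
            raise GraphValidationError(
                f"direction must be one of {sorted(DIRECTIONS)}, got {self.direction!r}"
            )


@dataclass(frozen=True)
class EdgeEvidence:
    """Evidence backing one association edge.

    ``weight`` is the number of distinct supporting publications. When
    ``citations`` is non-empty the weight must equal the number of distinct
    PubMed identifiers among them; a publication reporting both an up- and a
    down-regulation still counts once.
    """

    weight: int
    citations: tuple[CitationRecord, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.weight, (int, np.integer)) or isinstance(self.weight, bool):
            raise GraphValidationError(f"weight must be an integer, got {self.weight!r}")
        if self.weight < 1:
            raise GraphValidationError(f"edge weight must be >= 1, got {self.weight}")
        if self.citations:
            distinct = {c.pubmed_id for c in self.citations}
            if len(distinct) != self.weight:
                raise GraphValidationError(
                    f"weight {self.weight} does not match {len(distinct)} distinct PubMed ids"
                )

    @property
    def pubmed_ids(self) -> set[str]:
        return {c.pubmed_id for c in self.citations}


def _canon(identifier: str) -> str:
    """Canonical form for identifier comparison: trimmed, case-folded."""
    return identifier.strip().lower()


@dataclass
class MirnaDiseaseGraph:
    """Weighted bipartite association network between miRNAs and diseases.

    Identifiers are compared case-insensitively after whitespace trimming but
    stored in their first-seen form. Edge keys use the stored forms.
    """

    mirna_ids: set[str] = field(default_factory=set)
    disease_ids: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], EdgeEvidence] = field(default_factory=dict)
    # canonical id -> stored form, shared across both partitions
    _canonical: dict[str, str] = field(default_factory=dict, repr=False)

    # -- construction -----------------------------------------------------

    def _register(self, identifier: str, partition: str) -> str:
        name = identifier.strip()
        if not name:
            raise GraphValidationError("empty identifier")
        key = _canon(name)
        stored = self._canonical.setdefault(key, name)
        if partition == "mirna":
            if stored in self.disease_ids:
                raise GraphValidationError(
                    f"identifier {stored!r} already used as a disease; partitions must be disjoint"
                )
            self.mirna_ids.add(stored)
        else:
            if stored in self.mirna_ids:
                raise GraphValidationError(
                    f"identifier {stored!r} already used as a miRNA; partitions must be disjoint"
                )
            self.disease_ids.add(stored)
        return stored

    def add_edge(self, mirna_id: str, disease_id: str, evidence: EdgeEvidence) -> None:
        """Add or merge one association. Duplicate pairs pool distinct
        citations and recompute the weight from the pooled PubMed ids."""
        m = self._register(mirna_id, "mirna")
        d = self._register(disease_id, "disease")
        key = (m, d)
        if key in self.edges:
            self.edges[key] = _merge_evidence(self.edges[key], evidence)
        else:
            self.edges[key] = evidence

    # -- lookups ----------------------------------------------------------

    def resolve(self, identifier: str) -> Optional[str]:
        """Stored form of an identifier, or None if absent."""
        return self._canonical.get(_canon(identifier))

    def has_node(self, identifier: str) -> bool:
        return self.resolve(identifier) is not None

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_mirnas + self.n_diseases

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight(self, mirna_id: str, disease_id: str) -> int:
        return self.edges[(mirna_id, disease_id)].weight

    def diseases_of(self, mirna_id: str) -> set[str]:
        return {d for (m, d) in self.edges if m == mirna_id}

    def mirnas_of(self, disease_id: str) -> set[str]:
        return {m for (m, d) in self.edges if d == disease_id}

    def degree(self, identifier: str) -> int:
        stored = self.resolve(identifier)
        if stored is None:
            raise GraphValidationError(f"unknown node {identifier!r}")
        return sum(1 for (m, d) in self.edges if m == stored or d == stored)

    def induced_subgraph(
        self, query_mirnas: Iterable[str]
    ) -> "MirnaDiseaseGraph":
        """Subnetwork on the given miRNAs plus every disease adjacent to at
        least one of them (each miRNA's full sphere of influence)."""
        wanted = {self.resolve(m) for m in query_mirnas}
        wanted.discard(None)
        sub = MirnaDiseaseGraph()
        for (m, d), ev in sorted(self.edges.items()):
            if m in wanted:
                sub.add_edge(m, d, ev)
        return sub

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.mirna_ids, bipartite="mirna")
        g.add_nodes_from(self.disease_ids, bipartite="disease")
        for (m, d), ev in self.edges.items():
            g.add_edge(m, d, weight=ev.weight)
        return g

    def validate(self) -> None:
        """Re-check every container invariant; raises on violation."""
        if self.mirna_ids & self.disease_ids:
            raise GraphValidationError("partitions are not disjoint")
        for (m, d), ev in self.edges.items():
            if m not in self.mirna_ids or d not in self.disease_ids:
                raise GraphValidationError(f"edge ({m!r},{d!r}) endpoints not in partitions")
            if ev.weight < 1:
                raise GraphValidationError(f"edge ({m!r},{d!r}) has weight < 1")


def _merge_evidence(a: EdgeEvidence, b: EdgeEvidence) -> EdgeEvidence:
    """Pool two evidence records for the same pair.

    With citations on either side, the merged weight is the number of
    distinct pooled PubMed ids (the first-seen direction is kept per id).
    Two citation-free records are treated as disjoint literature batches and
    their weights add.
    """
    if not a.citations and not b.citations:
        return EdgeEvidence(weight=a.weight + b.weight)
    seen: dict[str, CitationRecord] = {}
    for c in a.citations + b.citations:
        seen.setdefault(c.pubmed_id, c)
    pooled = tuple(sorted(seen.values(), key=lambda c: c.pubmed_id))
    return EdgeEvidence(weight=len(seen), citations=pooled)


@dataclass
class ProjectedDiseaseGraph:
    """One-mode disease-disease projection: diseases are linked when they
    share at least one regulating miRNA; edge weights count shared miRNAs."""

    disease_ids: set[str] = field(default_factory=set)
    edges: dict[frozenset, int] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.disease_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def shared_count(self, d1: str, d2: str) -> int:
        return self.edges.get(frozenset((d1, d2)), 0)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.disease_ids)
        for pair, count in self.edges.items():
            u, v = sorted(pair)
            g.add_edge(u, v, weight=count)
        return g


@dataclass
class DegreeSummary:
    """Degree histogram plus density and an optional descriptive power-law
    slope gamma fitted to log10 P(k) vs log10 k."""

    degree_histogram: dict[int, int]
    density: float
    powerlaw_exponent_estimate: Optional[float] = None
    fit_r_squared: Optional[float] = None

    @property
    def n_nodes(self) -> int:
        return sum(self.degree_histogram.values())

    @property
    def max_degree(self) -> int:
        return max(self.degree_histogram) if self.degree_histogram else 0

    @property
    def median_degree(self) -> float:
        degrees: list[int] = []
        for k, c in self.degree_histogram.items():
            degrees.extend([k] * c)
        return float(np.median(degrees)) if degrees else 0.0


GraphLike = Union[MirnaDiseaseGraph, ProjectedDiseaseGraph, nx.Graph]


def _as_networkx(graph: GraphLike) -> nx.Graph:
    if isinstance(graph, nx.Graph):
        return graph
    return graph.to_networkx()


# ---------------------------------------------------------------------------
# operations


def build_graph(
    edge_records: Sequence[tuple[str, str, EdgeEvidence]]
) -> MirnaDiseaseGraph:
    """Assemble a validated graph from (mirna_id, disease_id, evidence)
    records; duplicate pairs are merged by pooling distinct citations."""
    graph = MirnaDiseaseGraph()
    for mirna_id, disease_id, evidence in edge_records:
        if not isinstance(evidence, EdgeEvidence):
            raise GraphValidationError("each record needs an EdgeEvidence")
        graph.add_edge(mirna_id, disease_id, evidence)
    graph.validate()
    return graph


def density(graph: GraphLike) -> float:
    """Simple-graph density 2E / (N(N-1)) over all nodes.

    Bipartite networks are treated as plain simple graphs here, so even a
    complete bipartite graph has density below 1.
    """
    g = _as_networkx(graph)
    n = g.number_of_nodes()
    if n < 2:
        raise GraphValidationError(f"density undefined for {n} node(s)")
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def degree_summary(graph: GraphLike, fit_powerlaw: bool = False) -> DegreeSummary:
    """Degree histogram, density and (optionally) a descriptive power-law
    exponent.

    The exponent gamma is the negated least-squares slope of
    log10 P(k) vs log10 k over strictly positive degrees with non-zero
    counts; this is a qualitative scale-free diagnostic, not a
    maximum-likelihood tail fit.
    """
    g = _as_networkx(graph)
    if g.number_of_nodes() == 0:
        raise GraphValidationError("degree summary undefined for an empty graph")
    hist: dict[int, int] = {}
    for _, k in g.degree():
        hist[k] = hist.get(k, 0) + 1
    dens = density(g) if g.number_of_nodes() >= 2 else 0.0

    gamma = None
    r2 = None
    if fit_powerlaw:
        n = g.number_of_nodes()
        ks = sorted(k for k in hist if k > 0)
        if len(ks) >= 2:
            x = np.log10(ks)
            y = np.log10([hist[k] / n for k in ks])
            slope, intercept = np.polyfit(x, y, 1)
            gamma = -float(slope)
            pred = slope * x + intercept
            ss_res = float(np.sum((y - pred) ** 2))
            ss_tot = float(np.sum((y - np.mean(y)) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DegreeSummary(hist, dens, gamma, r2)


def project_diseases(graph: MirnaDiseaseGraph) -> ProjectedDiseaseGraph:
    """One-mode projection onto the disease partition.

    Two diseases are linked iff some miRNA regulates both; the edge carries
    the number of such shared miRNAs. Diseases sharing no miRNA with any
    other disease are retained as isolated nodes.
    """
    proj = ProjectedDiseaseGraph(disease_ids=set(graph.disease_ids))
    neighbors: dict[str, set[str]] = {}
    for (m, d) in graph.edges:
        neighbors.setdefault(m, set()).add(d)
    for ds in neighbors.values():
        for d1 in ds:
            for d2 in ds:
                if d1 < d2:
                    key = frozenset((d1, d2))
                    proj.edges[key] = proj.edges.get(key, 0) + 1
    return proj


def shortest_path(
    graph: GraphLike, source: str, target: str
) -> Optional[list[str]]:
    """Minimum-hop path from source to target, or None when disconnected.

    Among all shortest paths the lexicographically smallest node sequence is
    returned, so repeated queries are deterministic. In the bipartite graph
    the path alternates miRNA and disease nodes.
    """
    g = _as_networkx(graph)
    if isinstance(graph, MirnaDiseaseGraph):
        src, tgt = graph.resolve(source), graph.resolve(target)
    else:
        src = source if g.has_node(source) else None
        tgt = target if g.has_node(target) else None
    if src is None or tgt is None:
        raise GraphValidationError(
            f"unknown node in path query: {source!r} -> {target!r}"
        )
    if src == tgt:
        return [src]
    try:
        dist_from_src = nx.single_source_shortest_path_length(g, src)
        if tgt not in dist_from_src:
            return None
        dist_to_tgt = nx.single_source_shortest_path_length(g, tgt)
    except nx.NetworkXError:  # pragma: no cover - guarded above
        return None
    total = dist_from_src[tgt]
    # Greedy walk: at every step take the smallest neighbor that still lies
    # on some shortest path; this yields the lexicographically least sequence.
    path = [src]
    current = src
    while current != tgt:
        step = dist_from_src[path[-1]]
        candidates = [
            v
            for v in g.neighbors(current)
            if dist_from_src.get(v) == step + 1
            and dist_to_tgt.get(v, math.inf) == total - step - 1
        ]
        current = min(candidates)
        path.append(current)
    return path
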