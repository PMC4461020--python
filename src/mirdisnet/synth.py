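"""Synthetic bipartite networks for testing and benchmarking.

Real miRNA-disease association networks are sparse with long-tail degree
distributions: a few hub miRNAs regulate many diseases (and a few diseases
are regulated by many miRNAs) while most nodes have low degree. The
preferential-attachment generator here reproduces that shape; the
Erdos-Renyi generator provides degree-homogeneous null fixtures; and
:func:`worked_example_fixture` builds the small five-edge network used
throughout the documentation and tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import EdgeEvidence, GraphValidationError, MirnaDiseaseGraph


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the scale-free bipartite generator.

    ``edges_per_new_node`` is the preferential-attachment parameter m: each
    grown node attaches to up to m existing nodes of the opposite partition.
    ``weight_p`` is the success probability of the geometric law for edge
    weights (small p gives a longer citation-count tail).
    """

    n_mirnas: int
    n_diseases: int
    edges_per_new_node: int = 2
    weight_p: float = 0.3
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_mirnas < 1 or self.n_diseases < 1:
            raise GraphValidationError("need at least one node per partition")
        if self.edges_per_new_node < 1:
            raise GraphValidationError("edges_per_new_node must be >= 1")
        if not (0.0 < self.weight_p <= 1.0):
            raise GraphValidationError("weight_p must lie in (0, 1]")
        limit = max(self.n_mirnas, self.n_diseases)
        if self.edges_per_new_node > limit:
            raise GraphValidationError(
                "edges_per_new_node exceeds the opposite partition size"
            )


def _draw_weight(rng: np.random.Generator, p: float) -> int:
    return int(rng.geometric(p))


def scale_free_bipartite(config: SynthConfig) -> MirnaDiseaseGraph:
    """Bipartite preferential-attachment growth.

    Starts from a single seed edge m1-d1, then alternately adds miRNA and
    disease nodes; each new node attaches to
    min(edges_per_new_node, opposite partition size) distinct existing
    nodes of the opposite partition, sampled with probability proportional
    to degree + 1 (the +1 lets degree-0 nodes acquire edges). Integer edge
    weights are drawn from a geometric law. Reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    m = config.edges_per_new_node
    mirnas = ["m1"]
    diseases = ["d1"]
    degree = {"m1": 0, "d1": 0}
    edges: list[tuple[str, str, int]] = []

    def attach(new_node: str, pool: list[str]) -> None:
        k = min(m, len(pool))
        weights = np.array([degree[v] + 1 for v in pool], dtype=float)
        chosen = rng.choice(
            len(pool), size=k, replace=False, p=weights / weights.sum()
        )
        for idx in sorted(chosen):
            other = pool[idx]
            pair = (new_node, other) if new_node.startswith("m") else (other, new_node)
            edges.append((pair[0], pair[1], _draw_weight(rng, config.weight_p)))
            degree[new_node] += 1
            degree[other] += 1

    # seed edge
    edges.append(("m1", "d1", _draw_weight(rng, config.weight_p)))
    degree["m1"] = degree["d1"] = 1

    next_m, next_d = 2, 2
    while next_m <= config.n_mirnas or next_d <= config.n_diseases:
        if next_m <= config.n_mirnas:
            node = f"m{next_m}"
            mirnas.append(node)
            degree[node] = 0
            attach(node, diseases)
            next_m += 1
        if next_d <= config.n_diseases:
            node = f"d{next_d}"
            diseases.append(node)
            degree[node] = 0
            attach(node, mirnas)
            next_d += 1

    graph = MirnaDiseaseGraph()
    for mi, di, w in edges:
        graph.add_edge(mi, di, EdgeEvidence(weight=w))
    graph.validate()
    return graph


def er_bipartite(
    n_mirnas: int,
    n_diseases: int,
    edge_prob: float,
    max_weight: int = 30,
    seed: Optional[int] = None,
) -> MirnaDiseaseGraph:
    """Erdos-Renyi bipartite graph: every (miRNA, disease) pair is an edge
    independently with ``edge_prob``; weights uniform on 1..max_weight."""
    if not (0.0 <= edge_prob <= 1.0):
        raise GraphValidationError("edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    graph = MirnaDiseaseGraph()
    for i in range(1, n_mirnas + 1):
        graph._register(f"m{i}", "mirna")
    for j in range(1, n_diseases + 1):
        graph._register(f"d{j}", "disease")
    for i in range(1, n_mirnas + 1):
        for j in range(1, n_diseases + 1):
            if rng.random() < edge_prob:
                w = int(rng.integers(1, max_weight + 1))
                graph.add_edge(f"m{i}", f"d{j}", EdgeEvidence(weight=w))
    graph.validate()
    return graph


def worked_example_fixture() -> MirnaDiseaseGraph:
    """The five-edge demonstration network used in the documentation.

    Three miRNAs and four diseases with weights m1-d1=20, m1-d2=30,
    m2-d3=2, m3-d3=16, m3-d4=10. Its maximum-weight matching is
    {(m1,d2), (m3,d3)} with objective 46, leaving m2 unmatched; the merge
    rule then restores d1 (impact 20 > 18, the weakest matched impact).
    """
    records = [
        ("m1", "d1", EdgeEvidence(weight=20)),
        ("m1", "d2", EdgeEvidence(weight=30)),
        ("m2", "d3", EdgeEvidence(weight=2)),
        ("m3", "d3", EdgeEvidence(weight=16)),
        ("m3", "d4", EdgeEvidence(weight=10)),
    ]
    graph = MirnaDiseaseGraph()
    for m, d, ev in records:
        graph.add_edge(m, d, ev)
    graph.validate()
    return graph
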