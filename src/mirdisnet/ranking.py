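"""Disease prioritization: cumulative impact, the post-matching merge rule,
and the end-to-end pipeline.

The matching stage is deliberately conservative: because selected edges may
not share vertices, a strongly supported association can lose out to a
combination that scores higher overall. The merge rule repairs this by
re-admitting any disease whose cumulative impact (summed edge weight from
the queried miRNAs) strictly exceeds that of the weakest matched disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import mwm
from .core import GraphValidationError, MirnaDiseaseGraph

logger = logging.getLogger(__name__)


class EmptyQueryError(GraphValidationError):
    """Raised when no queried miRNA is present in the graph."""


@dataclass
class DiseaseRanking:
    """Diseases ordered by cumulative impact (descending, then id)."""

    entries: list[tuple[str, int]]
    query_mirnas: set[str]

    def impact(self, disease_id: str) -> int:
        for d, score in self.entries:
            if d == disease_id:
                return score
        raise KeyError(disease_id)

    @property
    def diseases(self) -> list[str]:
        return [d for d, _ in self.entries]


@dataclass
class MethodTrace:
    """Provenance of the merge decision: the weakest matched disease and the
    impact threshold it sets."""

    threshold_disease: Optional[str] = None
    threshold_impact: Optional[int] = None
    degenerate: bool = False
    added_diseases: list[str] = field(default_factory=list)


@dataclass
class PrioritizedResult:
    """Final output of the pipeline: matched diseases, the impact ranking,
    and the merged ordered disease list."""

    mwm_diseases: set[str]
    ranking: DiseaseRanking
    final_diseases: list[str]
    method_trace: MethodTrace
    matching: Optional[mwm.MatchingSolution] = None

    @property
    def is_empty(self) -> bool:
        return not self.final_diseases


def cumulative_impact(
    graph: MirnaDiseaseGraph, query: Iterable[str]
) -> DiseaseRanking:
    """Rank every disease adjacent to the query by total edge weight from
    the queried miRNAs.

    Unknown query identifiers are dropped with a warning; if none remain an
    :class:`EmptyQueryError` is raised.
    """
    resolved: set[str] = set()
    for q in query:
        stored = graph.resolve(q)
        if stored is None or stored not in graph.mirna_ids:
            logger.warning("query miRNA %r not found in graph; dropped", q)
        else:
            resolved.add(stored)
    if not resolved:
        raise EmptyQueryError("no queried miRNA is present in the graph")
    impacts: dict[str, int] = {}
    for (m, d), ev in graph.edges.items():
        if m in resolved:
            impacts[d] = impacts.get(d, 0) + ev.weight
    entries = sorted(impacts.items(), key=lambda kv: (-kv[1], kv[0]))
    return DiseaseRanking(entries=entries, query_mirnas=resolved)


def merge(mwm_diseases: set[str], ranking: DiseaseRanking) -> PrioritizedResult:
    """Combine the matched disease set with the impact ranking.

    Let t be the minimum cumulative impact over the matched diseases. The
    final list is the matched set plus every disease whose impact is
    strictly greater than t, emitted in ranking order. With an empty matched
    set the result is empty and flagged degenerate.
    """
    if not mwm_diseases:
        trace = MethodTrace(degenerate=True)
        return PrioritizedResult(set(), ranking, [], trace)
    unknown = mwm_diseases - set(ranking.diseases)
    if unknown:
        raise GraphValidationError(
            f"matched diseases missing from ranking: {sorted(unknown)}"
        )
    threshold_disease = min(
        mwm_diseases, key=lambda d: (ranking.impact(d), d)
    )
    threshold = ranking.impact(threshold_disease)
    final = [
        d
        for d, impact in ranking.entries
        if d in mwm_diseases or impact > threshold
    ]
    added = [d for d in final if d not in mwm_diseases]
    trace = MethodTrace(
        threshold_disease=threshold_disease,
        threshold_impact=threshold,
        added_diseases=added,
    )
    return PrioritizedResult(set(mwm_diseases), ranking, final, trace)


def prioritize(graph: MirnaDiseaseGraph, query: Iterable[str]) -> PrioritizedResult:
    """End-to-end pipeline for a set of queried miRNAs.

    1. restrict to the induced subnetwork on the queried miRNAs and every
       disease they influence;
    2. solve the maximum-weight matching on that subnetwork;
    3. rank all influenced diseases by cumulative impact;
    4. merge matched diseases with strictly higher-impact ones.
    """
    query = list(query)
    if not query:
        raise EmptyQueryError("query must be non-empty")
    ranking = cumulative_impact(graph, query)  # validates the query
    sub = graph.induced_subgraph(ranking.query_mirnas)
    if sub.n_edges == 0:
        logger.warning("queried miRNAs have no associations; empty result")
        return PrioritizedResult(
            set(), ranking, [], MethodTrace(degenerate=True)
        )
    solution = mwm.solve(sub)
    result = merge(solution.matched_diseases, ranking)
    result.matching = solution
    return result
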