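"""Edge-list CSV reading/writing and GNU MathProg (GMPL) model export.

The canonical on-disk format is a UTF-8 CSV with columns
``mirna,disease,weight,pubmed_ids,direction``. Multi-valued cells (PubMed
ids, per-citation directions) use ";" as the inner separator. Result
exports carry the full provenance of each reported association: weight,
pooled PubMed ids, regulation directions, rank and score.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .core import (
    CitationRecord,
    EdgeEvidence,
    GraphValidationError,
    MirnaDiseaseGraph,
    build_graph,
)
from .ranking import PrioritizedResult

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised for malformed input files (missing columns, bad values)."""


@dataclass(frozen=True)
class EdgeCsvDialect:
    """Column layout of the edge-list CSV."""

    mirna_col: str = "mirna"
    disease_col: str = "disease"
    weight_col: str = "weight"
    pubmed_col: str = "pubmed_ids"
    direction_col: str = "direction"
    list_sep: str = ";"
    header: bool = True

    def __post_init__(self) -> None:
        cols = [
            self.mirna_col,
            self.disease_col,
            self.weight_col,
            self.pubmed_col,
            self.direction_col,
        ]
        if len(set(cols)) != len(cols):
            raise FormatError("CSV column names must be unique")
        if len(self.list_sep) != 1 or self.list_sep == ",":
            raise FormatError("list separator must be a single non-comma character")


DEFAULT_DIALECT = EdgeCsvDialect()


def _split_cell(cell: object, sep: str) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    return [part.strip() for part in text.split(sep) if part.strip()]


def _row_evidence(
    row: pd.Series, dialect: EdgeCsvDialect, line_no: int
) -> EdgeEvidence:
    pmids = _split_cell(row.get(dialect.pubmed_col), dialect.list_sep)
    directions = _split_cell(row.get(dialect.direction_col), dialect.list_sep)
    citations: tuple[CitationRecord, ...] = ()
    if pmids:
        if len(directions) == len(pmids):
            pairs = zip(pmids, directions)
        else:
            single = directions[0] if len(directions) == 1 else "unspecified"
            pairs = ((p, single) for p in pmids)
        seen: dict[str, CitationRecord] = {}
        for pmid, direction in pairs:
            try:
                seen.setdefault(pmid, CitationRecord(pmid, direction))
            except GraphValidationError as exc:
                raise FormatError(f"line {line_no}: {exc}") from exc
        citations = tuple(seen.values())

    raw_weight = row.get(dialect.weight_col)
    weight: Optional[int] = None
    if raw_weight is not None and not (
        isinstance(raw_weight, float) and pd.isna(raw_weight)
    ):
        text = str(raw_weight).strip()
        if text:
            try:
                weight = int(float(text)) if float(text) == int(float(text)) else None
            except ValueError:
                weight = None
            if weight is None:
                raise FormatError(f"line {line_no}: non-integer weight {text!r}")

    if citations:
        distinct = len({c.pubmed_id for c in citations})
        if weight is not None and weight != distinct:
            logger.warning(
                "line %d: weight %d disagrees with %d distinct PubMed ids; "
                "using the PubMed count",
                line_no,
                weight,
                distinct,
            )
        return EdgeEvidence(weight=distinct, citations=citations)
    if weight is None:
        raise FormatError(f"line {line_no}: row has neither weight nor pubmed ids")
    if weight < 1:
        raise FormatError(f"line {line_no}: weight must be >= 1, got {weight}")
    return EdgeEvidence(weight=weight)


def read_edge_csv(
    path: Union[str, Path], dialect: EdgeCsvDialect = DEFAULT_DIALECT
) -> MirnaDiseaseGraph:
    """Read an association graph from an edge-list CSV.

    The weight of each edge is taken from the weight column; when only
    PubMed ids are given, the weight is their distinct count; when both are
    present and disagree, the PubMed count wins with a logged warning.
    Unknown extra columns are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    frame = pd.read_csv(
        path,
        dtype=str,
        header=0 if dialect.header else None,
        skipinitialspace=True,
    ) if path.stat().st_size else pd.DataFrame()
    if frame.empty and not list(frame.columns):
        raise FormatError(f"{path}: empty file, not a CSV")
    for col in (dialect.mirna_col, dialect.disease_col):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if (
        dialect.weight_col not in frame.columns
        and dialect.pubmed_col not in frame.columns
    ):
        raise FormatError(
            f"{path}: needs a {dialect.weight_col!r} or {dialect.pubmed_col!r} column"
        )
    records = []
    for idx, row in frame.iterrows():
        line_no = int(idx) + 2  # 1-based, after the header line
        mirna = str(row[dialect.mirna_col]).strip() if pd.notna(row[dialect.mirna_col]) else ""
        disease = str(row[dialect.disease_col]).strip() if pd.notna(row[dialect.disease_col]) else ""
        if not mirna or not disease:
            raise FormatError(f"line {line_no}: empty miRNA or disease identifier")
        records.append((mirna, disease, _row_evidence(row, dialect, line_no)))
    return build_graph(records)


RESULT_COLUMNS = [
    "rank",
    "disease",
    "mirna",
    "weight",
    "pubmed_ids",
    "directions",
    "score",
    "method",
]


def write_result_csv(
    result: Union[PrioritizedResult, Sequence[tuple[str, int]]],
    graph: MirnaDiseaseGraph,
    path: Union[str, Path],
    query: Optional[set[str]] = None,
    method: Optional[str] = None,
    dialect: EdgeCsvDialect = DEFAULT_DIALECT,
) -> int:
    """Write a prioritization result with per-association provenance.

    One row is emitted per (queried miRNA, disease) association in the
    result's induced subnetwork, ordered by rank, then disease, then miRNA.
    Returns the number of data rows written.
    """
    if isinstance(result, PrioritizedResult):
        ordered = list(result.final_diseases)
        scores = dict(result.ranking.entries)
        mirnas = set(result.ranking.query_mirnas)
        method = method or "mwm"
    else:
        ordered = [d for d, _ in result]
        scores = dict(result)
        mirnas = {graph.resolve(q) for q in (query or set())} - {None}
        if not mirnas:
            mirnas = set(graph.mirna_ids)
        method = method or "motif"

    rows = []
    for rank, disease in enumerate(ordered, start=1):
        for (m, d), ev in sorted(graph.edges.items()):
            if d != disease or m not in mirnas:
                continue
            pmids = dialect.list_sep.join(sorted(ev.pubmed_ids))
            dirs = dialect.list_sep.join(
                c.direction for c in sorted(ev.citations, key=lambda c: c.pubmed_id)
            )
            rows.append(
                {
                    "rank": rank,
                    "disease": d,
                    "mirna": m,
                    "weight": ev.weight,
                    "pubmed_ids": pmids,
                    "directions": dirs,
                    "score": scores.get(disease, ""),
                    "method": method,
                }
            )
    rows.sort(key=lambda r: (r["rank"], r["disease"], r["mirna"]))
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.DictWriter(handle, fieldnames=RESULT_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    return len(rows)


def write_edge_csv(
    graph: MirnaDiseaseGraph,
    path: Union[str, Path],
    dialect: EdgeCsvDialect = DEFAULT_DIALECT,
) -> int:
    """Write the full graph back to the canonical edge-list CSV."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            [
                dialect.mirna_col,
                dialect.disease_col,
                dialect.weight_col,
                dialect.pubmed_col,
                dialect.direction_col,
            ]
        )
        count = 0
        for (m, d), ev in sorted(graph.edges.items()):
            cits = sorted(ev.citations, key=lambda c: c.pubmed_id)
            writer.writerow(
                [
                    m,
                    d,
                    ev.weight,
                    dialect.list_sep.join(c.pubmed_id for c in cits),
                    dialect.list_sep.join(c.direction for c in cits),
                ]
            )
            count += 1
    return count


_IDENT_RE = re.compile(r"[^A-Za-z0-9_]")


def _gmpl_name(identifier: str, taken: dict[str, str]) -> str:
    base = _IDENT_RE.sub("_", identifier) or "n"
    name = base
    suffix = 1
    while name in taken and taken[name] != identifier:
        suffix += 1
        name = f"{base}_{suffix}"
    taken[name] = identifier
    return name


def export_gmpl(
    graph: MirnaDiseaseGraph, path: Optional[Union[str, Path]] = None
) -> str:
    """Emit the matching formulation as a GNU MathProg model.

    One binary variable per existing edge, an objective summing
    weight * variable, and one <=1 constraint per vertex incident to at
    least one edge. The model text is returned and optionally written.
    """
    if not graph.edges:
        raise GraphValidationError("nothing to export: the graph has no edges")
    taken: dict[str, str] = {}
    var_names: dict[tuple[str, str], str] = {}
    node_names: dict[str, str] = {}
    for node in sorted(graph.mirna_ids | graph.disease_ids):
        node_names[node] = _gmpl_name(node, taken)
    for (m, d) in sorted(graph.edges):
        var_names[(m, d)] = f"X_{node_names[m]}_{node_names[d]}"

    lines = ["/* maximum-weight matching on the miRNA-disease network */", ""]
    for (m, d) in sorted(graph.edges):
        lines.append(f"var {var_names[(m, d)]}, binary;")
    lines.append("")
    terms = " + ".join(
        f"{graph.edges[(m, d)].weight} * {var_names[(m, d)]}"
        for (m, d) in sorted(graph.edges)
    )
    lines.append(f"maximize total_weight: {terms};")
    lines.append("")
    for m in sorted(graph.mirna_ids):
        incident = [var_names[(a, b)] for (a, b) in sorted(graph.edges) if a == m]
        if incident:
            lines.append(
                f"s.t. c_mirna_{node_names[m]}: " + " + ".join(incident) + " <= 1;"
            )
    for d in sorted(graph.disease_ids):
        incident = [var_names[(a, b)] for (a, b) in sorted(graph.edges) if b == d]
        if incident:
            lines.append(
                f"s.t. c_disease_{node_names[d]}: " + " + ".join(incident) + " <= 1;"
            )
    lines.extend(["", "solve;", "end;", ""])
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
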