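"""Similarity clustering of transcripts from pairwise match records.

Without a reference genome, isoforms and close paralogs of one gene end up
as separate assembled transcripts.  A self-to-self similarity search yields
pairwise matches; transcripts joined by a match passing both an
overlap-ratio and an identity threshold are merged into clusters by single
linkage (a match "to any sequence" of a cluster joins it).  Two presets are
used: gene-set deduplication (overlap ratio >0.60, identity >0.96) and
expression counting units (overlap ratio >0.80, identity >0.96).  Both
thresholds are strict inequalities.

The overlap ratio divides the matched overlap by the *shorter* of the two
transcript lengths, so a short isoform fully contained in a longer one
scores near 1; a longer-length denominator is available for sensitivity
analysis.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx
import pandas as pd

from .catalog import ClusterMap, ConsistencyError, TranscriptCatalog

#: (min_overlap, min_identity) for gene-set deduplication.
DEDUP_PRESET = (0.60, 0.96)
#: (min_overlap, min_identity) for expression counting units.
EXPRESSION_PRESET = (0.80, 0.96)


class MatchRecord(NamedTuple):
    """One pairwise similarity match (query != subject)."""

    query: str
    subject: str
    overlap_bp: int
    identity: float


def overlap_ratio(
    match: MatchRecord,
    len_query: int,
    len_subject: int,
    denominator: str = "shorter",
) -> float:
    """Overlap length divided by the shorter (default) or longer transcript."""
    if len_query <= 0 or len_subject <= 0:
        raise ValueError("transcript lengths must be positive")
    if match.overlap_bp < 0:
        raise ValueError("overlap length must be non-negative")
    if match.overlap_bp > min(len_query, len_subject):
        raise ConsistencyError(
            f"overlap {match.overlap_bp} exceeds shorter transcript "
            f"({min(len_query, len_subject)} bp) for {match.query}/{match.subject}"
        )
    if denominator == "shorter":
        denom = min(len_query, len_subject)
    elif denominator == "longer":
        denom = max(len_query, len_subject)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return match.overlap_bp / denom


def build_clusters(
    matches: Iterable[MatchRecord],
    catalog: TranscriptCatalog,
    min_overlap: float = EXPRESSION_PRESET[0],
    min_identity: float = EXPRESSION_PRESET[1],
    denominator: str = "shorter",
) -> ClusterMap:
    """Single-linkage clusters from matches passing both strict thresholds.

    Unmatched transcripts become singletons.  Each cluster is named after
    its representative: the longest member, ties broken by smallest id.
    """
    if not (0 < min_overlap <= 1) or not (0 < min_identity <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    lengths = catalog.lengths
    graph = nx.Graph()
    graph.add_nodes_from(catalog.ids)
    # every record is judged on its own; duplicate A-B / B-A pairs merge in
    # the graph, so the pair links iff any one record passes both thresholds
    for m in matches:
        if m.query == m.subject:
            continue
        for t in (m.query, m.subject):
            if t not in catalog:
                raise ConsistencyError(f"match references unknown transcript {t!r}")
        ratio = overlap_ratio(m, lengths[m.query], lengths[m.subject], denominator)
        if ratio > min_overlap and m.identity > min_identity:
            graph.add_edge(m.query, m.subject)

    assign: dict[str, str] = {}
    reps: dict[str, str] = {}
    for component in nx.connected_components(graph):
        members = sorted(component)
        rep = max(members, key=lambda t: (lengths[t], _NegStr(t)))
        for t in members:
            assign[t] = rep
        reps[rep] = rep
    return ClusterMap(
        assignments=pd.Series(assign).reindex(catalog.ids),
        representatives=pd.Series(reps),
    )


class _NegStr:
    """Orders strings descending inside a max() key (smallest id wins ties)."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s


# ---- match-table I/O -----------------------------------------------------

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(path: str | Path) -> list[MatchRecord]:
    """Parse BLAST tabular output (outfmt 6); self-hits are dropped.

    ``pident`` (0-100) becomes the identity fraction and the alignment
    length column becomes the overlap in bp.
    """
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    out = []
    for row in df.itertuples(index=False):
        if row.qseqid == row.sseqid:
            continue
        out.append(MatchRecord(str(row.qseqid), str(row.sseqid), int(row.length), row.pident / 100.0))
    return out


def read_match_tsv(path: str | Path) -> list[MatchRecord]:
    """Minimal 4-column match table: query, subject, overlap_bp, identity."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:4]) != ["query", "subject", "overlap_bp", "identity"]:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["query", "subject", "overlap_bp", "identity"],
        )
    return [
        MatchRecord(str(r.query), str(r.subject), int(r.overlap_bp), float(r.identity))
        for r in df.itertuples(index=False)
    ]


def write_match_tsv(matches: Iterable[MatchRecord], path: str | Path) -> None:
    pd.DataFrame(matches, columns=["query", "subject", "overlap_bp", "identity"]).to_csv(
        path, sep="\t", index=False
    )
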