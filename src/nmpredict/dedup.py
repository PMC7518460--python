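"""Splice-variant deduplication over an all-vs-all nucleotide similarity graph.

A de novo transcriptome assembly expresses one locus as several isoforms, so
counting transcripts overestimates gene numbers.  Two candidate transcripts
are treated as potential splice variants of one locus when an all-against-all
BLASTN hit between them has bit-score strictly greater than 100; variant bins
are the connected components of that graph (transitive merging — a shared
middle isoform joins two others even without a direct hit), and each bin is
represented downstream by its member with the longest ORF.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

DEFAULT_BITSCORE_MIN = 100.0


@dataclass(frozen=True)
class VariantBin:
    """One putative locus: a set of splice-variant transcripts and its representative."""

    members: frozenset[str]
    representative: str

    def __post_init__(self) -> None:
        assert self.representative in self.members


def build_variant_graph(
    self_hits: pd.DataFrame,
    candidate_ids: set[str] | list[str],
    bitscore_min: float = DEFAULT_BITSCORE_MIN,
) -> nx.Graph:
    """Graph over candidate ids with an edge per hit pair scoring > bitscore_min.

    Self-hits and hits touching non-candidate ids are ignored; the threshold
    is strict, so a bit-score of exactly ``bitscore_min`` creates no edge.
    """
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(candidate_ids)
    ids = set(candidate_ids)
    strong = self_hits[self_hits["bitscore"] > bitscore_min]
    for q, s in zip(strong["query_id"], strong["subject_id"]):
        if q != s and q in ids and s in ids:
            graph.add_edge(q, s)
    return graph


def bins_from_graph(graph: nx.Graph, orf_lengths: dict[str, int]) -> list[VariantBin]:
    """Connected components as variant bins, longest-ORF member as representative.

    Transcripts without an ORF enter with length 0; ties on ORF length break
    to the lexicographically smallest id.  Bins are returned sorted by their
    smallest member id so output order is deterministic.
    """
    bins = []
    for component in nx.connected_components(graph):
        representative = min(component, key=lambda tid: (-orf_lengths.get(tid, 0), tid))
        bins.append(VariantBin(members=frozenset(component), representative=representative))
    bins.sort(key=lambda b: min(b.members))
    return bins


def bins_frame(bins: list[VariantBin]) -> pd.DataFrame:
    """Long-form table for ``bins.tsv``: one row per member."""
    rows = [
        {
            "bin_id": f"bin{i:05d}",
            "member_id": member,
            "is_representative": member == b.representative,
        }
        for i, b in enumerate(bins)
        for member in sorted(b.members)
    ]
    return pd.DataFrame(rows, columns=["bin_id", "member_id", "is_representative"])
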