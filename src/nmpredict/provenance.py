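"""Green-algal-provenance filtering of protein homology hit tables.

Transcripts of putative green-algal origin are selected from BLASTP-style
tabular hits against a taxonomically broad protein database: hits above an
E-value cutoff (default 1e-10) are discarded, the remainder are ranked per
query, and a query is retained iff at least one of its top 5 ranked hits maps
to Viridiplantae.  Retained queries with any surviving hit (at any rank) to a
plastid-genome-encoded subject are then removed as likely plastid-encoded
proteins rather than nucleomorph/nuclear genes.

The hit tables are standard 12-column tabular output (outfmt 6).  Because
native BLAST hit order varies between versions, ranking here is an explicit,
deterministic key: ascending E-value, then descending bit-score, then
ascending subject id (or bit-score first via ``rank_by="bitscore"``), with one
best hit kept per subject so multiple HSPs of a pair collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import InvalidInputError

BLAST6_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "align_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
]

DEFAULT_EVALUE_CUTOFF = 1e-10
DEFAULT_TOP_N = 5
GREEN_LABEL = "Viridiplantae"


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Read headerless 12-column BLAST tabular output."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != len(BLAST6_COLUMNS):
        raise InvalidInputError(
            f"{path}: expected {len(BLAST6_COLUMNS)} tabular columns, got {df.shape[1]}"
        )
    df.columns = BLAST6_COLUMNS
    df["query_id"] = df["query_id"].astype(str)
    df["subject_id"] = df["subject_id"].astype(str)
    return df


@dataclass
class TaxonMap:
    """subject id -> taxon-group label, plus the set of plastid-encoded subjects.

    Subjects absent from the map resolve to "unknown".
    """

    groups: dict[str, str]
    plastid_subjects: set[str] = field(default_factory=set)

    def taxon_of(self, subject_id: str) -> str:
        return self.groups.get(subject_id, "unknown")

    @classmethod
    def from_files(cls, taxon_tsv: str | Path, plastid_list: str | Path | None = None) -> "TaxonMap":
        df = pd.read_csv(taxon_tsv, sep="\t", header=None, names=["subject_id", "taxon_group"])
        groups = dict(zip(df["subject_id"].astype(str), df["taxon_group"].astype(str)))
        plastid: set[str] = set()
        if plastid_list is not None:
            with open(plastid_list) as fh:
                plastid = {line.strip() for line in fh if line.strip()}
        return cls(groups=groups, plastid_subjects=plastid)


def _rank_key(df: pd.DataFrame, rank_by: str) -> pd.DataFrame:
    if rank_by == "evalue":
        by, ascending = ["evalue", "bitscore", "subject_id"], [True, False, True]
    elif rank_by == "bitscore":
        by, ascending = ["bitscore", "evalue", "subject_id"], [False, True, True]
    else:
        raise InvalidInputError(f"rank_by must be 'evalue' or 'bitscore', got {rank_by!r}")
    return df.sort_values(by=by, ascending=ascending, kind="mergesort")


def rank_hits(
    hits: pd.DataFrame,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    rank_by: str = "evalue",
) -> pd.DataFrame:
    """Filter one query's hits by E-value and order them deterministically.

    One hit is retained per subject (its best under the ranking key).
    """
    queries = hits["query_id"].unique()
    if len(queries) > 1:
        raise InvalidInputError(f"rank_hits expects hits of a single query, got {list(queries)}")
    kept = hits[hits["evalue"] <= evalue_cutoff]
    ranked = _rank_key(kept, rank_by)
    return ranked.drop_duplicates(subset="subject_id", keep="first").reset_index(drop=True)


def rank_all(
    hits: pd.DataFrame,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    rank_by: str = "evalue",
) -> dict[str, pd.DataFrame]:
    """rank_hits applied per query of a full hit table."""
    kept = hits[hits["evalue"] <= evalue_cutoff]
    ranked = _rank_key(kept, rank_by).drop_duplicates(
        subset=["query_id", "subject_id"], keep="first"
    )
    return {q: g.reset_index(drop=True) for q, g in ranked.groupby("query_id", sort=True)}


def select_green_candidates(
    ranked: dict[str, pd.DataFrame],
    taxa: TaxonMap,
    top_n: int = DEFAULT_TOP_N,
) -> set[str]:
    """Queries with >= 1 Viridiplantae subject among their top ``top_n`` ranked hits."""
    candidates: set[str] = set()
    for query, g in ranked.items():
        top = g["subject_id"].head(top_n)
        if any(taxa.taxon_of(s) == GREEN_LABEL for s in top):
            candidates.add(query)
    return candidates


def exclude_plastid(
    candidates: set[str],
    ranked: dict[str, pd.DataFrame],
    taxa: TaxonMap,
) -> tuple[set[str], set[str]]:
    """Split candidates into (retained, removed-as-plastid).

    A candidate is removed if any of its cutoff-surviving hits — at any rank,
    not only the top 5 — has a plastid-encoded subject.
    """
    removed = {
        q
        for q in candidates
        if q in ranked and any(s in taxa.plastid_subjects for s in ranked[q]["subject_id"])
    }
    return candidates - removed, removed
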