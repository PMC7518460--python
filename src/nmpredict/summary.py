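"""Functional summary of the Nm-candidate set from KEGG-orthology maps.

Known nucleomorph genomes are dominated by housekeeping genes (translation,
transcription, splicing) with few metabolic or photosynthesis genes, so the
category breakdown of a candidate set is the headline comparison.  KO
assignment itself is upstream; this module consumes a transcript->KO map and
a KO->category map and counts over Nm-candidates only, alongside the pooled
G+C% of the candidate transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import InvalidInputError
from .mixture import CandidateCall
from .orfs import Transcript, gc_percent_of_set

CATEGORIES = ("housekeeping", "photosynthesis", "splicing", "metabolic_other", "unknown")


@dataclass
class AnnotationMap:
    """transcript -> KO id (partial) and KO -> functional category (total on its KOs)."""

    transcript_ko: dict[str, str]
    ko_category: dict[str, str]

    def category_of(self, transcript_id: str) -> str | None:
        """Category for an annotated transcript, None if it has no KO."""
        ko = self.transcript_ko.get(transcript_id)
        if ko is None:
            return None
        return self.ko_category.get(ko, "unknown")

    @classmethod
    def from_files(cls, ko_map_tsv: str | Path, ko_categories_tsv: str | Path) -> "AnnotationMap":
        ko_map = pd.read_csv(ko_map_tsv, sep="\t", header=None, names=["transcript_id", "ko"])
        cats = pd.read_csv(ko_categories_tsv, sep="\t", header=None, names=["ko", "category"])
        bad = set(cats["category"]) - set(CATEGORIES)
        if bad:
            raise InvalidInputError(f"unknown functional categories {sorted(bad)}")
        return cls(
            transcript_ko=dict(zip(ko_map["transcript_id"].astype(str), ko_map["ko"].astype(str))),
            ko_category=dict(zip(cats["ko"].astype(str), cats["category"].astype(str))),
        )


@dataclass
class SummaryTable:
    n_candidates: int
    n_annotated: int
    n_photosynthesis: int
    n_splicing: int
    n_housekeeping: int
    n_metabolic_other: int
    n_unknown_annotated: int
    housekeeping_fraction: float
    candidate_gc_percent: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("# protein genes", self.n_candidates),
            ("# function annotated protein genes", self.n_annotated),
            ("# photosynthesis-related protein genes", self.n_photosynthesis),
            ("# splicing-related protein genes", self.n_splicing),
            ("# housekeeping protein genes", self.n_housekeeping),
            ("# other metabolic protein genes", self.n_metabolic_other),
            ("housekeeping fraction of annotated", round(self.housekeeping_fraction, 4)),
            ("G + C%", round(self.candidate_gc_percent, 2)),
        ]
        return pd.DataFrame(rows, columns=["feature", "value"])


def summarize(
    calls: list[CandidateCall],
    annotation: AnnotationMap,
    transcripts: dict[str, Transcript],
) -> SummaryTable:
    """Category counts and pooled G+C% over the Nm-candidate calls."""
    candidate_ids = [c.transcript_id for c in calls if c.is_nm_candidate]
    missing = [tid for tid in candidate_ids if tid not in transcripts]
    if missing:
        raise InvalidInputError(f"candidate ids missing from FASTA: {missing[:5]}")
    counts = {cat: 0 for cat in CATEGORIES}
    n_annotated = 0
    for tid in candidate_ids:
        cat = annotation.category_of(tid)
        if cat is None:
            continue
        n_annotated += 1
        counts[cat] += 1
    gc = (
        gc_percent_of_set([transcripts[tid] for tid in candidate_ids])
        if candidate_ids
        else 0.0
    )
    return SummaryTable(
        n_candidates=len(candidate_ids),
        n_annotated=n_annotated,
        n_photosynthesis=counts["photosynthesis"],
        n_splicing=counts["splicing"],
        n_housekeeping=counts["housekeeping"],
        n_metabolic_other=counts["metabolic_other"],
        n_unknown_annotated=counts["unknown"],
        housekeeping_fraction=counts["housekeeping"] / n_annotated if n_annotated else 0.0,
        candidate_gc_percent=gc,
    )
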