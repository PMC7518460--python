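"""Per-transcript TPM computation and the ln-TPM clustering feature.

TPM (transcripts per million) length-normalizes expected read counts so that
the values sum to 1e6 per sample: tpm_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j)
with expected count c and effective length l.  Nucleomorph genomes are
polyploid and highly expressed, so the natural log of TPM carries real
classification signal alongside the GC features.

Transcripts with zero TPM have no defined ln-TPM; they are excluded from
clustering and reported in a side list rather than pseudocounted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .errors import DegenerateInputError, InvalidInputError

TPM_SCALE = 1e6


@dataclass(frozen=True)
class AbundanceRecord:
    transcript_id: str
    expected_count: float
    effective_length: float
    tpm: float | None = None

    def __post_init__(self) -> None:
        if self.effective_length <= 0:
            raise InvalidInputError(
                f"effective_length must be positive for {self.transcript_id!r}"
            )
        if self.expected_count < 0:
            raise InvalidInputError(
                f"expected_count must be non-negative for {self.transcript_id!r}"
            )


def compute_tpm(records: list[AbundanceRecord]) -> list[AbundanceRecord]:
    """Fill the tpm field from counts and effective lengths, order preserved."""
    rates = [r.expected_count / r.effective_length for r in records]
    total = sum(rates)
    if total == 0:
        raise DegenerateInputError("all expected counts are zero; TPM undefined")
    return [replace(r, tpm=TPM_SCALE * rate / total) for r, rate in zip(records, rates)]


def ln_tpm(tpm: float) -> float | None:
    """Natural log of TPM; None for an unexpressed (zero-TPM) transcript."""
    if tpm < 0:
        raise InvalidInputError(f"negative TPM {tpm}")
    if tpm == 0:
        return None
    return math.log(tpm)


# RSEM .isoforms.results uses these exact headers; only the first three below
# are required, TPM is optional pass-through.
_REQUIRED = ("transcript_id", "effective_length", "expected_count")


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated abundance table (RSEM isoforms-results dialect).

    Requires columns transcript_id, effective_length, expected_count; a TPM
    column, if present, is carried through.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise InvalidInputError(f"abundance table {path} missing columns {missing}")
    return df


def abundance_records(df: pd.DataFrame, use_input_tpm: bool = False) -> list[AbundanceRecord]:
    """Convert a table to records, recomputing TPM unless asked to trust the input column."""
    records = [
        AbundanceRecord(
            transcript_id=str(row.transcript_id),
            expected_count=float(row.expected_count),
            effective_length=float(row.effective_length),
            tpm=float(row.TPM) if use_input_tpm and "TPM" in df.columns else None,
        )
        for row in df.itertuples(index=False)
    ]
    if use_input_tpm:
        if "TPM" not in df.columns:
            raise InvalidInputError("use_input_tpm requested but no TPM column present")
        return records
    return compute_tpm(records)


def abundance_frame(records: list[AbundanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "effective_length": [r.effective_length for r in records],
            "expected_count": [r.expected_count for r in records],
            "TPM": [r.tpm for r in records],
        }
    )
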