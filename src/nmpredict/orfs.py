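"""Longest-ORF detection and codon-position G+C composition.

Reduced genomes such as nucleomorphs drift toward low G+C, and the drift is
strongest at the codon positions under the weakest selective constraint.  The
fraction of G or C at the first and third codon positions of an open reading
frame (GC1, GC3) is therefore the core compositional signal used downstream to
separate nucleomorph-derived transcripts from nuclear ones.

An ORF here is a complete coding stretch: an ATG start, an in-frame run of
sense codons, and a terminal stop (TAA/TAG/TGA).  Both strands and all three
frames are scanned, because de novo transcriptome assemblies do not guarantee
sense orientation.  Partial ORFs clipped by contig ends are ignored: without a
stop (or start) the reading frame of the composition counts would be a guess.

Coordinates are 0-based, half-open, on the reported strand (for a minus-strand
ORF, ``start``/``end`` index into the reverse complement of the input).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import InvalidInputError

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_GC = frozenset("GC")
_UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class Transcript:
    """A named nucleotide sequence; uppercased on construction."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InvalidInputError("transcript id must be nonempty")
        if not self.seq:
            raise InvalidInputError(f"transcript {self.id!r} has an empty sequence")
        object.__setattr__(self, "seq", self.seq.upper())


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a (wrapped or unwrapped) multi-record FASTA into Transcripts.

    Raises InvalidInputError on duplicate ids.
    """
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InvalidInputError(f"duplicate transcript id {rec.id!r} in {path}")
        seen.add(rec.id)
        transcripts.append(Transcript(rec.id, str(rec.seq)))
    return transcripts


def write_fasta(transcripts: list[Transcript], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.seq), width):
                fh.write(t.seq[i : i + width] + "\n")


@dataclass(frozen=True)
class OrfRecord:
    """A complete ATG..stop ORF on one strand of a transcript.

    ``length_nt`` includes the stop codon; ``start``/``end`` are 0-based
    half-open offsets on the reported strand.
    """

    transcript_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    length_nt: int

    @property
    def codon_count(self) -> int:
        return self.length_nt // 3

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvalidInputError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != self.length_nt or self.length_nt % 3 or self.length_nt < 6:
            raise InvalidInputError(
                f"inconsistent ORF coordinates for {self.transcript_id!r}"
            )


def _complete_orfs_one_strand(seq: str) -> Iterator[tuple[int, int]]:
    """Yield (start, end) of every maximal complete ORF in all 3 frames.

    Within a frame, an ORF runs from the first ATG after the previous stop to
    the next stop codon; codons containing ambiguous bases are never starts or
    stops but may occur inside the ORF body.
    """
    n = len(seq)
    for frame in range(3):
        open_start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    yield open_start, i + 3
                    open_start = None
            elif open_start is None and codon == START_CODON:
                open_start = i


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def find_longest_orf(t: Transcript) -> OrfRecord | None:
    """Locate the longest complete ORF over all six frames of a transcript.

    Returns None when no ATG..stop ORF of >= 6 nt exists.  Ties on length are
    broken by strand ('+' preferred) and then by smaller start coordinate,
    making the result independent of scan order.
    """
    if not t.seq:
        raise InvalidInputError("empty sequence")
    best: OrfRecord | None = None
    best_key: tuple[int, int, int] | None = None
    for strand, s in (("+", t.seq), ("-", reverse_complement(t.seq))):
        for start, end in _complete_orfs_one_strand(s):
            # maximize length; prefer '+' strand, then smaller start
            key = (end - start, -(strand == "-"), -start)
            if best_key is None or key > best_key:
                best_key = key
                best = OrfRecord(t.id, start, end, strand, end - start)
    return best


def orf_nucleotides(t: Transcript, orf: OrfRecord, include_stop: bool = True) -> str:
    """Extract the in-frame ORF sequence on its reported strand."""
    s = t.seq if orf.strand == "+" else reverse_complement(t.seq)
    end = orf.end if include_stop else orf.end - 3
    return s[orf.start : end]


@dataclass(frozen=True)
class CodonCompositionProfile:
    """Per-codon-position G+C fractions of an in-frame sequence.

    Codons carrying an ambiguous base at position k are excluded from
    position k's denominator; ``gc_overall`` pools all counted positions.
    """

    gc1: float
    gc2: float
    gc3: float
    gc_overall: float
    n_codons_counted: int


def gc_by_codon_position(orf_seq: str) -> CodonCompositionProfile:
    """Count G+C fractions at codon positions 1, 2 and 3 of an in-frame string."""
    if not orf_seq or len(orf_seq) % 3 != 0:
        raise InvalidInputError(
            f"in-frame sequence length must be a positive multiple of 3, got {len(orf_seq)}"
        )
    gc = [0, 0, 0]
    counted = [0, 0, 0]
    for i in range(0, len(orf_seq), 3):
        for k in range(3):
            base = orf_seq[i + k]
            if base in _UNAMBIGUOUS:
                counted[k] += 1
                if base in _GC:
                    gc[k] += 1
    fractions = [g / c if c else 0.0 for g, c in zip(gc, counted)]
    total_counted = sum(counted)
    overall = sum(gc) / total_counted if total_counted else 0.0
    return CodonCompositionProfile(
        gc1=fractions[0],
        gc2=fractions[1],
        gc3=fractions[2],
        gc_overall=overall,
        n_codons_counted=len(orf_seq) // 3,
    )


def gc_percent_of_set(transcripts: list[Transcript]) -> float:
    """Pooled G+C percentage over all bases of a transcript set.

    This is the single-pass global count (not a per-transcript mean), with
    ambiguous bases excluded from both numerator and denominator — the
    convention used for reporting the G+C% of a candidate gene set.
    """
    if not transcripts:
        raise InvalidInputError("gc_percent_of_set requires a nonempty transcript list")
    gc = 0
    total = 0
    for t in transcripts:
        for base in t.seq:
            if base in _UNAMBIGUOUS:
                total += 1
                if base in _GC:
                    gc += 1
    if total == 0:
        raise InvalidInputError("no unambiguous bases in transcript set")
    return 100.0 * gc / total


def orf_table(
    transcripts: list[Transcript], count_stop_codon: bool = False
) -> "list[dict]":
    """Per-transcript ORF coordinates and composition rows for ``orfs.tsv``.

    Transcripts without a complete ORF are omitted.  By default the stop codon
    contributes to ``length_nt`` but not to the GC counts (stop codons are
    constrained to an A/T-rich triplet set and would bias composition).
    """
    rows = []
    for t in transcripts:
        orf = find_longest_orf(t)
        if orf is None:
            continue
        prof = gc_by_codon_position(orf_nucleotides(t, orf, include_stop=count_stop_codon))
        rows.append(
            {
                "transcript_id": t.id,
                "start": orf.start,
                "end": orf.end,
                "strand": orf.strand,
                "length_nt": orf.length_nt,
                "gc1": prof.gc1,
                "gc2": prof.gc2,
                "gc3": prof.gc3,
                "gc_overall": prof.gc_overall,
            }
        )
    return rows
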