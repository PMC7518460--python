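"""Truth-labelled synthetic inputs for the nucleomorph-prediction pipeline.

The generator emulates the statistical structure the analysis assumes: two
transcript populations whose ORFs differ in G+C at codon positions 1 and 3
(a low-GC "nucleomorph" population and a higher-GC "nuclear" one), log-normal
expression with the low-GC population expressed higher, plus non-green decoy
transcripts, splice-variant duplicates, and mock homology tables — a
provenance table in which green transcripts carry a Viridiplantae subject in
their top hits, some decoys carry plastid-encoded subjects, and others carry
a Viridiplantae hit only at rank 6; and an all-vs-all self-hit table linking
each variant pair with a strong bit-score and one unrelated pair at exactly
the binning threshold.

Every emitted transcript is a complete ORF (ATG, sense codons, terminal
stop), so the pipeline's own ORF finder recovers it exactly.  All output is
a deterministic function of the seed: identical seeds give byte-identical
files.  It does not emulate UTRs, sequencing error, codon-usage tables or
read-level data.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .orfs import START_CODON, STOP_CODONS, Transcript, write_fasta

_STOPS = sorted(STOP_CODONS)
_MAX_CODON_REDRAWS = 200

TAXON_GROUPS = ("Stramenopila", "Alveolata", "Opisthokonta", "Rhodophyta", "Bacteria", "Archaea")
GREEN_LABEL = "Viridiplantae"


@dataclass
class SimulationConfig:
    """Population sizes and feature-model parameters of the synthetic study.

    Defaults give a between-population Mahalanobis separation of roughly 7 in
    standardized feature space, i.e. clearly bimodal GC3 histograms.
    """

    seed: int = 7
    n_nucleomorph: int = 150
    n_nuclear: int = 350
    n_decoy_nongreen: int = 100
    gc3_low_mean: float = 0.25
    gc3_low_sd: float = 0.05
    gc3_high_mean: float = 0.55
    gc3_high_sd: float = 0.05
    gc1_low_mean: float = 0.35
    gc1_low_sd: float = 0.05
    gc1_high_mean: float = 0.55
    gc1_high_sd: float = 0.05
    ln_tpm_low_pop_mean: float = 4.0
    ln_tpm_low_pop_sd: float = 1.0
    ln_tpm_high_pop_mean: float = 2.0
    ln_tpm_high_pop_sd: float = 1.0
    orf_codon_count_range: tuple[int, int] = (60, 300)
    variant_duplication_rate: float = 0.1
    plastid_decoy_rate: float = 0.1

    def __post_init__(self) -> None:
        if min(self.n_nucleomorph, self.n_nuclear, self.n_decoy_nongreen) < 0:
            raise ConfigError("population sizes must be non-negative")
        for name in ("gc3_low", "gc3_high", "gc1_low", "gc1_high"):
            mean = getattr(self, f"{name}_mean")
            sd = getattr(self, f"{name}_sd")
            if not 0.0 < mean < 1.0:
                raise ConfigError(f"{name}_mean must lie in (0, 1), got {mean}")
            if sd <= 0:
                raise ConfigError(f"{name}_sd must be positive, got {sd}")
        if self.ln_tpm_low_pop_sd <= 0 or self.ln_tpm_high_pop_sd <= 0:
            raise ConfigError("expression sds must be positive")
        lo, hi = self.orf_codon_count_range
        if not 10 <= lo <= hi:
            raise ConfigError(f"bad orf_codon_count_range {self.orf_codon_count_range}")
        for name in ("variant_duplication_rate", "plastid_decoy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")


def _draw_base(rng: np.random.Generator, p_gc: float) -> str:
    if rng.random() < p_gc:
        return "G" if rng.random() < 0.5 else "C"
    return "A" if rng.random() < 0.5 else "T"


def simulate_transcript(
    target_gc1: float,
    target_gc3: float,
    codon_count: int,
    rng: np.random.Generator,
    transcript_id: str = "sim",
) -> Transcript:
    """A complete-ORF transcript with per-codon GC1/GC3 at the target rates.

    The first codon is ATG and the last a stop; internal codons draw their
    first and third bases G/C with the target probabilities (second base
    uniform) and are redrawn whenever they would form an in-frame stop.
    """
    if not 0.0 <= target_gc1 <= 1.0 or not 0.0 <= target_gc3 <= 1.0:
        raise ConfigError(f"GC targets must lie in [0, 1], got {target_gc1}, {target_gc3}")
    if codon_count < 2:
        raise ConfigError(f"codon_count must be >= 2, got {codon_count}")
    codons = [START_CODON]
    for _ in range(codon_count - 2):
        first = _draw_base(rng, target_gc1)
        third = _draw_base(rng, target_gc3)
        # Stop codons are avoided by redrawing the (uniform) middle base only,
        # so the realized GC1/GC3 marginals stay unbiased at their targets.
        for _attempt in range(_MAX_CODON_REDRAWS):
            codon = first + "ACGT"[rng.integers(4)] + third
            if codon not in STOP_CODONS:
                break
        else:
            raise ConfigError("GC targets conflict with stop-codon avoidance")
        codons.append(codon)
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return Transcript(transcript_id, "".join(codons))


@dataclass
class SimulatedBundle:
    """Paths to the emitted files plus the in-memory truth table."""

    outdir: Path
    fasta: Path
    abundance: Path
    provenance_hits: Path
    taxon_map: Path
    plastid_subjects: Path
    self_hits: Path
    ko_map: Path
    ko_categories: Path
    truth: Path
    truth_table: pd.DataFrame


def _blast_row(
    rng: np.random.Generator, query: str, subject: str, evalue: float, bitscore: float
) -> list:
    length = int(rng.integers(80, 400))
    pident = round(float(rng.uniform(35, 95)), 2)
    mism = int(round(length * (100 - pident) / 100))
    return [
        query,
        subject,
        pident,
        length,
        mism,
        int(rng.integers(0, 5)),
        1,
        length,
        1,
        length,
        evalue,
        bitscore,
    ]


def _loglinear_evalue(rng: np.random.Generator, lo_exp: float, hi_exp: float) -> float:
    return float(10.0 ** -rng.uniform(lo_exp, hi_exp))


def simulate_dataset(cfg: SimulationConfig, outdir: str | Path) -> SimulatedBundle:
    """Emit the full input bundle for one synthetic study into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    # --- subject pools and taxon map -------------------------------------
    green_subjects = [f"VIR_{j:03d}" for j in range(50)]
    other_subjects = {g: [f"{g[:3].upper()}_{j:03d}" for j in range(30)] for g in TAXON_GROUPS}
    plastid_subjects = [f"PMPLAST_{j:02d}" for j in range(20)]
    taxon_rows = [(s, GREEN_LABEL) for s in green_subjects]
    for g, subs in other_subjects.items():
        taxon_rows += [(s, g) for s in subs]
    # plastid-genome proteins are themselves green algal
    taxon_rows += [(s, GREEN_LABEL) for s in plastid_subjects]

    def rand_other_subject() -> str:
        g = TAXON_GROUPS[rng.integers(len(TAXON_GROUPS))]
        pool = other_subjects[g]
        return pool[rng.integers(len(pool))]

    # --- transcripts ------------------------------------------------------
    lo, hi = cfg.orf_codon_count_range
    populations = (
        ("nucleomorph", "NM", cfg.n_nucleomorph, cfg.gc1_low_mean, cfg.gc1_low_sd,
         cfg.gc3_low_mean, cfg.gc3_low_sd, cfg.ln_tpm_low_pop_mean, cfg.ln_tpm_low_pop_sd),
        ("nuclear", "NU", cfg.n_nuclear, cfg.gc1_high_mean, cfg.gc1_high_sd,
         cfg.gc3_high_mean, cfg.gc3_high_sd, cfg.ln_tpm_high_pop_mean, cfg.ln_tpm_high_pop_sd),
        ("decoy", "DC", cfg.n_decoy_nongreen, cfg.gc1_high_mean, cfg.gc1_high_sd,
         cfg.gc3_high_mean, cfg.gc3_high_sd, cfg.ln_tpm_high_pop_mean, cfg.ln_tpm_high_pop_sd),
    )
    transcripts: list[Transcript] = []
    truth_rows: list[dict] = []
    ln_expr: dict[str, float] = {}
    for label, prefix, n, g1m, g1s, g3m, g3s, em, es in populations:
        for i in range(n):
            tid = f"{prefix}{i:04d}"
            t1 = float(np.clip(rng.normal(g1m, g1s), 0.02, 0.98))
            t3 = float(np.clip(rng.normal(g3m, g3s), 0.02, 0.98))
            cc = int(rng.integers(lo, hi + 1))
            transcripts.append(simulate_transcript(t1, t3, cc, rng, tid))
            truth_rows.append({"transcript_id": tid, "population": label, "locus_id": tid})
            ln_expr[tid] = float(rng.normal(em, es))

    # --- splice-variant duplicates ---------------------------------------
    by_id = {t.id: t for t in transcripts}
    green_originals = [r["transcript_id"] for r in truth_rows if r["population"] != "decoy"]
    variant_pairs: list[tuple[str, str]] = []
    for tid in green_originals:
        if rng.random() >= cfg.variant_duplication_rate:
            continue
        parent = by_id[tid]
        cc = len(parent.seq) // 3
        drop = int(rng.integers(5, 21))  # codons removed from the ORF tail
        dup_seq = parent.seq[: 3 * (cc - 1 - drop)] + parent.seq[-3:]
        dup_id = f"{tid}v"
        transcripts.append(Transcript(dup_id, dup_seq))
        label = next(r["population"] for r in truth_rows if r["transcript_id"] == tid)
        truth_rows.append({"transcript_id": dup_id, "population": label, "locus_id": tid})
        ln_expr[dup_id] = float(rng.normal(ln_expr[tid] - 1.0, 0.3))
        variant_pairs.append((tid, dup_id))

    # --- abundances (RSEM-like expected counts) ---------------------------
    ids = [t.id for t in transcripts]
    lengths = {t.id: len(t.seq) for t in transcripts}
    eff_len = {tid: max(lengths[tid] - 150, 25) for tid in ids}
    rel = np.array([np.exp(ln_expr[tid]) for tid in ids])
    raw_counts = rel * np.array([eff_len[tid] for tid in ids])
    counts = raw_counts * (2e6 / raw_counts.sum())
    # a couple of unexpressed decoys exercise the zero-TPM reporting path
    zero_ids = {tid for tid in ids if tid.startswith("DC")}
    zero_ids = set(sorted(zero_ids)[:2])
    abundance = pd.DataFrame(
        {
            "transcript_id": ids,
            "length": [lengths[tid] for tid in ids],
            "effective_length": [float(eff_len[tid]) for tid in ids],
            "expected_count": [
                0.0 if tid in zero_ids else round(float(c), 2) for tid, c in zip(ids, counts)
            ],
        }
    )

    # --- provenance hit table ---------------------------------------------
    decoy_ids = sorted(tid for tid in ids if tid.startswith("DC"))
    n_plastid_decoys = int(round(cfg.plastid_decoy_rate * len(decoy_ids)))
    plastid_decoys = set(decoy_ids[:n_plastid_decoys])
    hit_rows: list[list] = []
    for tid in ids:
        if tid.startswith(("NM", "NU")):
            # one strong Viridiplantae hit + 4 weaker non-green: green rule met
            green = green_subjects[rng.integers(len(green_subjects))]
            hit_rows.append(
                _blast_row(rng, tid, green, _loglinear_evalue(rng, 30, 60), float(rng.uniform(200, 600)))
            )
            for _ in range(4):
                hit_rows.append(
                    _blast_row(rng, tid, rand_other_subject(),
                               _loglinear_evalue(rng, 11, 30), float(rng.uniform(60, 200)))
                )
        elif tid in plastid_decoys:
            # looks green at rank 1 but also hits a plastid-encoded protein
            green = green_subjects[rng.integers(len(green_subjects))]
            plastid = plastid_subjects[rng.integers(len(plastid_subjects))]
            hit_rows.append(
                _blast_row(rng, tid, green, _loglinear_evalue(rng, 30, 60), float(rng.uniform(200, 600)))
            )
            hit_rows.append(
                _blast_row(rng, tid, plastid, _loglinear_evalue(rng, 15, 40), float(rng.uniform(100, 400)))
            )
        else:
            # non-green decoy; half carry a Viridiplantae hit only at rank 6
            for _ in range(5):
                hit_rows.append(
                    _blast_row(rng, tid, rand_other_subject(),
                               _loglinear_evalue(rng, 20, 40), float(rng.uniform(80, 300)))
                )
            if rng.random() < 0.5:
                green = green_subjects[rng.integers(len(green_subjects))]
                hit_rows.append(
                    _blast_row(rng, tid, green, _loglinear_evalue(rng, 11, 14), float(rng.uniform(50, 80)))
                )
        # above-cutoff noise hit, removed by the E-value filter
        hit_rows.append(
            _blast_row(rng, tid, rand_other_subject(),
                       _loglinear_evalue(rng, 2, 9), float(rng.uniform(20, 50)))
        )

    # --- all-vs-all nucleotide self-hits ----------------------------------
    self_rows: list[list] = []
    for tid in ids:
        self_rows.append(_blast_row(rng, tid, tid, 0.0, float(2 * lengths[tid])))
    for a, b in variant_pairs:
        score = round(float(rng.uniform(150, 400)), 1)
        self_rows.append(_blast_row(rng, a, b, _loglinear_evalue(rng, 50, 100), score))
        self_rows.append(_blast_row(rng, b, a, _loglinear_evalue(rng, 50, 100), score))
    # one unrelated pair at exactly the binning threshold: must create no edge
    nuclear_ids = sorted(tid for tid in ids if tid.startswith("NU"))
    if len(nuclear_ids) >= 2:
        self_rows.append(_blast_row(rng, nuclear_ids[0], nuclear_ids[1], 1e-20, 100.0))

    # --- KO annotation maps ------------------------------------------------
    category_probs = {
        "nucleomorph": (("housekeeping", 0.60), ("splicing", 0.17), ("photosynthesis", 0.09),
                        ("metabolic_other", 0.11), ("unknown", 0.03)),
        "nuclear": (("housekeeping", 0.30), ("splicing", 0.10), ("photosynthesis", 0.20),
                    ("metabolic_other", 0.35), ("unknown", 0.05)),
    }
    annotated_prob = {"nucleomorph": 0.92, "nuclear": 0.80}
    ko_rows: list[tuple[str, str]] = []
    cat_rows: list[tuple[str, str]] = []
    ko_counter = 0
    for row in truth_rows:
        pop = row["population"]
        if pop == "decoy" or row["locus_id"] != row["transcript_id"]:
            continue
        if rng.random() >= annotated_prob[pop]:
            continue
        names, probs = zip(*category_probs[pop])
        cat = names[rng.choice(len(names), p=probs)]
        ko = f"K{ko_counter:05d}"
        ko_counter += 1
        ko_rows.append((row["transcript_id"], ko))
        cat_rows.append((ko, cat))

    # --- write everything ---------------------------------------------------
    truth_table = pd.DataFrame(truth_rows)
    paths = SimulatedBundle(
        outdir=outdir,
        fasta=outdir / "transcripts.fasta",
        abundance=outdir / "abundance.tsv",
        provenance_hits=outdir / "provenance_hits.tsv",
        taxon_map=outdir / "taxon_map.tsv",
        plastid_subjects=outdir / "plastid_subjects.txt",
        self_hits=outdir / "self_hits.tsv",
        ko_map=outdir / "ko_map.tsv",
        ko_categories=outdir / "ko_categories.tsv",
        truth=outdir / "truth.tsv",
        truth_table=truth_table,
    )
    write_fasta(transcripts, paths.fasta)
    abundance.to_csv(paths.abundance, sep="\t", index=False)
    pd.DataFrame(hit_rows).to_csv(paths.provenance_hits, sep="\t", index=False, header=False)
    pd.DataFrame(taxon_rows).to_csv(paths.taxon_map, sep="\t", index=False, header=False)
    paths.plastid_subjects.write_text("".join(s + "\n" for s in plastid_subjects))
    pd.DataFrame(self_rows).to_csv(paths.self_hits, sep="\t", index=False, header=False)
    pd.DataFrame(ko_rows).to_csv(paths.ko_map, sep="\t", index=False, header=False)
    pd.DataFrame(cat_rows).to_csv(paths.ko_categories, sep="\t", index=False, header=False)
    truth_table.to_csv(paths.truth, sep="\t", index=False)
    return paths


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["orf_codon_count_range"] = list(cfg.orf_codon_count_range)
    return d
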