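"""End-to-end orchestration: simulate -> features -> expression -> provenance
-> dedup -> cluster -> summarize, with a JSON run manifest.

The manifest records the configuration snapshot, the seed, SHA-256 digests of
every input, and the record-count funnel
(n transcripts -> n with ORFs -> n green candidates -> n after plastid
exclusion -> n representatives -> n clustered -> n Nm-candidates), which is
non-increasing along the filter chain.  Re-running with the same inputs and
seed reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import dedup, expression, mixture, orfs, provenance, summary
from .errors import ConfigError
from .simulate import SimulationConfig, config_to_dict, simulate_dataset

logger = logging.getLogger("nmpredict")
if not logger.handlers:  # stage-tagged lines to stderr
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("[nmpredict:%(stage)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults are the study's values: E-value cutoff 1e-10,
    Viridiplantae among the top 5 ranked hits, variant edges at bit-score
    strictly > 100, Nm-candidates at posterior strictly > 0.95.
    """

    fasta: str = ""
    abundance: str = ""
    provenance_hits: str = ""
    taxon_map: str = ""
    plastid_subjects: str = ""
    self_hits: str = ""
    ko_map: str = ""
    ko_categories: str = ""

    evalue_cutoff: float = provenance.DEFAULT_EVALUE_CUTOFF
    top_n: int = provenance.DEFAULT_TOP_N
    rank_by: str = "evalue"
    bitscore_min: float = dedup.DEFAULT_BITSCORE_MIN
    posterior_threshold: float = mixture.DEFAULT_POSTERIOR_THRESHOLD
    seed: int = 0
    n_init: int = 10
    tol: float = 1e-6
    max_iter: int = 500
    reg: float = 1e-6
    count_stop_codon: bool = False
    use_input_tpm: bool = False

    simulate: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", None)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        if sim_raw is not None:
            if "orf_codon_count_range" in sim_raw:
                sim_raw["orf_codon_count_range"] = tuple(sim_raw["orf_codon_count_range"])
            cfg.simulation = SimulationConfig(**sim_raw)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = config_to_dict(self.simulation)
        return d


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: dict[str, str]
    counts: dict[str, int]
    outputs: dict[str, str]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_all(cfg: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute every stage and write all stage outputs plus ``manifest.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.simulate:
        _log("simulate", f"emitting synthetic bundle (seed={cfg.simulation.seed})")
        bundle = simulate_dataset(cfg.simulation, outdir / "inputs")
        cfg.fasta = str(bundle.fasta)
        cfg.abundance = str(bundle.abundance)
        cfg.provenance_hits = str(bundle.provenance_hits)
        cfg.taxon_map = str(bundle.taxon_map)
        cfg.plastid_subjects = str(bundle.plastid_subjects)
        cfg.self_hits = str(bundle.self_hits)
        cfg.ko_map = str(bundle.ko_map)
        cfg.ko_categories = str(bundle.ko_categories)

    inputs = {
        "fasta": cfg.fasta,
        "abundance": cfg.abundance,
        "provenance_hits": cfg.provenance_hits,
        "taxon_map": cfg.taxon_map,
        "plastid_subjects": cfg.plastid_subjects,
        "self_hits": cfg.self_hits,
    }
    for name in ("ko_map", "ko_categories"):
        if getattr(cfg, name):
            inputs[name] = getattr(cfg, name)
    digests = {name: _sha256(path) for name, path in inputs.items()}

    # --- sequence features -------------------------------------------------
    transcripts = orfs.read_fasta(cfg.fasta)
    by_id = {t.id: t for t in transcripts}
    orf_rows = orfs.orf_table(transcripts, count_stop_codon=cfg.count_stop_codon)
    orf_df = pd.DataFrame(
        orf_rows,
        columns=["transcript_id", "start", "end", "strand", "length_nt",
                 "gc1", "gc2", "gc3", "gc_overall"],
    )
    _write_tsv(orf_df, outdir / "orfs.tsv")
    orf_lengths = dict(zip(orf_df["transcript_id"], orf_df["length_nt"].astype(int)))
    _log("features", f"{len(transcripts)} transcripts, {len(orf_df)} with complete ORFs")

    # --- expression --------------------------------------------------------
    abundance_df = expression.read_abundance(cfg.abundance)
    records = expression.abundance_records(abundance_df, use_input_tpm=cfg.use_input_tpm)
    tpm = {r.transcript_id: r.tpm for r in records}
    _write_tsv(expression.abundance_frame(records), outdir / "abundance.tsv")
    _log("tpm", f"{len(records)} abundance records")

    # --- provenance filtering ---------------------------------------------
    hits = provenance.read_blast_tab(cfg.provenance_hits)
    taxa = provenance.TaxonMap.from_files(cfg.taxon_map, cfg.plastid_subjects)
    ranked = provenance.rank_all(hits, cfg.evalue_cutoff, cfg.rank_by)
    green = provenance.select_green_candidates(ranked, taxa, cfg.top_n)
    retained, removed = provenance.exclude_plastid(green, ranked, taxa)
    (outdir / "green_candidates.txt").write_text("".join(s + "\n" for s in sorted(retained)))
    (outdir / "excluded_plastid.txt").write_text("".join(s + "\n" for s in sorted(removed)))
    _log("provenance", f"{len(green)} green candidates, {len(removed)} removed as plastid")

    # --- splice-variant dedup ---------------------------------------------
    self_hits = provenance.read_blast_tab(cfg.self_hits)
    graph = dedup.build_variant_graph(self_hits, retained, cfg.bitscore_min)
    bins = dedup.bins_from_graph(graph, orf_lengths)
    _write_tsv(dedup.bins_frame(bins), outdir / "bins.tsv")
    representatives = sorted(b.representative for b in bins)
    _log("dedup", f"{len(bins)} variant bins")

    # --- clustering --------------------------------------------------------
    orf_by_id = {row["transcript_id"]: row for row in orf_rows}
    features: list[mixture.FeatureVector] = []
    unexpressed: list[str] = []
    for tid in representatives:
        if tid not in orf_by_id:
            continue  # no complete ORF: no codon-position features
        t_tpm = tpm.get(tid)
        if t_tpm is None:
            continue
        ln = expression.ln_tpm(t_tpm)
        if ln is None:
            unexpressed.append(tid)
            continue
        row = orf_by_id[tid]
        features.append(mixture.FeatureVector(tid, row["gc1"], row["gc3"], ln))
    (outdir / "unexpressed.tsv").write_text(
        "transcript_id\n" + "".join(s + "\n" for s in unexpressed)
    )
    X = mixture.feature_matrix(features)
    Xs, std = mixture.standardize(X)
    model = mixture.em_fit(
        Xs, seed=cfg.seed, n_init=cfg.n_init, tol=cfg.tol,
        max_iter=cfg.max_iter, reg=cfg.reg,
    )
    model.save(outdir / "model.json", std)
    post = mixture.posterior(model, Xs)
    low_idx = mixture.identify_low_gc_component(model, std)
    calls = mixture.call_nm_candidates(
        post, low_idx, [f.transcript_id for f in features], cfg.posterior_threshold
    )
    calls_df = pd.DataFrame(
        {
            "transcript_id": [f.transcript_id for f in features],
            "gc1": [f.gc1 for f in features],
            "gc3": [f.gc3 for f in features],
            "ln_tpm": [f.ln_tpm for f in features],
            "posterior_low_gc": [c.posterior_low_gc for c in calls],
            "is_nm_candidate": [c.is_nm_candidate for c in calls],
        }
    )
    _write_tsv(calls_df, outdir / "calls.tsv")
    n_candidates = int(calls_df["is_nm_candidate"].sum())
    _log("cluster", f"{len(features)} clustered, {n_candidates} Nm-candidates "
                    f"(log-likelihood {model.log_likelihood:.2f}, {model.n_iter} EM iterations)")

    # --- summary ------------------------------------------------------------
    if cfg.ko_map and cfg.ko_categories:
        annotation = summary.AnnotationMap.from_files(cfg.ko_map, cfg.ko_categories)
        table = summary.summarize(calls, annotation, by_id)
        _write_tsv(table.to_frame(), outdir / "summary.tsv")
        _log("summarize", f"{table.n_annotated}/{table.n_candidates} candidates KO-annotated, "
                          f"G+C% {table.candidate_gc_percent:.2f}")

    counts = {
        "n_transcripts": len(transcripts),
        "n_with_orf": len(orf_df),
        "n_green_candidates": len(green),
        "n_after_plastid_exclusion": len(retained),
        "n_representatives": len(representatives),
        "n_clustered": len(features),
        "n_nm_candidates": n_candidates,
    }
    outputs = {
        p.name: str(p)
        for p in sorted(outdir.glob("*.tsv")) + [outdir / "model.json"]
        + sorted(outdir.glob("*.txt"))
    }
    manifest = RunManifest(
        config=cfg.to_dict(),
        seed=cfg.seed,
        input_digests=digests,
        counts=counts,
        outputs=outputs,
    )
    manifest.save(outdir / "manifest.json")
    return manifest


def evaluate_calls(calls_tsv: str | Path, truth_tsv: str | Path) -> dict[str, float]:
    """Precision/recall of Nm-candidate calls against simulation truth.

    Predictions are at the representative (locus) level; recall is measured
    over nucleomorph loci, precision over called representatives.
    """
    calls = pd.read_csv(calls_tsv, sep="\t")
    truth = pd.read_csv(truth_tsv, sep="\t")
    label = dict(zip(truth["transcript_id"], truth["population"]))
    loci = truth[truth["population"] == "nucleomorph"]["locus_id"].unique()
    called = set(calls[calls["is_nm_candidate"]]["transcript_id"])
    called_loci = {
        lid
        for lid in truth[truth["transcript_id"].isin(called)]["locus_id"]
    }
    tp = sum(1 for tid in called if label.get(tid) == "nucleomorph")
    precision = tp / len(called) if called else 0.0
    recall = sum(1 for lid in loci if lid in called_loci) / len(loci) if len(loci) else 0.0
    return {"precision": precision, "recall": recall,
            "n_called": len(called), "n_true_loci": int(len(loci))}
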