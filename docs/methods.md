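# Methods

## Problem and model

Nucleomorph genomes — relic endosymbiont nuclei — share two strong signatures:
elevated A+T content, most pronounced at the weakly constrained codon
positions, and high transcript abundance relative to nuclear homologs.  Given
a transcriptome assembly that mixes nuclear and nucleomorph transcripts, the
package models each green-algal-origin transcript as a draw from a
two-component multivariate Gaussian mixture over the features

    x = (GC1, GC3, ln TPM)

with a covariance matrix shared by both components (tied).  The tied
constraint reflects the assumption that within-population dispersion is driven
by shared biology (gene length, codon position coupling, expression noise)
rather than by population identity, and it halves the covariance parameters,
which matters at a few hundred points.  The component with the lower mean GC3
(after undoing the z-scoring) is interpreted as the nucleomorph population;
GC3 is used as the discriminating coordinate because the third codon position
is the least constrained by protein sequence and therefore tracks genome-wide
compositional pressure most closely, with mean GC1 as the tie-break.
Transcripts whose posterior probability for that component strictly exceeds
0.95 are called Nm-candidates; the strict inequality also fixes the behavior
at the boundary value itself.

## Upstream decision rules

The classification operates on a filtered, deduplicated transcript set:

- **E-value cutoff 10⁻¹⁰** on protein homology hits, applied before anything
  else; hits are ranked by ascending E-value, ties by descending bit-score,
  then by subject id.  BLAST's native output order is version-dependent, so
  the ranking key is explicit and configurable (`rank_by: evalue|bitscore`).
  Multiple HSPs of a query/subject pair collapse to the best one.
- **Top-5 Viridiplantae rule**: a query is of putative green-algal origin iff
  one of its first five ranked hits maps to Viridiplantae.  Rank 6 does not
  count.
- **Plastid exclusion** removes any candidate with a surviving hit — at any
  rank, not just the top 5 — to a plastid-genome-encoded subject; the rule is
  deliberately unconditional because a plastid hit anywhere indicates the
  transcript is probably plastid-derived regardless of what outranks it.
- **Variant bins** are connected components of the graph whose edges are
  all-vs-all nucleotide hits with bit-score strictly greater than 100.
  Components rather than pairwise cliques: "bins of variants from one locus"
  describes a partition, and two isoforms that both align to a third should
  merge even when they do not align to each other.  The longest-ORF member
  represents the bin, ties broken by smallest id.

## ORFs and composition

An ORF must be complete — ATG start, no internal in-frame stop, terminal
TAA/TAG/TGA — and both strands are scanned, because de novo assemblies do not
guarantee sense orientation.  Partial ORFs at contig ends are ignored: codon
positions are undefined without an anchored frame.  Coordinates are 0-based
half-open on the reported strand.  The stop codon counts toward ORF length but
is excluded from GC1/GC2/GC3 by default (`count_stop_codon: false`): stop
codons are drawn from a fixed A/T-rich triplet set and would bias composition,
most visibly in short ORFs.  Codons with an ambiguous base at position k are
excluded from position k's denominator only.  The candidate-set G+C% reported
in the summary is the pooled base count over whole candidate transcripts (not
a per-transcript mean, not ORF-restricted).

TPM is recomputed from expected counts and effective lengths
(tpmᵢ = 10⁶·(cᵢ/ℓᵢ)/Σⱼ(cⱼ/ℓⱼ)); an input TPM column can be trusted instead
(`use_input_tpm`), and both paths agree on RSEM-consistent tables.
Zero-TPM transcripts have no ln TPM; they are excluded from clustering and
listed in `unexpressed.tsv` rather than pseudocounted, so the exclusion is
visible instead of silently distorting the expression axis.

## EM: numerics and initialization

Standardization uses the population (÷n) standard deviation; the choice is
arbitrary at these sample sizes but is fixed so that results are bit-stable.
A constant feature column is an error naming the feature, not a silent NaN.

The E-step works entirely in log space (Gaussian log-densities via a Cholesky
factor of the tied covariance; responsibilities normalized with log-sum-exp),
so extreme separations cannot underflow.  The M-step covariance is the
responsibility-weighted pooled scatter divided by n, plus a ridge
`reg·I = 10⁻⁶·I` guaranteeing positive-definiteness.  Convergence is declared
when the mean per-point log-likelihood improves by less than `tol = 10⁻⁶`;
`max_iter = 500` is a safety net rarely approached.

Each of the `n_init = 10` restarts initializes component means at k distinct
data points drawn by the seeded generator, with uniform weights and the pooled
sample covariance; the restart with the best final log-likelihood wins.
Per-point random responsibilities were considered and rejected: averaging
i.i.d. random responsibilities over n points puts both component means within
O(1/√n) of the pooled mean, which is the mixture's symmetric saddle point,
and near the saddle the per-iteration likelihood gain is already below any
usable tolerance, so EM "converges" without ever separating the components.
Random-point means break the symmetry at initialization.  The seed is a
required, logged parameter (it lands in `model.json` and the run manifest).

Two exact identities are used as tests rather than tolerances: EM's
log-likelihood sequence is non-decreasing, and after any M-step the mixture's
total covariance (tied matrix plus between-component scatter) equals the
sample covariance of the data, even when the data contain no real cluster
structure.

## Synthetic studies

`simulate` emits a complete input bundle: FASTA transcripts, an RSEM-like
abundance table, a provenance hit table with a taxon map and plastid subject
list, an all-vs-all self-hit table, KO annotation maps, and truth labels.
Defaults define the study conditions used throughout the tests and the
acceptance script:

| parameter | low-GC (nucleomorph) | high-GC (nuclear) |
|---|---|---|
| GC3 target | 0.25 ± 0.05 | 0.55 ± 0.05 |
| GC1 target | 0.35 ± 0.05 | 0.55 ± 0.05 |
| ln-expression | 4.0 ± 1.0 | 2.0 ± 1.0 |

with 150 nucleomorph, 350 nuclear and 100 decoy transcripts, ORFs of 60–300
codons, a 10% splice-variant duplication rate and a 10% plastid-decoy rate.
The per-axis standardized gaps (≈6σ on GC3, 4σ on GC1, 2σ on expression)
combine to a Mahalanobis separation near 7 — clearly bimodal GC3 histograms,
the regime the method is designed for.  The true generative parameters of any
real organism are unknown and not claimed; the GC3 values bracket what reduced
AT-rich genomes versus GC-balanced nuclear genomes typically show.

Sequences are built codon by codon: ATG, then internal codons whose first and
third bases are G/C with the target probabilities (second base uniform), then
a random stop.  A codon that would form an in-frame stop has its middle base
redrawn; redrawing the whole codon would push realized GC3 up by ~0.02 at
low-GC targets (stops are T·A/T·G patterns), whereas the middle-base redraw
leaves the GC1/GC3 marginals exactly at target.  The fixed start codon still
adds (1−target)/n_codons to whole-ORF GC3, which is visible only in very short
ORFs.  Splice variants are re-emissions of a parent with a tail-truncated ORF
and a strong (>100) self-hit; decoys get non-green top-5 hits, half of them
with a Viridiplantae hit exactly at rank 6, and a fraction get a plastid
subject hit so that both filter rules fire on realistic inputs.  Everything
derives from one seeded generator, so identical seeds give byte-identical
files.

What the generator does **not** emulate — UTRs and intergenic sequence, codon
usage structure beyond positional GC, sequencing error, incomplete ORFs,
overlapping mixed-provenance populations, and hit tables with alignment-level
realism — bounds what the tests show: passing them demonstrates the estimator
and the decision rules are implemented correctly and recover truth under the
assumed model, not that the model is adequate for any particular organism.
Real assemblies with weak GC separation will produce overlapping components
and posterior mass spread across them; the 0.95 threshold then trades recall
for precision, and the scatter/histogram export (`calls.tsv`) exists precisely
so that separation can be inspected.

## Problem sizes

Tests and the acceptance script run the full pipeline on the 654-transcript
default bundle and the EM recovery experiment on twenty 2,000-point datasets;
the simulator convergence check uses 5,000 transcripts with short ORFs.  These
sizes put standard errors well below the asserted tolerances while keeping the
whole suite fast.

## Known limitations

- Only the standard genetic code; no partial-ORF rescue at contig ends.
- The low-GC component is identified by mean GC3; a genome whose reduction did
  not shift GC3 (none is known) would defeat the labelling rule.
- k is fixed at 2; no model selection, no non-tied covariance structures.
- KO categories are consumed, not assigned; the functional summary reproduces
  the table's structure, not any specific KEGG release's annotations.
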