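# Methods

This note documents the models, defaults and numerical choices behind
`codewise`, and what the synthetic benchmark does and does not
demonstrate.

## Transcript model and input conventions

A transcript is a stranded nucleotide sequence stored in the DNA
alphabet (U→T on ingest) with a Cuffcompare-style class code from the
closed vocabulary `{=, j, o, c, x, s, u, -}`; codes `x` and `s` mark
antisense transcripts. Unknown codes are preserved with a warning
rather than rejected, since assemblers emit a larger code set than the
eight this package interprets. Gene and class metadata travel as
`gene=`/`class_code=` FASTA header tokens because GTF-level assembly
parsing is upstream of this tool. A transcript counts as *expressed*
when the sum of its FPKM values across the time course is strictly
greater than 1 (boundary rows are dropped). Orientation is inferred
from the class code alone; genome coordinates are out of scope.

## Longest-ORF batch translation

An ORF starts at an ATG and ends at the first in-frame stop codon
(TAA/TAG/TGA), stop included; run-off spans with no in-frame stop do not
count. `orf_len` includes the stop codon — so a transcript that is
exactly one ORF has ORF ratio 1.0 — while the protein excludes it
(`protein_len = orf_len/3 − 1`). "Longest" is measured in nucleotides
of the span; ties break to the 5′-most start. Codons containing N do
not translate: an ambiguous in-frame codon encountered before any stop
invalidates that candidate span. Scanning is forward-strand only, as
transcripts are already stranded. The implementation is a per-frame
linear scan with precomputed next-stop events; the test suite holds it
to exact agreement with a brute-force span enumerator on thousands of
random sequences.

## Feature extraction

Twelve features per transcript: transcript length, ORF ratio, 5′-UTR
ratio, protein length, GC content (computed over non-N bases), T/A
ratio, G/C ratio, conserved-domain count, domain truncation ratio
(truncated hits / total hits), structure MFE, and the optional
MapMan-bin flag and CPC score. Zero-denominator content ratios are
clamped (denominator→1) and flagged rather than emitted as NaN, so
downstream scaling never sees non-finite values. Domain counts count
hits, not distinct accessions, by default; a `dedupe` switch collapses
to accessions. A transcript absent from the hit table contributes
(0, 0); one absent from the annotation table gets `in_mapman_bin = 0`
and a missing CPC score.

**Folding backends.** MFE is pluggable. The preferred backend is the
ViennaRNA thermodynamic folder (kcal/mol) through its Python binding.
The built-in alternative is a base-pair-maximisation dynamic program
with pair pseudo-energies GC = −3, AU = −2, GU = −1 and a minimum
hairpin loop of 3 unpaired bases; it returns a pseudo-energy on an
arbitrary scale. Classifier correctness depends only on the feature's
discriminative *ordering* (more stable ⇒ lower energy), which both
backends preserve. The built-in DP is O(n³) pure Python and is meant
for short sequences and oracle testing; fold long transcripts with
ViennaRNA. Throughout the package MFE units are treated as opaque
model units.

## The weighted SVM classifier

* **Scaling.** Per-feature linear map of the training minimum to −1 and
  maximum to +1; constant features map to 0. Test data are transformed
  with the training map and may land outside [−1, +1].
* **Splitting.** Stratified random 75/25 partition preserving per-class
  proportions within rounding (a 3:1 class ratio stays 3:1 on both
  sides), deterministic given a seed.
* **Training.** scikit-learn SVC (LibSVM) with per-class weights
  {noncoding: 3, coding: 1} by default. The 3:1 weight compensates for
  the roughly 3:1 coding:noncoding imbalance typical of training
  compendia; the direction and magnitude are configurable. The cost
  parameter defaults to C = 1, gamma to `"scale"`; no grid search is
  performed.
* **Calibration.** Probabilities are a Platt sigmoid (near-unregularised
  logistic fit) on SVM decision values obtained by 5-fold stratified
  cross-validation within the training set, so calibration is not biased
  by in-sample margins. The two class probabilities sum to 1 and the
  reported label is their argmax; ambiguous transcripts sit near
  0.5/0.5.
* **Evaluation.** Accuracy, confusion counts with coding as the positive
  class, and trapezoidal ROC AUC of the coding-class probability (tied
  scores rank-averaged). A single-class test set has no AUC and reports
  it as absent.
* **Feature assessment.** PCA on the scaled features (variance fractions
  normalised to sum to 1, loadings per component) and LDA fitted on a
  stratified split with held-out accuracy and AUC.

Models serialise with joblib and round-trip bit-identically in their
decision outputs; a model records its feature schema and refuses
prediction on a mismatched column set (relevant because the MapMan and
CPC features are optional).

## Co-expression analyses

* **Normalisation.** Rows are mean-centred and scaled to unit sum of
  squares (the GeneCluster convention); constant rows become all-zero
  and are flagged.
* **k-means.** Euclidean k-means, best of `iterations` (default 500)
  random restarts by within-cluster sum of squares; each restart runs
  Lloyd's algorithm to convergence (tol 1e−6, cap 300 sweeps).
  Super-cluster assignment (e.g. 25 clusters → early / mid-to-late /
  desiccation groups) is a user-supplied mapping, since grouping
  reflects biological stage knowledge, not geometry.
* **Network.** Edges join transcript pairs with Pearson r ≥ 0.9 by
  default. The threshold applies to the signed correlation
  (`signed_positive`), reflecting the co-expression reading of the
  analysis; an `absolute` mode (|r| ≥ t) is provided because either
  convention is defensible. No additional significance filtering is
  applied beyond the threshold. Constant rows are excluded from edge
  formation with a warning.
* **Connectivity and hubs.** Degree of connectivity of node x in
  super-cluster sc is m/n (neighbors within sc over sc size);
  super-cluster connectivity is the median over members (degree
  distributions are skewed, so the median, with the mean of the central
  pair for even counts, represents them better than the mean). Hubs
  sort by degree descending with lexicographic transcript-id
  tie-breaking; per-gene deduplication (keep the best isoform) is a
  switch, as in practice at most one isoform per gene surfaces as a hub.
* **Sense–antisense screen.** Pearson r with a two-sided p-value from
  the t transform (df = timepoints − 2), via scipy; a pair is
  significant iff p < 0.05. Pairs with a constant member are flagged
  not significant with a reason rather than erroring.
* **Splice-variant domain categories.** Within an isoform group: any
  member with zero domains ⇒ `no_known_domain`; identical
  domain-accession sets (counts may differ) ⇒ `similar`; otherwise
  `disparate`.

## Synthetic benchmark

The generator's defaults define the benchmark conditions; they live in
one dataclass (`GeneratorConfig`) so fixtures are auditable.

| quantity | coding | noncoding |
|---|---|---|
| rows (benchmark preset) | 3,000 | 1,000 |
| length (lognormal median, nt) | 1,500 (σ=0.45) | 600 (σ=0.5) |
| ORF ratio (Beta) | mean 0.70 | mean 0.20 |
| 5′-UTR ratio (Beta, ∧ 1−ORF) | mean 0.10 | mean 0.45 |
| domains | 1–4 uniform | 0 w.p. 0.95 |
| truncation per domain | Bernoulli(0.1) | Bernoulli(0.1) |
| MFE (Normal, model units) | −371 (sd 80) | −134 (sd 50) |
| GC content | Normal(0.42, 0.04) | same |
| MapMan bin present | 0.9 | 0.05 |

Protein length follows from ORF ratio and length; the CPC-like score is
a noisy monotone function of ORF ratio and protein length (so adding it
barely moves accuracy, as a score redundant with those features
should). Distribution families (lognormal lengths, Beta ratios,
Gaussian energies) are package choices made once for realism; the
per-class energy means and the qualitative orderings between classes
are the anchored conditions. GC content is deliberately
non-discriminative so the classifier cannot lean on it.

Sequence generation embeds a designed ATG…stop ORF of target length
inside ATG-free UTRs, with a stop cassette (stops in all three frames,
no ATG) opening the 3′-UTR; each sequence is verified against the ORF
finder and resampled until the realised longest ORF equals the design.
Noncoding sequences get a short designed ORF the same way, capping their
realised ORF ratio near its target.

Expression profiles follow three archetypes over 10 time points — early
decline, mid-to-late plateau, and a final-day desiccation spike — scaled
by lognormal amplitudes with multiplicative lognormal noise (sd 0.25 on
the log scale by default). Designated sense–antisense pairs share
(sign +1, default) or mirror (sign −1) the sense profile with small
independent noise; at zero noise the pair correlation is exactly 1 and
k-means at k=3 recovers the archetypes exactly.

**What passing means.** The benchmark's class-conditional separations
are generous (the energy means sit ~3 class-sds apart, and ORF/domain
features separate further), so the scaled-down SVM metrics land at or
near ceiling, comfortably above the headline thresholds. Real
transcriptomes are harder: features correlate differently, class
boundaries are contaminated by mis-assembled transcripts, and noncoding
training examples are scarce and biased. Passing here demonstrates the
pipeline's correctness — scaling, weighting, calibration, evaluation and
the generator's contracts — not field accuracy on new species.

## Problem sizes and determinism

The test suite and the acceptance script run the full 4,000-row
benchmark with five split/train seeds (medians reported to absorb
split sampling noise) and use 30–300-row matrices for network and
clustering oracles; these sizes keep every oracle exact or tightly
calibrated while completing in seconds. Every stochastic step
(generation, splitting, training, clustering) takes an explicit seed,
and fixed seeds reproduce splits, decisions and reports exactly.

## Known limitations

* The built-in folding backend is a pairing-count pseudo-energy, not a
  thermodynamic nearest-neighbor model, and emits no structure string.
* Non-AUG starts, multi-ORF reporting and codon-usage scoring are out of
  scope for the translator.
* Super-cluster membership is user-supplied; the package does not infer
  developmental stages from profiles.
* The CLI's `manifest.json` is written by the directory-producing
  subcommands (`simulate`, `train`); single-file subcommands log their
  configuration to stderr instead.
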