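# codewise

Coding-potential classification and isoform-level co-expression analysis
for plant transcriptomes.

RNA-Seq of developing plant tissues (the motivating system is the
soybean embryo over a 10-point seed-filling/desiccation time course)
assembles tens of thousands of transcripts of mixed character: protein
coding mRNAs, long noncoding RNAs (lncRNA/lincRNA), and antisense
transcripts, many of them alternatively spliced isoforms of the same
gene. Deciding which transcripts can encode protein, and which isoforms
co-express with which, is the first step toward assigning them
functions. This package provides that workflow for bioinformaticians
working at the isoform level:

* a **batch translator** that finds the longest AUG→stop open reading
  frame per transcript and reports translation statistics (5′-UTR
  length, ORF length and ratio, protein length and sequence);
* a **12-feature extraction pipeline**: transcript length, ORF ratio,
  5′-UTR ratio, potential protein length, GC content, T/A and G/C
  ratios, conserved-domain count and truncation ratio (from Batch
  CD-Search-style hit tables), minimum free energy (MFE) of the
  predicted RNA secondary structure, and optional MapMan-bin and CPC
  score features;
* a **class-weighted SVM classifier** with per-transcript
  coding/noncoding probabilities;
* **co-expression tools**: k-means clustering of temporal profiles into
  developmental super-clusters, a correlation-threshold network,
  degree-of-connectivity/hub analysis, nearest-neighbor sub-networks,
  Pearson screening of sense–antisense pairs, and conserved-domain
  categorisation of splice-variant groups;
* a **synthetic-data generator** that reproduces the statistical
  structure these analyses assume, so everything is testable end to end
  without downloads.

## The classifier

Each transcript *i* is represented by a feature vector **x**ᵢ ∈ ℝ¹²,
min–max scaled per feature into [−1, +1] on the training set. A support
vector machine

  f(**x**) = sign( Σᵢ αᵢ yᵢ K(**x**ᵢ, **x**) + b ),  yᵢ ∈ {+1 coding, −1 noncoding}

is trained with the noncoding (minority) class up-weighted 3:1 to
prevent unbalanced training; linear, RBF and polynomial kernels are
available (linear is the best-performing default). Per-transcript
probabilities come from Platt sigmoid calibration of cross-validated
decision values, so ambiguous transcripts are visible as probabilities
near 0.5. Coding transcripts separate from noncoding ones through
longer ORFs and proteins, conserved domains, and more stable (more
negative MFE) secondary structure; nucleotide content carries little
signal.

In the network component, the degree of connectivity of node *x* inside
super-cluster *sc* is m/n — its neighbor count m within *sc* over the
super-cluster size n — a super-cluster's connectivity is the median over
its members, and hubs are the top-ranked nodes.

## Worked example

```python
from codewise import (benchmark_config, generate_feature_table,
                      stratified_split, train, evaluate, predict)

config = benchmark_config(seed=42)          # 3,000 coding + 1,000 noncoding
X, y = generate_feature_table(config)
(X_tr, y_tr), (X_te, y_te) = stratified_split(X, y, train_frac=0.75, seed=1)
model = train(X_tr, y_tr, kernel="linear", class_weight_noncoding=3.0, seed=1)
report = evaluate(model, X_te, y_te)
print(f"accuracy = {report.accuracy:.3f}  AUC = {report.auc:.3f}  "
      f"TNR = {report.true_negative_rate:.3f}")
print(predict(model, X_te.iloc[:3]).round(3))
```

prints

```
accuracy = 0.999  AUC = 1.000  TNR = 0.996
               coding_prob  noncoding_prob      label
transcript_id
C01014                 1.0             0.0     coding
C02479                 1.0             0.0     coding
N00096                 0.0             1.0  noncoding
```

i.e. on the held-out quarter of the synthetic benchmark the weighted
linear SVM classifies 99.9 % of transcripts correctly, ranks coding
above noncoding essentially perfectly (trapezoidal ROC AUC), and rejects
99.6 % of true noncoding transcripts (the true-negative rate), with a
calibrated probability pair per transcript.

The same workflow is available from the shell:

```sh
codewise simulate --preset benchmark --seed 42 --out run/
codewise train --features run/features.tsv --labels run/labels.tsv \
    --kernel linear --weight-noncoding 3 --seed 1 --out run/model/
codewise classify --model run/model/model.joblib \
    --features run/features.tsv --out run/predictions.tsv
```

plus `cluster`, `network`, `hubs`, `neighbors`, `antisense` and
`domains-categorize` subcommands for the co-expression side.

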