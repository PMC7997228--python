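# m6apred

Prediction of RNA N6-methyladenosine (m6A) sites from fixed-length,
adenine-centered sequence windows (41 nt by default).  The pipeline:

1. **Feature encoding** — eight encoders fused into one matrix: binary
   one-hot (BE), trinucleotide composition (TNC), enhanced nucleic acid
   composition (ENAC, sliding window), K-spaced nucleotide pair
   frequencies (KSNPFs), nucleotide chemical properties (NCP), pseudo
   dinucleotide composition (PseDNC), and position-specific nucleotide /
   dinucleotide propensities (PSNP/PSDP).  For 41-nt input the fused
   matrix has 164 + 96 + 148 + 123 + (16+λ) + 64 + 41 + 40 columns
   (722 at λ = 30).
2. **Feature selection** — elastic net (native cyclic coordinate descent)
   on the 0/1 labels; columns with nonzero coefficients survive.
3. **Classifier** — a feed-forward neural network (2–3 hidden layers,
   dropout after each, sigmoid output) implemented natively in numpy with
   the seven standard activations, optimizers, and weight initializers.
4. **Hyper-parameter search** — a native tree-structured Parzen estimator
   (TPE) over the mixed conditional search space, minimizing
   1 − mean CV accuracy.
5. **Evaluation** — Sn, Sp, ACC, MCC, and rank-based AUC under stratified
   5-fold cross-validation.  All label-dependent steps (propensity
   matrices, feature selection) are refitted inside each training fold.

A synthetic-data generator (position-weight model with planted
per-position base enrichment in positives) stands in for the public
benchmark FASTA files, which can also be used directly.

## CLI

```bash
# synthesize a labeled dataset
m6apred simulate --n-pos 1000 --n-neg 1000 --motif-strength 0.6 \
    --seed 1 --out-pos pos.fasta --out-neg neg.fasta

# grid-search encoder parameters (K_max; PseDNC lambda and w)
m6apred sweep-params --pos pos.fasta --neg neg.fasta --out sweep.json

# train: encode -> select -> train, with CV metrics; writes a model bundle
m6apred train --pos pos.fasta --neg neg.fasta --seed 1 --out bundle/

# TPE hyper-parameter search (writes a JSONL trial log)
m6apred tune --pos pos.fasta --neg neg.fasta --trials 20 --out trials.jsonl

# score new sequences / evaluate on held-out files with a trained bundle
m6apred predict --bundle bundle/ --fasta new.fasta --out scores.tsv
m6apred evaluate --bundle bundle/ --pos test_pos.fasta --neg test_neg.fasta
```

`train` accepts a YAML config (`--config`) covering encoder parameters
(`k_max`, `psednc_lambda`, `psednc_w`, `enac_window`), the selection block
(`alpha`, `beta`), the network block (`dnn:`), CV (`k_folds`, `seed`) and
the TPE budget (`tpe_trials`).  Defaults mirror the published method's
choices (k = 5 folds, α grid 0.01–0.1, K_max = 5, λ = 30, w = 0.5).

A bundle directory contains the encoder parameters, fitted propensity
matrices, the selection model, network weights (plain-text TSV), CV
metrics, and a manifest with config hash and versions.  `predict` and
`evaluate` are strictly read-only.

## Library use

```python
from m6apred import (
    SyntheticConfig, generate_synthetic, fit_propensity, encode_set, fuse,
    fit_elastic_net, apply_selection, DnnConfig, build_dnn, train_dnn,
    predict_proba, compute_metrics,
)

seqs = generate_synthetic(SyntheticConfig(n_pos=500, n_neg=500, seed=0))
psnp = fit_propensity(seqs, order=1)
fm = fuse([encode_set(seqs.sequences, "TNC"),
           encode_set(seqs.sequences, "PSNP", propensity=psnp)])
sel = fit_elastic_net(fm, seqs.labels, alpha=0.01)
X = apply_selection(fm, sel)
net = train_dnn(build_dnn(DnnConfig(), X.n_features), X, seqs.labels)
print(compute_metrics(seqs.labels, predict_proba(net, X)))
```
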