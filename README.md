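# lstaloc

Predicting the subcellular compartment of long noncoding RNAs (and, in a
multi-label mode, mRNAs) from sequence alone, with a deep network built around
**long-short term attention** over variable-length inputs. The package is a
complete, tested toolkit: per-nucleotide physicochemical encoding, a
length-agnostic convolutional encoder, the attention/recurrent feature
extractor, focal losses for imbalanced data, a full evaluation suite,
stratified cross-validation with grid search, occlusion-based attribution, and
a synthetic-data generator so every stage is exercisable end to end without
any database downloads.

## Who this is for

Computational biologists who want a self-contained, CPU-friendly
reimplementation of this family of RNA localization classifiers — to train on
their own FASTA + label tables, to probe which sequence windows drive a
prediction, or to use the pieces (adaptive-pool encoder, long-short term
attention, focal losses, metrics) as a library.

## The model

A sequence of length L over {A,C,G,T,N} is encoded as an L×8 matrix: one-hot
identity (A,T,C,G), the electron–ion interaction pseudopotential
(A 0.1260, T 0.1335, C 0.1340, G 0.0806), and the 3-bit nucleotide chemical
property code (ring structure, functional group, hydrogen bonding).

The network never pads or truncates:

1. **CM encoder** — two parallel branches (kernel sizes 3 and 5), each three
   stages of valid 1D convolution (64/64/32 filters), ReLU, and *adaptive* max
   pooling to 512/256/128 positions. Output per branch: 128×32, for any L.
2. **LSTA** — 6-head attention in which every query position attends to its
   short-term window (w=128) **and** to r=4 long-range summary rows formed by
   a learned, input-dependent softmax projection of all keys/values
   (`K̄ = PᵀK`, `Ṽ = PᵀV`); the two key/value sets are layer-normalized
   separately before concatenation, and logits are scaled by 1/√d_k.
3. **Bi-LSTM** — forward + backward recurrences (hidden 16) concatenated to
   32 channels per position; fused with the LSTA output into 128×64.
4. **TextCNN head** — convolutions of sizes 1/3/5 (64 filters each), global
   max pooling, branch concatenation, one fully connected layer; softmax for
   the 5-class lncRNA mode or element-wise sigmoid for the 6-class
   multi-label mRNA mode.

Training minimizes the focal loss
`−α(1−p_true)^γ ln p_true` (γ=2), or its per-class multi-label
generalization `Σᵢ FLᵢ/n` with class weights αᵢ, under AdamW.

Evaluation reports ACC, macro precision/recall/F1, macro MCC, micro/macro
AUROC and micro AUPRC.

## Worked example

```bash
# 1. generate a synthetic five-compartment dataset with planted motifs
lstaloc generate --preset learnable --per-class 60 --seed 1 --out data/

# 2. cross-validation with the fast short-schedule configuration
lstaloc cv --fasta data/sequences.fasta --labels data/labels.tsv \
           --train-preset short --seed 1 --folds 3 --out runs/cv
```

The `cv` command prints the cross-validated metric summary; the run above
(300 sequences, ~5 minutes on one CPU core) prints

```
acc: 0.610 ± 0.092
macro_precision: 0.588 ± 0.115
macro_recall: 0.610 ± 0.092
macro_f1: 0.564 ± 0.090
macro_mcc: 0.512 ± 0.110
mi_auc: 0.902 ± 0.045
ma_auc: 0.870 ± 0.059
mi_auprc: 0.753 ± 0.090
```

A micro-averaged AUROC of 0.90 against a chance level of 0.5 shows the
network has clearly learned the planted class↔motif associations from only
~200 training sequences per fold; the hard-call metrics (accuracy, macro F1)
lag the ranking metrics because at this data scale and epoch budget the
network is still mid-consolidation — they climb toward the mid-0.9s with
more sequences and longer schedules (see `docs/methods.md` for convergence
characteristics and limitations). Training on real data uses the same
commands with your own FASTA and two-column label TSV; `lstaloc predict`
writes per-class probabilities and `lstaloc attribute` writes per-position
occlusion scores showing *which* windows of a sequence support a
compartment call.

As a library:

```python
from lstaloc import learnable_spec, generate_dataset, SequenceDataset, cross_validate
from lstaloc.presets import short_schedule_config

seqs, labels = generate_dataset(learnable_spec(seed=1))
ds = SequenceDataset.from_sequences(seqs, labels,
        ("Nucleus", "Exosome", "Cytoplasm", "Cytosol", "Ribosome"))
result = cross_validate(ds, short_schedule_config(seed=1), k=5)
print(result.summary())
```

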