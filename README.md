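# spliceae

Detection of lincRNA transcription (splice) sites in DNA sequence with a
stacked denoising auto-encoder.

Long intergenic non-coding RNAs (lincRNAs) are spliced like coding
transcripts: introns end at 3′ **acceptor** junctions (consensus `AG`) and
begin at 5′ **donor** junctions (consensus `GT`). `spliceae` frames site
detection as binary classification of fixed-length windows centred on the
candidate splice dinucleotide — 90 nt for acceptors, 15 nt for donors —
and is aimed at anyone who wants a small, fully seeded, NumPy-only
re-implementation of this classic pipeline: five numeric DNA encodings, a
two-hidden-layer denoising auto-encoder with greedy layer-wise pretraining
and supervised fine-tuning, the standard seven-metric confusion-matrix
evaluation, and a sliding-window scanner that nominates unannotated sites
from FASTA.

## The model

Each auto-encoder layer encodes and reconstructs its input,

$$h = S_f(Wx + b_h), \qquad x^* = S_g(W'h + b_x),$$

and is pretrained to minimise the denoising cost
$\sum_{x \in X} \mathbb{E}\,[L(x, x^*)]$, where the expectation is over
random masking of a fraction of input positions and $L$ is squared error
(or cross-entropy). Layers train greedily on the hidden codes of their
predecessors; a sigmoid output unit is then fine-tuned through the whole
stack on binary cross-entropy with L2 weight decay, keeping the
best-validation parameters. Predictions are evaluated with
Sn, Sp, Acc, Mcc, Ppv, Pc and F1 on a 0–100 scale, with explicit handling
of invalid (zero-denominator) values and degenerate single-class
("training failure") runs.

Windows are encoded numerically under any of five schemes — `dax`, `eiip`,
`complementary`, `enthalpy` (dinucleotide ΔH), `galois4` — all shipped as
overridable tables and rescaled to [0, 1] by default. See
[docs/methods.md](docs/methods.md) for defaults, assumptions and
limitations.

## Worked example

Simulate a labelled donor-site dataset and a small genome with planted
sites, train a model, and evaluate it:

```
$ spliceae simulate --site-type donor --n-pos 500 --n-neg 500 \
      --genome-length 5000 --n-sites 8 --seed 4 --out-prefix demo
$ spliceae train --windows demo.windows.tsv --encoding dax \
      --epochs 60 --seed 0 --model-out demo.model.npz
metric  value
Sn      96.0
Sp      92.0
Acc     94.0
Mcc     88.1
Ppv     92.3
Pc      88.9
F1      94.1
```

The table is the validation split's confusion-matrix summary: the trained
model recovers 96.0% of true donor windows (Sn) at 92.0% specificity,
94.0% overall accuracy and a Matthews correlation of 88.1. Scanning the
simulated genome nominates candidate sites as BED6 (score = 1000·probability);
the planted anchor at 1-based position 556 ranks among the three
highest-scoring calls (short 15-nt donor windows carry little context, so
background `GT` occurrences also score well — see the limitations section
of the methods note):

```
$ spliceae scan --model demo.model.npz --fasta demo.genome.fasta \
      --site-type donor --threshold 0.8 --out demo.calls.bed
$ sort -k5,5nr demo.calls.bed | head -3
synthetic_chr   2775    2777    donor   920     +
synthetic_chr   2732    2734    donor   917     +
synthetic_chr   555     557     donor   915     +
```

Published benchmark confusion tables can be re-evaluated directly; for
example the acceptor-data EIIP column (cells as percent of total):

```
$ cat confusion.yaml
tp: 49.4
fp: 0.2
fn: 0.4
tn: 50.4
as_percent: true
$ spliceae evaluate --confusion confusion.yaml
metric  value
Sn      99.2
Sp      99.6
Acc     99.4
Mcc     98.8
Ppv     99.6
Pc      98.8
F1      99.4
```

Invalid cells render as `–` and degenerate single-class runs append a `*`
training-failure marker, matching the conventions of the printed tables.

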