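# mgeclass

Three-class classification of metagenomic DNA fragments as **phage**,
**chromosome**, or **plasmid**, using a dual-path convolutional network
over two one-hot encodings of each fragment:

* **base one-hot (BOH)** — one 4-bit row per base of the forward strand
  followed by the reverse complement (`2L x 4`), with
  A=[0,0,0,1], C=[0,0,1,0], G=[0,1,0,0], T=[1,0,0,0];
* **codon one-hot (COH)** — the sequence expanded into all six reading
  frames (three offsets on each strand), each complete codon a 64-bit
  one-hot row (`2(L-2) x 64`), columns ordered lexicographically
  (AAA=0 … TTT=63).

Each encoding feeds its own convolutional stack (64 kernels of length 6,
then 128 and 256 kernels of length 3, with max pooling of length 3 and
batchnorm+dropout between convolutions, ending in global average
pooling); the two 256-vectors are concatenated and passed through a
512-node dense layer into a 3-way softmax. Training uses Adam and
categorical cross-entropy. Three models cover fragment-length groups
A (100–400 bp), B (400–800 bp), and C (800–1,200 bp); longer sequences
are scanned with non-overlapping 1,200 bp windows whose scores are
combined by window-length-weighted averaging. A score threshold expands
the three labels into six (adding "uncertain X" when the top score falls
below it).

The network is implemented directly on numpy/scipy (im2col convolutions,
hand-written backpropagation, sparse matmuls for the one-hot input
layers), so training and prediction run on a plain CPU with no deep
learning framework.

The package also includes:

* `mgeclass.simulate` — a seeded synthetic-data generator: per-class
  order-k Markov "genomes", uniform fragment lengths per group
  (A/B/C/D, group D = 5,000–10,000 bp), and substitution / indel error
  channels — so the whole pipeline is trainable and testable offline;
* `mgeclass.evaluate` — 3-class confusion matrices, per-class
  one-vs-rest TPR/FPR/AUC, threshold sweeps, and the derived
  `life_score = (phage − chromosome)/phage` and
  `trans_score = (plasmid − chromosome)/plasmid` statistics.

## CLI

```sh
# 1. generate a labelled synthetic dataset (group A, 500 fragments/class)
mgeclass simulate --group A --n-per-class 500 --seed 1 \
    --out-fasta train.fa --out-truth truth.tsv

# 2. train the group-A model
mgeclass train --group A --fasta train.fa --epochs 6 --seed 1 \
    --model-dir models/group_a

# 3. score sequences (repeat --model-dir per group for mixed lengths)
mgeclass predict --fasta contigs.fa --model-dir models/group_a \
    --threshold 0.5 --out results.tsv

# 4. compare predictions against the simulator's truth table
mgeclass evaluate --results results.tsv --truth truth.tsv --out-prefix eval
```

`predict` writes a tab-separated table with columns
`id, length, phage_score, chromosome_score, plasmid_score, label`;
scores are softmax probabilities summing to 1, and `label` is one of
the six categories. Sequences shorter than 100 bp are skipped with a
warning (optionally listed via `--skip-file`).

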