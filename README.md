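# repgru

Nucleotide-level annotation of repetitive DNA with a shared-weight
bidirectional GRU with attention.

Repeats make up 40–50% of mammalian genomes, and annotating them is a
standard first step of genome projects. `repgru` labels every position
of a genomic sequence with one of five classes — *no repeat*, HSAT2,3
(ATTCC-motif satellites), alphoid (171 bp centromeric satellite), Alu
(~300 bp SINE) or LINE-1 (~6 kb retrotransposon) — by learning from
existing annotations (RepeatMasker `.out` or BED) and transferring them
to new sequence. It is aimed at people who need fast, licence-free
repeat annotation or masking and already have a trusted annotation to
learn from.

## Method in brief

Sliding windows (length 342, step 50) are one-hot encoded on both
strands; a single-weight-set GRU processes the forward and the
reverse-complement stream, their per-position outputs and final hidden
states are averaged, and an additive attention layer
(`e_t = v·tanh(W_a h_t + U_a s)`) provides a window-level context to a
position-wise softmax over the 5 labels. Overlapping window
probabilities are max-aggregated per position, converted to signed
logit scores

    s_i = −10·ln(q_i/(1−q_i))  if the argmax label is "no repeat",
    s_i =     ln(q_i/(1−q_i))  otherwise,   q_i = min(max_c p_i^c, 0.99)

and segmented with an all-maximal-scoring-segments algorithm extended
by a minimum-score threshold and an X-drop rule. Segments inherit their
majority class, mixed segments are split, short ones (≤ 50 bp) are
dropped, and the result is written as BED. Details and design
decisions: [docs/methods.md](docs/methods.md).

The network is implemented directly in numpy (hand-derived
backpropagation, verified against finite differences in the tests), so
the package has no deep-learning framework dependency.

## Worked example

Everything below is reproducible without downloads: the package ships a
simulator that plants the four repeat archetypes on a random background
and emits the ground truth.

```sh
# 1. simulate a 50 kb genome with planted repeats + truth BED
cat > sim.cfg <<CFG
genome_length = 50000
seed = 7
CFG
repgru simulate --config sim.cfg --out-dir demo
# stderr: genome of 50000 bp with 12 planted elements:
#         {'HSAT23': 1000, 'ALPHOID': 855, 'ALU': 2407, 'LINE1': 3996}

# 2. train on it (a one-minute demo model; see docs/methods.md for defaults)
cat > train.cfg <<CFG
max_epochs = 15
random_state = 0
CFG
repgru train --fasta demo/genome.fa --labels demo/truth.bed \
             --config train.cfg --out demo/model

# 3. annotate the same sequence and compare against the truth
repgru predict --fasta demo/genome.fa --model demo/model \
               --step 50 --out demo/pred.bed
# stderr: chr1: 7 segments
head -3 demo/pred.bed
# chr1    4725    5238    LINE1   220
# chr1    5661    5728    LINE1   26
# chr1    5940    6118    LINE1   52
repgru evaluate --pred demo/pred.bed --gold demo/truth.bed \
                --fasta demo/genome.fa --out demo/report.json
# stderr: MCC_5 = 0.5324
```

`demo/report.json` contains the 5-class Matthews correlation
coefficient (`mcc5`), per-class false positive / false negative rates
on the base-pair level (`FPR_c = |P_c\A_c|/|A_¬c|`,
`FNR_c = |A_c\P_c|/|A_c|`), one-vs-rest MCCs, the confusion table and
boundary-level sensitivity/specificity at δ = 50 bp. In this one-minute
demo the satellites are recovered essentially perfectly (HSAT2,3 and
alphoid FNR 0.00 and 0.04), LINE-1 is partially found and the eight Alu
copies are still missed — dispersed single-consensus families need more
training than 15 epochs on 50 kb. A model trained with the package
defaults on a 200 kb simulated genome reaches MCC₅ ≥ 0.8 on a held-out
100 kb genome; the test suite asserts this end to end.

The same pipeline is available as a library through a scikit-learn
style estimator:

```python
from repgru import RepeatAnnotator
annotator = RepeatAnnotator(random_state=0)
annotator.fit([train_seq], [train_labels], validation_data=([val_seq], [val_labels]))
segments = annotator.annotate(test_seq)       # classified Segment list
mcc5 = annotator.score([test_seq], [test_labels])
```

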