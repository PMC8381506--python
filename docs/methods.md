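# Methods

## The problem

Roughly 40–50% of mammalian genomes consist of repetitive elements.
`repgru` annotates, at single-nucleotide resolution, four classes that
differ sharply in structure:

* **HSAT2,3** — simple satellites built from noisy variations of the
  ATTCC pentamer, without a consistent repeat-unit reference;
* **alphoid** (alpha satellite) — centromeric tandem arrays of a
  ~171 bp monomer;
* **Alu** — a primate SINE of ~300 bp, dispersed in high copy number;
* **LINE-1** — an autonomous retrotransposon of ~6 kb, typically
  present as 5′-truncated copies of heterogeneous length.

Every position of a genome receives one of five labels (the four
classes plus *no repeat*). Training data are existing annotations
(RepeatMasker `.out` files or BED); the trained model then transfers
those annotations to new sequence.

## Model

A window of `w` bases (default 342) is one-hot encoded over the
alphabet A, C, G, T, N (five channels; N marks ambiguity codes and
assembly gaps). The window enters the network twice — forward strand
and reverse complement — and one GRU with a **single weight set**
processes both streams, so learned features are orientation-independent
and the recurrent parameters are counted once. The reverse-complement
stream is re-reversed into forward coordinates before the two
per-position output streams are averaged element-wise; the final hidden
states of the two streams are averaged likewise.

An additive attention layer scores each averaged position output
`h_t` against the averaged final hidden state `s`:

    e_t = v · tanh(W_a h_t + U_a s),   α = softmax(e),
    c = Σ_t α_t h_t

The context vector `c` summarises the window and is concatenated to
each position's features; a position-wise dense layer with softmax then
yields `p_i^c`, the probability of label `c` at position `i`. The
network is implemented directly in numpy — forward pass and analytic
backpropagation through time — and the gradients are validated against
central finite differences in the test suite.

Windows are slid with a step (default 50 for both training pools and
prediction). The window length is fixed per trained model; the
prediction step is free and trades running time against accuracy: each
position collects one probability per covering window, and only the
per-class **maximum** is kept (streaming, O(n·5) memory). An extra tail
window anchored at `n − w` ensures the sequence end is always covered
by a full-length window; sequences shorter than one window are padded
with N rows on the right and padded rows are excluded from aggregation.
Leading and trailing N-runs are trimmed before prediction and the
trimming offset is added back to all reported coordinates.

## From probabilities to segments

Per position, `q_i = min(max_c p_i^c, 0.99)` (the cap removes the
logit's singularity at 1) and `c_i` is the argmax label (ties toward
the smallest class id). The signed score is

    s_i = −10 · ln(q_i / (1 − q_i))   if c_i = 0 (no repeat)
    s_i =       ln(q_i / (1 − q_i))   otherwise,

so confident repeat positions score up to ln 99 ≈ 4.6 and confident
background positions score strongly negative (factor −10, which keeps
segments from extending across long non-repetitive stretches). The
natural logarithm is used; any fixed base would only rescale scores and
thresholds jointly.

All maximal scoring segments of `s_1 … s_n` are found with the classic
disjoint-all-maximal-subsequences algorithm, extended by two rules: an
**X-drop** — when the running score of the current extension falls more
than `x` below the maximum reached so far, the extension is closed at
that maximum and the segments found so far are frozen (never merged
with later segments) — and a **minimum score**: segments whose total
score is below the threshold are discarded. With `x = ∞` and threshold
`−∞` the output equals the classic solution; the test suite verifies
exact equivalence against a quadratic brute-force oracle on a thousand
random inputs in both regimes.

Within each segment, *no repeat* positions inherit the majority repeat
class of the segment (ties toward the smallest class id); segments
containing several classes are split into maximal single-class runs,
each re-scored as the sum of its members' `s_i`; segments not longer
than `min_length` bp (default 50) are discarded. Shipped thresholds are
`min_score = 5·ln 99 ≈ 23.0` and `xdrop = 10·ln 99 ≈ 46.0` — i.e. a
segment must accumulate at least five saturated repeat positions'
worth of score, and an extension tolerates a drop of ten such units.
Both are deliberate stand-ins exposed in the configuration; they were
not tuned against any benchmark.

## Training

Batches are composed with explicit class floors governed by
`r ∈ [0, 1]`: a batch of `n` windows contains at least `⌊n·r⌋` windows
with at least one repeat-annotated position, and among those at least
`⌊n·r/|C|⌋` windows per repeat class (|C| = 4), so rare classes are
oversampled relative to their genomic frequency. The remaining slots
are uniform over the pool — keeping background-only windows in every
batch, which matters: with `r = 1` the model never sees pure background
and its validation loss diverges.

The loss is per-position categorical cross-entropy, minimised with Adam
(default learning rate 0.01, seeded). Early stopping monitors the
validation loss: training halts once it has not strictly decreased for
`patience` (default 10) consecutive epochs, and the parameters of the
best-validation epoch are restored. Divergence (non-finite loss) raises
an error rather than silently continuing.

Two regularisation mechanisms address a failure mode specific to
repeat annotation: each family in a training genome is represented by
few, individually mutated copies, and an unregularised network
memorises those copies (training loss ≈ 0.05 against validation
≈ 0.23 in our simulations) and under-detects unseen copies — worst for
LINE-1, whose 6 kb consensus is covered at depth 1–3 by a realistic
training genome.

* **Substitution augmentation** (default rate 0.05): at every batch
  presentation a random fraction of window positions is replaced by
  random bases (labels unchanged), and the reverse-complement stream is
  rebuilt consistently. This synthesises ever-new "mutated copies" of
  the training repeats and is the single most effective lever for
  generalising to unseen copies in our simulations (held-out MCC₅ 0.75
  → 0.90).
* **Inverted dropout** on the averaged per-position recurrent outputs
  (default 0, available as a knob): helps on its own but converges much
  more slowly than augmentation.

The learning rate is halved whenever the validation loss has stalled
for 4 consecutive epochs (down to a floor of 1e-3); the validation
curve is noisy at a fixed rate.

Defaults: batch size 32, `r = 0.5`, at most 40 epochs (desk-scale; an
epoch is `pool size // batch size` batches), hidden size 32, attention
size 8. Hidden and attention sizes are deliberate desk-scale stand-ins
exposed in the configuration, not tuned optima.

## Synthetic genomes

The generator plants the four structural archetypes on a uniform ACGT
background: HSAT-like tandem arrays of the mutated ATTCC motif
(60–300 copies per array), alphoid-like tandem arrays of a fixed random
171 bp monomer (3–12 monomers, per-copy substitutions), dispersed
copies of one random 300 bp Alu-like consensus (substitutions + 1%
indels) and dispersed copies of one random 6 kb LINE-like consensus,
each 5′-truncated with probability 0.5 at a uniform point (minimum
300 bp kept from the 3′ end). Default densities are 2% HSAT, 2%
alphoid, 5% Alu and 8% LINE of the genome's base pairs, with 5%
per-base substitution against the consensus — chosen as a plausible
desk-scale miniature of the classes' real abundance ordering and
divergence. Elements never overlap or nest (10 bp minimum gap), so the
ground truth is unambiguous; everything is a deterministic function of
the seed. One **family library** (the consensus sequences) can be
shared by several simulated genomes, the way chromosomes of one genome
share repeat families; training, validation and test genomes are
simulated that way.

What the simulation does *not* emulate: GC skew and compositional
heterogeneity of real genomes, nested and fragmented insertions,
phylogenetic substructure within families (real LINE-1 has ~194 repeat
IDs), transduction, and the sheer scale of real chromosomes. Passing
the end-to-end test therefore shows that the architecture, training
loop and segmentation recover planted family structure under realistic
divergence — not that the tool matches annotation quality on a real
genome.

## Numerical choices and edge cases

* One-hot column order A, C, G, T, N (fixed for reproducibility).
* Argmax and majority-vote ties break toward the smallest class id.
* "Improvement" in early stopping means strictly lower than the best
  validation loss so far (no minimum delta).
* Probabilities enter the logit after capping at 0.99; scores are
  finite by construction.
* All-N (empty after trimming) input yields an empty track and no
  segments; all-no-repeat segments are dropped with a warning.
* The length filter is strict (`length > min_length`).
* Positions that are N in the input count as class 0 in evaluation
  unless a mask is supplied (`--exclude-n` in the CLI).
* Boundary-level evaluation matches gold and predicted segments
  greedily, one-to-one, in coordinate order; both end points must agree
  within δ (inclusive) and the class must match.
* float32 throughout training and inference; the gradient-check test
  runs the same code in float64.

## Problem sizes in the shipped tests

The end-to-end recovery test and the acceptance script train on a
200 kb genome with a 50 kb validation genome and score a 100 kb test
genome (prediction step 50, default thresholds). These sizes are the
package's chosen desk-scale study conditions: large enough for ~130
planted elements per genome and a stable MCC, small enough to train in
minutes on one CPU.

## Known limitations

* The quality reachable on real chromosomes depends on hyperparameters
  (hidden size, window, r, learning rate) that would need re-tuning;
  the shipped defaults are desk-scale.
* Segment boundaries are not polished; per-base recall near repeat
  edges is weaker than in segment cores.
* No multi-class simultaneous segmentation: only the per-position
  maximum probability is scored (genuinely ambiguous base pairs are
  rare in real gold standards).
* Soft-masked (lowercase) input is uppercased, not interpreted.
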