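# Methods

This note documents the models, numerical choices and limitations behind
`selcnn`, in the spirit of a methods appendix: what is simulated, what is
learned, and what the test suite does and does not demonstrate.

## Codon substitution model

Sequences evolve over the 61 sense codons of the universal genetic code.
For codons *i*, *j* differing at exactly one nucleotide position the
unnormalized substitution rate is

    q_ij = π_j · κ^[transition] · ω_c^[nonsynonymous]

where π are the stationary codon frequencies, κ the transition/transversion
ratio, and ω_c the dN/dS ratio of the site's class *c*. Multi-nucleotide
changes and changes into stop codons have rate zero. Each gene carries three
site classes with proportions (p0, p1, p2): S0, strong purifying,
ω0 ~ U(0.1, 0.5); S1, weak purifying, ω1 ~ U(0.5, 0.9); and S2, whose ω2
determines the gene's label — purifying genes draw ω2 ~ U(0.9, 1.0), neutral
genes fix ω2 = 1, positive-selection genes (label 1) draw ω2 ~ U(1.5, 5).
Per gene, κ ~ U(2, 3), p0 ~ U(0.5, 0.8), p2 ~ U(0.01, 0.1), p1 = 1 − p0 − p2,
and the root length in codons comes from a gamma distribution (shape 4.2,
scale 85 — a realistic gene-length distribution) rounded and
rejection-sampled into [100, 600].

**Normalization.** The three class matrices are scaled jointly by
ν = Σ_c p_c Σ_i π_i (−Q_c[i,i]), the gene's mixture expected rate, so one
unit of branch length equals one expected substitution per codon site *for
the gene as a whole*. Branch lengths are therefore directly the divergence
parameter d (baseline 0.2 per branch on the balanced 8-taxon tree rooted at
its midpoint).

**Stationary frequencies.** Codon frequencies default to uniform (1/61).
They are configurable; nothing downstream assumes uniformity. With uniform
π the generator is symmetric and the chain's stationary law is exactly
uniform, which the stationarity test exploits.

## Indel process and the event-level simulator

Indels occur in whole-codon units, preserving reading frame. Relative to
the unit-mean substitution rate, each codon site carries a total indel rate
r (baseline 0.1), split equally between insertions and deletions
(ratio 1:1). Lengths are geometric over k ≥ 1 codons,
P(k) = q(1−q)^(k−1) with q = 0.35 (mean ≈ 2.86 codons). Insertions choose
one of the L+1 inter-codon slots uniformly; inserted codons draw states
i.i.d. from π and site classes i.i.d. from (p0, p1, p2). Deletions choose a
uniform start site and truncate at the sequence end (the event still counts
once; the drawn length is logged separately from the applied length).

Each branch is simulated as an exact continuous-time event process
(Gillespie): total rate = Σ_sites substitution exit rate + L·r; event times
are exponential; event types and targets are sampled proportionally to
their rates. This costs more than endpoint sampling via the matrix
exponential, but makes event counts (substitutions, insertions, deletions)
exact observables — they are part of the package's test surface — and the
single-branch end-state distribution is verified against `expm` directly.

A global column registry tracks homology: every root site and every
insertion creates a column with a fixed position in the master ordering, so
the true alignment (and a per-column site-class annotation) is emitted
without ever running an aligner. Columns deleted from every surviving
lineage are dropped. Insertions by different lineages at the same ancestral
slot are placed adjacently in registry order; their relative order is
arbitrary, which is correct in the sense that such codons are not
homologous.

Ambiguities the simulator resolves by explicit convention (the underlying
geometric-indel literature is ambiguous on all three): lengths are in codon
units with success probability q = 0.35; the indel rate is defined against
the *normalized* (mean-1) substitution rate; inserted sites draw fresh
classes and states as above.

## Dataset assembly

Gene classes mix 40% purifying / 10% neutral / 50% positive by default, so
labels are balanced. Classes are allocated deterministically (largest-
remainder quotas, scheduled by maximum remaining deficit) so a 1,000-gene
dataset contains exactly 500 label-1 genes, and every prefix of the dataset
is approximately balanced. Each gene consumes an independent RNG substream
keyed by (master seed, gene index): datasets are reproducible and
order-independent, and any single gene can be regenerated in isolation.

## Encoding

Alignment characters map to five binary channels in the fixed order
(gap, T, G, C, A), i.e. A:00001, C:00010, G:00100, T:01000, −:10000 reading
bits left to right. `N` (accepted on read; never emitted by the simulator)
encodes as all-zero. Batch padding is also all-zero — deliberately distinct
from the gap channel, and deliberately *not* masked: the classifier sees
padding exactly as zero input, which reproduces the known depressed-saliency
artifact near the padded right edge of long batches. The record container is
a versioned binary stream (header + length-prefixed records) supporting
streaming reads.

## Classifier

Seven convolutional layers. Layer 1 applies an n×3 filter with stride 3:
one output position per codon column, seeing all n taxa — the codon
structure is hard-coded rather than learned. Layers 2–7 are width-3,
stride-1, same-padded convolutions over codon columns. Every conv layer is
followed by ReLU, batch normalization, dropout (default p = 0.5) and
width-2 average pooling (floor semantics; the pool is skipped when the
feature map is already shorter than the pool width, so short genes remain
well-defined under the 7-layer stack). Global average pooling, a ReLU dense
layer (width 64) and a single sigmoid unit produce the score Z ∈ [0, 1];
Z ≥ 0.5 is classified as positive selection (inclusive threshold).

Per-layer filter counts (default 32, 32, 64, 64, 128, 128, 256), the dense
width, and the pool width are package defaults, all configurable. Training
uses Adam (lr 0.001) on binary cross-entropy, batches of 512 alignments
zero-padded to the longest member and reshuffled every epoch, 50 epochs, a
5% validation split, Glorot-uniform initialization, and no early stopping.
An optional `shuffle_rows` flag permutes each alignment's rows per epoch,
ablating the tree information carried by the fixed row order.

The network is implemented directly in numpy (float64) with hand-written
forward/backward passes. This keeps the package dependency-light, makes
training bit-reproducible for a fixed seed, and gives exact input gradients
for saliency; the same backprop is verified against central finite
differences to 1e-3 relative error. At inference, dropout is off and batch
norm uses running statistics, and examples are bucketed by length so scores
are independent of batch partitioning. The cost is speed: this engine is
suitable for desk-scale experiments (thousands of genes), not the
million-gene full-scale profile, which is documented as a named preset.

## Evaluation

Confusion counts and rates use the inclusive Z ≥ 0.5 rule. ROC and PR
curves are built over all distinct score thresholds plus endpoints; AUCs by
trapezoidal integration, which gives tied scores half-concordance (the
Mann–Whitney convention, verified against a brute-force pairwise oracle).
The PR curve's recall→0 endpoint repeats the precision of the
highest-score point rather than forcing precision 1. Single-class truth
raises an explicit undefined-metric error instead of returning a number.
A small adapter ingests externally produced CODEML LRT p-value tables for
side-by-side comparison; no likelihood computation is performed here.

## Saliency

For an input alignment A0 the input gradient w = ∂Z/∂A |_{A0} is computed
by backpropagation (on the sigmoid output Z, pre-threshold; dropout off,
batch norm frozen), and the saliency matrix is M_ij = max_c |w_ijc| over
the five channels. The linearization's intercept is never materialized.
For comparison with per-codon site classes, the per-codon-column aggregate
takes the max over the 3 nucleotide columns and all rows (max is the
conservative aggregator; mean is available). Enrichment of saliency on S2
columns is summarized by the two group means, their ratio, a Mann–Whitney
rank-sum statistic, and a seeded column-label permutation p-value with the
add-one estimator. With no S2 columns the summary is returned as undefined
(NaN) rather than raising. The saliency–site-class enrichment statistic is
this package's own summary of a relationship that is otherwise only
inspected visually; it is not a reproduction of any published number.

## Scaled-down study conditions

The full-scale training regime (10⁶ genes, 50 epochs, batch 512, filters up
to 256) is far beyond a single-CPU test suite, so the suite demonstrates
learning at desk scale: 4,000 balanced training genes with root lengths
100–150 codons at baseline divergence (d = 0.2, r = 0.1), evaluated on
1,000 held-out genes. At this scale the full-scale defaults are mis-sized:
dropout 0.5 prevents any learning, and the default filter counts memorize
4,000 genes without generalizing. The desk-scale profile therefore keeps
the seven-convolution architecture but sets the later convolutions to
width 1 with no intermediate column pooling — making layers 2–7 a
per-codon-column feature extractor whose global average is the gene-level
evidence, the multiple-instance structure this task actually has — with
reduced filters (64, then 32), dropout 0.1, learning rate 0.003, batch 8,
20 epochs, and per-epoch row shuffling as augmentation. The discriminative
signal is real but subtle: a reference probe (logistic regression on
per-column amino-acid/codon diversity histograms) reaches held-out ROC AUC
≈ 0.86 under these conditions, and the desk-scale network reaches ≈ 0.83,
against ≈ 0.65–0.72 for width-3/pooled variants that dilute sparse column
detectors before they can be thresholded. A permuted-label control (same
data and recipe, labels shuffled) is trained alongside and must score at
chance on held-out genes, separating real signal from leakage. Passing
these tests shows the pipeline can extract a genuine selection signal from
its own simulations; it says nothing about accuracy on real genes, on
re-aligned (error-containing) alignments at full scale, or about any
trained model shipping with the package (none does).

## Numerical and degenerate-input choices

* Rejection sampling of root lengths terminates with probability 1; the
  degenerate config min = max is honored exactly.
* A lineage that loses all sites stops evolving (no re-insertion into an
  empty sequence); with root length ≥ 100 this is never observed in
  practice.
* Frequency vectors are validated to sum to 1 within 1e-9.
* Batch-norm uses eps 1e-5 and momentum 0.9 running statistics.
* The sigmoid is computed in the numerically stable split form; the BCE
  gradient is taken with respect to the logit.
* Ties in scores: half-concordance in AUC; classification is inclusive at
  the threshold.

## Known limitations

* The simulator's tree space is balanced trees with equal branch lengths
  (arbitrary Newick is parsed but topology inference is out of scope), one
  fixed genetic code, and site classes constant across branches.
* No aligner is re-implemented; external aligners are optional adapters
  (only their absence is handled gracefully) and the default pipeline uses
  true alignments.
* The numpy training engine is single-threaded; the full-scale profile is
  a documented preset, not something the test suite executes.
* Saliency is a first-order explanation; it is validated against finite
  differences and enriched on positively selected columns at desk scale,
  but no sitewise ω estimator is derived from it.
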