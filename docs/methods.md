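# Methods

## Problem setting

Metagenomic reads are short, and the genes they carry are routinely cut by
the read boundaries. `orfstack` therefore operates on candidate ORFs of
four completeness classes, scanned per (strand, frame) with codons read
5'→3' on the coding strand:

1. **complete** — first start codon after the previous stop, through the
   next stop codon inclusive;
2. **upstream-incomplete** — the frame's first codon through the first
   stop codon, when no start precedes that stop;
3. **downstream-incomplete** — a start codon through the frame's last
   whole codon, when no stop follows;
4. **both-ends-incomplete** — all whole codons of the frame, when it
   contains neither stop nor start.

Start codons default to the prokaryotic set {ATG, GTG, TTG}
(configurable); stops are {TAA, TAG, TGA}. Per stop-to-stop segment only
the longest ORF (earliest start) is emitted; nested ORFs are not. ORFs
shorter than 60 bp are discarded — shorter ORFs carry too little signal.
The ORF span includes its stop codon, and the stop codon counts in all
frequency features (the codon vocabulary is all 64 codons). Codons
containing N are kept in the span but excluded from every count; an ORF
with more than 10% ambiguous codons is dropped.

**Labeling.** An ORF is *coding* when, mapped through its fragment's
provenance to genome coordinates, it overlaps an annotated gene on the
same strand, in the same codon frame, over ≥ 80% of the ORF's length
(`min_overlap_frac`, exposed). This is a convention, not a ground truth:
ORFs extending a gene by a short in-frame head remain coding, heavily
truncated overlaps do not.

## Features

119 dimensions, fixed order `[orfc | mcu(64) | mau(21) | zcps(9) |
zcpd(24)]`; the column-name manifest is `orfstack.features.FEATURE_NAMES`.
Conventions the equations leave open, fixed here:

* all frequencies are over countable (N-free) codons, stop codon
  included in the denominator;
* codon order is lexicographic DNA (AAA…TTT); RNA codon names map U→T;
* amino acid order is alphabetical one-letter code + STOP; the MAU is
  exactly the 64→21 genetic-code aggregation of the MCU (this linearity
  is asserted in tests);
* codon phase of an incomplete ORF is defined by its own codon list (for
  an upstream-incomplete ORF the frame is anchored at its stop codon),
  not by position in the fragment;
* dinucleotide frequencies p₁₂/p₂₃ are per countable codon, so each of
  the 16-vectors sums to 1 and every Z-curve contrast lies in [−1, 1].

## Classifier

Each DSN module computes Y = Uᵀσ(WᵀX_m), where X_m stacks the raw
features, all previous modules' outputs, and a constant bias row (the
module equations carry no bias otherwise). U is solved in closed form,
ridge-stabilized with ε = 1e−8 — negligible bias, guaranteed solvability.

**Fine tuning.** The printed update rule this design descends from is
typographically garbled and, taken literally, *ascends* the minimized
objective. The contract implemented instead is unambiguous: gradient
descent on E(W) = ‖U*(W)ᵀσ(WᵀX_m) − T‖² with U*(W) the closed-form
minimizer, refit after every step. By the envelope theorem the exact
gradient of the ridge objective is

∇_W = 2 X_m [(U*(Y − T)) ∘ H ∘ (1 − H)]ᵀ,

verified against central finite differences to < 1e−5 relative error.
Steps that would increase E are halved (up to 12 times, then skipped), so
E is non-increasing by construction.

**Initialization.** The bottom module's W comes from a
Bernoulli–Bernoulli RBM (CD-1, 10 epochs, learning rate 0.1, batch 100)
trained on the features min-max scaled to [0, 1] and interpreted as
Bernoulli probabilities; the learned hidden bias becomes the bias row.
Modules ≥ 2 warm-start from the previous module's W, with the rows for
the newly stacked outputs drawn from N(0, 0.01). We tried fan-in-scaled
random initialization for upper modules first; its training error
regularly started ~60% above the fine-tuned bottom module's and 20
fine-tuning epochs did not recover, so stacking made the fit *worse*.
With the warm start each module begins at its predecessor's error and can
only improve; the empirical monotone-stacking property (E_m ≤ E_{m−1},
asserted with 1% slack on the synthetic suite) then holds strictly. It is
a property of this initialization, not a theorem.

**Scaling.** Network inputs are z-standardized per dimension; the RBM
sees the min-max image. Both affine maps are fitted on training data only
and stored in the model file (`.npz` with a JSON metadata block, format
version checked on load).

**Defaults** (the method's hyperparameters are not prescribed anywhere;
these are ours, all in `TrainConfig`): 3 modules, 128 hidden units,
fine-tune 20 epochs at η = 1e−3 with step halving, seed 0. On the
synthetic suite accuracy saturates well before these budgets; they are
sized for CPU-second training.

## Evaluation

Positive class is *coding*. TPR = TP/(TP+FN), PPV = TP/(TP+FP),
ACC = (TP+TN)/n, F1 = harmonic mean of PPV and TPR. Zero-denominator
rates are NaN with an `undefined` flag — never silently 0. Cross-
validation is stratified (training sets are balanced throughout, so folds
should be too); the reported spread is the sample standard deviation over
folds (ddof = 1). F1 is the per-fold mean of fold-level F1 values, not
the F1 of the mean rates; the two differ in the third decimal.
`average_rows` aggregates repeated-run tables the way such benchmark
tables print their average row: column means of the values and column
means of the per-run deviations.

## Synthetic data

`generate_genome` emulates a prokaryotic chromosome as alternating
intergenic gaps (i.i.d. nucleotides, uniform by default) and
non-overlapping genes on uniformly random strands: ATG + body codons
drawn i.i.d. from a 61-dim sense-codon distribution + a stop drawn from
(TAA, TAG, TGA) weights (0.6, 0.2, 0.2), lengths 90 bp + 3·Geometric
(mean 600 bp), gap lengths geometric with mean set so the expected coding
density is 0.6. The default codon bias places 80% of the mass on 8
randomly chosen codons — a deliberately strong preference.

What this world does **not** emulate: sequencing errors (the fragmenter
is error-free by design), overlapping genes, operons, GC skew and
inter-species composition differences. A green end-to-end test therefore
establishes that the pipeline is wired correctly and that the features
separate codon-biased genes from background — not that real-metagenome
accuracy is reached.

One consequence worth stating explicitly: even with a *uniform* codon
bias equal to the intergenic composition, the classes remain separable
(measured ~0.82–0.87 CV accuracy), because planted genes are long
in-frame stop-free regions and the ORF-coverage feature sees exactly
that. The genuinely signal-free null is label permutation, which sits at
chance (0.48 ± 0.06) as asserted in the test suite.

**Fragmentation** samples start positions uniformly *with replacement*
(coverage is an expectation) and randomizes the reported strand, matching
how shotgun reads arrive from either strand. N bases are accepted in
input but never generated.

## Numerical notes and limitations

* Determinism: every stochastic step flows from one `numpy` Generator
  seeded by the config; identical config + seed reproduces model files
  bit for bit.
* `fit_upper_weights` uses a Cholesky-backed solve of (HHᵀ + εI); for
  ε = 0 and rank-deficient H it may fail — tests compare against
  `lstsq` at ε = 0 on well-conditioned problems only.
* The step-halving line search never re-grows η; fine tuning is
  monotone but conservative.
* Balanced subsampling is uniform without replacement per class and
  errors out (naming the class) when a class is too small.
* The six-frame scanner emits at most one ORF per stop-to-stop segment;
  nested or overlapping same-frame gene arrangements are out of scope,
  as are translation-initiation-site rescoring and FASTQ/quality input.
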