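# Methods

## Chaos game representation and FCGR

The CGR maps a DNA sequence to points in the unit square by the iterated
midpoint rule P_i = 0.5·(P_{i−1} + corner(s_i)) from P_0 = (0.5, 0.5), with
corners A = (0,0), T = (1,0), G = (1,1), C = (0,1). Every coordinate is a
dyadic rational strictly inside (0, 1). The frequency CGR divides the square
into a 2^K × 2^K grid and counts points per cell.

Two conventions required a decision:

* **Transient points.** The cell of point i is determined by the K most
  recent bases only when i ≥ K; the first K−1 points reflect shorter
  prefixes (plus the centre offset). By default these transients are
  excluded, which makes the FCGR exactly the table of overlapping k-mer
  counts (total = L − K + 1) and gives the module a clean independent
  oracle — a naive sliding-window substring counter. The
  `include_transient` flag restores strict all-L-points chaos-game
  counting, binning transients into the half-open cell their exact
  coordinates occupy.

* **Exact binning.** Cell indices are computed from the nucleotide bits
  with integer arithmetic, which provably equals floor(2^K · coordinate)
  of the exact dyadic point. Flooring the *float* trajectory would be
  wrong: beyond ~55 bases the coordinate's low-order bits fall below double
  precision and the rounded value can land exactly on a grid line (e.g.
  the x-coordinate after `T`×60 then `A` rounds to exactly 0.5). The float
  trajectory is kept for rendering and plots only.

* **Orientation.** Row 0 is the top of the image, i.e. the high-y (C/G)
  side; columns increase toward the T/G side. The grayscale rendering maps
  the fullest cell to black: pixel = round(255·(1 − count/max)), all-zero
  grids render white, and each cell is replicated into a square pixel
  block (nearest-neighbour, deterministic). Only the direction of the
  shading and the 0–255 range are externally constrained; the linear ramp
  and block upscaling are this package's choices.

Multi-K handling: concatenated normalized vectors (length Σ 4^K) for the
vector backends; one 64 × 64 channel per K for the image backends, with
per-K models averaged ("simple averaging") by default and a single
multi-channel model as the `multik="channels"` alternative.

## Physicochemical features

Index tables are standardized per index to mean 0 / population SD 1 over
all 4^order oligos; standardization uses the population SD (one convention
had to be fixed; either satisfies the invariants). The built-in
dinucleotide table carries six helical step parameters (Twist, Tilt, Roll,
Shift, Slide, Rise in degrees/Å) compiled from crystallographic averages
with reverse-complement symmetry (Tilt and Shift change sign). The built-in
trinucleotide table carries the DNase-I-derived bendability consensus scale
and a derived step-averaged Roll. No specific index set is canonical for
this task; any tab-delimited table covering all oligos can be substituted,
and results with autocovariance features depend on the set chosen.

Autocovariance uses the per-sequence mean of the index profile and divides
each lag-d sum by the exact number of summed terms (L − order − d + 1), not
L — variants exist in the literature, so this is stated explicitly.
Ordering is index-major then lag-major, with cross-index terms (ordered
pairs, u1 ≠ u2) appended for DACC/TACC; emitted CSV headers name every
column so downstream PCA is reproducible. Dimensions: N·lag and
N·lag + N·(N−1)·lag.

The parallel-correlation pseudo compositions use
Θ(a, b) = (1/N)·Σ_u (P_u(a) − P_u(b))², averaged over all pairs at distance
j ≤ λ, combined with the oligomer frequencies through the weight w so the
vector sums to 1; defaults λ = 8, w = 0.5, matching the parameterization
used throughout the feature tables.

## Pipeline, PCA and leakage

Scaling and PCA are fit on the training fold only and applied to the test
fold. Whether the original experiments fit on all data is unknowable from
their description; the leak-free variant is the default and a
`pca_fit="all"` switch reproduces the leaky one. PCA is a full SVD of the
centered training matrix (via scikit-learn); the retained count m is the
smallest with cumulative explained-variance ratio ≥ the target rate, and a
deterministic sign convention (largest-magnitude loading positive) removes
SVD sign ambiguity. FCGR vectors, although already normalized, are
standardized like every other feature before SVM/ELM — one uniform rule.

## Classifiers

* **SVM** — RBF kernel; exhaustive (C, γ) grid scanned in order (C outer,
  γ inner) with seeded stratified internal CV on the training portion;
  ties broken by first-in-scan-order; refit on the full training fold.
  Library default grid: C = 2^−5..2^15 and γ = 2^−15..2^3 in ×4 steps.
  Decision values pass through a logistic so every backend emits
  probability-like scores in [0, 1].
* **ELM** — random Gaussian input weights and biases (seeded), sigmoid
  hidden layer (default 500 units; unconstrained externally, so
  configurable), output weights by ridge-regularized least squares
  (ridge 1e−6) against one-hot labels. With n_hidden ≥ n distinct training
  points the fit interpolates, which is tested.
* **XGBoost** — logistic-objective boosted trees, defaults 100 trees,
  depth 6, η = 0.3, fixed seed.
* **MLP** — flattened [0,1] images → three 50-unit ReLU layers → 2-way
  softmax; Adamax, lr 0.001, 5 epochs, cross-entropy (210,052 parameters
  for one 64 × 64 channel).
* **CNN** — conv(3×3, 64) + batch-norm + ReLU → 2×2/2 max-pool →
  conv(3×3, 32) + BN + ReLU → pool → FC(100) + ReLU + dropout 0.5 →
  FC(50) + ReLU + dropout 0.5 → softmax; Adamax, lr 0.001, 20 epochs.
  "Same" padding and pooling after each block give the clean
  64 → 32 → 16 map sizes and an 8192-wide flatten. Batch size 64 and BN
  momentum 0.9 are this package's defaults. Both nets are implemented
  directly in NumPy (im2col convolution, hand-written backprop, Adamax);
  dropout and batch statistics are disabled at inference, so scoring is
  deterministic, and all randomness flows from one seeded generator.

A single global seed fans out to per-stage seeds by hashing the stage name,
so any stage can be re-run in isolation with identical randomness.

## Evaluation

Stratified K-fold CV assigns each class's shuffled members round-robin to
folds (per-class counts differ by ≤ 1). Sn, Sp, ACC and MCC come from the
confusion matrix; genuinely undefined 0/0 metrics are reported as 0 with a
warning so degenerate folds do not abort sweeps (a matrix with a nonzero
MCC denominator is always evaluated by the formula, even when all
predictions are wrong and MCC = −1). AUC uses the Mann–Whitney rank form
with 0.5 tie credit. Headline numbers are computed on pooled out-of-fold
predictions — lower variance and a well-defined MCC — with per-fold metrics
retained; stratification and pooling are the package's choices where the
convention is externally unspecified.

## Synthetic data

The generator emulates two-class 147 bp sequence sets whose classes differ
in k-mer composition with a tunable effect size:

* **markov** — the negative class is an order-1 chain with uniform rows;
  in the positive class the row after C/G is tilted toward C/G and the row
  after A/T toward A/T by mixing the uniform row with a bias row
  ([0.05, 0.45, 0.45, 0.05] and its mirror) at weight `effect`. The tilt
  is symmetric, so mononucleotide composition stays near uniform and the
  class signal lives in dinucleotides and longer k-mers — K ≥ 2 FCGR
  carries much more signal than K = 1, mirroring the qualitative benefit
  of multi-K combinations.
* **periodic** — AA/TT dinucleotides planted every 10 bp with
  per-site probability `effect` in the positive class, mimicking the
  ~10 bp bendability periodicity of nucleosomal DNA; negatives are i.i.d.
  uniform.

`effect = 0` makes the classes identically distributed (chance-level
control); generation is deterministic to the FASTA byte given a seed. The
generator reproduces composition biases only — not deformation-energy
profiles, positioning-sequence grammar, or genomic background
heterogeneity — so passing tests demonstrate pipeline correctness and
sensitivity calibration, not real-genome accuracy.

## Problem sizes and defaults in the automated checks

The end-to-end check uses 500+500 sequences of 147 bp at effect 0.8 with a
3 × 3 (C, γ) SVM grid (C ∈ {0.5, 8, 128}, γ ∈ {2^−9, 2^−6, 2^−3}, internal
3-fold) — a compact grid sized for a quick, fully deterministic run; the
full exponential grid remains the library default for real analyses.
Neural-net tests use small image sets and reduced epochs; the stated
architectures are unchanged.

## Known limitations

* Published benchmark accuracies are not reproduced offline; the `repro`
  CLI verb documents the manual, network-dependent procedure.
* The exact physicochemical index sets behind published DAC/TAC results
  are unrecoverable; absolute feature values depend on the table supplied.
* The ELM output-weight solve is dense (O(n_hidden³)); hidden sizes beyond
  a few thousand are impractical.
* The NumPy CNN is CPU-bound and intended for the 64 × 64 FCGR images, not
  large image corpora.
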