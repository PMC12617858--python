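# Methods

## The obscured model

Classical genomic prediction maps a genotype's marker dosages **x** ∈ {0,1,2}ᵐ
directly to a trait value. The obscured model deliberately withholds that
information: for a query genotype A and a reference genotype B, the model sees
only the *obscured vector* v(A,B) ∈ {0,1}ᵐ with vᵢ = 1 iff A and B carry the
same code at marker i, together with B's (z-scored) trait value y_B. It is
trained to regress y_A on (v(A,B), y_B) over every ordered pair of training
individuals. Agreement is exact code equality — a heterozygote never
"partially matches" a homozygote — so v is the binary refinement of the
simple-matching similarity; its mean is the matching coefficient, and GBLUP's
genomic relationship entry for the pair is the analogous scalar summary.

The network follows the DeepGS extractor motif: the obscured bits are treated
as a 1-D signal in genomic marker order (after any selection, original column
order is preserved) and passed through

1. a bank of 8 one-dimensional convolution filters of width 18, ReLU;
2. max pooling of width 4;
3. dropout (rate 0.2) and a fully connected reduction to a 32-unit embedding
   with ReLU and dropout 0.1;
4. concatenation with the scalar y_B;
5. a two-layer estimator (33 → 32 → 1, ReLU then linear).

Training is end-to-end mean-squared-error minimization with mini-batch Adam
(step size 10⁻³, batch 64) for exactly 20 epochs. Kernel and pool widths are
clipped to the input length so the minimum practical marker count (8) remains
a valid configuration. The implementation is plain numpy with explicit
backpropagation (verified against central finite differences to ~10⁻⁸
relative error); the model is a few thousand parameters and this keeps
training bit-reproducible from (data, config, seed). All stochastic layers
are disabled at inference, which is a pure function of parameters and inputs.

Pairs are enumerated ordered and without self-pairs by default, so n training
individuals yield n(n−1) rows; both directions appear with the phenotype
roles swapped. Self-pairs (which ask the model to predict y_A from y_A)
are available behind a flag. Pair rows are materialized batchwise from
indices, never all at once.

## The ensemble

A single base model is trained once on the full training fold. Prediction for
a query genotype g averages predict(v(g, gᵣ), yᵣ) over a fixed set of
*reference instances* (gᵣ, yᵣ) from the training fold. Reference subsets are
an inference-time choice:

- **random** — uniform without replacement;
- **targeted** — candidates ranked by their mean squared error when used to
  predict every *other* training instance (self term excluded), lowest first,
  ties to the lower index.

Subset size is round-half-away-from-zero of fraction × fold size, floored at
one. The targeted profile is computed on the standardized trait scale, once
per fold, and re-thresholded per fraction.

## Feature selection

Two density-reduction steps run in a fixed order, both fit on the training
fold only:

- **Sliding-window dedup** (default w = 8): scanning left to right, a marker
  is dropped when an identical column *survives* within the previous w
  positions. Survivor-based comparison makes the scan idempotent. Note that
  survivor *sets* at different w need not nest — removing a mid-chain
  duplicate can unshield a later copy — but the survivor count is
  non-increasing and the redundant-pair count non-decreasing in w.
  "Identical" means exact column equality; a column and its allele-recoded
  complement are treated as distinct.
- **Mutual information**: the trait is discretized into 10 equal-frequency
  bins (rank-proportional, deterministic under ties) and the plug-in MI
  Σ p(x,y)·log(p(x,y)/(p(x)p(y))) over the empirical joint histogram scores
  each marker; the top k are kept, ties to the lower original index. The
  plug-in estimator was chosen over nearest-neighbour alternatives because it
  is fully deterministic and admits an exact brute-force oracle.

## Baselines

Ridge regression is solved in closed form with an unpenalized intercept.
GBLUP uses the VanRaden method-1 relationship matrix, G = ZZᵀ/(2Σpⱼ(1−pⱼ))
with Z centered by twice the training-fold allele frequencies, and a fixed
variance ratio λ in place of a REML estimate — the harness needs a
deterministic closed-form comparator, and GRM-form prediction is
algebraically identical to ridge on centered markers (kernel/primal duality,
checked to 10⁻⁸ in the tests). Random forest is a thin scikit-learn wrapper
kept for sweep completeness.

## Evaluation

Three-fold cross-validation with one shared, serializable fold plan (seeded
shuffle, round-robin; sizes differ by ≤ 1). Trait z-scores (n−1 denominator)
and feature scores are re-fit inside each training fold; all metrics are on
the standardized scale, which is why well-calibrated MSE values sit near 1
for an uninformative predictor. Every report row carries both Pearson
correlation and MSE. When predictions are constant the correlation is
reported as an explicit undefined flag, never as 0 — a compressed prediction
range is precisely the pathology the paired metrics are meant to expose, and
the train-vs-test squared-error heatmap (rows = references, columns = test
individuals) gives the per-reference view of the same phenomenon.

## The synthetic generator

The generator emulates the data shape the method assumes: n individuals ×
m biallelic markers in LD blocks, exact duplicate columns, and an additive
polygenic trait. Defaults — the package's standard study conditions — are
n = 300, m = 1000, block size 10, within-block flip probability 0.1, 20 QTL,
h² = 0.6, 5% duplicated columns within distance ≤ 8, allele frequencies
uniform on (0.1, 0.9). Each block draws a template column Binomial(2, p);
members copy it entrywise, redrawing with the flip probability, so
within-block neighbours are correlated and blocks are independent. Causal
effects are N(0,1); environmental noise is scaled against the realized
genetic variance to hit the target h². The trait is returned raw and
standardized downstream, fold-scoped, like real data.

What the generator does *not* emulate matters for interpreting results:
individuals are exchangeable draws with no families, founder/F₁ structure or
admixture, so overall relatedness carries far less information than in a real
breeding panel. The obscured model — which by construction leans on
relatedness structure — therefore attains much lower absolute held-out
correlation here (≈0.05–0.2 at the default h² = 0.6) than the ridge/GBLUP
baselines (≈0.55–0.65), while on real panels with strong population structure
the published gap is small. Passing the synthetic-data checks demonstrates
the pipeline's correctness, its plateau behaviour over reference fractions,
and the equivalence of random vs targeted selection — not a claim about the
obscured model's absolute accuracy on structured germplasm. On a
near-noiseless oligogenic trait an information ceiling is visible: agreement
bits hide *which* dosage is shared, so pair-level accuracy saturates around
the conditional-mean oracle on causal agreement patterns (≈0.44 PCC in the
shipped configuration) even though the full-reference ensemble reaches
PCC > 0.8.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at n = 300,
m = 1000 with 256 MI-selected markers feeding the network (the fold's ~40,000
ordered pairs × 20 epochs dominate runtime at roughly a minute per training
on one CPU); the plateau experiment uses one held-out fold per seed, 3 seeds
in the tests and 5 in the acceptance script. The loader is exercised at the
full published canola scale (459 × 16,166) on a synthetic stand-in.

Other fixed choices: missing marker cells are an error by default (equality-
based obscuring is undefined for missing codes), with column-mode imputation
opt-in; duplicate IDs, empty tables and non-integer codes fail loudly;
z-scoring a constant trait raises rather than returning zeros; training
raises a divergence error naming the epoch if the loss goes non-finite;
random draws everywhere go through seeded numpy generators, and reference
sets, fold plans and selections serialize to JSON so a run can be replayed.

## Known limitations

- GBLUP's λ is fixed (or grid-picked), not REML-estimated; reported GBLUP
  accuracy is therefore a lower bound on a tuned mixed model.
- The MI estimator's plug-in bias is unconcerning for ranking but its scores
  should not be read as calibrated information estimates.
- The obscured network's hyperparameters are declared defaults, not a tuned
  configuration; everything lives in `NetConfig`.
- Heterozygote phasing, dominance/epistasis simulation and multi-environment
  traits are out of scope.
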