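# Methods

## Problem and model

`epibayes` classifies tumour samples into cancer types (or subtypes) from
bulk gene-expression profiles, and attaches an *epistemic uncertainty* to
every call — the part of predictive variability that comes from not
knowing the network weights, which shrinks with more training data.  The
classifier is a fully connected network (default hidden widths 250 and
95, logistic-sigmoid activations, softmax output) whose weights carry a
mean-field Gaussian variational posterior

    q(w | δ) = ∏_j N(w_j | μ_j, σ_j²),     p(w_j) = N(0, 1),

fitted by Bayes by Backprop: stochastic minimization of the Monte-Carlo
negative ELBO

    L = (1/n) Σ_i [ κ·(log q(w⁽ⁱ⁾|δ) − log p(w⁽ⁱ⁾)) − log p(batch | w⁽ⁱ⁾) ],

with reparameterized draws w⁽ⁱ⁾ = μ + σ·ε⁽ⁱ⁾, σ = softplus(ρ), and a
categorical likelihood.  κ is the complexity-term weight per mini-batch;
κ = 1/(number of batches) recovers the exact mini-batch ELBO.

Inputs are log2(x+1)-transformed normalized counts (the Xena/RSEM
convention), stored as plain TSV/CSV with one id column; the in-memory
orientation is always samples × genes.  Missing values are rejected, not
imputed — harmonizing two cohorts drops the genes one of them lacks
(`align_features`), mirroring standard practice for cross-cohort
prediction.

## Gradients and optimization

No autograd framework is used: the gradients are derived analytically and
implemented in numpy.  For a reparameterized draw, the total μ-derivative
of log q vanishes (the density term cancels the path term) and its
ρ-derivative is −softplus′(ρ)/σ; prior and likelihood gradients flow
through the draw with ∂w/∂μ = 1 and ∂w/∂ρ = ε·softplus′(ρ).  The
likelihood gradient is ordinary backpropagation with the softmax
cross-entropy identity.  Correctness is pinned by a central
finite-difference check at fixed ε (relative error < 1e−4 in the test
suite).  Optimization is Adam (β₁ = 0.9, β₂ = 0.999) with learning rate
1e−3, batch size 128, one Monte-Carlo draw per step, 200 epochs; all
defaults configurable.  Initialization: μ ~ N(0, 0.1²), initial σ = 0.05;
the point-estimate DNN baseline (hidden 250/55, L2 weight decay 1e−4)
uses Xavier-uniform initialization.  Training aborts with a diagnostic on
a non-finite loss.  Everything is a pure function of (data, config,
seed): identical configurations give identical parameters.

### Tempered complexity weight

With N training samples far below the weight count, the untempered ELBO
optimum sits close to the prior and the classifier underfits.  Model
hyperparameters are therefore selected by five-fold cross-validation on
the training split, the package's standard tuning procedure.  For the
bundled benchmark (800 training samples, ~50k weights) this selection was
run once over κ-multipliers {1, 0.3, 0.1} × epochs {200, 400} and chose a
multiplier of 0.3 at 200 epochs (CV accuracy 0.909 vs 0.824 untempered);
that value ships in the benchmark configuration (`TrainConfig.kl_multiplier`,
default 1.0 elsewhere).  Tempered posteriors are standard practice for
variational BNNs in exactly this small-data regime.

## Uncertainty estimation

At inference, T weight draws (default T = 500; the benchmark uses 100)
produce softmax vectors p̂_t per sample.  The epistemic uncertainty is the
empirical second-moment matrix Ξ = (1/T) Σ_t (p̂_t − p̄)(p̂_t − p̄)ᵀ; its
diagonal holds per-class predictive variances, and the scalar ξ is the
diagonal entry at the predicted class (so 0 ≤ ξ ≤ 0.25).  Both are
checked against brute-force variance computations to 1e−12.

**Filtering.**  The threshold is the mean ξ of *correct training*
predictions; a test prediction is retained iff its ξ is strictly below
the threshold (boundary drops; a per-class threshold variant exists).
Reports on filtered predictions always carry the retained fraction, so
the accuracy/coverage trade-off stays visible.

**Correction.**  Per class c, ordinary least squares fits

    logit(p̄_c) = α_c + β_c·√ξ + ε,   ε ~ N(0, σ²),

over training samples predicted as c (classes with < 3 points, or no
spread in the regressor, are flagged and get β = 0).  The canonical
corrected probability subtracts the uncertainty term on the scale the
model was fitted on: p_corr = f⁻¹(f(p̄_c) − β_c·√ξ⁽ᶜ⁾), f = logit.  A
`literal` variant, f⁻¹(p̄_c − β_c·ξ⁽ᶜ⁾), applies the correction with the
mean probability untransformed and the variance to the first power; the
two are not equivalent and the canonical form is the default.

**Application scope.**  By default each class's coefficients correct the
samples *predicted as that class* — the population its regression was
fitted on — so the correction recalibrates the confidence reported with
each call.  An `all_classes` scope applies every class's coefficients to
every sample, which lets corrected calls flip; it is exposed but not
default, because subtracting β_c·√ξ from every class's logit compares
per-class fit constants rather than evidence: when a confusable class
pair has asymmetric slopes (the class predicted more often accumulates a
confident arm in its regression and hence a steeper slope), every
ambiguous sample migrates to the steeper-sloped member and that class
absorbs the whole pair.  On the bundled benchmark this collapse costs up
to 16 accuracy points; the matched scope never loses more than the
regression can justify.

## Synthetic cohorts and their oracle

`simulate.generate_cohort` emulates the statistical structure the
classifier assumes: in log2 space, class k's mean is a baseline (default
6) plus ±`mean_shift` (default 4) on the informative genes, with the sign
pattern drawn i.i.d. Rademacher per (class, gene) from the seed;
non-informative genes share the baseline; observations add isotropic
Gaussian noise (default sd 1) and clip at 0.  A confusable pair (a, b, ω)
replaces b's informative signature by (1−ω)·own + ω·a's — ω = 1 makes the
pair indistinguishable, emulating anatomically adjacent tumour types.
Class imbalance is allowed via per-class sample counts.

Because noise is isotropic and shared, the two-class equal-prior Bayes
error is Φ(−d/2) with d = ‖μ_a − μ_b‖/σ (truncation ignored; negligible
when the baseline sits several σ above 0).  The generator is validated by
comparing the nearest-true-centroid error on a large cohort against this
closed form (within 3 Monte-Carlo standard errors).

What the generator does **not** model: count-level noise
(negative-binomial dispersion), batch effects, dropout/zero inflation,
gene–gene correlation beyond the class means, and realistic library-size
variation.  Passing tests therefore demonstrate the pipeline's
statistical machinery, not performance on real RNA-seq; the accuracy
numbers on synthetic cohorts are not comparable to numbers on TCGA-scale
data.

## Feature selection

Two steps, each = PCA ranking + logistic-regression plateau search:

1. PCA (gene-wise centering, no variance scaling, up to 10 components) on
   the full matrix; genes ranked by absolute factor loading.
2. The same procedure re-run on the matrix restricted to the step-1
   genes, giving the final panel.

`pca_top_loading_genes` returns each component's top-loading genes in
component-major order.  For the count scan, genes are ranked round-robin
across components (top |loading| first within each), so a prefix of
length m approximates "m/n_components genes per component"; an L2
logistic-regression classifier (raw expression values, unit penalty —
rescaling would equalize informative and noise genes) is evaluated by
stratified k-fold CV at each count in a grid, and the smallest count
within `tolerance` (default 0.01) of the best accuracy is kept.  Default
grids scan {1, 2, 5, 10, 20, 50} genes per component.  For the bundled
marker-recovery benchmark the grids start at ~2× the planted panel size:
at near-zero Bayes error the CV trace cannot distinguish a lucky smaller
subset from the full panel, so scanning below the plausible panel size
only adds noise to the plateau choice.

The single-gene screen fits a one-gene classifier per gene under k-fold
CV and reports one-vs-rest precision/recall/F1 per (gene, class) from the
pooled held-out predictions, flagging pairs with both precision and
recall above 0.75.

## Evaluation

Confusion matrices use rows = actual, columns = predicted.  Overall
accuracy is correct/total = trace/sum.  Per-class precision, recall and
F1 are one-vs-rest; zero-denominator cases are reported as 0 with an
explicit flag rather than NaN, keeping per-class tables total.
Micro-averaged recall equals overall accuracy by construction.

## Bundled benchmark and problem sizes

The default pipeline configuration simulates 5 classes × 200 samples on
100 genes (20 informative, shift 4, noise 1) with one ω = 0.9 confusable
pair, splits 80:20 stratified, trains the BNN (and DNN/logistic-regression
baselines), and runs T = 100 Monte-Carlo iterations.  These sizes keep a
full run around 15 s on one CPU while leaving the confusable pair's Bayes
error (~10% pairwise) large enough that filtering and correction have
errors to work with.  The marker-recovery benchmark uses 10 classes × 60
samples on 2000 genes with 8 informative.

## Numerical choices

- Probabilities are clipped at 1e−12 before log-likelihoods and into
  [1e−7, 1−1e−7] before logit.
- σ = softplus(ρ) keeps scales positive under unconstrained optimization;
  softplus and sigmoid use overflow-safe forms.
- OLS uses `numpy.linalg.lstsq` on the [1, √ξ] design; residual variance
  uses n−2 degrees of freedom.
- Stratified splitting allocates per-class training counts by floor +
  largest remainder (ties broken by class order), so balanced 80:20
  splits are exact and per-class proportions are always within one
  sample of the global fraction.
- Expression tables are written with 17 significant digits so doubles
  survive the text round-trip bit-exactly.
- Seeds: every stochastic stage takes an explicit seed; the pipeline
  derives stage seeds from one top-level seed by fixed offsets.

## Known limitations

- The correction's `all_classes` scope is unstable for strongly
  confusable pairs (see above); it is retained for completeness, not as
  a default.
- The mean-field posterior underestimates weight correlations; ξ is a
  diagonal summary and ignores cross-class covariance of the draws
  (the full matrix is available via `epistemic_matrix`).
- At very small sample-to-parameter ratios the ELBO needs tempering;
  the CV-based selection described above should be re-run for cohorts of
  a different scale.
- Aleatoric (label/measurement) uncertainty is out of scope: it cannot
  be reduced by model fitting and is not modelled here.
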