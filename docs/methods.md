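# Methods

`gpbench` benchmarks algorithms that predict a quantitative trait from
genome-wide biallelic markers (genomic prediction / genomic selection).
This note records the models, the conventions adopted where several were
defensible, the numerical choices, and what the synthetic data can and
cannot show.

## Data model and conventions

A dataset is a lines × markers genotype matrix with calls coded
`{-1, 0, 1}` for `{aa, Aa, AA}`, where `A` is the reference allele when
known and otherwise the most common allele (count ties broken
lexicographically, which is arbitrary but deterministic and tested), plus a
per-line trait table. Each trait is min-max normalized to `[0, 1]` over the
full line set before splitting; because the test fraction is moderate this
leaks only the two extreme order statistics, but a strict train-only
variant is available (`normalize_phenotypes(values, reference=train_values)`
scales by the training range only) for users who want a no-leakage
guarantee. Lines missing any required trait value are dropped
from both tables. Missing genotype calls are a hard error: the pipeline
expects pre-imputed genotypes and deliberately ships no imputation.

Evaluation uses replicated hold-outs: per replicate, `floor(0.2 n)` lines
(at least one) form the test set and the rest train; a validation slice for
early stopping is carved from the training lines only. Replicate test sets
are sampled independently by default ("a different 20% each time"); a
partition mode that cycles disjoint test sets is available. Every
stochastic component receives a seed derived by SHA-256 from the master
seed and the (algorithm, trait, replicate) coordinates, so any single cell
is re-runnable in isolation and whole runs are bit-reproducible.

Comparison statistics: Pearson r and MSE on test lines only (constant
predictions leave r undefined; such replicates are recorded as degenerate
and excluded from means with a count, rather than scored 0); mean r per
algorithm × trait; "% of best r" = 100 · mean r / best mean r within the
trait; tie-averaged ranks; the variance of r across replicates; pairwise
win percentages (strict wins, ties tracked separately, so
`wins[a,b] + wins[b,a] + ties[a,b] = 100`); ensembles as the per-line
arithmetic mean over 11 members (all learners except the CNN) or a
5-member subset spanning the model families; and one-sided paired Wilcoxon
signed-rank tests (exact null when feasible) with Benjamini–Hochberg
q-values for before/after comparisons. Repeated-measures ANOVA is not
re-implemented; `BenchmarkOutput.results_frame()` exports the tidy
per-replicate table any statistics environment can consume.

## Synthetic data

The simulator generates what the benchmark needs and no more: independent
biallelic markers with per-marker allele frequencies drawn from a
configurable range (Hardy–Weinberg genotype proportions when outbred; only
homozygotes for inbred panels), additive and pairwise-epistatic trait
architectures with Normal, Laplace or sparse-mixture effect distributions,
and Gaussian environmental noise scaled so `var(g)/var(y)` hits the target
heritability in expectation. Epistasis is multiplicative between randomly
paired QTL on mean-centered marker columns, so at intermediate allele
frequencies the interaction variance is orthogonal to the additive
variance — an `epistatic_only` trait is, by construction, invisible to
additive models (tested: out-of-sample r of the best linear predictor
< 0.2).

What the simulator does **not** emulate: linkage disequilibrium (beyond an
optional crude block-copy mode with flip noise), population structure,
dominance, genotype-by-environment interaction, and the extreme
allele-frequency spectra of real panels. Real marker panels tag causal loci
redundantly through LD, which makes real datasets *easier* per marker than
independent-marker simulations at the same p:n. Tests passing on this
generator therefore validate estimator contracts and protocol integrity,
not expected accuracy on any particular crop dataset.

## Whole-genome linear models

`fit_ridge_blup` solves `y = mu + Xb + e`, `b ~ N(0, sigma2_b I)` by REML:
the marker kernel `K = XX'` is projected onto the n−1-dimensional contrast
space orthogonal to the intercept, and the restricted likelihood is
maximized over the variance ratio `delta = sigma2_e/sigma2_b` by a bounded
one-dimensional search on log delta (tolerance well below 1e-6 on the
ratio). Effects are the BLUPs `X'(K + delta I)^{-1}(y − mu)`, identical to
ridge regression at penalty delta. A constant response returns the
zero-effect fit with the constant as intercept.

`fit_bayesian_regression` implements single-site Gibbs samplers:

* **BRR** — one common marker variance (uniform shrinkage);
* **BayesA** — per-marker scaled-inverse-chi-square variances
  (differential shrinkage);
* **BayesB** — BayesA plus a point mass at zero with prior probability
  `pi_zero` (default 0.95, fixed; a Beta-updated variant is available since
  the literature is split on estimating it), sampled via the exact marginal
  Bayes factor for inclusion;
* **Bayesian LASSO** — the normal–exponential mixture of Park & Casella,
  with inverse-Gaussian updates for the local scales and a Gamma update for
  `lambda^2`.

Defaults: 12,000 sweeps, 2,000 burn-in, no thinning. Prior scales follow
the common elicitation that markers explain half the phenotypic variance a
priori (`r2 = 0.5`): with `MSx` the summed marker variances and df = 5, the
marker-variance prior mode is `var(y)·r2/MSx` (divided by `1 − pi_zero` for
BayesB), the residual prior mode `var(y)·(1 − r2)`, and the LASSO rate
starts at `lambda^2 = 2·MSx·(1 − r2)/r2`. These formulas are stated because
they are a convention, not a law; they are the scale-aware defaults users
of the standard Bayesian-regression toolboxes would recognize. Convergence
is summarized (split-chain potential scale reduction on `sigma2_e`) but not
enforced. Chains are seed-deterministic; a non-finite state raises with the
iteration index.

Correctness is established against independent oracles rather than
eyeballs: the ridge closed form against brute-force minimization of the
penalized objective (1e-8); BRR with frozen variance components against the
fixed-penalty ridge solution it is conjugate to (within Monte-Carlo error,
bounded by 4 posterior-sd-based standard errors with a conservative
autocorrelation allowance); and BayesB with `pi_zero = 0` against BayesA
(model-reduction identity). Marker-effect recovery on additive simulations
(n=1000, p=200, 20 QTL, h2=0.7) uses 4,000 sweeps / 1,000 burn-in —
posterior means of 200 effects are stable far earlier than the default
chain length, and the recovery statistic is a correlation, not a tail
quantile.

## Kernel and tree learners

SVR (linear / polynomial / RBF kernels), Random Forest and Gradient Tree
Boosting are scikit-learn estimators behind the package's uniform
fit/predict contract, with impurity importances renormalized to sum to 1.
Default search grids (overridable in configuration): SVR C on a log grid
1e-3…1e3, gamma 1e-5…1e-1, polynomial degree {2, 3}; trees max_depth
{3, 5, 10, 50} (shallow depths included deliberately — they usually win on
marker data), max_features {0.1…1.0}, GTB learning rate {0.01, 0.1};
epsilon fixed at 0.1 and 500 trees by default. rrBLUP, BRR and BL expose no
user hyperparameters — their regularization is estimated from the data.
One caveat surfaced by testing: tree importances are equivariant to marker
permutation only up to the tree builder's RNG tie-breaking, so the
equivariance test asserts rank agreement, not bitwise equality.

## Neural networks

Both networks are implemented directly on numpy. This is a design choice,
not a shortcut: the seeded-initialization procedure needs to write
first-hidden-layer weight columns explicitly, and the early-stopping and
restart rules below are exact, unit-testable functions of the validation
trace.

**Multilayer perceptron.** One to three fully connected hidden layers of
5–100 nodes (nine canonical architectures in the default grid), ReLU or
sigmoid activations, linear output, inverted dropout (grid: 10% and 50%),
L2 weight penalty, full-batch Adam on MSE. Starting weights are Xavier
draws, `N(0, 2/(fan_in + fan_out))`, biases zero. Early stopping: an epoch
counts as "flat" when the relative validation-MSE change
`|MSE_t − MSE_{t−1}|/MSE_{t−1}` is below 0.1% (the relative reading of
"change < 0.1%"; an absolute reading would depend on the trait's scale and
would never fire on [0,1]-normalized traits of typical MSE ~0.03); training
stops after 10 consecutive flat epochs, counted only after a 10-epoch
burn-in — a trace flat from epoch 5 stops at epoch 20. If the stopped
network's validation predictions are near-constant (variance below 1e-8 ×
the validation-phenotype variance) the run restarts from fresh starting
weights, at most 3 times, then fails loudly. This degeneracy is real, not
hypothetical: with thousands of input markers, ReLU networks regularly
collapse to constant output after an aggressive first step (every hidden
unit dead); sigmoid networks do not die this way, which is why the
high-dimension experiment below fixes the sigmoid activation.

**Seeded initialization.** A donor model fitted on the training lines
(ridge-BLUP, BayesB, Bayesian LASSO, or Random Forest) provides one score
per marker. The first `round(0.25 · H)` nodes of the first hidden layer
(ordering is arbitrary before training, so "the first" is as good as any)
receive that score vector as incoming weights, linearly rescaled so its
standard deviation equals that of the Xavier-initialized remainder of the
layer, then perturbed entrywise with `N(0, sd_xavier)` noise —
*multiplicatively* by default, exactly as specified by the procedure's
description. Multiplicative mean-zero noise randomizes the seed's signs
(each weight is the seed value times a symmetric-about-zero draw), leaving
mainly a magnitude pattern; because it is unclear whether that is intended,
an additive variant (`w + N(0, sd_xavier)`), which preserves ~3/4 of the
donor signs, sits behind a flag. Random-Forest importances are non-negative
and are mean-centered before rescaling (toggleable) so seeds carry sign
variation at all. Seeding only a quarter of the nodes, and noising them,
re-introduces randomness so the network is nudged toward, not locked to,
the donor's solution; a 50% seeding mode exists but is not a default (it
measurably hurts validation error). Restarted seeded runs re-seed from the
same donor scores with fresh noise.

**Convolutional network.** Markers are one-hot encoded (three channels:
aa/Aa/AA present). Fixed layer order: 1-D convolution (default 16 filters,
width 5, stride 1) → ReLU → max-pool (width 2) → dropout (0.25) → dense
(width 32, ReLU) → batch normalization → linear output. Mini-batch Adam,
batch size 100, at most 1,000 epochs, patience-10 early stopping on
validation loss with min_delta 0 (the convention of the mainstream
deep-learning toolkits, distinct from the MLP's relative-change rule), and
the same degenerate-restart policy. The convolutional defaults are
package conventions, config-overridable, searched by randomized draw when a
search is requested. All backpropagation (including through max-pool
argmaxes and batch-norm batch statistics) is verified against numerical
gradients in the test suite.

## Feature selection and the overlap null

Markers are ranked on training lines only by Random Forest impurity
importance, Elastic Net |coefficients|, or BayesA |posterior-mean effects|
(absolute values: a ranking needs magnitudes; signs are irrelevant to
selection). The Elastic Net's L1:L2 ratio starts at 0.10 and steps down by
0.02 until at least the target number of markers (8,000 canonically; 4,000
for low-marker panels) survives, with the overall penalty strength chosen
once by internal cross-validation at the starting ratio and frozen during
the loop (the ratio loop is the published procedure; the strength is not,
so it is fixed a priori rather than co-tuned). Floor at 0.02 — pure ridge
keeps every coefficient, so the loop terminates. Top-k selection breaks
score ties by original marker order (stable), making nested selections
(`top-k1 ⊆ top-k2`) exact.

The overlap null asks how many markers three independently drawn top-8,000
panels of 332,178 markers would share by chance. Rather than materialising
three 8,000-subsets 10,000 times, the intersection size is sampled exactly
by chained hypergeometric draws — `|S1 ∩ S2| ~ HG(p; k, k)` and, given the
running intersection m, `|S ∩ S3| ~ HG(p; m, k)` — which is
distribution-identical (subsets are uniform and independent, so only the
running intersection size matters) and runs in milliseconds at genome
scale. A direct subset-materialising sampler is kept and cross-checked
against the chained one on small panels. Percentiles use the inverted-CDF
convention so the reported value is an attained count. At these defaults
the null mean is `p(k/p)^3 ≈ 4.6` and the 99th percentile is 10 — the
yardstick against which observed selection overlaps (hundreds of shared
markers) are judged non-random.

## The high-dimension neural-network experiment

The headline qualitative claim — training-only feature selection rescues
the multilayer perceptron when markers vastly outnumber lines — is
packaged as `ann_feature_selection_experiment`: n=400 lines, p=8,000
markers (p:n = 20), additive h2=0.6 with 20 QTL, 10 paired simulations;
per dataset the same sigmoid network (one hidden layer of 50, learning
rate 1e-3) is trained on all markers and on the top 500 by
Random-Forest ranking, and the arms are compared by a one-sided sign test.
The trait is moderately oligogenic by design: a 500-marker panel can only
carry the signal if the signal is concentrated enough to be found at this
sample size, which is the regime in which selection can help at all;
independent markers make this harder, not easier, than LD-rich real panels.
A network still degenerate after all restarts scores r = 0 (a constant
predictor has no predictive correlation). Runtime is a few minutes on one
CPU.

## Problem sizes and tolerances

Test and driver problem sizes (hundreds of lines, tens to a few hundred
markers; 8,000 markers only where the high-dimension regime is the point)
are chosen so every Monte-Carlo check uses enough replication for its
tolerance: binomial/hypergeometric checks use 3–4 analytic standard
errors, sampler comparisons use Monte-Carlo standard errors with a
conservative autocorrelation inflation, and qualitative comparisons use
exact sign or signed-rank tests. Linear-algebra identities are asserted at
1e-8 or tighter; the seeded-weight rescaling at 1e-6; floating-point
associativity (e.g. a three-member mean of identical predictions) at 1e-14.

## Known limitations

* No LD-aware simulation; no dominance; single-environment traits only.
* The Bayesian prior-elicitation constants mirror a convention, not a
  fitted choice; sensitivity to `r2` is not explored.
* The CNN hyperparameter space is searched by randomized draw only, and
  its defaults are conventions.
* Tree-importance equivariance holds only up to RNG tie-breaking.
* The CLI covers the common paths (simulate/encode/select/train/benchmark/
  summarize/fixtures); exotic workflows are expected to use the library.
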