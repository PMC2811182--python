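# Methods

## Problem setting

A transcriptional regulatory network over `n` genes is a signed directed
graph; the task is to rank all `n(n-1)` ordered non-self gene pairs
(regulator, target) by the evidence that the regulation exists, using two
complementary data types:

- **deletion data** — steady-state expression of every gene in the wild
  type and in each single-gene deletion strain (homozygous null mutants
  and, for diploids, heterozygous single-copy deletions);
- **perturbation data** — trajectories of all genes sampled at a series of
  time points after an initial perturbation at time 0.

Deletion data expose simple, strong, direct regulation (deleting the only
activator of a gene collapses its expression). Perturbation data expose
what deletion data cannot: redundant inputs (OR-type circuits where either
activator suffices), regulators that are silent in the wild type, and
masked effects. The method learns from both and merges the predictions.
Self-regulation is excluded throughout, and no attempt is made to separate
direct from indirect regulation.

## Noise model for deletion data

Every measured level is the true signal plus zero-mean Gaussian noise with
a variance shared across genes. For gene `j` with true wild-type level
`r_j` and noise SD `sigma`, the probability that the observed level `x_ij`
in the deletion strain of gene `i` deviates as far as it does by chance is
the two-sided tail `p_ij = 2(1 - Phi(|x_ij - r_j| / sigma))`; the
regulation probability is `1 - p_ij`.

Neither `r_j` nor `sigma` is observable, so both are refined iteratively:

1. classify each off-diagonal pair at gate `alpha = 0.05`: pairs with
   `p >= alpha` join the unaffected set `U` (the gate is deliberately
   permissive so that `U` stays free of real regulation);
2. re-estimate `sigma^2` from the residuals over `U`;
3. re-estimate `r_j` as the mean of gene `j`'s levels in strains where it
   was judged unaffected, plus the observed wild type (itself an unbiased
   observation of `r_j`).

Iteration stops at a fixpoint of `U` or after 50 rounds. Per-gene sample
variances (denominator `n-1`) seed the first classification pass; the
re-estimates pool across genes, matching the gene-independent noise
assumption (a per-gene mode is available via `pool_sigma=False`).

**Selection-bias correction.** Step 2 estimates the variance from
residuals retained *because* `|z| < z_alpha`; the raw mean square of such
truncated residuals underestimates `sigma^2` by the factor
`1 - 2 z_a phi(z_a) / (1 - alpha)` (about 0.76 at `alpha = 0.05`). Without
correction the iteration is a shrink-reclassify feedback loop: a smaller
`sigma` expels more pairs from `U`, which shrinks `sigma` further; in
simulation the estimate collapsed to ~0.6-0.7 of the true SD and false
positives at the 0.99 probability cut rose several-fold. Dividing the raw
mean square by the truncation factor makes the estimator consistent; the
recovered SD is then within a few percent of truth. Even with a perfect
`sigma`, the 0.99 cut admits ~1% of null pairs by construction, so a small
number of false positives among many null pairs is expected behaviour, not
a defect.

Degenerate noiseless input floors `sigma` at 1e-8 expression units. An
empty `U` (everything looks regulated) raises an error suggesting a larger
`alpha`.

**Signs.** The default convention is biological: a deletion that lowers
the target marks the deleted gene as an activator (+1), a deletion that
raises it marks a suppressor (-1). The inverse reading is available via
`noise.flip_signs`. Signs are attached to predictions but never scored.

## Differential-equation models for perturbation data

Each target `j` is modelled by `dx_j/dt = g(x_R) - lambda_j x_j` over a
small candidate regulator set `R` with either

- linear production `g = alpha_j + sum_k beta_jk x_k`, or
- sigmoidal production `g = m_j / (1 + exp(-(sum_k beta_jk x_k + b_j)))`.

`lambda_j` is first-order decay; positive `beta` marks activation and
negative `beta` suppression. Full-network regulator sets are intractable
and over-parameterised, so the scans use single regulators and "guided"
sets (previously predicted regulators plus one candidate under test).
Pair scans over all regulator pairs are deliberately not implemented: the
extra parameters over-fit without improving ranking accuracy.

**One-step prediction.** The model is scored by one-step-ahead
prediction: from the *observed* state at each time point, one second-order
Runge-Kutta step predicts the target at the next time point, and the
objective `S` sums the squared prediction errors over all consecutive
time-point pairs of all trajectories (uniform spacing is not assumed).
Trapezoidal (Heun) RK2 is used. Because regulators are held at their
observed values within a step and the target never regulates itself, the
production term is constant within a step and the update collapses to the
closed form

    pred = x + h (1 - h*lambda/2) (g - lambda x),

which makes `S` exactly differentiable: the gradient and Hessian with
respect to the parameters are assembled analytically (verified against
central finite differences to relative error below 1e-5). Predictions are
floored at zero — expression is a concentration — and floored steps
contribute zero derivative (a subgradient choice; fitting instances keep
states positive, where the floor is inactive).

**Fitting.** `S` is non-convex; it is minimised by safeguarded Newton
descent from random restarts (weights and bias ~ Uniform(-1, 1), rates and
decay ~ Uniform(0, 1); the ranges are a pragmatic choice for expression
data on an O(1) scale). A non-positive-definite Hessian is damped to
positive definiteness from its smallest eigenvalue (`H + mu I`), every
step passes a backtracking line search, `lambda` and `m` are projected to
be nonnegative, and a restart stops when the relative improvement in `S`
falls below 1e-10 or after 100 iterations. All restarts run as one
vectorised batch. Restart draws are keyed by (target, candidate, base-set
size), so scan results are independent of iteration order and a guided
scan with an empty base reduces bit-exactly to the single scan. The
canonical restart count is 100; the pipeline default is 20, which on the
benchmark sizes used here finds the same minima in almost all fits (the
`n_restarts` flag restores 100).

**Flagging.** Within one target's candidate scan of one model type, a
candidate is flagged when its `S` lies more than two *sample* standard
deviations below the mean of that scan. Pooling per target keeps targets
with different expression scales comparable. Fewer than three candidates,
or zero spread, flags nothing.

## Combining predictions: seven batches

Pairs are assigned greedily, each to the first batch whose criterion it
meets:

| batch | criterion | within-batch order |
|---|---|---|
| 1 | homozygous regulation probability > 0.99 | probability desc |
| 2 | flagged by BOTH single-regulator model types | mean per-type z-score of -S desc |
| 3 | flagged by BOTH guided model types | as batch 2 |
| 4 | flagged by exactly ONE single model type | flagging model's -S desc |
| 5 | flagged by exactly ONE guided model type | as batch 4 |
| 6 | hom AND het probability > 0.95 with agreeing signs | min(hom, het) probability desc |
| 7 | everything else | homozygous probability desc |

The guided scans' base regulator sets are the regulators each target
acquired in batches 1-2 of a preliminary assembly (computed once, not
iterated). Batch 2/3 must merge two incommensurable `-S` scales; averaging
per-type z-scores is one defensible choice and is the only place a scale
convention was invented. Ties break by homozygous probability, then
lexicographic pair order, so output is fully deterministic. Without
heterozygous data batch 6 is empty (with a warning) and nothing else
changes. `swap_batches` re-runs the greedy assignment under any
permutation of the seven criteria, which supports the ablation that swaps
the deletion-driven and perturbation-driven first tiers.

## Synthetic benchmark generator

`simulate.generate_benchmark` produces a signed random network, its hom /
het deletion steady states, perturbation trajectories, and the gold
standard, with the structure of the in silico challenge benchmarks:

- dynamics `dx_i/dt = m_i g_i(x) - lambda_i x_i` with sigmoidal
  production; per-target gates combine multiple regulators additively
  inside one sigmoid (SUM), or as max/min of per-regulator sigmoids
  (OR/AND). OR gates manufacture exactly the deletion-invisible redundant
  activators that motivate the perturbation models;
- defaults: edge density 0.15 (10-gene scale), activator fraction 0.75,
  gate mix 80% SUM / 20% OR, `m, lambda ~ U(0.5, 1.5)`, weight magnitudes
  `U(2, 4)` (clearly saturating regulation), biases centring genes
  mid-range, measurement noise SD 0.025, 4 trajectories of 21 points at
  `dt = 0.25`. These are plausible stand-ins chosen once, not calibrated
  to any published dataset; all are configurable;
- homozygous deletion clamps the gene at zero; heterozygous deletion
  halves its maximum production rate (gene dosage);
- steady states integrate the ODE until the sup-norm of `dx/dt` drops
  below 1e-9 (non-convergence within the time budget raises, as happens
  for oscillatory networks); trajectories start from the wild-type steady
  state perturbed multiplicatively (lognormal, unit log-SD);
- measurement noise is iid additive Gaussian, clamped at zero.

What the generator does *not* emulate: module-extraction topologies from
real organisms, stochastic (SDE) kinetics, gene- or experiment-specific
error structure, and microarray normalisation artefacts. Passing tests on
these benchmarks therefore demonstrate correctness of the machinery and
recovery under the model's own assumptions, not performance on real
microarray data.

## Evaluation

AUROC (trapezoidal) and AUPR (step-wise summation) score the full ranking
against the gold standard, signs ignored. Empirical p-values come from
uniform random permutations of the ranking with the add-one estimator
`(1 + #{metric >= observed}) / (B + 1)`, which never returns 0; the
canonical `B` is 100,000, configurable down for desk scale. (Permuting the
ranking or the gold labels gives the same null; ranking shuffles are
used.) Across five networks of one size the p-values aggregate by
geometric mean, and the overall score is `-(1/2) log10(pbar_AUPR *
pbar_AUROC)`.

The per-batch accuracy table counts (predicted, correct) per batch with a
Total row; totals always equal `n(n-1)` and the gold edge count. Whether
batches 2-6 rescue more of the edges missed by batch 1 than chance is an
exact hypergeometric upper tail `P(X >= c)` with population = pairs *not*
predicted in batch 1, successes = true edges missed by batch 1, and draws
= predictions of batches 2-6.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on simulated data:
ten 10-gene benchmarks at default noise for the end-to-end recovery check
(pipeline restarts 20), and single 50- and 100-gene runs at one restart
with shorter trajectories for the ranking-size conservation checks — the
partition size being verified is independent of restart count. These sizes
are the package's own desk-scale choices; the method itself has no size
limit beyond compute.

## Known limitations

- Indirect regulation is reported as regulation; chains inflate batch-1
  false positives exactly as the underlying method intends.
- The noise model assumes a single global Gaussian noise scale; strongly
  heteroscedastic data would need the per-gene mode or an external error
  model.
- One-step prediction conflates model misfit with trajectory measurement
  noise at the prediction seeds; objectives are comparative, not absolute
  goodness-of-fit statistics.
- The 0.99 / 0.95 / 2-SD / 0.05 thresholds are the method's constants,
  exposed in `RunConfig` but not learned from data.
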