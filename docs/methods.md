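# Methods

This note documents the models and procedures implemented in `chemuq`, the
numerical choices behind them, what the synthetic data does and does not
emulate, and the problem sizes the test suite and `scripts/acceptance.py`
use.

## Data model and splits

Compounds are binary fingerprint vectors: hashed circular fingerprints of
radius 3 folded to 32768 bits (RDKit Morgan generator, counts binarized,
0-based bit indexing). Activity labels are {0,1}; when a continuous pIC50
column is supplied, label = 1 iff pIC50 ≥ threshold (the boundary is
inclusive — the convention is a package choice since only the thresholds
themselves are standard). Rows whose fingerprint is all-zero are dropped
with a warning (Tanimoto similarity is undefined for empty bit sets).

Cross-validation folds must separate chemical series, not just compounds.
We use single-pass leader (sphere-exclusion) clustering: compounds are
visited in a seeded random order; each joins the first existing cluster
whose *leader* (founding compound) has Tanimoto similarity ≥ t (default
t = 0.6, configurable — the literature does not fix a single value), else
it founds a new cluster. Consequences that the tests verify: every member
is within 1 − t of its leader, and leaders are mutually < t similar.
Whole clusters are then assigned to 5 folds by greedy balancing (largest
cluster first, to the currently smallest fold, ties between equally small
folds broken by a seeded draw). Pure random cluster assignment can produce
badly unbalanced folds under heavy-tailed cluster sizes; the greedy rule
keeps fold sizes within one cluster of each other while remaining random
over ties. A split uses 3 folds for training, 1 for validation (early
stopping, hyperparameter and prior tuning, Platt fitting) and 1 for
testing.

## Baseline network

Two layers: `logit = W2 · ReLU(W1ᵀx + b1) + b2`, dropout between the
layers, sigmoid output. Implementation is NumPy/SciPy with sparse input
matrices. Choices:

- **Optimizer** Adam (β₁ = 0.9, β₂ = 0.999), minibatch size 128, seeded
  shuffling. Weight decay is decoupled (applied multiplicatively to W1, W2
  after each Adam step, not to biases).
- **Initialization** fan-in-scaled uniform U(±1/√fan_in) for all
  parameters, seeded per repeat.
- **Early stopping** validation BCE evaluated each epoch; default patience
  10 (patience is clamped to the epoch budget); the best-validation
  snapshot is restored, never the last epoch.
- **Dropout** inverted scaling at training and at stochastic inference
  (survivors divided by 1 − rate), so the deterministic pass needs no
  rescaling and MC dropout reuses the same code path.
- **Probability clipping** ε = 10⁻⁷ on every probability output keeps BCE
  and logit transforms finite.

## Uncertainty quantification

All three methods approximate the posterior predictive by a sample
average p(y|x,D) ≈ (1/M) Σₘ p(y|x,θₘ), averaged in **probability space**
(an average of sigmoids, not a sigmoid of an average). MC dropout draws M
stochastic forward passes (default 100); deep ensembles train M networks
from different seeds on identical data (default 50, no bagging); HBLL
samples last-layer weights by HMC (below). The only logit-space operation
in the package is the Platt-stacking interface, which logit-transforms the
*mean* probability because an averaged-probability model exposes no other
ensemble-level logit.

## HMC Bayesian last layer

Given a trained network, the hidden activations H of the training folds
are frozen and a Bayesian logistic regression is placed on them:
prior w ~ N(0, τ⁻¹I) over all h+1 parameters (the bias included — one
scalar knob), likelihood Bernoulli(σ([H|1]w)). The log posterior, its
gradient and its negative Hessian `[H|1]ᵀ diag(σ(1−σ)) [H|1] + τI` are
analytic.

- **MAP** damped Newton with step halving; the objective is strictly
  concave for τ > 0, so the optimum is unique. Convergence at relative
  gradient norm 10⁻⁶; failure raises with diagnostics.
- **Preconditioning** the *mass matrix* is the MAP Hessian: momenta are
  drawn from N(0, Hessian) (via its Cholesky factor, with a one-shot
  10⁻⁸·I jitter if factorization fails) and positions update through
  Hessian⁻¹. In the quadratic approximation this makes every posterior
  direction oscillate at unit frequency, which is what makes a fixed
  (L, ε) workable without adaptation. The orientation matters: feeding the
  Hessian into the *position* update instead would amplify the posterior's
  anisotropy (frequencies λᵢ rather than √λᵢ) and stall mixing — the test
  suite checks the lag-1 autocorrelation improvement on an
  ill-conditioned Gaussian explicitly.
- **Sampler** vanilla HMC, one chain, leapfrog with L steps of size ε and
  a Metropolis accept/reject on the total energy error. Defaults mirror
  the study protocol (500 burn-in, 1000 retained, L = 1200, ε = 0.01); the
  tests and the acceptance script shrink to L ≈ 10–25, ε ≈ 0.2 with a few
  hundred samples, which in the preconditioned frame yields acceptance
  rates ≥ 0.98 in seconds. Non-finite trajectories are rejected and
  counted; more than 50% divergence aborts with an error. No NUTS and no
  step-size adaptation by design.
- **Prior tuning** τ is selected on the validation fold over a log-spaced
  grid (default 10⁻³…10³, 7 points) by validation BCE (the selection
  metric is configurable; BCE is the default because it is the proper
  score the network itself optimizes). Ties prefer the larger τ (stronger
  regularization). The study engine tunes τ once on the first repeat's
  network and reuses it across repeats: the protocol tunes the prior per
  model type, and per-repeat re-tuning would multiply the HMC cost by the
  grid size for no change in the comparison.

Predictions average σ([H|1]wₘ) over the retained draws; by Jensen's
inequality they are never more extreme than the MAP plug-in prediction
(beyond Monte Carlo error), which is exactly the pull-toward-0.5 that
repairs overconfident baselines.

## Platt scaling

`p = σ(a·z + b)` fitted by unregularized maximum likelihood (mean BCE) on
the validation fold — a 2-parameter convex problem solved with BFGS from
(1, 0); a cross-check against scikit-learn's unpenalized logistic
regression is part of the suite. A slope a ≤ 0 triggers a warning, not an
error. Optional classic target smoothing ((N₊+1)/(N₊+2), 1/(N₋+2)) is off
by default. With a > 0 the map is strictly monotone, so AUC is preserved
exactly; the fit can always return (1, 0), so calibration-set BCE never
degrades.

## Metrics

- Binned calibration error CE = (1/N) Σ_b n_b |acc(b) − conf(b)|.
  **ECE**: B fixed-width bins, half-open [k/B, (k+1)/B), last bin closed.
  **ACE**: rank-based equal-count bins (sizes differing by at most one),
  with tied prediction values coalesced into the bin of their first sorted
  occurrence — without tie coalescing a constant base-rate predictor, which
  is perfectly calibrated, would be charged a spurious error. B defaults
  to 10 (the dominant convention); all study metrics share one binning
  config. Empty bins contribute zero.
- Brier decomposition (binned Murphy form): REL = (1/N)Σ n_b(conf−acc)²,
  RES = (1/N)Σ n_b(acc−ȳ)², UNC = ȳ(1−ȳ) with ȳ the empirical base rate
  of the evaluated set. REL − RES + UNC = BS exactly when predictions are
  constant within bins; otherwise the within-bin variance/covariance terms
  account for the gap (verified in the tests).
- AUC is the Mann–Whitney statistic (ties ½; scikit-learn backend), BCE
  uses natural log on clipped probabilities. Model comparisons use
  two-sided t-tests at p = 0.05: paired between the baseline and its
  modifications (which share base-model seeds), Welch-unpaired otherwise;
  zero-variance paired differences raise a degenerate-test error rather
  than reporting a meaningless p.

## Synthetic data

`gen_fingerprint_dataset` emulates the statistical skeleton of assay
extractions: sparse binary rows (~40 bits of 1024 by default), cluster
structure (each cluster has a bit template; members copy template bits
with probability `within_cluster_overlap` plus Poisson-distributed private
bits), and a logistic ground truth: sparse Gaussian weights rescaled to a
fixed logit spread, intercept solved by bisection so the mean true
probability hits the target active ratio (defaults 0.25; assay extractions
range from ~0.08 to ~0.26), labels Bernoulli with an optional seeded flip
(default 5%). It does **not** emulate chemotype-activity correlation
beyond what the shared bits induce, assay noise heterogeneity, or the
32k-bit dimensionality of real fingerprints — so passing tests demonstrate
correct machinery and reproducible qualitative behaviour, not performance
on real assay data.

`gen_miscalibrated_predictions` draws latent calibrated probabilities from
a Beta matched to the base rate (concentration 2, dispersed so every bin
is populated), labels from those probabilities, and reports
σ(logit(p)/T): T < 1 overconfident, T > 1 underconfident, T = 1 calibrated
by construction. The maximum-likelihood Platt slope on such a stream is T
itself, which is what the recovery tests assert.

## Replicated experiments and problem sizes

- **Selection experiment** (`selection_metric_experiment`): 10 replicates;
  each draws a fresh dataset (1200 compounds, 256 features, 60 clusters,
  strong signal, 10% label noise), pits an over-capacity config (hidden
  1024, no dropout, no weight decay) against a strongly regularized one
  (hidden 32, dropout 0.7, weight decay 10⁻³), selects by repeat-averaged
  validation BCE and by validation accuracy (3 repeats), and compares the
  repeat-averaged test ECE of the two selections. The claim checked is
  directional: the BCE-selected config's test calibration is at least as
  good in ≥ 7/10 replicates. The mechanism at this scale: validation BCE
  tracks test calibration; accuracy is blind to it, so when the two
  metrics disagree the accuracy pick is at best a coin flip.
- **Stacking experiment** (`stacking_experiment`): (a) Platt-stacking an
  overconfident averaged-probability stream (T = 0.5, n = 50 000) must
  strictly reduce test ECE; (b) an HBLL fitted on 3000 synthetic compounds
  (validation-tuned τ) is already calibrated, and stacking must move its
  test ECE by less than the binning noise bound 0.4·√(B/n_test) — the
  expected ECE of an exactly calibrated predictor under B bins, from
  E|Binomial noise| per bin.

These sizes keep the whole suite and the acceptance script at a few
minutes each on one CPU; the package-level defaults (50 ensemble members,
100 dropout passes, L = 1200, 32k-bit fingerprints, the full τ and HP
grids) remain the configuration a full-scale study would run.

## Known limitations

- The MLP is CPU-bound NumPy; it is adequate for desk-scale studies and
  tests, not for multi-million-compound screens.
- Single-chain HMC with fixed (L, ε) relies on the Hessian preconditioner;
  severely non-Gaussian last-layer posteriors (tiny n, huge h) may need
  smaller steps. Multi-chain support exists for diagnostics only.
- ACE tie handling makes the ACE of heavily quantized prediction sets
  depend on the coalescing rule; any alternative convention changes the
  error for tied streams.
- Platt stacking fits on the validation fold; under strong cluster shift
  between validation and test folds the transferred calibration map can be
  slightly off (visible as the small ECE movement the stacking experiment
  bounds).
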