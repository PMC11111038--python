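# Methods

`affectgcn` implements a small-data pipeline for predicting which patients
with a history of depressive symptoms are likely to intensify their negative
affect in the near term, using nothing but short experience-sampling (ESM)
mood logs: six feelings (angry, fearful, sad, event pleasantness, cheerful,
relaxed) rated 1–7 at ten beeps per day over six days.

The pipeline has five stages:

1. **Network construction.** Days 1–5 of each patient's log are reduced to a
   6×6 signed, directed lag-1 coefficient matrix by multilevel vector
   autoregression (VAR).
2. **Labeling.** Day 6 supplies a binary outcome via the IDF ratio
   (intensification of depression-related feelings).
3. **Augmentation.** The 126 labeled networks are expanded ~50× by bounded
   uniform edge jitter.
4. **Classification.** A graph convolutional network (GCN) predicts the label
   from each network plus its node features.
5. **Evaluation.** Augment → 5-fold CV → confusion metrics, repeated many
   times and averaged.

## Multilevel VAR

For each outcome feeling *j* a linear mixed model is fitted across all
patients *i* and within-day consecutive beep pairs *t−1 → t*:

y_ijt = (a_j + u_ij) + Σ_k (Φ_jk + b_ijk) · y_ik,t−1 + ε_ijt

with a random intercept and six random slopes per subject. A patient's
network is A_i = Φ + b_i (fixed effects plus the predicted BLUP deviations),
so edge (j, k) is the subject-specific lagged effect of feeling *k* on
feeling *j*.

Modeling choices:

* **Lag convention.** Pairs are formed only between consecutive beeps of the
  same day. Overnight gaps are many hours long; carrying lag-1 structure
  across them would mix time scales. Day ranges and the minimum usable rows
  per patient (default 8; sparser patients are excluded with a warning) are
  configurable.
* **Diagonal random-effects covariance.** Seven random terms per outcome
  with a free 7×7 covariance is badly overparameterized at ~45 rows per
  subject; the diagonal structure keeps the REML problem estimable.
* **Estimation.** REML via `statsmodels` MixedLM, one model per outcome.
  L-BFGS is run first and its solution is then refined with derivative-free
  Powell iterations: on this variance-component surface the gradient-based
  stop can report convergence while the fixed effects are still ~0.03 from
  the optimum (visible as disagreement with pooled OLS in the
  no-heterogeneity case, where REML fixed effects must essentially coincide
  with OLS). A fit that ends neither converged nor near the pooled-OLS
  reference raises. One 126-patient cohort (≈5,700 rows × 6 outcomes) fits
  in ~2–3 minutes on one CPU.
* **Predictors are entered raw**, with the subject random intercept
  absorbing level differences; person-mean centering is available behind a
  flag (`center=True`) for sensitivity analyses.
* **Node features** default to each node's own feeling mean over days 1–5.
  The alternative reading — only negative-feeling nodes carry features —
  is available via `negative_only=True`.

## IDF labeling

IDF = (mean of all non-missing negative-feeling ratings on day 6) /
(the same mean over days 1–5). All beeps × the three negative items pool
into a single mean on each side, which is the simplest reading of
"day-6 negative affect over the 5-day average". A patient is labeled 1 when
IDF **strictly** exceeds the case threshold (ties → 0). The three standard
cases use thresholds 1.0, 1.2 and 1.5; any threshold ≥ 1 is accepted.
Raising the threshold can only shrink the labeled-1 share — this
monotonicity is property-tested.

## Augmentation

Each edge value *a* receives independent additive noise drawn from
Uniform(−0.01·|a|, +0.01·|a|) (bound configurable in (0, 1]). Using |a|
makes negative edges jitter symmetrically, zero edges stay exactly zero, and
no edge can change sign for bounds < 1. Node features and labels are copied
verbatim — only edges are perturbed. With the default factor 50 and
originals included, 126 patients yield exactly 6,300 graph samples; the
factor and whether originals are kept are configurable.

## GCN classifier

The classifier is a dense NumPy GCN (6-node graphs make GPU frameworks
pointless here) wrapped as a scikit-learn estimator over flattened
(n, 42) arrays — 36 adjacency entries plus 6 node features:

* Adjacency normalization (default `signed_rownorm`): self-loops are added
  and each row is divided by its absolute sum, preserving the sign and
  direction information of the VAR coefficients. `abs_rownorm` and the
  textbook symmetric normalization of |A+I| are provided for ablation.
* Propagation: H⁽ˡ⁺¹⁾ = σ(Â H⁽ˡ⁾ W⁽ˡ⁾ + b⁽ˡ⁾) with sigmoid hidden units
  (ReLU optional), two layers of width 16 by default.
* Readout: mean over the six node embeddings, then a sigmoid head; the
  graph-level output is exactly invariant to node relabeling.
* Training: binary cross-entropy, mini-batch RMSprop (ρ = 0.9, lr 0.001 by
  default), Glorot initialization, all randomness seeded. Gradients are
  hand-derived and verified against finite differences.
* **Feature scaling.** Node features are mapped affinely from the 1–7
  Likert range to [0, 1] (`feature_scaling="likert"`). Z-scoring is
  available but not the default: it centers the (often nearly constant)
  Likert means at zero, and since the features are the only input the
  propagation step can spread, a centered H⁰ leaves Â with almost nothing
  to act on — empirically the network signal becomes unlearnable. A fixed
  affine map keeps the constant component that carries Â's row structure
  into the readout and is data-independent, hence leak-free across CV
  splits.

Ties at probability 0.5 are classified 0.

## Evaluation protocol

One repetition: re-augment the original labeled networks with a
repetition-specific seed, split the pool into k = 5 folds, train on 4/5 and
predict the held-out fold, accumulating a single confusion matrix across the
five folds. The protocol runs 150 such repetitions by default and reports
the arithmetic means of per-repetition accuracy (%) and F1 — the mean *is*
the aggregate, with no reweighting.

Two fold schemes are implemented because they answer different questions:

* **pooled** (default) shuffles all augmented samples before splitting.
  Replicates that differ from a training sample by ≤1% per edge routinely
  land in the test fold, so pooled scores measure the reference protocol —
  *including* its replicate leakage — not generalization to new patients.
* **grouped** confines all replicates of a patient to one fold and is the
  recommendation for honest generalization estimates. On synthetic cohorts
  pooled ≥ grouped in expectation, and the package asserts this leakage
  direction as a one-sided check.

A permutation null (`shuffle_labels=True`) randomly permutes the labels of
the augmented pool each repetition; a sound protocol must then fall back to
the majority-class rate. Shuffling is at the sample level deliberately:
patient-level shuffling leaves replicate leakage intact and would conflate
the null check with the leakage comparison.

Degenerate confusion ratios follow the zero convention (precision, recall
and F1 are 0 when their denominators vanish), matching scikit-learn's
`zero_division=0`.

## Synthetic cohorts

The generator emulates the reference sampling design: 126 patients × 6
days × 10 beeps × 6 feelings on a 7-point scale. Latent affect follows a
per-patient VAR(1); subject heterogeneity adds i.i.d. N(0, sd²) deviations
to every coefficient; innovations are Gaussian. The chain restarts from its
stationary mean at each day boundary, mirroring the within-day lag
convention of the estimator. Ratings are produced by a fixed affine map —
scale midpoint 4 plus the latent deviation from the base stationary mean —
rounded and clamped to [1, 7]; with the default innovation SD of 1 the
stationary SD is ≈1.05, so ±3 SD spans the scale and clamping affects <1%
of ratings. Missingness is completely at random.

Defaults: lag matrix with 0.3 autoregression, +0.1 within-polarity and
−0.1 cross-polarity cross-lags (spectral radius 0.8, qualitatively an
empirical affect network: inertia, amplification within negative/positive
affect, damping between); intercepts 0; slope SD 0.05; 30% of patients
"prone" with a +1 latent-unit (≈ +1 Likert point) day-6 shift of the
negative feelings.

Two optional planting fields differentiate prone patients *before* day 6,
so that end-to-end learnability can be tested: `prone_autocorr_shift` adds
to the negative feelings' autoregressive coefficients (a denser, more
self-sustaining negative-affect loop — the classic network signature of
depression vulnerability), and `prone_baseline_shift` adds a tonic
elevation of negative affect on all days (which cancels out of the IDF
ratio but separates the node features). Both default to 0.

What the generator does **not** emulate: circadian and weekday structure,
informative missingness, floor effects of healthy scales (real negative
affect is right-skewed near 1, ours is symmetric around 4), treatment
effects, and item-specific measurement error. Passing tests therefore show
that the pipeline recovers structure it is pointed at under its own
assumptions — not that the reference study's accuracy figures transfer to
any real cohort.

## Numerical notes and scaled test conditions

* Likert rounding is classical measurement error: it attenuates estimated
  lag coefficients by roughly var(latent)/(var(latent)+1/12) ≈ 7%. At the
  recovery-test scale (126 patients × 50 beeps) this bias plus sampling
  noise keeps every fixed effect within ±0.05 of truth.
* Repetition seeds derive as `(protocol.seed + repetition) mod (2³¹−1)`;
  identical configuration and seed reproduce every artifact byte-for-byte.
* The acceptance/learnability experiments run a scaled protocol chosen for
  desk-scale iteration: 20 repetitions, augmentation factor 10 and GCN
  epochs 100 at RMSprop lr 0.01 — the learning rate is 10× the reference
  value to pair with the 10× smaller pool, keeping the total optimization
  budget per fold comparable to the full 6,300-sample, lr-0.001 protocol.
  Measured on the planted cohort: pooled 81.4% vs a 59.5% majority
  baseline, grouped 77.4%, shuffled-label null exactly at the baseline.
* Equivariance caveat: refitting after a relabeling of the feelings
  reproduces permuted networks only to the optimizer's stopping tolerance
  (~10⁻³), because Powell's coordinate search is not permutation-symmetric.

## Known limitations

* The pooled protocol's scores should never be quoted as generalization
  performance; use `split_mode="grouped"`.
* With 7 random-effect variances per outcome at n = 126, variance
  components are weakly identified; fixed effects (the network backbone)
  are robust, but individual BLUP deviations are strongly shrunken and
  their variances should not be interpreted.
* IDF pools all beeps into one mean per side; patients with few day-6
  beeps get noisy labels, and the package does not model that noise.
* The GCN sees one scalar feature per node; richer node features (e.g.
  variances, instability measures) are out of scope.
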