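# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of the package. Nothing here reports an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task structure

Eight stimuli are the complete factorial of three binary attributes. Three
classification rules split them 4/4: the value of attribute 1 (*low*
complexity), the exclusive-or of attributes 2 and 3 (*medium*), and
three-way parity (*high*). Each problem is learned over 4 functional runs
of 32 trials (8 stimuli × 4 repetitions, pseudo-randomized so every
16-trial sub-block shows each stimulus twice). Trial timing: stimulus
3.5 s, fixation jittered 0.5–4.5 s, feedback 2 s, inter-trial fixation
jittered 2–6 s, all on a 0.5 s grid, within a 388 s run. Jitter
distributions are uniform over those windows; the underlying study states
only that timing was jittered, so the shape is an assumption. The window
defaults follow the timing that is jointly consistent with 32 trials in
388 s. The high-complexity problem is scheduled first, with low/medium
order counterbalanced across participants, and physical features are
permuted onto abstract attributes per participant (fixed across problems).

## The learning model

SUSTAIN represents category knowledge as clusters. With stimuli encoded as
per-attribute one-hot pairs and `mu_ij` half the city-block distance
between stimulus and cluster *j* on attribute *i*, cluster activation is

    act_j = sum_i lambda_i^gamma exp(-lambda_i mu_ij) / sum_i lambda_i^gamma

Clusters compete by lateral inhibition: the winner's output is
`act^beta / sum(act^beta) * act`; category evidence is the winner's
association-weight vector scaled by this output, and the response follows
an exponential (Luce) rule with consistency `d`. Supervised learning:

- recruit a new cluster at the stimulus when the winner predicts the wrong
  category or its activation falls below the threshold `tau_h` (and on the
  first trial);
- otherwise move the winner toward the stimulus at rate `eta`, update its
  association weights by a humble-teacher delta rule at rate `eta`, and
  step each tuning `lambda_i` along the receptive-field gradient
  `eta * exp(-lambda mu) (1 - lambda mu)`, clamped at zero.

Free parameters and fitting bounds: `gamma` ∈ [0, 20], `beta` ∈ [0, 20],
`eta` ∈ [0, 1], `d` ∈ [0, 30], `tau_h` ∈ [0, 1]. Defaults are the mean
fitted values reported for this paradigm (γ = 8.96, β = 1.51, η = 0.08,
d = 17.04, τ_h = 0.11), which the synthetic-data generator also uses.

Design choices where the formulation is open:

- **Winner ties go to the most recently recruited cluster.** When class
  rules change between problems, a fresh cluster recruited at an
  already-occupied position ties the stale cluster at activation exactly 1;
  breaking ties toward the newest cluster lets relearning proceed (the
  alternative, lowest index, deadlocks every problem after the first).
  Both rules are deterministic.
- **Zero clusters (or d = 0) → chance responding** [0.5, 0.5].
- **A tie in association weights does not count as a misprediction**, so a
  freshly recruited cluster is not duplicated on its next appearance.
- **Probability floor 1e-6** per trial in the likelihood; negligible at
  fitted consistency values.
- **Initial tunings λ = 1 on all attributes**; the scale is absorbed by γ.

The likelihood of a participant is the product over responded trials of the
probability that the model emits the participant's response, with model
state carried across the three problems in the experienced order; trials
without a response are excluded from the likelihood but still drive
learning, since feedback was displayed regardless. Fitting maximizes this
by differential evolution (seeded, Sobol initialization). The package's
documented fitting budget is popsize 10, up to 60 generations; this is also
the budget of the parameter-recovery test. The attention trajectory is the
per-trial λ vector from replaying the experienced trial order at the best
parameters.

**Identifiability caveat.** On single-participant data (384 trials), `eta`
trades off against `tau_h` and `d`: a high-threshold, fast-learning
"memorization" configuration can fit one stochastic realization slightly
better than the generating parameters. Exhaustive optimization therefore
tends to inflate `eta` on some replicates; the recovery study in the
acceptance suite quantifies this at the documented budget. Conclusions
about individual parameter values from single-participant fits should be
drawn cautiously.

**Carryover dynamics.** With full state carryover and the parity problem
first, the model often ends problem 1 with clusters exactly on the stimuli.
The receptive-field gradient at distance zero is `+eta` on every attribute,
so tunings then grow equally and attention compression stays near zero in
later problems. Fresh-state runs show the classic behavior (the
unidimensional problem is solved by two clusters with strongly concentrated
attention). For this reason the learning-curve complexity ordering and the
attention-concentration properties are asserted on fresh-state simulations,
one problem at a time; this is a genuine property of the model under this
design, not an implementation artifact, and it is why generative behavioral
orderings under carryover should not be over-interpreted.

## Attention metrics

Tunings are normalized to sum to 1; entropy is Shannon entropy in bits with
0·log 0 = 0; the attention-compression index is `1 − entropy/log2(3)`,
which is 0 at uniform and 1 at one-hot weights. (The printed form of this
index elsewhere divides by `log2(1/3)`, which is negative and contradicts
the stated 0–1 range; the package treats that as a sign typo and divides by
`log2 3`.) Per-trial compression values are averaged within learning block
(one functional run); the alternative — compressing block-averaged
weights — was not used, since tunings are extracted per trial.

## Synthetic activation patterns

Each (problem, run) yields a 32 × voxels matrix: a low-rank signal plus
i.i.d. Gaussian noise.

- **Exact intrinsic rank.** Score axes are orthonormalized and
  variance-balanced (QR of a centered Gaussian matrix), so the noise-free
  matrix has exactly `intrinsic_rank` equal signal eigenvalues and the 90%
  criterion returns exactly that rank for ranks up to 9. Random unbalanced
  axes would occasionally drop below the planted rank at r ≈ 8.
- **Scaling.** Scores are scaled by `sqrt(n_voxels / rank)` so total
  per-voxel signal variance equals `signal_sd²` (default 1) regardless of
  rank. Without this, isotropic noise across hundreds of voxels dominates
  total variance and the component count saturates, decoupling it from the
  planted dimensionality. A consequence is that overall univariate signal
  power is constant across conditions, mirroring the univariate control
  analysis.
- **Category and attribute coding.** The leading axis carries a class-mean
  offset of `category_separation` (units of per-axis signal SD); one
  additional axis per problem-relevant attribute carries that attribute's
  binary contrast (`attr_amplitude`, default 0.8). For the XOR and parity
  rules, attribute axes do not linearly separate the classes; the category
  axis does.
- **Default schedules** emulate the study conditions: intrinsic rank starts
  at 12 for every problem and declines linearly over blocks to 4 × complexity
  level (low → 4, medium → 8, high → 12), so dimensionality falls fastest
  for the simplest problem; category separation is `0.15 · block ·
  (4 − complexity)`, growing over blocks fastest for low complexity. Noise
  SD defaults to 0.3.

The forward BOLD model sums each trial's beta pattern times its convolved
3.5 s boxcar, plus seeded random patterns for correct/incorrect feedback
(2 s boxcars) and response impulses, plus optional Gaussian noise, at
TR = 2 s.

## Single-trial estimation (least-squares-separate)

The canonical HRF is an SPM-convention double gamma (peak delay 6 s,
undershoot 16 s, unit dispersions, undershoot ratio 1/6, mode at 5 s),
normalized to peak 1 and sampled by convolution on a 0.1 s grid. Each
trial's design holds its own convolved boxcar, one regressor pooling all
other stimulus events, correct/incorrect feedback boxcars, response-button
impulses, six motion columns (zeros for synthetic data) and an intercept —
13 columns. OLS is solved per target trial; all-zero regressors are
structurally absent and harmless under the minimum-norm solution, and true
rank deficiency falls back to the pseudo-inverse with a warning. A
high-pass (128 s discrete-cosine) plus linear detrend helper is provided
for the full-BOLD path.

LS-S is exact when the signal is representable in its collapsed design: a
trial whose amplitude differs from a shared background is recovered to
machine precision when events do not overlap. With heterogeneous other-trial
amplitudes, the single collapsed regressor cannot absorb them and the
misfit leaks through shared nuisance/intercept regressors — the familiar
LS-S approximation; the tests assert the exact cases and the LS-S = LS-A
identity on orthogonal designs.

## Compression and searchlight

Pattern matrices are voxel-centered (no variance scaling); explained
variance comes from the eigenvalues of the 32 × 32 Gram matrix (identical
to squared singular values; both the standalone PCA and the searchlight use
one shared routine so component counts agree exactly). `k` is the smallest
count whose cumulative ratio reaches the criterion (0.9), compared with a
1e-12 tolerance; a zero-variance matrix returns k = 1 flagged degenerate.
Compression is `1 − k/32`, so one learning block = one functional run of
32 trials. Searchlight spheres are integer-lattice offsets with Euclidean
norm ≤ 4 voxels (257 offsets), truncated at the mask; centers with fewer
than `min_sphere_voxels` (default 10) in-mask voxels are left undefined.
Coordinates are 0-based voxel indices; the NIfTI affine is used for I/O
only.

## Category discrimination

Loadings are trial projections onto the retained PC axes (unnormalized).
The score sums, over the k retained PCs, the explained-variance-weighted
absolute difference of category-mean loadings. It is invariant to label
swaps and scales linearly under global pattern scaling (loadings scale,
ratios do not). A label-permutation null (class counts preserved, add-one
p-value) calibrates it against chance. Note the score's chance level
depends on the total pattern variance and the retained-component count, so
comparisons across conditions should be made within the study's balanced
design (as the mixed models do) or against the permutation null.

## Group statistics

All group models are frequentist linear mixed-effects regressions with
participant random intercepts (REML), replacing Bayesian MCMC estimation:
the scientific content is the fixed/random structure and the coefficient
signs, not the estimation machinery. Complexity is coded numerically 1/2/3
and block 1–4, so the block × complexity interaction is one coefficient.
The voxel-wise map saves the interaction's Wald t; clusters are extracted
two-sided at a t threshold from the residual degrees of freedom with
faces+edges (second-nearest-neighbor) connectivity; the cluster-extent
threshold is a user parameter. Voxels with singular fits are flagged and
excluded. Trial-by-trial accuracy is modeled by fixed-effects logistic
regression (participant intercept dummies) with type-II likelihood-ratio
chi-squares for repetition, complexity and their interaction; the
learning-order covariate is constant within participant — collinear with
the intercept dummies — so it is tested in a pooled logistic model instead.
The neural→attention regression includes block, complexity, their
interaction, accuracy and order, and exports partial residuals (both
measures residualized on everything except each other) for plotting.

## Problem sizes used by the tests

The acceptance-style tests run the full synthetic study at 23 participants,
20 seeded replicates and a 12³ volume with a radius-4 spherical mask
(~250 voxels), with searchlight radius 4; the parameter-recovery study fits
20 single participants (384 trials each) at the documented DE budget; the
pipeline smoke profile uses 5 participants. Unit tests use 8³–10³ volumes.
These sizes keep the whole suite at desk scale while preserving the study's
design structure (3 problems × 4 runs × 32 trials, high problem first,
low/medium counterbalanced).

## What passing tests do and do not show

The generator plants the hypothesized structure (rank falling with
learning, fastest for simple problems; category separation rising), so the
direction tests validate that the pipeline *recovers* planted structure
through the full searchlight + mixed-model path — they do not, and cannot,
re-establish the empirical claim on real brains. Real fMRI noise is
temporally autocorrelated, spatially smooth and physiologically structured;
the generator's noise is i.i.d. Gaussian, and its signal axes are globally
shared across the mask rather than regionally localized. Registration,
motion, and preprocessing are out of scope.
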