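# Methods

`tonguedx` implements a deep radial basis function (RBF) classifier for
screening diabetes mellitus (DM) from categorical tongue features of the
kind scored in Traditional Chinese Medicine (TCM) practice, together
with the surrounding machinery needed to study it end to end: a
synthetic cohort generator, evaluation metrics, a 5x2 cross-validation
model-comparison test and an experiment pipeline.  This note records the
model, its assumptions, the tunable parameters, and the design choices
made where the design was genuinely open.

## Feature schema and encoding

A participant record holds eight tongue features: body shape
(medium/enlarged/small), colour (mild red/red/pale/bluish), four
multi-label surface marks (red spots, black spots, fissures, petechiae),
teeth markings (yes/no), fur colour (white/black/yellow/none), saliva
(normal/dry/wet) and fur thickness (thin/thick/no fur), plus an optional
DM / non-DM label.  The classifier takes a fixed 8-dimensional numeric
vector: `[tongue_color, tongue_body, fur_color, fur_thickness,
spot_score, saliva, fissures, teeth_markings]`, every coordinate in
[0, 1].

Two encoding schemes are provided:

* **ordinal** — categories coded in vocabulary order, uniformly spaced
  in [0, 1].  The spot score pools the non-fissure surface marks
  (`count/3`); fissures and teeth markings are 0/1 flags.
* **severity-scaled** — the same geometry, but categories ordered by
  their conventional clinical association with diabetes, so that the
  signs regarded as DM-linked (bluish tongue, yellow fur, thick fur, dry
  saliva) receive the largest codes.

The choice matters for learning: under the severity ordering, risk is
monotone in each coordinate, whereas under the listing order the
DM-associated category of a feature may sit in the interior of the code
range, forcing the classifier to learn non-monotone coordinate effects.
The cohort-recovery experiments therefore use the severity-scaled
scheme; the schema tests exercise both.

Fur colour `none` exists because the published fur-colour counts cover
only 2,400 of 2,675 participants; the remaining 275 records take the
explicit `none` category, and every record with no fur coating has fur
colour `none` by construction.

## Synthetic cohort generator

The study cohort this package emulates is private, so all experiments
run on synthetic cohorts drawn to match its published composition:
2,675 participants, 1,658 DM; per-feature category counts as published
(e.g. 1,332/915/428 for tongue body); surface-mark prevalences
1489/1044/1038/205 of 2,675; four seasonal acquisition phases
(530/750/1062/333 participants, DM counts 272/483/723/180).

**Sampling modes.**  In *quota* mode every single-valued feature's
category counts are reproduced exactly (shuffled quota fill); surface
marks are exact-count draws without replacement.  In *multinomial* mode
all marginals hold in expectation.  Features are sampled independently
given the marginals except for the `no_fur -> none` tie.  The saliva
marginal follows the published count table (1884/518/273); the published
percentage figures for saliva are internally inconsistent with those
counts and are not used.

**Label model.**  Each record gets a score `s` = sum of per-category
log-odds offsets; `P(DM | x) = sigmoid(b + s)` with the intercept `b`
calibrated by bisection so the expected DM count equals `n_dm` (with all
offsets zero the calibrated intercept is exactly `logit(n_dm/n_total)`).
Defaults put +1 log-odds on thick fur, yellow fur, bluish tongue and
teeth markings — the signs conventionally linked to high diabetes
prevalence — and 0 elsewhere.  `strong_effects(scale)` is the
strengthened variant used in the recovery experiments: +2 on those four
categories and −2 on every other category of the same features.  Under
those offsets the Bayes-optimal rule ("at least two of the four risk
signs") attains about 0.90 accuracy; this ceiling is worth keeping in
mind when reading the recovery results below.

In multinomial mode labels are independent Bernoulli draws.  In quota
mode the label vector is drawn from the *conditional Bernoulli* law —
independent Bernoulli(p_i) conditioned on the total equalling `n_dm` —
via a backward dynamic program over success counts and a forward
sequential draw.  Because the intercept is calibrated so that the
expected total already equals `n_dm`, conditioning on the total barely
perturbs the per-record inclusion probabilities, and the effect
structure of the logistic model is preserved while the class sizes stay
exact.  (A simpler weighted-sampling-without-replacement scheme was
evaluated and rejected: at a 62% selection fraction it compresses the
inclusion probabilities so strongly that the planted effects largely
vanish.)

Phases, when requested, are assigned label-conditionally in proportion
to the published phase-by-class sizes and have no effect on features.

**What the generator does not emulate.**  Real tongue-image data would
carry correlated features (e.g. colour-coating dependence), rater noise,
seasonal drift in the features themselves, and a richer conditional
structure than a main-effects logistic model.  Tests passing on these
cohorts therefore demonstrate that the pipeline recovers a known
planted structure, not that the classifier reaches any particular
accuracy on clinical data.

## Deep RBF network

Every layer (hidden and output) applies an affine map `u = x W + b`
followed by Gaussian radial units with per-unit centers `r_i` in the
mapped space and widths `sigma_i`:

    a_i = c_i * exp( -||u - r_i||^2 / (2 sigma_i^2) )

This realises the radial functional connection
`f(x) = sum_i c_i phi(||x w - r_i||^2)` with the norm-side linear map
read as the layer's trainable input transform; the mixing coefficients
`c_i` are kept at 1 and not trained.  An identity input map is the
special case `W = I` (available only when fan-in equals the unit
count).  Centers come from k-means (seeded k-means++ start, Lloyd
iterations to the assignment fixpoint, cap 300) on the layer's mapped
input; widths follow one of two rules:

* **nearest-center** (default): `sigma_i` = mean distance to the two
  nearest other centers (the single other center at k = 2; the data's
  RMS radius at k = 1);
* **cluster-spread**: `sigma_i` = RMS radius of the unit's k-means
  cluster.

Zero widths arising from duplicate centers fall back to the mean
positive width (1.0 if none).  Only the affine parameters are trained;
centers and widths stay fixed, as in classical RBF practice.

**Error and gradients.**  The training loss is the conventional
per-output squared error `E = 1/2 sum_k (t_k - y_k)^2` against one-hot
targets over the two output units (DM / non-DM), averaged over the
mini-batch.  Backpropagation chains the Gaussian derivative
`dA_i/du = A_i (r_i - u)/sigma_i^2` through the stack; output-layer and
hidden-layer weight gradients have the standard `delta * input` form.
Analytic gradients agree with central finite differences to better than
1e-6 relative error (tested over randomized small networks).  A
linear-output mode (affine output, no Gaussian) exists for gradient
diagnostics.

**Pretraining.**  Greedy layer-wise autoencoding: each hidden layer in
order is paired with a linear decoder and trained by mini-batch gradient
descent to minimise the mean squared reconstruction error of its own
input; the best-so-far encoder parameters are restored at the end, so a
layer's final loss never exceeds its initial loss.  The encoder is then
frozen and its encodings feed the next layer.

**Fine-tuning.**  Mini-batch gradient descent, batch 40, learning rate
0.2, targets one-hot, data reshuffled each epoch by seed, gradients
averaged within the batch; training stops when the epoch-mean error
falls below the convergence criterion 1e-6 or at `max_epochs`
(default 500).

**Numerical stabilisers** (both are package design choices where the
training recipe was open):

* *Gradient clipping* (default block norm 0.2).  The chained
  `1/sigma^2` factors of a deep Gaussian stack can make first-epoch
  gradients orders of magnitude too large for a fixed step; unclipped
  runs frequently collapse the representation onto a constant-output
  saddle within one epoch.  Clipping bounds the step while leaving the
  small-gradient regime near convergence untouched.
* *Output-center refresh* (optional, default off).  With fixed output
  geometry the "wrong-class" output unit saturates near
  `exp(-D^2/2 sigma^2)` where `D` is the inter-center distance — with
  the nearest-center rule at k = 2 this floors the training error around
  5e-2 regardless of separability.  Refreshing the output centers by one
  Lloyd step per epoch (widths fixed) lets fine-tuning contract the
  class clusters onto the centers and push the centers apart, driving
  the error to the 1e-6 criterion on separable data.  The refresh is off
  by default because on noisy, overlapping data it can track a merging
  cluster into the same saddle it cures on clean data.  The convergence
  tail is initialisation-dependent and logarithmically slow (the
  repulsive force scales with the already-small off-unit activation);
  typical separable-data runs converge between ~600 and ~2500 epochs.
* *Restarts* (default 1).  `restarts = R` runs the full pipeline from R
  derived seeds and keeps the model with the lowest final training
  error; collapsed runs have conspicuously high training error and are
  filtered out.  The cohort experiments use R = 3.

**Architecture.**  `hidden_layer_sizes` defaults to 3-5-7-5-3-4-3 (seven
hidden layers), the configuration described for the 8-input tongue
feature case.  The cohort experiments use the equal-width deep variant —
six hidden layers of 8 units, the input-neuron count — which the source
design also describes; the narrow 3-unit first layer of the default
stack discards category information on the cohort task (it costs roughly
3 accuracy points there).  Both are plain config choices.

**Prediction.**  Scores are the two output activations; the class is the
argmax, with exact ties resolved to non-DM (the first output unit).  For
ROC analysis the positive-class score is normalised as
`s_DM / (s_DM + s_nonDM)`.

Models serialise losslessly to a single versioned JSON document
(config, arrays as nested lists, training log).

## Evaluation

Confusion counts take DM as positive.  The six diagnostics are accuracy,
precision, sensitivity, specificity, F1 (harmonic mean of precision and
sensitivity) and error rate.  Error rate is computed as `1 - accuracy`
so the pair sums to 1 exactly; ratios with zero denominators are
reported as NaN and flagged, never silently zeroed.  The ROC curve
sweeps thresholds over the distinct scores in descending order with tied
scores grouped; AUC is the trapezoid area, equal to the Mann-Whitney
pairwise-comparison statistic.

## 5x2 CV paired t test

Five seeded random 50/50 splits (re-split up to 20 times if a half ends
up single-class); each model is trained on each half and tested on the
other, giving differences `d_A, d_B` per iteration, per-iteration
variance `s_i^2 = (d_A - m_i)^2 + (d_B - m_i)^2`, and Dietterich's
statistic `t = d_{A,1} / sqrt(mean_i s_i^2)` referred to a t
distribution with 5 degrees of freedom, two-sided.  Zero pooled variance
(e.g. literally identical models) is flagged as a degenerate
"no difference" outcome with p = 1 and no rejection, since the statistic
is undefined there.  The test is two-sided as the conservative default.
Under a null with two equal-accuracy classifiers the empirical type-I
error at alpha = 0.05 sits near nominal (checked over 200 replicates on
reduced-size models).

## Pipeline

`run_experiment` chains simulate -> encode -> stratified 70/30 split
(per-class train size = round-half-up of fraction x class size) ->
pretrain + fit -> held-out evaluation -> ROC -> stratified fivefold
cross-validation on the training portion only, writing every artifact
(cohort table, split report, model JSON, metrics JSON, fold table, ROC
points, structured log with per-epoch losses) into one directory.  The
held-out test portion never enters the cross-validation loop.  Fold
sizes within a class differ by at most one, remainders going to the
lowest-index folds.  Everything is deterministic under a fixed seed.

## Problem sizes used in the shipped experiments

The recovery study trains on the full-size synthetic cohort (2,675
records, 70/30 split) with the 8x6 network, 200 fine-tuning epochs and
3 restarts, over 5 cohort seeds for each effect model (strong and null).
The type-I error study uses 200 replicates of a 120-record null cohort
with a single-hidden-layer (4-unit) network trained for 8 epochs — a
deliberately small model, since only the *equality* of the two
classifiers matters under the null.  The gradient check uses 100
randomized 2-input, 3-unit, 2-output networks.

## Known limitations

* Fixed centers and widths make the optimisation landscape saddle-prone;
  the stabilisers above manage but do not eliminate this (hence
  restarts).
* On the strong-effect cohorts the classifier reaches within roughly one
  accuracy point of the Bayes ceiling (~0.90); closing that last point
  would require the true parametric family (a logistic model in category
  indicators), which the network can only approximate.
* The 5x2 CV test assumes the two models' fold accuracies are
  exchangeable under the null; heavily unbalanced or tiny datasets break
  the half-split retry logic before the statistic is computed.
* The generator's independence assumptions understate the feature
  correlations of real cohorts; see the generator section.
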