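# tonguedx

Deep radial basis function (RBF) classification of diabetes mellitus
from categorical tongue features, with a synthetic cohort generator,
confusion-matrix diagnostics, ROC analysis and a 5x2 cross-validation
model-comparison test.

## The problem

Traditional Chinese Medicine reads systemic state from tongue
appearance; signs such as yellow or thick fur (coating), a bluish tongue
body and teeth markings are associated with the Xiao-Ke syndrome that
corresponds to diabetes mellitus.  This package implements a screening
classifier over eight such features — tongue colour and body shape,
surface marks, teeth markings, fur colour and thickness, saliva state —
scored per participant, and everything needed to study it reproducibly
when the underlying clinical cohort is not available: a generator that
draws synthetic cohorts matching the published cohort composition
(2,675 participants, 1,658 DM) with a configurable class-conditional
logistic effect model.

## The model

Every layer of the network applies a trainable affine map `u = xW + b`
followed by Gaussian radial units with fixed, data-derived geometry:

    a_i = exp( -||u - r_i||^2 / (2 sigma_i^2) )

Centers `r_i` are k-means centroids of the layer's mapped input; widths
`sigma_i` follow a nearest-center or cluster-spread rule.  The stack is
pretrained greedily layer by layer as autoencoders (each layer learns to
reconstruct its own input through a linear decoder), then fine-tuned by
mini-batch gradient descent (batch 40, learning rate 0.2) on the squared
error `E = 1/2 sum_k (t_k - y_k)^2` against one-hot DM / non-DM targets,
until the epoch-mean error reaches 1e-6 or an epoch cap.  Model
selection, evaluation (accuracy, precision, sensitivity, specificity,
F1, error rate, ROC/AUC) and the Dietterich 5x2 CV paired t test
(`t = d_A,1 / sqrt(mean_i s_i^2)`, t distribution with 5 df) complete
the pipeline.  See `docs/methods.md` for assumptions, parameter
defaults and numerical choices.

## Worked example

```python
from tonguedx import CohortSpec, simulate_cohort, split_cohort, NetworkConfig, fit, predict
from tonguedx.cohort import strong_effects
from tonguedx.schema import encode_records
from tonguedx.metrics import confusion, metrics, roc_curve

spec = CohortSpec(effects=strong_effects(), seed=7)   # +/-2 log-odds planted effects
records = simulate_cohort(spec)
train, test = split_cohort(records, 0.7, seed=7)

Xtr, ytr = encode_records(train, "severity-scaled")
Xte, yte = encode_records(test, "severity-scaled")
config = NetworkConfig(hidden_layer_sizes=(8,)*6, max_epochs=200, restarts=3, seed=7)
net, report = fit(config, Xtr, ytr)

labels, scores = predict(net, Xte)
rep = metrics(confusion(labels, yte))
```

prints (via the obvious format calls):

```
cohort: 2675 records, train 1873, test 802
trained: 200 epochs, final train MSE 0.1185
accuracy    0.911
precision   0.931
sensitivity 0.926
specificity 0.889
F1          0.928
error rate  0.089
AUC         0.903
```

The cohort is drawn at the published composition, split 70/30 stratified
(1161 + 712 train, 497 + 305 test).  Under the planted +/-2 log-odds
effect model the Bayes-optimal rule attains roughly 0.90 accuracy, so a
held-out accuracy near 0.91 on this seed means the network has recovered
essentially all of the planted class structure; sensitivity and
specificity show the recovery is balanced across classes.

## Command line

```sh
tonguedx simulate --seed 1 --out cohort.csv
tonguedx train --cohort cohort.csv --seed 1 --out model.json
tonguedx evaluate --model model.json --cohort cohort.csv
tonguedx crossval --cohort cohort.csv --folds 5
tonguedx compare --cohort cohort.csv --seeds 0 1     # 5x2 CV t test
tonguedx report --config run.yaml --out artifacts/   # full pipeline
```

Exit codes distinguish configuration (2), data (3) and training (4)
errors.

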