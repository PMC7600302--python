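# mieff — motor-imagery BCI efficiency analysis

Between 15% and 30% of brain-computer-interface users never develop
usable motor-imagery (MI) control.  `mieff` is a toolkit for studying
this *BCI inefficiency*: it computes neurophysiological indicators of
MI ability from EEG, the bi-class classification accuracy they are
meant to predict, and a Wide&Deep regression network that jointly
extracts a data-driven subject indicator and regresses it on the
accuracy response — then clusters subjects into efficiency groups.

It is aimed at BCI/EEG researchers who want to evaluate performance
predictors on their own cohorts or on fully synthetic ones.

## What it computes

* **xi1 — pre-training desynchronization.**  The resting power
  spectrum of each sensorimotor channel is fitted over 4–40 Hz with two
  Gaussian rhythm peaks (mu, beta) on a hyperbolic noise floor
  `kappa1 + kappa2 / f**eta`; xi1 is the maximal excess of the spectrum
  over the fitted floor, averaged over the channel configuration.
* **xi2 — initial-training synchronization.**  Event-related
  de/synchronization (ERD/ERS) curves `z(t) = (power(t) - ref)/ref` per
  band, channel and class; xi2 is the normalized squared distance
  between the left- and right-hand curves over the MI interval,
  `max_{band,c} ||z_l - z_r||^2 / (||z_l|| ||z_r||)`.
* **Accuracy response.**  Sliding-window CSP + regularized LDA with
  repeated stratified cross-validation at window lengths
  {0.5, 1.0, 1.5, 2.0} s over the MI interval.
* **Wide&Deep regression.**  Per-channel short-time moment features →
  per-electrode dense tanh branches (`ceil(1.5 d)` units) →
  concatenation → dense tanh layer (`ceil(0.5 h C)`) → one-neuron
  linear output, plus a direct linear shortcut from the raw features;
  trained with full-batch Adam on MAE with elastic-net regularization.
  Evaluated by Spearman rank correlation, in-sample and leave-one-out,
  against linear-correlation and scalar-network baselines.
* **Efficiency clustering.**  k-means on the accuracy profiles with
  silhouette-selected k, groups ordered I–III by mean accuracy, and a
  residual-based outlier group IV of non-predictable subjects.

A seeded synthetic-EEG generator (1/f background + band-limited mu/beta
rhythms with class-lateralized ERD, controlled by a latent efficiency)
makes every stage testable end to end.  See `docs/methods.md` for the
full model description.

## Worked example

Regress the accuracy response of a 50-subject synthetic cohort on
moment features, and compare with the linear baseline on the scalar
indicator:

```python
import numpy as np
import mieff
from mieff.drn import moment_features, linear_baseline

coh = mieff.make_regression_cohort(50, seed=0)
feats = np.stack([[moment_features(ch, coh.fs) for ch in subj]
                  for subj in coh.signals])
res = mieff.DeepRegressionNetwork(feats, coh.responses).fit(epochs=2000, seed=0)
print(res.summary())
print(f"linear baseline Spearman r: {linear_baseline(coh.scalar_indicators, coh.responses).r:.4f}")
```

```
Wide&Deep Regression Network Results
==============================================
No. subjects:               50
Variant:                    moment features
Channels (C):               2
Feature length (d):         55
Branch width (h):           83
Concat width (h*C):         166
Hidden width (theta2):      83
Epochs run:                 2000
Converged (plateau):        False
Final loss (MAE+penalty):   0.01312
In-sample Spearman r:       0.9992
==============================================
linear baseline Spearman r: 0.4314
```

The cohort's response is a strongly nonlinear (sigmoidal) but monotone
function of a latent efficiency, and the scalar indicator saturates:
rank correlation on the scalar stalls at 0.43, while the feature-fed
network linearizes the relationship almost perfectly (r = 0.999
in-sample; leave-one-out stays within a few points — run
`mieff.loo_evaluate(feats, coh.responses)` to reproduce).

## Command line

```sh
mieff all --out-dir run --seed 7            # simulate + full pipeline
mieff simulate --out-dir run --n-subjects 12
mieff indicators --out-dir run
mieff response --out-dir run
mieff regress --out-dir run --loo
mieff cluster --out-dir run
```

Each stage persists CSV tables (`indicators.csv`, `response.csv`,
`regression.csv`, `clusters.csv`) plus an HDF5 cohort container and a
JSON manifest recording configuration and seeds, so runs are exactly
reproducible.  A YAML config (`--config run.yaml`) mirrors the flags.
An optional loader for the public 52-subject MI collection's
per-subject `.mat` layout is provided in `mieff.io`.

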