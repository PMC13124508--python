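# imtscast

Forecasting of **irregular multivariate clinical time series** (IMTS):
per-variable observation streams with non-uniform timestamps, heavy
missingness and cross-variable asynchrony, as produced by ICU monitors and
electronic health records. Given a patient's history over an observation
window [0, T], the model predicts any variable's value at arbitrary future
query times τ ∈ (T, T + H] — without interpolation, imputation or
pre-alignment of the raw data.

## Method

Each univariate series is cut into temporally aligned, non-overlapping
patches at several duration scales L₁ < … < L_S (default {1, 2, 4, 8, 24}
hours). Every non-empty patch is encoded in two domains and fused:

* a **time-aware convolution** whose filter is *generated* per observation
  by a meta-network and softmax-normalized over the observation index, so
  filter size adapts to however many observations the patch holds;
* a **time-aware Fourier-analysis stack** applied point-wise
  (cos/sin/GELU blocks modulated by value and rescaled timestamp) and
  mean-pooled, capturing oscillatory structure directly on the uneven
  sample times.

Scale embeddings are aligned to the finest-scale canonical timeline,
fused, and contextualized per variable by a transformer encoder. For each
canonical interval k a **dynamic directed graph** over the N variables is
learned from the contextualized embeddings concatenated with Lomb-Scargle
spectral power (the periodogram defined for unevenly sampled data);
row-softmax scores give a row-stochastic adjacency A_k, and a
symmetric-normalized GCN with self-loops propagates information between
variables. Forecasts at query time τ come from the last interval's state
through a time-aware Fourier output layer. Training minimizes a
horizon-weighted squared error, w(τ) = 1 + α(τ − T), which reduces to the
masked MSE at α = 0.

A synthetic **physiological-cohort simulator** with planted ground truth
(coupling graph, shared quasi-circadian rhythms, trends, vitals/labs
sampling split, tunable missingness) makes every stage testable offline,
including recovery of the planted inter-variable graph. See
`docs/methods.md` for the full model description and design rationale.

## Worked example

```python
import numpy as np
from imtscast import (generate_cohort, default_config, split_episodes,
                      fit_standardizer, apply_standardizer,
                      Forecaster, ModelConfig, TrainingConfig,
                      fit_forecaster, evaluate_model)
from imtscast.graph import default_probe_frequencies, graph_recovery_auroc
from imtscast.train import cohort_mean_adjacency, desk_training_config

episodes, truth = generate_cohort(default_config(seed=11))
train, valid, test = split_episodes(episodes, (2/3, 1/6, 1/6), seed=0)
std = fit_standardizer(train)
train, valid, test = ([apply_standardizer(e, std) for e in part]
                      for part in (train, valid, test))

probe = default_probe_frequencies(train, 10)
model = Forecaster(ModelConfig.small(seed=1), probe)
fit_forecaster(model, train, valid, desk_training_config(seed=100))

print(evaluate_model(model, test))
abar = cohort_mean_adjacency(model, test)
print("graph recovery AUROC:",
      round(graph_recovery_auroc(abar, truth.coupling), 3))
```

On the default cohort (8 variables, 300 episodes split 200/50/50, 80%
missingness, two densely sampled driver variables feeding six lab-sparse
dependents) this prints standardized test errors of
`MSE ≈ 0.49, MAE ≈ 0.54` — roughly half the variance of the targets, most
of the remainder being the dependents' residual phase uncertainty — and a
graph recovery AUROC of `1.0`: ranking the entries of the time-averaged
learned adjacency perfectly separates planted coupling edges from
non-edges. The same quantities are recomputed independently (different
cohort and model seeds) by the acceptance script below.

A command-line interface mirrors the library:

```bash
imtscast simulate cohort/ --seed 7
imtscast train cohort/ runs/model.npz --seed 7
imtscast evaluate cohort/ runs/model.npz --seed 7
imtscast perturb cohort/ runs/model.npz --seed 7 --rhos 0.0,0.3,0.5
imtscast graphs cohort/ runs/model.npz runs/graphs/ --seed 7
```

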