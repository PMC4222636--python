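# dpkf — a Dirichlet-process Kalman filter model of memory updating

When does new experience modify an old memory, and when does it create a
new one?  `dpkf` implements a statistical answer: the memory system
performs optimal filtering under a generative model in which the world
usually drifts slowly but occasionally jumps between distinct
"dynamical modes".  Each inferred mode is a temporally extended memory
trace; observations assigned to the same mode blend together
(retroactive interference), while an inferred jump opens a fresh mode
and protects the old trace.

The package is aimed at computational cognitive scientists who want to
simulate the model, fit it to trial-level behavioral data from
prediction/reconstruction tasks, and reproduce the standard analyses
(interference crossover, cross-validated model comparison, inferred
mode counts).

## The model

Observations `y_t ∈ R^D` arise from the state `x_t^(k)` of the active
mode `z_t`, which is drawn from a **sticky Chinese restaurant process**:

    P(z_t = k)   ∝  N_k + β·1[z_{t-1} = k]      (existing mode k)
    P(z_t = new) ∝  α

where `N_k` counts the trials already assigned to mode `k`, `β ≥ 0` is
a stickiness (persistence) bonus and `α ≥ 0` the concentration.  A new
mode's state is drawn from `N(m0, c)`; every created mode's state
diffuses as `x ← λx + N(0, q)` whether or not it is active, and the
active mode emits `y_t = x_t^(z_t) + N(0, r)` (all covariances
diagonal).

Inference (the **DP-KF**) is sequential and maintains a single
high-probability partition: each trial is scored against every
instantiated mode and a potential new mode by prior × likelihood, the
MAP mode is hard-assigned, and only that mode receives the
per-dimension Kalman update with gain `η = σ²_pred / (σ²_pred + r)`.
A dormant mode's predictive variance grows with the time since it was
last active, so old traces become tolerant of prediction errors.
`α = 0` reduces the model exactly to a classical Kalman filter; `q = 0`
freezes each mode's state (the "stationary" variants).

Memory **reconstruction** of a probed past trial is Rauch–Tung–Striebel
smoothing run *within* the probed trial's mode (never across modes),
with a retrieval-noise constant (default 5) added to the sensory
variance.

## Worked example

```python
import numpy as np
from dpkf import Hyperparameters, run_filter, reconstruct

rng = np.random.default_rng(0)
truth = 0.5 * np.arange(30); truth[15:] += 8.0          # ramp with a jump
y = (truth + rng.normal(0, 1, 30))[:, None]

hp = Hyperparameters(alpha=1.0, beta=0.0, q=0.2, r=1.0, v=1.0,
                     m0=0.0, c=1000.0, n_dims=1)
trace = run_filter(y, hp)
print("modes created:", trace.n_modes)
print("assignments:  ", "".join(str(z) for z in trace.assignments))

rec = reconstruct(trace, y, probe_t=3)
print(f"reconstruction of trial 3: {rec.estimate[0]:.2f} "
      f"(observed {y[2,0]:.2f}, mode {rec.mode}, chain length {len(rec.chain)})")
```

prints

```
modes created: 2
assignments:   111111111111111222222222222222
reconstruction of trial 3: 2.36 (observed 1.64, mode 1, chain length 15)
```

The filter opens a second mode exactly at the jump, and the
reconstruction of trial 3 (observed at 1.64) is smoothed only over the
pre-jump chain — pulled toward its 15-trial mode mean, untouched by
post-jump data.  Comparing one-step predictions right after the jump
shows the catch-up behavior:

```
post-jump |prediction error|, DP-KF: [0.7  1.05 1.83 2.25]
post-jump |prediction error|, KF:    [6.83 5.11 4.51 4.02]
```

the DP-KF is back at noise level one trial after the jump, while the
single-mode KF (`alpha=0`) smears across it for many trials.

## What is in the package

| module | contents |
| --- | --- |
| `dpkf.generative` | sticky-CRP prior, generative simulator, morph protocols |
| `dpkf.filter` | DP-KF sequential inference (`run_filter`), per-mode Kalman updates |
| `dpkf.smoother` | within-mode RTS smoothing, `reconstruct` |
| `dpkf.task` | trajectory generator (gradual/jump blocks), sessions, synthetic participants |
| `dpkf.fit` | maximum-likelihood fitting of the 4 nested variants, even/odd cross-validation, reconstruction likelihoods |
| `dpkf.analysis` | distance/interference analysis with 2×2 repeated-measures ANOVA, mode-count comparison, Fisher-z correlations, demo simulations |

A thin CLI wraps the pipeline:

```
dpkf simulate --n-participants 20 --seed 0 --out cohort.csv
dpkf fit cohort.csv --variant dpkf --seed 0 --out fits.json
dpkf crossval cohort.csv --variant dpkf --seed 0 --out cv.json
dpkf evaluate cohort.csv fits.json --out recon.json
dpkf reproduce --seed 1 --out-dir demo_out
```

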