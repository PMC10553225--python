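# eegdyn

State-space analysis of resting-state EEG network dynamics.

Resting-state EEG is not stationary: cortex-wide phase coupling, network
topology and oscillatory power drift between recurring electrophysiological
regimes on a seconds timescale. `eegdyn` implements the full analysis chain
that turns multichannel resting recordings into interpretable *state
dwell-times* and relates them to behaviour — for researchers studying, e.g.,
response control in ADHD cohorts, or any setting where the tendency to
occupy particular network regimes is the quantity of interest.

## The method

For each of the four canonical bands (delta 1–3 Hz, theta 4–7 Hz, alpha
8–12 Hz, beta 13–30 Hz) the recording is z-scored, band-passed with a
zero-phase Kaiser-designed FIR (10% passband ripple, transition width
0.2 × band centre), and Hilbert-transformed. Three global metrics are then
evaluated on sliding windows centred on a 1 s grid:

- **Phase-lag index (PLI)** of every sensor pair,
  `PLI = |⟨sign(Δφ)⟩|`, averaged over all pairs — consistent nonzero phase
  lags score 1, symmetric or zero-lag phase relations score 0;
- **Modularity Q** of the PLI graph,
  `Q = (1/W) Σᵢⱼ (Aᵢⱼ − sᵢsⱼ/W) δ(mᵢ, mⱼ)`, maximised with a seeded
  Louvain heuristic and averaged over 100 runs;
- **Band power**, the mean squared band-limited signal across sensors.

Window lengths are matched on temporal degrees of freedom η = 2·B·D so that
the estimator uncertainty 1/√η = 0.15 is equal across bands (delta 11.11 s,
theta 7.40 s, …). Each metric yields a T × 4 observation sequence per
participant (one column per band; T = 300 for a 5-minute recording).

The sequences are modelled with a **Gaussian hidden Markov model**
(parameters π, μ, Σ, P; full covariances) fitted by multi-sequence
Baum–Welch EM (absolute log-likelihood tolerance 0.005, best of 10 random
restarts) and decoded with Viterbi. Each participant's **dwell-time** — the
proportion of observations spent in each state, overall and split by
eyes-open (EO) / eyes-closed (EC) condition — feeds the statistical layer:
Welch/pooled t-tests of EO vs EC dwell (validation), 2×2 ANOVAs,
dwell-time OLS regressions (one state column dropped for the simplex
collinearity), partial F-tests for moderation,
`F(p−q, n−p−1) = ((SSE_R − SSE_F)/(p−q)) / MSE_F`, and Fisher r-to-z
correlation comparisons.

A synthetic-data module generates state-switching multichannel recordings
(band-limited noise through the same filters as the analysis path, hidden
states switching on 1 s boundaries, optional phase-lagged couplings) and
balanced 2×2 phenotype cohorts whose behavioural scores depend linearly on
ground-truth dwell-times — so every stage of the chain is testable against
known truth without any data download.

## Worked example

```python
import numpy as np
from eegdyn import make_cohort, plan_windows, default_bands
from eegdyn.synthetic import cohort_dwell_profiles
from eegdyn.inference import eo_ec_validation, dwell_regression

for b in default_bands():
    p = plan_windows(b)   # uncertainty 0.15 -> eta = 44.4
    print(f"{b.name}: window {p.length:.2f} s")

tab, gt = make_cohort(n_per_cell=28, seed=7)      # 112 participants
val = eo_ec_validation(cohort_dwell_profiles(tab, 4))
dwell = tab[[f"dwell_s{s+1}" for s in range(4)]].to_numpy()
fit = dwell_regression(dwell, tab["rt_sd"])
print(f"F({fit.df1}, {fit.df2}) = {fit.overall_f:.2f}, R2 = {fit.r2:.3f}")
```

prints

```
delta: window 11.11 s
theta: window 7.41 s
alpha: window 5.56 s
beta: window 1.31 s
F(3, 108) = 7.37, R2 = 0.170
```

The window lengths are the η-matched values per band. The cohort's state 2
is boosted during eyes-closed blocks; `eo_ec_validation` flags it at
t = −12.3 (p < 1e-25), and the regression recovers the built-in negative
dwell→reaction-time-variability coefficient (state 2: −0.366, SE 0.083,
true value −0.30) with an overall F on (3, 108) degrees of freedom — three
dwell predictors for four states, one column dropped for the simplex
constraint.

The same chain runs end-to-end from the command line:

```bash
eegdyn run --out-dir out --seed 1 --metric power --n-states 4
```

which simulates a cohort of recordings, computes metric sequences, fits the
state model and writes dwell tables plus a tidy statistics table under
`out/`.

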