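# Methods

## Overview

`eegdyn` characterises resting-state EEG as a trajectory through a small
set of recurring electrophysiological regimes. The chain has three stages:
(1) band-specific sliding-window metrics turn a channels × samples
recording into one T × 4 observation sequence per metric (phase-lag index,
modularity, power; one column per band); (2) a Gaussian hidden Markov model
turns those sequences into per-participant state dwell-times; (3) a
statistical layer validates the states against the eyes-open/eyes-closed
(EO/EC) manipulation and relates dwell-times to behaviour.

## Spectral decomposition

Recordings are z-scored per channel (mean 0, sample SD 1 with denominator
N−1; per-channel rather than whole-array normalisation removes per-sensor
gain differences — the alternative is one config switch away in callers
that need it). Four bands are analysed: delta 1–3, theta 4–7, alpha 8–12,
beta 13–30 Hz, each with filter transition width 0.2 × band centre
frequency. Filters are linear-phase FIRs sized by Kaiser-window order
estimation from a 10% ripple specification and applied forward–backward,
so the effective magnitude response is squared (≈40 dB stopband) and net
phase distortion is zero. Instantaneous phase is the angle of the analytic
(Hilbert) extension, kept wrapped in (−π, π]; power is the squared
band-limited signal itself, not the envelope.

Filter transients: the first and last ⌈order/2⌉ samples of each filtered
channel are excluded from window statistics. Edge artifacts otherwise
inflate the phase-lag index near the recording boundaries.

A consequence of the band scheme worth knowing: beta's lower transition
edge (13 − 4.3 = 8.7 Hz) lies inside the alpha passband, so a purely
alpha-band signal passes the beta filter at roughly one-ninth relative
power. This is a property of the band definitions, not of the
implementation; tests of band separation therefore demand a 10× power
ratio against delta/theta but only 5× against beta.

## Window geometry

Sliding-window lengths are matched on temporal degrees of freedom
η = 2·B·D (B bandwidth in Hz, D length in seconds), holding the estimator
uncertainty 1/√η at 0.15 (η = 44.4): delta 11.11 s, theta 7.41 s, alpha
5.56 s, beta 1.31 s. Published analyses of this design print 3.70 s and
1.48 s for alpha and beta, which is inconsistent with B = high − low under
the same rule; the formula is authoritative here and per-band lengths are
config-overridable for users who want to reproduce a specific table.
Printed lengths in this package's own reports are truncated (not rounded)
to two decimals, matching the convention evident in the reference values.

Windows are centred on the integer-second observation grid and truncated
at the recording edges (and at the filter-transient boundary), so every
band yields exactly T aligned observations for a T-second recording. Each
observation carries the EO/EC condition at its window centre; windows
spanning a block boundary are labelled by their centre.

## Metrics

**PLI.** For a channel pair, the absolute mean sign of the wrapped phase
difference over the window; sign(0) contributes 0, the standard convention
that makes zero-lag (volume-conduction-like) synchrony score 0. The global
value is the mean over the strictly-upper-triangular pair matrix.

**Modularity.** The PLI pair matrix is an undirected weighted graph.
Q = (1/W) Σᵢⱼ (Aᵢⱼ − sᵢsⱼ/W) δ(mᵢ, mⱼ) over ordered pairs, with sᵢ node
strength and W the full-matrix weight total (the upper-triangle-sum
convention differs only by a factor 2 that cancels between the edge term
and the null model). Partitions come from an in-package Louvain heuristic:
greedy single-node moves to the neighbouring community with maximal Q
gain, community aggregation, repeat; node visiting order is randomised by
a seed, and the reported value is the mean Q over (by default) 100 seeded
runs, since the heuristic's outcome is order-dependent. Per-run seeds are
derived from one master seed, so consensus values are reproducible.

**Power.** Mean squared band-limited signal over the window, averaged
across channels.

## State model

Observation sequences are z-scored per participant and per dimension
(removing inter-subject scale differences), then pooled: one group-level
model is fitted with all participants' sequences treated as independent
realisations of shared parameters — the analysis assumes one common state
space, so dwell-times are comparable across participants. Per-participant
fitting is available by passing a single sequence.

The model is a Gaussian HMM with full covariances. Estimation is
multi-sequence Baum–Welch EM with per-step scaling; convergence is an
absolute change in total log-likelihood below 0.005 (the tolerance is in
log-likelihood units; with z-scored observations the total log-likelihood
is O(10³–10⁴), making this a strict criterion). Ten random restarts are
fitted (means drawn from random data rows, covariances from the pooled
data covariance plus jitter, Dirichlet-random initial/transition rows) and
the highest-likelihood fit is kept. Covariances carry a 1e−6 diagonal
floor; a collapsing covariance is re-regularised with escalating jitter
and a logged warning. Decoding is Viterbi in log space with ties broken
toward the lower state index, so outputs are deterministic.

State labels are arbitrary, so fitted states are reported in canonical
order: descending mean overall dwell-time. The default state count is 4,
with a sensitivity sweep over {3, 5, 6} available (`state_sweep`); the
log-likelihood is non-decreasing in the state count on the same data,
which the sweep reports for inspection. State indices are 0-based
throughout.

## Statistical layer

EO/EC validation compares each state's per-participant EO and EC
dwell-times with a two-sample t-test; an F-ratio variance pre-check at
α = .05 selects the pooled-variance test when variances are compatible and
Welch's test with Satterthwaite degrees of freedom otherwise. Group
comparisons use effect-coded 2×2 ANOVAs (Type-III-equivalent; exact for
the balanced design). Dwell-time regressions drop one state column
(default: the last canonical state) because dwell-times sum to one; the
overall F, R² and SSE are invariant to the choice, and each coefficient is
interpreted relative to the dropped state. Moderation is the partial
F-test for the joint significance of dwell × moderator interaction terms
added to a main-effects model. Correlation comparisons use the Fisher
r-to-z transform. No multiple-testing correction is applied; raw p-values
are reported with test counts so users can correct downstream, and p < .10
is labelled "marginal" in outputs.

## Synthetic data

`make_recording` renders a hidden state path (switching only on whole
1 s boundaries, aligned with the observation grid so dwell recovery is
exactly defined) as a sum over bands of white noise passed through the
same band-pass filters as the analysis path — generator and analyser agree
on band definitions by construction — scaled by the active state's band
gains, plus white sensor noise. Designated channels can share a common
band-limited driver with a constant phase offset applied via the analytic
signal, giving an analytically known pairwise PLI of 1 in the noise-free
limit; an optional channel partition shares per-group drivers with small
fixed intra-group lags to plant modular topology.

`make_cohort` simulates a balanced 2×2 (diagnosis × sex) cohort, 28 per
cell by default (112 participants). Each participant's state path follows
a sticky Markov chain (stickiness 0.8, giving realistic multi-second state
runs) whose stationary distribution is uniform during EO blocks and has
one state's occupancy multiplied by 3 during EC blocks — an
eyes-closed-boosted state emulating the posterior alpha rise with eye
closure (the strong Berger effect justifies a large factor). Behavioural
scores are linear in the true dwell-times plus Gaussian noise
(default: reaction-time variability loaded at −0.3 on the EC-boosted
state, noise SD 0.05 — chosen so the planted effect is detectable but not
trivial at n = 112); response-control measures (RT mean/SD, proportion
correct) are additionally realised through a per-participant synthetic
trial table (72 trials; RT-SD intercept 0.35 s, RT-mean 1.6 s, accuracy
0.8, typical of children's perceptual-decision data), so the observed
columns carry trial-sampling noise on top of the structural linkage.

What the generator does **not** emulate: 1/f background spectra, ocular
or muscle artifacts, volume conduction, head geometry. Passing tests
demonstrate that the chain recovers the structure it assumes — band-gain
profiles emitted i.i.d. given a Markov state path — not that real EEG
satisfies those assumptions. Effect sizes are chosen for testability, not
to mimic any particular dataset.

## Problem sizes and numerical choices

The default synthetic montage is 32 channels at 250 Hz (configurable);
tests and the bundled demo configuration use smaller montages and shorter
recordings, which leave every shape and recovery property unchanged.
Simulation-based checks use: 20 sequences × 300 observations for HMM
recovery; 10⁴ replications for Monte-Carlo type-I error of the test
statistics; 200 seeded replications for end-to-end cohort recovery.
Half-open [start, end) intervals everywhere; 0-based sample indexing
internally with user-facing times in seconds; all generators and fits are
bit-reproducible given (parameters, seed), with derived seeds spawned from
the master seed via `numpy.random.SeedSequence`.

## Known limitations

- The Louvain heuristic is exact only empirically: on small graphs with
  clear community structure it attains the enumerated optimum in ≥95% of
  seeded runs, but on weakly structured graphs (near-degenerate modularity
  landscapes) single-node-move heuristics — this one and reference
  implementations alike — can stop short of the global maximum.
- One group-level HMM assumes a shared state space; participants whose
  dynamics are genuinely idiosyncratic will be summarised poorly.
- EM converges to local optima; restarts mitigate but do not eliminate
  this, and likelihood is non-decreasing only up to the covariance-floor
  regularisation (monitored to 1e−6).
- EDF input is read-only and requires a sidecar schedule file; the native
  interchange format is the documented delimited text matrix.
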