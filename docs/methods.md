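# Methods

`siteexposure` analyzes how a transcription factor (TF) gains access to a
binding site buried inside a nucleosome, following the site-exposure picture:
the nucleosomal DNA transiently unwraps, exposing the site, and the TF traps
the unwrapped state by binding.  The package covers the full analysis chain
used in single-molecule FRET (smFRET) studies of this process — stochastic
simulation of trace data, two-state idealization, dwell-time kinetics, global
rate fitting, ensemble titration fitting, and free-energy comparison — so
that every estimator can be validated against data with known ground truth.

## The three-state kinetic model

States and transitions:

```
  1 (wrapped, high FRET)  <--k12/k21-->  2 (unwrapped, exposed)
  2  <--k23*[TF] / k32-->  3 (unwrapped, TF bound, low FRET)
```

* `k12`, `k21` — nucleosome unwrapping/rewrapping rates (1/s).  Rewrapping is
  fast (~10 ms time scale), so state 2 is populated ~1% of the time or less.
* `k23` — bimolecular binding rate constant to the *exposed* site (1/nM/s);
  `k32` — TF dissociation rate (1/s).
* Concentrations are nM and rates 1/s everywhere in the package.

The master equation `dX/dt = R X` over the column-convention generator `R`
has eigen-solution `X(t) = C0 + C- exp(l- t) + C+ exp(l+ t)`.  Because
`k12 << k21` and, at the concentrations of interest, `k12 << k23*[TF]`,
the slow relaxation of the "binding" variant of `R` (with `k32 = 0`, state 3
absorbing) is the apparent high-to-low FRET rate, and the slow relaxation of
the "release" variant (`k12 = 0`, state 1 absorbing) is the low-to-high
rate:

```
k_HL(c) = k12 / (1 + k12/(kon_eff c)),   kon_eff = (k12/k21) k23
k_LH(c) = k32 / (1 + kon_eff c / k12)
```

Only the triple `(k12, k32, kon_eff)` is identifiable from rate-vs-
concentration data; `k21` and `k23` enter only through their ratio.  The
package still carries `k21` explicitly (default 100 1/s for simulation,
consistent with ~10 ms rewrapping) so simulations run the full four-rate
chain; closed forms agree with the numeric eigenvalues to <2% throughout the
regime `k12 << k21, k23 c` (property-tested).

Derived scales: `KD_eff = k32/kon_eff` (apparent dissociation constant of
occupancy, comparable to the ensemble S1/2) and `c_cross = k12/kon_eff =
k21/k23`, the concentration where binding to the exposed site outpaces
rewrapping.  Their ratio `k32/k12` distinguishes the outer-region regime
(ratio << 1; occupancy saturates long before the crossover, FRET transitions
report individual binding/dissociation events) from the inner-region regime
(ratio ~ 1; `k_HL` saturates at `k12` and `k_LH` falls as the TF exchanges
many times per unwrapping episode).

## Synthetic data

The generator emulates the study conditions of the smFRET experiments:

* **State paths**: exact Gillespie simulation of the four-rate chain,
  starting in state 1 (configurable).  Per-trace random streams come from
  `numpy.random.SeedSequence.spawn`, so cohorts are reproducible and any
  trace can be regenerated alone.
* **Emission**: state 1 emits at `E_high = 0.75`; states 2 and 3 both emit
  at `E_low = 0.15` (the unwrapped DNA geometry, not TF occupancy, sets the
  dye separation).  Frames average the emission by occupancy time and add
  Gaussian noise `sd = 0.08`.  The levels are arbitrary but representative;
  real levels depend on labelling positions and are configurable.
* **Frame time 0.1 s, trace length 120 s, 400 traces per concentration**
  (the published cohort scale).  The acquisition rate of the original
  experiments is not stated; 0.1 s is chosen so the ~10 ms rewrapping
  flicker is far sub-frame (unobservable, as in the real measurement) while
  the ~0.1-2.5 1/s apparent rates give tens of events per trace.
* **Concentration grids**: 1-10 nM for the outer-region construct (P26),
  50-500 nM for inner-region constructs (P31, P36), matching the published
  ranges.
* **Titrations**: `E(c) = E0 - sum_i dE_i c/(S_i + c)` on a 12-point
  logarithmic grid 0.1-3000 nM, 3 replicates, noise sd 0.02.  Two-event
  defaults use amplitudes (0.3, 0.25) of `E0 = 0.75`, mirroring the
  >50% total FRET drop of the published curves.
* Optional exponential photobleaching truncates traces (off by default) to
  exercise the bleach-detection/truncation path.

What the generator does **not** emulate: photophysics (blinking, spectral
crosstalk, gamma), baseline drift, heterogeneous per-molecule rates, and the
multiple low-FRET sub-states seen in some real traces.  Passing recovery
tests therefore demonstrate estimator correctness under the model's own
assumptions, not robustness to these real-data complications.

## Idealization

Traces are reduced to two-state step functions with a maximum-likelihood
Gaussian HMM (EM + Viterbi decoding; `hmmlearn` backend).  Initialization:
means at the 10th/90th percentiles, equal sds at the trace sd, symmetric
transition probability 0.05; up to 3 jittered restarts; tolerance 1e-6 in
log-likelihood, max 500 iterations.  States are canonically ordered by mean.
Real analyses often use variational-Bayes idealizers for this step; since
the labels are consumed only as dwell times, plain ML with two states is
sufficient and fully specifiable.  The number of states is fixed at two,
deliberately collapsing any low-FRET sub-states.

A fit is declared **degenerate** when the two fitted means separate by less
than 3x the mean fitted sd.  This matters for transition-free traces: EM
happily splits a single noisy level into two pseudo-states ~0.05 apart and
would otherwise flood the dwell pools with junk one/two-frame dwells.
Degenerate traces carry a single-state labelling and are excluded from rate
estimation.  If EM fails on data that do show two separated levels, a
midpoint-threshold idealization is returned with a `fallback` flag.

A threshold idealizer (label high iff E > cutoff, optional single-frame blip
filter) provides an independent cross-check; on default-SNR cohorts it
agrees with the HMM on >=95% of frames.

## Dwell-time analysis

Dwells are contiguous same-label runs times the frame time.  The first and
last runs of every trace are right-censored.  Dead time: dwells shorter than
`t_min = 2` frames are discarded and all likelihoods are left-truncated
(renormalized on `[t_min, inf)`) — single-frame events are ambiguous at this
SNR.

Censoring policy: by default censored dwells contribute survival terms
`S(t)/S(t_min)` to the likelihood.  For a single exponential this gives the
closed form `rate = n_uncensored / sum(t_i - t_min)`.  The alternative of
excluding censored dwells entirely is available but not default: whenever
mean dwells are not small relative to the trace length (e.g. ~26 s dwells in
120 s traces for P31 at 50 nM), exclusion length-biases the retained dwells
short by tens of percent, while the survival likelihood stays unbiased.

Both one- and two-component exponential fits are computed (the mixture by
Nelder-Mead over `(log l1, log l2, logit a)` with multiple starts); a
likelihood-ratio test (chi-squared, 2 df, alpha = 0.05) selects between
them, with BIC reported alongside.  Real data show double-exponential dwell
distributions with a dominant fast population; when the mixture wins, the
reported "primary" rate is the larger-amplitude component (ties to the
faster), which also absorbs the dead-time spike occasionally present at
`t_min`.  Per-concentration standard errors are nonparametric bootstrap over
traces (default 200 replicates), refitting the selected model.

**Missed-event correction.**  Dwells of the opposite state shorter than the
idealizer's detection limit go unseen and merge the flanking dwells, biasing
both apparent rates low.  To first order `k_obs = k_true exp(-k_opp tau)`;
the pipeline inverts this pair by fixed-point iteration.  The dead time
`tau` is a measured property of the idealizer, not a fit parameter: the
isolated-event detection probability curve of the two-state HMM at default
SNR integrates to ~1.6 frames, and the pipeline uses 1.5 frames.  Without
the correction, apparent `k_HL` runs 10-25% low (worst for sparse
inner-region cohorts, where the global fit amplifies the differential bias
into ~-25% on `k12`); with it, recovered triples land within ~7% of truth
across constructs and seeds.  Set `missed_event_frames: 0` to disable.

## Global kinetic fitting

`k_HL(c)` and `k_LH(c)` are fit jointly for the shared triple
`(k12, k32, kon_eff)` by weighted least squares in log-parameter space
(positivity without constraints), multi-start from data-driven heuristics.
Weights default to inverse bootstrap variances so neither curve dominates;
an unweighted option exists for sensitivity checks.  Confidence intervals
are a parametric bootstrap of the rate points (each point's rates redrawn
from Gaussians at its SE, default 500 replicates): with only 3-4
concentrations, resampling point identities is nearly information-free,
while the parametric form propagates the measured uncertainties and
correctly widens the `k12` interval when the concentration range stops short
of `c_cross`.

The simple two-state linear fit (slope of `k_HL` through the origin, and the
inverse-variance-weighted mean of `k_LH`) is provided for outer-region data;
on saturating data it underestimates `kon_eff`, which is the point of the
comparison.  Fold changes between constructs are ratios of fitted parameters
with first-order error propagation.

## Ensemble titrations

Titrations are fit to one- or two-event binding isotherms
(Hill coefficient fixed at 1) by bounded nonlinear least squares.  The model
is parameterized by the saturation efficiency `E_inf >= 0` and non-negative
amplitudes, making the constraint `E0 - sum(dE) >= 0` structural; S-values
are fit in log space, bounded within two decades of the sampled range, from
a grid of starts.  Replicates enter individually so standard errors reflect
replicate scatter; concentration-zero points pin `E0`.  One vs two events is
decided by an extra-sum-of-squares F-test at alpha = 0.05 — a quantitative
stand-in for the visual "two inflection points" judgement.  A minimal affine
conversion between acceptor-ratio measurements and FRET efficiency is
included; full spectral unmixing is out of scope.

With the default grid the second event of the P23-like truth (S2 = 380 nM)
sits less than a decade below the top concentration, so its precision is
information-limited to ~20% (unbiased); the first event recovers to <15%.

## Free-energy profile and landscape comparison

Relative occupancy free energies are `ddG = ln(v / v_ref)` in kBT, where `v`
is an ensemble S1/2 or a kinetic `KD_eff`, with first-order error
propagation; the reference construct (default P26) sits at exactly 0.
Binding sites map onto the unwrapping coordinate as `inner_edge_bp + 3`
(the DNA must unwrap ~3 bp past the inner edge of the site), placing P26 at
position 29.  Against an unwrapping-landscape table (TSV, linearly
interpolated), the profile is first calibrated by a constant shift at
position 29 — making the comparison invariant to reference choice — and then
compared by a two-sample Kolmogorov-Smirnov test on position-matched values;
a paired sign-flip permutation test on the residuals is available as an
alternative since the published analysis does not state its exact KS
construction.  Energies can be reported in kcal/mol via 0.593 kcal/mol per
kBT (298 K).

The repository does not redistribute the published force-spectroscopy
unwrapping landscape; `synthetic_unwrapping_landscape()` generates a
clearly-labelled synthetic stand-in with the same qualitative shape (shallow
outer region, sharp ~4.5 kBT rise between 30 and 35 bp).  Quantitative
agreement statements (e.g. the published KS P-value) require the real
landscape table, supplied by the user.

The bundled ensemble S1/2 table reproduces the ~30 bp accessibility barrier:
mapped positions <= 32 vs >= 34 differ by >= 3 kBT (a ~100-fold change in
apparent affinity over a few base pairs).

## Problem sizes and determinism

Recovery runs use the published cohort scale — 400 traces per concentration,
four concentrations per construct, 120 s traces at 0.1 s frames — and
complete in ~30 s per construct on one CPU; unit tests use smaller cohorts.
Every stochastic step (simulation, bootstraps, permutation tests) is seeded,
with per-trace and per-stage streams derived from a single master seed, so
identical configurations produce identical reports.

## Known limitations

* The dwell pipeline's biases (frame discretization, boundary-frame
  ambiguity, residual missed events) are corrected only to first order;
  residual systematic error is a few percent, which matters most for the
  extrapolated `k12` of constructs whose concentration range stays well
  below `c_cross`.
* The dead time `tau = 1.5` frames was measured for the default SNR
  (level gap 0.6, noise 0.08); markedly different SNRs warrant re-measuring
  the detection curve.
* Two FRET levels are assumed; systems with resolvable intermediate levels
  need a different idealizer.
* The missed-event correction assumes exponential opposite-state dwells;
  it is first-order and capped (factor e^0.5) for stability when rates
  approach the frame rate.
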