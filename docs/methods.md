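# Methods

## The estimation problem

Widefield (one-photon) optogenetic stimulation drives many neurons at
once.  Any response of a downstream neuron C could have been caused by any
of the co-stimulated neurons, so regressing C's response on one stimulated
neuron's spiking is confounded: naive regression (OLS) and cross-correlogram
(CCH) readouts report effective connections that do not exist.  The
package estimates *effective connectivity* — the change in a postsynaptic
neuron's spike probability caused by one extra presynaptic spike,
including network-mediated paths — using two ideas from econometrics:

* **Instrumental variable (IV / Wald).**  The presynaptic neuron's
  absolute refractory period makes it randomly unable to comply with
  stimulation.  The indicator Z ("spiked 1–2 ms before stimulus onset")
  affects the during-stimulus response X but, conditional on the network
  state, nothing else — so the Wald ratio
  `(E[Y|Z=0] − E[Y|Z=1]) / (E[X|Z=0] − E[X|Z=1])` identifies the causal
  effect of X on the downstream response Y.  Note the flip relative to
  textbook IV notation: Z = 1 marks *non*-compliance, and absolute
  refractoriness forces `E[X|Z=1] = 0`.
* **Difference in differences (DiD).**  Slow network states (up/down
  states, common drive) violate instrument independence.  Subtracting the
  response in a reference window shifted one window width earlier
  (Y*, X*) cancels additive trends shared by the strata (parallel-trends
  assumption).  The IV/DiD ratio is implemented exactly as the four-term
  numerator over the four-term denominator; under the default windows X*
  coincides with Z, so the denominator is `−(1 + E[X|Z=0])` while the
  numerator gains the transmission of the refractory-period spike itself —
  the two effects cancel and the ratio still converges to the causal
  effect (verified on the three-neuron system, where IV/DiD on the
  connected pair agrees with the calibrated ground truth to <1%).

## Generative model

Spiking is a binomial GLM on 1-ms bins: neuron i spikes at t+1 with
probability `sigmoid(h_i(t) − b + U_i(t))`, where `h_i` collects the last
H = 10 ms of its own spikes through a refractory filter (−100 on lags 1–3,
−30·exp(−(lag+4)/2) after) and of presynaptic spikes through weights W and
an exponential coupling filter supported on lags 1–5.  The bias b = 5 sets
a ~6.6 Hz baseline; with the standard confounder drive the population sits
near 10 Hz.  The drive U is a sum of pulse trains (optogenetic stimulus:
amplitude γ_S on three bins per onset; excitatory/inhibitory confounders:
11-bin pulses) with clipped-Poisson onset spacing.  History before t = 0
is silent; a discarded burn-in (default 1000 ms) removes the transient.

**Coupling-filter lag origin.**  The package's default coupling filter is
`c(lag) = exp(−α (lag − 1))`, i.e. a *unit first tap*.  The alternative
`exp(−α·lag)` (first tap `e^−0.2`) is available via
`NetworkSpec(coupling_lag_origin=0)`.  The unit-tap convention is the one
under which the closed-form causal effect of a single presynaptic spike,
`σ(W − b) − σ(−b)`, is exact for a non-refractory pair; empirically it is
the only convention under which the r = 0 calibration control recovers
slope 1.00 (the decayed-tap convention gives ~0.71), which is the model
check the calibration procedure is built on.

## Ground-truth calibration

Errors are computed against `β_ij = α (σ(W_ij − b) − σ(−b))`.  The
shrinkage constant α absorbs everything the closed form ignores —
coupling decay across the 2-ms response window, responses that escape the
window, and refractory suppression of the downstream window.  It is
measured by `calibrate_alpha`: two-neuron blocks (one per weight on a grid
spanning 1–7, run jointly as a block-diagonal network so each weight gets
the full 10^6 steps), trials on a regular 50-ms grid, 2-ms X and Y windows
at offsets 0 and +2 ms, OLS conditional differences regressed through the
origin on the closed form.  A companion block with the refractory filter
removed must recover slope 1 (it does: 1.01 ± 0.02); the refractory block
gives **α = 0.66 ± 0.02** (`CALIBRATED_ALPHA`, mean of five 10^6-step
runs).  The originally reported constant 0.9477 (`DEFAULT_ALPHA`) is kept
as a reference but could not be reproduced under any trial construction we
tried (stimulated and unstimulated trials, 2- and 3-bin pulses, several
window offsets); the calibration trial construction behind that constant
is under-specified, and all internal error metrics therefore use the
self-consistent 0.66.  The dominant shrinkage mechanism is mechanical:
when the presynaptic spike falls in the first bin of the X window, the
downstream response at lag 1 lands *before* the Y window and refractorily
suppresses it.

## Windows

Z/X/Y are 2-ms windows at offsets −2/0/+2 ms from stimulus onset,
half-open `[t₀, t₀+2)` so the three windows tile the axis exactly and the
starred (DiD) windows coincide with the preceding window.  A spike 1–2 ms
before onset leaves the neuron absolutely refractory through the whole X
window, so `E[X|Z=1] = 0` holds exactly on simulated data (asserted in
tests).  The printed indicator with closed intervals would overlap at
endpoints at 1-ms resolution; half-open windows resolve that.

## Cross-correlogram baseline

Counts of postsynaptic-minus-presynaptic lag pairs over ±50 ms; baseline
from convolution with a unit-mass hollow Gaussian (SD 10 ms, hollow
fraction 0.6, reflection padding — defaults follow the methodology the
estimator derives from; both configurable since they are not printed).
Spike transmission probability sums baseline excess over lags 3–6 ms
(inclusive) per presynaptic spike.  Significance requires both the
Poisson continuity-corrected tail probability of the positive-lag peak
against the smoothed baseline (p_fast) and against the maximum
negative-lag bin (p_diff) to fall below 0.01.  Note that in this
simulator monosynaptic transmission peaks at 1–2 ms lag, so the 3–6 ms
window can report near-zero or negative transmission for genuinely
connected pairs; this is a property of the printed window, kept as is.

## Optics model

Kubelka–Munk scattering `T = 1/(S r + 1)` times conical geometric loss
`ρ²/(r+ρ)²` with `ρ = (d/2)√((n/NA)² − 1)`; Hill photocurrent
`P = I_max I^h/(K^h + I^h)`.  Defaults: S = 10.3 mm⁻¹, fiber radius
0.1 mm (the source tabulates "0.1 μm", read as an erratum: the geometry
formula needs the fiber diameter and a 0.2-μm fiber is not physical),
NA = 0.37, n = 1.36, I₀ = 10 mW/mm², I_max = 642 pA, h = 0.76,
K = 0.84 mW/mm².  Neurons occupy cone-truncated spherical shells (cone
half-angle asin(NA/n)), so shell counts grow ~r²; because the Hill
exponent is < 1 the summed per-shell photocurrent *increases* with
distance over [0, 1 mm] — widefield stimulation is not local.  Stimulus
gains are the normalized photocurrent at a neuron's random distance
(density ∝ r² over [0, 0.7 mm]); γ_S scales the gain ceiling.

## Synthetic data: what it does and does not emulate

The generator reproduces the stated world: binomial-GLM spiking with
absolute/relative refractoriness, pulsed stimulation with clipped-Poisson
timing, slow confounder drives, Dale's-law Gaussian connectivity with
1/√n scaling, and distance-distributed stimulus gains.  It does not model
membrane potentials, conduction delays, synaptic plasticity, measurement
noise (spike sorting, jitter), or non-stationary opsin kinetics.  A green
test therefore establishes that the estimators behave as claimed *within
this model class*, not that they would on recorded data.

## Desk-scale experiments

The original sweeps are cluster-scale (hundreds of networks, ~10^6-trial
convergence).  Shipped defaults reduce them to minutes on one CPU
(networks ≤ ~180 neurons, 10^5–10^6 simulated ms); `configs/*.yaml` carry
figure-scale versions.  Two scaled-down caveats matter when reading the
ordinal comparisons:

* The IV-side estimators converge slowly because refractory (Z = 1)
  trials are rare (~1.3% of trials at baseline rates): their sampling
  noise floor dominates until ~10^5 trials per pair.
* At fixed connectivity scale σ, per-entry weights shrink as 1/√n, so
  small networks draw occasional large weights whose errors dominate MAE
  comparisons across sizes; desk-scale size comparisons average several
  network draws.

## Numerical choices

* Sigmoid evaluated in a branch-safe form; probabilities never exactly 0/1.
* Undefined estimates (empty stratum, zero denominator) propagate as NaN
  and are excluded (and counted) in every aggregate.
* Bootstrap SEs resample the 32-cell joint distribution of
  (Z, X, Y, X*, Y*) — exact nonparametric bootstrap at O(n_boot) cost.
* Condition number: SVD of the N×N covariance of the spike matrix over
  time; σ_min at machine-epsilon scale flags degeneracy (reported ∞).
* Clipped Poisson = draw-then-clip, not rejection; degenerate clipping
  (min = mean = max) gives a regular grid.
* Onsets whose windows cross raster edges are dropped, never clipped.
* Autapses are excluded (the refractory filter already carries
  self-history).

## Known limitations

* α = 0.9477 is not reproduced (see calibration section); all error
  metrics are self-consistently calibrated instead.
* The 3–6 ms transmission window under-reads 1–2 ms synapses (above).
* `iv_did`'s printed four-term denominator is kept verbatim; a
  `drop_xstar` variant exists for sensitivity analysis.
* Weak-instrument variance makes IV-side estimates unstable below ~10^4
  trials per pair; the bootstrap SEs surface this.
* On the three-neuron system IV/DiD retains a residual bias of ~−0.03 on
  the unconnected pair (about 5% of the connected pair's effect, against
  27% for OLS's spurious positive).  Pulsed confounders violate the
  parallel-trends assumption at pulse edges — the reference window and
  the response window do not see identical drive — so "zero within
  Monte-Carlo error" eventually fails as the SE shrinks below this
  residual at ≥10^5 trials.
* Like any balanced Dale matrix, the assembled connectivity carries a
  rank-1 E/I mean mode dominating its raw largest singular value; the
  fluctuation spectrum matches the half-size draw (within ~7%).
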