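# Methods

`srsync` implements a complete desk-scale analysis of stochastic resonance
(SR) in neural synchronization: a synthetic generator of source-level EEG with
noise-modulated phase resetting and inter-source coupling, Morlet
time-frequency decomposition with baseline-normalized power (ERSP), normalized
power-ratio SR curves with per-subject and group criteria, trial-wise
cross-coherence (phase-locking value, PLV), and a two-criterion resampling
inference with a red/blue/gray cell classification. This note documents the
models, the parameters that matter, the numerical choices, and what passing
tests do and do not establish.

## The generative model

### Ongoing gamma activity and stimulus phase reset

Each simulated source emits, per trial,

```
x(t) = a_bg * n_1/f(t) + a_osc * (1/M) * sum_m cos(2*pi*f0*t + phi_m(t))
```

where `n_1/f` is Gaussian noise with power spectral density proportional to
1/f over 1–100 Hz (normalized to unit variance in expectation, so the process
stays Gaussian and stationary), and the oscillation is the *mean of a
population* of `M = 50` unit oscillators at `f0 = 40 Hz`. Before stimulus
onset each oscillator's phase offset `phi_m` is an independent draw from
Uniform(−π, π]: the population resultant is small (≈ 1/√M) and the aggregate
40-Hz rhythm has random phase and low amplitude. At `t = 0` every offset
relaxes exponentially (time constant `tau_reset = 25 ms`, wrap-aware shortest
path) toward a target drawn from von Mises(0, κ).

The von Mises concentration κ controls how completely the population
synchronizes on the stimulus-locked phase. Partial alignment raises the
aggregate amplitude toward `R(κ) = I1(κ)/I0(κ)`, producing (i) an event-locked
gamma power increase measurable by ERSP and (ii) inter-trial phase coherence
at 40 Hz. This population formulation matters: a *single* oscillator whose
phase is merely reset leaves the trial-averaged power spectrum unchanged
(per-trial `|W|²` does not depend on phase), so phase reset without population
aggregation produces no ERSP response at all. The population mean is the
model of an independent-component activation — the summed dendritic currents
of a tuned neural group.

### The stochastic-resonance profile

Acoustic noise level enters through a single inverted-U profile,

```
kappa(sigma) = kappa0 + kappa_sr * (sigma/sigma_opt)^2 * exp(1 - (sigma/sigma_opt)^2)
```

with `kappa(0) = kappa0`, a unique interior maximum `kappa0 + kappa_sr` at
`sigma = sigma_opt`, and decay back to `kappa0` for large noise. The
underlying studies establish only the qualitative inverted-U shape; this
two-parameter form was chosen for its closed-form peak and smoothness, and its
parameters are a modeling choice, not a fit to any published curve.

Noise-condition labels map to linear amplitude as `sigma = scale * 10^(dB/20)`
with the no-noise label at exactly 0. Defaults: `scale = 1`, `sigma_opt = 1`,
so the profile peaks at the "0 dB" condition; reset parameters
`kappa0 = 0.2`, `kappa_sr = 2.5` give `R(κ)` spanning ≈ 0.10 (no noise) to
≈ 0.80 (optimal noise) — a strong but not saturated response, chosen once so
that a 100-trial study resolves the peak condition reliably.

### Inter-source coupling

A coupled pair shares, inside one (band × window) cell, band-centre
oscillations whose per-trial phase difference is von Mises(0, λ) with λ given
by the same profile form (defaults: alpha band 9–14 Hz, window 50–300 ms,
`kappa0 = 0`, `kappa_sr = 4`). Outside the window the two phases are
independent; the prescription is entered and left through a 10-ms wrap-aware
exponential relaxation so the instantaneous phase is continuous. Coupling is
*trial-wise* (the reference phase is random per trial), so trial-shuffling
surrogates destroy it — unlike the stimulus-locked 40-Hz reset, which is
deliberately invisible to trial shuffling. Configurations that give the same
source two contradictory phase prescriptions in overlapping pixels are
rejected.

### Scale

Defaults: 10 subjects × 4 sources × 6 conditions × 100 trials, 250 Hz,
epochs −150..+450 ms. The emulated study used ~950 trials per condition;
100 is the deliberate desk-scale choice, and all recovery criteria are stated
at that size.

## Time-frequency analysis

* **Grid.** 25 geometrically spaced bins over 5–55 Hz. Cycle counts grow as
  `cycles(f) = c0 * (f/f_min)^0.5` with `c0 = 3` — slower-than-linear growth,
  giving proportional bandwidth with improving temporal resolution.
* **Wavelets.** Complex Morlet kernels with `sigma_t = cycles/(2*pi*f)`,
  truncated at ±2.5 σ_t, normalized to unit kernel sum so a unit-amplitude
  cosine at the centre frequency yields |coeff| = 0.5. Phases agree with
  MNE's Morlet transform to < 0.05 rad on strong signals (tested).
* **Edge policy.** No zero padding: coefficients are valid only where the
  truncated kernel fits inside the epoch, and invalid pixels are excluded from
  every window statistic. Consequence: with 600-ms epochs whose baseline
  abuts the epoch edge, frequencies below ≈ 30 Hz have no valid baseline
  sample; those ERSP rows are masked invalid rather than imputed. The gamma
  range that carries the 40-Hz analysis remains fully analyzable; PLV cells
  (which need no baseline) use the whole grid.
* **ERSP.** `P(f,t)` is the trial-mean squared magnitude; baseline power per
  frequency is the arithmetic mean of `P` over the *valid* samples inside the
  baseline window (−150..−50 ms by default); the map is `10*log10(P/baseline)`.
  With an arithmetic-mean baseline the mean *power ratio* over the baseline is
  exactly 1 by construction, while the mean of the dB values is only ≈ 0
  (Jensen's inequality); the tests assert the exact identity and bound the dB
  gap.
* **Custom band.** The subject-specific gamma window is the contiguous
  frequency span around the peak response pixel (30–50 Hz × response window)
  where the per-frequency profile stays ≥ 50% of the peak dB; ties break to
  the lower frequency; absent any positive response the conventional 35–45 Hz
  fallback is used. The 50% span rule and the tie-break are this package's
  choices (no width rule is published).

## Power-ratio SR curves

Window power ratio = `10^(S/10)` with `S` the *sum* of ERSP dB over valid
window pixels — taken literally, so the ratio is a product of per-pixel
ratios. (Using the mean instead would only rescale monotonically within a
fixed window and leave the argmax and the normalized curve unchanged.)
Curves are normalized per subject × source × ear × band-mode by the maximum
across the six conditions. A subject shows SR when the unique curve maximum
falls at an added-noise condition; any tie is conservatively counted as no SR.

Group criteria per condition: the 2-SE flag uses the standard error of the
condition itself (the rule could equally be stated with the control's or the
paired-difference SE; the condition SE is adopted and documented); the Dunnett flag is a two-sided many-to-one comparison of each
added-noise condition against the no-noise control on within-subject
differences with pooled variance (df = m(n−1)), with critical values from
10⁵ Monte-Carlo draws of the exact null pipeline (cached per (n, m, α), fixed
internal seed so pipelines are byte-reproducible). Null family-wise error is
calibrated at 0.05 ± 0.02 by test.

One deliberate departure from the emulated study: when a subject contributes
several components to one cluster, the study kept the one with the *greatest
SR effect* — a selection rule that biases toward finding SR. The pipeline
takes exactly one series per subject × source and does not replicate that
selection.

## Phase locking and inference

PLV is the phase-only form: each trial contributes the *unit* phasor of its
cross-spectral product, so amplitudes cancel exactly; zero coefficients carry
no phase and are dropped per pixel with the effective N recorded. Under
independence the window-mean PLV is ≈ √(π/4N) (Rayleigh), which the tests pin
at N = 100 and use to verify the N^(−1/2) bias law.

* **Permutation test** (condition difference): pixel values pooled across
  subjects, random bipartition preserving group sizes, 1000 surrogates,
  significant only if the observed difference exceeds all of them (exact
  level 1/1001, verified by calibration). The exchange unit is the pixel
  value — a literal pooling of everything in the window; subject-level exchange
  would be stricter and is noted, not default.
* **Per-subject masks**: 200 trial-pairing shuffles of one source, pixel
  significant when the empirical p `(1 + #{surr >= obs})/(n_shuffle + 1)` is
  ≤ 0.01 — for 200 shuffles, exceeding the 2nd-largest surrogate, null rate
  2/201. Several shuffling constructions would qualify; trial-order
  permutation of one member is the one adopted (it preserves both marginals
  and kills trial pairing).
* **Group mask**: exact binomial threshold `k_min` = smallest k with
  `P(Bin(n, 0.01) >= k) < 0.001` (k_min = 3 for n = 7..10), then a contiguity
  filter keeping only 4-connected clusters of ≥ 3 pixels (the cluster size and
  4-connectivity are this package's choices).
* **Classification**: red requires an added-noise condition passing both
  criteria with no reliable no-noise locking; blue requires reliable no-noise
  locking, reliable locking in at least half the added-noise conditions, and at least one significant condition
  difference; gray otherwise.

## Numerical and degenerate-input choices

* All randomness flows through `numpy.random.Generator`s derived from explicit
  seeds (`SeedSequence([seed, stage, indices...])`); identical config + seed
  gives bit-identical epochs and byte-identical CSVs (tested).
* CSV floats are written at 6 significant digits; the epochs container stores
  float32.
* `binomial_kmin` returns 0 when alpha ≥ 1 (unconstrained) and raises an
  infeasible error when no k ≤ n meets the bound (e.g. n = 2, p = 0.05,
  α = 0.001).
* Exact zero coefficients (possible only for degenerate inputs) are excluded
  from PLV and surrogate statistics rather than mapped to zero phasors.
* Zero-variance group curves short-circuit the Dunnett t statistic: any
  nonzero mean difference is flagged.

## What the synthetic data does and does not establish

The generator reproduces the statistical structure the analysis assumes —
random-phase ongoing oscillations, stimulus-locked partial reset with an
inverted-U noise profile, trial-wise band-limited coupling, 1/f background —
and the tests show the pipeline recovers planted SR reliably at study scale
and stays at chance under null profiles. It does not emulate volume
conduction or ICA unmixing error, non-stationary arousal drift, artifacts,
inter-subject variability in optimal noise level (all subjects share
`sigma_opt`), or amplitude asymmetries between hemispheres. Passing tests
therefore validate the *methods* — calibration, exactness, recovery power —
not any claim about real cortical sources.

## Problem sizes used in tests

Recovery and calibration tests run at the study's stated desk scale
(10 subjects × 100 trials; 2000 permutation replicates; 25–50 seeded runs for
classification and compound-null checks). Generator shape invariants
(e.g. the inverted-U ITC peak) use reduced replicate counts with binomial
slack. The pipeline determinism check runs on a 3-subject, 2-source, 40-trial
configuration — determinism is a property of the computation, not of the
problem size.
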