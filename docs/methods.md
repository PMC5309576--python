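# Methods

This note documents the models, estimators and numerical choices behind
`tidalcompare`, and what the synthetic-data tests do and do not establish
about real recordings.

## The measurement problem

Two devices observe the same breathing simultaneously. The
pneumotachograph (PNT) measures airflow at the mouth at 100 Hz; tidal
volume is its running integral. Structured light plethysmography (SLP)
measures thoraco-abdominal (TA) wall displacement at 30 Hz in arbitrary
units. The devices measure different physical quantities, are started by
hand (unknown relative delay), and differ in gain, noise and baseline
behaviour, so some disagreement in the derived tidal indices is expected;
the question is whether it is small enough for the devices to be used
interchangeably. All timing indices are computed from *unfiltered*
signals; filtering exists only to serve cross-correlation alignment,
because band-pass filtering can distort marker timing.

## Synthetic recordings

### Breath model

A breath train is a sequence of contiguous breaths. Per breath, tI and tE
are drawn independently from gamma distributions (positive support)
parameterised by mean and coefficient of variation; markers accumulate
from t = 0. Within a breath, volume rises over the inspiratory limb as a
symmetric Beta CDF,

    v(u) = A · I_u(a, a),   u = t/tI ∈ [0, 1],

and falls over the expiratory limb as A·(1 − I_w(b, b)). Flow is the
analytic derivative A·f_Beta(u; a, a)/tI. Because the symmetric Beta
median is exactly ½, the flow magnitude where each limb crosses 50 % of
the tidal excursion is A·f(a)/tI with f(a) = 0.5^(2a−2)/B(a, a), giving
the closed form

    IE50 = (tE/tI) · f(a)/f(b).

Given a target IE50, one limb keeps the baseline concentration a = 2 and
the other concentration is solved by Brent's method on f's increasing
branch. Two properties motivated this family over cosine limbs with a
power-law time warp:

* an exact analytic IE50 per breath, so every downstream IE50 estimate has
  a closed-form oracle; and
* non-degenerate curvature at the markers. A power-law warp u^p places a
  zero-curvature (flat) extremum at the warped limb's start; under
  measurement noise a flat extremum lets the detected marker wander
  0.1–0.2 s toward the flat side, a simulation artifact rather than a
  device property. In the physiological IE50 range the Beta
  concentrations stay near 2–3 and all extrema have finite curvature.

### Device chains

* **PNT**: flow = analytic flow + white Gaussian noise (default SD
  0.005 L/s ≈ 1 % of peak flow); volume = cumulative-trapezoid integral
  of the *noisy* flow, exactly as a pneumotachograph acquisition chain
  integrates. The volume therefore carries a small random-walk component,
  and the conservation invariant (∫flow = volume to 10⁻⁶·A) holds by
  construction.
* **SLP**: displacement = gain · v(t − δ) + drift + noise at 30 Hz, with
  device gain (default 1, jittered across subjects), start delay δ
  (default 0.5 s — manual start synchronisation), sinusoidal baseline
  drift (default 0.05 au over a 40 s period) and white noise (default
  0.003 au, 0.6 % of the tidal excursion, consistent with the smoothness
  of averaged full-wall displacement traces). An optional monotone
  piecewise-linear time warp through per-marker jitter N(0, σ) models
  breath-timing distortion between the TA wall and airflow; its
  closed-form consequence (tTot difference SD = σ√2) is used as a
  pipeline oracle.
* **Artifact breaths** (swallows, glitches): short (0.6 s) low-amplitude
  (0.1·A) oscillations inserted after a breath with a configured
  per-breath probability, flagged in the ground truth.

Defaults describe resting adult breathing (tI 1.85 s, tE 2.60 s, RR
≈ 13.5 brpm, IE50 1.2, tidal volume 0.5 L); `SimConfig.post_exercise()`
is an elevated preset (tI 0.66 s, tE 0.73 s, RR ≈ 43 brpm, IE50 0.99).
Within-subject timing CV defaults to 0.10 — a free parameter of the
generator, chosen as typical quiet-breathing variability; it is not
calibrated against any cohort, and cohort-level between-subject jitter
(CV 0.15 on timing means, IE50 and gain) is likewise a modelling choice.
Per-subject seeds are spawned from the master seed by counter.

### What the simulator does not model

Regional (ribcage vs abdomen) wall motion, thoraco-abdominal asynchrony,
posture and movement artifacts, camera/grid reconstruction noise
structure, apnoea, and amplitude (tidal-volume) drift across breaths.
Passing tests therefore establish correctness of the *algorithms* under
controlled violations (noise, drift, lag, gain, jitter, artifacts), not
device performance on clinical data.

## Preprocessing

1. **Resampling**: the SLP trace is raised to the PNT rate with scipy's
   PCHIP (monotone piecewise cubic Hermite) interpolant — it reproduces
   samples, preserves monotone spans, and cannot overshoot.
2. **Alignment filter**: order-5 elliptic band-pass, 0.5 dB pass-band
   ripple, ≥ 50 dB stop-band, edges 0.05–10 Hz, realised as second-order
   sections. Applied forward and backward (`sosfiltfilt`) with
   odd-reflection padding sized to 3× the slowest pole's decay to 1e-9
   (capped below the trace length), so in-band features do not move.
3. **Lag estimation**: normalised (zero-mean, unit-energy over the
   overlap) cross-correlation of the two *filtered* copies over ±5 s;
   normalisation makes the estimate invariant to inter-device gain.
   Ties — possible for periodic signals — resolve to the smallest
   absolute lag. A peak below 0.5 flags the pair for a manual lag
   override (`--lag-override`), the programmatic analogue of aligning a
   recalcitrant pair by eye.
4. **Truncation**: the estimated lag is applied to the *unfiltered*
   traces and both are cut to the shared epoch, sample-exactly. Analysis
   then drops a 15-s lead-in and keeps a 45-s epoch (both configurable).

### Interpolation fidelity

A design budget of 5 ms is attached to the resampling step. Two facts
matter when measuring it:

* A shape-preserving interpolant pins its extrema to the input extremum
  samples (at a data local maximum the monotone constraint forces a zero
  derivative), so the distance from *continuous-time truth* is governed
  by the 30 Hz acquisition — up to half an input interval, 16.7 ms — for
  any such interpolant. That distance is a property of the sampling, not
  of the interpolation.
* The displacement *introduced by the resampling step* — resampled-grid
  extrema versus the original 30 Hz sample extrema — is what the budget
  can control. Measured over a seeded suite of 100 random respiratory-band
  (≤ 2 Hz) multi-tone waveforms it is 6.7 ms (exactly 2/300 s): on an
  asymmetric flat top the 100 Hz argmax can land on the second-nearest
  grid point, slightly beyond the idealized half-output-sample (5 ms)
  bound. `scripts/acceptance.py` recomputes this number; the acceptance
  suite asserts the 5 ms budget and the assertion fails by that 1.7 ms
  margin — kept as an honest statement of the discrepancy rather than
  widened.

## Breath detection

Candidate extrema are zero crossings of the first derivative (central
differences), with the derivative — never the signal — smoothed by a
0.2 s moving average so noise does not make crossings chatter. Each
candidate is refined to the most extreme raw sample nearby (the window is
clipped so candidate order is preserved) and then to sub-sample precision
by the vertex of a three-point parabola, clamped to ±1 sample.
Consecutive same-kind extrema collapse to the more extreme one.

Screening replaces the visual curation a human scorer would do, with
explicit rules so runs are reproducible:

* **reversal pruning**: adjacent extremum pairs whose excursion is below
  25 % of the candidate envelope are removed iteratively (noise chatter
  around flat extrema, artifact oscillations). When a removed trough
  near-ties its same-kind neighbour, the *later* position is kept — an
  inspiratory start is the last trough before the rise, so after pruning
  an oscillation inside a flat pause the marker must sit at the pause's
  end;
* **assembled-breath rules**: tTot within [0.5, 15] s and inspiratory
  amplitude ≥ 25 % of the median. Partial breaths at the epoch edges are
  dropped because a breath needs all three markers.

Every removal is logged with its reason. Device pairing is a greedy
one-to-one nearest match on inspiratory-start times within 0.5 s —
proximity rather than ordinal index, so a breath missed by one device
desynchronises nothing.

On noise-free recordings the pipeline recovers every interior marker
within one sample at 100 Hz (property-tested). With realistic noise the
residual marker error is a few tens of ms and is biased toward an
extremum's flatter limb; both devices share the bias, so it largely
cancels in the differences (residual tI/tE biases of ±0.01–0.09 s in the
default study, consistent in magnitude with published device
comparisons).

## Parameters

Timing indices are exact arithmetic on the markers (tI + tE ≡ tTot,
RR·tTot ≡ 60 to machine precision, asserted per row). IE50 interpolates
|rate| where each limb crosses the midpoint between the level at
inspiratory start and at expiratory start; the SLP rate trace is the
central-difference derivative of the (resampled, unfiltered)
displacement. A limb crossing the midpoint more than once contributes a
time-weighted mean |rate| (weights are half the gap to each neighbouring
crossing) and flags the breath; zero-excursion breaths get a missing
IE50 and keep their timing indices. Subject summaries are unweighted
means over the epoch's breaths; ratio indices are averaged as per-breath
ratios, not ratios of means.

## Agreement statistics

Differences are d = x_SLP − x_PNT; plots put the PNT (reference) value on
the x-axis. The SD uses n−1. For breath-level data the one-way
random-effects ANOVA estimator gives σ̂²_w = MSW and σ̂²_b = (MSB −
MSW)/n₀ with the unbalanced n₀ = (N − Σn_i²/N)/(k−1), truncated at zero;
LOA use √(σ̂²_b + σ̂²_w). A single subject falls back to pooled
Bland–Altman with a flag. The estimator is validated against a
random-intercept ML fit (statsmodels MixedLM) as an independent route.

Limit standard errors use the delta method: Var(L) = Var(bias) +
1.96²·Var(SD) with the normal-theory Var(SD) = σ²/(2m). The effective m
is the subject count for averaged data; for breath-level data m_eff =
σ²_tot/Var(bias) with Var(bias) = σ²_b/k + σ²_w/N, which adjusts for the
variance components. These choices are calibrated empirically: over 1000
null simulations the per-limit Wald test rejects at 3–7 % (nominal 5 %),
and simulating at the computed minimum detectable change yields 70–90 %
empirical power (nominal 80 %). The power check shifts the second group's
*bias* — moving one limit while leaving the limit SEs the formula
conditions on unchanged; inflating the SD instead would change SE₂ and no
procedure could attain the nominal power. Per-limit two-sided p-values
are reported as a [lower, upper] pair, plus an optional joint 2-df
chi-square using the within-group covariance of the two limits,
Cov(L_low, L_up) = Var(bias) − 1.96²·Var(SD). No multiple-testing
correction is applied across the seven parameters.

Kurtosis is reported in the Pearson convention (normal = 3). A note on
the robustness folklore that mean ± 1.96·SD limits are conservative for
peaked distributions: it is not true pointwise in kurtosis (a Laplace
sample, kurtosis 6, has 93.7 % coverage), but it does hold for the
outlier-contamination peakedness seen in real breath differences (most
differences near zero, rare large ones); the property test uses that
contamination model.

## Pipeline and reproducibility

Sessions (e.g. REST1, REST2, POST_CST) are simulated or ingested
independently with seeds spawned from the master seed; REST1 vs REST2
and Combined-REST (concatenated differences) vs POST_CST are compared by
Wald tests and the post-hoc detectable change. All outputs are plain CSV
plus a JSON manifest (seed, config hash, package version); identical
config and seed reproduce byte-identical tables. Problem sizes in the
shipped tests (cohorts of 2–20 subjects, 45-s epochs, 600–1000 Monte-
Carlo replicates) keep the full suite around ten seconds while leaving
every estimator's calibration property actually exercised.

## Known limitations

* Marker timing inherits a discretisation floor from the 30 Hz SLP rate;
  perfect agreement is only reached when both devices share samples.
* IE50 on noisy displacement is the least stable index (it divides two
  interpolated derivative values); its LOA are accordingly the widest,
  as they are in real device comparisons.
* The repeated-measures estimator assumes exchangeable breaths within a
  subject (no serial correlation) and a common within-subject variance.
* The Wald tests treat sessions as independent; subjects shared between
  REST1 and REST2 induce a positive correlation the test ignores, making
  it mildly conservative for between-session differences.
* No tidal-volume calibration: SLP amplitudes are arbitrary units, so
  only timing and ratio indices are compared.
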