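# Methods

This note records the models implemented in `pelletpk`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations. It states no result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The pharmacokinetic model

Drug disposition is the classical two-compartment mammillary model: a
central (plasma) compartment exchanging with a peripheral one at first-order
rates k12/k21 and eliminating at k10, fed by a first-order oral absorption
depot (rate ka) that switches on at a lag time tlag after administration.
The central concentration is the triexponential in the hybrid constants
alpha/beta (the negated eigenvalues of the disposition system,
alpha·beta = k21·k10 and alpha+beta = k12+k21+k10) and ka. The peripheral
"concentration" is the peripheral amount divided by the central volume Vd,
which is the form the deconvolution mass balance needs.

Parameters and defaults (the reconstructed sobrerol set, in
`pelletpk.datasets`):

| symbol | value | units | meaning |
|---|---|---|---|
| k12, k21 | 0.82, 0.95 | 1/h | central↔peripheral distribution |
| k10 | 0.5693 | 1/h | elimination (back-solved as alpha·beta/k21) |
| ka | 2.40 | 1/h | first-order absorption |
| tlag | 0.18 | h | absorption onset delay |
| Vd | 44.94 | L | apparent volume (Vd/F; F fixed at 1) |
| transit | 8 | h | gastrointestinal absorption window per dose |

Bioavailability F is not separately identifiable from oral data alone, so
F = 1 and Vd is the apparent volume. The published Vd is printed with
units "L/h"; it is treated as L.

**Transit cutoff.** Absorption from each administration stops at the 8-h
gastrointestinal transit time. The published form of the post-absorption
curve is a bolus biexponential, which is discontinuous against the oral
curve at the cutoff; we instead continue the trajectory by two-compartment
disposition *from the actual compartment amounts at the cutoff* (an
eigen-decomposition of the 2×2 disposition matrix), which reduces to the
bolus formula when the peripheral amount is zero and keeps the profile
continuous (verified to <1e-9 at the cutoff). Drug not yet absorbed at the
cutoff is lost.

**Multiple dosing** is single-day superposition of per-dose trajectories:
thrice daily = 0/8/16 h, twice daily = 0/12 h, once daily = 0 h, evaluated
over a 24-h window on a 0.01-h grid. Day-one superposition (not steady
state) is adopted; it reproduces the published 12.8 h / 13.6 h durations of
action within 0.2 h, which supports that reading of the original analysis.

**Profile metrics.** Cmax is the grid maximum, AUC the trapezoid rule, and
t>MEC the measure of {t : C(t) > MEC} with threshold crossings located by
linear interpolation inside grid steps.

## Model reconstruction

`fit_oral_two_compartment` minimizes unweighted squared error on
concentrations (1/y and 1/y² weighting available), parameterized in
(log k12, log k21, log k10, log ka, log Vd, tlag). Fitting the micro
constants keeps every candidate in the feasible cone alpha > k21 > beta.
Twenty log-uniform starts over [0.01, 10] /h (tlag uniform on [0, first
sample time]; Vd seeded from dose/Cmax), deterministic given the seed;
bounds [1e-4, 50] /h on rates; ties in SS broken toward the smallest tlag.

**Flip-flop canonicalization.** The oral two-compartment curve is invariant
under exchanging the absorption exponent with a disposition exponent
(k21 unchanged, Vd rescaled by ka'/ka), so the model is only locally
identifiable. The fit enumerates the feasible representations and reports
the one with the largest ka — the standard reading for an immediate-release
product, where absorption is faster than disposition. Without this
convention, noise-free parameter recovery is impossible in principle. For
genuinely slow-absorbing (SR) data this convention would be wrong; the
package never fits SR plasma data (SR absorption rates come from the
ka–kd link instead).

ka ≈ alpha or ka ≈ beta (within 1e-9) is rejected as degenerate rather than
patched with the removable-singularity limit; no study scenario needs it.

A caveat the tests document: with the sobrerol parameter set, ka (2.40) and
alpha (2.08) nearly coincide, so ka is weakly identified from noisy data —
at 5% multiplicative noise its median recovery error is ~17% even for fits
started at the truth (the linearized sampling sd is far larger), while beta
and Vd recover within 15%. Green noise-recovery tests therefore establish
accuracy for the well-identified parameters only.

## Dissolution kinetics

Four standard release models on the fraction scale: f = k0·t,
f = 1 − e^(−kd·t), f = kH·√t, f = kKP·t^n. All are fitted by least squares
in natural space (log-linearization only seeds the nonlinear fits, avoiding
noise-distortion bias); zero/Higuchi have closed-form estimators.
Korsmeyer–Peppas uses only points with f ≤ 0.6, the conventional validity
range of the power law. Fractions above 1 (assay overshoot up to 1.05 is
tolerated in I/O) are clipped to 1 for fitting. `best_model` picks the
highest R², breaking ties within 1e-9 toward fewer parameters, so exact
√t data reports as Higuchi rather than the two-parameter power law.

The f2 similarity factor is computed on the percent scale over shared time
points: f2 = 50·log10(100/√(1 + mean((R−T)²))). Identical profiles give
exactly 100; a uniform 10-percentage-point difference gives
100 − 25·log10(101) ≈ 49.89 — the conventional "50" is attainable only to
that precision because of the formula's unit regularizer.

## IVIVC

**Deconvolution.** The absorbed amount per step is the central-compartment
mass balance: ΔD = {ΔC1 + (k10·C1 + k12·C1 − k21·C2)Δt}·Vd, cumulated and
normalized by dose. C2 is propagated alongside C1 by its own mass balance
(dC2/dt = k12·C1 − k21·C2), so no peripheral measurements are needed.
Numerics: trapezoidal (Crank–Nicolson) stepping rather than the
left-rectangle rule — O(Δt²), so the Δt = 0.001 h analytic-recovery check
(f_abs vs 1 − e^(−ka(t−tlag))) passes with margin, and nothing changes at
the working Δt = 0.01 h. Negative increments (noise) are floored at zero;
the cumulative fraction is capped at 1.02. Sparse observed profiles must be
densified through the fitted model first (the two-step approach); splines
are deliberately not offered.

**Time scaling (Levy plot).** For fraction levels 0.05–0.85 in steps of
0.05 (configurable; the original levels are unstated), the in vivo time is
inverse-interpolated from f_abs and the in vitro time comes from the
closed-form inverse of the dissolution model; OLS of t_vitro on t_vivo
gives the scaling. In vivo times are absolute (lag included), which is what
produces the small negative intercept. Unattained levels are dropped with a
warning; fewer than three is an error.

**Convolution** superposes bolus disposition responses weighted by the
absorption increments — the exact inverse operation up to discretization;
the round trip is held to 2% sup-norm.

**ka–kd link.** The affine map ka = 0.478·kd + 0.0229 (reference constants
in `pelletpk.ivivc`) converts a formulation's dissolution constant into the
absorption constant used in the oral model; it is consistent with the IR
anchor (kd = 4.99 /h → ka ≈ 2.40 /h). `calibrate_ka_kd_link` refits it from
(kd, ka) pairs.

## Dose design

HED = animal dose (mg/kg) × (Km_animal/Km_human) × body weight, with mouse
Km 3, adult Km 37, 60 kg. The MEC is the closed-form single-dose peak of
the highest no-effect HED (146 mg), located by a coarse grid plus bounded
scalar refinement. Symptom inhibition is defined as
(vehicle − treated)/vehicle clinical score at the plateau day — the
original definition is unstated, so this choice is flagged; the PK/PD
conclusion used downstream is only the *ranking* (t>MEC correlates best
with inhibition), not the regression values.

The design contour evaluates t>MEC over a (kd, per-administration dose)
grid at fixed frequency, exploiting exact dose linearity: one unit-dose
regimen simulation per kd, rescaled per dose. Defaults kd ∈ [0.05, 1.2]
step 0.05, dose ∈ [100, 1500] mg step 10. The minimal-dose search bisects
to 1 mg using the monotonicity of t>MEC in dose. Note that t>MEC is *not*
globally monotone in kd: in the dissolution-limited regime (small kd) faster
release extends the duration, but at large kd the higher peak/faster tail
trade-off reverses the trend — the monotone claim is asserted only where it
holds.

The coating DoE is abstracted as a full quadratic response surface in three
coded factors (coating weight gain, HPMC/EC ratio, curing temperature) with
the first-order kd as response, fitted by OLS (rank checked; aliased terms
reported) and inverted by grid search over the coded (A, B) square at fixed
C. The original factor-level assignments are not public, so the surface is
validated on synthetic designs only and the published factor windows are
not reproduction targets.

## Synthetic data

Generators are pure functions of (parameters, seed); zero noise reproduces
the closed-form model values exactly. Multiplicative noise is mean-one
log-normal with CV = level (the common bioanalytical convention;
sigma² = ln(1+CV²)); additive Gaussian noise is offered for dissolution
data. Defaults mirror the study's stated world: the 300 mg profile at the
published eight sampling times, IR dissolution sampled 5–120 min and SR
0.5–8 h, the 13-run Box–Behnken coating design (the only standard 3-factor
3-level 13-run layout), and the five EAE regimens with their published mean
scores (jitter by the reported SDs is optional). Noise-study tests use a
densified 11-point schedule, since the 8-point clinical schedule leaves the
absorption phase under-sampled. What the generators do **not** emulate:
inter-subject variability, assay quantification limits, non-sink
dissolution conditions, or day-to-day carryover — green tests say nothing
about those.

## Limitations

* Linear PK only: no saturable absorption/elimination, no steady-state
  accumulation analytics (day-one superposition is the stated convention).
* The IVIVC assumes dissolution-rate-limited absorption of a highly
  soluble, highly permeable drug; it will not transfer to permeability- or
  solubility-limited compounds.
* The absorption cutoff is a hard 8-h gate, not a physiological transit
  distribution.
* The ka–kd link and time-scaling map are calibrated on a single
  immediate-release anchor; applying them far outside kd ∈ [0.03, 5] /h is
  extrapolation.
* The EAE dose-response side uses published group means; no re-analysis of
  animal-level data is possible or attempted.
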