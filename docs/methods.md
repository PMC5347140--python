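# Methods

## Dose–response model and fitting

All curve fitting uses the four-parameter logistic on the
log10-concentration scale,
`y = bottom + (top − bottom) / (1 + 10^((logIC50 − log x)·h))`,
either with free asymptotes (`full4p`, used for viability and pHH3) or
normalised to top = 100 / bottom = 0 (`normalized3p`, used for
tubulin-corrected pPKB, tracer displacement, turbidity and AlphaScreen
activity).  The full model is parameterised as (logIC50, h, bottom,
span ≥ 0) so top ≥ bottom holds by construction.  Concentrations are molar
throughout; percent responses are never clipped before fitting; duplicate
wells are fitted jointly rather than averaged (with duplicates the residual
degrees of freedom, and hence the standard errors, are honest).

Fitting is damped least squares (`scipy.optimize.least_squares`, trust
region reflective) with a multi-start grid — slope magnitudes
{0.5, 1, 2, 4} signed by the empirical trend, crossed with the quartiles of
the tested log-concentration range — because steep-slope objectives are
multimodal.  The best residual sum of squares wins; near-ties go to the
shallower slope.  Standard errors come from the Gauss–Newton curvature at
the optimum (inverse of JᵀJ scaled by the residual variance).

**Ambiguity rule.** A fit is ambiguous (its slope and IC50 are not used
downstream) when any of: the optimiser fails; |se(h)/h| > 0.5; the fitted
IC50 lies more than one log10 unit outside the tested range; or the
modelled response change across the tested range is under 10% of the curve
span.  The last condition marks series with no detectable response (e.g. a
flat pPKB readout for a pure destabiliser) that a boundary fit can
otherwise masquerade as converged.  The thresholds are deliberately simple
and transparent; on the synthetic panels they exclude essentially all
non-responding series and almost no responding ones.

Confidence-interval behaviour: over seeded noisy replicates (9-point
half-log series in duplicate, Gaussian noise s.d. 5%), the ±1.96·se
interval for log IC50 covers the truth ~92–95% of the time — slightly
anti-conservative, as expected for plug-in nonlinear-regression errors.

## Panel profiling

The Hill-slope matrix uses only viability fits.  A cell line is excluded
from the whole panel if its fit is ambiguous for *any* drug, so every drug
pair is compared on the identical line set; exclusions are logged as an
audit trail.  The penalty score for a drug pair is the unnormalised sum of
per-line squared slope differences — the simplest least-square form, whose
scale matches the convention that unlike-mechanism pairs exceed 100 on a
36-line panel (expected total 36·(Δh̄² + σ_a² + σ_b²)).  Relative
sensitivity divides each line's IC50 by the drug's arithmetic panel mean.

## Target engagement and the selectivity window

Engagement of a target at concentration x is the fraction of that curve's
maximal effect: (top − y)/span for inhibition readouts (pPKB),
(y − bottom)/span for activation readouts (pHH3, "% of the drug's own
maximal response").  The inverse,
`x = EC50 · (level/(100 − level))^(1/|h|)`, gives the concentration
reaching a required engagement level.  The window of selective PI3K
inhibition runs from the concentration reaching the required pPKB
inhibition (default 90%) to the concentration reaching the tolerated
fraction of maximal mitotic response (default 20%); it exists iff the lower
bound is strictly below the upper.  Drugs with no detectable pHH3 response
(ambiguous fit, or fitted span under 5%) have their mitotic EC50 replaced
by the 20 µM non-responder cap, both in the EC50(pHH3)/IC50(pPKB) ratio
and as the window's upper bound.  Mean plasma concentration is
AUC(0–24 h)/24 h, the standard steady-state average.  Where several cell
lines are summarised, engagement levels are averaged arithmetically with
the s.d. reported.

## Binding affinity

Emission ratios are background-subtracted 665/620 signals; wells with a
non-positive corrected donor signal are dropped.  Displacement curves (% of
vehicle ratio) are fitted with the normalised model, and the competition
IC50 is corrected to a dissociation constant with Cheng–Prusoff,
`Kd = IC50/(1 + [tracer]/Kd_tracer)` — the standard correction for a
single-site tracer-displacement design; an ATP-competition term is not
included because the assay contains no ATP.  Final tracer concentrations
are the 3× stock values divided by 3 (equal-volume three-component mix).
Under the single-site competition model
`bound = L/(L + Kd_L(1 + I/Kd_I))`, the normalised displacement curve is
exactly logistic with unit slope and IC50 = Kd_I·(1 + L/Kd_L), so the
corrected Kd is exact in the noiseless limit; the round-trip test holds it
within 10% at 2% multiplicative noise across 10 nM–1 µM.

## Microtubule dynamics

Events shorter than 0.5 µm (growth phases; boundary inclusive, since the
exclusion is stated for events strictly shorter) or lacking a clearly
observed start and end are filtered out, with counts logged.  Velocities
are length/duration averaged per movie (in vitro) or per cell, then
summarised as mean ± s.d. across groups.  Two catastrophe estimators are
exposed because the two imaging contexts use different conventions: per
movie 1/mean(growth duration) in vitro, and growth events per total growth
time (per minute) per cell.  For one group the two coincide
(N/Σt = 1/mean), and both are consistent for exponential growth durations.
A per-event mean-of-1/t variant is also provided for comparison but is not
a default: the reciprocal of an exponential has no finite mean, so that
statistic systematically overweights short events and does not converge to
the rate.  Rescue frequency is rescues per total shortening time, the
censoring-correct rate estimator when shortening can also end by reaching
the seed.  Turbidity curves subtract each well's t = 0 absorbance, and the
per-condition ΔOD340 maximum is normalised to the vehicle mean before
dose–response fitting.  Group comparisons delegate to the two-sided
Mann–Whitney test on per-movie/per-cell summaries.

## High-content cytometry

The mitotic index applies the two-step rule (mean *and* maximum pHH3
intensity above their thresholds) to non-border nuclei only; border
exclusion applies to this readout specifically.  Default thresholds are the
99th percentiles of the vehicle wells' intensities — a deliberately
conservative stand-in for instrument-calibrated values, and therefore
biased low when the vehicle mitotic fraction exceeds 1%; analyses that need
calibrated fractions should supply plate-specific thresholds.  Condensed
nuclei are classified by a configurable linear score (default: intensity
density weighted +1, area −20) — a stand-in for a trained two-class
classifier, since the original feature weights are instrument-specific.

Cell-cycle gating is mode-anchored: a kernel density on log2 DNA intensity
is searched for the ~2×-spaced peak pair with the highest combined density
(the G1/G2-M doublet; the lower member is G1 — robust even under mitotic
arrest, when G2/M outgrows G1), falling back to the global mode for
single-phase populations.  Gates are fixed multiples of the G1 mode
(defaults: sub-G1 < 0.6, G1 < 1.3, S < 1.7, G2/M ≤ 2.6; above 2.6 reported
separately as >4N), making the fractions invariant to global linear
intensity rescaling.  The four fractions are normalised to sum to 100.

## The synthetic-data generators

Generators are pure functions of (parameters, seed) and emulate the study
conditions: 9-point half-log dilution series (3.16 nM–31.6 µM) in
duplicate across 44-line panels; Gaussian readout noise of 5% (1% for the
small pHH3 fractions); per-line sensitivity factors lognormal with 0.25
log10 s.d., shared across drugs of like mechanism so sensitivity profiles
correlate within a class.

The mechanism model composes viability from component survival curves:
a cytostatic PI3K arm (slope −1) and a cytotoxic microtubule arm (slope
−3), combined for dual drugs by response independence (Bliss-type product
of surviving fractions; a minimum-survival alternative is configurable).
Two fixed offsets encode the target-engagement geometry: the cellular pPKB
readout is 9× more potent than the cytostatic viability effect (so ~90%
pathway inhibition coincides with half-maximal growth inhibition), and the
pHH3 response sits 1.75× above the cytotoxic viability EC50 with slope +2
(so growth is halved at ~25% of the maximal mitotic response, and
cytotoxicity precedes full mitotic arrest).  Reference scenarios put both
arms of the dual drug near 1 µM (PI3K arm 1.2 µM, microtubule arm 0.8 µM,
slightly the stronger), which reproduces the characteristic outcome: the
dual drug's growth IC50 is microtubule-driven, and its selectivity-window
bounds invert.

What the generators do *not* emulate: plate/edge effects, heteroscedastic
or outlier noise, correlated replicate errors, partial-response viability
plateaus, tracer depletion at high affinity, photobleaching or segmentation
errors in imaging.  Passing tests therefore demonstrate correctness of the
estimators and the pipeline logic under the stated statistical model, not
robustness to instrument artefacts.

## Problem sizes and numerical choices

The narrative analysis simulates the full 44-line, 5-drug panel (660
curves); tests use 6–8-line panels, 200–1000 kymograph events, 1000
penalty-score replicates, 2000–6000 nuclei per well and 500 coverage
replicates — sizes chosen so each property is measured well inside its
tolerance while the suite stays quick.  Estimator-consistency tests average
over 20 seeded replicate datasets, checking the estimators' central
behaviour rather than a single draw.  Concentrations are handled internally
as log10 molar; exponents are clipped at ±300 to avoid overflow; RSS ties
in the multi-start are broken toward the shallower slope.

## Known limitations

- The ambiguity rule is a reasoned reconstruction of "high uncertainty of
  slope steepness", not a reimplementation of any vendor's flag; threshold
  choices (0.5 relative slope error, 1 decade, 10% span) are documented
  defaults, not fitted.
- The penalty score is reported unnormalised; comparisons across panels of
  different size need rescaling.
- Cell-cycle gating assumes a detectable G1 (or single-phase) population;
  fully arrested wells with no G1/G2-M doublet fall back to the global
  mode and should be inspected.
- No pharmacokinetics beyond the AUC/24 h steady-state average, no protein
  binding correction, no plate-effect normalisation, and no 5-parameter
  asymmetric logistic.
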