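# Methods

`cvrpipe` implements a hippocampal cerebrovascular-reactivity (CVR) analysis
for a two-wave older-adult imaging cohort: estimation of CVR from a
CO2-inhalation BOLD-fMRI experiment, construction of cross-scanner
standardized change scores for structural metrics, and a covariate-adjusted
association suite with false-discovery-rate control. Because the cohort data
it targets are access-controlled, the package carries a first-class
synthetic-data generator whose ground truth drives every test.

## The CVR measurement model

During the scan the participant breathes through a face mask following a
block paradigm: 60 s of medical air to establish the normocapnic baseline,
then two 75-s blocks of 5% CO2 in air, each followed by a 75-s air washout
(total 360 s). Inhaled CO2 raises arterial CO2, dilates cerebral
microvessels, and increases the BOLD signal; the size of that response per
mmHg of end-tidal CO2 (EtCO2) is the cerebrovascular reactivity,

    CVR = %ΔBOLD / ΔEtCO2   [%BOLD/mmHg].

**End-tidal extraction.** The capnometer records CO2 partial pressure
continuously; the end-tidal value of a breath is the maximum CO2
concentration at the end of exhalation. Breaths are detected as local maxima
separated by at least `min_breath_period` (default 2 s) with prominence at
least `prominence_fraction` (default 0.25) of the trace range; flat
end-tidal plateaus are reported at their midpoint. This detector is provably
equivalent to an exhaustive per-breath windowed maximum on generated traces,
which is how the tests check it.

**Normalization and the regressor.** The breath-wise envelope is
piecewise-linearly interpolated onto the BOLD sampling grid and normalized
by subtracting the baseline-window mean and dividing by the maximum
end-tidal value:

    n(t) = (EtCO2(t) − baseline mean) / max EtCO2.

One unit of `n` therefore corresponds to `max EtCO2` mmHg. An optional bulk
haemodynamic delay can be estimated by maximizing the cross-correlation with
the BOLD series over a grid in [0, 15] s (step 0.5 s); it is off by default
since delay correction is not part of the core model.

**ΔEtCO2** is the mean end-tidal value over breaths in the second half of
each CO2 block — the half-open interval (block midpoint, block end], where
EtCO2 has stabilised — minus the mean over the initial air block, averaged
across CO2 blocks.

**GLM and unit conversion.** The BOLD series is regressed by ordinary least
squares on (intercept, n(t), polynomial drift up to order `drift_order`,
default 1). On percent-signal-change data the CVR is `beta / max EtCO2`; on
raw scanner units it is `100 · beta / (intercept · max EtCO2)`. The two
parameterizations (normalized regressor vs. raw mmHg regressor) are
algebraically identical, and the tests assert their numerical equivalence.

*Choice of the %BOLD reference.* Percent signal change needs a baseline
signal estimate. Defining it as the mean over the normocapnic window is
simple but biased whenever additive scanner drift is present, because the
drift contaminates the window mean. The pipeline therefore defaults to the
GLM-intercept reference (`percent_mode="intercept"`): the intercept is the
drift-free estimate of the baseline signal, and with it the noiseless
recovery of a planted CVR is exact to machine precision even under drift.
The baseline-window mode remains available (`percent_mode="baseline"`) and
the window is configurable.

*No prewhitening.* Production fMRI tools prewhiten against temporal
autocorrelation. At the scale of a single ROI series with modeled drift the
OLS point estimate is unbiased under AR(1) noise — the loss is efficiency,
not accuracy — so the estimator stays plain OLS and the tests verify
unbiasedness over noisy replicates. Standard errors of the CVR itself are
not propagated downstream; only the point estimate enters the cohort
analysis.

**ROI extraction and outliers.** ROI means are unweighted averages over mask
voxels; hippocampal CVR is the simple mean of the left and right ROI means.
Implausible CVR values are flagged by the robust rule
|value − median| > k · MAD with k = 6 and the raw median absolute deviation
(no 1.4826 normal-consistency factor — the rule is stated directly in MAD
units). The inequality is strict, so an all-equal sample flags nothing.

## Standardized change scores

Waves 1 and 2 were acquired on different scanners, so raw volumes and
diffusion metrics are not directly comparable across waves. Within each wave
every metric is z-scored (sample SD, n−1), and longitudinal change is

    Δ = z_wave2 − z_wave1.

Any positive-scale affine scanner effect applied uniformly within a wave
cancels exactly — this invariance is asserted numerically to 1e−10. The
price is that Δ measures *relative* change (a participant's trend compared
to the cohort), not absolute change; no atrophy rates are estimated.
Orientation differs by family: for GMV and FA a more negative Δ means more
decline, for MD/RD/L1 a more positive Δ does. Participants missing either
wave of a metric are excluded listwise for that metric.

WMH volume is treated differently because its segmentation is consistent
across the two scanners: it is expressed as a percentage of total brain
volume (grey + white + CSF), log-transformed (natural log by default; the
base is configurable since conventions differ), and its change is the plain
difference of log-percent values, positive meaning WMH growth.

## Association suite

Each model is an OLS linear regression of one structural outcome on one CVR
exposure plus covariates:

* cross-sectional (wave-2 outcomes): age at wave 2 + sex; hippocampal-volume
  outcomes additionally adjust for total grey-matter volume (the covariate
  sets reported for these models vary between age+sex and age+sex+total GMV;
  the suite uses the latter and records the choice in the output metadata);
* longitudinal (Δ outcomes): age at wave 1 + sex + inter-wave interval.

Sex is coded as a binary indicator (male = 1, female = 0 reference); the
coding affects only the sex coefficient, not the exposure effect. Models are
fitted on complete cases. Reported per model: β with 95% CI and two-sided
t-test p; Cohen's f² for the whole model, R²/(1−R²), and for the exposure,
(R²_full − R²_reduced)/(1−R²_full) with the reduced model dropping the
exposure; and the Shapiro–Wilk statistic of the residuals, which is reported
but never used to discard a fit.

The full design comprises 19 models per exposure: 2 hippocampal-GMV models
(left/right, using the matching hemisphere's CVR), 16 tract models (FA, MD,
RD, L1 × corpus callosum, cingulum bundle, internal capsule, fornix, using
the hippocampal average CVR), and 1 WMH model. Benjamini–Hochberg step-up
adjustment is applied within each family of four tracts per diffusion
metric; the single-test GMV and WMH models carry no adjusted p. The BH
implementation is checked against a brute-force step-up definition
(adjusted_i ≤ q exactly when the largest-i rule rejects hypothesis i) on
random inputs over a grid of q.

A note on reproducing published adjusted p-values from printed tables:
adjusted values computed from 3-decimal rounded raw p-values can differ from
values computed on unrounded p by one unit in the last place (observed for
two RD-family cells); the acceptance checks compare at 3 decimals with that
1-ulp allowance.

## The synthetic-data generator

**Capnometry.** Each breath occupies one breath period (default 12
breaths/min) and consists of a raised-cosine rise from the inspiratory floor
(default 4 mmHg), a flat end-tidal plateau occupying `plateau_fraction`
(default 0.3) of the breath, and a raised-cosine fall. Breath boundaries sit
at the floor, so the per-breath maximum is unambiguous — a deliberate
property that lets an exhaustive windowed-maximum oracle certify the
detector. The plateau target is 40 mmHg at baseline plus an 8-mmHg
hypercapnic boost (conventional values for 5% CO2 in older adults; the study
conditions do not pin these down, so they are free parameters, not
estimates), approached at block transitions with a first-order time constant
(default 10 s) that emulates physiological wash-in. Optional breath-to-breath
plateau jitter and a baseline drift parameter generate QC-failing traces.
The sampler refuses rates below 4 samples per breath.

**BOLD.** The forward model inverts the CVR definition:

    s(t) = s0 · (1 + CVR · (EtCO2(t) − baseline)/100)
           + a·t + b·t² + AR(1) noise,

with `noise_sd` the stationary (marginal) SD of the AR(1) process
(innovations scaled by √(1−φ²)). Small 4-D volumes of independent voxels are
supported for map-level tests. Not modeled: haemodynamic convolution beyond
a bulk delay, cardiac/respiratory physiological noise, motion — so passing
tests certify the estimator under the stated signal model, not robustness to
every artefact of real fMRI.

**Cohort.** Default structure mirrors the target sample: n = 154, 26%
female, age 68.2 ± 4.4 y at wave 1, 8.7 ± 1.2 y between waves, hippocampal
CVR ~ truncated-positive Normal(0.205, 0.07) %/mmHg (CVR is a positive
vasodilatory response; rejection sampling enforces positivity). Per metric,
latent wave-1 values are Gaussian with means/SDs typical of such cohorts
(hippocampal volumes ~3 cm³, tract FA 0.5–0.72, diffusivities in mm²/s);
the latent annual change is a base age-typical rate (e.g. −0.015 cm³/yr
hippocampal volume, −0.0012/yr FA) plus a planted `longitudinal_effect` ×
CVR; wave-2 adds `cross_sectional_effect` × CVR; observed values apply a
per-wave affine scanner effect and measurement noise. Planted effects are
zero by default (null cohort), which is what the calibration checks use;
`CohortSpec.with_effect` plants effects for recovery and coverage tests.

## Numerical choices and edge cases

* All randomness flows from `numpy.random.default_rng(seed)`; per-voxel
  streams are spawned from a `SeedSequence`. Identical seeds give
  bit-identical outputs.
* Drift columns are raw time powers (t, t²); with ≤ 360 s series the normal
  equations are well conditioned and the intercept keeps its meaning as the
  signal at t = 0.
* Regressor resampling clamps at the series edges for at most one median
  breath interval; beyond that the acquisition window is treated as
  uncovered and rejected. If the end-tidal series does not span the
  paradigm's blocks (e.g. a short excerpt), the regressor's ΔEtCO2 is NaN
  rather than an error.
* The QC steady-state check uses the least-squares slope of second-half
  breath values (tolerance 0.02 mmHg/s); the baseline-return check compares
  the second half of each post-CO2 air block to the initial baseline
  (tolerance 2 mmHg). The visual inspection it codifies has no published
  thresholds; both are configurable and logged.
* Degenerate inputs error early: zero-variance waves cannot be z-scored,
  R² = 1 has no finite f², empty masks and rank-deficient designs are
  rejected, `to_percent_change` refuses to run twice.

## Problem sizes

Tests and the acceptance script run the paradigm at 20-Hz capnometry
(7 200 samples), 178 BOLD volumes at TR 2 s, 200 noisy replicates for
unbiasedness, 500 replicate cohorts of n = 154 for type-I error (16 tract
models each, 8 000 p-values) and CI coverage, and 50–100 random traces for
the detector oracle. These sizes give Monte-Carlo standard errors small
enough for the stated tolerances while keeping a full run in well under a
minute for the unit suite.
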