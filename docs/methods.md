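# Methods

This note documents the models, estimators, defaults, and design choices
behind the package, and what the synthetic-cohort tests do and do not
establish about real data.

## Spectral estimation

Power spectra are Welch average periodograms: Hann-tapered segments of
10 s (the minimum giving 0.1 Hz native resolution) with 50 % overlap,
constant detrending, density scaling. Segments in which any lead exceeds
200 µV absolute amplitude are dropped from the average — a deterministic
surrogate for the visual artifact screening used clinically; no filtering
is applied anywhere. The output is always the canonical grid of 181 bins
from 2.0 to 20.0 Hz at exactly 0.1 Hz; if the native resolution is not
bin-exact (fs·10 s not an integer), the spectrum is linearly interpolated
onto the grid. Each per-segment periodogram is computed by
`scipy.signal.periodogram`; with no artifact segments the result is
bit-identical to `scipy.signal.welch` (tested).

**Alpha peak.** The center frequency is the argmax of power within
8–13 Hz, refined by three-point parabolic interpolation (sub-bin
precision is needed to resolve the <1 Hz treatment-related shifts; for
noise-free Gaussian bumps the error is ≤0.05 Hz on-grid and ≤0.1 Hz
off-grid). Ties break toward the lower frequency. A monotone band has no
peak; the band argmax is returned with a `low_prominence` flag.

**FWHM.** Width between the two half-maximum crossings around the peak,
each located by linear interpolation between adjacent grid points. The
half-maximum is measured on peak height *above the aperiodic baseline*
when a fit is supplied (raw half-maximum otherwise): raw half-max of a
small peak on a 1/f background is dominated by the background. If either
crossing falls outside 8–13 Hz the width is undefined (NaN), flagging a
band-clipped peak. At single-lead Welch noise levels (~47 segments) the
first-crossing rule is biased low — noise dips cross the half level
early — so the pipeline reports the frontal FWHM measured on the 7-lead
frontal average spectrum, where the bias is negligible; the per-lead
operation remains available.

## Aperiodic (1/f) component

The frontal-average spectrum is fitted in log₁₀ *P* – log₁₀ *f*
coordinates over the full 2–20 Hz band with a straight line (no knee
term). The robust estimator is iteratively reweighted least squares with
a Tukey bisquare loss, tuning constant 4.685 (95 % Gaussian efficiency),
residual scale = normalized median absolute deviation re-estimated each
iteration, convergence when the maximum weight change is below 1e-8
(≤100 iterations; non-convergence returns the last iterate, flagged).
Bins with zero final weight are the outliers — in practice, the alpha
peak. When the inlier residuals collapse to machine noise (noiseless
input) the scale estimate degenerates; bins at machine-level residual are
then inliers and everything else stays rejected. An OLS variant provides
the non-robust baseline. Noiseless power laws are recovered to ≤1e-6 in
slope and offset by both methods.

A caveat worth recording: over 2–20 Hz the mean of log₁₀ *f* is ≈0.98,
i.e. the design's pivot sits at ≈9.6 Hz — inside the alpha band. An alpha
bump centered near the pivot barely tilts the OLS slope (bias ~0.005 for
a 3× bump at 10 Hz), so the robust-vs-OLS contrast is only resolvable
when measurement noise contributes less slope noise than that; the
estimator-comparison property tests therefore use log-normal noise
σ = 0.02, while slope-recovery checks at the reported operating points
use σ = 0.05.

## Stimulation planning

The intrinsic alpha frequency is the amplitude-weighted mean of the four
occipital center frequencies (visual cortical frequency is presumed
preserved), clamped to 8–13 Hz. Leads whose center frequency deviates
from it by more than 0.5 Hz (default; ~5 grid bins, above the peak
localization error) are targeted, each at the intrinsic frequency;
occipital leads are never targeted because they define the reference.
Session parameters ramp linearly over the planned course (default 6
weeks): intensity 25→60 % of resting motor threshold, inter-train
interval 30→10 s, 12 s trains (midpoint of the 10–15 s range), 40 min
sessions. Where source documents disagree on the intensity range
(25–60 %MT vs "machine power 20–60 %"), the motor-threshold-referenced
range is used.

The weekly update recomputes intrinsic frequency and targets from fresh
EEG and advances the ramp one step. The clinical-feedback rule is not
publicly specified; the package implements one conservative, documented
rule behind a strategy interface: if the PCL-5 total rose by more than 5
points since the previous week, the ramp is held for one week. Missing
scores produce an EEG-only update, flagged.

## Psychometrics

PCL-5: 20 items each 0–4, total 0–80, screening cutoff 33 (total ≥ 33 is
PTSD-positive). Responder = baseline-to-final drop strictly greater than
5 points; strictly greater than 10 is clinically meaningful (strict
inequalities, following the figure-caption convention "Δ>5" / "Δ≤5"
over the looser prose). HAM-A/HAM-D enter as totals; the conventional
bands are applied, and a total of 24 — which falls in a gap between the
published "moderate" ranges and "greater than 24 = severe" phrasing on
both scales — is assigned to severe.

## Cohort statistics

Summaries report n/mean/SD/median/min/max for RAW and CFB data by
timepoint, excluding subjects missing that timepoint (listwise deletion
within each test). CFB *t*-tests are two-sided one-sample tests of
μ = 0; paired tests reduce to one-sample tests on differences. The sign
test bins paired center frequencies into 0.5 Hz bins anchored at 8.0 Hz
(bin width not publicly specified; 0.5 Hz matches the granularity of the
published binned-frequency maps, configurable), drops ties, and uses the
exact two-sided binomial distribution on the non-tied count. The
repeated-measures ANOVA is a two-way mixed design (between = group,
within = week) computed from explicit sums of squares with no sphericity
correction, verified against `pingouin.mixed_anova` and a brute-force SS
decomposition; its conservation identity (total = group + subjects
within groups + week + interaction + error) holds to 1e-10.
Threshold-exceedance proportions use strict inequalities. Fisher
comparisons against the prior VA standard-rTMS study use the published
percentages as fixed constants with assumed completed arm sizes of 62
(active) and 63 (sham). No multiple-testing correction is applied
anywhere, matching the source analysis.

## Synthetic cohort generator

Each lead's expected PSD is `10^offset · f^(−exponent) + amp ·
Gaussian(f; center, σ)`. Time series are realized by inverse-FFT spectral
shaping of complex Gaussian noise (the power law held constant below
0.5 Hz to bound the variance), which makes the model the exact
expectation of the Welch estimate — the estimators are probed against a
bin-wise known truth. Default amplitudes put the aperiodic power at
10 Hz at 20 µV²/Hz with a 2–3.2× relative alpha peak, giving ~±100 µV
time-domain excursions, realistic for resting EEG and safely below the
200 µV artifact clip.

Subject dynamics (defaults = the study conditions): responders' per-lead
centers start deviated above the subject's intrinsic frequency (cohort
intrinsic mean 9.6 Hz, SD 0.2; deviations mean +0.9 Hz, SD 0.3, so
pre-treatment region means sit above 10 Hz) and converge linearly onto
the intrinsic frequency by week 6; peak σ narrows 1.0→0.6 Hz, relative
amplitude rises 2.0→3.2, aperiodic exponent steepens 0.61→0.95.
Nonresponders keep their deviations, width and amplitude; their exponent
flattens 0.73→0.34.

Baseline PCL-5 totals are drawn from a normal left-truncated at the
screening cutoff 33, with the untruncated (µ, σ) solved numerically so
the post-truncation moments equal 53.3 / 11.46; integer rounding and the
0–80 cap shift the realized mean by ≲0.1. Weekly scores follow
`baseline − drop · ramp(week) + noise` (noise SD 1.5, floor/cap at the
instrument range). The ramp is a saturating exponential (τ = 1.5 weeks)
that reaches 1 at the week-4 plateau: improvement concentrates in the
first treatment week and is essentially complete by week 4, matching the
reported trajectory shape. Responder total drops are calibrated so the
responder week-4 mean score is ≈17.7 (drawn per subject, floored so the
drop exceeds the responder threshold with margin); nonresponder drops
are near zero (mean 0.5, SD 1.5), keeping the expected nonresponder CFB
within the ≤5-point definition. The reported week-4 "score > 32" group
mean of 47.2 belongs to a score-split partition, not the responder
split, and is not a generator target.

Dropout is a two-phase geometric hazard (6.6 %/week through the planned
course, 12.2 %/week after), calibrated to the reported attrition
(~31 % by treatment 27, ~92 % by week 22); a subject's final score is
the last observed week (LOCF), as in the per-timepoint n accounting of
the source tables. All randomness flows from one root seed through named
streams (subject, week, purpose), so enlarging a cohort preserves
existing subjects byte for byte.

**What the synthetic tests show — and don't.** Passing recovery tests
shows the estimators are unbiased under the generator's stationary
Gaussian spectra with exactly Gaussian alpha peaks and exactly linear
log-log backgrounds. Real resting EEG has non-Gaussian artifacts, peak
asymmetry, spectral knees below 2 Hz, split alpha peaks, and
nonstationarity — none of which the generator emulates (only optional
amplitude clips exercise the artifact flagger). Cohort-level agreement
with the published summary numbers demonstrates calibration of the
generator, not reproduction of the clinical result.

## Problem sizes and numerical choices

The test suite uses 60–240 s epochs at 125–250 Hz, cohorts of 1–8
subjects for the EEG pipeline and 2,000–10,000 subjects for score-only
calibration; the acceptance script uses 50 spectra per slope study, 20
subjects (4-minute, 250 Hz epochs) for the alpha-center study, and
10,000 subjects for calibration. In the alpha-center study, the
between-subject 0.2 Hz jitter is drawn as stratified normal deviates so
the generating grand mean equals the nominal value at n = 20; the
marginal spread is preserved. Ties at equal peak power break toward
lower frequency; plans are deterministic functions of their inputs; the
report serializes to sorted-key JSON and is hash-identical across runs
with the same seed.

## Known limitations

- The proprietary frequency-selection algorithm used clinically is not
  public; only the disclosed deviation/intrinsic rule is implemented,
  and the score-feedback rule is a declared stand-in.
- The four-region montage partition (frontal 7 / central 5 / parietal 3 /
  occipital 4) is the unique exhaustive reading of the published region
  endpoints plus the frontal lead count; the published endpoint ranges
  are not literally contiguous and cannot all be taken verbatim.
- EDF support covers the plain 19-channel layout written by this package
  and common label variants (T3/T7 etc.); annotations, discontinuous
  records, and non-EEG channels are out of scope.
- The aperiodic model is a single straight line over 2–20 Hz: no knee,
  no multi-peak parametrization, region averages only.
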