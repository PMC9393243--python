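# Methods

This note records the models, conventions and parameter choices behind
`tdlymph`, and what its synthetic pipeline does and does not establish
about real animal data.

## Physical setting

The thoracic duct (TD) is the body's largest lymphatic vessel, returning
most lymph to the venous system at the lymphovenous junction. When
central venous pressure (CVP) rises chronically — here through tricuspid
regurgitation (TR), which lets right-ventricular systole drive pressure
back into the right atrium and great veins — two things happen to the
duct: lymph production rises (more capillary ultrafiltration to drain)
and the duct's outflow afterload rises (it empties against a higher
venous pressure). The measurable consequences this package quantifies
are a large sustained rise in TD flow (TDQ) and pressure (TDP), outward
remodeling and wall thickening of the duct, and retrograde flow episodes
once the dilated duct's valves no longer coapt.

## Biomechanical model

Three classical relations, all evaluated in SI after unit normalization:

* **Wall shear stress** (Poiseuille, laminar flow in a circular tube):
  τ = 32 µQ/(π D_i³). Sign follows the flow; negative flow yields
  negative shear with a retrograde flag. The lymph viscosity µ is not
  measurable in routine studies; the default is the water-like 1.0 cP,
  held in the config and overridable (`--mu-cp`), never hidden in the
  results. Reports carry τ in both dyn/cm² and Pa side by side: reported
  WSS magnitudes in this literature are sometimes a factor of ten apart
  from recomputation depending on which of the two units the column
  actually used, and dual reporting keeps that ambiguity visible instead
  of resolving it silently.
* **Inner diameter from incompressibility**: for a cylindrical vessel of
  constant wall volume, D_i = √(D_o² − 4 A_o/(π λ)), with A_o the
  no-load wall cross-sectional area and λ = l/l_o the axial stretch of
  the mounted segment. A negative radicand means the stated geometry is
  impossible and raises an error naming the record.
* **Circumferential (hoop) wall stress**: the thin-wall Laplace form
  σ = P_i r/h with r the inner radius (D_i/2). An inverted variant
  σ = P_i h/r circulates in print; it is dimensionally a pressure times
  a small aspect ratio and cannot produce the kilopascal-scale stresses
  observed at TD geometry (P·h/r ≈ tens of Pa at 8 mmHg, r/h ≈ 27), so
  the Laplace form is the default and the inverted one is kept only
  behind `--stress-convention as-printed` for documenting the
  discrepancy. Only the Laplace form is consistent with the observation
  that wall thickening *lowers* hoop stress after remodeling.

**Remodeling ratios.** The TR/control ratio row is computed as the ratio
of group means (deterministic, defined even for unpaired groups) and
displayed half-up at two significant figures. When paired per-animal
baseline/day-28 values exist, the mean-of-per-animal-ratios convention
is also computed; for strongly skewed variables (baseline TDQ has SD
larger than its mean) the two conventions differ materially, which is
why both are surfaced rather than blended.

## Waveform summarization

Traces are uniformly sampled series of pressure (mmHg) or TD flow
(ml/min). The summary triple is the time average plus the means of
per-cycle maxima (systolic) and minima (diastolic). Cycle segmentation
is deliberately parameter-light and ECG-free: local extrema gated by a
prominence threshold of 20% of the trace's interquartile range, with a
minimum separation of 0.25 s (swine heart rate stays below 240 bpm).
Constant traces degrade to a mean-only summary with the extrema reported
as the mean and a flag; non-constant traces with fewer than two detected
cycles raise, instructing the caller to record a longer trace. This is a
stated convention of the package: source studies rarely document how
their systolic/diastolic venous values were extracted.

Retrograde metrics for flow traces use sample-wise Riemann sums, so the
time fraction (fraction of samples below zero) and volume fraction
(|Σ min(v,0)| / Σ|v|) share one discretization. The TR-induction
endpoint is a mean RV−RA gradient below 2 mmHg (down from ~6 mmHg with
a competent valve).

Stability: the time-average is stable to 1% down to ~2× the dominant
frequency, but per-cycle extrema are inherently biased low near the
Nyquist limit (a pure tone sampled at 2.7× its frequency loses ~5% of
its peak), so the extrema-stability property is only claimed, and
tested, for sampling ≥ 20× the cardiac frequency.

## Pressure–diameter processing

The ex vivo test raises a fluid column in 1 cm steps to 15 cm, then 20
and 30 cm; pressure is the hydrostatic head (98.0665 Pa per cmH₂O),
reported in mmHg. The vessel is passive (calcium-free EGTA bath), so no
active-tone correction applies. Curves are kept raw: linear
interpolation between measured points, no smoothing and no constitutive
fit; the derived quantities are the diameter-ratio (stretch) curve
normalized to the lowest-pressure diameter, and secant compliance
ΔD/ΔP over a stated window (default: the 1 cm to 15 cm span of the fine
grid). Extrapolation outside the measured range is refused.

## Group statistics

Summaries are mean ± SD (n−1 denominator; SD flagged undefined at
n = 1). The group comparison is the two-tailed Welch test — the
"two-sample unequal variance t-test" of spreadsheet terminology — with
the Welch–Satterthwaite degrees of freedom, significant at p < 0.05. No
multiple-testing correction is applied, matching the single-variable
testing style of the source study design; the report records the number
of tests run so readers can apply their own correction.

## Synthetic cohort generator

The generator's defaults *are* the study conditions: n = 6 animals per
group, the printed group means and SDs for morphometry (D_o, h), lymph
flow and pressures (TDQ, TDP, cisterna chyli pressure), ventricular
masses, and the systolic/diastolic/mean triples for artery, jugular
vein, right atrium and right ventricle at baseline, 10 minutes and 4
weeks after TR induction.

**Distributions.** Variables are non-negative, and several have printed
SDs comparable to or larger than their means, so draws come from a
lower-truncated normal whose *parent* parameters are solved so that the
truncated distribution has the configured mean and SD (plain truncation
of a normal parameterized by the printed values would inflate the
baseline TDQ mean by ~54%). When the target coefficient of variation
exceeds what any zero-truncated normal can reach (CV ≥ 1 — baseline TDQ
at 0.78 ± 1.06 ml/min, and the most skewed diastolic venous pressures),
a moment-matched gamma on the same support is used instead; it is the
natural non-negative two-moment family for an intermittent,
near-stagnant flow.

**Sample-moment matching.** By default
(`moment_match="sample"`) the draws of each cohort are additionally
standardized so the *sample* mean and SD equal the configured values
exactly — the `mvrnorm(empirical = TRUE)` convention — by an affine map
when that respects the lower bound, and otherwise by a two-parameter
power transform `lower + c·(z−lower)^p` solved to match both moments on
the bounded support. This makes every generated cohort a faithful stand-
in for the published group statistics: downstream summaries reproduce
the configured table, and the Welch contrasts at n = 6 reproduce the
published significance pattern deterministically. The alternative
`moment_match="population"` keeps honest distributional draws with
sampling noise; under it, the borderline TDP contrast (8.2 ± 3.2 vs
14.6 ± 5.7 mmHg, t ≈ 2.40 at n = 6) has only ~50% power, which is worth
remembering when interpreting any single six-animal study.

**Within-animal structure.** D_o and h are sampled; D_i = D_o − 2h and
A_o = π λ (D_o² − D_i²)/4 (λ uniform on [1.0, 1.6]) are derived, so the
geometry round-trips exactly through the incompressibility relation.
A consequence: the derived D_i inherits an SD near that of D_o (~0.37 mm
in the control group) rather than the separately printed ~0.29 mm — the
three printed SDs are mutually inconsistent with the thickness identity
(they would require a D_o–D_i correlation slightly above 1), so the
generator preserves the identity and the D_o and h moments, and matches
D_i in mean only. Similarly, no level-plus-amplitude model can match all
three SDs of a systolic/diastolic/mean triple; the mean-pressure SD is
matched exactly and the amplitude SD is a least-squares compromise. The
split factor a (diastolic = mean − a·A) is derived per site and epoch
from the configured triple so all three printed means are reproduced
(fallback 0.35 when a triple is incomplete). TR animals also carry a
paired baseline row (control-parameter draws) with baseline TDQ tied to
the terminal value through a per-animal fold drawn at 11.7 ± 4.7
(truncated below 1.5), enabling both ratio conventions. Beyond these
identities, variables are independent: no within-animal correlation
structure is published, and none is invented.

**Traces and curves.** Flow traces are a mean level plus cardiac
(1.5 Hz) and respiratory (0.25 Hz) sinusoids and Gaussian noise, with
amplitudes scaled to the animal's mean flow; the post-TR state adds
randomized per-cycle negative troughs (depth referenced to the day-28
group mean) deep enough that the trace crosses zero, mirroring observed
retrograde episodes, and every trace is recentered so its time average
equals the configured mean exactly. Pressure traces use a cosine-power
pulse whose exponent is solved (via the Beta-function mean of cos^{2k})
so the duty cycle reproduces the configured mean between the configured
extremes. The lymph-flow time course is a saturating exponential
anchored exactly at 1-fold (day 0) and 3-fold (1 hour), holding the
plateau fold (default 10) from day 2 onward, with mean-preserving
lognormal day-to-day jitter (SD 0.12, so the plateau wanders over
roughly the reported 8–11-fold band). P–D curves use
D(P) = D_max − (D_max − D_0) e^{−P/k} on the protocol height grid with
(D_0, D_max, k) = (2.0, 3.6, 4.0) for control and (2.6, 4.4, 5.0) mmHg
for TR — chosen so the curves pass near the loaded in vivo diameters at
the respective duct pressures and so the TR curve dominates the control
curve pointwise — plus 0.02 mm measurement noise and 5% per-animal size
jitter.

**What the generator does not emulate.** Closed-loop lymph formation
and clearance (no conservation-of-mass dynamics), beat-to-beat
variability and arrhythmia, measurement drift, within-animal
correlations beyond the geometric identities, and any histology.
Passing tests on synthetic cohorts therefore demonstrate that the
analysis layer is correct and well-calibrated against known ground
truth — not that the physiological model generating real data looks
like this generator.

## Numerical choices

* mmHg is stored at its full factor 133.322 Pa; display rounding is
  half-up at the column's printed precision, with floats pre-rounded to
  12 significant digits so binary representation artifacts (0.255
  stored as 0.25499…) do not flip a rounding.
* Ratio-row display uses two significant figures, half-up.
* The truncated-normal parent solve and the pulse-exponent solve use
  Brent's method on bracketing intervals; parent solutions are cached.
* Degenerate inputs have defined behavior throughout: zero flow gives
  zero shear; constant traces give mean-only summaries; SD-0 configs
  generate exact-mean cohorts; identical groups give t = 0, p = 1.
* Problem sizes in the test and acceptance workloads — 10⁴ random
  inputs for oracle equivalence, 2×10⁴ replicates for type-I
  calibration, 500 replicate cohorts for power, n = 1000 per group for
  moment recovery — were chosen as the smallest sizes at which the
  Monte-Carlo error is negligible relative to the tolerance being
  checked; everything runs in seconds on one core.

## Known limitations

* Thin-wall stress only; no Lamé thick-wall distribution, residual
  stress or opening angle, although the remodeled TR wall (h/r ≈ 0.14)
  is near the edge of the thin-wall regime.
* Lymph viscosity is an assumption (1 cP), not a measurement; shear
  stresses scale linearly with it.
* The unit layer covers exactly the dimensions used here; it is not a
  general unit-algebra system.
* The prominence-based cycle segmentation is a convention; device-based
  or ECG-gated extraction may differ systematically, particularly for
  low-pulsatility venous traces.
* Printed per-animal-derived columns (stress means computed from
  unreported per-animal inputs) cannot be reproduced from group means
  under any stress convention and are treated as reference anchors, not
  recomputation targets.
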