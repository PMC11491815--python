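# Methods

This note documents the models, conventions and design choices behind
`accelflight`, in the order data flows through the pipeline.

## Sensor model

Traces are tri-axial accelerations in g (x lateral, y longitudinal, z
vertical). The quantizer maps each value to the nearest level of the
grid −R + k·Δ, k ∈ [0, 2ᵇ−1], Δ = 2R/2ᵇ (Δ = 0.0625 g for the default
±8 g, 8-bit logger). Ties round half away from zero, symmetric in ±;
out-of-range values saturate to the extreme levels, mimicking a
saturating MEMS output. Quantization is idempotent and nonexpansive
(|q(v) − v| ≤ Δ/2 in range). Subsampling keeps indices 0, f, 2f, … with
the rate divided by f; kept samples are bit-identical.

## VeDBA

Static acceleration is a centred running mean per axis; the window is
expressed in samples (default 5, i.e. 0.22 s at 23 Hz) so the same
5-sample filter applies at any rate. At the series boundaries the
window is clipped to the samples that exist (the first output of a
5-sample filter averages samples 0–2), which preserves length without
inventing padding values. DBA is raw minus static; VeDBA is its
Euclidean norm per sample. Segment means use half-open time intervals
[start, start+duration) with 0-based timestamps i/rate; an interval
containing no sample is an error rather than a silent zero.

## Synthetic data generator

The generator emulates a chick-rearing field campaign and is the
package's test bed; its defaults are the study conditions, not tuning
knobs.

**Behaviour sequence.** Bouts form a Markov chain over six behaviours in
which the next behaviour is drawn from fixed weights with the current
behaviour excluded, so bouts are maximal by construction and the
per-behaviour duration laws survive segmentation intact. The stationary
time share of behaviour i is π_i·E[d_i] / Σ_j π_j·E[d_j] (renewal
reward), with π the chain's stationary bout distribution;
`SyntheticConfig.expected_flight_fraction()` evaluates it exactly. The
default weights put the flying share at ≈ 0.137 of recording time.
Realized shares fluctuate around this value with a sd of roughly 3
percentage points for a 10-minute window and ≈ 1 point for a 2 h
deployment — tests of the stationary share therefore run at the 2 h
deployment length.

**Duration laws.** All bout durations are log-normal, clipped at a
behaviour-specific maximum. Flight bouts use median 1.8 s, σ = 0.7,
clipped at 60 s: mean bout 2.30 s, 99.3% of bouts under 10 s, and
occasional 30–50 s flights. (σ = 0.9 would leave only ~97% under 10 s,
inconsistent with the target bout structure.) Inactive bouts are capped
at 60 s — provisioning parents perch in short stretches between nest
visits — which also keeps a 2 h activity budget representative.

**Signal model.** Each behaviour is a carrier sinusoid plus a
half-amplitude first harmonic plus white noise, riding on the 1 g
gravity bias of the z axis, with a per-behaviour axis mix: wingbeats
(20 Hz) are vertical-dominant, bill wiping (8 Hz) lateral-dominant,
food shaking (10 Hz) longitudinal, preening (5 Hz) and swallowing
(3 Hz) intermediate, inactive is gravity plus 0.02 g noise. The
maintenance-behaviour tiers are free design choices — real kinematic
signatures of these behaviours are not published — chosen so the
classes are separable the way distinct behaviours are in annotated
aviary data; the axis mixes follow the obvious kinematics (a lateral
head wipe shakes the lateral axis).

**Flight styles and effort.** A configurable fraction of flight time
(default 70%) is bounding flight: 0.3 s flap bursts alternating with
ballistic pauses (default 25% duty cycle) during which raw acceleration
on all axes is ~0 g (folded wings, free fall). Per-flight effort
multiplies the flap amplitude by a log-normal factor with mean 1 whose
spread decays with bout duration (sd 0.35·e^{−T/6 s}), giving short
flights the wide effort range of take-offs, manoeuvres and descents
while long commuting flights converge. The flap amplitude itself is
calibrated, separately per flight style, so that a long flight's mean
VeDBA equals the configured asymptote (0.76 g by default); because the
running mean mixes flap and pause samples, mean VeDBA is not exactly
linear in amplitude, and the calibration solves the scale by a short
fixed-point iteration against a fixed-seed reference bout. Traces are
synthesised at 4× the requested rate and decimated by taking every
fourth sample, so a 20 Hz wingbeat recorded at 23–25 Hz aliases exactly
as a real logger would; quantization (±8 g, 8 bits) is applied last.

**Populations.** Per-sex Gaussian laws for mass, single-wing area and
semi-span (defaults anchored to measured group means/sds of breeding
pied flycatchers), brood sizes 3–8 weighted towards 5–7, tagging hours
uniform over the 17 h foraging day. Draws are floored at 20% of the
mean so measures stay positive.

**What the generator does not emulate.** No diel activity modulation,
no coupling of effort to morphology, no sensor drift or mounting
misalignment, no weather. Null results of the correlation and
trend tests on synthetic data are therefore the expected outcome, and a
passing pipeline demonstrates measurement validity, not biology.

## Classification

Windows are consecutive, non-overlapping, 16 samples (~0.7 s at 23 Hz;
the trailing partial window is dropped). Features per window: per-axis
mean, sd, min, max, skewness, excess kurtosis; pairwise axis
correlations; window-local mean and max VeDBA (5-sample running mean
inside the window); and the dominant non-DC bin of the z-axis power
spectrum with its power. Constant windows define correlations, skewness
and kurtosis as 0 (detected at sd < 1e-10 to absorb float cancellation).
The classifier is XGBoost with 200 trees, depth 4, learning rate 0.1,
single-threaded histogram growth for reproducibility, and
inverse-frequency class weights (flight and rare maintenance behaviours
would otherwise be swamped by perching). Training requires ≥ 2 classes
and ≥ 10 windows per class; the train/validation split is stratified
80/20 with a fixed seed. Models serialise to booster JSON plus a
sidecar with class names and feature order; reloading reproduces
predictions exactly.

Training data come from 100 Hz aviary recordings subsampled by four to
25 Hz (video annotation needs the high rate, classification the field
rate), while field data are 23 Hz; the model is applied across that
small rate mismatch unchanged. On default
synthetic data this transfer costs a few points of precision but stays
above 90% window-level flight recall and precision.

## Segmentation and metrics

Window labels collapse to flying/non-flying. The gap rule — flip every
single non-flying window flanked by two flying ones — is evaluated in
one left-to-right pass against the *original* sequence, so in
F,N,F,N,F both isolated N's flip; runs of ≥ 2 N never change; leading
and trailing N's have no second flank and never fill. The rule is
idempotent and only increases flight time, by exactly (filled windows) ×
window duration. There is no symmetric rule for lone flying windows: a
single flying window is a valid ~0.7 s flight. Maximal flying runs
become bouts; durations are integer multiples of the window duration.

R_flight is Σ bout durations / recording duration; T_flight is the mean
bout duration (undefined, not zero, without flights); VeDBA_mean,bird
weights every flight equally (a duration-weighted variant is an
option). The tagging time of a bird is the midpoint of its recording.
Recordings under 10 min and birds without flights are flagged, not
dropped. Window quantization and gap filling bias the estimated
R_flight slightly upward (≈ 1 point on synthetic defaults); the
recovery bound used in tests is 2 × window duration × bouts /
recording duration.

## Effort model

Per-flight mean VeDBA is Weibull with both parameters log-linear in
ln T: k(T) = exp(α₀ + α₁ ln T), λ(T) = exp(β₀ + β₁ ln T), which keeps
both positive for every T > 0. The exact log-likelihood is maximised
over the four coefficients by L-BFGS-B from moment-based starting
values (shape from the coefficient of variation via the Justus
approximation, scale from the mean), with a Nelder-Mead multi-start
over the slope terms if the first attempt fails; non-convergence is
flagged in the result. Exponents are capped at 500 to avoid overflow at
extreme trial points. No censoring is modelled; observations below the
sensor resolution enter as-is. Parameter recovery on simulated data
keeps slope biases within ±0.05 at n = 5000 and shrinking with n.

## Statistics

Between-sex tests are Welch (unequal variances, fractional df), the
form implied by fractional degrees of freedom in field reports;
pooled-variance is an option. Proportions are arcsine-square-root
transformed. Paired tests use within-pair differences with df = n−1;
a zero-variance difference is flagged as degenerate rather than
producing a spurious statistic. Brood size enters a one-way ANOVA as a
categorical factor (levels with < 2 birds are dropped). The
morphology–effort relation is a Pearson correlation with the
least-squares line and R². The diel trend is a tricube-weighted local
linear regression (span 0.75) evaluated on an hour grid, with a
pointwise standard-error band from the equivalent-kernel weights and a
residual variance estimated at the data points; the band widens where
data are sparse. No multiple-testing correction is applied by default.

## Morphometrics and extrapolation

Inputs are the measured single-wing area and semi-span; doubling to S
and b happens inside the derivation, and no body-root correction is
applied. SI units internally, field units (g, mm, mm²) at the CSV
boundary; g = 9.81 m s⁻². Note that ratios of group means (AR, N from
mean mass/area/span) differ slightly from group means of per-bird
ratios; the package computes per-bird ratios and aggregates afterwards.

Extrapolations are explicit arithmetic under an assumptions object:
17 h foraging day, 9.74 m s⁻¹ flight speed (a migratory estimate
assumed to carry over to foraging flight — overridable), flights
treated as one leg of an out-and-back pair for radii. The activity
ratio 1:x is defined as total-to-flight time, x = 1/R_flight (a 13.66%
flight proportion gives 1:7.3); the non-flying-to-flying alternative
would give 1:6.3 and is not used.

## Problem sizes

Default analysis and acceptance runs use a 30 min aviary session at
100 Hz for training and field sessions of 20–30 min at 23 Hz per bird
(8 birds in the acceptance script, 26 in the analysis chain), ~2000–
3000 bouts for duration-structure checks and n = 1000–10000 for
simulation-based calibration checks. These sizes give stable estimates
(sampling sd of a bird's realized flight share ≈ 1–2 points) while the
whole chain runs in seconds.

## Known limitations

Bout-edge windows dilute per-flight mean VeDBA (the running mean
straddles the bout boundary and edge windows mix behaviours), so
bird-level effort sits a few hundredths of a g below the long-flight
asymptote. The classifier transfer from 25 Hz training to 23 Hz field
data relies on amplitude/axis structure; frequency features shift under
aliasing and are not rate-corrected. The Weibull model fits marginal
per-flight effort and ignores bird identity (no mixed effects). The
loess band is a pointwise plug-in estimate, not a simultaneous band.
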