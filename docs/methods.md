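# Methods

This note records the models, defaults and numerical choices behind
`sonictal`, and what the synthetic benchmarks do and do not establish.

## Problem setting

Chronic mesial-temporal-lobe epilepsy (mTLE) in rodents produces
spontaneous electrographic seizures: runs of repetitive 2–20 Hz sharp
EEG waves with amplitudes elevated above the inter-ictal background,
lasting at least 3 s. A therapy study records each animal for a 24 h
observation period before and after an intervention (phenytoin, focused
ultrasound over the ictal focus, or both), summarizes each period by
per-animal *seizure indices* — ictal count, mean ictal duration per
event, mean ictal amplitude per event — and compares the per-animal
post/pre normalized indices between groups. A companion in vitro arm
measures unbound phenytoin in paired equilibrium-dialysis runs under
different sonication pulsing schemes, and the acoustic exposure itself
is characterized by standard dosimetry (duty cycle, I_SPTA, peak
rarefactional pressure, mechanical index) plus a simplified
radiation-force estimate on the drug–albumin complex.

## Synthetic cohort generator

The generator reproduces the *statistical* structure this analysis
assumes, not seizure biophysics.

**Background.** Pink noise (power ∝ 1/f above a 0.5 Hz knee, flat
below; no DC), rescaled to an exact RMS (default 50 µV). One scale
parameter; no circadian or state dynamics.

**Ictal events.** Trains of biphasic transients (sharp Gaussian
deflection plus a slower opposite afterwave, widths scaled to the
repetition period) at a per-event repetition frequency drawn uniformly
on 2–20 Hz, with a raised-cosine onset/offset ramp ≤ 0.5 s and a peak
amplitude of `event_snr` (default 5) times the background RMS with
lognormal per-event spread (σ = 0.2). Event durations are lognormal
(median ≈ 5.8 s, σ_log = 0.25, mean ≈ 6 s) left-truncated at the 3 s
ictal definition. Sub-threshold artifact bursts (0.5–2.5 s, default
2/hour of signal) exercise the detector's duration filter.

**Counts and pairing.** Each animal carries a latent per-period event
rate

    λ_i = μ_g · (0.4 + Gamma(shape 0.3, mean 0.6)),

i.e. a floored gamma mixture with mean μ_g (group baselines 145, 89 and
133 events per period) and SD/mean ≈ 1.1 — counts are strongly
overdispersed, as observed in chronic mTLE cohorts. The floor encodes
the screening inclusion criterion: only animals with established
spontaneous recurrent seizures enter a cohort, so arbitrarily small
rates do not occur. Pre- and post-period counts are Poisson draws
*sharing* λ_i; the intervention multiplies the post rate by the group's
`rate_multiplier` times a small per-animal lognormal spread
(`effect_sd` = 0.05). Sharing the latent rate is what makes per-animal
post/pre normalization a low-variance estimator, matching the small
spread of normalized changes seen in such cohorts despite count SDs of
the order of the means.

**Effect calibration.** The default multipliers were fixed once, by a
count-level Monte Carlo of this model, so that the *group mean of
per-animal post/pre ratios* — the estimator the analysis reports —
recovers mean normalized changes of −57 %, −27 % and +13 % in ictal
count for the combined, drug-only and ultrasound-only groups, and
−15 % / +22 % / +20 % in ictal duration. Because the mean of ratios is
not the ratio of means, the calibrated rate multipliers (0.425, 0.717,
1.115) differ slightly from the naive count ratios.

**Sessions and desk scaling.** A period always represents the 24 h
observation protocol, recorded as `sessions_per_period` (default 8)
sessions of `session_hours` (default 3 h). `event_rate_mean` governs
expected events *per period*; shortening `session_hours` compresses
only the inter-ictal background, not the seizure sample, so a
desk-scaled cohort (e.g. 1 h sessions) preserves the count statistics
and the power of the pre/post comparison while cutting signal volume
threefold. Events are packed into sessions with ≥ 3 s separation
(uniform Dirichlet gaps), so the detector's 1 s merge rule cannot fuse
distinct planted events; impossible packings raise a generation error
after bounded retries.

**Dialysis emulator.** For each paired run, one concentration per
cassette condition: condition mean + shared run effect
(σ = 0.04 µg/mL) + independent Gaussian noise with the condition SD,
truncated at zero. Default means: control 0.55, off-focus 0.59, and
at-focus 0.60–0.65 µg/mL across the six pulsing sets (set 4, 50 ms
pulses at 10 Hz, highest at 0.65); SDs 0.07–0.10 µg/mL. The default of
8 paired runs matches the repeated-measures design's (5, 35) degrees of
freedom.

**What passing tests do not show.** Real inter-ictal EEG is
non-stationary, contains physiological artifacts the generator does not
model, and real ictal morphology evolves within events. Detector
sensitivity/FDR figures on this generator certify the implementation
under its assumptions, not clinical performance.

## Detector

Automates the screening rule: band-pass 2–20 Hz (4th-order Butterworth,
zero-phase `sosfiltfilt`), sliding RMS envelope (0.5 s window, 0.1 s
step), threshold at `median + 5·MAD` of the envelope, merge
supra-threshold runs separated by < 1 s, discard runs < 3 s, boundaries
by linear interpolation of the outer threshold crossings. The
median/MAD baseline is robust to the small ictal fraction; a two-pass
re-estimate (exclude candidates, re-threshold) exists behind a config
flag but is off by default. Because the threshold is data-derived,
detections are invariant to overall gain. The 30 Hz low-pass used for
display in such studies is treated as a display aid only. Measured
durations carry a small (≈ 0.2 s) boundary bias from the envelope
window and onset ramps; it is symmetric across periods and cancels in
the normalized indices.

## Indices

Ictal amplitude of an event is the area under the rectified trace
divided by the event duration (trapezoid rule at native sampling, on
the band-passed signal by default; a constant |x| = A yields A, a sine
of amplitude A yields 2A/π). Indices are computed per animal × period;
normalization is strictly per animal (post/pre ratio and percent
change). Animals with a zero or undefined pre-period index are flagged
and dropped listwise per index with logging. Group summaries always
average per-animal changes — the group mean of ratios, not the ratio of
group means; with the printed group means 145 → 61 the latter would be
−57.9 %, a different quantity from the per-animal mean of −57 %.

## Group statistics

Paired t (one-tailed a priori in the post < pre direction for count and
duration, two-tailed for amplitude), one-way between-group ANOVA with
Tukey–Kramer post-hoc (studentized-range distribution with the
harmonic-mean correction; reduces to Tukey's HSD at equal n; a
Bonferroni-adjusted variant of the pairwise p-values is reported
alongside, since "Tukey–Kramer with Bonferroni correction" is
ambiguous), Fisher's LSD for the dialysis parameter sets, and a one-way
repeated-measures ANOVA computed from its sums of squares with
df = (k−1, (k−1)(n−1)) and no sphericity correction by default
(Greenhouse–Geisser available via `correction="gg"`). Degenerate
inputs: identical pairs give t = 0, p = 1; constant nonzero differences
raise an error rather than returning an infinite statistic.

## Dosimetry

Plane-wave relation P = √(2ρcI) with degassed-water defaults
(ρ = 1000 kg/m³, c = 1480 m/s) — the constants are config-exposed since
the printed 0.38 MPa for 5 W/cm² does not state them; MI = P_r/√f₀;
in situ pressure after 17 % transcranial pressure attenuation at
600 kHz. Albumin is modelled as a 7 × 1.5 × 1.5 nm semi-axis ellipsoid;
surface area uses the Thomsen approximation (p = 1.6075), which
reproduces the reported ≈ 105.1 × 10⁻¹⁸ m² (the exact prolate closed
form gives ≈ 105.7 and is available behind a flag). Radiation force is
the absorbed-momentum estimate F = 0.2 · P_r[Pa] · (SA/2), reported in
pN; following the source arithmetic the pressure chain is carried at
its two-decimal reported precision (0.38 → 0.32 MPa), which yields
3.4 pN (full precision would give 3.3). Beam FWHM is read off a regular
intensity grid along the principal axes through the maximum with linear
interpolation and explicit undersampling/boundary errors. Safety flags:
MI < 1.9 (FDA soft-tissue guideline) and I_SPTA ≤ 3 W/cm² (IEC 60601-2).

## Problem sizes used by the benchmarks

The acceptance script runs the full default cohort (3 groups × 10
animals × 2 periods × 8 sessions) with desk-scaled 1 h sessions at
500 Hz — ≈ 0.9 × 10⁹ samples screened in ≈ 2 minutes — plus the
analytic dosimetry chain. Unit tests use smaller cohorts (2–3 animals,
0.1–0.2 h sessions) chosen so each check still exercises the full
generate → detect → index path. The stochastic acceptance bands are the
2-standard-error tolerances implied by the reported per-animal SDs at
n = 10; by design Monte Carlo the binding constraint is the drug-only
group's count change (irreducible per-seed SD ≈ 5 percentage points
from Poisson counting noise at the configured rates against a ±7-point
band), so an occasional out-of-band seed is expected behaviour of the
study conditions, not an implementation defect.

## Known limitations

No circadian structure, anesthesia or electrode artifacts in the
generator; no seizure-type classification (Racine labels are inputs);
no pharmacokinetics linking the dialysis arm to the in vivo effect; no
wave propagation or thermal modelling beyond the analytic dose chain;
EDF support is single-channel on the write side.
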