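# Methods

This note documents the models, estimators and numerical choices behind
`remfrag`, and what the synthetic cohort does and does not emulate.

## Design under study

A within-subject two-condition protocol: each subject sleeps one
undisturbed control night (CTR) and one REM-fragmentation night (FRG) on
which wrist vibrations are delivered during REM sleep until a cortical
arousal appears.  Around each night sit three emotional-reactivity /
recognition sessions (T0 baseline, T1 next morning, T2 48-h follow-up).
The scientific questions the pipeline answers: did the manipulation
fragment REM without wrecking sleep architecture; what spectral signature
did the stimulation evoke; did fragmentation abolish the normal overnight
habituation of the cardiac orienting response (HRD); and does the size of
the induced posterior alpha response predict the habituation failure.

## Sleep macrostructure and transitions

Hypnograms are 30-s epoch sequences over {W, N1, N2, N3, REM} between a
lights-off and a lights-on marker.  Definitions: TST = sum of sleep-stage
minutes in bed; SOL = lights-off to the first N1 or N2 epoch; WASO = wake
minutes between sleep onset and the last sleep epoch; SE = TST/TIB × 100;
REM latency = sleep onset to first REM epoch; awakenings = maximal W bouts
inside the sleep period.  `REMfr` counts, per hour of REM sleep: cortical
arousals and body movements logged during REM epochs plus maximal non-REM/
wake bouts flanked by REM on both sides.  Two conventions worth noting:
interrupting bouts have no length cap (none is standard), and an arousal
logged in the REM epoch immediately preceding an interrupting bout is not
counted twice — the bout subsumes it.

Transition matrices count consecutive epoch pairs within the in-bed
window (wake before sleep onset therefore contributes to the W row; the
window is the only defensible choice given the markers available).  Rows
never visited are NaN, not zero.  The between-condition comparison is a
paired *t* per cell with pairwise NaN exclusion; the Bonferroni factor is
the number of computable cells in that comparison, not a fixed 25, and
cells with zero-variance differences are flagged not-computable.

## Stimulation-locked ERSP

Epoch selection applies four exclusive rules in order: outside-REM,
not-final-in-train, artifact, full awakening.  A "train" groups
stimulations whose onsets are ≤ 40 s apart (the protocol's suspension
interval); the rule order means "final" is judged among in-REM
stimulations.  The full-awakening horizon is any W epoch intersecting the
15-s post-stimulus window.

Time–frequency analysis: complex Morlet wavelets on a 5–40 Hz grid in
0.2-Hz steps (176 frequencies), 16-ms time step, cycle counts linear in
frequency from 7 at 5 Hz to 42 at 40 Hz (`7 + (f−5)·35/35`), favoring
frequency precision.  Power is averaged across epochs per channel first,
then divided by the mean power of the −2000…−1000 ms baseline window at
the same frequency and converted to dB; the quoted order (average, then
correct) is implemented literally.  Time points whose wavelet half-support
(5 σ_t, σ_t = n_cycles/2πf) spills over an epoch edge are set NaN and
excluded from every downstream statistic — edge-contaminated baselines are
worse than shorter baselines.  Band reductions use inclusive bounds on the
0.2-Hz grid (theta 5–7.8, alpha 8–11.8, sigma 12–15.8, beta 16–29.8,
low-gamma 30–40 Hz) over the 0–6 s post-stimulus window.

## Cluster-based permutation inference

All multiple-comparison correction is nonparametric.  Point statistics are
thresholded at the two-tailed cluster-formation alpha (default .05);
same-sign suprathreshold points are grouped — full 2-D adjacency on the
time–frequency grid, or a channel graph built from montage coordinates
(Delaunay triangulation of azimuthally projected positions, pruned of hull
chords, plus a distance threshold grown until the median neighbor count
reaches ~6).  The cluster statistic is the mass (sum of point *t* values;
mass rather than extent is the common default).  Nulls: random sign flips
of per-subject difference maps for paired designs (exact under exchange-
ability), random permutation of the behavioral covariate for correlation
clusters, whose formation threshold is the |r| corresponding to the
cluster alpha at the sample size and whose mass sums r-derived *t* values.
Both cluster signs are compared against the permutation distribution of
the maximum absolute mass; Monte-Carlo p uses the add-one rule, so
p ≥ 1/(n_permutations+1).  Default 5000 permutations; simulation studies
in the tests use 500, which changes the p resolution, not the validity.
For each significant correlation cluster the cluster-mean map is
re-correlated with the behavior (the scatter statistic reported alongside
topographies).

## Autonomic metrics

IBI artifact correction flags beats whose interval deviates from a
centered rolling median (window 5) by more than a distribution-based
criterion blending 3.32× the quartile deviation of successive differences
with (median IBI − 2.9 QD)/3 — parameters of the published detection
criterion family; the exact constants are free parameters here.  Flagged
beats are replaced by a cubic spline through the remaining beats; records
with > 50% flagged are rejected.

HRD is computed on instantaneous HR (60000/IBI at beat times) linearly
interpolated to a 10-Hz grid: mean HR in the 2 s before onset minus the
minimum HR within 6 s after; positive = deceleration (the orienting
response).  "Lowest heartbeat value" is read as minimum instantaneous HR,
the convention that makes larger values mean stronger deceleration; the
interpolated-grid mean (rather than a beat-wise mean) is used for the
pre-window.

EDA pre-processing: anti-aliased down-sampling to 10 Hz, zero-phase
second-order 1-Hz Butterworth, Gaussian smoothing with a 10-sample (1-s)
window.  CDA.SCR replaces a full continuous-decomposition optimization
with regularized non-negative deconvolution against a Bateman kernel
(τ_rise 0.75 s, τ_decay 2 s, unit-area normalization), a documented
simplification: the driver is a non-negative rate (µS/s) on the data grid,
solved by NNLS with an L2 penalty (ridge 0.01 — small because the trace is
already low-passed; at this value an isolated planted driver mass is
recovered within ~2%).  CDA.SCR is the mean driver over the 1–6 s window;
a trial "responds" when the reconstructed phasic amplitude reaches
0.05 µS there.  Non-responder screening drops subjects responding to
< 20% of negative baseline (T0) stimuli in either condition.

## Recognition memory

Equal-variance signal detection: d′ = z(HR) − z(FAR) with boundary
replacements HR = 1 → 1 − 1/(2 N_old) and FAR = 0 → 1/(2 N_new).  The two
mirrored cases (HR = 0, FAR = 1), which the source convention leaves
unstated, receive the symmetric corrections so d′ stays finite and the
label-swap antisymmetry holds exactly.

## Mixed models and planned contrasts

Each outcome is fit with fixed factors Condition × Session × StimulusType
(full factorial), a participant random intercept, and — for trial-level
reactivity outcomes — a crossed stimulus-ID random intercept implemented
as variance components.  Estimation is REML via statsmodels; if the
crossed structure fails to converge the model falls back to the
participant-only structure and says so (`fallback_used`).  Omnibus terms
are Wald chi-square tests; planned-contrast p values use a *t* reference
with residual degrees of freedom (n − k).  A Satterthwaite approximation
would be preferable but is not available in the estimation backend; the
df method is labeled in the output, and with thousands of trial-level
observations the difference is negligible.  The nine planned comparisons
(T0vT1, T0vT2, T1vT2 within each condition; CTR vs FRG at each session)
are estimated emmeans-style from balanced cell-mean rows of the design,
Bonferroni-multiplied by 9 and capped at 1.  Interpretation is
hierarchical: main effects are subordinated to interactions involving the
same factor, interactions to higher-order interactions.

## Synthetic cohort: what is emulated

Every generator is a pure function of (config, seed, subject, condition,
session); subject-level latent parameters come from per-subject streams
derived from the global seed, so any subset regenerates identically.

**Hypnograms** are first-order Markov walks (30-s steps, 960 epochs ≈ 8 h).
The default transition matrices were calibrated once so their stationary
distributions reproduce a realistic ~88%-efficiency night with ~20% REM /
~8% N1 of sleep under CTR and ~12% REM / ~13% N1 under FRG — the
fragmentation signature (REM→REM down, REM→N1 up, N1→N2 down, wake rows
untouched).  The stimulation protocol is played inside REM runs with the
real rules (escalating 7-step intensity, 3-s on / 3-s off, 40-s suspension
holding the effective intensity, restart at minimum each REM period, stop
at stage change), with a per-step arousal-probability curve and two stray
out-of-REM stimulations per night.  A limitation worth knowing: the stage
sequence is drawn first and the protocol overlaid, so arousal events do
not themselves cause the subsequent stage transitions — the elevated
REM→N1 probability of the FRG matrix carries that effect at the
distribution level.

**EEG epochs** are 1/f^β background (β = 1) plus band-limited noise bursts
from t = 0 (alpha 3 dB / sigma 2.5 / beta 2 dB for 6 s; low-gamma 1.5 dB
for 2 s — the transient gamma response), weighted topographically
(posterior-dominant alpha, widespread sigma/beta, centro-posterior gamma).
Burst variances are calibrated in the wavelet measurement domain: a joint
fixed point over all bursts accounts for the Gaussian spectral smoothing
(σ_f = f/n_cycles) that attenuates a burst at its own band edges and
leaks neighboring bursts in, so the planted per-channel dB is what the
band-averaged ERSP recovers (verified to ±0.5 dB at 50 epochs).  Between-
subject variation of the alpha effect (SD 1 dB) loads on a posterior-focal
topography — subjects differ mainly in the posterior, wake-like alpha
intrusion — which is what makes the brain–behavior cluster localized
rather than whole-scalp.  No spindles, slow oscillations or ocular
artifacts are simulated; passing tests demonstrate correct recovery of
band-limited power changes, not robustness to real sleep microstructure.

**Autonomic trials** (28 per session: 14 negative, 14 neutral) integrate
beat times from an instantaneous-HR trajectory with a raised-cosine dip
starting 0.5 s post-onset (duration 4 s; peak depth = planted HRD).  The
negative-stimulus amplitude table is CTR (8, 4.5, 4.5) vs FRG (8, 8, 8)
bpm across (T0, T1, T2): the control condition habituates, fragmentation
does not.  Neutral stimuli get half the amplitude; trial noise SD 2 bpm,
subject offset SD 1 bpm, per-stimulus offsets SD 0.8 bpm shared across
subjects (the crossed random effect), and subject-level session-change
deviations SD 2 bpm.  No magnitude for the habituation drop is published;
3.5 bpm was chosen once as a clearly supra-threshold effect (≈ 9× the
trial-mean SE) and documented as a free parameter.  EDA traces carry a
Bateman-shaped SCR (peak 0.35/0.15 µS negative/neutral, scaled by session
habituation and a subject factor) at 1.2–3 s latency with response
probabilities 0.80/0.45; 10% of subjects are planted non-responders
(negative-response probability 0.10) to exercise the screening rule.

**Recognition** draws old/new decisions from the equal-variance SDT model
with session d′ (2.2, 1.8, 1.5) — memory declines over time with no
condition effect — criterion 0.25, subject SD 0.3.

**Coupling**: each subject's FRG session-change deviation equals
`σΔ (r·z_alpha + √(1−r²)·ε)` with r = 0.7, where z_alpha is the
standardized latent alpha deviation — so the planted posterior-alpha /
ΔHRD correlation is 0.7 at the latent level.  Measurement layers (channel-
level topography noise 0.5 dB, 28-trial HRD averaging) attenuate the
recoverable correlation mildly; the recovered cluster-mean r lands within
±0.1 of the target.  `generate_band_topography_cohort` emulates the output
of the ERSP stage directly at the subject level (planted topography +
channel noise) for operating-characteristic studies where rerunning the
wavelet chain hundreds of times would be pointless.

## Problem sizes and numerical choices

Simulation studies run at the design's size (17 subjects; 15 for the
reactivity models, mirroring the exclusions) with 200 replicate cohorts
and 500 permutations per test; the full pipeline run uses up to 10
stimulation epochs per subject at 125 Hz (a rate chosen so the 16-ms ERSP
step is an exact 2-sample decimation).  Mixed-model replicate studies use
the participant-only random structure — the crossed fit is reserved for
single full-size analyses, where its cost is irrelevant.  Degenerate
inputs are contracts, not crashes: zero REM yields an undefined `REMfr`
(not an exception), zero-variance cells and zero-power baselines are
flagged and excluded, constant behavior vectors are explicit errors.

## Known limitations

* The LMM stage's trial-level p values ignore subject×session random
  variation beyond the planted intercepts (as does the modeled analysis);
  its type-I calibration is verified only under the matching null.
* The CDA.SCR simplification is not a reimplementation of the full
  continuous-decomposition optimizer; absolute driver units agree with it
  only up to the kernel-normalization convention.
* EDF support targets plain uncompressed EDF with one sampling rate across
  channels; EDF+ annotations are not written.
* The synthetic EEG validates spectral power recovery only; no claim is
  made about artifact robustness, source geometry, or staging accuracy on
  real recordings.
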