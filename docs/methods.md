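# Methods

`catrack` re-implements, as a tested pipeline over synthetic recordings, a
longitudinal awake two-photon calcium-imaging analysis: fluorescence trace
conditioning, calcium-transient detection and activity categorization,
four-week dynamics of matched neurons, pairwise synchrony of binarized
activity, behavioral epoch segmentation, and 3D amyloid-plaque proximity.
This note documents the models, the pinned numerical procedures, the
parameters that matter, and what the synthetic benchmark does and does not
show about real data.

## Trace conditioning

Somatic fluorescence F_ROI(t) is contaminated by out-of-focus neuropil
signal; the compensated trace is

    F_comp(t) = F_ROI(t) + c · (median(F_neuropil) − F_neuropil(t)),  c = 0.7.

Adding the neuropil median back keeps the trace on the raw-fluorescence
scale, so a constant neuropil leaves the trace unchanged and the operation
is invariant to adding a constant to the neuropil channel.

The compensated trace is low-pass filtered at 5 Hz (4th-order Butterworth,
zero-phase). At the native 10 Hz frame rate the cutoff equals Nyquist, so
the filter is skipped with a logged notice (pinned: skip when cutoff ≥ 0.95
× Nyquist); the step only matters for higher-rate inputs. Slow trends
(bleaching, brain-state drift) are removed by subtracting the running 8th
percentile in a centered ±50 s window; edge windows are truncated, never
padded, and percentiles interpolate linearly between order statistics. The
window filter is an O(N·W) incrementally sorted sliding window (numba),
because it runs once per neuron-session at cohort scale.

**F0 and the noise band.** The baseline offset and the noise scale are
estimated from "quiescent" frames so that the procedure works for rarely
and highly active cells alike:

1. B(t) = running 8th percentile of the detrended trace in a ±0.5 s window;
2. residual r = detrended − B;
3. q = 60th percentile of r;
4. quiescent frames: r < q;
5. f0_offset = median of the detrended trace over quiescent frames;
6. noise_sd = standard deviation of r over quiescent frames.

Transients occupy the upper tail of r, so quiescent-frame selection is
robust to event density. Two consequences of the restriction to the lower
60% are worth knowing: on pure white noise of sd σ, f0_offset sits at about
−0.51 σ (not 0) and noise_sd at about 0.567 σ (truncated-normal
shrinkage). Both constants are frozen in the test suite from a Monte-Carlo
oracle. All detection and binarization thresholds are expressed in
noise_sd units above f0_offset, which makes the whole chain exactly
invariant to affine rescaling of the raw fluorescence — the effective
detection threshold corresponds to roughly 2 raw noise sd above baseline.

ΔF/F is (detrended − f0_offset) / f0_raw, where f0_raw is the median of
the compensated, low-passed but *not* trend-subtracted trace over quiescent
frames: detrending removes the absolute baseline that the denominator
needs. Neurons with f0_raw ≤ 0 are flagged and excluded from AUC analyses.

## Transient detection and activity categories

Detection runs on the detrended trace smoothed with a centered 5-frame
boxcar (edge-truncated). A transient is a supra-threshold run (strictly
above f0_offset + 3·noise_sd) lasting at least 10 consecutive frames
(1.0 s at 10 Hz, i.e. "more than 9 frames"). Candidate peaks are the local
maxima of the smoothed trace above threshold; peaks closer than 15 frames
(1.5 s) are merged by iterative greedy suppression keeping the higher peak.
Two detector details are design choices:

- **Run splitting.** A single supra-threshold run holding several peaks ≥15
  frames apart is split at the minima between the surviving peaks. Without
  this, trains above ~4 transients/min fuse (the tail of one event bridges
  into the next) and sensitivity collapses for exactly the highly active
  cells the analysis is about.
- **Prominence floor.** Candidate local maxima must also be prominent by
  ≥3·noise_sd, so noise wiggles riding on a transient's tail do not split
  one event into several. Both rules are scale-free.

The minimum peak height of 3·noise_sd is guaranteed by the threshold and is
checked before merging. Per session, activity is summarized as transients
per minute, the trapezoidal integral of max(ΔF/F, 0) per minute (the
positive part — a signed integral of a zero-baseline trace cancels noise
symmetrically and measures nothing), and the activity category: rarely
active < 0.25, intermediately active 0.25–4 (boundaries inclusive), highly
active > 4 transients/min. A neuron is "active" if it shows ≥1 transient.

On the standard benchmark (100 neurons, rates log-uniform 0.25–8/min,
SNR 5, 8.3 min at 10 Hz, fixed seed) the detector reaches event-level
sensitivity ≈ 0.98 and precision ≈ 0.97 at ±5-frame peak matching, with
the rate error ≤ 0.5 transients/min for every neuron.

## Longitudinal dynamics

All cross-session statistics consume a tidy longitudinal table (neuron ×
session with rate, AUC, category, FOV and cohort labels); neurons are
matched by ID. Implemented: per-neuron Δrate; the within-FOV similarity
index, pinned as the Pearson correlation across neurons of per-neuron rates
between two sessions (undefined for constant vectors; such FOVs are
excluded from averages), with a seeded neuron-identity shuffle null
(exhaustive enumeration available for tiny n); 3×3 category transition
matrices with conserved counts; per-category reoccurrence rates (pooled or
per FOV); "novel highly active" neurons — high at a session and not high at
the immediately preceding one — with source-category fractions and mean
rate gain (seeded percentile bootstrap, 10 000 resamples); two-sample KS
and Mann-Whitney comparisons (exact p for n·m ≤ 10 000, asymptotic
otherwise, via scipy).

## Synchrony

Each neuron's detrended trace is smoothed over 20 frames (2 s) and
binarized at f0_offset + 2·noise_sd (same noise-band estimator as
detection, hence scale-free). Pairwise synchrony is the Pearson R of the
binary vectors, which on binary data equals the phi coefficient of the 2×2
co-occurrence table; pairs with a constant vector are flagged undefined and
excluded from means (exclusion counts reported). The chance level is a
circular time-shift shuffle — each neuron's vector is rolled by an
independent uniform shift — preserving event counts and autocorrelations.
Correlations can be restricted to behavioral epoch classes (a frame mask
retaining < 100 frames flags the FOV), to pairs whose two members share an
activity category, and binned by in-plane centroid distance (an FOV whose
pairs do not cover all distance bins is flagged).

## Behavior

A binary whisking track is segmented into whisk epochs (maximal runs of 1
lasting ≥ ceil(0.33 s × frame rate) frames; 4 frames at 10 Hz) and
stationary epochs. Because the indicator decays over seconds,
whisk-associated activity is read in the 2 s window after each whisk
offset, truncated at the next whisk onset; windows left shorter than 1 s
are discarded entirely (their frames belong to no epoch class). Stationary
frames are those in no whisk epoch, no whisk-associated window and no
discarded window; the three masks are pairwise disjoint and, together with
discarded frames, cover the session. Grooming is not distinguished from
whisking; one binary track encodes both.

## Plaque geometry

The plaque-dye channel of a structural z-stack is cleaned per slice:
median-background subtraction of both channels, subtraction of the
indicator channel (bleed-through removal), then a 3×3 in-plane median
filter. The difference is deliberately not floored at zero — clipping
censors the negative noise tail that the threshold estimator needs.
Each slice is binarized at background + 3 robust sd, with background the
slice median and sd = 1.4826 × the one-sided MAD of sub-median voxels
(falling back to supra-median deviations when an externally clipped input
leaves the sub-median set empty). On Gaussian noise this recovers the true
sd while ignoring bright plaque signal, and keeps the noise-positive
fraction below 2%.

A neuron's plaque distance is the minimum anisotropy-scaled 3D Euclidean
distance from its ROI centroid to any plaque-positive voxel center
(voxel sizes default to 0.673 × 0.673 × 0.5 µm). The k-d-tree query is
followed by a direct distance recomputation to the returned voxel, so the
value agrees exactly with a brute-force scan (verified on random
anisotropic fixtures). An empty mask yields an infinite distance, classed
distant. Neurons are close iff distance ≤ 40 µm (alternative cutoffs and
distance bins supported). Stratified dynamics include only neurons with a
distance record at every session and assign the stratum from the
first-session distance (the defining session is not specified upstream;
baseline is the pinned choice). Suspect assignments (e.g. nearest voxel on
the volume border) are reported as flags rather than manually re-measured.

## Synthetic-data generator

The generator emulates the statistical structure of the study's recordings
so that every stage is verifiable without raw data. Defaults are the study
conditions: three sessions of 5000 frames at 10 Hz (8.3 min), cohort
compositions from the observed category counts — wild-type-like
94/309/81 and amyloidosis-model-like 177/951/444 (rare/intermediate/high)
— and per-category rate ranges 0.01–0.24, 0.25–4.0 and 4.1–12
transients/min, sampled log-uniform (the 12/min ceiling keeps events
separable at 10 Hz).

- **Event trains.** Renewal processes with a 2 s refractory interval and
  rate-corrected exponential gaps (mean inter-event interval = 1/rate
  exactly). A pure Poisson train would routinely place events closer than
  the detector's 1.5 s merge distance, making the detection benchmark
  unwinnable for reasons unrelated to the detector. Because the study's
  class weights are weights of *observed* classes at this session length,
  each neuron-session's train is rejection-sampled until its realized class
  matches the assigned one; otherwise count quantization near the 0.25/min
  boundary reshuffles ~6 percentage points of the composition.
- **Fluorescence model.** baseline + Σ amplitude·kernel(t − tᵢ) +
  mix·neuropil + drift + white noise, with a unit-peak difference of
  exponentials (rise 0.18 s, decay 1.8 s, GCaMP6s-like — a single event
  spans well over 10 frames at 10 Hz), lognormal amplitudes (median ΔF/F
  0.8, σ = 0.35; the source reports no per-event amplitude statistics, so
  these are free defaults chosen to give SNR 5 at the default noise sd),
  a slow sinusoidal drift, and a shared per-FOV neuropil fluctuation
  (AR(1), ρ = 0.97, plus a sinusoid) mixed into every soma at 0.7 — the
  same factor the compensation step assumes. The measured neuropil trace
  is the shared fluctuation plus small independent measurement noise.
- **Session-to-session dynamics.** Rates evolve by normal drift (sd 1
  transient/min per 2-week step) with a *reflecting* boundary at zero — a
  floored walk piles silent neurons at rate 0 and would make rarely active
  neurons artificially persistent, contradicting the near-zero rare-class
  reoccurrence the analysis is meant to exhibit. The amyloidosis-like
  preset adds +0.3/min mean drift to currently intermediately active
  neurons (a mechanism for gradual hyperactivity recruitment, not a fitted
  value); the wild-type-like preset drifts with mean 0.
- **Shared network events** control pairwise synchrony: session-wide event
  times (2/min) that each neuron joins with probability p (0.10 wild-type-
  like, 0.20 amyloidosis-like), scaled by min(1, rate) so rarely active
  neurons are not lifted out of their class, and compensated in the
  individual event rate so the realized total rate matches the assigned
  one. Options: participation decaying with distance from a random
  epicenter (for distance-dependent synchrony) and confinement of shared
  events to whisking-associated frames.
- **Whisking** is an alternating renewal process: exponential quiet phases
  (mean 20 s — unconstrained upstream, chosen to give long quiet
  wakefulness interrupted by brief bouts) and exponential whisk bouts
  (mean 1 s).
- **Plaques** are unions of anisotropy-corrected spheres in a 350 × 350 ×
  120 µm volume (520 × 520 px, 0.5 µm z steps), 18 plaques of lognormal
  radius (median 8 µm) growing 1.5 µm per session. This geometry puts the
  median nearest-plaque distance in the mid-30s of µm, decreasing across
  sessions as plaques grow, and splits the population into comparable
  close/distant strata. A rendering helper adds background, noise and
  indicator bleed-through to produce raw two-channel stacks for the cleanup
  pipeline.

The ground-truth manifest records the realized event times and rates, the
programmed (intended) rates, categories, shared-event times, centroids,
plaque geometry and whisk epochs; identical seeds give bit-identical
output.

**What passing tests do and do not show.** The generator's noise is white
and Gaussian, its neuropil is a single shared trace, events are isolated
kernel bumps without indicator saturation or motion artifacts, and neuron
identity across sessions is perfect. Passing the benchmark therefore shows
the chain implements its rules correctly and recovers structure under
realistic SNR and drift — it does not certify performance on real
recordings with registration errors, z-drift, overlapping somata or
indicator nonlinearity, all of which are upstream of this pipeline's
inputs.

## Problem sizes and numerical choices

The acceptance script and the heavy tests run the full chain on cohorts of
484 (wild-type-like) and 1572 (amyloidosis-like) neurons × 3 sessions ×
5000 frames; pairwise synchrony uses the first 100 neurons per cohort
(4950 pairs); the detection benchmark uses 100 neurons; the distance-bin
type-I calibration uses 100 table-level runs of 400 neurons. Bootstrap CIs
use 10 000 percentile resamples. All randomness flows from
`numpy.random.default_rng` seeds; per-session and per-stage streams are
spawned from the root seed. Degenerate inputs are flagged, never fatal:
flat traces (noise_sd = 0) refuse detection/binarization, constant rate
vectors make the similarity index undefined, empty categories make
reoccurrence undefined for that FOV, and empty plaque masks give infinite
distances.

## Known limitations

Movie registration, ROI segmentation and whisker-video processing are out
of scope (masks, traces and binary whisk tracks are inputs). The
repeated-measures ANOVA layer of the original analysis is replaced by
exported tidy tables usable with any stats tool. The similarity index and
the shuffle used upstream are under-specified in the source text; the
Pearson pinning and the circular-shift shuffle are documented choices, not
confirmed definitions. Whether "plaque border" distance subtracts a plaque
radius is likewise not distinguishable from the text; nearest-positive-
voxel distance is used.
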