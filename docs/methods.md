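# Methods

## Scope

`ambitopo` implements a cross-subject EEG decoding pipeline for a
two-class visual-ambiguity task, together with a synthetic-EEG generator
that serves as its ground truth. Real-data ingestion is out of scope; the
HDF5 epoch container documents the layout such data would need
(`/subject_<k>/data` as trial × channel × sample, per-trial LA/HA labels,
`fs`/window/channel attributes).

## Stimulus model

Necker-cube stimuli are parameterized by the inner-edge contrast
`I ∈ [0, 1]`. Ambiguity rises linearly from `a = 0` at `I = 0` to
`a = 100%` at `I = 0.5` and mirrors for `I > 0.5` (right-oriented cubes),
so the eight session contrasts (0.15, 0.25, 0.4, 0.45 and their mirror
images) give the ambiguity ladder 30, 50, 80, 90% twice. LA pools
a ∈ {30, 50}%, HA pools a ∈ {80, 90}%. A session presents 25 trials per
contrast in randomized order — 100 LA + 100 HA trials, each class balanced
50/50 by cube orientation — with presentation times uniform in
[1, 1.5] s and pauses uniform in [3, 5] s. Trial epochs are cut −2…+2 s
around stimulus onset.

## Synthetic EEG

Each trial of each subject is

* **1/f background**: Gaussian noise with power spectral density ∝ f^−χ
  (χ = 1), synthesized in the frequency domain and normalized to unit
  variance; each channel mixes an independent process with a
  channel-shared process (amplitude fraction 0.3) so that neighboring
  channels are positively correlated, as sensor-space cluster statistics
  assume.
* **ongoing alpha**: a sinusoid with per-trial frequency ~ N(10, 0.5²) Hz,
  random phase, amplitude 0.5 (units of the background SD), present in
  both classes.
* **HA-only effects**: for each effect specification (channel set,
  `[f_lo, f_hi]` Hz, `[t_lo, t_hi]` s, gain), a Hann-enveloped sinusoidal
  burst at the band center frequency with random phase per trial.

The burst amplitude is calibrated *against the analysis wavelet*: the
generator measures the background's mean wavelet power inside the effect
box on a 20-trial probe, measures the in-box wavelet power of the
unit-amplitude enveloped burst, and scales so that in-box power is
multiplied by approximately the requested gain. A steady-state
calibration would be badly off here because a burst much shorter than the
wavelet (σ ≈ 0.16 s) has most of its energy smeared outside its window.
Gain 1 injects nothing, making LA and HA exchangeable (the null).

Per-subject variability: each subject gets independent noise, an
independently re-randomized schedule when none is supplied, and a
jittered realization of every effect (Gaussian jitter of the band and
window edges, default 0.25 Hz / 0.01 s; lognormal gain jitter, default
σ = 0.1). One master seed fans out to per-subject `SeedSequence` streams,
so runs are bit-reproducible and subjects are independent.

Defaults emulate the study design: 20 subjects, 31 channels, 250 Hz, and
three HA effects — anterior theta 7–9 Hz / 0–0.15 s, occipito-parietal
beta 22–24 Hz / 0.02–0.2 s, fronto-parietal high beta 31–32 Hz /
0.35–0.42 s — with gain 2.5, a value chosen as a realistic "clearly
present but noisy" class effect.

What the generator does *not* emulate: eye blinks and other artifacts
(the pipeline's ICA-style cleaning step is therefore out of scope),
behavioral responses, non-stationarities across a session, volume-
conduction-realistic topographies (effects are boxcar in channel space),
and realistic between-subject anatomy. Passing tests therefore certify
the pipeline's statistics and plumbing, not real-EEG effect sizes.

## Montage

31 standard 10-10 positions from MNE's `standard_1020` template,
azimuthal-equidistantly projected about the best-fit head sphere (nose
+y) and scaled to the unit disc. The spatial neighbor graph connects
channels within 0.5 of each other in these coordinates, giving median
degree 5 and at least 2 neighbors everywhere — the usual density for
sensor-space cluster correction. Reduced-scale simulations use a
16-channel subset with threshold 0.6.

## Spectral analysis

* Band-pass 1–100 Hz (FIR, ~3 cycles of the low cut-off) and a 50-Hz
  notch (2 Hz wide), both applied forward-backward so filtering is
  zero-phase and cluster time bounds suffer no group delay.
* Morlet wavelet `W(f,t) = exp(2iπft)·exp(−t²/2σ²)` with `σ = n/(2πf)`
  and cycles rule `n = f`, i.e. constant σ = 1/(2π) ≈ 0.159 s at every
  frequency and frequency-proportional spectral bandwidth. The rule is
  pluggable (`cycles_rule`), since a fixed-σ reading is unusual; it is
  implemented literally and its consequences (time bounds smeared by
  ±~0.16 s, ~1 Hz spectral Gaussian) are visible in recovered cluster
  bounds. Kernels are unit-energy; power is |convolution|², evaluated by
  FFT on the epoch cropped to the output window plus kernel support.
  An error is raised if the output window comes within 3σ of the epoch
  edges.
* Grids: 4–40 Hz in 1-Hz steps and 50 time points over [−0.5, +0.5] s by
  default (the triplet space stays ~31 × 37 × 25 post-stimulus). Reduced
  runs use 2-Hz steps and 25 time points.
* ERSP: `(WP − B)/B` with `B` the time-mean of prestimulus WP per
  (channel, frequency), computed per trial; the baseline window defaults
  to [−0.5, 0) s. A pointwise pre/post pairing has no natural alignment,
  so the time-mean convention is used. A configurable floor guards
  against near-zero baselines (error names the offending
  channel/frequency). Known artifact: an effect within ~2σ of stimulus
  onset leaks into the baseline, slightly biasing that channel/frequency's
  ERSP downward elsewhere; visible as occasional weak opposite-polarity
  clusters at high gain.

## Cluster-based permutation contrast

Subject-mean HA and LA ERSPs (post-stimulus segment) enter a paired
t-test per triplet (df = N−1; zero-variance triplets get t = 0 with a
logged warning). Triplets with |t| above the two-tailed p = 0.01 Student
threshold are kept if at least 2 spatial channel-neighbors at the same
(frequency, time) bin are suprathreshold with the same sign (the
min-neighbor convention; configurable, 0 disables). Connected components
— channel adjacency, ±1 frequency bin, ±1 time bin, no diagonal steps,
polarities separate — are scored by summed |t| (cluster mass).

The null flips the HA/LA assignment per subject (sign-flip of the
subject difference — the exchangeability unit of a paired design; trial
permutation would test a different hypothesis), recomputes the t-map and
re-clusters with identical settings, and records the per-polarity maximum
cluster mass; 2000 Monte-Carlo flips by default, exhaustive 2^N
enumeration for N ≤ 20. Only the permuted mean needs recomputing: the
second moment of the differences is flip-invariant, so the per-permutation
t-map is a single matrix product. Monte-Carlo p-values use the
+1-corrected counting rule `p = (1 + #{null ≥ mass})/(1 + n_perm)`
(always positive); exhaustive nulls contain the identity and use the
plain proportion, with a ~1e-8 relative tolerance absorbing float noise
between the observed and identity-permutation arithmetic paths. A cluster
is significant at p < 0.025 per tail (family-wise 0.05 two-tailed). Both
polarities are computed and reported. Cluster bounds are the min/max of
member bins mapped to axis units; the channel set is the member union.

## Topograms

For every trial and significant cluster, ERSP is averaged over the
cluster's time-frequency box at *all* channels and interpolated onto a
64 × 64 (configurable, 224 available) head-disc image by thin-plate-spline
RBF over the projected electrode positions — smooth and exact at the
electrodes. Pixels outside the unit disc take a background value. Color
limits are symmetric about 0, fixed for a whole run at the 98th
percentile of |cluster-averaged ERSP| pooled across subjects, and
recorded in `render_meta` together with the montage hash: per-image
normalization would erase exactly the intensity differences the
classifier needs. Images are stored single-channel; grayscale PNG export
(`s<subject>_t<trial>_c<cluster>_<label>.png`) is optional.

## Classifier

LOSO: one fold per subject, the fold's training set being every image of
the other subjects (no image hash overlaps, asserted in tests). The
default model is a small, fully seeded numpy CNN — three 3×3 conv + ReLU
+ 2×2 max-pool blocks (8/16/32 channels), a 64-unit dense layer, softmax
cross-entropy, Adam (lr 1e-3, batch 32) — deterministic given a seed,
verified by gradient checks against numerical differentiation. A
residual-block variant (`arch="resnet"`) provides a deeper topology.
Early stopping monitors a held-out slice of the *training* subjects
(default 15%, patience 3), never the test subject. LA is class 0, HA
class 1 and the positive class for precision/recall; image-level metrics
are primary, with trial-level fusion (mean class probability over a
trial's cluster images) reported alongside.

## Stability analysis

The cluster pipeline is re-run N times with one subject excluded (same
settings and seed policy). Re-extracted clusters are matched to the
all-subject ("common") clusters by maximal time-frequency box overlap
within polarity, greedily, largest overlap first; an unmatched common
cluster is recorded as absent for that exclusion (never imputed). For
matched clusters, `Δf` and `Δt` normalize the summed absolute bound
movement by twice the common width (in percent); both are 0 exactly when
the intervals coincide and are invariant to axis rescaling. Accuracy is
then regressed on the per-cluster deltas by OLS (statsmodels) over
complete cases, reporting coefficients, standardized betas, R², F and
p-values. Repeated-measures ANOVA tables are deliberately not provided.

## Test scale and numerical choices

The suite runs every stage at sizes a single CPU handles in minutes,
chosen once as the package's test scale:

* Null calibration: 200 synthetic null datasets of subject-mean ERSP maps
  (8 channels × 10 freqs × 10 times, N = 8, 500 permutations) generated
  directly at the ERSP level — the cluster test's input — rather than via
  raw EEG, since calibration of the test does not depend on the spectral
  chain. Observed family-wise positive rate must be ≤ 0.05.
* Monte-Carlo vs. exhaustive: N = 5 subjects, 2000 draws vs. all 32
  sign-flips, agreement within 3 binomial SEs.
* Effect recovery: N = 12 subjects, 100 trials/class, gain 2.5, 16
  channels at 125 Hz, 2-Hz frequency grid, 500 permutations, 20 seeded
  runs. The injected box (8–16 Hz × 0.1–0.4 s) is deliberately large
  relative to the analysis point-spread (±~0.16 s, ±~1 Hz plus the
  burst's own ~4/T spectral width): bounds of a box smaller than the
  resolution limit — e.g. the 0.07-s-long third default effect — are
  resolution-limited, not recovery failures. Time and frequency Jaccard
  ≥ 0.5 required in ≥ 90% of runs.
* Classifier sanity: 5 subjects × 40 trials × one gain-4 effect, 64×64
  images; mean LOSO accuracy ≥ 0.70 required, and with labels shuffled
  (association broken everywhere) pooled accuracy must stay inside the
  95% binomial band around 0.5. With separable features, shuffling
  *training* labels alone does not give binomial chance: the network
  amplifies whatever residual association the finite shuffle leaves, so
  the chance check evaluates against the shuffled labels.

Other numerics: ERSP of constant power is zero to one ulp of the baseline
mean (asserted at 1e-15); max-pool ties break toward the first element
(determinism); montage duplicate coordinates and isolated channels are
errors; `fs < 2 × top analysis frequency` is an error.

## Known limitations

* The constant-σ wavelet rule trades frequency resolution for none of the
  usual multi-resolution benefit above ~20 Hz; narrow high-frequency
  effects blur accordingly.
* Burst injection cannot confine energy below the time-bandwidth limit;
  "ground-truth" boxes are nominal, and recovered bounds include the
  point-spread of both the burst and the wavelet.
* The numpy CNN is desk-scale: ~10⁴ images × 64×64 is comfortable,
  ImageNet-scale backbones are not its purpose.
* The permutation test assumes within-subject exchangeability of HA/LA;
  unbalanced or unpaired designs are not supported.
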