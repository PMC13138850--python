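# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices made where the design was open, and what the tests do
and do not establish.

## LN models and constraints

Both models predict the spike count in each 1/85-s bin from the preceding
30 stimulus frames on a 15×15 stimulus-pixel crop centered on the cell.

**Rank-two DoG model.** `R(x,y,t) = G1(x,y)T1(t) − G2(x,y)T2(t)` with
parametric Gaussians `G = A·exp(−½(p−μ)ᵀC⁻¹(p−μ))`. Constraints and their
enforcement:

- shared center: one stored mean vector backs both Gaussians;
- same amplitude sign: a fixed polarity sign (from the STA) times
  softplus-positive magnitudes;
- SPD covariances: `C = LLᵀ` with a lower-triangular factor whose diagonal
  is softplus-positive, so gradient steps cannot leave the SPD cone;
- unit-norm temporal filters: `T = v/‖v‖` re-parameterization, exact at
  every step.

No constraint forces the surround Gaussian to be wider than the center;
the data decide.

**Rank-one model.** A free 15×15 spatial matrix (225 parameters) and a
free 30-tap temporal filter; no constraints beyond the softplus gain
`α > 0`.

**Output nonlinearity.** `f(x) = α·log1p(exp(x+β))`, computed via
`logaddexp` for stability. Predictions are valid-mode only: the first 29
bins of every contiguous segment (each trial's non-repeating and repeating
stretches are separate segments) carry no prediction, so no pre-stimulus
history is fabricated.

## Training

Gradients are analytic (the models have at most ~260 parameters, so
hand-derived chain rules through the Gaussian rendering, Cholesky factors,
norm reparameterization, convolution, softplus and Poisson loss are exact
and fast); the optimizer is Adam. Settings, with defaults:

| parameter | default | note |
|---|---|---|
| max epochs | 500 | |
| early-stop patience | 30 epochs | on validation correlation |
| scheduler patience / factor / floor | 15 / 0.1 / 1e-7 | reduce-on-plateau |
| initial learning rate | 0.009 (white noise), 0.005 (movie), 0.001 (adaptation) | |
| mini-batch | 256 contiguous valid bins, reshuffled each epoch | keeps 30-frame histories intact |
| train/validation split | 80/20 of trials, shuffled, seeded | non-repeating segments only |
| Poisson-loss ε | 1e-12 | guards log(0) |

Parameters of the best validation epoch are restored at early stop. The
trial split, batch order and initialization all derive from the fit seed.

**Initialization.** The DoG decomposition has near-degenerate alternative
optima: two similar-width Gaussians with distinct temporal filters can
mimic a single wide center, which biases `G1`-based center sizes low. The
fit is therefore seeded the way LN fits conventionally are — from the STA:
the center covariance starts at the isotropic second moment of the
smoothed STA peak (surround at twice that width), `T1` at the STA's
temporal course at the peak pixel, and the surround magnitude starts small
(0.05), reflecting the weak surrounds seen under white noise. Remaining
values: amplitudes 0.5, α = 1, β = 0, `T2` a unit-normalized standard
normal draw; the rank-one spatial filter starts at N(0, 0.01).

**Out-of-domain adaptation.** All spatial parameters are frozen (the
returned parameter object carries the input's spatial values through
verbatim, so serialization is byte-identical); only temporal filters and
the nonlinearity train, at learning rate 0.001 with the same scheduler.
Both ensembles are trimmed to equal non-repeating frame counts before any
fit (whole trailing trials first, then trailing frames).

## Synthetic data

The generator emulates the recording structure the analysis assumes:
trials of non-repeating (training) frames followed by a repeating (test)
sequence identical across trials; frames are mean-zero contrast values at
85 Hz, stored at stimulus-pixel resolution with block expansion to screen
pixels available.

- **White noise**: independent binary ±contrast per stimulus pixel per
  frame (Gaussian optional); contrast 0.3. Spatially flat spectrum.
- **Naturalistic surrogate**: windows into a larger periodic latent image
  with a 1/f amplitude (1/f² power) spectrum and uniform random phases,
  viewed along a seeded random-walk gaze path (step SD 1 stimulus pixel,
  integer positions) emulating fixational eye movements; the latent
  content is refreshed as an AR(1) mixture with coefficient 0.95, which
  preserves the marginal spectrum. The measured radial log–log slope is
  ≈ −2 over the middle frequency decade.
- **Model neurons**: LN–Poisson cells with biphasic temporal filters and
  DoG spatial filters. Amplitudes are scaled so the white-noise drive SD
  is 1.5, and the softplus gain is set so the mean rate is ~15 Hz; β =
  −0.2. Two qualitative classes: *midget-like* (OFF, center σ 1.2–1.8 px,
  center covariance ×1.5 under the naturalistic ensemble) and
  *parasol-like* (ON, σ 1.8–2.6 px, unchanged center). Surround/center
  volume ratio 0.10 under white noise vs 0.55 under the surrogate when
  adaptation is enabled; with `adapt=false` both parameter sets are
  identical. Counts are Poisson with per-bin mean rate/85; repeating
  segments get fresh noise per trial. Rates for the first 29 bins of each
  segment use mean-gray-padded history (those bins are excluded from
  fitting and evaluation; padding keeps repeating-segment rates identical
  across trials).

What the generator does **not** emulate: photorealistic image content and
its higher-order statistics, chromatic structure, luminance differences
between ensembles (the emulated study argues luminance does not explain
the effects; a mean-offset option exists but is off), adaptation dynamics
within a trial, spike-history dependence, and inter-cell correlations.
Passing tests therefore show that the *pipeline* recovers and detects the
modeled effects, not that real RGCs behave this way.

## Evaluation

Test performance is the Pearson correlation between the model prediction
on the repeating sequence and the across-trial mean response, valid bins
only. The typeset form of this correlation elsewhere mixes summation
ranges; plain sample Pearson correlation over all test bins is used.
Undefined correlations (constant traces) are excluded with counts logged.
Reliability is the correlation between averaged odd- and even-numbered
repeating trials (1-based). Group comparisons use two-sided Wilcoxon
signed-rank tests on paired per-cell differences; groups with fewer than
five valid pairs are flagged underpowered.

## Receptive-field quantification

- `dog_params`: `S = 4π√(λ₁λ₂)` from the center Gaussian; surround
  amplitude from the full `R` after normalizing the center pixel at the
  max frame to magnitude 1 — the softplus absorbs overall filter scale, so
  normalization is required for cross-model comparability. The surround
  frame is searched within ±6 frames of the max frame among frames whose
  center pixel retains the cell's polarity; the opposite-polarity search
  spans the whole 15×15 crop. Ties break toward the earliest frame;
  amplitudes below 1e-4 are reported as 0 in summary outputs.
- `posthoc_dog`: bounded least squares (scipy `least_squares`, trf) of a
  shared-mean, same-sign DoG to a spatial filter. Initialization `A_c =
  A_s = 0.5`, `σ_c = 1.2`, `σ_s = 1.5`, off-diagonals 1e-3, mean at the
  crop center; off-diagonals are parameterized as bounded correlations so
  the covariances stay SPD; amplitudes are capped at 10× the image's
  dynamic range. Broad-surround filters can trap that start in a
  degenerate two-identical-Gaussians basin, so when the residual is poor
  the fit restarts deterministically from moment-informed widths (×1,
  ×1.5, ×2) and keeps the best solution. Two equal-covariance Gaussians
  are collapsed to the canonical single-Gaussian form (amplitude
  difference, `A_s = 0`).
- `threshold`: separable Kaiser window (β = 7), max-abs normalization,
  20%-of-peak threshold, area of the 8-connected component containing the
  peak; surround from the windowed, normalized filter smoothed with a
  Gaussian kernel (σ = 1.5 px).
- Mean receptive fields: each cell's RF is rescaled so its center-pixel
  temporal-trace extremum is +1 (ON) / −1 (OFF) — for rank-two filters
  "the" temporal filter is not unique, so the center-pixel trace stands in
  — then the surround-frame slice is shifted by integer pixels to a common
  center (vacated pixels = mean gray 0) and averaged.
- µm² conversion: pixels² × (stimulus-pixel pitch)², with the stimulus
  pixel = `stim_pixel_factor` × screen-pixel pitch.

## Spectral analysis

Per-frame 2-D FFTs of center-cropped square frames (orthonormal
normalization, so summed power equals summed squared contrast), radially
averaged into unit-width annuli by rounded radius. The DC bin is excluded
everywhere; "the first data point" used for normalization is the first
non-DC annulus. Each annulus reports the mean sample radius as its
frequency, which makes closed-form comparisons exact at the annulus level.
No window is applied before the FFT. Filter transfer functions use the
unnormalized FFT of the zero-padded filter, so a unit impulse is the
identity filter. Filtered spectra come in two modes — circular convolution
per frame, or multiplication of the power spectrum by the squared transfer
magnitude — which are mathematically identical (an amplitude-domain switch
reproduces plain-magnitude multiplication).

**Whitening percent.** With `D(s,f) = |log10 s(f)|` the log-distance of a
normalized spectrum to the flat reference, the score is `100·(D(unf,f*) −
D(filt,f*))/D(unf,f*)` at the in-band `f*` maximizing the reduction; the
band runs from the 2nd radial bin to the frequency where the filter's
transfer magnitude falls to 10% of its peak. **Simulated filters**: center
Gaussians from the small/large mean-RF DoG fits, made isotropic (largest
diagonal entry) with amplitude 1; the subtracted surround's amplitude
(0.05–1.0, step 0.05) and width scale (1.2–4.0×, step 0.2) are chosen by
grid search to minimize the maximal in-band |log10| of the filtered,
renormalized target spectrum — a reproducible stand-in for manual tuning.

## Problem sizes

Tests and the acceptance script run at desk scale: a 120×160 screen
(30×40 stimulus pixels), typically 6 trials × (20 s + 5 s), 20-cell
populations for the adaptation experiment, 5 seeds × ~5.5 min of white
noise for parameter recovery, and 20 runs × 8 cells × (10 s × 4 trials)
for the null calibration; spectra use 30-pixel crops and ≤ 400 frames.
The production configuration (600×800 screen, 10–20 trials, minutes-long
trials) is expressible through the same `RunConfig`. STA convergence to
the full spatiotemporal filter at the default 15 Hz mean rate takes tens
of minutes of stimulus; the STA-recovery test uses a well-driven cell
(drive SD 3, 30 Hz) with 15 min of noise.

## Known limitations

- The DoG center/surround split is weakly identified when the generative
  surround is weak; the STA-informed initialization mitigates but cannot
  remove this, and recovered center sizes carry ~10% median error at desk
  scale.
- The naturalistic surrogate's windowed spectra deviate from an exact
  power law at the lowest and highest annuli; slope checks use the middle
  decade.
- `equalize_training_frames` leaves trimmed frames in memory (they are
  simply unreferenced), so the frame-coverage invariant applies to
  generator output, not trimmed views.
- Pipeline outputs are byte-reproducible for a given config hash and seed;
  the manifest's timestamps are excluded from that guarantee.
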