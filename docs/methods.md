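# Methods

This note documents the models behind `vocsketch`, the defaults that
matter, what the synthetic data do and do not emulate, and the numerical
choices a user should know about.

## Auditory spectrogram

The peripheral model (`auditory_model`) runs at 8 kHz and produces a
frames × channels matrix of non-negative values:

1. **Spectral analysis.** 32-ms Hann-windowed STFT, hopped every 8 ms
   (125 frames per second). Frame *t* covers samples `[t·hop, t·hop+win)`;
   frame count is `ceil(n/hop)`, so 1 s yields exactly 125 frames.
2. **Cochlear filterbank.** 128 channels with center frequencies
   `CF(k) = 90 · 2^(k/24)` Hz (24 per octave, constant Q). The top channel
   sits at ≈3526 Hz, its upper edge near 3629 Hz; a printed figure of
   3623 Hz for this configuration is within ~0.2% of the geometric
   progression and we implement the progression, not the printed digit.
   Each channel is a Gaussian weighting of spectral magnitude around its
   CF, row-normalized; channel bandwidth is constant-Q but floored at 3/4
   of an FFT bin, since below ~350 Hz the nominal constant-Q bandwidth is
   narrower than the 31-Hz spectral resolution of the 32-ms window.
3. **Lateral inhibition.** `L_k = max(Y_k − 0.5·Y_{k−1}, 0)` across
   adjacent channels. A full first-difference (coefficient 1.0) would
   cancel spectrally smooth (broadband) inputs almost entirely under these
   symmetric channel shapes and make the white-noise reference of the
   auditory distance degenerate, so the coefficient defaults to 0.5.
4. **Temporal integration.** First-order leaky integrator with a 128-ms
   time constant, sampled at the frame rate.

Every stage is positively homogeneous, so spectrogram values scale
linearly with input gain. With 128 channels every 8 ms the full
representation spends 16000 coefficients per second.

**Inversion** reverses the chain: the integrator is inverted exactly (it
is an invertible IIR), the inhibition recursion is unwound (exact off the
rectification floor), channel values are mapped back to non-negative
spectral magnitudes by ~30 multiplicative (Richardson–Lucy-style) updates
— the filterbank is nearly rank-deficient at the low end, so a
pseudo-inverse is numerically explosive — and a waveform is recovered by
Griffin–Lim magnitude projection from a seeded random-phase start
(default 50 iterations, early stop when the relative error improvement
drops below 1e-4). The iterate whose re-analysis is closest to the target
spectrogram is returned, which makes reconstruction error non-increasing
in the iteration budget by construction.

## Tonal / noise decomposition

`decompose` finds quasi-periodic content by STFT peak picking (46-ms Hann
window, 75% overlap): a peak must be a local maximum, within 50 dB of the
frame maximum, and at least 14 dB above the frame's median level — the
median-prominence gate is what keeps broadband noise from seeding tracks.
Peaks are linked frame-to-frame by nearest-frequency continuation (max
jump 50 Hz) and tracks shorter than 4 frames are dropped; only tracks
below 4 kHz count as tonal. Peak frequencies are refined by parabolic
interpolation in log magnitude (≲0.3% error for stationary tones).

The tonal waveform is resynthesized by inverting the STFT restricted to a
±2-bin mask around each track's trajectory; the noise component is the
time-domain residual, so **tonal + noise equals the input exactly**. This
masking construction replaces a per-partial oscillator bank: subtracting
oscillator-bank output requires phase-exact resynthesis and still leaves
residue proportional to the frequency estimation error, whereas the mask
removes the partial's actual energy. A consequence worth knowing: strongly
narrowband noise (bandwidth comparable to a few STFT bins) is partly
classified as tonal, which is the usual behavior of sinusoidal modeling.

Global defaults stand in for per-sound hand tuning; reproducing a specific
recorded corpus faithfully would require adjusting the tracking thresholds
per file.

## Sketches

`sketch` implements the four-step pipeline: separate; sparsify + invert
the tonal part; LPC-render the noise part; remix.

- **Maximum-picking** keeps the largest spectrogram cells within each
  non-overlapping 1-s block of frames, `round(budget × block duration)`
  cells per block (final partial block pro-rated), ties broken by lower
  time then lower channel index. Budgets at or above 16000/s return the
  input unchanged.
- **LPC noise model.** Frames of length hop/(1−overlap) (75% overlap →
  4×hop) are Hann-windowed; autocorrelation-method LPC (Toeplitz solve,
  zero-lag regularized by a relative 1e-9) fits the all-pole filter, which
  then shapes seeded unit white noise. Each synthesized frame is scaled so
  its windowed energy matches the input frame's exactly, frames are
  overlap-added with window-power (incoherent) normalization, and a final
  smooth per-hop gain pass pins each output frame's RMS to the input's —
  filtered-noise frames otherwise fluctuate a few tenths of a dB around
  the target. Silent frames consume their random draw so outputs are
  identical regardless of which frames are active.
- **Recombination.** The tonal path runs at 8 kHz (the model's rate); the
  noise path runs at the input rate to keep broadband character. The two
  sketched components are rescaled to the exact energies of the referent's
  tonal and noise components — preserving the referent's energy ratio by
  construction — and the mix is scaled to the referent's overall energy.

Quality presets (Q1/Q2/Q3) are fixed at 160/800/4000 tonal coefficients
per second with LPC order 7/16/36 at 44/20/9-ms hops; between adjacent
presets the hop grows by ≈√5 and the order shrinks by ≈√5, splitting the
fivefold budget reduction evenly between the two paths. The Q1 LPC preset
realizes 7/0.044 ≈ 159.1 coefficients/s; presets store the printed
parameter values and the bookkeeping reports the realized rate.

## Acoustic distances

The **auditory distance** time-stretches both sounds to a common 4.6 s
(phase vocoder: 1024-sample window at ≤16 kHz, 75% overlap, standard phase
propagation), computes auditory spectrograms, and takes the dynamic
time-warping cost with steps {(1,0),(0,1),(1,1)}, Euclidean local cost,
and no warping window. Costs are not normalized by path length — the
common-duration stretch already equalizes scale — but a config switch
(`path_normalize`) exposes the alternative. The unit is fixed by a seeded
reference pair (white noise vs 1-kHz tone, both 4.6 s), so distances are
comparable across runs.

The **feature distance** standardizes 13 features to zero mean and unit SD
over the stimulus set under analysis (referents + sketches + imitations
pooled) and takes the Euclidean norm. Features with zero variance over the
set are dropped with a warning. Implementation stand-ins, chosen so that
relative comparisons behave like the original closed-source descriptors:
loudness = frame RMS in dB; pitch and pitch strength from autocorrelation
with parabolic lag refinement (strength = normalized autocorrelation
peak; pitch statistics gated at strength > 0.2); "main spectral peak" =
frequency of the largest STFT bin per frame; "active" frames are within
40 dB of the loudest frame. The two-piece linear regression searches every
interior breakpoint exhaustively, fits each piece by independent OLS, and
reports the second-piece slope and joint R²; a constant series is defined
as a perfect fit (slopes 0, R² = 1).

## Signal detection

d′, ln β and upc are computed per 12-trial cell (6 target, 6 distractor)
on log-linear-corrected rates: H = (hits+0.5)/7, F = (fa+0.5)/7. Perfect
discrimination maps to d′ = 2·z(6.5/7) = 2.93. We report
ln β = (z(H)² − z(F)²)/2, the *negative* of the textbook likelihood-ratio
log-beta, so that liberal ("yes"-prone) responding is positive; note that
ln β is identically 0 whenever H = F, i.e. bias is invisible in β at zero
sensitivity. upc = 100·Φ(d′/2) follows from the no-bias assumption
F = 1 − H. Printed d′/upc pairs from grouped data generally do not satisfy
upc = Φ(d′/2) exactly when both were averaged before printing; the formula
is applied per cell here.

**Estimator bias.** The log-linear correction trades infinite estimates
for shrinkage: by exact binomial enumeration the per-cell estimator's
expectation at a true d′ of 2.0 (unbiased criterion, 6/6 trials) is 1.81,
and at 1.5 it is 1.40. Parameter-recovery checks therefore validate the
Monte-Carlo pipeline against this analytic expectation; recovery of the
*true* value within ±0.15 holds for true d′ up to ≈1.5 and fails by
design of the correction at 2.0. Averaging corrected per-cell estimates
can not undo this shrinkage; pooling counts across cells before computing
d′ would.

The four-way mixed ANOVA of grouped sensitivity data is out of scope; the
per-cell output table is tidy and feeds any standard ANOVA tool. The
planned best-imitator comparisons use a Bonferroni family-wise alpha of
.05/4, exposed as `BONFERRONI_ALPHA`.

## Synthetic data

The generators emulate the *structure* of a recorded corpus, not its
sound: morphological profiles are implemented as envelope/event recipes
(impulsive = one sharp burst ≤0.5 s with ~30-ms decay; repeated = ≥3
bursts whose attack/decay scale with the period so inter-burst gaps are
genuinely silent; stationary = steady hum or band noise with <20% level
variation; complex = ≥10 overlapping micro-events with a drifting
spectral center), with harmonic-complex carriers for tonal categories and
band-passed noise otherwise. Default durations are 0.5/2.0/2.0/2.5 s.

"Imitations" are explicitly not vocal-tract simulations: they re-impose
measured trajectories (temporal envelope, pitch contour, spectral center)
on a voice-like carrier (soft pulse train at the tracked pitch, or
time-varying band noise), with per-feature fidelity knobs in [0, 1] that
blend the trajectory toward its mean and add seeded jitter. Their purpose
is to dissociate overall acoustic distance from feature-specific fidelity.
Quantitative "imitation quality" has no canonical definition; the knobs
are this package's operationalization.

Simulated observers are equal-variance Gaussian: P(yes) = Φ(±d′/2 − c).
Passing tests on this material shows the *pipeline's* correctness —
budget accounting, estimator behavior, distance ordering — not that the
distances or sketches are perceptually valid for real recordings.

## Problem sizes and other choices

- The sketch-quality scaling study uses 12 synthetic referents (3 per
  profile, alternating tonality) × 3 qualities. The headline statistic is
  the correlation between log mean distance per quality and log budget;
  a pooled per-sketch correlation is also reported, and is expected to be
  much weaker because between-referent distance scales differ by orders
  of magnitude. Per-referent monotonicity is tracked as the fraction of
  adjacent quality steps where distance fails to decrease (tolerated at
  5%; 24 ordered comparisons make that tolerance meaningful).
- The agreement between the two distance models is measured over all 28
  pairwise distances among an 8-sound corpus (one target and one
  distractor category per profile): pooling pairs that span the full
  similarity range is what makes the correlation informative —
  sketch-to-referent distances alone are dominated by between-referent
  scale differences and correlate near zero.
- Observer recovery uses 4–8 simulated participants × 56 cells per true
  d′ value.
- ISTFT overlap-add floors the window-power normalizer at 1% of its
  interior value; without the floor, resynthesis of *modified* spectra
  (masking, magnitude substitution) amplifies the first/last few
  milliseconds without bound. Exact STFT round-trips therefore hold in
  the interior only; contracts that need exactness (decomposition
  additivity) are built in the time domain.
- All stochastic stages take explicit integer seeds and are bit-exact
  reproducible; max-picking ties and track ordering are deterministic.

## Known limitations

- Level equalization is RMS-based (dBFS target), not phon-accurate
  loudness; playback calibration is out of scope.
- The peripheral model is a fixed linear-ish approximation of cochlear
  processing; no cortical (rate-scale) stage, and hair-cell nonlinearity
  constants are frozen package defaults.
- Narrowband noise is partly absorbed into the tonal path (inherent to
  sinusoidal modeling with global thresholds).
- The feature extractors are self-contained equivalents, not bit-exact
  reimplementations, of the proprietary descriptor toolchains they stand
  in for.
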