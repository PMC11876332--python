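# Methods

This note documents the models, parameter choices and numerical
conventions behind `acoustemp`, and what the synthetic experiments do and
do not demonstrate.

## The synthetic recording generator

`acoustemp.synth` emulates a manual needle insertion into a
water-saturated open-cell foam held in a cooling water bath, recorded at
48 kHz by a microphone on the needle hub.

**Phase structure.** Each recording is: a 0.5 s pre-roll of background
noise; a louder broadband initiation pulse (50 ms, 4× the event
amplitude); a quiet approach (1.5 s); forward motion through the foam
(annotated [L1, L2]); a dwell (1 s, [L2, L3]); retraction ([L3, L4]); and
a 0.5 s tail. The forward-motion duration is `10·thickness_cm /
speed_mm_s` seconds.

**Events.** A bubble crossing is modelled as a percussive click: an
exponentially damped sinusoid with random phase and ±20% amplitude
jitter. The decay constant defaults to 1 ms — a millisecond-scale
transient is the physical picture of a thin bubble wall rupturing, and it
makes each event register as exactly one envelope maximum, which is what
lets the peaks-per-cm calibration match the bubble density. Events are
placed at quasi-regular positions along the travel path (uniform spacing
with ±20% jitter, mirroring the visually regular foam cell structure), so
the forward-motion event count is exactly `round(density × thickness)`
and is invariant to insertion speed. Retraction crosses the same bubbles
in reverse at the retraction speed.

**Temperature effect.** The generative temperature dependence is a
linear shift of the event centre frequency,
`f(T) = 4000 Hz + 50 Hz/°C · (T − 37.5 °C)`, with an optional linear
effect on the decay constant (zero by default). The real physical
mechanism is not established; this form was chosen as the simplest
controllable effect that makes the event spectrum strictly monotone in
temperature, which is the property the regression stage must recover.
The slope of 50 Hz/°C spreads the 20–55 °C range over 1.75 kHz — several
mel bins per 5 °C group at the 256-bin resolution, a clearly learnable
but not trivial signal at the configured SNR.

**Noise and amplitudes.** White Gaussian noise with σ = 0.01; event peak
amplitude 0.08 (8× the noise σ), so genuine events sit far in the upper
tail of the envelope-maxima distribution and the μ + σ threshold
separates them cleanly.

**Dataset assembly.** Eight temperature groups (20–55 °C in 5 °C steps),
22 recordings per group by default (176 total). The measured temperature
of a recording is the group value minus a cool-down offset drawn
uniformly in [0, b(group)], where the bound b scales from 20% of the
1.4 °C cap for the coldest group to the full cap for the hottest — the
bath cools faster when hot. Per-recording forward speeds are uniform in
[5, 10] mm/s; the total L1→L4 motion time is drawn uniformly in
[7, 12] s and the retraction speed is derived from it, which guarantees
the annotated motion span always lies in the configured range (a fixed
retraction speed cannot achieve this across the whole speed range).
Seeding uses `numpy.random.SeedSequence` spawning, so regeneration under
a fixed seed is byte-identical, including written WAV files.

**What the generator does not emulate.** Real needle–foam friction is
broadband and nonstationary; real events vary in morphology and overlap;
room noise, handling noise and the water bath are absent; the real
temperature signature is unknown and almost certainly not a pure
frequency shift. Passing the synthetic recovery experiment therefore
demonstrates that the *pipeline* (detection → segmentation → features →
grouped training) can extract a temperature-dependent spectral signature
when one exists; it says nothing about the size of the real effect.

## Peak detection

The envelope is the rectified waveform convolved four times with a
20-point uniform kernel. Each pass is a zero-padded, length-preserving
("same") convolution; with an even kernel the window extends `taps/2`
samples into the past and `taps/2 − 1` into the future, keeping detected
peak times aligned with the annotations. Candidates are all interior
local maxima; on a flat plateau the first sample counts. μ and σ are
computed per recording over all candidate amplitudes; σ is the population
standard deviation by default (`ddof` exposed), and the retained set is
`amplitude ≥ θ = μ + σ`. With zero candidates the detector returns an
empty result with μ = σ = θ = 0 rather than failing. Peaks are detected
over the full recording; downstream dataset construction windows them to
the forward motion [L1, L2].

The peaks-per-cm rate divides the retained-peak count in a time window by
the travel distance `speed · Δt / 10` cm. On simulated insertions into
the two reference foams (20 and 9 bubbles/cm) the detector recovers the
bubble density within a few percent, averaged over 20 seeds, and the rate
is insensitive to speed within 5–10 mm/s.

## Segmentation and features

Chunks are 100 ms (4,800 samples at 48 kHz). Sliding chunks hop 75 ms
(25% overlap) starting at L1, discarding a final partial window.
Peak-centred chunks place the peak at `W/2 + d` with `d` a uniform
*integer* in [−W/4, +W/4]; chunks that would cross the recording
boundary are discarded with a warning rather than shifted, because
shifting would distort the uniform offset distribution.

Mel spectrograms use a centred magnitude STFT (Hann window, FFT 2048,
hop 512, reflect padding; `1 + N//hop` frames) projected onto a 256-filter
Slaney-style mel bank (linear below 1 kHz, logarithmic above, triangular
filters with 2/(f_hi − f_lo) area normalisation) spanning 1 Hz–20 kHz,
then converted to dB relative to the chunk maximum and floored at −80 dB.
At this resolution many low-frequency filters are narrower than one FFT
bin and can be identically zero; the dB floor absorbs them. The per-chunk
dB reference makes features exactly gain-invariant, which complements the
gain augmentation. An all-zero chunk maps to a spectrogram identically at
the floor.

## Augmentation

Waveform-domain, applied before feature extraction in the fixed order
time-stretch → pitch-shift → gain, then centre-crop/zero-pad back to the
chunk length. Time stretch is a standard phase vocoder (per-bin phase
accumulation at FFT 2048 / hop 512); pitch shift combines a vocoder
stretch with linear-interpolation resampling and is parameterised in
semitones over [−3, +3]; gain is uniform in [−5, +5] dB; the stretch
factor is uniform in [0.9, 1.1]. Zero-width ranges pinned at the identity
disable a transform exactly, so an identity specification returns the
input bit-for-bit. Labels and lengths are never modified.

In the synthetic recovery experiment augmentation is disabled: the
injected temperature signature *is* a spectral position, so a ±3-semitone
pitch shift (±700 Hz at 4 kHz) would overwrite a 50 Hz/°C effect, and
gain augmentation is a no-op under the per-chunk-maximum dB reference.
On real data, where the temperature signature is presumably not a pure
pitch effect, augmentation guards against overfitting; its contracts are
tested separately.

## Regression model and training

The default backbone is the standard 18-layer residual network (7×7/2
stem, four stages of two basic blocks, global average pooling) with the
classification head replaced by a single linear output; spectrograms are
replicated to three channels and bilinearly resized to 224×224 for it.
Pretrained weights are not shipped; when requested, the model falls back
to random (He) initialisation and records that in the run log and on
`model.pretrained_loaded`. A small 3-block CNN (8/16/32 channels,
flatten, 64-unit hidden layer, 1 output; ≈ 140k parameters) operates on
native 256×10 spectrograms and is the workhorse for desk-scale
experiments — it flattens instead of globally pooling because the
temperature signature lives in *where* the energy sits on the mel axis.

All layers, AdamW (decoupled weight decay 0.01, skipped for biases and
norm parameters) and the cosine schedule
`lr(e) = lr_final + (lr_init − lr_final)(1 + cos(πe/E))/2` are
implemented on numpy with manual backpropagation; gradients are checked
against central finite differences in the test suite.

Cross-validation is fivefold grouped by recording: recordings are
shuffled, ordered by descending chunk count, and greedily assigned to the
currently smallest fold, which balances fold sizes well within ±20% while
keeping recording sets disjoint. Inside the loop, labels are standardised
with train-fold statistics and predictions mapped back to °C; all
reported MSE/RMSE values are on the Celsius scale. Each epoch evaluates
the held-out fold; the per-fold "best RMSE" is the minimum over epochs,
and both the best fold and the mean ± sd across folds are reported, since
either reading of "best" may be wanted. Held-out predictions are captured
at each fold's best epoch.

The desk-scale recovery experiment (8 groups × 4 recordings, ≈ 640
peak-centred chunks, small CNN, 10 epochs, 5 folds) reaches a mean best
held-out RMSE of ≈ 2.5 °C against a label standard deviation of ≈ 11 °C,
comfortably beating the factor-of-two bar the experiment sets; it runs in
about two minutes on one CPU. Problem sizes in the tests were chosen as
the smallest that make the statistical assertions stable.

## Evaluation conventions

RMSE is chunk-level by default (recording-level aggregation — the mean
over forward-motion chunks — is also provided; a recording with no
qualifying chunks yields an undefined marker, not a number). The group
table reports, per temperature group, the measured min/max/mean/sd, the
predicted mean, and the absolute delta between the two means, plus
max/min/mean of the deltas across groups. Quantiles for violin data use
linear interpolation between order statistics. Prediction traces flag
each peak as inside or outside [L1, L2]; out-of-motion points (the
initiation pulse) stay visible in the trace but are excluded from
aggregates.

## Numerical and degenerate-input conventions

- Envelope convolution slices the full convolution explicitly, so length
  is preserved even when the kernel is longer than the signal.
- PCM16 WAV writing scales by 32768 with clipping, matching the read
  divisor, so int16-representable data round-trips sample-exactly.
- `detect_peaks` requires a non-negative envelope and at least 3 samples;
  a monotone ramp yields an empty result.
- Fold assignment, dataset generation and training derive all randomness
  from spawned `SeedSequence` children of one seed.
- File formats carry a `format_version`; loaders reject unknown major
  versions.

## Known limitations

- The real-data headline metrics require the deposited corpus and a
  full-scale (70-epoch × 5-fold, 18-layer) training run; the packaged
  experiments validate the pipeline on synthetic data only.
- No pretrained backbone weights are available offline, so the 18-layer
  network trains from scratch when used.
- The phase vocoder and linear-interpolation resampler are adequate for
  augmentation but are not transcription-quality DSP.
- The generator's temperature effect is an idealisation; transfer of the
  recovery result to real tissue audio is an open experimental question.
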