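# Methods

## The paradigm and its timing model

The workbench models a copy-mode single-marker oddball session. A *trial*
is one random pass over all `n_markers` (default 12) markers; each flash
occupies `flash_duration` (0.125 s) followed by an interstimulus interval
drawn i.i.d. uniformly from `isi_values` ({0.12, 0.14, 0.16, 0.18, 0.20,
0.22} s; the engine being emulated promises only "pseudorandom" ISIs, so
i.i.d. uniform is the least-structured choice). Trials within a repetition
are separated by the 0.5 s intertrial interval; a *repetition* is the 10
trials scored to make one selection and is preceded by a 5 s target cue
(five blinks at 1 Hz). Blocks of k = {3, 5, 6, 6} repetitions are framed by
5 s start/end cues and 20 s baselines, with 5 s between consecutive
repetitions of a block (k − 1 intervals per block — none after the last).

Two accounting choices matter for the session-duration figure: inter-block
rest (a questionnaire pause of 30–60 s) is *not* part of the schedule, and
the pre-session idle state has zero length. Under these conventions the
expected session length is analytic —
4·2·(5 + 20) + 20·(5 + 39.9) + (2+4+5+5)·5 = 1178 s = 19.63 min — and
seeded simulation concurs (19.64 ± 0.03 min over 50 seeds), matching the
published 19.7 ± 0.3 min for this protocol. The per-selection time is
`n_markers · l · (flash_duration + mean ISI) + (l − 1) · ITI`, i.e. 39.9 s
("40 s") at l = 10.

The no-repeat constraint is enforced across trial and repetition
boundaries *within* a block and resets at block starts (whether the
original engine constrained across blocks is unknowable; a block boundary
contains minutes of cues and baseline, so the choice is inconsequential).
Trials are drawn by rejection: permutations are resampled until the first
element differs from the previous block-stream marker, which keeps the law
uniform over admissible permutations.

## Synthetic EEG

Each channel's background is Gaussian 1/f^α noise (α = 1 by default),
generated by spectral shaping and scaled to `noise_scale` µV RMS. Target
flashes add a two-component Gaussian-pulse template — N200-like
(200 ms, −2.5 µV, σ 25 ms) and P300-like (310 ms, +5 µV, σ 45 ms) —
weighted per channel by a centro-parietal gain profile peaking at Pz and
shifted as a whole by a per-event Gaussian latency jitter (σ 20 ms).
Nontarget flashes add nothing by default. An optional common-mode mains
sinusoid can be enabled to exercise the analysis band.

Because every epoch is later z-scored, absolute microvolt values are
conventions; only the ERP-to-background ratio is meaningful. The default
`noise_scale` = 14 µV was calibrated once, by pilot simulation across
12–35 µV, to the level at which a default subject reproduces the
qualitative regime this paradigm is reported to occupy: single-trial
sensitivity near 1/3 rising to ~1.0 when all ten trials are accumulated.
Below ~12 µV the task saturates from two trials; above ~25 µV accumulation
no longer reaches high sensitivity.

What the generator does *not* emulate: eye-blink/EMG artifacts, channel
covariance (channels are independent), inter-subject morphology
differences, habituation or vigilance drift, and steady-state visual
responses (flash-locked periodicity is suppressed by the jittered ISI in
the real paradigm; an optional periodic artifact can be added to
demonstrate this). Tests passing on this generator therefore certify the
pipeline's mechanics and statistical behavior under idealized P300-like
signals, not performance on real recordings.

One consequence of real paradigm timing is reproduced faithfully: with
~0.3 s between flashes and 600 ms epochs, neighboring templates leak into
each epoch. Even with zero background noise, the epoch of the flash that
follows a target contains that target's P300 tail, so single-trial (l = 1)
selection is not guaranteed perfect in the noise-free limit; the noise-free
separability check in the tests uses non-overlapping flash spacing.

## Preprocessing and featurization

The bandpass is exactly the stated design — 41 symmetric taps, 1.5–10 Hz,
Chebyshev window (sidelobe attenuation unspecified in the source protocol;
60 dB chosen) — applied causally with explicit 20-sample group-delay
compensation rather than forward–backward, so the stated order keeps its
meaning. A 41-tap filter at 512 Hz cannot be sharp at 1.5 Hz; the measured
response (documented by the tests) is gentle at the low edge, and no
attempt is made to "improve" it.

Epochs span [0, 600) ms from flash onset — 307 samples at 512 Hz, no
pre-stimulus baseline — and are detrended and z-scored per channel.
Featurization concatenates the eight channels channel-major and keeps
every second element of the concatenated vector (indices 0, 2, 4, …),
giving d = ⌈8·307/2⌉ = 1228. The alternative reading — decimating each
channel separately — would give 8·154 = 1232 and is therefore wrong for
this paradigm's printed dimensionality; because 307 is odd, the
concatenated rule takes the even-indexed samples of odd channels and the
odd-indexed samples of even channels. Decimation is plain subsampling: the
signal is already band-limited to 10 Hz, less than a tenth of Nyquist.

## ERP statistics

Coherent averages pool all epochs and all eight channels into one
307-sample waveform per condition. The P300 is read off as the highest
amplitude inside 150–450 ms (sample indices 77–230; ties to the earlier
latency). Target/nontarget window differences use a two-sided
Mann–Whitney U over the pooled per-sample amplitudes of the two averages,
Bonferroni-corrected across the subjects of a run (the correction method
was unspecified; both raw and corrected p are reported). Group-level peak
magnitudes are compared with a two-sided paired Wilcoxon signed-rank test;
on the default 20-subject synthetic study every target peak exceeds its
nontarget pair, giving W = 0, p < 0.001.

Two statistical caveats are deliberate reproductions, not defects:

1. *Pooled window samples are not exchangeable.* Band-limited averages are
   smooth, so the ~154 window samples carry far fewer effective degrees of
   freedom than the rank test assumes. The type-I control test therefore
   uses spectrally white null noise, where exchangeability holds (measured
   rate 0/500 at α = 0.005); under pink noise the nominal level should not
   be taken literally.
2. *Per-epoch standardization caps the test's power.* Detrending and
   z-scoring pull every average toward zero mean over the epoch, so inside
   any window the positive P300 region is rank-offset by negative flanks;
   the pooled MWUT's effective AUC stays near 0.55 even for clean
   templates, and its rejection rate at α = 0.005 on default synthetic
   subjects is ~10%, far below what the procedure achieves on real data
   reported for this paradigm. The tests assert the attainable property
   (systematic rejection above the nominal rate, and decisive rejection
   under a window-wide shift); the weakness is a property of the procedure
   itself.

## Classifier

The discriminant is a squared-loss regression of ±1 labels with an L1
penalty, fitted by LARS. Cross-validation computes the full LARS-lasso
path per fold (path length capped at 300 steps) and evaluates it on a
50-point logarithmic λ grid spanning the all-zero solution down to 10⁻⁴ of
it — the coefficient path is piecewise linear in λ, so grid evaluation by
linear interpolation is exact. Folds are contiguous and unshuffled
(deterministic fits), squared error is the selection criterion, ties go to
the stronger penalty, and no class re-balancing is applied (training data
are ~1:11 target:nontarget by construction). The final model is refitted
at the chosen λ on all training rows.

Scoring uses s(x) = wᵀx without the bias: within a trial the bias shifts
all twelve marker scores equally, so the accumulated-score argmax is
invariant to it (property-tested). Argmax ties break to the lowest marker
index. The training/evaluation split excludes the first (operator
training) block and holds out the last nine analysis repetitions,
training on the remaining eight; with blocks of 3/5/6/6 this trains on
block II plus the first half of block III.

On the default study the CV-selected models keep ~30–50 of 1228 features.
A sparse selector cannot correlate highly with a dense generative
template (pooled-window Pearson r has median ≈ 0.25); on the selected
support the alignment is strong (median r ≈ 0.78). Both levels are
asserted by the tests.

## Evaluation

Each evaluation repetition contributes one selection; a correct selection
credits the target and all 11 nontargets, a wrong one costs exactly one
target and one nontarget, giving the structural identity
k = n_reps·(n_markers − 1) − (n_reps − j) and, for the default 9×12
geometry, accuracy = (90 + 2j)/108. Metrics are kept at full precision
internally and rounded to two decimals only in reports. Across-subject
aggregation uses medians and linear-interpolation quartiles. AUROC is
computed per accumulated-trial count l on the accumulated marker scores
pooled over evaluation repetitions (marker = target as positive class) and
summarized as mean ± SD over l = 1…10.

## Study conditions and problem sizes

The reference simulated study runs 20 subjects through the full default
session (20 repetitions, 2400 flashes, ~19.6 min of signal at 512 Hz);
per-subject seeds are spawned from one base seed (default 20180214), and
every stochastic operation takes an explicit generator. The timing
acceptance computation averages 50 seeded sessions. The statistical
calibration suites use 500 null subjects (type-I) and the 20-subject study
(power, recovery, sensitivity curves).

## File formats

Events are TSV (onset_s, duration_s, marker_id, event_type, block,
repetition, trial, is_target; −1 marks inapplicable indices). Recordings
round-trip either losslessly as raw little-endian float64 with a JSON
sidecar, or as 16-bit EDF (one-second records, physical units µV,
symmetric per-channel physical range; worst-case quantization error is one
step). The EDF writer and reader are a minimal implementation of the
16-bit continuous subset of the format; the test suite cross-checks the
reader against MNE. Models persist as JSON with the weight vector stored
sparsely; run configs are YAML with an exact round-trip and a SHA-256
provenance hash that changes iff any field changes.

## Known limitations

- The generator's channels are independent; spatial filtering methods
  would look artificially favorable on it.
- The pooled-sample MWUT is reproduced as specified; see the ERP caveats
  above before interpreting its p-values on band-limited data.
- The EDF writer targets this package's recordings (identical sampling
  rate across channels, integer Hz); it is not a general EDF library.
- Free-mode (non-copy) operation, online retraining, and alternative
  classifiers beyond the pluggable linear-scorer interface are out of
  scope.
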