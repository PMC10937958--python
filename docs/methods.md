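# Methods

`lfpstate` implements a multi-structure local-field-potential (LFP)
brain-state analysis of the kind used to characterize psychotomimetic
(NMDA-antagonist) challenges and antipsychotic treatment effects in rodent
models, together with a synthetic-data generator that provides ground truth
for every estimator.  This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic harness does and does
not demonstrate.

## Signal model and preprocessing

Recordings are continuous multichannel voltage (channels x time, uV) at
2 kHz, with channels mapped to anatomical structures (default vocabulary:
amyg, dStr, OC, OFC, PC, mPFC, M1, S1, thal, vHipp, vStr) and hemispheres
(lesioned/intact).  Analysis operates on **bipolar derivations**: the
difference of two electrodes within the same structure, which cancels
volume-conducted far-field signals.  The default pairing sorts channels by
id within a (structure, hemisphere) group and pairs consecutive ones, each
channel used at most once; an all-combinations mode exists for
electrode-level coupling analyses.  The choice is a convention — nothing
downstream depends on which particular within-structure pairs are
differenced, only that both members share a structure.

Condition epochs are half-open `[start, end)` intervals in seconds from
recording start, sliced sample-accurately (floor of `start*fs` /
`end*fs`).  Rational-ratio polyphase resampling (anti-aliased) brings
higher-rate acquisitions to 2 kHz.

## Spectral decomposition

Power spectra use 50%-overlapping 8-s Hanning windows over 0-300 Hz.  An
8-s window natively yields 0.125 Hz spacing; four native bins are
mean-pooled per output bin, centered on multiples of 0.5 Hz, giving the
declared 0.5 Hz grid while keeping the 8-s window.

The arrhythmic (fractal, `~1/f^alpha`) component is separated by
**irregular resampling (IRASA)**: for each factor `h` in
{1.10, 1.15, ..., 1.90} the segment is resampled by `h` and `1/h`
(polyphase, first/last second trimmed against filter edge effects) and the
resampled series is treated as if still sampled at the original rate.  A
power law is invariant under this operation while narrowband rhythms are
displaced in frequency, so the median over `h` of
`sqrt(S_up(f) * S_down(f))` estimates the fractal spectrum.  The rhythmic
measure is

    oscillatory_db(f) = 10 * log10( total(f) / fractal(f) )    [dB_fractal]

which is 0 dB wherever the signal is purely arrhythmic.  On synthetic
`1/f^2` input the decomposition is unbiased to within ~0.1 dB over
5-250 Hz.  IRASA is computed per analysis block (default 60 s,
configurable) rather than per 8-s window: the `1/h` downsampling of an 8-s
window would leave less than one full Welch window, whereas a 60-s block
keeps the 8-s Welch geometry intact after resampling.  Blocks are the
temporal unit of everything downstream.

## Oscillation detection

Fractal-normalized spectra, averaged across the electrode pairs of a
structure and across the 8-s windows of a block, are fitted with a
Gaussian peak on a linear background:

    y(f) = A exp(-((f - B)/C)^2) + D f + E

`A` is peak height (dB_fractal), `B` peak frequency (Hz), `C` width (Hz),
`D`/`E` the background slope and offset.  Fitting is bounded nonlinear
least squares from a deterministic 3x3 multi-start grid (B at three points
inside the admissible band, C in {3, 8, 15} Hz), tie-broken by lowest
residual then lowest B; the linear start comes from a polynomial fit.  R2
is computed on the fitted range against the mean-only model.  A block is a
**positive detection** iff all thresholds hold as strict inequalities:
R2 > 0.2, 2 < A < 100, B inside the band (115-170 Hz HFO, 30-70 Hz gamma),
1 < C < 20, -1 < D < 1, -10 < E < 10.  Fit ranges pad the admissible band
by ~15 Hz (HFO fitted over 100-185 Hz, gamma over 20-85 Hz) so the linear
background is identifiable.  One Gaussian per band per block; no multi-peak
fitting.  Note the field describes gamma as ~30-90 Hz while the detector
bound is 30-70 Hz; the detector follows the printed bound.

Session summaries per (structure, hemisphere, condition):

- **detection rate** — percent of blocks with a positive detection;
- **peak frequency** — median of B across detected blocks (undefined when
  nothing was detected, reported as missing);
- **band power** — mean oscillatory_db over a 20 Hz band centered on the
  session peak frequency (41 inclusive bins at 0.5 Hz).

## Phase coupling (kappa)

HFO phase relations are quantified only where oscillations exist: phase
samples are gated to blocks where the detector fired in *both* structures
of a pair.  Each bipolar trace is band-passed (4th-order Butterworth,
zero-phase `sosfiltfilt`) at the session peak frequency +-10 Hz — the same
20 Hz band used for band power — and the analytic-signal angle gives
instantaneous phase.  Pairwise phase differences are decimated to one
sample per oscillation cycle (`fs/center_f`) to reduce serial dependence,
then summarized by a fitted circular normal (von Mises) distribution:
mean direction mu and concentration kappa (`sigma^2 = 1/kappa`).  Kappa is
inverted from the mean resultant length R by Fisher's piecewise
approximation (three regimes at R = 0.53 and 0.85), capped at 500 to keep
degenerate all-identical samples finite; estimates need n >= 10.
Treatment effects are reported as delta-kappa matrices over structure
pairs (condition minus reference), with missing cells propagated as
missing.  Kappa is estimated on samples pooled per structure pair
(per-electrode-pair estimation is available through the all-pairs bipolar
mode).

## Permutation entropy

Temporal complexity per channel uses ordinal patterns of order m = 6 with
no embedding delay: each window of 6 consecutive samples maps to the
Lehmer index of its rank permutation (ties broken by first occurrence —
irrelevant for continuous signals, deterministic for integer fixtures).
PE of a 30,000-sample window (15 s at 2 kHz) is `-sum p ln p` over the
720-pattern distribution, reported both raw (nats) and normalized by
ln(720).  Windows slide at a 2,000-sample (1 s) hop by default — the hop is
a smoothness/cost trade-off, and window means are insensitive to it on
stationary input — and never straddle condition boundaries; per-channel
means per condition are the representative values.  At 2 kHz a 6-sample
pattern spans 3 ms, well below an HFO period (~7 ms), so PE probes
dynamics on a finer timescale than the oscillations themselves.

## Brain-state similarity

A condition's global state is the concatenation of per-structure
time-averaged oscillatory_db spectra over 1-300 Hz (599 bins each) in a
declared, recorded structure order; comparing vectors with different
orders is an error, not a silent misalignment.  Per-structure spectra are
averaged across electrode pairs before concatenation (a per-electrode mode
can be built from the all-pairs bipolar set).  States are compared by
Pearson correlation; treatments are located by per-animal coefficients
against the baseline and vehicle states, summarized as medians with
quartiles, tested with Wilcoxon rank-sum between treatments, and pairwise
reference-vs-others comparisons use Kruskal-Wallis.  Tests are suppressed
(descriptives only) below 3 animals per group, and degenerate
all-identical comparisons are not tested.

## Statistics

Observations nest as channels within sessions within animals, so
condition comparisons use a **hierarchical permutation test**: condition
labels are permuted at the session level within each animal (the
exchangeable unit), and the statistic is the difference of animal-level
means, where an animal's per-condition value is the mean of its session
means.  `p = (1 + #{|T*| >= |T|}) / (1 + n_perm)`, guaranteeing validity
at finite permutation counts.  This is a deliberate distribution-free
replacement for a nested ANOVA / GLMM-with-Dunnett analysis: it honors the
same nesting without mandating a mixed-model engine, at the cost of not
producing variance components or simultaneous intervals; externally fitted
mixed-model results can be compared against it.  A rank-based mode makes
the test invariant to monotone transforms.  When a test repeats across
the 11 structures, Benjamini-Hochberg FDR-adjusted maps are emitted next
to the raw ones.

## Synthetic-data generator

The generator is phenomenological, not biophysical: it reproduces the
statistical features the analysis measures, with ground truth recorded in
a ledger.

- **Arrhythmic background**: Gaussian noise shaped in the Fourier domain
  with `|H(f)| = f^(-alpha/2)` (exact target exponent, O(n log n)),
  rescaled to a configured RMS (default 50 uV).  The per-condition
  exponent doubles as the entropy regime: steeper spectra are smoother
  and carry lower permutation entropy, emulating the reduced temporal
  complexity of the psychotomimetic state.
- **Oscillatory episodes**: a complex Gaussian envelope low-passed to the
  band width, mixed to the (per-episode, optionally jittered) center
  frequency — episode timing and carrier are shared across structures,
  emulating globally co-occurring HFOs that share a frequency.  Each
  structure carries a configurable phase lag; with finite kappa a von
  Mises deviation is drawn per episode and structure, so the episode-level
  lag distribution has exactly the configured concentration.  Episode
  edges get 0.1-s cosine ramps.
- **Amplitude calibration**: strength is specified in dB_fractal at the
  band center.  Within a structure, consecutive channels carry the
  oscillation with gains +1/2 and -1/2, so the bipolar pair difference
  carries it at unit gain and exact phase; the per-structure gain is set
  so the oscillation PSD equals `ref * (10^(A/10) - 1)`, with `ref` the
  measured bipolar background PSD of that structure at the center
  frequency.  The injected amplitude then equals the measured dB_fractal
  value at the band center within about +-0.3 dB (the +-1 dB contract is
  tested).
- **Episode schedules** are Poisson (rate in episodes/min, durations
  uniform in a configurable range, default 10-60 s — real HFO episode
  durations are not well constrained, so this is an explicit free choice);
  explicit schedules override.
- **Pose tracks**: a centroid that is stationary between scheduled bouts
  and moves at the scheduled speed during them, with optional constant
  turning (heading integrates `turn_rate_deg_s`), body parts offset along
  the heading, and per-part Gaussian jitter emulating tracking noise.

What the generator does **not** emulate: non-stationary fractal slopes,
movement and chewing artifacts, electrode drift and impedance changes,
cross-frequency coupling, volume-conducted rhythmic sources, and realistic
spatial covariance beyond the shared-oscillation structure.  Passing the
synthetic contracts therefore demonstrates estimator correctness under the
assumed signal model, not robustness to real-recording pathologies.

## Demo experiment and problem sizes

The bundled demo (`lfpstate run`, `pipeline.demo_config`) uses 3 animals x
2 sessions x 3 conditions (baseline / vehicle / treatment), three lesioned-
hemisphere structures (mPFC, vStr, OFC) with 2 channels each, 120-s
epochs, and 60-s analysis blocks.  The vehicle condition carries a 6 dB,
145 Hz HFO with kappa = 16 phase locking (mPFC leading vStr by pi/8) over
a steep (alpha 2.3) background; treatment halves the contrast (3 dB,
kappa = 2, alpha 1.8); baseline has no oscillation and the flattest
background (alpha 1.3).  These sizes keep a full run to a couple of
minutes on one CPU while leaving every direction contrast (detection rate,
kappa, entropy, state similarity, bout rate) clearly resolvable; they are
deliberately far smaller than a real chronic-recording study, so absolute
effect sizes are not comparable to in-vivo values — only directions and
estimator contracts are.

## Numerical conventions and degenerate inputs

- Frequency grid 0-300 Hz at 0.5 Hz; band-power bins inclusive of both
  endpoints; epochs and blocks half-open.
- Detection thresholds are strict inequalities exactly as printed
  (A = 2.0 is a non-detection).
- Peak-fit failures return a non-detection with NaN parameters rather
  than raising.
- Zero-variance state vectors, all-constant entropy windows, empty phase
  overlaps, and undersized circular samples are reported as
  undefined/missing with a reason — never silently coerced to 0.
- Bout minimum duration 0.5 s at 25 fps rounds up to 13 frames; speed is
  median-filtered over 5 frames before thresholding (raw mode available);
  heading for turning uses displacement direction with frames slower than
  1 cm/s excluded.
- All randomness flows through `numpy.random.Generator` seeds; sessions,
  pipeline runs, and permutation tests are bitwise reproducible.
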