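# Methods

## The problem this package addresses

When listeners hear isochronous speech in which monosyllabic words appear
at a fixed rate and higher-order linguistic units (two-word phrases,
four-word sentences) are built from them, EEG shows spectral peaks not only
at the acoustic (syllabic) rate but — for listeners who understand the
language — also at the abstract phrasal and sentential rates.  The strength
of that "cortical tracking" can then be related, across subjects, to an
independent electrophysiological index of comprehension: the N400, the
negative ERP deflection ~300–500 ms after a semantically incongruent word.

`cortrack` implements that complete analysis chain — frequency-tagging
spectra with a neighbor-bin baseline and a one-tailed peak test, the
N400 window and point-wise contrasts with FDR control, and the rank
correlations linking the two — together with a synthetic EEG generator that
provides ground truth for every stage, so the pipeline's statistical
behaviour can be verified without any recorded data.

## Paradigm arithmetic

With syllable duration `d = 0.320 s` and `w = 4` words per sentence, the
sentence lasts `d·w = 1.28 s`; the tagged rates are

    f_sent = 1/1.28 = 0.78125 Hz,  f_phrase = 2·f_sent = 1.5625 Hz,
    f_syll = 4·f_sent = 3.125 Hz,

printed as 0.78 / 1.56 / 3.12 Hz (half-to-even rounding at two decimals —
the rounding rule that matches all three displayed values).  A trial holds
12 sentences; the first is dropped from analysis to avoid the auditory
onset transient, so the epoch is `11 × 1.28 = 14.08 s` and the spectral
resolution `1/14.08 ≈ 0.071 Hz`.  Durations are carried as exact rationals
(`fractions.Fraction`) so each tagged rate lands on an integer DFT bin by
construction (bins 11 / 22 / 44); `bin_index` raises `MisalignedFrequency`
beyond a 1e-6-cycle tolerance.

## Synthetic cohorts

**Oscillatory response.**  Within each trial, channel *c* carries
`Σ_k A_k · g_osc(c) · sin(2π f_k t + φ_k)` over the three tagged rates,
with per-subject amplitudes `A_k` (µV) and uniform random phases; `g_osc`
is a smooth fronto-central gain map in [0, 1] on a schematic 64-channel
10-10 layout (62 scalp channels + 2 zero-gain mastoids).  Modeling the
response as phase-locked sinusoids at exactly the tagged rates (rather
than per-syllable transients) gives analytically known ground truth at the
only bins the analysis interrogates.

**Background noise.**  Gaussian 1/f ("pink") noise, synthesized in the
frequency domain with power ∝ 1/f, independent across channels, calibrated
to a per-subject RMS `noise_scale` (default ~10 µV).  Averaging n
independent Gaussian noise processes equals one process scaled by 1/√n in
distribution; the large Monte-Carlo experiments use this identity
(`evoked_noise`) to draw trial averages directly.

**N400.**  Each critical-word marker adds a Gaussian-windowed deflection
(SD 80 ms) centered at the subject's latency (defaults: native group
400 ms, second-language group 450 ms), projected through a centro-parietal
gain map.  Both conditions share a base deflection; the incongruent
increment is calibrated — including the discrete template/window overlap
and the ROI-mean gain — so that the incongruent-minus-congruent ROI mean
over 300–700 ms equals the subject's `n400_effect` (negative = canonical
N400) in the noise-free limit.  A noise-free subject recovers the injected
effect to well within 2%.

**Coupling.**  A Gaussian copula (latent Pearson `r = 2 sin(π ρ_s / 6)`)
imposes a target Spearman correlation `coupling_rho` between
`amp_sentential` and `|n400_effect|`; a second latent link
(`behavior_coupling_rho`) couples the same factor to the comprehension
rating and listening score.  Marginals are truncated normals (strictly
monotone quantile transforms, so the copula's rank structure is preserved
exactly; `coupling_rho = 1` yields perfectly co-ranked draws).  The
canonical negative sign of the difference wave then makes the *measured*
sentential-peak × N400 correlation negative, mirroring how such effects
are reported.

**Artifacts.**  With probability `artifact_rate` (default 0.123) per
event-aligned segment, a boxcar excursion of ±[100, 300] µV is added on a
random channel subset; ground-truth flags are stored in the recording
metadata, so rejection bookkeeping can be checked exactly.  Ocular sources
are not simulated; frontal-channel exclusion plus amplitude rejection
stand in for ocular cleaning at the fidelity level the pipeline is tested.

**Behavioral scores** (comprehension rating 0–4, question accuracy,
listening score) are drawn per subject from truncated normals; group means
default to 3.68/2.95, 0.95/0.90 and 0.97/0.86 for the native/second-language
cohorts.

## Preprocessing

* **FIR band-pass** — Hamming-windowed sinc; transition width
  `min(lo, 0.1·hi)` Hz, order `ceil(3.3/(width/fs))` (16 501 taps for
  0.1–25 Hz at 500 Hz); applied zero-phase by convolving with the kernel's
  autocorrelation (forward-backward equivalent), odd-reflection padding at
  the edges.  Entrainment band 0.1–25 Hz; ERP band 0.1–30 Hz.
* **Referencing** — common average for the tagging analysis (after
  excluding the chronically noisy temporal channels T7/T8/TP7/TP8 and the
  mastoids), linked mastoids for the ERP analysis (mastoids dropped
  afterwards; designated frontal channels excluded as the ocular guard).
* **Interpolation** — bad channels replaced by the inverse-distance mean
  of their good Delaunay-triangulation neighbors on the 2-D layout.
* **Epochs** — half-open sample windows `[round(e+tmin·fs),
  round(e+tmax·fs))`, 0-based event indices.  Entrainment epochs start one
  sentence after trial onset (7 040 samples); ERP epochs span −100…700 ms
  (400 samples).
* **Rejection** — an epoch is dropped when |amplitude| exceeds 75 µV on
  any retained channel; evaluated after filtering, referencing and
  baseline correction (the pre/post-baseline order is not dictated by the
  analysis definition; "after" was adopted).  Rejection is idempotent and
  order-independent.
* **Baseline** — per epoch and channel, subtract the mean over
  −100…0 ms.  Under the half-open convention a linear ramp is zeroed at
  the mean time of the window's samples (−51 ms at 500 Hz), not at the
  continuous midpoint.

## Tagging statistics

Evoked power is the one-sided amplitude-spectrum power of the
trial-averaged signal: `P_k = (2|X_k|/N)²` (so a sinusoid of amplitude A
gives exactly A² µV² at its bin), in dB re 1 µV².  No taper is used —
every tagged rate completes an integer number of cycles in the epoch, so
leakage is structurally zero.  Normalization subtracts the mean dB of the
two bins on each side (dB subtraction = power ratio against the local
noise floor); dB conversion precedes the subtraction.  Per subject, dB
spectra are averaged over all retained scalp electrodes, and the group
test is a one-tailed paired t across subjects of peak vs neighbor-mean
power, df = n−1.  The statistic is oriented as (peak − neighbors), so
genuine tracking yields *positive* t values; reports that orient the
difference the other way simply flip the sign.

Degenerate inputs: zero-variance differences give p = 0 (all positive),
p = 1 (all negative) or t = 0, p = 0.5 (all zero); power below 1e-30 µV²
is floored at −300 dB before the log.

## ERP statistics

Subject-level inference throughout: per-subject condition ERPs, then a
two-tailed paired t across subjects of the ROI-mean amplitude
(14 central/centro-posterior channels) in the 300–500 and 500–700 ms
windows (half-open in samples), with a 95% t CI on the mean difference.
The point-wise map computes a paired t at every (electrode, sample) and
controls FDR by Benjamini–Hochberg over the joint electrode × time family
(the more conservative reading of a point-wise correction).  With the
default 400 ms latency and 80 ms template SD, most of the simulated effect
mass falls in the early window; the late window captures the tail.

## Correlations and group comparisons

Cohort-table columns are min–max scaled and then Spearman-correlated
(scaling is order-preserving, hence provably harmless for rank
correlations — asserted exactly in the tests); p values use the
t-approximation with df = n−2 (exact permutation p available for n ≤ 10).
Group behavioral comparisons use the pooled-variance independent t
(df = n₁+n₂−2), the test consistent with a between-group df of 42 at
22 + 22 subjects.

## Validation experiments and problem sizes

`cortrack.experiments` re-runs the pipeline on cohorts with known truth.
Problem sizes are the package's own choices, selected so every experiment
is informative at desk scale:

* **Type-I error** — 1 000 null cohorts (n = 22, all amplitudes 0,
  noise ~N(10, 2) µV), 16 channels, trial averages drawn via the 1/√n
  identity; rejections pooled over the three tagged bins.  A 1/f floor is
  locally convex in dB, which biases the sentential (lowest-frequency)
  test very slightly conservative; pooling reports the procedure's overall
  calibration (~0.05).
* **Detection** — full simulate → filter → re-reference → epoch → FFT →
  test path on a 16-channel montage subset, 22 subjects × 30 trials per
  cohort, cohort seeds 1–20 per group at the frozen config SNR.
* **N400 recovery/coverage** — noise-free recovery through epoching,
  baseline and the ROI window; CI coverage over 500 ERP-level cohorts
  (ROI channels, 53 epochs/condition) against the analytic truncated-normal
  population mean.
* **FDR control** — 200 pure-noise ERP cohorts, 16 channels × 400 samples;
  with no true effects the false-discovery proportion is 1 exactly when
  the mask is non-empty; the smooth (pink) noise makes BH strictly
  conservative here (mean FDP ≈ 0.02–0.03).
* **Correlation recovery** — 500 drawn cohorts at `coupling_rho` 0.6 and
  0.0, correlating the latent sentential amplitude with the N400 magnitude
  through the same scale-then-Spearman path used on measured tables.

## SNR tuning (frozen in `configs/default.json`)

The defaults are calibrated so the full-scale run reproduces the
qualitative group pattern.  The procedure: (1) estimate the evoked noise
floor per bin analytically — pink noise of RMS 10 µV averaged over 30
trials leaves ≈0.05 µV² per 0.071 Hz bin near 1 Hz — and place the
native-group amplitudes (0.8/1.0/1.5 µV sentential/phrasal/syllabic,
i.e. 8–14 dB above floor after referencing losses) where detection is
essentially certain at n = 22; (2) set the second-language sentential
amplitude an order of magnitude below the floor (0.03 µV, SD 0.025) so the
group test stays at its null level while the latent parameter remains
continuous for the copula; (3) verify once on cohort seeds 1–20 (native:
20/20 significant at every rate; second-language: 0/20 sentential, 20/20
phrasal and syllabic) and freeze.  A consequence worth knowing: at this
SNR the *measured* second-language sentential peak is noise-dominated, so
correlations computed from measured peaks are near null even though the
latent coupling is 0.6; the coupling is therefore validated at the latent
level, and the measured-level correlation machinery is validated on the
native-amplitude scale and on synthetic tables.

## Numerical choices

* Recordings are generated and stored in float32 (the container's declared
  precision); generators accept `dtype=float64`, under which a noise-free
  trial's spectrum is pure at the tagged bins to better than 1e-9 relative
  (float32 storage adds ~1e-7 quantization).
* Pink noise is synthesized at the next FFT-friendly length and cropped
  (stationary, so the crop is innocuous).
* Determinism: every generator is a pure function of (parameters, seed);
  seeds derive from a master seed via `numpy.random.SeedSequence` spawning.
  Repeated runs of the same config produce byte-identical numeric reports;
  timestamps appear only in the log.
* Epoch/window conventions are half-open everywhere; event times are
  sample indices, never seconds.

## What passing tests do and do not show

The generator emulates phase-locked narrowband responses, 1/f noise,
condition-dependent ERP templates and gross artifacts.  It does not emulate
spatially correlated noise, ocular/muscle sources with realistic
topographies, non-stationarities, per-syllable evoked transients, or a
volume-conduction head model — so green tests certify the *analysis
machinery* (calibration, recovery, error control) rather than robustness
to every property of recorded EEG.
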