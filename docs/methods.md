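# Methods

This note documents the models, estimators, parameter choices and known
limitations of the package, in the order of the analysis chain.

## Synthetic sessions

The generator produces the data the estimators assume, with ground truth
attached; it is first-class, tested code, not a fixture.

**Non-stationary oscillator.** The instantaneous frequency performs a
Gaussian random walk (default 0.02 Hz per sample at 1 kHz) reflected into
the band (default 3.5–9 Hz), with a weak mean reversion
(2·10⁻⁴ per step) toward the nominal mean. The reversion is needed
because a purely reflected walk is stationary around the band *midpoint*
(6.25 Hz for 3.5–9 Hz), whereas the emulated rhythm has a ~6 Hz mean in
an asymmetric band; the chosen reversion keeps the long-run mean at
6 Hz while the walk still explores most of the band within a minute.
Phase is the cumulative integral of frequency, so the returned phase is
exact by construction and usable as ground truth.

**Phase-locked spiking.** Spikes are a thinned inhomogeneous Poisson
process with rate `base_rate · exp(κ cos(φ − φ₀)) / I₀(κ)`. The von
Mises gain has unit time-average when the phase sweeps uniformly, so
`base_rate` is the realized mean rate; `κ = 0` reduces exactly to a
homogeneous Poisson process. In the κ→∞ limit the spike-phase
distribution collapses onto φ₀ with circular SD ≈ 1/√κ — note that
individual spikes still scatter at that scale, so "all phases equal φ₀"
holds only in the SD sense (the test asserts circular SD < 0.05 rad at
κ = 500).

**Phase-amplitude coupling.** The gamma envelope is
`1 + depth · cos(φ_θ − φ_max)`, by default maximal at the theta trough
(φ_max = π for a cosine oscillator). `depth = 0` yields a constant
envelope; the envelope is returned so closed-form tests need no
demodulation.

**Co-firing.** Each sender spike is copied with probability
`copy_prob` to the receiver at `lag ± jitter` (lag may be negative for
the reverse-direction control), on top of independent Poisson background
spikes.

**Sessions.** Default sessions have 2 bundles × 4 microwires, 24 hit +
16 miss trials, epochs −7…+7 s at 1 kHz, with the condition-dependent
structure confined to the 2–3 s window of interest: hits carry 8 Hz
theta / 70 Hz gamma / 20 ms lags, misses 5 Hz / 62 Hz / 60 ms — the
frequency-shift scenario. Channel LFPs are gain-weighted mixtures
(gains ~U(0.6, 1.4) per wire) of the bundle's shared theta and gamma
plus white noise (SD 0.4 of the unit theta amplitude; optional 1/f
noise). Distinct per-wire gains matter: with identical gains the
Gram-Schmidt re-reference would annihilate the shared oscillation,
whereas real wires see the source at different strengths. Each bundle
hosts a "sender" unit locked to the *other* bundle's theta (a distal
coupling) and a "receiver" unit locked to its own bundle's gamma which
also echoes the sender's spikes at the condition lag — the chain the
pair-selection rule must rediscover. Everything regenerates
bit-identically from (design, seed).

What the generator does **not** emulate: biophysical waveforms beyond a
stereotyped spike template, spatially realistic volume conduction,
recording drift, multi-unit waveform mixtures, or TTL artifacts. Passing
recovery tests therefore demonstrates estimator correctness under the
assumed statistical structure, not robustness to every pathology of
patient recordings.

## Preprocessing

Fixed order: low-pass → spike interpolation → line-noise removal →
epoching/downsampling → artifact rejection → re-referencing.

- Low-pass: Butterworth order 2 at 300 Hz, applied forward-backward
  (zero phase). Zero-phase application is a deliberate choice — causal
  filtering would bias every downstream phase estimate.
- Spike interpolation replaces [t−2 ms, t+6 ms] around each detected
  spike by a straight line between the flanking samples; overlapping
  spans are merged, spans at record edges clipped. Idempotent on clean
  data.
- Line noise: per-epoch least-squares fit of a sine+cosine pair at the
  line frequency, subtracted. This assumes the mains component is
  stationary within an epoch and — unlike a notch — preserves
  physiological activity at that frequency.
- Epoching: polyphase anti-aliased resampling to 1 kHz, 14 s epochs
  (−7…+7 s, 14001 samples); out-of-bounds cues are dropped and logged.
- Artifact rejection: (1) channel RMS amplitude in −0.5…5 s z-scored
  across channels, z > 3 drops the channel; (2) per-trial mean RMSA
  z-scored across trials, z > 4 drops the trial; (3) per-trial maximum
  raw amplitude, z > 4 drops the trial; (4) channels need ≥ 25 surviving
  trials. Note an across-channel z-score is bounded by √(n_channels−1),
  so rule (1) can only fire with ≳ 11 channels — with a single 8-wire
  bundle it is a no-op by arithmetic, which matches its intent of
  catching broken wires among many.
- Re-referencing: per trial, each channel is orthogonalized against the
  mean of the *surviving* same-bundle neighbors,
  `x′ = x − (⟨x,r⟩/⟨r,r⟩) r`, removing shared (volume-conducted)
  variance; channels without neighbors are dropped and logged.

## Unit classification and densities

`c2` sums the across-spike waveform SD over the rising flank (from the
point of maximum curvature to the peak) and divides by the spike height;
it is scale-invariant and zero for identical waveforms. The curvature
search runs from the waveform start to the peak — the flank's start is
not otherwise quantifiable. SU requires `c2 < 3` (strict) and an
ISI-violation rate ≤ 1% at 3 ms. Inclusion requires ≥ 50 spikes in
either condition, mean spike count > 2 and mean rate > 1 Hz in 0–4 s
(strict inequalities).

Spike densities convolve the 1 kHz binary train with a unit-area
Gaussian of 250 ms support and σ = support/6 (≥ 99.7% of mass inside the
stated support — only the length is conventionally reported, so σ is a
package choice). Normalization:
`z(t) = (sd(t) − μ_bl)/(σ_bl + λ)` with baseline −1000…−125 ms and
λ = 0.1, which keeps z finite for silent baselines. Spike-train spectra
use a 25 ms kernel, DPSS tapers with ±2 Hz smoothing over the 1 s
window, averaged over trials.

## Phase and power estimation

Morlet wavelets with σ_t = cycles/(2πf): 6 cycles on 2–40 Hz (1 Hz
steps), 12 cycles on 40–80 Hz (2 Hz steps); the high band transforms the
first temporal derivative of the LFP (np.gradient · fs) to whiten the
spectrum before phase extraction. Wavelet normalization affects power
scale only, never phase; power comparisons are all within-frequency, so
the choice is immaterial here. The Hilbert variant band-passes
(Butterworth order 3, zero-phase; 4 Hz wide for the low band, 8 Hz for
the high band) and takes the analytic signal; wavelet and Hilbert phases
agree within ~0.1 rad on band-limited signals in the window of interest.
Coefficients within one wavelet σ_t of an epoch edge are flagged invalid
(`edge_valid_mask`); the 2–3 s window sits 4 s from the nearest edge at
every analysis frequency.

Power normalization: per channel and frequency, trial power averaged
over −0.5…5 s is z-scored as (trial − median)/SD across trials; trials
with max |z| > 2.5 are discarded. 1/f correction fits a line to the
log-log spectrum, back-transforms the residual and z-normalizes it; a
numerically exact power law returns a zero spectrum rather than
amplified rounding noise. ITPC is PPC across trials per time-frequency
point.

## Spike-field coupling

PPC is computed via the exact identity `(|Σe^{iθ}|² − n)/(n(n−1))`,
verified against the O(n²) definition to 1e−12. The Rayleigh p-value
uses the standard small-sample exponential approximation
(z = nR̄²; Zar's series), cross-checked against an independent
implementation; Benjamini-Hochberg FDR at q = 0.05 runs across the
frequencies of one band (per-band correction is an interpretation — the
source procedure does not state whether bands were pooled). Screening
requires ≥ 30 spikes in the window of interest.

The pair-count null shuffles the spike↔LFP trial pairing (per pair, 100
shuffles; hit/miss counts and spike counts preserved), re-screens, and
builds the null distribution of significant-pair counts from 10,000
draws. A caveat the synthetic data makes explicit: when spikes are
strongly rhythmic at the LFP frequency and the oscillator is coherent
across the short window, shuffled pairings retain elevated Rayleigh
statistics (each wrongly-paired trial contributes a concentrated phase
cluster at a random offset). The null is therefore conservative in
exactly the situation where spike rhythmicity, not phase coupling, drives
the statistic.

Peak detection takes interior local maxima of the PPC spectrum within
the band (theta 3–13 Hz, gamma 45–75 Hz), requires the peak to exceed
0.005 in *both* conditions, and breaks ties toward the lower frequency.
Condition contrasts use paired t-tests across pairs per frequency with
FDR, and the per-pair peak-frequency shift uses a paired t-test.

The selection-bias control recomputes, per pair, 5000 shuffled
pseudo-hit/pseudo-miss PPC spectra keeping only shuffles that survive
the all-trials screen, then z-transforms the real condition spectra by
the kept shuffles' mean/SD. The corrected spectra feed the same
peak-frequency analysis; note the z *magnitudes* scale with spike count
by construction (SD of the null shrinks with more spikes), so only
peak locations and within-pair contrasts are interpretable.

## Directionality (PSI)

Cross-spectra between the unit's spike density (25 ms kernel,
σ = 10/2.355 ms) and the distal LFP are estimated from 500 ms Hann
segments with 50% overlap within the window, averaged over trials and
segments, and normalized to complex coherency. The phase slope is
accumulated over a 5 Hz window:
`Ψ(f) = Im Σ C*(f′)C(f′+δf)`; positive Ψ means the spike series leads.
Ψ is exactly antisymmetric under argument swap. z-normalization uses 100
shuffles of the spike-trial assignment per condition, which removes
spike-count bias from the condition contrast. Minimum 60 spikes
(30 in the relaxed mode). The segment length/overlap are package
choices; 500 ms gives 2 Hz resolution, the finest that still yields ≥ 3
segments per 1 s trial.

## Theta-gamma coupling and waveshape controls

The modulation index bins gamma amplitude into 18 uniform theta-phase
bins on [−π, π) (left-closed; empty bins use the 0·log 0 = 0
convention) and measures the entropy deficit of the normalized profile.
Phase and amplitude series are concatenated across trials within a
condition (per-trial MI averaging is the alternative; concatenation was
chosen as the variance-minimizing option for 1 s windows). The shuffle
null permutes the phase-trial↔amplitude-trial assignment within
condition (200 shuffles), preserving both marginals; MI is z-scored by
the null's mean/SD, making the hit/miss contrast insensitive to trial
counts. Channels qualify when their bundle carries both a locally
gamma-coupled and a distally theta-coupled LFP, and when both conditions
have PPC peaks in 5–11 Hz (theta) and 50–80 Hz (gamma); the MI is
evaluated at each condition's own peak pair. The group contrast is a
Wilcoxon signed-rank test (exact under n = 6 channels).

Harmonic control: the MI contrast is repeated with gamma forced to
8 × the condition's theta peak (9 Hz → 72 Hz). If waveshape asymmetry
masquerades as coupling, the harmonic contrast is at least as strong as
the real one.

Asymmetry index: the trace is band-passed at the theta peak ± 2 Hz;
filtered peak/trough times are adjusted to the raw-signal extrema within
± a quarter cycle. The adjustment uses the *cycle-averaged* raw waveform
around the filtered anchors (one offset per extremum type) rather than
per-cycle argmax: per-cycle adjustment on noisy data systematically
shrinks the measured asymmetry (noise pulls the argmax toward the
shallow flank), while the cycle average is unbiased and recovers planted
asymmetry within ±0.05 up to noise SD of 50% of the signal amplitude.
`AI = (T_asc − T_desc)/ω` with ω the nominal cycle length; trials with
fewer than two full cycles are skipped.

## Co-firing

Spike trains are smoothed (25 ms support, ~10 ms FWHM Gaussian; the
sweep 15/25/35/45 ms is a supported robustness check) and
cross-correlated per lag on a ±100 ms, 1 ms grid (the lag bound is a
package choice). The correlation is the dot product summed over matched
trials; because correlations are evaluated at lags far below the trial
length, this equals the concatenated-train correlation up to negligible
boundary terms, and it lets the 2000 receiver-trial shuffles reuse a
precomputed trial-pair correlation tensor (each shuffle is a sum over a
permuted diagonal, so the full null costs no additional FFTs). z-scoring
by the shuffle mean/SD absorbs all rate and trial-count scaling. Pairs
are retained when the condition-mean z exceeds 1 at any lag — a weak
screen that reliably keeps genuine co-firing but, being a max over ~200
standardized lags, also passes a substantial fraction of null pairs;
inference rests on the subsequent peak-lag statistics, not on the
filter. Peak lags are the global z maximum over 0…+100 ms
(sender→receiver) or −100…0 ms (reverse control), ties toward zero, and
the condition contrast is a paired t-test across pairs.

## Behavioral arithmetic

Hits require both cued-recall selections correct. With two targets among
four candidates chosen sequentially without replacement:
p(both) = (2/4)(1/3) = 1/6 ≈ 16.67%, p(none) = 1/6, p(one) = 2/3,
p(miss) = 5/6 ≈ 83.3%. A constant phase lag Δφ at coupling frequency f
implies a co-firing latency Δφ/(2πf); a quarter cycle (π/2) gives
31.25 ms at 8 Hz and 62.5 ms at 4 Hz — the faster the oscillation, the
tighter the co-firing window.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything on synthetic
data sized for desk-scale verification: 40 spike-LFP pairs for the
frequency-shift recovery, 24 sender/receiver pairs for the lag recovery,
1000 uniform-phase simulations for the screening type-I rate, and
sessions of 2 bundles × 4 wires with 30–40 trials for the end-to-end
runs; shuffle counts in integration tests are reduced below the
reference defaults (which `RunConfig` pins) since the shuffle machinery
is exercised identically at any count. Zero-variance situations
(identical trials, exact power laws, silent baselines) return defined
values rather than NaNs, and every exclusion (spike minimums, missing
peaks, artifact rules) is logged with the rule that fired.

## Limitations

- The synthetic LFP mixes oscillations linearly with Gaussian noise;
  estimator behavior under heavy-tailed artifacts is untested.
- The pair-count null and the coincidence filter have the structural
  caveats noted above; both are faithful to the described procedures.
- PSI assumes a frequency-constant delay within the 5 Hz slope window.
- Anatomical/region-resolved analyses and spike sorting itself are out
  of scope; units enter as sorted spike trains with waveform stacks.
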