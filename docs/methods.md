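# Methods

## Generative model

Each synthetic epoch (channels × samples, µV; −1.0 to +2.0 s around
stimulus onset at 500 Hz by default) is a sum of independent components:

* **1/f background** — white Gaussian noise spectrally shaped to a
  power-law spectrum with exponent 1.0 (DC removed), scaled to 4 µV RMS.
  The prestimulus period is stationary noise; nothing about prestimulus
  dynamics is modelled beyond that.
* **Late theta with phase reset** — a sustained post-stimulus oscillation
  (sigmoid-ramped plateau 0.3–1.7 s, 6 µV) at the centre of the coupling
  phase band (7.5 Hz). Its phase at the reset latency (1.0 s) is drawn per
  trial from a von Mises law whose concentration κ depends on the
  condition (defaults κ_SE = 1.2, κ_UE = 0.4); each trial also receives a
  Gaussian frequency jitter with σ_f = 1/(2π·reset_width) (reset_width
  0.3 s → σ_f ≈ 0.53 Hz). Phases therefore agree at the reset latency and
  decohere away from it, so inter-trial alignment is *localised* in time
  around 1.0 s even though the oscillation's amplitude is sustained. This
  is the classic phase-reset account: an ongoing rhythm with natural
  frequency variability whose phase is pinned by the stimulus-locked
  process. The von Mises law was chosen because it is the canonical
  circular distribution with a closed-form mean resultant length
  I₁(κ)/I₀(κ), which the tests use as an analytic oracle.
* **Early broadband reset** — a Gaussian burst (σ = 80 ms at 0.2 s, 5 µV)
  of four cosines spanning 4–20 Hz sharing one von Mises phase draw
  (κ = 2.0 in *both* conditions): a task-generic evoked reset that also
  shapes the ERP.
* **Theta–gamma coupling** — on the right-ATN channel only, a 45 Hz
  carrier with random phase per trial and envelope
  `gamma_amp · plateau(t) · (1 + m·cos φ_theta(t))`, the multiplicative
  phase–amplitude coupling model; the depth m is the participant's
  coupling gain (clipped to [0, 0.95]), scaled by 0.3 under UE.
* **ERP transient** — a damped 5 Hz sinusoid from 0.05 s (τ = 0.15 s),
  peak-normalised to 4 µV, identical in expectation across trials and
  conditions.

Channel roles: frontal, L-ATN and R-ATN carry the early and late resets;
only R-ATN carries coupling; frontal and L-ATN reset concentrations do
*not* differ by condition (the condition effect is confined to R-ATN);
the dorsomedial channels carry background and ERP only.

**Participant-level structure.** A latent standard normal z scales each
participant's reset concentrations (factor 1 + 0.5·z, floored at 0.1);
the coupling gain loads on ρ·z + √(1−ρ²)·u with independent u, giving
gains N(0.5, 0.2²) clipped at 0. The across-participant correlation
between reset strength and coupling gain thus targets
`participant_effect_rho` (default 0.9). The spreads (κ cv 0.5, gain sd
0.2) are set so that, with 40 trials per condition, participant
differences exceed single-participant estimation noise — a prerequisite
for across-participant correlations of magnitude ~0.8 to be observable at
n = 7 at all.

Everything derives from one integer seed through `SeedSequence` spawning:
parameter draws first, then one child stream per trial.

### What the generator does *not* emulate

No biophysical thalamocortical dynamics, volume conduction, epileptiform
activity, artifacts, line noise, or non-stationary background. Passing
tests therefore demonstrate that the *estimators and statistics* behave
correctly on signals with the intended ground-truth structure — not that
the scientific conclusions would survive real-data confounds such as
shared reference, artifact contamination, or non-sinusoidal rhythms.

## Time–frequency decomposition

Complex Morlet wavelets (5 cycles, zero-mean, from
`mne.time_frequency.morlet`) are applied by frequency-domain convolution
in single-precision complex; this matches MNE's `tfr_array_morlet` to
~1e-7 relative error (asserted in the tests against that reference) and is
roughly an order of magnitude faster, which the permutation-scale
simulation studies need. Signals shorter than the longest wavelet are
zero-padded symmetrically before convolution.

The default analysis grid is 2–100 Hz in 1 Hz steps. The output time axis
is trimmed by **2 Gaussian standard deviations of the longest wavelet**
per side (0.8 s at 2 Hz), keeping ≥95 % of that wavelet's energy inside
the epoch for every retained sample; on the default epoch this leaves
≈ −0.20…1.20 s, so both analysis windows (0–0.5 s, 0.9–1.1 s) are
interior. Cluster maps are decimated to 100 Hz (every 5th sample) —
far above the bandwidth of a 5-cycle wavelet at ≤100 Hz.

Band summaries use the **complex mean** of amplitude·e^{iφ} across
in-band bins (not a circular mean of phases), so low-amplitude bins
contribute proportionally; band phase and amplitude are the argument and
modulus of that mean.

## Alignment, coupling, synchrony

* PAI is computed per participant/channel/condition after balancing trial
  counts by seeded random subsampling of the larger condition (original
  epoch order preserved). Balancing keeps the two conditions' positive
  bias floors (~1/√K) identical.
* Window summaries average PAI over all grid points in closed
  window × band intervals.
* The modulation index concatenates the band phase and amplitude series
  across a condition's epochs within the analysis window (0.5–1.5 s
  default) and takes |mean(A·e^{iφ})|. The surrogate z-score shifts the
  amplitude circularly **within each trial independently** (200
  surrogates, ≥0.1 s shift). Whole-series shifts of the concatenated
  series are also provided (the 1-D path) but are not used by the
  pipeline: when phases are partially stimulus-locked, shifts near
  multiples of the epoch length re-align amplitude with *other* trials'
  phases and inflate the surrogate spread, biasing the z-score downward
  exactly when alignment is strong. Per-trial shifts preserve both
  marginals and are free of that repetition artifact. All surrogate
  values are obtained exactly via one FFT cross-correlation per trial.
* The phase-locking value between channels is |mean over epochs of
  e^{i(φ_A−φ_B)}| per time–frequency point.

## ERPs

Per trial: zero-phase band-pass 1–8 Hz (symmetric Hamming-window FIR,
~1651 taps at 500 Hz for a 1 Hz transition width and ~53 dB stop-band,
applied by centred convolution on reflect-padded data), subtraction of
the −0.2–0 s baseline mean, then averaging. Peak extraction takes the
largest absolute deflection in the window, earliest sample on ties.
The ERP–alignment correlation pools (|ERP(t)|, band-mean PAI(t)) pairs at
the PAI grid times over participants of one condition; with 7
participants as the unit of observation the printed significance levels
of such correlations would be unreachable, so time points are the unit,
and a per-participant reading remains possible by passing single objects.

## Group statistics

* Paired two-sided t-tests across participants at each map point
  (participants contribute both conditions). Zero-variance points get
  t = 0, p = 1 with a logged warning rather than an exception.
* Cluster-forming threshold p < 0.05; clusters are 4-connected components
  (no diagonals — conservative and standard for grid maps), positive and
  negative t clustered separately; cluster statistic = point count. The
  permutation null swaps condition labels within participant (sign-flips
  of paired differences; the t denominator is reconstructed from the
  precomputed Σd² so each permutation is a single matrix product), and
  records the largest cluster over both signs. Cluster
  p = (1 + #{null ≥ observed})/(1 + N) — never exactly zero.
* Pearson r carries t = r√(n−2)/√(1−r²) with a Student-t two-sided p;
  BH-FDR uses `statsmodels` (`fdr_bh`), cross-checked in the tests
  against a brute-force implementation of the step-up definition. The FDR
  family is all correlations computed in one pipeline run.
* Fisher z comparison: z = (atanh r₁ − atanh r₂)/√(1/(n₁−3)+1/(n₂−3)),
  two-sided unit-normal p.

## Study problem sizes

The calibration studies run the generator → decomposition → PAI →
cluster-test chain on a reduced 20-frequency (2–21 Hz) × ~140-time-point
map per cohort: 200 null cohorts for the type-I rate, 20 effect cohorts
(fixed κ_SE = 1.5 vs κ_UE = 0, no participant spread — the stated study
condition) for detection, 100 cohorts per ρ for correlation recovery, and
10 coupling-depth levels × 20 replicates for monotonicity; these sizes
keep the whole validation reproducible on a single CPU in minutes.
Monotonicity is assessed by the Spearman correlation between depth and
the per-level *mean* z-score: replication averages out single-run
estimation noise, so the statistic reflects the response curve rather
than the noise floor (the z-score saturates at high depth because the
surrogate spread itself grows with the coupled component).

## Known limitations

* The surrogate z-score saturates for coupling depths ≳0.6; it orders
  effect sizes correctly but is not linear in depth.
* With partially stimulus-locked coupling, any surrogate scheme trades
  off evoked against induced coupling; the per-trial shift scheme
  measures total coupling and does not attempt the decomposition.
* The wavelet family, cycle count and frequency resolution are fixed
  choices; quantities sensitive to them are validated as properties
  (invariances, calibration, monotonicity), not as point values.
* Correlations over n = 7 participants are intrinsically noisy
  (null median |r| ≈ 0.31); single-cohort correlation values should be
  read accordingly, which is why the validation reports medians over many
  cohorts.
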