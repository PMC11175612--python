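# Methods

## The measurement problem

Late *Drosophila* embryos (roughly the last third of embryogenesis) move inside
the vitelline membrane, first in a disorganised, muscle-autonomous way
("myogenic" phase, beginning ~16 hours after egg laying, hAEL), then in
rhythmic bursts of activity and inactivity that require neural input
("neurogenic" phase, ~18 hAEL until hatching, ~21 hAEL).  Under incident
illumination, any movement changes the path of light reflected off the embryo,
so the mean grey value (MGV) of a rectangular region of interest (ROI) drawn
over the embryo fluctuates frame to frame.  The MGV trace is therefore a
cheap, whole-embryo motility signal — but it rides on slow developmental
trends (gradual morphological change, the step-like brightening when the
tracheae fill with gas, the discontinuity at hatching) that must be removed
before movement can be quantified.

## Movement pipeline

Given a raw MGV trace sampled at frame rate `fs` (default 4 Hz):

1. **Rolling baseline.**  A centred moving average with a 60-sample window
   (15 s at 4 Hz): `window // 2` samples on each side of every sample, the
   window shrinking symmetrically at the trace edges.  15 s is long relative
   to individual movements (~1 s) and short relative to developmental change,
   so the baseline tracks development and ignores movement.  A centred (not
   trailing) window avoids a 7.5-s phase lag in the baseline; a flag discards
   the half-window margins instead of shrinking for users who prefer edge-free
   output.
2. **Rectify.**  `|raw − baseline|` per sample.
3. **Threshold.**  Deviations strictly below 0.01 intensity units are set to
   exactly 0 (empirical sensor-noise floor).  Thresholding is applied
   per-sample, before any summation, bout detection or FFT; a post-sum
   variant is available for sensitivity analysis.
4. **Crop at hatching.**  Hatch times are user annotations (as in manual
   scoring of when the larva breaches the membrane); `suggest_hatch` offers
   an advisory candidate — the largest sustained raw-MGV step in the final
   third of the recording, with a confidence in units of robust sample noise
   — but is never applied automatically.
5. **Phase sums.**  Movement per phase is the sum of the thresholded
   rectified deviations over half-open windows, by default myogenic
   [16, 18) hAEL and neurogenic [18, hatch) hAEL; an annotated boundary
   overrides the defaults.  Time is carried in hAEL everywhere; frame index
   conversion (`record_start + frame / fs / 3600`) happens only at I/O.

## Spectral and bout analysis

The rhythmic phase is characterised with a sliding-window FFT over the
thresholded movement trace: 1-h windows, 30-min steps, per-window mean
subtraction, rectangular taper by default (Hann behind a flag), one-sided
amplitudes normalised as `2|X_k|/N` with the DC bin removed.  With this
normalisation an on-bin sinusoid of amplitude A reads A at its frequency;
absolute amplitudes are nonetheless only comparable within this pipeline, so
cross-study comparisons should use peak *periods*, not amplitudes.  The
period-amplitude view re-indexes amplitude by `p = 1/f` within a band of
4–1800 s (Nyquist-safe at 4 Hz up to half the FFT window); the band's mode
("modal period") is the summary used for genotype contrasts.

Bouts are detected on the thresholded movement trace by smoothing with a
centred 10-s moving average, taking maximal runs above a user threshold,
merging runs separated by gaps shorter than 10 s, and discarding bouts
shorter than 5 s.  With a threshold at half the plateau level, the smoothed
edge ramp crosses the threshold exactly at the true edge, so on clean
square-wave activity the detector recovers counts and durations exactly; on
realistic traces the reported duration includes a predictable widening of a
few seconds from smoothing (symmetric across genotypes, so contrasts are
unaffected).

## Ratiometric calcium activity

Two channels are imaged per cycle (1.5 s): a calcium sensor (GCaMP6s-like
"signal") and a calcium-insensitive reporter (tdTomato-like).  Movement
multiplies both channels by the same factor, so the per-cycle ratio
signal/reporter cancels it.  Activity is the ratio minus its baseline,
defined as the minimum of the ratio in a 10-min window centred on each cycle
(shrinking at the ends), then summed over the recording window.  Negative
excursions from channel-specific noise are retained — clipping would bias
cohort comparisons.  The subtractive form is the default; the conventional
division-normalised ΔF/F is available behind `normalise=True`.

## Synthetic recordings

The generator produces traces with the structure the pipeline assumes, plus
ground truth, so every stage is testable without recorded data.  Per-trace
model:

* **Baseline:** linear drift (default 0.5 intensity units/h) + a sigmoidal
  tracheal gas-filling step (default height 2.0 at 19.5 hAEL, 30-s time
  constant, ~2-min 10–90 % rise) + a discontinuity at hatching (default
  −1.0 at 21.0 hAEL).
* **Myogenic phase** (16–18 hAEL): a Poisson process (default 2 events/min)
  of transient events, each one full sine cycle of ~1 s with
  gamma-distributed amplitude (mean 0.5, CV 0.5).  A full zero-mean cycle
  leaves the 15-s rolling baseline essentially unperturbed; overlapping
  events are thinned so per-component ground-truth accounting is exact.
* **Neurogenic phase** (18 hAEL–hatch): bouts recurring strictly periodically
  (default period 180 s, duration 60 s, optional start jitter, default 0 so
  spectral recovery is exact), carrying a sinusoidal oscillation scaled by
  the bout amplitude (default 1.0).  The default carrier frequency is
  60/61 Hz ≈ 0.98 Hz — about one movement per second, and an exact spectral
  null of the 61-sample centred boxcar, so the default baseline filter
  ignores the carrier completely.  This encodes the premise behind the 15-s
  window: individual movements are the thing the baseline is designed not to
  track.  The carrier's own spectral lines sit at periods ≤ ~1 s, outside
  the 4–1800-s analysis band, so spectrogram peaks reflect bout periodicity.
* **Noise:** additive Gaussian, default sd 0.005 (half the 0.01 threshold).

Genotype presets: `wild_type` as above; `silenced` (neural silencing, e.g.
Kir expression) sets the bout amplitude to zero and leaves the myogenic
parameters untouched; `mutant` halves event and bout amplitudes, shortens
the bout period to 120 s and the bout duration to 30 s (movement reduced,
bursts more frequent and shorter).  The mutant effect sizes are free
parameters — chosen here as clear, plausible magnitudes — because only the
direction of each effect is established; all are overridable in the cohort
config.

Ground truth records every bout interval, event time, phase boundary and the
rectified activity injected per phase (accumulated component by component, so
it equals `sum(|movement|)` over rendered samples to 1e-9 relative).
Cohorts derive per-embryo seeds deterministically from the cohort seed and
are bit-for-bit reproducible.

Matched calcium pairs share a strictly positive multiplicative motion
artifact; the signal channel adds one fast-rise/exponential-decay transient
(τ = 6 s, unspecified kinetics in the source data, so a standard GCaMP6s-like
choice) per event time.

What the generator does **not** emulate: biomechanics or optics of the
embryo (only mean-intensity equivalence), amplitude drift within a phase,
bout-to-bout amplitude variability, invading larvae after a neighbour
hatches, photobleaching, or non-Gaussian camera noise.  Passing tests
therefore demonstrate that the pipeline recovers what it claims from signals
with this structure — not that the biological claims hold, and not
robustness to artifacts outside this list.

## Statistics

Group comparisons follow a normality-gated battery.  A sample is "normal"
only if all four of D'Agostino & Pearson, Anderson-Darling, Shapiro-Wilk and
Kolmogorov-Smirnov fail to reject at α = 0.05 (the KS member is Lilliefors,
since mean and sd are estimated from the sample); any single rejection routes
to the nonparametric branch, and n < 8 is "indeterminate" (treated as
non-normal).  Two groups: Welch's t, or Mann-Whitney U — exact enumeration
when min(n) ≤ 8 with no ties, tie-corrected continuity-corrected normal
approximation otherwise — with Bonferroni adjustment across the planned
comparisons (two, for the two phases).  Three or more groups: Welch's and
Brown-Forsythe's heteroscedastic ANOVAs followed by pairwise Dunnett-T3-style
tests (Welch pairwise t with a studentized-maximum-modulus family adjustment
evaluated via the independence bound `1 − P(|T_ν| < t)^m`), or
Kruskal-Wallis followed by Dunn's rank z tests with Bonferroni adjustment.
All tests are two-sided by default.  Empirical type-I error of the
two-group battery on null normal data (n = 15/15, 10,000 replicates) is
~0.05.

qPCR closed forms: primer efficiency `E = d^(−1/s)` from the dilution factor
`d` and standard-curve slope `s` (the textbook slope −3.32 for d = 10 gives
E = 2), flagged against the conventional acceptance band [1.9, 2.2]; fold
change `2^ΔCT_goi / 2^ΔCT_ref` with ΔCT = control − mutant, invariant to
uniform CT shifts.

## Numerical choices and edge behaviour

* Windows on time are half-open `[start, end)`; pixel rectangles are 0-based
  half-open (ImageJ's 1-px-grid convention converted at the parser).
* The rolling mean/minimum windows shrink at trace edges rather than padding.
* `detect_bouts` merges before applying the minimum-duration filter (two
  60-s bouts 5 s apart become one 125-s bout at the default 10-s merge gap).
* Tie-break in `suggest_hatch`: the earlier of equal steps.
* Values exactly at the noise threshold survive thresholding (strict `<`).
* MGV reductions flatten ROI pixels to a contiguous row-major copy before
  averaging so results are bit-identical to a per-pixel reference loop.

## Known limitations

* The hatching discontinuity contaminates the rolling baseline for half a
  window (~7.5 s) before the crop point; on default synthetic traces this
  adds one short spurious bout and a fraction of a percent to the neurogenic
  sum.  Annotating hatch a few seconds early removes it if it matters.
* Spectrogram amplitudes depend on the documented normalisation and taper;
  only within-pipeline comparisons are meaningful.
* AVI reading requires an imageio video plugin (ffmpeg/pyav) at runtime;
  TIFF is the lossless, always-available path.
* The Dunnett T3 family adjustment uses the independence bound rather than
  the exact studentized-maximum-modulus tables; adjusted p-values are
  slightly conservative.
* Problem sizes in the test-suite cohorts (12 embryos per genotype, 7.5-h
  recordings at 4 Hz) were chosen to exercise every stage at realistic scale
  while keeping the suite quick to run.
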