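# Methods

`tbslice` re-implements, as a tested library, the quantification procedures
used in theta-burst magnetic-stimulation experiments on entorhino-hippocampal
slice cultures: stimulation-protocol timing, c-Fos positive-cell counting,
miniature-EPSC event statistics, time-lapse dendritic-spine analyses
(including the diagonal-averaged "unit matrix" correlation statistic), the
calcium-imaging activity pipeline, and the statistical decision layer that
ties them together.  Because no raw recordings are available at desk scale,
every stage is paired with a synthetic-data generator that produces inputs
with known ground truth; the test suite and `scripts/acceptance.py` verify
each stage by parameter recovery against that truth.

## Stimulation protocol

The iTBS600 protocol packs 600 pulses into 3-pulse bursts at 50 Hz, bursts
at 5 Hz, with 10 bursts per duty cycle and 20 cycles.  We place the time
origin at the first pulse and measure the 8-s inter-cycle interval from the
end of the 2-s burst-train window, so one duty cycle spans exactly
`bursts_per_cycle / burst_rate + inter_cycle_gap` = 10 s and the last pulse
falls at 191.84 s.  Protocol descriptions of this family do not always fix
whether the silent interval is measured window-end-to-cycle-start or
pulse-to-pulse; the window-based reading is the one under which 2 s of
bursts plus an 8-s interval tile the timeline in exact 10-s cycles.
`segment_train` inverts the generator with
two gap thresholds (defaults 0.1 s and 1 s, between the protocol's
intra-burst 0.02 s, inter-burst 0.2 s and inter-cycle ~8 s spacings) and is
property-tested as an exact round trip.

The 11-point imaging schedule of the spine experiment is packaged as
`ImagingSchedule`: daily scans on days 0-4, stimulation one hour after the
day-4 scan, hourly scans for five hours post-stimulation, and a final scan
24 h post-stimulation.  Times are hours from the first scan; the 24-h
analysis window comprises the 7 labels from the day-4 baseline onward.

## c-Fos counting

Counting follows the particle-analysis macro logic: maximum-intensity
projection of the five planes centered on the stack midpoint (start index
`(z - n) // 2`, deterministic for even depths), Otsu binarization computed
on the masked region (gain-invariant), 8-connected component labeling, and
filtering by area (default 30-500 px²) and circularity `4πA/P²`.
Circularity is capped at 1.0 before filtering — the ImageJ convention —
because discrete perimeter estimates can push digitized discs slightly
above the theoretical maximum.  The original macro's threshold rule and
filter ranges are not published, so all are exposed in configuration and
the defaults are stated here rather than claimed as reproductions.
Normalization divides each culture's raw count by the mean count of the
control cultures in the same batch and region; control means are exactly 1
after normalization by construction.

## mEPSC analysis

The original recordings were scored with a proprietary detector, so the
detector here is our own and is documented rather than claimed equivalent.
Events are negative biexponential deflections (default rise 0.5 ms, decay
4 ms) on a noisy baseline.  Detection: (1) rolling-median baseline
subtraction (51-ms window); (2) 1-ms boxcar smoothing; (3) robust noise SD
from the median absolute deviation of the smoothed residual; (4) candidate
minima below 3x that SD, merged within a 5-ms refractory window;
(5) acceptance of candidates whose waveform correlates with the
biexponential template (r >= 0.6) *and* whose smoothed peak exceeds 4.5x
the robust SD.  The two-part acceptance matters quantitatively: at 10 kHz a
3-SD threshold alone admits hundreds of smoothed noise dips per minute; on
synthetic traces with event amplitude 5x the raw noise SD, false candidates
peak below ~5 SD of the smoothed trace while true events exceed ~6.7 SD, so
the scale criterion removes nearly all false positives while recall stays
at 1 (measured precision/recall ~0.97/0.98).  Amplitude is taken from the
unsmoothed residual at the peak; area integrates the smoothed deflection
from onset (walk-back to baseline) to return-to-baseline or 10 decay
constants, whichever comes first.

Group statistics follow the standard conventions: per-neuron histograms of
amplitudes or areas normalized to unit sum and averaged without weighting
(neurons with no events are excluded with a warning); event frequency =
count / duration; and the summated area rescaled to a standard two-minute
recording, `(sum of areas) x 2 / duration_in_minutes`.

## Spine-trajectory analyses

Spine sizes (arbitrary fluorescence units) are tracked per dendritic
segment over the 11-point schedule; within a segment, spine IDs are ordered
so that adjacent IDs are physically closer.  Analyses:

* **Baseline normalization** divides every spine's series (and every
  segment's density series) by its own day-4 value.
* **Size-binned change**: Δ = (size(t) − size(day4)) / size(day4), binned
  by day-4 size with right-closed edges labeled by their upper limits;
  default edges are the day-4 quantiles {0.2, 0.4, 0.6, 0.8, 1.0}.  The
  original figure's edges are not recoverable from text, so edges are
  explicit configuration for any reproduction attempt.
* **Classification**: enlarged iff size(t) > size(t_ref); ties count as
  shrunk (conservative toward enlargement claims).  Transition tables count
  enlarged/shrunk paths between 2 h and 24 h over co-observed spines.
* **Correlation matrices**: Pearson correlation (Spearman available by
  configuration) of raw size series over the 7-point 24-h window.  Raw rather than normalized sizes are used because
  Pearson correlation is scale-invariant, so the choice only affects which
  series are flagged constant.  Constant series yield NaN entries that are
  carried, not zero-filled.
* **Unit matrix**: the elementwise mean of all `n − k + 1` contiguous
  k x k principal submatrices sliding along the diagonal (k = 15), which
  makes correlation structure comparable across segments with different
  spine counts.  NaN entries are excluded per cell with support counts
  recorded.  Segments with fewer than 15 spines are skipped rather than
  padded — padding would fabricate correlations.  Variance maps are the
  per-cell sample variance across unit matrices.

## Calcium pipeline

Per-unit traces are the mean intensity over each label's pixels, frame by
frame.  The activity metrics are computed on ΔF/F0 = (F − trend) / F0 where
the trend is a centered rolling median (reflection-padded) and F0 is the
mean of the trend — a robust baseline insensitive to transients ("trend
mean"; a whole-trace-mean option exists).  The even-window median takes the
upper-middle order statistic, which reproduces the center value exactly on
constant and affine segments.

**Detrend window.**  Rolling-window settings quoted as a bare "20" are
ambiguous between frames and seconds when the acquisition rate is not
fixed.  A median baseline is only
robust if the window is long relative to the transient: at 10 Hz a
20-*frame* (2-s) window centered on a GCaMP6f-like transient (decay 0.6 s)
contains more elevated frames than baseline frames, so the median tracks
the transient and clips it by ~40% of its peak — enough to push events
below the detection threshold and bias recovered spike rates by −30 to
−50%.  `analyze_traceset` therefore interprets the rolling window as 20
*seconds* of data by default (200 frames at the default 10 Hz); the
`detrend_rolling_median` function itself keeps its frame-based `window=20`
parameter for direct use.  With this reading, spike-rate recovery bias on
synthetic traces is within 10% across 0.5-2 spikes/min at SNR 5.

**Spike detection** thresholds at mean + 3 SD of the ΔF/F0 trace (SD over
the full trace, matching the stated rule) and counts upward crossings
separated by at least 1 s.  A crossing is confirmed only if two or more
frames exceed the threshold within 0.5 s — indicator transients hold
several frames above threshold, single-frame noise excursions do not;
without this, independent frame noise alone produces ~0.8 false
spikes/min at 10 Hz.  Trace AUC is the trapezoid integral of the signed
ΔF/F0 trace (a clip-at-zero option exists); spectral AUC integrates the
one-sided Welch periodogram over a configurable band.  Synchrony is the
mean Pearson correlation over all unit pairs in a culture.

## Statistics

* **Mann-Whitney U**: for combined n ≤ 20 the p-value is exact over all
  C(n, n1) group labelings of the pooled values, computed by dynamic
  programming over midrank sums (midranks make the enumeration correct
  under ties); the null U distribution is symmetric about n1·n2/2 and the
  two-sided p is the probability of a deviation at least as large as
  observed.  Larger samples use the tie-corrected normal approximation.
* **Chi-square** on 2x2 tables: Pearson statistic, df = 1, continuity
  correction off by default.
* **Mixed-model decision rule**: the group effect is the fixed-effect
  coefficient of a random-intercept model (clusters = neurons or cultures,
  statsmodels MixedLM, REML).  Confidence intervals are reported at 95, 99,
  99.5, 99.9, 99.95 and 99.99%; an effect is significant at a level iff
  that CI excludes zero.  Because the group indicator is a cluster-level
  covariate, intervals use a t reference with clusters − 2 degrees of
  freedom (the between-within correction); with plain normal quantiles the
  95% interval covers the truth in only ~92.5% of clustered null
  simulations at 8 clusters per group, versus ~95% with the correction.
  With fewer than two clusters in a group the model is unidentifiable and
  an OLS interval is reported with a logged caveat.

## Synthetic-data generators

All generators are bit-reproducible given (parameters, seed).

* **Calcium** (`CalciumSimParams`): Poisson spikes per unit (default
  1/min; stimulated group multiplies the rate by 2) convolved with a
  difference-of-exponentials kernel (rise 0.1 s, decay 0.6 s, GCaMP6f-like)
  peaking at `transient_amplitude x baseline` (default 0.25, i.e. peak
  ΔF/F0 = 0.25), on a baseline with sinusoidal drift (5% amplitude, 120-s
  period) and Gaussian noise (5% of baseline — SNR 5 against the default
  transient).  A renderer turns a trace set into a movie + label mask whose
  mean-intensity extraction returns the traces exactly.
* **Spines** (`SpineSimParams`): log-sizes start at N(0, 0.4²) and follow a
  mean-reverting update (rate 0.3/day) with per-scan-step innovations
  (SD 0.15) whose cross-spine correlation decays with ID distance as
  exp(−d/4), rescaled so adjacent spines correlate at +0.5 and the most
  distant pair at −0.2 (positive-definiteness of the resulting matrix is
  checked at construction; the defaults have minimum eigenvalue ~0.41 at 20
  spines).  Innovations are per scan step rather than per unit time — the
  schedule's hourly and daily steps carry equal fluctuation — which keeps
  the generator simple and matches how fluctuations enter the analyses.
  The stimulated condition adds a 30% enlargement to the smallest day-4
  tercile at every post-stimulation scan.  Mean reversion acting on extreme
  baseline sizes produces the small-spines-grow / large-spines-shrink
  pattern; note that baseline-binned change analyses also receive a
  regression-to-the-mean contribution from fluctuation noise, which is one
  reason the real experiment contrasts stimulated against control rather
  than against zero.
* **mEPSC** (`MepscSimParams`): Poisson events (1 Hz) with log-normal
  amplitudes (median 15 pA, log-SD 0.35), negative biexponential kernel
  (0.5/4 ms), Gaussian noise (3 pA), 10 kHz sampling, 120 s.  Truth areas
  use the analytic kernel integral.
* **c-Fos** (`CfosImageParams`): non-overlapping ellipses (equivalent
  radius 4-9 px, eccentricity 0-0.6) at fixed intensity over optional
  Gaussian background noise, rendered across 7 z-planes with a Gaussian
  z-profile brightest at the midpoint.  The truth count re-measures every
  blob on its own isolated rendering with the same area/circularity
  definitions the counter uses, then applies the default filter ranges.

### What the generators do not emulate

Real recordings contain bleaching and focus drift beyond a single slow
sinusoid, overlapping cells and uneven staining, spatially correlated
(non-white) imaging noise, electrode drift and access-resistance changes,
missing spine observations, and non-Poisson (bursty) event statistics.
Passing recovery tests on these generators therefore demonstrates that the
analysis chain is implemented correctly and is unbiased under its own
assumptions — not that it would be unbiased on real data.

## Problem sizes

The verification suite uses 100 units per condition for calcium rate
recovery (300-s traces), five 60-s traces for mEPSC precision/recall, 50
random c-Fos fixtures, 1000 clustered replicates for mixed-model coverage,
30-40 replicates of 200-segment ensembles for the spine drift pattern, and
100-segment paired ensembles for the unit-matrix contrast.  These sizes
keep Monte-Carlo error comfortably below the tolerances being checked.

## Known limitations

* Equivalence with the proprietary event detector used on the original
  recordings cannot be established; only parameter recovery on synthetic
  truth is claimed.
* The LMM intervals are Wald-type with a between-within df correction, not
  profile or Satterthwaite intervals; coverage is validated by simulation
  only for the balanced designs exercised here.
* The c-Fos macro's true filter parameters are unknown; counts on real
  images would require calibrating the exposed configuration.
* The unit-matrix statistic is only computed for segments with at least 15
  spines, matching the analysis convention rather than imputing data.
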