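# Methods

This note documents the analysis model, the synthetic-signal generator,
the numerical choices, and what the test suite does and does not
establish about real recordings.

## The measurement model

FTCD laterality analysis treats the two middle-cerebral-artery velocity
traces as proportional to perfusion in the two hemispheres. Because the
insonation angle and vessel geometry make the raw device units
incomparable between probes (and between sessions), all inference is
performed on *relative* changes: each channel is normalized so that its
mean over all included epochs is 100, and each trial is baseline
corrected against the 10 s preceding the "Clear Mind" cue. After those
two steps, a task-evoked velocity increase of x% of baseline appears as
a value of ≈ x in normalized units, and the left-minus-right difference
over the period of interest (POI) is the laterality index (LI) in
percentage points.

### Preprocessing chain

1. **Downsampling** 100 → 25 Hz by non-overlapping block means. Block
   averaging is the simplest deterministic anti-alias consistent with
   "downsampling"; the marker channel uses block *max* so no rising
   edge can be lost.
2. **Epoching** from −11 to +30 s around the cue (−11 to +26 s for the
   overt paradigm). The device flags the letter cue, not the "Clear
   Mind" cue, so epoching subtracts a configurable `marker_offset_s`
   (5 s covert, 3 s overt) first.
3. **Manual exclusion** of trials with visible spiking/dropout, loaded
   from per-participant sidecar files so deposited exclusion lists can
   be replayed.
4. **Extreme-value screening**: per channel, samples beyond the
   0.0001–0.999 empirical quantiles of all included-trial samples are
   flagged. A trial with exactly one flagged sample has it replaced by
   that trial/channel's mean (computed excluding the flagged sample, so
   the artifact does not contaminate its own replacement); a trial with
   two or more is excluded. Quantiles use the linear-interpolation
   ("type 7") convention, the default of the statistical environments
   these pipelines are usually written in, and are computed per
   participant × language × channel.
5. **Normalization** to a per-channel grand mean of 100 over included
   trials. Per channel rather than pooled, because probe gains differ.
   Excluded trials are transformed alongside for diagnostics but never
   re-enter any statistic.
6. **Heart-cycle integration**: systolic peaks are detected on the mean
   of the two channels (both arteries share the cardiac cycle) with a
   minimum peak distance of 60/`max_hr_bpm` s (defaults 40–150 bpm) and
   a prominence floor of ¼ of the epoch's 10–90 percentile spread. Each
   channel is replaced by its per-cycle mean, anchored at cycle
   midpoints and linearly interpolated back onto the 25 Hz grid; samples
   outside the first/last midpoint take the nearest cycle's mean.
   Epochs with fewer than two detectable peaks are excluded
   (`no-pulse`). This step is the one non-idempotent operation in the
   chain (integrating an already-flattened series finds no pulse), so
   the stage machinery refuses to re-run it.
7. **Baseline correction**: per trial and channel, the mean over
   −10–0 s is subtracted.
8. **Range rejection**: trials containing normalized values below 60 or
   above 140 are excluded. Although this is the last step, the 60–140
   window only makes sense on the mean-100 scale, so the screen is
   evaluated on the normalized, pre-baseline-corrected values (step 7
   snapshots them). After baseline correction values centre on 0 and
   the window would reject everything; this is the only
   order-consistent reading.

Steps must run in order; exclusions are monotone (no step re-includes a
trial); participants with fewer than 15 usable trials in any condition
(strict "fewer than": 15 itself is kept) are excluded entirely.

### Laterality estimation and screening

The mean-method LI is the POI mean of L − R of the grand-average
waveform; by linearity it equals the mean of the per-trial LIs, whose
sample SD/√n is the participant's SE. The categorization CI is
two-sided 95% Student-t with n−1 degrees of freedom — appropriate at
~20 trials; the legacy peak method uses a 2 s window (±1 s) centred on
the largest |L − R| in the POI, earliest sample winning ties. The
SE-outlier rule pools the SEs of all datasets (both languages) into one
distribution — the rule speaks of the SEs "among all participants"
without separating languages — and flags a participant whose SE exceeds
Q3 + 2.2·IQR in *either* language.

### Group statistics

Split-half reliability assigns odd/even parity from presentation order
*before* any exclusion (an excluded trial simply vanishes from its
parity class) and correlates cohort odd-LIs with even-LIs by Spearman.
The L1–L2 agreement analysis reports the Spearman correlation, the
fraction of paired differences within a ±2.5 repeatability bound (the
bound expected to contain 95% of differences when two measures of this
reliability are equivalent), and the JZS Bayes factor of the paired
t-test:

    BF10 = ∫ (1+ng)^(−1/2) (1 + t²/((1+ng)ν))^(−(ν+1)/2) π(g) dg
           ÷ (1 + t²/ν)^(−(ν+1)/2),   ν = n − 1,

with π(g) the inverse-gamma(½, r²/2) mixing density of a Cauchy(0, r)
effect-size prior, r = √2/2. The integral is evaluated by adaptive
quadrature after the substitution g = u/(1−u) (relative tolerance
1e-8); an independent Monte-Carlo mixture estimate serves as the test
oracle. Results carry both directions; printed reports use the
convention of the R `BayesFactor` package, where values < 1 favour the
null of equal means. The age-of-acquisition contrast uses Welch's
t-test (groups of this kind are small and unbalanced, so pooling
variances is unsafe); "early" acquisition means strictly before 6
years.

## The synthetic generator

Each channel is synthesized at 100 Hz as

    v(t) = g(t) · B · (1 + A·c(t)) · (1 + r(t)/100) + ε(t)

with baseline velocity `B` (60/55 device units left/right), raised-
cosine systolic pulse train `c(t)` (amplitude `A` = 0.35 of baseline,
participant heart rate ~ Normal(70, 8) bpm, per-cycle period jitter
Normal(0, 3%) truncated at ±10%), white Gaussian noise ε (SD 3% of
baseline), slow multiplicative gain drift `g(t)` (piecewise linear
between trial onsets, node SD 3%), and a task response `r(t)` in % of
baseline: a ramp starting at word-generation onset reaching plateau
after a 3 s hemodynamic lag, held until generation ends, decaying over
5 s. The plateau amplitude is `gain + λ/2` on the left and
`gain − λ/2` on the right (bilateral gain 4%), so the true lateralized
difference is λ percentage points. Trial-to-trial attentional
fluctuation jitters λ by Normal(0, 1.0 pp) per trial — this is what
gives single-trial LIs a realistic nonzero SE (~0.2–0.4), makes the
SE-outlier rule and split-half reliability non-vacuous, and places
cohort split-half Spearman around 0.8–0.9.

Two design points matter:

* **Exactness by construction.** The pipeline normalizes by the
  whole-epoch mean, which includes the response itself, so a naive x%
  response would recover slightly less than x (a relative shrinkage of
  about the epoch-mean response fraction). The generator pre-compensates
  the emitted amplitudes by that analytically computed factor, so the
  population LI equals λ exactly; with stochastic terms switched off
  (`SyntheticConfig.noiseless()`) the pipeline recovers λ to within
  ~0.01 pp, the residual being heart-cycle interpolation and epoch-edge
  effects.
* **Tail structure.** An empirical-quantile screen flags a fixed ~0.1%
  of samples *wherever they lie*. In real recordings those tail samples
  come overwhelmingly from artifacts and slow drift concentrated in a
  few trials, which is why the screen removes few trials in practice.
  A generator with only white noise would scatter its extreme samples
  uniformly over trials and the ≥2-extremes rule would reject most of
  them. The gain drift and burst-shaped artifacts (spikes: 0.2–0.8 s
  multiplicative bursts ×3–10 on both channels, as headset motion
  produces; dropouts: 0.2–0.5 s single-channel zero-clamps) concentrate
  the tails so the screen behaves as on real data. With default rates
  (0.06/0.04 events per trial) about 20% of trials are excluded —
  deliberately on the conservative side of real cohorts (~6%), so the
  downstream minimum-trial logic is exercised.

Randomness is organized as one root seed with per-participant
substreams (participant index as spawn key), so enlarging a cohort
never reshuffles earlier participants, and identical configurations are
bit-identical.

**What passing tests do not show:** the generator has no respiratory or
vasomotion band, no autocorrelated measurement noise, no asymmetric
vessel anatomy, and its artifact taxonomy is crude. Recovery and
calibration results therefore validate the *pipeline arithmetic* and
its screening logic, not FTCD's physiological validity; absolute
exclusion rates and reliability coefficients on real data will differ.

## Numerical and design choices

* Marker onsets are rising-edge crossings of a configurable threshold
  (default 1.0) debounced at 10 s — shorter than any inter-trial
  interval in either paradigm; markers are extracted at the full
  100 Hz before downsampling so onsets keep sample precision.
* The overt paradigm's epoch window is −11 to +26 s (covering the
  −10–0 s baseline and 6–20 s POI within its 36 s trial); its trial
  count defaults to 20.
* Degenerate inputs raise rather than warn: zero channel mean at
  normalization, empty baseline or POI slices, < 2 trials for an SE,
  zero-variance t-tests.
* Quantile convention everywhere is linear interpolation (type 7).
* Ties in peak location resolve to the earliest time; Bland–Altman
  "within bounds" is inclusive (|d| ≤ bound); SE-outlier flagging is
  strict (> threshold), so an all-equal SE cohort flags nobody.
* With fewer than 4 participants the SE quartiles are not meaningful:
  the filter logs a warning and flags nobody.
* Test problem sizes: cohort-level checks use 24 participants × 23
  trials (the design the defaults emulate); the null-calibration check
  uses 1000 single-language participants, enough for a ±1% binomial
  band around the nominal 2.5% one-tail rate.

## Known limitations

* The exp-export reader is a tolerant best-effort parser (skip
  non-numeric lines, take the first four numeric columns); real device
  exports should be spot-checked against it before a reproduction run.
* Heart-cycle integration assumes both channels share peak timing; in
  severe unilateral signal loss the shared-peak assumption degrades
  gracefully (the epoch is usually excluded as `no-pulse` or
  out-of-range) but is not separately modelled.
* The screen/normalization interaction means LI values are only
  comparable across analyses run with the same paradigm configuration.
* Whether the original pipelines pooled extreme-value quantiles across
  channels, and how they interpolated after cycle averaging, are not
  documented; the choices here (per-channel quantiles, midpoint-linear
  interpolation) are stated so they can be changed in one place.
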