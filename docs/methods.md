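# Methods

This note documents the models, estimators and numerical choices behind
`traceblink`, and what the synthetic sessions do and do not establish
about real recordings.

## Synthetic sessions

The generator emulates a wide-field CA1 recording during trace
eye-blink conditioning: 20 Hz frames; trials of 350 ms tone, 250 ms
trace interval, 100 ms puff; inter-trial intervals drawn uniformly on
35 ± 5 s ("pseudo-randomized"); a 1024 × 1024 pixel field at
1.312 µm/pixel. Defaults (all overridable on `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| `basal_rate` | 1.7 events/min | Poisson background event rate per cell |
| `resp_fraction_co` / `resp_fraction_ex` | 0.15 / 0.11 | fraction of cells tone-locked during conditioning / extinction |
| `overlap_jaccard` | 0.10 | Jaccard overlap of the two identities |
| `resp_prob_co` / `resp_prob_ex` | 0.13 / 0.07 | per-trial probability a responsive cell emits one event in the 1 s post-tone window |
| `kernel_rise` / `kernel_decay` | 0.1 s / 0.6 s | difference-of-exponentials indicator kernel, unit peak |
| `noise_sd` | 0.1 | white-noise SD as a fraction of unit event amplitude |
| `cr_prob` | 0.65 | per-trial probability of a conditioned eye closure |
| `spont_closure_rate` | 0.2 | fraction of 600 ms non-stimulus windows containing a spontaneous closure |

Responsive fractions, per-trial response probabilities, the basal rate,
the spontaneous-closure rate and the trial geometry mirror the recording
conditions the analysis was designed for; the kernel is a generic fast
indicator (any rise slower than 2 frames and decay under 5 s behaves
equivalently; both time constants are parameters).

**Noise level.** `noise_sd = 0.1` (peak SNR 10) reflects somatic
GCaMP6f transients in wide-field imaging, which sit an order of
magnitude above the shot-noise floor. This choice is also structural:
the detector excludes events with amplitude below 7 SD of the preceding
trace, so a generator emitting unit-amplitude events in noise with
SD > 1/7 would, by construction, produce *undetectable* events and
could not emulate a recording in which the method operates.

**Eye traces.** Closures are trapezoidal dips (150–400 ms long, 3–8%
deep); puff-evoked closures are deeper (45%) and sustained (1 s), so
they always exceed conditioned dips. Spontaneous dips are placed as a
Poisson process in the non-stimulus periods with intensity
λ = −ln(1 − r)/(E[L] + w − 1), where r is the target per-window closure
rate, w = 12 frames, and E[L] (the mean sub-threshold span of a dip) is
estimated from the dip-shape distribution itself; this makes the
*measured* sliding-window closure rate match `spont_closure_rate` in
expectation rather than only the dip count.

**Seeding.** A single master seed fans out through
`numpy.random.SeedSequence` spawn keys into per-purpose and per-cell
substreams, so enlarging the population leaves existing cells'
trajectories bit-identical, and generation is reproducible across runs.

What the generator does *not* model: neuropil/scattering background
(the background-subtraction stage is exercised with explicit background
traces), amplitude heterogeneity across events, bursting, slow drift in
fluorescence or eye area, motion artifacts, and eye-video segmentation
noise. Passing tests therefore establish correctness of the estimators
under the stated statistical structure, not robustness to every
pathology of real data.

## Baseline normalization

The baseline is the mean of a normal distribution fit to the values at
or below the trace's 50th percentile (inclusive), on the assumption of
Gaussian noise around a true quiescent level with sparse positive
transients. A plain Gaussian MLE on that truncated subsample is biased
low by ≈ 0.8 σ; the default estimator instead reflects the lower-half
sample about its maximum to restore symmetry before taking the mean,
which cancels the truncation bias exactly (algebraically the estimate
equals the trace median, hence exact scale-equivariance and robustness
to transients occupying up to half the trace). The naive truncated MLE
is available as `method="truncated_mle"` for comparison.

## Event detection

Per trace: multitaper spectrogram with a 20-frame (1 s) window sliding
in 1-frame (50 ms) steps, time-bandwidth 2 with 3 DPSS tapers, each
window demeaned; power is averaged over the bins in (0, 2] Hz (DC
excluded). Candidate onsets are outliers of the power first difference
beyond 3 scaled MADs (consistency constant 1.4826; the unscaled MAD is
an option) from its global median. Within a run of consecutive
outliers, the first member of each positive stretch is a candidate, so
a run spanning two overlapping transients yields both onsets.

Numerical choices that matter:

* **Onset reference.** The power first jumps when the transient enters
  the window's trailing edge, so a candidate maps to the *end* of the
  offending window (start and center are options). The onset is then
  refined backward from the event peak to the last frame at or below a
  level 20% up the transient (at least 2 noise SDs above the local
  pre-event median); on clean transients this recovers the true onset
  frame exactly, which matters because the amplitude is measured from
  the onset sample.
* **Peak.** First local maximum after the candidate with prominence
  above the trace's robust noise SD; candidates that resolve to the
  same peak merge into one event.
* **Amplitude gate.** Events with amplitude below 7 SD of the trace in
  the 10 s before onset are discarded. The gate's SD defaults to a
  first-difference noise estimate (scaled MAD of the differenced
  window / √2): slow calcium transients have frame-to-frame slopes well
  below the noise, so this estimates the noise floor even when other
  events fall inside the window, whereas a plain SD (available as
  `sd_estimator="plain"`) is inflated by any preceding transient and
  censors closely spaced events. Onsets within 10 s of the recording
  start fall back to the first second of trace, logged.
* A noiseless trace has MAD 0; any nonzero power change then counts as
  an outlier, keeping isolated transients detectable in degenerate
  synthetic inputs.

Measured on synthetic sessions at defaults: onset error ≤ 2 frames,
recall ≈ 0.95 and precision ≈ 1.0 at ±5-frame matching, recovered basal
rates within 15% of configured values across 0.5–4 events/min (the
residual deficit comes from genuinely overlapping transients less than
~1 s apart, which no onset-based detector can split). On pure noise the
detector reports < 0.2 events/min.

## Responsive cells

The binarized trace is 1 on rising phases. The per-cell null draws, per
shuffle, 20 disjoint 1 s segments uniformly from the non-stimulus mask
(frames more than 2 s before or 8 s after any tone onset) and averages
the binary trace over them; 1000 shuffles form the null distribution.
Segments are drawn per cell, per shuffle, from independent seeded
substreams; disjointness uses vectorized rejection sampling with a
seeded greedy fallback. Cells whose mask cannot host 20 disjoint
segments are rejected with an error. A cell is responsive when its mean
binary amplitude over the twenty 1 s post-tone windows *strictly*
exceeds the null's 95th percentile (ties are not responsive; the
percentile uses linear interpolation). Latency is the mean first-event
delay over trials with an in-window event, undefined otherwise.

Calibration measured by the acceptance suite: on 2000 cells with no
tone-locking the criterion flags ≈ 5%, as the 95th-percentile threshold
implies. Power at the default conditions is intrinsically limited: with
a 13% per-trial response probability, a quarter of truly responsive
cells fire on ≤ 1 of 20 trials and are statistically indistinguishable
from the basal null, capping achievable sensitivity near ~0.6–0.65 even
with perfect event detection.

## Behavior

Eye area is normalized by the session mean. The "standard eye area"
line is fit in two passes: least squares on the central 95%
value-percentile band, then a refit on frames whose residuals lie
within ±1.96 robust SDs — the central 95% of the noise distribution
about the line. The second pass is what makes the fit insensitive to
closures, which are one-sided and can occupy more of the session than a
percentile trim can remove. The CR threshold is 2% *of* the line below
it (multiplicative, hence invariant to uniform rescaling of the area
trace). A trial is a CR when the area crosses below threshold in the
half-open window [tone onset, puff onset): the tone-onset frame counts,
the puff-onset frame does not. Spontaneous closures slide a 12-frame
window in 1-frame steps across windows fully contained in the
non-stimulus mask.

## Networks

Per trial, cells with an event onset in [tone, tone + 1 s) get a 1; the
outer product of that vector with itself is the single-trial
co-occurrence matrix, and trial sets are combined by summation. Edges
connect responsive-union cells with any non-zero lower-triangle count
("any value greater than zero"; weighted counts are stored on the edges
but not used for edge existence). Spectral biclustering (scikit-learn,
3 × 3 grid, fixed seed) is a presentation aid for co-modulated groups
and feeds no quantitative statistic. Density and degree are 2m/n(n−1)
and 2m/n; edge and cell overlaps are Jaccard indices in percent, and
2 × 2 contrasts of shared versus unshared counts use two-sided Fisher's
exact tests.

## Spatial statistics

Neighbour-identity fractions average, over labeled cells, the
percentage of other cells within 100 µm (76 px) sharing the label
(cells with no neighbour are skipped). The bootstrap reassigns the same
number of labels uniformly (1000 draws) and reports a two-tailed
empirical p, floored at 1/n_boot. Co-registration rasterises ROI masks,
estimates a translation by FFT cross-correlation (rotation not
modeled), then matches ROIs greedily in ascending centroid distance
subject to both criteria: centroids within 50 px and pixel overlap of
at least 50% — fractional to the *smaller* ROI by default ("first",
"second" configurable), the conservative reading when ROI sizes differ.

## Pipeline conventions

Trial blocks follow the experimental design: the final 20 CS-US trials
define a training session, extinction is the first 20 CS-only trials,
and within-day stability is estimated from trial blocks 1–20 vs 21–40
of a late training session. Heat-map sorting averages trials on
[tone − 2 s, tone + 8 s], subtracts the mean of the 12 pre-tone frames,
and orders cells by descending mean fluorescence in the 12-frame
tone–puff window, with stable (cell-id) tie-breaking; an external
permutation reproduces matched-cell comparisons across sessions.
Summaries carry the seed and a config hash; re-running with the same
config and seed reproduces every output bit for bit.

## Problem sizes

The test and acceptance suites run desk-scale versions of the study:
100–2000 cells, 20–60 trials, 12–30 minute sessions, 20 seeds for the
population-separation property. These sizes give the statistics quoted
above (binomial/Poisson standard errors of a few percent) while keeping
the full suite to a few minutes on one core.

## Known limitations

* Events are homogeneous in amplitude; amplitude-dependent behaviour of
  the 7-SD gate (e.g. censoring of small events after large ones under
  the plain-SD variant) is exercised only qualitatively.
* Overlapping transients within ~1 s merge into one detected event, so
  recovered rates under-shoot by several percent at high event rates.
* The co-occurrence analysis is onset-based by design; rising-phase
  overlap variants are out of scope.
* Rotation and non-rigid deformation are not handled in co-registration.
* Eye analysis starts from area traces (or binary mask stacks); raw
  eye-video segmentation is upstream of this package.
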