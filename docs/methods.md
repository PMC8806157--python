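# Methods

This note records the models, numerical choices and known limitations of
the package, in the order the pipeline applies them.

## Scope and data model

The pipeline starts from extracted ΔF/F traces (one per somatic ROI),
a raw LFP channel and a stimulus-onset table; ROI extraction,
motion/bleach correction and acquisition are upstream. All times are
seconds from recording start, with sample timestamps at sample centres
(frame *k* at *(k + 0.5)/rate*), which removes 0/1-based frame ambiguity.
On-disk formats are plain CSV with mandatory headers (written with 17
significant digits and read with exact round-trip float parsing, so
write→read is bit-identical) or a single HDF5 container with datasets
`/dff`, `/lfp`, `/stimuli`. Acquisition-sync recovery is out of scope: an
explicit per-session alignment offset (default 0) shifts the LFP clock.

## ROI quality control

Geometry criteria (inclusive bounds): roundness = perimeter²/(4π·area)
≤ 2.2, oblongness = major/minor second-moment axis ratio ≤ 3.6, area in
[5, 500] px. These formulas are standard, dimensionless and
orientation-invariant; upstream extraction tools define their metrics
internally, so both are configurable stand-ins and are computed with
`skimage.measure.regionprops`/`perimeter` (a rasterized disk of radius 10
scores roundness ≈ 1.09, oblongness 1.0). Trace criteria: baseline drift
(worst sliding-100-frame linear-fit endpoint change relative to the window
median) ≤ 25%, baseline stability (mean of window medians over their SD —
an inverse coefficient of variation, large = stable) ≥ 1000, and zero
saturated frames; the saturation value of the source data must be supplied
(none is assumed otherwise). Skewness and kurtosis are recorded but never
used in the decision. Manual anatomical exclusion is represented as an
optional include-list, not automated. The stability metric's units are a
stated convention — the 1000 threshold is configurable and has no external
definition to check against.

## Detrending

Slow drift (bleaching, focal drift) is removed by LOWESS with a 100-frame
span and two robustness iterations. The trace is odd-extended (mirrored
about its endpoint values) by one span on each side before smoothing, so
boundary samples see full symmetric neighbourhoods and the smoother
behaves the same at the edges as in the interior; a straight line is still
removed exactly. The trend is recentred so the detrended trace has exactly
zero mean; the baseline fit below estimates any residual offset.

## Baseline and event detection

The noise model per ROI is estimated by iterative Gaussian fitting to the
histogram of all samples: Freedman–Diaconis bins, least-squares Gaussian
fit to bin counts, censoring of samples above μ + 2σ, refit, iterating to
relative σ change < 1e-3 (cap 20 iterations; a robust median/SD fallback
guards non-convergent fits). Censoring matters because transients
contaminate the upper tail: on traces with 10% of samples inside large
transients the naive whole-trace SD overestimates σ several-fold while
the iterative fit stays within a few percent.

An event is a maximal run of samples above μ + 2σ containing at least one
sample ≥ μ + 4σ, with start at the run's first sample, end at the first
sample after the run, peak at the run argmax. The 4 SD sample may occur
anywhere in the run (equivalent to a peak requirement for unimodal
transients). The inter-event interval is onset-to-onset. Detection runs at
the native 7.5 Hz on detrended traces — detecting on interpolated data
would manufacture resolution — and event times carry directly into the
aligned timebase because both share one clock. Thresholds are recomputed
per session. Sessions need ≥ 3 active ROIs (inclusive) to proceed.

## Alignment and sweeps

Calcium is linearly interpolated onto the 2 kHz grid (values at frame
times are preserved; beyond the first/last frame the edge value is held).
The LFP is decimated 20 kHz → 2 kHz with a zero-phase FIR anti-alias
filter (cutoff below the output Nyquist), preserving stimulus timing to
within half an output sample; the filter is applied even though
acquisition hardware low-passes at 2 kHz, because synthetic LFPs are not
pre-filtered. Sweeps run stimulus-onset to next-onset, truncated to a
common grid of at most 10 s, so 10 stimuli give exactly 9 sweeps; the
period after the last stimulus is not a sweep.

## Ensemble trace, epochs, patterns

Threshold-normalisation zeroes samples below each ROI's 4 SD threshold
and divides the rest by that ROI's session maximum: events are graded,
not binary, and baseline noise cannot create spurious ensemble structure.
The ensemble trace is the across-ROI mean.

Epoch detection operates on the sweep-averaged ensemble trace after a
50 ms moving-average smoothing (raw interpolated traces are
piecewise-linear and full of micro-extrema). Epoch 1 is the most
prominent local maximum in (0, 1] s with prominence ≥ 10% of the sweep's
dynamic range; epoch 2 is the minimum of [max(t₁, 1), 3] s; epoch 3 the
most prominent qualifying maximum in (t₂, 5] s. Equal-prominence ties go
to the earliest candidate. Absent epochs are reported as missing, never
as zero. Pattern typing formalises the visual classification: A when the
first maximum exists and dominates the second, B when the second maximum
exists and either no first maximum exists or it is dominated, C when only
the minimum exists. Smoothing window and prominence floor are
configurable; both were fixed before validation and the epoch-recovery
experiments run at these defaults.

The ensemble fraction counts an ROI as active when any detected event
interval intersects the 10 ms window centred on the epoch time — interval
overlap, not onset containment, because at 7.5 Hz native sampling only
interval overlap is meaningful at 10 ms scale. Per-stimulus fractions
apply the session-level epoch latency at each stimulus onset, matching
epoch determination on averaged sweeps.

## Similarity and the shuffle null

Per-stimulus binary activity patterns are compared with the normalized
Hamming distance (differing positions / length), averaged over all
unordered stimulus pairs within an epoch. Normalisation by length makes
slices with different ROI counts comparable. Hamming is defined for two
zero vectors (distance 0), which Jaccard and cosine are not — the reason
it is used for the ensemble-minimum epoch. Pairwise ROI correlation is
Pearson on detrended (not thresholded) traces; pairs with constant rows
are skipped and counted.

The null rotates each ROI independently by a uniform random number of
**whole frames** of the native series and recomputes the epoch metrics,
1,000 times by default. Frame-granular shifts are deliberate: detected
event boundaries lie on the frame-centre lattice, and with a stimulus
period that is a whole number of frames, so do the epoch windows. Shifts
drawn at finer granularity would let surrogate windows fall off that
lattice and systematically under-count boundary overlaps, biasing the
null low; with frame shifts the null is calibrated (observed values fall
inside the central 95% of their null ≈ 95% of the time on
stimulus-unlocked data). Epoch times are held fixed at the observed values
during shuffling by default; a re-detection mode recomputes epochs on each
surrogate's averaged sweep (using a precomputed per-ROI sweep-sum array,
so each surrogate costs one slice per ROI). Re-detection is the right
comparison when the observed epoch time is itself selected as an extremum
of the same data — the null then inherits the identical selection step —
and is what the calibration experiments use. Event counts and per-row
value multisets are conserved exactly under rotation; the ensemble-trace
time average is computed with exactly-rounded summation (`math.fsum`), so
its conservation under shuffling is bit-exact rather than
floating-point-approximate.

## LFP measures

Stimulus artifacts are found by threshold search on |V − median|, merging
crossings closer than 50 ms. fEPSPs are measured in a configurable 2–50 ms
post-stimulus window (first 2 ms blanked as artifact), referenced to a
10 ms pre-stimulus baseline, with negative-going polarity (stratum
radiatum convention) and magnitude reported; the window replaces manual
cursor placement. Slope is a linear fit over the 20–80% span of the rise
toward the peak, signed. The input/output curve maps intensity to mean
peak across a session's 10 stimuli; the test intensity is the smallest
whose mean response is 30–50% of maximum, falling back with a warning to
the intensity nearest 40%. LTP normalisation divides post-HFS peaks by the
baseline-session mean; a slice is flagged excluded when the mean
normalized amplitude across the post-HFS sessions is below 1 — the mean
across all three post sessions is used because the protocol text does not
single one out. HFS parameters (4 trains, 100 Hz, 1 s, 10 s ISI) are
stored and validated, never delivered.

## Synthetic sessions

The generator emulates the recording protocol: 50 ROIs × 720 frames at
7.5 Hz (96 s), 10 stimuli 10 s apart starting at 2 s, LFP at 20 kHz.
Per ROI: Gaussian noise (SD 0.02 ΔF/F), a slow additive drift (decaying
exponential, amplitude 0.01, τ 40 s, optional linear term), and
transients shaped as peak-normalised double exponentials (rise 50 ms,
decay 300 ms — representative GCaMP6f kinetics), amplitude 6× noise SD
with ×1–1.5 variability, evaluated in continuous time so onsets are not
frame-quantized. Spontaneous events are homogeneous Poisson at 0.2 Hz per
ROI — a placeholder within the range seen in active slice preparations,
chosen for recovery testing rather than as an estimate of any real
preparation. The LFP is noise (10 µV SD) plus a one-sample 5 mV artifact
per stimulus and a negative alpha-function fEPSP (0.5 mV, τ 5 ms, 3 ms
onset latency).

Evoked structure follows the three-epoch phenomenology. Pattern A: an
epoch-1 core (40% of ROIs) and a weaker epoch-3 core (15%); per stimulus,
core members participate with probability `p_repeat` (default 0.9) and
others with a 2% leak, with evoked onsets placed so transient peaks land
at the programmed latencies (0.4 s and 3.5 s) with 30 ms jitter. Pattern B
omits epoch 1; C omits both maxima. The ensemble minimum is modelled as
V-shaped suppression of the spontaneous rate over 1–3 s post-stimulus.
Because the ensemble trace is the event rate convolved with the
supra-threshold transient profile, the trace minimum trails the rate
minimum by about half a transient's persistence; the rate vertex therefore
leads the programmed minimum (1.8 s) by 0.2 s so the ground-truth label
marks where the activity minimum actually lands. Group profiles multiply
the spontaneous rate (HFHI-like: ×1.5) and membership reliability
(×0.72), mirroring elevated transient counts with degraded pattern
reliability.

What the generator does **not** emulate: pixel-level movies and ROI
cross-contamination, motion, genuine bleaching nonstationarity beyond the
smooth drift term, correlated noise across ROIs, indicator saturation and
nonlinearity, and realistic fEPSP waveform diversity. Passing recovery
tests therefore demonstrates the pipeline's correctness on data obeying
its stated assumptions, not robustness to every artifact of real
recordings.

## Validation experiment sizes

The acceptance experiments use 20 sessions for epoch/pattern recovery and
paired reliability comparisons, 100 stimulus-unlocked plus 40 evoked
sessions with 200-shuffle nulls for calibration, 20 sessions per group for
the cohort rate-ratio, 50 ROIs for detector sensitivity, ~10⁶ noise
samples for the 4 SD tail check, and 10⁴ random triples for the metric
axioms. These sizes give binomial standard errors comfortably inside the
asserted bands while keeping a full run in minutes.

## Known limitations

- Quartiles for outlier fences use the inclusive-median (Tukey hinge)
  method; other conventions move fences slightly.
- The stability threshold (1000) and the roundness/oblongness formulas are
  conventions standing in for tool-internal definitions.
- Epoch re-detection mode reports missing epochs on surrogates whose
  averaged sweep has no qualifying extremum; those iterations are dropped
  from that epoch's null.
- The fallback when no intensity lands in the 30–50% band (nearest to
  40%) is a formalisation of a judgement call and warns when it fires.
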