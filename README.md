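# ca1ensemble

Analysis of stimulus-evoked CA1 neuronal-ensemble dynamics from
simultaneous calcium imaging and local field potential (LFP) recordings in
acute hippocampal slices.

Experiments of this kind image ~100 GCaMP6f-expressing somata in stratum
pyramidale at 7.5 Hz (720 frames per session) while Schaffer-collateral
stimuli — 10 pulses, 10 s apart — evoke field responses recorded at 20 kHz
in stratum radiatum. The package takes extracted ΔF/F traces, the LFP and a
stimulus table, and produces per-session event, ensemble and similarity
metrics, together with a circular-shift chance level for each of them. It
is written for slice electrophysiologists and imaging labs who want this
analysis reproducible end to end, plus a seeded synthetic-session generator
so every stage can be validated without any recording.

## The analysis

**Calcium events.** Each ROI trace is detrended with locally weighted
regression (LOWESS), and its noise baseline (μ, σ) is estimated by
iteratively fitting a Gaussian to the histogram of all samples, censoring
values above μ + 2σ between refits. A calcium transient is a contiguous
excursion above μ + 2σ containing at least one sample at or above μ + 4σ;
start/end are the 2 SD crossings. Per-ROI features: count, frequency,
amplitude, duration, inter-event interval. Sessions with fewer than 3
active ROIs are excluded.

**Ensemble trace.** Per ROI, samples below the 4 SD threshold are zeroed
and the rest divided by that ROI's session maximum, so values lie in
[0, 1]; the across-ROI mean is the ensemble trace — the instantaneous
fraction-weighted activity of the ensemble. Calcium (upsampled from 7.5 Hz)
and LFP (decimated from 20 kHz) meet on a common 2 kHz clock, and the
ensemble trace is cut into 10 s inter-stimulus sweeps (10 stimuli → 9
sweeps) and averaged.

**Epochs and patterns.** The averaged sweep shows up to three epochs: a
first maximum within 1 s of the stimulus, an ensemble minimum at 1–3 s, and
a second maximum within 5 s. Sessions are typed A (dominant first maximum
plus minimum), B (second maximum plus minimum), or C (minimum only). The
**ensemble fraction** is the fraction of ROIs with a transient overlapping
a 10 ms window at each epoch time; the **ensemble distance** is the mean
normalized Hamming distance between the binary active-ROI patterns of
different stimuli (Hamming, unlike Jaccard or cosine, is defined between
two all-zero patterns — the typical case during the minimum).

**Chance levels.** Every epoch metric is compared against a shuffle null:
each ROI's time series is circularly rotated by an independent random
number of frames and the metrics recomputed, 1,000 times by default.

## Worked example

```python
import numpy as np
from ca1ensemble import AnalysisConfig, SyntheticParams, generate_session
from ca1ensemble.pipeline import run_session

bundle, truth = generate_session(SyntheticParams(seed=1))   # Type-A session
result = run_session(bundle, AnalysisConfig(rng_seed=1), n_shuffles=200)
ep = result.epochs
print(f"valid={result.valid}  active ROIs={result.n_active_rois}  sweeps={result.n_sweeps}")
print(f"pattern={result.pattern}  t1={ep.t1_s:.2f} s  t2={ep.t2_s:.2f} s  t3={ep.t3_s:.2f} s")
```

prints

```
valid=True  active ROIs=50  sweeps=9
pattern=A  t1=0.47 s  t2=1.69 s  t3=3.54 s
```

The generator programmed its first ensemble maximum at 0.4 s, the minimum
at 1.8 s and the second maximum at 3.5 s; the pipeline recovers all three
within the sweep-averaging tolerance and types the session A. Its epoch-1
ensemble fraction (0.440) sits far above the 97.5th percentile of its
200-shuffle null (0.172) — the stimulus-locked ensemble is nothing like
chance — while the epoch-1 Hamming distance (0.226) reflects the programmed
90% membership reliability.

The same pipeline is scriptable from a shell:

```
ca1ensemble synth --out sessions/ --seed 3 --n-sessions 5 --pattern A
ca1ensemble run --session sessions/session000 --out out/ --seed 3
ca1ensemble cohort --manifest sessions.csv --out out/
```

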