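# Methods

This note documents the models, algorithms and numerical choices behind
`driftbench`: a modular pipeline for estimating and compensating probe drift
in high-density extracellular recordings, together with the ground-truth
simulator and metrics used to benchmark each stage.

## The problem

In chronic and acute electrophysiology with long silicon probes
(Neuropixels-class devices), brain tissue moves relative to the rigid shank.
A neuron that drifts along the probe axis presents different waveforms to
different channels over time, violating the stationarity assumption of spike
sorters. Drift correction estimates the displacement signal from spiking
activity and re-interpolates the traces so that each channel virtually
follows the tissue.

The pipeline is decomposed into exchangeable stages:

1. **peak detection** — negative threshold crossings in robust noise units;
2. **peak localization** — per-spike source positions (center of mass, grid
   convolution, monopolar triangulation);
3. **motion inference** — displacement per 2 s time bin (and per 50 um depth
   window when non-rigid) from the time-resolved depth histogram of peaks
   (iterative template or decentralized registration);
4. **motion interpolation** — trace re-evaluation at drift-corrected
   positions (snap, inverse distance weighting, kriging).

## Coordinate and unit conventions

Positions are `(x, y)` in micrometers; `y` is depth along the shank,
increasing from the probe bottom (`y = 0`) upward, and is the only axis on
which drift acts. Traces are microvolts, float32, time-major
`(n_samples, n_channels)`; sample indexing is 0-based with
`t = frame / sampling_rate`. Positive displacement means the tissue (and
therefore the spike depths) moved toward larger `y`.

## Ground-truth simulator

Units are modelled as **monopolar current sources**: a source of strength
`k` (uV·um) at distance `d` from a channel produces a peak-to-peak amplitude
`k / d`. Each unit carries one biphasic temporal shape (Gaussian trough,
width ~0.15 ms, followed by a positive rebound ~0.3 of the trough at
+0.5 ms; per-unit jitter of these shape parameters is seeded). Because the
same shape is scaled on every channel, per-channel amplitudes obey the
monopole law exactly — a deliberately favorable regime for the monopolar
localizer, and a simplification relative to biophysical simulators whose
templates decay faster in the far field and change shape with distance.

A **template bank** pre-computes each unit's waveforms along a vertical
101-step, 1-um-pitch line centered on its home depth; rendering a spike
looks up the step nearest to the unit's displaced position, so displacement
is quantized at 0.5 um worst case.

Study conditions (generator defaults):

* probe: 4 staggered columns, 18/22 um x/y pitch (Neuropixels-1.0-like);
  128 channels at paper scale, 64 at desk scale;
* sampling rate 32 kHz; uncorrelated Gaussian noise, 5 uV STD;
* firing: Poisson at 5 Hz per unit, optionally sine-modulated (3-min
  period, clipped at 0.5 Hz), with a 2 ms refractory period;
* per-spike amplitude jitter N(1, 0.05);
* unit placement: x uniform over the probe span, depth uniform or bimodal
  (two truncated Gaussians at 1/8 and 7/8 of the span, SD = span/10),
  off-plane distance z uniform on [20, 40] um, strength k **log-uniform**
  on [2000, 12000] uV·um. The long-tailed strength distribution mirrors
  real recordings, where most units sit near the detection threshold; a
  uniform-large choice produces an unrealistic multi-unit background many
  times the thermal noise.

Drift signals (all zero before 60 s):

* *zigzag (rigid)* — triangular oscillation between 0 and 30 um at
  30 um/min, uniform across depth;
* *zigzag (non-rigid)* — the same signal scaled linearly from 1.0 at the
  probe bottom to 0.4 at the top;
* *bumps (non-rigid)* — piecewise-constant displacement levels at event
  times with inter-event intervals uniform on [30, 90] s; each event draws
  a top displacement on [-20, 20] um and a bottom displacement on
  [-40, 40] um, linear in depth between; an optional (default on) 3 um,
  40 Hz sinusoid is added. The sinusoid is far faster than the 2 s
  estimation bins, so no histogram-based method can track it; it acts as a
  small irreducible error floor.

The 3 x 2 x 2 factorial of drift kind, depth distribution and rate profile
gives the twelve benchmark scenarios. Every scenario has a **static twin**:
with the same seed, the drifting and static recordings share spike trains,
amplitude-jitter draws, and the noise array sample for sample, so any
difference is attributable to drift alone.

What the simulator does *not* emulate: correlated or non-Gaussian noise,
electrode-size filtering, x-axis drift, bursting or rate adaptation,
waveform shape changes with distance, electrode drift-induced artifacts.
Passing benchmarks here therefore demonstrate correctness of the pipeline
machinery under monopole assumptions, not performance on real tissue.

## Detection and localization

Noise is estimated per channel as MAD/0.6745 on a seeded 10 s subsample.
A sample is a peak if it is below −10 noise units, is the minimum of its
channel within ±0.2 ms, and no more-negative (in noise units) candidate
exists within 50 um and ±0.2 ms (locally-exclusive rule; ties broken toward
the lower channel id). Waveforms are cut 2 ms around each peak (64 samples
at 32 kHz) on channels within 75 um of the detecting channel; peaks whose
window crosses a recording edge are dropped and counted.

* **Center of mass** — peak-to-peak(ptp)-weighted mean of neighbor channel
  positions; always inside their convex hull.
* **Grid convolution** — a catalog of templates is built by placing the
  prototype waveform `H(t)` (median of 1000 peak-normalized detection-
  channel waveforms) at 5-um grid nodes with Gaussian spatial decays
  (sigma in {10, 20, 30, 40, 50} um). Scalar products between the waveform
  and the catalog are computed; negatives are discarded, only the top 10%
  retained, and the position is the product-weighted mean of node
  positions. The x coordinate is weakly identified on probes whose x span
  is a few tens of um; depth (the drift axis) is the meaningful output.
* **Monopolar triangulation** — nonlinear least squares of
  `ptp(c) = k / dist(c, (x, y, z))`, initialized at the center of mass
  with z = 20 um. The implementation is a batched damped Gauss-Newton over
  `(x, y, log z)` (log keeps z positive) with `k` profiled out in closed
  form at each step (`k* = sum(ptp/d) / sum(1/d^2)`); per-peak Levenberg
  damping grows on rejected steps. Noiseless recovery is well below 1 um;
  with 5% amplitude noise the median depth error is ~1 um. Peaks with
  fewer than four nonzero-ptp channels fall back to the center of mass.

For motion estimation, at most 30 000 peaks are localized (uniform seeded
subsample) — about 200 per 2 s bin at desk scale, far above the ~20 per bin
needed for stable histograms.

## Motion inference

Peaks are binned into a 2 s x 5 um activity histogram (plus 20 equal bins of
log10 |amplitude| between the 1st and 99th percentile for the iterative
method).

**Iterative template** (Kilosort-2.5 style): each temporal bin of the 3-D
histogram is aligned to a target template over integer shifts of up to 15
spatial bins, scoring by the mean elementwise product; the target starts as
the central temporal bin and is iteratively replaced by the mean of the
aligned bins until no shift changes (max 20 rounds). The output is anchored
to the target's frame, i.e. carries an arbitrary constant offset — the
evaluation's median alignment removes it. Non-rigid refinement adds one
non-iterated alignment pass per 50 um depth block; the block is selected by
a Gaussian depth taper rather than a hard crop, because hard cropping lets
mass from neighboring blocks slide into the window and corrupts the argmax.

**Decentralized registration**: normalized cross-correlations between every
pair of temporal bins (optionally only pairs within a 120 s horizon) give
pairwise displacements `D_ij ≈ d_j − d_i` (sub-bin resolution by parabolic
interpolation around the integer argmax) with weights `W_ij` equal to the
correlation at the maximum, floored at 0. The per-bin displacement
minimizes `sum W_ij (d_j − d_i − D_ij)^2` via LSMR; the gauge is fixed by
`median(d) = 0` per connected component. Non-rigid estimation repeats this
on Gaussian-tapered sub-histograms per 50 um window and then re-solves with
a quadratic smoothness penalty (weight 1.0) on adjacent-window differences.
The taper SD is **3x the window step** (150 um), the window-sigma ratio
used by decentralized-registration implementations in this field; a taper
as narrow as half the window starves each window of counts and multiplies
the per-window error several-fold at desk scale.

## Interpolation

Kernels map source channels to target positions (the channel positions
shifted *up* by the estimated motion, so channels follow the tissue), are
recomputed once per 2 s motion bin, and are applied to every sample in the
bin. Kernel matrices have shape `(n_source, n_target)` and are applied as
`traces @ W`; every column sums to 1, so outputs are convex combinations of
source samples.

* *snap* — one-hot nearest source (ties to the lowest channel id);
* *IDW* — inverse-squared-distance weights over the 3 nearest sources; a
  target within 1e-9 um of a source takes that source outright;
* *kriging* — `K = exp(−|dx|/20 − |dy|/30)` (city-block, um);
  `W_raw = (K_xx + 0.01 I)^{-1} K_xy`; entries below 0.001 (including any
  negative ones) are zeroed before column normalization. A column that
  sparsifies to zero falls back to snapping, so the kernel never
  degenerates.

`border_mode="remove_channels"` drops channels within max |motion| of the
probe's y extremes, where interpolation would extrapolate.

## Evaluation

**Motion error**: the estimate is resampled onto the ground-truth grid,
shifted by the global `median(gt − est)` (registration only determines
displacement up to a constant), and the absolute error is reported per
(depth window, time bin) with per-depth, per-time and global means.

**Waveform dispersion**: per unit, ground-truth-timed waveforms on the five
channels with the most negative template amplitude; `sigma` = mean over
samples and channels of the across-spike STD, normalized by the template
RMS; ratios are taken against the static twin with best channels chosen on
the static condition. On raw traces the multi-unit background — identical
in both twins — dominates `sigma` and compresses all ratios toward 1. The
dispersion benchmark therefore applies the standard preprocessing chain
(highpass 150 Hz, common median reference, local whitening in a 150 um
radius) before interpolating, which is also the order in which correction
runs inside sorting pipelines; whitening suppresses the spatially
correlated background, after which ground-truth kriging interpolation
yields mean ratios below 1 (spatial smoothing reduces the uncorrelated
noise) while the uncorrected drifting twin is above 1 for every unit.

**Agreement**: spikes matched one-to-one within ±0.4 ms; agreement
`TP / (N_i + N_j − TP)`; each ground-truth unit greedily takes its best
sorted unit (ties to the lower id). Sorted units are classified
well-detected (best match with accuracy ≥ 0.8, inclusive), overmerged
(> 0.2 agreement with more than one GT unit), redundant (> 0.2 with a GT
unit it is not the best match of) or false positive, in that precedence.
Ground-truth-informed merging unions, per GT unit, all sorted units at
agreement ≥ 0.2 assigned to it, collapsing duplicate spikes within ±0.4 ms.

## Preprocessing

Zero-phase order-3 Butterworth highpass at 150 Hz, applied in overlapping
10 s chunks (0.5 s margins; the transient at 150 Hz decays well inside the
margin). Common median reference subtracts the cross-channel median per
sample. Local whitening estimates each channel's neighborhood (150 um)
covariance on a seeded 10 s subsample with a relative ridge of 1e-6, and
takes the channel's row of the symmetric inverse square root (ZCA), so each
output channel has unit variance against its neighborhood.

## Problem sizes and numerical choices

The desk-scale preset (64 channels, 64 units, 300 s; 120–300 s for
benchmarks that hold several recordings at once) preserves at least ~100
peaks per 2 s histogram row while keeping the full localization x inference
grid and the simulator itself comfortable on a single CPU; the paper-scale
preset (128 channels, 256 units, 600 s) reproduces the source study's
conditions. All randomness flows through `numpy.random.default_rng` seeded
per stream (noise, jitter, placement, spike times, subsamples), so every
recording, peak table and motion estimate is bit-reproducible from the
scenario seed.

Degenerate inputs are handled without crashes: all-zero ptp falls back to
the detecting channel; empty histograms warn and return zeros; zero-variance
histogram rows carry zero weight; disconnected pairwise graphs are solved
per component and flagged; ill-conditioned kriging systems are ridge
regularized; empty non-rigid windows are interpolated from neighbors and
flagged.

## Known limitations

* The monopole far field decays as 1/r — slower than real extracellular
  spikes — so simulated recordings carry a heavier multi-unit background
  than matched real data; metrics computed on raw (unwhitened) traces
  inherit that bias.
* The 40 Hz bump sinusoid is unobservable at the 2 s histogram resolution
  and contributes an irreducible ~1 um error floor to bump scenarios.
* Motion is estimated and corrected along depth only; x/z drift is out of
  scope.
* The iterative-template estimate carries a constant gauge (its target
  anchor); comparisons must be offset-aligned, as the evaluation does.
* Interpolation quality degrades at the probe borders, where only partial
  source information exists; border-channel removal is the mitigation, not
  a fix.
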