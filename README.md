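# driftbench

Modular drift correction and ground-truth benchmarking for high-density
extracellular recordings.

Long silicon probes (Neuropixels-class) record hundreds of channels, but the
brain tissue slowly moves relative to the rigid shank — *drift* — which
distorts spike waveforms over time and degrades spike sorting. `driftbench`
implements the standard drift-correction pipeline as exchangeable stages and
ships a fully controlled simulator of drifting recordings, so every stage
can be benchmarked against known ground truth:

| stage | methods |
|---|---|
| peak detection | locally exclusive negative threshold crossings (10 MAD) |
| peak localization | center of mass · grid convolution · monopolar triangulation |
| motion inference | iterative template (Kilosort-2.5 style) · decentralized (pairwise + LSMR) |
| motion interpolation | snap · inverse distance weighting · kriging |

The core models, briefly. A spike's peak-to-peak amplitude on channel `c` at
position `p_c` is modelled as a monopole, `ptp(c) = k / ||p_c − p||`, and the
source position `p = (x, y, z)` is recovered per peak by nonlinear least
squares (monopolar triangulation). Peak depths are binned into a 2 s × 5 µm
activity histogram `H(t, y)`; the decentralized method estimates pairwise
displacements `D_ij ≈ d_j − d_i` between all time bins by normalized
cross-correlation and solves `min Σ W_ij (d_j − d_i − D_ij)²` for the motion
signal `d(t)` (per 50 µm depth window when non-rigid). Traces are then
re-evaluated at the drift-corrected positions with a kriging kernel
`W = (K_xx + 0.01 I)^{-1} K_xy`, `K = exp(−|Δx|/20 − |Δy|/30)`, columns
normalized to sum to 1.

The simulator renders matched *static twins* — same spikes, same amplitude
jitter, bit-identical noise, zero drift — for the twelve benchmark scenarios
(3 drift signals × 2 depth distributions × 2 firing-rate profiles), so the
error introduced by drift and removed by correction can be measured exactly.

## Worked example

```python
import numpy as np
from driftbench.simulate import ScenarioDescriptor, simulate_scenario
from driftbench.benchmark import estimate_motion_pipeline
from driftbench.motion_estimate import motion_from_drift_field
from driftbench.evaluate import motion_error

# 64-channel, 64-unit, 300 s recording with rigid triangular drift
# (30 um amplitude at 30 um/min, starting at 60 s)
desc = ScenarioDescriptor("zigzag_rigid", "uniform", "homogeneous", seed=0)
pair = simulate_scenario(desc, preset="desk")

# detect peaks, localize them by monopolar triangulation, and infer the
# motion with decentralized registration (2 s x 5 um bins, 50 um windows)
motion = estimate_motion_pipeline(pair.drifting, "monopolar", "decentralized")

gt = motion_from_drift_field(pair.drift, motion.t_centers,
                             motion.window_centers)
err = motion_error(gt, motion)
print(f"windows: {len(motion.window_centers)}, "
      f"time bins: {len(motion.t_centers)}")
print(f"median-aligned mean error: {err.global_mean:.2f} um")
print("error by depth window:", np.round(err.mean_over_time, 2))
```

Output:

```
windows: 7, time bins: 150
median-aligned mean error: 1.03 um
error by depth window: [0.62 0.62 0.62 0.66 0.87 1.56 2.27]
```

The estimated motion tracks the 30 µm triangular drift to about 1 µm — well
below the 22 µm inter-electrode pitch — with the expected degradation toward
the probe border (the last windows), where fewer channels constrain the
localization.

The same pipeline is exposed on the command line:

```bash
driftbench simulate --scenario bumps/uniform/homogeneous --duration 300 \
    --seed 0 --out sim/
driftbench detect sim/drifting --out peaks.csv
driftbench localize sim/drifting peaks.csv --method monopolar --out locs.csv
driftbench estimate-motion sim/drifting --localize monopolar \
    --infer decentralized --out motion.csv
driftbench correct sim/drifting --motion motion.csv --method kriging \
    --out corrected/
driftbench evaluate --gt sim/gt_motion.csv --est motion.csv
```

`driftbench benchmark --config cfg.yaml` runs whole scenario × method grids
and writes a tidy `results.csv` plus a `manifest.json` that records seeds,
versions and per-stage timings.

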