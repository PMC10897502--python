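"""Ground-truth simulator for drifting high-density recordings.

The generator renders a Neuropixels-like probe (4 staggered columns, 18/22 um
x/y pitch) with units modelled as monopolar current sources: the peak-to-peak
amplitude seen by a channel at distance ``d`` from a source of strength ``k``
is ``k / d``. Each unit carries a fixed biphasic temporal waveform (negative
trough followed by a positive rebound) whose shape is identical on every
channel, so per-channel amplitudes follow the monopole law exactly. Drift
moves a unit along the depth (y) axis; a template bank pre-computed on a
101-step, 1-um-pitch vertical line supplies the waveform at the displaced
position. Matched *static twins* share spike trains, amplitude jitter and the
noise realization sample-for-sample with their drifting counterpart.

Study conditions baked into the defaults: drift starts at 60 s; zigzag drift
is triangular with 30 um amplitude at 30 um/min; the non-rigid variant scales
it linearly from 0.4 at the probe top to 1.0 at the bottom; bump events arrive
with inter-event intervals uniform on [30, 90] s, with per-event displacement
linear in depth between a top draw on [-20, 20] um and a bottom draw on
[-40, 40] um, plus an optional 3 um, 40 Hz sinusoid; units fire as Poisson
processes at 5 Hz mean (optionally sine-modulated with a 3-min period, clipped
at 0.5 Hz); noise is uncorrelated Gaussian with 5 uV STD; sampling rate 32 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.stats import truncnorm

from .core import ProbeGeometry, Recording, SortingGT, build_probe

__all__ = [
    "DriftField",
    "TemplateBank",
    "ScenarioDescriptor",
    "generate_drift_signal",
    "sample_unit_depths",
    "generate_spike_trains",
    "place_units",
    "build_templates",
    "render_recording",
    "scenario_grid",
    "simulate_scenario",
    "DESK_PRESET",
    "PAPER_PRESET",
    "DRIFT_KINDS",
    "DEPTH_MODES",
    "RATE_PROFILES",
]

DRIFT_KINDS = ("zigzag_rigid", "zigzag_nonrigid", "bumps")
DEPTH_MODES = ("uniform", "bimodal")
RATE_PROFILES = ("homogeneous", "sine")

DRIFT_START_S = 60.0

# scale presets: desk keeps the full method grid tractable on one CPU while
# preserving >= 20 peaks per 2 s histogram row; paper matches the source study.
DESK_PRESET = dict(n_channels=64, n_columns=4, n_units=64, duration=300.0)
PAPER_PRESET = dict(n_channels=128, n_columns=4, n_units=256, duration=600.0)

_X_PITCH = 18.0
_Y_PITCH = 22.0
_FS = 32000.0


class OptionError(ValueError):
    """Unknown closed-set option (drift kind, depth mode, rate profile)."""


@dataclass
class DriftField:
    """Displacement (um) of the tissue relative to the probe, on a grid.

    ``disp[i, j]`` is the displacement of a source at depth ``depths[i]`` at
    time ``times[j]``; positive values move sources toward larger y (up).
    Evaluation between grid nodes is (bi)linear with constant extrapolation.
    """

    times: np.ndarray       # (n_times,) seconds
    depths: np.ndarray      # (n_depths,) um
    disp: np.ndarray        # (n_depths, n_times) um
    kind: str = "custom"

    def at(self, depth: float, t) -> np.ndarray:
        """Displacement at one depth for an array of times."""
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        rows = self.disp
        if len(self.depths) == 1:
            return np.interp(t, self.times, rows[0])
        d = float(np.clip(depth, self.depths[0], self.depths[-1]))
        j = int(np.searchsorted(self.depths, d, side="right") - 1)
        j = min(j, len(self.depths) - 2)
        w = (d - self.depths[j]) / (self.depths[j + 1] - self.depths[j])
        lo = np.interp(t, self.times, rows[j])
        hi = np.interp(t, self.times, rows[j + 1])
        return (1.0 - w) * lo + w * hi

    def max_abs(self) -> float:
        return float(np.abs(self.disp).max())


def _triangular_zigzag(times: np.ndarray, amplitude: float, speed_um_per_s: float):
    """Triangular oscillation between 0 and ``amplitude``, starting at 60 s."""
    s = np.zeros_like(times)
    active = times >= DRIFT_START_S
    rise = amplitude / speed_um_per_s            # time to reach the peak
    ph = (times[active] - DRIFT_START_S) % (2 * rise)
    s[active] = np.where(ph < rise, speed_um_per_s * ph,
                         amplitude - speed_um_per_s * (ph - rise))
    return s


def generate_drift_signal(
    kind: str,
    duration: float,
    probe_y_extent: float,
    seed: int = 0,
    dt: float | None = None,
    amplitude: float = 30.0,
    speed_um_per_min: float = 30.0,
    nonrigid_top_scale: float = 0.4,
    bump_interval_s: tuple = (30.0, 90.0),
    bump_top_range: tuple = (-20.0, 20.0),
    bump_bottom_range: tuple = (-40.0, 40.0),
    sinusoid: bool = True,
    sinusoid_amplitude_um: float = 3.0,
    sinusoid_freq_hz: float = 40.0,
) -> DriftField:
    """Generate one of the three benchmark drift signals.

    All signals are zero before 60 s. The depth axis convention is y = 0 at
    the probe bottom, y = ``probe_y_extent`` at the top; the non-rigid scaling
    therefore decreases linearly from 1.0 at y = 0 to ``nonrigid_top_scale``
    at the top.
    """
    if kind not in DRIFT_KINDS:
        raise OptionError(f"unknown drift kind '{kind}' (options: {DRIFT_KINDS})")
    if duration <= DRIFT_START_S:
        raise ValueError(f"duration must exceed the {DRIFT_START_S} s drift-free head")
    if dt is None:
        dt = 0.0025 if (kind == "bumps" and sinusoid) else 0.05
    if dt > 0.1:
        raise ValueError("dt must be <= 0.1 s")

    times = np.arange(0.0, duration + dt / 2, dt)
    depths = np.array([0.0, probe_y_extent])
    speed = speed_um_per_min / 60.0

    if kind in ("zigzag_rigid", "zigzag_nonrigid"):
        base = _triangular_zigzag(times, amplitude, speed)
        if kind == "zigzag_rigid":
            disp = np.vstack([base, base])
        else:
            disp = np.vstack([1.0 * base, nonrigid_top_scale * base])
        return DriftField(times, depths, disp, kind)

    # bumps: piecewise-constant displacement levels at random event times
    rng = np.random.default_rng([int(seed), 103])
    event_times = []
    t = DRIFT_START_S
    while True:
        t = t + rng.uniform(*bump_interval_s)
        if t >= duration:
            break
        event_times.append(t)
    bottom = np.zeros_like(times)
    top = np.zeros_like(times)
    for et in event_times:
        b = rng.uniform(*bump_bottom_range)
        a = rng.uniform(*bump_top_range)
        after = times >= et
        bottom[after] = b
        top[after] = a
    if sinusoid:
        wig = sinusoid_amplitude_um * np.sin(2 * np.pi * sinusoid_freq_hz * times)
        wig[times < DRIFT_START_S] = 0.0
        bottom = bottom + wig
        top = top + wig
    return DriftField(times, depths, np.vstack([bottom, top]), "bumps")


def sample_unit_depths(
    n_units: int, mode: str, probe: ProbeGeometry, seed: int = 0
) -> np.ndarray:
    """Draw unit depths along the probe span.

    ``uniform`` draws iid over the probe y span. ``bimodal`` draws from an
    equal-weight mixture of two truncated Gaussians centered at 1/8 and 7/8
    of the span with SD = span/10, leaving a low-density central region.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if mode not in DEPTH_MODES:
        raise OptionError(f"unknown depth mode '{mode}' (options: {DEPTH_MODES})")
    rng = np.random.default_rng([int(seed), 104])
    lo, hi = float(probe.y.min()), float(probe.y.max())
    span = hi - lo
    if mode == "uniform":
        return rng.uniform(lo, hi, size=n_units)
    centers = np.array([lo + span / 8.0, lo + 7.0 * span / 8.0])
    sd = span / 10.0
    comp = rng.integers(0, 2, size=n_units)
    depths = np.empty(n_units)
    for c in (0, 1):
        m = comp == c
        a, b = (lo - centers[c]) / sd, (hi - centers[c]) / sd
        depths[m] = truncnorm.rvs(a, b, loc=centers[c], scale=sd,
                                  size=m.sum(), random_state=rng)
    return depths


def generate_spike_trains(
    n_units: int,
    duration: float,
    profile: str = "homogeneous",
    mean_rate: float = 5.0,
    period: float = 180.0,
    floor: float = 0.5,
    refractory_ms: float = 2.0,
    sampling_rate: float = _FS,
    seed: int = 0,
) -> SortingGT:
    """Poisson spike trains, homogeneous or sine-modulated.

    The sine profile is the inhomogeneous rate
    ``r(t) = max(floor, mean_rate * (1 + sin(2 pi t / period)))`` realized by
    thinning; the floor prevents silent stretches. A ``refractory_ms`` dead
    time is enforced per unit (spikes closer than that to their predecessor
    are removed), as real neurons and biophysical simulators do; at 5 Hz this
    removes about 1% of spikes.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if profile not in RATE_PROFILES:
        raise OptionError(f"unknown rate profile '{profile}' (options: {RATE_PROFILES})")
    if mean_rate <= 0 or floor < 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng([int(seed), 105])
    spikes = {}
    rate_max = max(floor, 2.0 * mean_rate)
    ref = int(round(refractory_ms / 1000.0 * sampling_rate))
    for u in range(n_units):
        if profile == "homogeneous":
            n = rng.poisson(mean_rate * duration)
            t = np.sort(rng.uniform(0.0, duration, size=n))
        else:
            n = rng.poisson(rate_max * duration)
            t = np.sort(rng.uniform(0.0, duration, size=n))
            r = np.maximum(floor, mean_rate * (1.0 + np.sin(2 * np.pi * t / period)))
            t = t[rng.uniform(0.0, rate_max, size=n) < r]
        frames = np.unique((t * sampling_rate).astype(np.int64))
        frames = frames[frames < int(duration * sampling_rate)]
        if ref > 0 and len(frames) > 1:
            keep = np.ones(len(frames), dtype=bool)
            last = frames[0]
            for i in range(1, len(frames)):
                if frames[i] - last < ref:
                    keep[i] = False
                else:
                    last = frames[i]
            frames = frames[keep]
        spikes[u] = frames
    return SortingGT(np.arange(n_units), spikes)


def place_units(
    n_units: int,
    probe: ProbeGeometry,
    depth_mode: str = "uniform",
    z_range: tuple = (20.0, 40.0),
    k_range: tuple = (2000.0, 12000.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Home positions (x, y, z) and monopole strengths k for ``n_units`` units.

    x is uniform over the probe's x span, y follows ``depth_mode``, z (the
    off-plane distance) is uniform, and k is log-uniform over ``k_range`` —
    a long-tailed amplitude distribution, as in real recordings where most
    units sit near the detection threshold and a few are very large. The
    defaults give roughly 50-600 uV peak-to-peak at the closest channel, so
    most units are detectable over 5 uV noise with a 10-MAD threshold.
    """
    rng = np.random.default_rng([int(seed), 106])
    y = sample_unit_depths(n_units, depth_mode, probe, seed=seed)
    x = rng.uniform(probe.x.min(), probe.x.max(), size=n_units)
    z = rng.uniform(*z_range, size=n_units)
    k = np.exp(rng.uniform(np.log(k_range[0]), np.log(k_range[1]),
                           size=n_units))
    return np.column_stack([x, y, z]), k


@dataclass
class TemplateBank:
    """Per-unit templates on a 1-um-pitch vertical drift line.

    ``templates[u]`` has shape (n_steps, n_channels, n_waveform_samples) in
    uV; step ``s`` places the unit at its home depth plus ``s - n_steps // 2``
    um, so the central step is the undisplaced home position.
    """

    templates: np.ndarray    # (n_units, n_steps, n_channels, M) float32
    positions: np.ndarray    # (n_units, 3) home (x, y, z)
    k: np.ndarray            # (n_units,)
    step_um: float = 1.0
    sampling_rate: float = _FS

    @property
    def n_units(self) -> int:
        return self.templates.shape[0]

    @property
    def n_steps(self) -> int:
        return self.templates.shape[1]

    @property
    def center_step(self) -> int:
        return self.n_steps // 2

    @property
    def n_samples(self) -> int:
        return self.templates.shape[3]

    def step_for_displacement(self, disp_um) -> np.ndarray:
        return np.rint(np.asarray(disp_um) / self.step_um).astype(np.int64) + self.center_step


def biphasic_waveform(
    n_samples: int,
    sampling_rate: float,
    trough_sd_ms: float = 0.15,
    rebound_delay_ms: float = 0.5,
    rebound_sd_ms: float = 0.25,
    rebound_amp: float = 0.3,
) -> np.ndarray:
    """Unit biphasic spike shape: Gaussian trough (min = -1) then rebound."""
    t_ms = (np.arange(n_samples) - n_samples // 2) / sampling_rate * 1000.0
    w = -np.exp(-0.5 * (t_ms / trough_sd_ms) ** 2)
    w = w + rebound_amp * np.exp(-0.5 * ((t_ms - rebound_delay_ms) / rebound_sd_ms) ** 2)
    return w / -w.min()


def build_templates(
    units: SortingGT,
    probe: ProbeGeometry,
    waveform_ms: float = 2.0,
    n_steps: int = 101,
    step_um: float = 1.0,
    sampling_rate: float = _FS,
    shape_jitter: float = 0.1,
    seed: int = 0,
) -> TemplateBank:
    """Monopole forward model evaluated on a vertical line of drift steps.

    For unit u with home position (x, y, z) and strength k, the waveform on
    channel c at step s is ``(k / dist(c, (x, y + s - n_steps//2, z))) * h_u``
    where ``h_u`` is the unit's biphasic shape (seeded per-unit jitter of the
    trough width and rebound). Requires z > 0 at every step.
    """
    if units.positions is None or units.k is None:
        raise ValueError("units must carry positions and strengths")
    pos = np.asarray(units.positions, dtype=np.float64)
    if np.any(pos[:, 2] <= 0):
        raise ValueError("singular distance: unit z must be > 0")
    m = int(round(waveform_ms / 1000.0 * sampling_rate))
    rng = np.random.default_rng([int(seed), 107])
    n_units = units.n_units
    offsets = (np.arange(n_steps) - n_steps // 2) * step_um
    templates = np.empty((n_units, n_steps, probe.n_channels, m), dtype=np.float32)
    cx, cy = probe.x, probe.y
    for u in range(n_units):
        xu, yu, zu = pos[u]
        h = biphasic_waveform(
            m, sampling_rate,
            trough_sd_ms=0.15 * (1 + shape_jitter * rng.uniform(-1, 1)),
            rebound_delay_ms=0.5 * (1 + shape_jitter * rng.uniform(-1, 1)),
            rebound_amp=0.3 * (1 + shape_jitter * rng.uniform(-1, 1)),
        ).astype(np.float32)
        dy = cy[None, :] - (yu + offsets[:, None])           # (n_steps, n_ch)
        dist = np.sqrt((cx[None, :] - xu) ** 2 + dy ** 2 + zu ** 2)
        scale = (units.k[u] / dist).astype(np.float32)
        templates[u] = scale[:, :, None] * h[None, None, :]
    return TemplateBank(templates, pos, np.asarray(units.k, dtype=np.float64),
                        step_um, sampling_rate)


def render_recording(
    bank: TemplateBank,
    spikes: SortingGT,
    probe: ProbeGeometry,
    drift: DriftField | None = None,
    duration: float | None = None,
    noise_std: float = 5.0,
    amp_jitter: float = 0.05,
    seed: int = 0,
) -> Recording:
    """Render traces = Gaussian noise + per-spike templates at drifted steps.

    With ``drift=None`` this produces the *static twin*: the same seed yields
    identical spike trains (they are inputs), identical per-spike amplitude
    jitter draws, and an identical noise array sample-for-sample, so the
    drifting and static recordings differ only through template placement.
    """
    fs = bank.sampling_rate
    if duration is None:
        last = max((f[-1] for f in spikes.spikes.values() if len(f)), default=0)
        duration = (last + bank.n_samples) / fs
    n_samples = int(round(duration * fs))
    n_ch = probe.n_channels
    traces = np.empty((n_samples, n_ch), dtype=np.float32)

    noise_rng = np.random.default_rng([int(seed), 101])
    chunk = 1 << 20
    for a in range(0, n_samples, chunk):
        b = min(a + chunk, n_samples)
        block = noise_rng.standard_normal((b - a, n_ch), dtype=np.float32)
        if noise_std != 1.0:
            block *= noise_std
        traces[a:b] = block
    if noise_std == 0.0:
        traces[:] = 0.0

    jit_rng = np.random.default_rng([int(seed), 102])
    m = bank.n_samples
    half = m // 2
    for ui, u in enumerate(spikes.unit_ids):
        frames = spikes.spikes[int(u)]
        amps = 1.0 + amp_jitter * jit_rng.standard_normal(len(frames))
        if len(frames) == 0:
            continue
        if drift is None:
            steps = np.full(len(frames), bank.center_step, dtype=np.int64)
        else:
            d = drift.at(bank.positions[ui, 1], frames / fs)
            steps = bank.step_for_displacement(d)
            bad = (steps < 0) | (steps >= bank.n_steps)
            if np.any(bad):
                t_bad = frames[bad][0] / fs
                raise ValueError(
                    f"displacement at t={t_bad:.2f} s exceeds the template bank "
                    f"range for unit {u}"
                )
        tmpl_u = bank.templates[ui]
        for f, s, a in zip(frames, steps, amps):
            t0, t1 = f - half, f - half + m
            w0 = max(0, -t0)
            w1 = m - max(0, t1 - n_samples)
            if w1 <= w0:
                continue
            traces[t0 + w0:t0 + w1] += np.float32(a) * tmpl_u[s, :, w0:w1].T
    return Recording(traces, fs, probe, provenance="raw")


@dataclass(frozen=True)
class ScenarioDescriptor:
    """One cell of the 3 x 2 x 2 benchmark grid."""

    drift: str
    depth: str
    rate: str
    seed: int = 0

    def __post_init__(self):
        if self.drift not in DRIFT_KINDS:
            raise OptionError(f"unknown drift kind '{self.drift}'")
        if self.depth not in DEPTH_MODES:
            raise OptionError(f"unknown depth mode '{self.depth}'")
        if self.rate not in RATE_PROFILES:
            raise OptionError(f"unknown rate profile '{self.rate}'")

    @property
    def name(self) -> str:
        return f"{self.drift}/{self.depth}/{self.rate}"


def scenario_grid(seeds=(0,)) -> list[ScenarioDescriptor]:
    """Full factorial of drift kind x depth distribution x rate profile.

    ``seeds`` is broadcast over the grid: a single seed applies to every
    scenario, or one seed per scenario (12) may be given.
    """
    combos = list(product(DRIFT_KINDS, DEPTH_MODES, RATE_PROFILES))
    seeds = list(seeds)
    if len(seeds) == 1:
        seeds = seeds * len(combos)
    if len(seeds) != len(combos):
        raise ValueError(f"need 1 or {len(combos)} seeds, got {len(seeds)}")
    return [ScenarioDescriptor(d, p, r, s)
            for (d, p, r), s in zip(combos, seeds)]


@dataclass
class SimulatedPair:
    """A drifting recording, its static twin (optional), and the ground truth."""

    probe: ProbeGeometry
    gt: SortingGT
    drift: DriftField
    drifting: Recording
    static: Recording | None = None
    descriptor: ScenarioDescriptor | None = None
    params: dict = field(default_factory=dict)


def simulate_scenario(
    descriptor: ScenarioDescriptor,
    preset: str | dict = "desk",
    duration: float | None = None,
    make_static: bool = False,
    noise_std: float = 5.0,
    sampling_rate: float = _FS,
    sinusoid: bool = True,
) -> SimulatedPair:
    """Generate a full ground-truth recording for one scenario descriptor."""
    p = dict(DESK_PRESET if preset == "desk" else
             PAPER_PRESET if preset == "paper" else preset)
    if duration is not None:
        p["duration"] = duration
    probe = build_probe(p["n_channels"], p["n_columns"], _X_PITCH, _Y_PITCH,
                        staggered=True, electrode_size=12.0)
    seed = descriptor.seed
    positions, k = place_units(p["n_units"], probe, descriptor.depth, seed=seed)
    gt = generate_spike_trains(p["n_units"], p["duration"], descriptor.rate,
                               sampling_rate=sampling_rate, seed=seed)
    gt.positions, gt.k = positions, k
    bank = build_templates(gt, probe, sampling_rate=sampling_rate, seed=seed)
    drift = generate_drift_signal(descriptor.drift, p["duration"],
                                  probe.y_extent, seed=seed, sinusoid=sinusoid)
    drifting = render_recording(bank, gt, probe, drift=drift,
                                duration=p["duration"], noise_std=noise_std,
                                seed=seed)
    static = None
    if make_static:
        static = render_recording(bank, gt, probe, drift=None,
                                  duration=p["duration"], noise_std=noise_std,
                                  seed=seed)
    return SimulatedPair(probe, gt, drift, drifting, static, descriptor, p)
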