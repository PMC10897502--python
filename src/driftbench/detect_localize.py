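"""Peak detection and the three peak-localization estimators.

Detection finds negative threshold crossings (in MAD-based noise units) that
are local minima on their channel within a +/-0.2 ms sweep, then applies a
spatio-temporal exclusion rule: a peak is suppressed when a more-negative peak
(in noise units) exists within 50 um and the same sweep window.

Localization estimates per-peak source positions from the peak-to-peak (ptp)
amplitudes on the channels around the detecting channel:

* center of mass — ptp-weighted mean of channel positions;
* grid convolution — projection on a catalog of Gaussian-decay templates on a
  fine spatial grid, position = product-weighted mean of grid nodes;
* monopolar triangulation — nonlinear least-squares fit of the monopole law
  ptp(c) = k / dist(c, p), returning (x, y, z, k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d

from .core import Recording

__all__ = [
    "PeakLocations",
    "WaveformSet",
    "PrototypeWaveform",
    "estimate_noise_levels",
    "detect_peaks",
    "select_peaks",
    "extract_waveforms",
    "make_prototype",
    "localize_com",
    "localize_grid",
    "localize_mono",
    "localize_peaks",
    "LOCALIZE_METHODS",
]

LOCALIZE_METHODS = ("com", "grid", "monopolar")

_MAD_TO_STD = 0.6744897501960817  # Phi^-1(0.75): MAD of a Gaussian in STD units


def estimate_noise_levels(
    rec: Recording, subsample_s: float = 10.0, seed: int = 0
) -> np.ndarray:
    """Robust per-channel noise scale: MAD / 0.6745 on a seeded subsample (uV)."""
    rng = np.random.default_rng([int(seed), 301])
    n_sub = min(rec.n_samples, int(subsample_s * rec.sampling_rate))
    idx = np.sort(rng.choice(rec.n_samples, size=n_sub, replace=False))
    sample = rec.get_traces()[idx]
    med = np.median(sample, axis=0)
    return np.median(np.abs(sample - med), axis=0) / _MAD_TO_STD


def detect_peaks(
    rec: Recording,
    threshold: float = 10.0,
    radius_um: float = 50.0,
    sweep_ms: float = 0.2,
    noise_levels: np.ndarray | None = None,
    chunk_s: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Detect negative threshold crossings with spatio-temporal exclusion.

    Returns a frame-sorted table with columns ``frame`` (sample index),
    ``channel`` (channel index) and ``amplitude`` (uV trace value at the
    crossing, negative). ``threshold`` is in per-channel MAD noise units.
    """
    if noise_levels is None:
        noise_levels = estimate_noise_levels(rec, seed=seed)
    noise_levels = np.asarray(noise_levels, dtype=np.float64)
    thr_uv = -threshold * np.maximum(noise_levels, 1e-12)
    sweep = max(1, int(round(sweep_ms / 1000.0 * rec.sampling_rate)))
    pos = rec.geometry.positions
    n_ch = rec.n_channels
    diff = pos[:, None, :] - pos[None, :, :]
    within = np.sqrt((diff ** 2).sum(-1)) <= radius_um

    frames_out, chans_out, amps_out = [], [], []
    step = max(2 * sweep + 2, int(round(chunk_s * rec.sampling_rate)))
    for a in range(0, rec.n_samples, step):
        b = min(a + step, rec.n_samples)
        lo = max(0, a - 2 * sweep)
        hi = min(rec.n_samples, b + 2 * sweep)
        x = rec.get_traces(lo, hi).astype(np.float32, copy=False)
        local_min = minimum_filter1d(x, size=2 * sweep + 1, axis=0,
                                     mode="nearest")
        cand = (x < thr_uv[None, :].astype(np.float32)) & (x <= local_min)
        fr, ch = np.nonzero(cand)
        if len(fr) == 0:
            continue
        order = np.argsort(fr, kind="stable")
        fr, ch = fr[order], ch[order]
        amp_uv = x[fr, ch].astype(np.float64)
        amp_mad = amp_uv / noise_levels[ch]          # negative, in MAD units

        i0 = np.searchsorted(fr, fr - sweep, side="left")
        i1 = np.searchsorted(fr, fr + sweep, side="right")
        counts = i1 - i0
        total = int(counts.sum())
        is_ = np.repeat(np.arange(len(fr)), counts)
        offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        js = np.repeat(i0, counts) + offs
        keep_pair = is_ != js
        is_, js = is_[keep_pair], js[keep_pair]
        stronger = (amp_mad[js] < amp_mad[is_]) | (
            (amp_mad[js] == amp_mad[is_]) & (ch[js] < ch[is_])
        )
        cond = stronger & within[ch[is_], ch[js]]
        suppressed = np.zeros(len(fr), dtype=bool)
        suppressed[is_[cond]] = True

        keep = ~suppressed & (fr + lo >= a) & (fr + lo < b)
        frames_out.append(fr[keep] + lo)
        chans_out.append(ch[keep])
        amps_out.append(amp_uv[keep])

    if frames_out:
        frame = np.concatenate(frames_out)
        channel = np.concatenate(chans_out)
        amplitude = np.concatenate(amps_out)
    else:
        frame = np.empty(0, np.int64)
        channel = np.empty(0, np.int64)
        amplitude = np.empty(0, np.float64)
    df = pd.DataFrame({"frame": frame.astype(np.int64),
                       "channel": channel.astype(np.int64),
                       "amplitude": amplitude})
    return df.sort_values(["frame", "channel"], ignore_index=True)


def select_peaks(peaks: pd.DataFrame, max_n: int, seed: int = 0) -> pd.DataFrame:
    """Uniform random subsample of the peak table (frame-sorted), for speed."""
    if len(peaks) <= max_n:
        return peaks
    rng = np.random.default_rng([int(seed), 302])
    idx = np.sort(rng.choice(len(peaks), size=max_n, replace=False))
    return peaks.iloc[idx].reset_index(drop=True)


@dataclass
class WaveformSet:
    """Waveform blocks cut around detected peaks, grouped by detecting channel.

    ``groups`` maps a detecting channel to ``(row_indices, neighbor_channels,
    data)`` where ``data`` has shape (n_peaks, n_neighbors, n_samples) in uV
    and ``row_indices`` index into ``peaks`` (the kept, frame-sorted table).
    """

    peaks: pd.DataFrame
    groups: dict
    channel_positions: np.ndarray
    sampling_rate: float
    n_dropped_edges: int = 0

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def n_samples(self) -> int:
        for _, _, data in self.groups.values():
            return data.shape[2]
        return 0

    def ptp(self) -> dict:
        """Per-peak per-neighbor peak-to-peak amplitudes, by detecting channel."""
        out = {}
        for det, (rows, neigh, data) in self.groups.items():
            out[det] = data.max(axis=2) - data.min(axis=2)
        return out

    def detection_waveforms(self) -> np.ndarray:
        """(n_peaks, n_samples) waveform of each peak on its detecting channel."""
        out = np.empty((self.n_peaks, self.n_samples), dtype=np.float32)
        for det, (rows, neigh, data) in self.groups.items():
            j = int(np.flatnonzero(neigh == det)[0])
            out[rows] = data[:, j, :]
        return out


def extract_waveforms(
    rec: Recording,
    peaks: pd.DataFrame,
    radius_um: float = 75.0,
    waveform_ms: float = 2.0,
    batch: int = 512,
) -> WaveformSet:
    """Cut per-peak waveform blocks on channels within ``radius_um``.

    The window of ``waveform_ms`` is centered on the peak frame (2 ms at
    32 kHz gives 64 samples). Peaks whose window would cross a recording edge
    are dropped and counted in ``n_dropped_edges``.
    """
    m = int(round(waveform_ms / 1000.0 * rec.sampling_rate))
    half = m // 2
    frames = peaks["frame"].to_numpy()
    ok = (frames - half >= 0) & (frames - half + m <= rec.n_samples)
    n_dropped = int((~ok).sum())
    kept = peaks.loc[ok].reset_index(drop=True)
    pos = rec.geometry.positions
    window = np.arange(m) - half

    groups = {}
    chans = kept["channel"].to_numpy()
    kept_frames = kept["frame"].to_numpy()
    traces = rec.get_traces()
    for det in np.unique(chans):
        rows = np.flatnonzero(chans == det)
        d = np.linalg.norm(pos - pos[det], axis=1)
        neigh = np.flatnonzero(d <= radius_um)
        data = np.empty((len(rows), len(neigh), m), dtype=np.float32)
        for a in range(0, len(rows), batch):
            b = min(a + batch, len(rows))
            idx = kept_frames[rows[a:b], None] + window[None, :]
            data[a:b] = traces[idx[:, :, None],
                               neigh[None, None, :]].transpose(0, 2, 1)
        groups[int(det)] = (rows, neigh, data)
    return WaveformSet(kept, groups, pos, rec.sampling_rate, n_dropped)


@dataclass
class PrototypeWaveform:
    """Typical single-channel spike shape H(t), peak-normalized (trough = -1)."""

    h: np.ndarray
    n_used: int = 0


def make_prototype(
    wfs: WaveformSet, n: int = 1000, seed: int = 0
) -> PrototypeWaveform:
    """Median over ``n`` peak-normalized single-channel waveforms."""
    if wfs.n_peaks == 0:
        raise ValueError("cannot build a prototype from zero peaks")
    if wfs.n_peaks < n:
        warnings.warn(f"only {wfs.n_peaks} peaks available (< {n}); using all")
        n = wfs.n_peaks
    rng = np.random.default_rng([int(seed), 303])
    idx = rng.choice(wfs.n_peaks, size=n, replace=False)
    w = wfs.detection_waveforms()[idx].astype(np.float64)
    scale = -w.min(axis=1, keepdims=True)
    scale[scale <= 0] = 1.0
    h = np.median(w / scale, axis=0)
    h = h / max(-h.min(), 1e-12)
    return PrototypeWaveform(h, n_used=n)


@dataclass
class PeakLocations:
    """Per-peak estimated source positions, aligned with a peak table."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray | None = None
    k: np.ndarray | None = None
    method: str = ""
    flags: np.ndarray | None = None   # True where a fallback was applied
    peaks: pd.DataFrame | None = None  # the (kept) peak table these align with

    def __len__(self):
        return len(self.x)

    def to_dataframe(self) -> pd.DataFrame:
        d = {"x": self.x, "y": self.y}
        if self.z is not None:
            d["z"] = self.z
        if self.k is not None:
            d["k"] = self.k
        df = pd.DataFrame(d)
        df.attrs["method"] = self.method
        return df


def localize_com(wfs: WaveformSet) -> PeakLocations:
    """Center of mass: ptp-weighted mean of neighbor channel positions."""
    n = wfs.n_peaks
    x = np.empty(n)
    y = np.empty(n)
    flags = np.zeros(n, dtype=bool)
    pos = wfs.channel_positions
    for det, (rows, neigh, data) in wfs.groups.items():
        ptp = (data.max(axis=2) - data.min(axis=2)).astype(np.float64)
        tot = ptp.sum(axis=1)
        bad = tot <= 0
        tot[bad] = 1.0
        x[rows] = ptp @ pos[neigh, 0] / tot
        y[rows] = ptp @ pos[neigh, 1] / tot
        x[rows[bad]] = pos[det, 0]
        y[rows[bad]] = pos[det, 1]
        flags[rows[bad]] = True
    return PeakLocations(x, y, method="com", flags=flags)


def localize_grid(
    wfs: WaveformSet,
    prototype: PrototypeWaveform,
    sigmas_um=(10.0, 20.0, 30.0, 40.0, 50.0),
    grid_pitch_um: float = 5.0,
    top_fraction: float = 0.10,
    node_margin_um: float = 30.0,
    node_radius_um: float = 100.0,
) -> PeakLocations:
    """Grid convolution: project waveforms on a catalog of decayed prototypes.

    Catalog templates are the prototype ``H(t)`` placed at grid nodes with a
    Gaussian spatial decay of width sigma (one template per node x sigma).
    Scalar products of the waveform with the catalog are computed, negative
    products are discarded, only the top ``top_fraction`` is retained, and the
    position is the product-weighted mean of node positions. If every product
    is non-positive the center of mass is used and the peak is flagged.
    """
    pos = wfs.channel_positions
    h = prototype.h.astype(np.float64)
    xs = np.arange(pos[:, 0].min() - node_margin_um,
                   pos[:, 0].max() + node_margin_um + grid_pitch_um / 2,
                   grid_pitch_um)
    ys = np.arange(pos[:, 1].min() - node_margin_um,
                   pos[:, 1].max() + node_margin_um + grid_pitch_um / 2,
                   grid_pitch_um)
    nodes = np.column_stack([g.ravel() for g in np.meshgrid(xs, ys)])

    com = localize_com(wfs)
    n = wfs.n_peaks
    x = np.empty(n)
    y = np.empty(n)
    flags = np.zeros(n, dtype=bool)
    for det, (rows, neigh, data) in wfs.groups.items():
        nd = np.linalg.norm(nodes - pos[det], axis=1)
        sub = nodes[nd <= node_radius_um]
        d2 = ((sub[:, None, :] - pos[neigh][None, :, :]) ** 2).sum(-1)
        decay = np.concatenate(
            [np.exp(-d2 / (2.0 * s ** 2)) for s in sigmas_um], axis=0
        )                                            # (n_nodes*n_sigma, n_neigh)
        node_xy = np.tile(sub, (len(sigmas_um), 1))
        a = np.tensordot(data.astype(np.float64), h, axes=([2], [0]))
        prods = a @ decay.T                          # (n_peaks_g, n_templates)
        np.maximum(prods, 0.0, out=prods)
        thr = np.quantile(prods, 1.0 - top_fraction, axis=1, keepdims=True)
        w = np.where(prods >= thr, prods, 0.0)
        tot = w.sum(axis=1)
        ok = tot > 0
        x[rows[ok]] = (w[ok] @ node_xy[:, 0]) / tot[ok]
        y[rows[ok]] = (w[ok] @ node_xy[:, 1]) / tot[ok]
        x[rows[~ok]] = com.x[rows[~ok]]
        y[rows[~ok]] = com.y[rows[~ok]]
        flags[rows[~ok]] = True
    return PeakLocations(x, y, method="grid", flags=flags)


def _fit_monopole_batch(
    ptp: np.ndarray,
    cx: np.ndarray,
    cy: np.ndarray,
    x0: np.ndarray,
    y0: np.ndarray,
    init_z_um: float = 20.0,
    max_iter: int = 60,
    step_tol: float = 1e-4,
):
    """Batched damped Gauss-Newton fit of ptp(c) = k / dist(c, (x, y, z)).

    Positions are optimized over (x, y, log z) — the log parameterization
    keeps z strictly positive — while the linear parameter k is profiled out
    in closed form at every step (for fixed position the optimal strength is
    ``sum(ptp/d) / sum(1/d^2)``). A per-peak Levenberg damping factor grows
    on rejected steps and shrinks on accepted ones.
    """
    n = ptp.shape[0]
    theta = np.column_stack([x0, y0, np.full(n, np.log(init_z_um))])
    lam = np.full(n, 1e-3)

    def model(th):
        dx = cx[None, :] - th[:, 0:1]
        dy = cy[None, :] - th[:, 1:2]
        z = np.exp(th[:, 2:3])
        d = np.sqrt(dx * dx + dy * dy + z * z)
        k = (ptp / d).sum(1) / (1.0 / (d * d)).sum(1)
        np.maximum(k, 0.0, out=k)
        return d, z, k

    d, z, k = model(theta)
    r = ptp - k[:, None] / d
    cost = (r * r).sum(1)
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        inv_d3 = 1.0 / (d * d * d)
        kx = k[:, None]
        jx = -kx * (cx[None, :] - theta[:, 0:1]) * inv_d3
        jy = -kx * (cy[None, :] - theta[:, 1:2]) * inv_d3
        ju = kx * (z * z) * inv_d3
        j = np.stack([jx, jy, ju], axis=2)             # (n, C, 3)
        a = np.einsum("ncp,ncq->npq", j, j)
        g = np.einsum("ncp,nc->np", j, r)
        a[:, np.arange(3), np.arange(3)] *= 1.0 + lam[:, None]
        try:
            delta = -np.linalg.solve(a, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            a[:, np.arange(3), np.arange(3)] += 1e-8
            delta = -np.linalg.solve(a, g[..., None])[..., 0]
        trial = theta + delta
        trial[:, 2] = np.clip(trial[:, 2], np.log(1e-1), np.log(1e3))
        d_t, z_t, k_t = model(trial)
        r_t = ptp - k_t[:, None] / d_t
        cost_t = (r_t * r_t).sum(1)
        accept = cost_t <= cost
        theta[accept] = trial[accept]
        cost[accept] = cost_t[accept]
        lam[accept] = np.maximum(lam[accept] / 3.0, 1e-8)
        lam[~accept] = np.minimum(lam[~accept] * 10.0, 1e8)
        d, z, k = model(theta)
        r = ptp - k[:, None] / d
        converged |= accept & (np.abs(delta).max(1) < step_tol)
        if converged.all():
            break
    return theta[:, 0], theta[:, 1], np.exp(theta[:, 2]), k, converged


def localize_mono(
    wfs: WaveformSet,
    init_z_um: float = 20.0,
    max_iter: int = 60,
) -> PeakLocations:
    """Monopolar triangulation: fit ptp(c) = k / dist(c, (x, y, z)) per peak.

    The fit is initialized at the center of mass with z = 20 um; z stays
    positive through a log parameterization and the source strength k is
    profiled out in closed form. Peaks with fewer than 4 nonzero-ptp channels
    fall back to the center of mass (z, k set to NaN) and are flagged, as are
    fits that did not reach the step tolerance (best iterate returned).
    """
    pos = wfs.channel_positions
    n = wfs.n_peaks
    out_x = np.empty(n)
    out_y = np.empty(n)
    out_z = np.full(n, np.nan)
    out_k = np.full(n, np.nan)
    flags = np.zeros(n, dtype=bool)
    com = localize_com(wfs)
    for det, (rows, neigh, data) in wfs.groups.items():
        ptps = (data.max(axis=2) - data.min(axis=2)).astype(np.float64)
        usable = (ptps > 0).sum(1) >= 4
        bad_rows = rows[~usable]
        out_x[bad_rows] = com.x[bad_rows]
        out_y[bad_rows] = com.y[bad_rows]
        flags[bad_rows] = True
        if not np.any(usable):
            continue
        rr = rows[usable]
        x, y, z, k, conv = _fit_monopole_batch(
            ptps[usable], pos[neigh, 0], pos[neigh, 1],
            com.x[rr], com.y[rr], init_z_um=init_z_um, max_iter=max_iter,
        )
        out_x[rr], out_y[rr], out_z[rr], out_k[rr] = x, y, z, k
        flags[rr] |= ~conv
    return PeakLocations(out_x, out_y, out_z, out_k, method="monopolar",
                         flags=flags)


def localize_peaks(
    rec: Recording,
    peaks: pd.DataFrame,
    method: str = "monopolar",
    radius_um: float = 75.0,
    waveform_ms: float = 2.0,
    seed: int = 0,
) -> PeakLocations:
    """Convenience wrapper: extract waveforms then localize with ``method``."""
    if method not in LOCALIZE_METHODS:
        raise ValueError(f"unknown localization method '{method}' "
                         f"(options: {LOCALIZE_METHODS})")
    wfs = extract_waveforms(rec, peaks, radius_um, waveform_ms)
    if method == "com":
        loc = localize_com(wfs)
    elif method == "grid":
        proto = make_prototype(wfs, seed=seed)
        loc = localize_grid(wfs, proto)
    else:
        loc = localize_mono(wfs)
    loc.peaks = wfs.peaks
    return loc
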